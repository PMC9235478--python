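"""End-to-end orchestration: files in, result table and artifacts out."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .polar import to_polar
from .significance import two_stage_select
from .sumstats import harmonize_and_merge, read_sumstats, write_panel_tsv
from .vonmises import DEFAULT_TOL, KappaCurve, builtin_curve
from .whitening import estimate_null_covariance, zca_cor_whiten

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    sumstats: list  # file paths, one per trait
    trait_names: list | None = None
    column_map: dict | None = None
    delimiter: str | None = None
    drop_ambiguous: bool = False
    whiten: bool = True
    mahalanobis_threshold: float = 5.0
    r_q_threshold: float = 0.05
    theta_q_threshold: float = 0.05
    qvalue_method: str = "storey"
    tol: float = DEFAULT_TOL
    kappa_curve: str = "builtin"  # or a path to a calibration table
    seed: int = 0
    out_prefix: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.sumstats) < 2:
            raise ValueError("need summary statistics for at least two traits")
        for thr in (self.r_q_threshold, self.theta_q_threshold):
            if not (0.0 < thr < 1.0):
                raise ValueError("q-value thresholds must lie in (0, 1)")
        if not (0.0 < self.tol <= 1e-4):
            raise ValueError("tol must lie in (0, 1e-4]")


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute read -> harmonize -> whiten -> polar -> test -> select.

    Returns the per-SNP result table; when ``config.out_prefix`` is set,
    also writes <prefix>.results.tsv, <prefix>.panel.tsv,
    <prefix>.whitening.json and a <prefix>.manifest.json with row counts
    at every stage.
    """
    counts = {}
    scans = []
    for i, path in enumerate(config.sumstats):
        name = (
            config.trait_names[i]
            if config.trait_names and i < len(config.trait_names)
            else None
        )
        scan = read_sumstats(
            path,
            column_map=config.column_map,
            trait_name=name,
            delimiter=config.delimiter,
        )
        counts[f"read:{scan.trait_name}"] = len(scan)
        scans.append(scan)

    panel = harmonize_and_merge(scans, drop_ambiguous=config.drop_ambiguous)
    counts["merged"] = panel.m
    smallest = min(counts[k] for k in counts if k.startswith("read:"))
    if panel.m < 0.5 * smallest:
        logger.warning(
            "harmonization kept %d of %d variants (>50%% dropped)",
            panel.m,
            smallest,
        )

    model = None
    if config.whiten:
        model = estimate_null_covariance(
            panel, threshold=config.mahalanobis_threshold
        )
        counts["null_covariance_snps"] = model.n_null
        panel = zca_cor_whiten(panel, model)

    polar = to_polar(panel)
    if config.kappa_curve == "builtin":
        curve = builtin_curve(polar.p)
    else:
        curve = KappaCurve.read_tsv(config.kappa_curve)
    results = two_stage_select(
        polar,
        curve,
        r_q_threshold=config.r_q_threshold,
        theta_q_threshold=config.theta_q_threshold,
        tol=config.tol,
        qvalue_method=config.qvalue_method,
    )
    # prepend z columns for audit
    for j, name in enumerate(panel.trait_names):
        results.insert(
            min(6, results.shape[1]), f"z_{name}", panel.Z[:, j]
        )
    counts["stage1_survivors"] = int(results["r_significant"].sum())
    counts["shared"] = int(results["shared_flag"].sum())

    if config.out_prefix:
        prefix = config.out_prefix
        results.to_csv(f"{prefix}.results.tsv", sep="\t", index=False)
        write_panel_tsv(panel, f"{prefix}.panel.tsv")
        if model is not None:
            model.to_json(f"{prefix}.whitening.json")
        manifest = {
            "version": __version__,
            "config": {
                k: v
                for k, v in vars(config).items()
                if k != "extra" and not callable(v)
            },
            "row_counts": counts,
        }
        with open(f"{prefix}.manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    logger.info("pipeline finished: %s", counts)
    return results
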