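"""Synthetic multi-trait z-score panels with known ground truth.

The generator emulates, at the z-score level, a multi-trait GWAS in
which ~10% of SNPs are specific to each trait, ~10% are horizontally
pleiotropic and the rest are null, while the per-SNP z-scores of
different traits share a correlated noise component (default rho = 0.8)
as produced by sample overlap and phenotypic correlation.  Each SNP's
z-vector is its true effect vector plus equicorrelated unit-variance
Gaussian noise.  No linkage disequilibrium is simulated: SNPs are
independent, which is the generator's main departure from real panels.

The default effect magnitude follows the GWAS regime the false-positive
experiments emulate: a per-trait heritability h2 spread over all of the
trait's causal SNPs at sample size n gives a per-SNP z noncentrality of
sqrt(n * h2 / M_causal) (defaults n = 549, h2 = 0.6), which at desk
scale is well below 1 -- individual causal SNPs are barely
distinguishable from null, exactly as in a small-cohort polygenic GWAS.
Power experiments use a fixed large magnitude instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .polar import to_polar
from .significance import chi_sf
from .sumstats import MultiTraitZPanel
from .vonmises import KappaCurve, builtin_curve, theta_pvalues
from .whitening import estimate_null_covariance, zca_cor_whiten

__all__ = [
    "EffectSpec",
    "SimDesign",
    "SimTruth",
    "simulate_panel",
    "simulate_null_permuted",
    "fpr_experiment",
    "FprSummary",
    "write_sumstat_files",
]


@dataclass(frozen=True)
class EffectSpec:
    """Distribution of true effect magnitudes on the z scale.

    family:
      - "heritability": constant magnitude sqrt(n_individuals * h2 /
        M_causal), where M_causal is the number of SNPs affecting a trait
        under the design (derived at draw time).
      - "fixed": constant ``magnitude``.
      - "halfnormal": |N(0, magnitude^2)|.
    """

    family: str = "heritability"
    magnitude: float = 6.0
    n_individuals: int = 549
    h2: float = 0.6

    def magnitudes(self, size: int, m_causal_per_trait: int, rng) -> np.ndarray:
        if size == 0:
            return np.empty(0)
        if self.family == "heritability":
            if m_causal_per_trait < 1:
                raise ValueError("no causal SNPs under this design")
            mag = np.sqrt(self.n_individuals * self.h2 / m_causal_per_trait)
            return np.full(size, mag)
        if self.family == "fixed":
            return np.full(size, float(self.magnitude))
        if self.family == "halfnormal":
            return np.abs(rng.normal(0.0, self.magnitude, size=size))
        raise ValueError(f"unknown effect family '{self.family}'")


@dataclass(frozen=True)
class SimDesign:
    """Design of one simulated multi-trait panel.

    Fractions are per class: each trait gets ``frac_specific_per_trait``
    of SNPs specific to it, ``frac_pleiotropic`` of SNPs affect all
    traits, and the remainder is null.
    """

    m_total: int = 50_000
    p: int = 2
    frac_specific_per_trait: float = 0.10
    frac_pleiotropic: float = 0.10
    rho: float = 0.8
    effect_dist: EffectSpec = field(default_factory=EffectSpec)
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.m_total < 1000:
            raise ValueError("m_total must be >= 1000")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")
        total = self.p * self.frac_specific_per_trait + self.frac_pleiotropic
        if total >= 1.0:
            raise ValueError("class fractions must sum to < 1")

    @property
    def n_specific_per_trait(self) -> int:
        return int(round(self.m_total * self.frac_specific_per_trait))

    @property
    def n_pleiotropic(self) -> int:
        return int(round(self.m_total * self.frac_pleiotropic))

    @property
    def m_causal_per_trait(self) -> int:
        return self.n_specific_per_trait + self.n_pleiotropic


@dataclass
class SimTruth:
    """Ground-truth class labels and effect vectors for a simulated panel."""

    labels: np.ndarray  # "null", "specific", "pleiotropic"
    specific_trait: np.ndarray  # trait index for specific SNPs, -1 otherwise
    effects: np.ndarray  # m x p true effect vectors

    def is_specific(self) -> np.ndarray:
        return self.labels == "specific"

    def is_pleiotropic(self) -> np.ndarray:
        return self.labels == "pleiotropic"

    def is_null(self) -> np.ndarray:
        return self.labels == "null"


def _rng_for(design: SimDesign, replicate: int, stream: str) -> np.random.Generator:
    # named substreams keyed on (seed, replicate) for reproducibility
    tag = sum(ord(ch) for ch in stream)
    return np.random.default_rng(
        np.random.SeedSequence([design.seed, replicate, tag])
    )


def _equicorr_noise(rng, m: int, p: int, rho: float) -> np.ndarray:
    cov = np.full((p, p), rho)
    np.fill_diagonal(cov, 1.0)
    L = np.linalg.cholesky(cov)
    return rng.standard_normal((m, p)) @ L.T


def _variant_frame(m: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1, dtype=np.int64) * 1000,
            "ea": "A",
            "oa": "G",
            "ambiguous": False,
        }
    )


def simulate_panel(
    design: SimDesign, replicate: int = 0
) -> tuple[MultiTraitZPanel, SimTruth]:
    """Simulate one replicate of the three-class design.

    Specific SNPs have a single nonzero effect entry with random sign;
    pleiotropic SNPs have all entries nonzero with one magnitude per SNP
    and independent signs.  Noise is equicorrelated with correlation
    rho.  Deterministic given (design.seed, replicate).
    """
    m, p = design.m_total, design.p
    rng = _rng_for(design, replicate, "panel")

    effects = np.zeros((m, p))
    labels = np.full(m, "null", dtype=object)
    specific_trait = np.full(m, -1, dtype=int)

    cursor = 0
    n_spec = design.n_specific_per_trait
    for j in range(p):
        idx = slice(cursor, cursor + n_spec)
        mag = design.effect_dist.magnitudes(n_spec, design.m_causal_per_trait, rng)
        effects[idx, j] = mag * rng.choice([-1.0, 1.0], size=n_spec)
        labels[idx] = "specific"
        specific_trait[idx] = j
        cursor += n_spec
    n_pleio = design.n_pleiotropic
    idx = slice(cursor, cursor + n_pleio)
    mag = design.effect_dist.magnitudes(n_pleio, design.m_causal_per_trait, rng)
    effects[idx, :] = mag[:, None] * rng.choice([-1.0, 1.0], size=(n_pleio, p))
    labels[idx] = "pleiotropic"

    Z = effects + _equicorr_noise(rng, m, p, design.rho)
    panel = MultiTraitZPanel(
        variants=_variant_frame(m),
        trait_names=[f"trait{j + 1}" for j in range(p)],
        Z=Z,
    )
    truth = SimTruth(
        labels=np.asarray(labels, dtype=object),
        specific_trait=specific_trait,
        effects=effects,
    )
    return panel, truth


def simulate_null_permuted(design: SimDesign, replicate: int = 0) -> MultiTraitZPanel:
    """Panel with every SNP null but the inter-trait correlation retained.

    The z-score-level analog of permuting phenotypes as pairs: genotype-
    phenotype association is destroyed while the correlation between the
    traits' z-scores survives.
    """
    m, p = design.m_total, design.p
    rng = _rng_for(design, replicate, "permuted")
    panel = MultiTraitZPanel(
        variants=_variant_frame(m),
        trait_names=[f"trait{j + 1}" for j in range(p)],
        Z=_equicorr_noise(rng, m, p, design.rho),
    )
    return panel


@dataclass
class FprSummary:
    """Mean and SD across replicates of an empirical false positive rate."""

    mode: str
    mean: float
    sd: float
    per_replicate: np.ndarray
    n_replicates: int
    m_total: int


def fpr_experiment(
    design: SimDesign,
    mode: str,
    curve: KappaCurve | None = None,
    alpha: float = 0.05,
    mahalanobis_threshold: float = 5.0,
) -> FprSummary:
    """Empirical false-positive-rate experiment across replicates.

    mode="permuted": fraction of all SNPs with p_r < alpha on fully null
    panels (after covariance estimation and whitening).

    mode="specific": fraction of ground-truth trait-specific SNPs with
    p_theta < alpha on three-class panels run through the full pipeline
    (whitening, polar transform, kappa lookup, angle test) -- these are
    the SNPs that would falsely be called pleiotropic.
    """
    if mode not in ("permuted", "specific"):
        raise ValueError("mode must be 'permuted' or 'specific'")
    if design.n_replicates < 1:
        raise ValueError("need at least one replicate")
    if mode == "specific" and curve is None:
        curve = builtin_curve(design.p)

    rates = np.empty(design.n_replicates)
    for rep in range(design.n_replicates):
        if mode == "permuted":
            panel = simulate_null_permuted(design, rep)
            truth = None
        else:
            panel, truth = simulate_panel(design, rep)
        model = estimate_null_covariance(panel, threshold=mahalanobis_threshold)
        white = zca_cor_whiten(panel, model)
        polar = to_polar(white)
        if mode == "permuted":
            p_r = chi_sf(polar.r, design.p)
            rates[rep] = float(np.mean(p_r < alpha))
        else:
            p_t = theta_pvalues(polar, curve)
            sel = truth.is_specific()
            rates[rep] = float(np.mean(p_t[sel] < alpha))
    return FprSummary(
        mode=mode,
        mean=float(np.mean(rates)),
        sd=float(np.std(rates, ddof=1)) if design.n_replicates > 1 else 0.0,
        per_replicate=rates,
        n_replicates=design.n_replicates,
        m_total=design.m_total,
    )


def write_sumstat_files(panel: MultiTraitZPanel, truth: SimTruth | None, prefix):
    """Write per-trait summary-stat TSVs (beta = z, se = 1) plus truth.

    Lets the full file-based pipeline be exercised end to end on
    simulated data.  Returns the list of per-trait paths.
    """
    paths = []
    for j, name in enumerate(panel.trait_names):
        df = panel.variants[["id", "chrom", "pos", "ea", "oa"]].copy()
        df.columns = ["snp", "chr", "pos", "ea", "oa"]
        df["beta"] = panel.Z[:, j]
        df["se"] = 1.0
        path = f"{prefix}.{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))
        paths.append(path)
    if truth is not None:
        tdf = pd.DataFrame(
            {
                "id": panel.variants["id"],
                "label": truth.labels,
                "specific_trait": truth.specific_trait,
            }
        )
        for j, name in enumerate(panel.trait_names):
            tdf[f"effect_{name}"] = truth.effects[:, j]
        tdf.to_csv(f"{prefix}.truth.tsv", sep="\t", index=False)
    return paths
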