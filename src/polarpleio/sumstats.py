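"""Reading GWAS summary statistics and cross-trait allele harmonization.

Each trait arrives as a delimited text table with per-variant effect size
(beta), standard error (SE) and alleles; z = beta/SE.  Before any joint
analysis the effect alleles must agree across traits: a variant reported
on swapped alleles in a later trait has its z sign flipped, strand flips
are resolved by reverse complementing when a direct or swapped match
fails, and variants whose alleles cannot be reconciled are dropped.
Palindromic (A/T, C/G) variants are retained but flagged, since their
strand cannot be determined from the alleles alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "TraitScan",
    "MultiTraitZPanel",
    "read_sumstats",
    "harmonize_and_merge",
    "write_panel_tsv",
    "read_panel_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_COLUMN_MAP = {
    "id": "snp",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "beta": "beta",
    "se": "se",
    "z": "z",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class TraitScan:
    """Per-trait summary statistics with computed z-scores."""

    trait_name: str
    df: pd.DataFrame  # columns: id, chrom, pos, ea, oa, z (beta/se optional)
    n_dropped: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MultiTraitZPanel:
    """Aligned m x p matrix of per-SNP, per-trait z-scores.

    Every row's alleles are expressed on the first trait's orientation.
    ``variants`` holds id/chrom/pos/ea/oa plus an ``ambiguous`` flag for
    palindromic variants.
    """

    variants: pd.DataFrame
    trait_names: list
    Z: np.ndarray

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape != (len(self.variants), len(self.trait_names)):
            raise ValueError("Z shape inconsistent with variants/trait_names")

    @property
    def m(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait_name: str | None = None,
    delimiter: str | None = None,
) -> TraitScan:
    """Read one trait's summary statistics from delimited text.

    ``column_map`` maps canonical field names (id, chrom, pos,
    effect_allele, other_allele, beta, se, z) to the file's column names;
    unmapped fields fall back to the defaults.  z is computed as beta/se
    when absent.  Rows with se <= 0, missing alleles or non-finite values
    are dropped and counted in ``TraitScan.n_dropped``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(
        path,
        sep=delimiter if delimiter else r"\s+",
        float_precision="round_trip",
    )

    required = ["id", "chrom", "pos", "effect_allele", "other_allele"]
    for key in required:
        if cmap[key] not in df.columns:
            raise ValueError(f"missing mapped column '{cmap[key]}' (field {key})")
    has_z = cmap["z"] in df.columns
    has_beta = cmap["beta"] in df.columns and cmap["se"] in df.columns
    if not has_z and not has_beta:
        raise ValueError(
            f"need either a z column ('{cmap['z']}') or beta+se columns "
            f"('{cmap['beta']}', '{cmap['se']}')"
        )

    out = pd.DataFrame(
        {
            "id": df[cmap["id"]].astype(str),
            "chrom": df[cmap["chrom"]].astype(str),
            "pos": pd.to_numeric(df[cmap["pos"]], errors="coerce"),
            "ea": df[cmap["effect_allele"]].astype(str).str.upper(),
            "oa": df[cmap["other_allele"]].astype(str).str.upper(),
        }
    )
    dropped = {}
    if has_z and not has_beta:
        out["z"] = pd.to_numeric(df[cmap["z"]], errors="coerce")
    elif has_z:
        # z column wins when both are present (passthrough contract)
        out["z"] = pd.to_numeric(df[cmap["z"]], errors="coerce")
        out["beta"] = pd.to_numeric(df[cmap["beta"]], errors="coerce")
        out["se"] = pd.to_numeric(df[cmap["se"]], errors="coerce")
    else:
        beta = pd.to_numeric(df[cmap["beta"]], errors="coerce")
        se = pd.to_numeric(df[cmap["se"]], errors="coerce")
        bad_se = se <= 0
        dropped["se_nonpositive"] = int(bad_se.fillna(False).sum())
        se = se.where(~bad_se)
        out["beta"] = beta
        out["se"] = se
        out["z"] = beta / se

    ok = (
        out["z"].notna()
        & np.isfinite(out["z"])
        & out["pos"].notna()
        & (out["pos"] >= 1)
        & (out["ea"] != "")
        & (out["oa"] != "")
        & (out["ea"].str.upper() != "NAN")
        & (out["oa"].str.upper() != "NAN")
        & (out["ea"] != out["oa"])
    )
    dropped["unparseable"] = int((~ok).sum()) - dropped.get("se_nonpositive", 0)
    out = out[ok].copy()
    out["pos"] = out["pos"].astype(np.int64)

    dup = out["id"].duplicated()
    if dup.any():
        logger.warning(
            "%s: %d duplicated variant ids, keeping first occurrence",
            trait_name or path,
            int(dup.sum()),
        )
        dropped["duplicate_id"] = int(dup.sum())
        out = out[~dup]

    if len(out) == 0:
        raise ValueError(f"no parseable rows in {path}")
    for key, n in dropped.items():
        if n:
            logger.info("%s: dropped %d rows (%s)", trait_name or path, n, key)
    name = trait_name if trait_name is not None else str(path)
    return TraitScan(trait_name=name, df=out.reset_index(drop=True), n_dropped=dropped)


def _revcomp(allele: str) -> str:
    return allele.translate(_COMPLEMENT)[::-1]


def _is_palindromic(ea: str, oa: str) -> bool:
    return _revcomp(ea) == oa if set(ea + oa) <= set("ACGT") else False


def harmonize_and_merge(
    scans: list,
    drop_ambiguous: bool = False,
) -> MultiTraitZPanel:
    """Align alleles across scans and assemble the joint z-score panel.

    Only variants present in every scan are kept.  For each variant and
    each later trait: a direct allele match keeps the z sign, a swapped
    match flips it; failing both, the reverse complement is tried the
    same way (never for palindromic pairs); otherwise the variant is
    dropped.  Palindromic variants are flagged ``ambiguous`` and dropped
    only when ``drop_ambiguous`` is set.
    """
    if len(scans) < 2:
        raise ValueError("need at least two trait scans")
    names = [s.trait_name for s in scans]
    if len(set(names)) != len(names):
        raise ValueError("trait names must be unique")

    ref = scans[0].df.set_index("id")
    keep = ref.index
    for s in scans[1:]:
        keep = keep.intersection(s.df["id"])
    if len(keep) == 0:
        raise ValueError("no variants shared by all scans")
    # preserve the first scan's order
    keep = ref.index[ref.index.isin(keep)]

    ref = ref.loc[keep]
    ea0 = ref["ea"].to_numpy()
    oa0 = ref["oa"].to_numpy()
    Z = np.empty((len(keep), len(scans)))
    Z[:, 0] = ref["z"].to_numpy()
    ok = np.ones(len(keep), dtype=bool)

    for jcol, s in enumerate(scans[1:], start=1):
        d = s.df.set_index("id").loc[keep]
        ea, oa, z = d["ea"].to_numpy(), d["oa"].to_numpy(), d["z"].to_numpy()
        direct = (ea == ea0) & (oa == oa0)
        swapped = (ea == oa0) & (oa == ea0)
        sign = np.where(direct, 1.0, np.where(swapped, -1.0, np.nan))
        unresolved = np.flatnonzero(~direct & ~swapped)
        for i in unresolved:
            if _is_palindromic(ea[i], oa[i]) or _is_palindromic(ea0[i], oa0[i]):
                continue  # never strand-flip palindromic pairs
            rc_ea, rc_oa = _revcomp(ea[i]), _revcomp(oa[i])
            if rc_ea == ea0[i] and rc_oa == oa0[i]:
                sign[i] = 1.0
            elif rc_ea == oa0[i] and rc_oa == ea0[i]:
                sign[i] = -1.0
        bad = np.isnan(sign)
        if bad.any():
            logger.info(
                "%s: %d variants with irreconcilable alleles dropped",
                s.trait_name,
                int(bad.sum()),
            )
        ok &= ~bad
        Z[:, jcol] = np.where(bad, np.nan, sign * z)

    ambiguous = np.array([_is_palindromic(a, b) for a, b in zip(ea0, oa0)])
    if drop_ambiguous:
        ok &= ~ambiguous
    if not ok.any():
        raise ValueError("no variants left after allele harmonization")

    variants = pd.DataFrame(
        {
            "id": np.asarray(keep)[ok],
            "chrom": ref["chrom"].to_numpy()[ok],
            "pos": ref["pos"].to_numpy()[ok],
            "ea": ea0[ok],
            "oa": oa0[ok],
            "ambiguous": ambiguous[ok],
        }
    ).reset_index(drop=True)
    return MultiTraitZPanel(variants=variants, trait_names=names, Z=Z[ok])


def write_panel_tsv(panel: MultiTraitZPanel, path) -> None:
    df = panel.variants.copy()
    for j, name in enumerate(panel.trait_names):
        df[f"z_{name}"] = panel.Z[:, j]
    # repr round-trips doubles exactly, so re-reading reproduces z bit-wise
    df.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_panel_tsv(path) -> MultiTraitZPanel:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    zcols = [c for c in df.columns if c.startswith("z_")]
    if len(zcols) < 2:
        raise ValueError("panel file needs at least two z_<trait> columns")
    names = [c[2:] for c in zcols]
    meta_cols = [c for c in ["id", "chrom", "pos", "ea", "oa", "ambiguous"] if c in df]
    return MultiTraitZPanel(
        variants=df[meta_cols].copy(),
        trait_names=names,
        Z=df[zcols].to_numpy(dtype=float),
    )
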