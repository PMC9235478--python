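"""Distance test, Storey q-values and two-stage selection of shared SNPs.

Stage 1 tests each SNP's distance r against a central chi distribution
with p (number of traits) degrees of freedom; stage 2 tests the angle of
the stage-1 survivors against the von Mises null.  False discovery rate
control is applied separately per stage with Storey q-values: q_r over
all SNPs, q_theta only over the SNPs with q_r below the stage-1
threshold.  A SNP is called shared when both q-values pass (default
0.05/0.05).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .polar import PolarTable
from .vonmises import DEFAULT_TOL, KappaCurve, theta_pvalues

__all__ = ["chi_sf", "qvalues", "two_stage_select"]

logger = logging.getLogger(__name__)

_STOREY_LAMBDAS = np.arange(0.05, 0.96, 0.05)


def chi_sf(r, p: int):
    """Survival function of the central chi distribution with p df at r.

    Equivalent to the chi-square survival function at r^2.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    r = np.asarray(r, dtype=float)
    out = stats.chi.sf(r, df=p)
    return float(out) if out.ndim == 0 else out


def _storey_pi0(pvec: np.ndarray) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on
    lambda = 0.05, 0.10, ..., 0.95, smoothed with a cubic polynomial and
    read off at the largest lambda.  Falls back to 1 when the smoother
    misbehaves (estimate <= 0 or > 1) or the input is too small.
    """
    m = pvec.size
    if m < 100:
        return 1.0
    pi0s = np.array(
        [np.mean(pvec > lam) / (1.0 - lam) for lam in _STOREY_LAMBDAS]
    )
    try:
        coef = np.polyfit(_STOREY_LAMBDAS, pi0s, 3)
        pi0 = float(np.polyval(coef, _STOREY_LAMBDAS[-1]))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate fit
        return 1.0
    if not np.isfinite(pi0) or pi0 <= 0 or pi0 > 1:
        logger.info("pi0 smoother returned %.3f; falling back to pi0 = 1", pi0)
        return 1.0
    return pi0


def qvalues(pvec, method: str = "storey"):
    """FDR-adjusted q-values for a vector of p-values.

    ``method="storey"`` estimates the null proportion pi0 with the
    smoother; ``method="bh"`` forces pi0 = 1, reproducing
    Benjamini-Hochberg.  Output order matches input; q-values are made
    monotone by the standard step-up cumulative minimum.
    """
    p = np.asarray(pvec, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError(f"unknown method '{method}'")
    pi0 = _storey_pi0(p) if method == "storey" else 1.0

    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def two_stage_select(
    polar: PolarTable,
    curve: KappaCurve,
    r_q_threshold: float = 0.05,
    theta_q_threshold: float = 0.05,
    tol: float = DEFAULT_TOL,
    qvalue_method: str = "storey",
) -> pd.DataFrame:
    """Run both tests and flag significantly shared SNPs.

    Returns a result table with one row per SNP: r, theta_trans, p_r,
    q_r, p_theta, q_theta and shared_flag.  p_theta is reported for every
    SNP for diagnostics, but q_theta is computed strictly on the stage-1
    survivor subset (q_r < r_q_threshold); non-survivors carry NaN
    q_theta and shared_flag False.
    """
    p_r = chi_sf(polar.r, polar.p)
    q_r = qvalues(p_r, method=qvalue_method)
    p_t = theta_pvalues(polar, curve, tol=tol)

    survivors = q_r < r_q_threshold
    q_t = np.full(len(polar.r), np.nan)
    if survivors.any():
        q_t[survivors] = qvalues(p_t[survivors], method=qvalue_method)
    else:
        logger.warning("no SNPs pass the stage-1 distance filter")
    shared = survivors & (q_t < theta_q_threshold)

    res = pd.DataFrame(
        {
            "r": polar.r,
            "theta_trans": polar.theta_trans,
            "p_r": p_r,
            "q_r": q_r,
            "p_theta": p_t,
            "q_theta": q_t,
            "r_significant": survivors,
            "shared_flag": shared,
        }
    )
    if polar.variants is not None:
        meta = polar.variants.reset_index(drop=True)
        res = pd.concat([meta, res], axis=1)
    return res
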