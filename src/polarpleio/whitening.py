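"""Null-covariance estimation and ZCA-cor whitening of z-score panels.

Sample overlap and phenotypic correlation between GWAS make the per-SNP
z-scores of different traits correlated even for SNPs with no effect.
The null covariance is estimated on SNPs without a large overall effect
(Mahalanobis distance below a threshold, default 5) and removed with the
ZCA-cor whitening transform W = P^{-1/2} V^{-1/2}, which among all
whitening transforms keeps each decorrelated component maximally
correlated with its original counterpart.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["WhiteningModel", "estimate_null_covariance", "zca_cor_whiten"]

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-10


@dataclass
class WhiteningModel:
    """Estimated null covariance and its ZCA-cor whitening transform.

    Attributes
    ----------
    sigma : (p, p) ndarray
        Covariance of null-SNP z-scores (zero mean assumed).
    corr : (p, p) ndarray
        Correlation matrix P derived from sigma.
    sdev : (p,) ndarray
        Standard deviations (the diagonal of V^{1/2}).
    W : (p, p) ndarray
        Whitening matrix P^{-1/2} diag(1/sdev); W sigma W^T = I.
    n_null : int
        Number of SNPs in the final (filtered) estimate.
    mahalanobis_threshold : float
        Distance cutoff used for the null subset.
    trait_names : list of str or None
    """

    sigma: np.ndarray
    corr: np.ndarray
    sdev: np.ndarray
    W: np.ndarray
    n_null: int
    mahalanobis_threshold: float
    trait_names: list | None = None

    @property
    def p(self) -> int:
        return self.sigma.shape[0]

    def to_json(self, path) -> None:
        obj = {
            "trait_names": self.trait_names,
            "mahalanobis_threshold": self.mahalanobis_threshold,
            "n_null": self.n_null,
            "sigma": self.sigma.tolist(),
            "corr": self.corr.tolist(),
            "sdev": self.sdev.tolist(),
            "W": self.W.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "WhiteningModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            sigma=np.array(obj["sigma"]),
            corr=np.array(obj["corr"]),
            sdev=np.array(obj["sdev"]),
            W=np.array(obj["W"]),
            n_null=int(obj["n_null"]),
            mahalanobis_threshold=float(obj["mahalanobis_threshold"]),
            trait_names=obj.get("trait_names"),
        )


def _inv_sqrt_sym(mat: np.ndarray) -> np.ndarray:
    """Inverse symmetric square root via eigen-decomposition.

    Eigenvalues are floored at 1e-10 for stability on near-singular input.
    """
    vals, vecs = np.linalg.eigh(mat)
    if np.any(vals <= 0):
        logger.warning("correlation matrix has non-positive eigenvalues; flooring")
    vals = np.maximum(vals, _EIG_FLOOR)
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def _zca_cor_matrix(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sdev = np.sqrt(np.diag(sigma))
    if np.any(sdev <= 0):
        raise np.linalg.LinAlgError("singular covariance (zero variance trait)")
    corr = sigma / np.outer(sdev, sdev)
    W = _inv_sqrt_sym(corr) @ np.diag(1.0 / sdev)
    return corr, sdev, W


def _cov_zero_mean(Z: np.ndarray) -> np.ndarray:
    # z-scores are centered at zero under the null, so no mean subtraction
    return (Z.T @ Z) / Z.shape[0]


def estimate_null_covariance(
    panel,
    threshold: float = 5.0,
    iterate: bool = False,
    max_iter: int = 20,
) -> WhiteningModel:
    """Estimate the null covariance on SNPs without large overall effect.

    Two passes: pass 1 computes a zero-mean covariance on all rows; pass 2
    recomputes it on the rows whose Mahalanobis distance under the pass-1
    covariance is below ``threshold`` (the distance itself, not its
    square).  With ``iterate=True`` the filtering is repeated until the
    retained set stabilizes.

    Raises
    ------
    ValueError
        If the filtered subset is smaller than 10*p.
    numpy.linalg.LinAlgError
        If the covariance is singular.
    """
    Z = np.asarray(panel.Z if hasattr(panel, "Z") else panel, dtype=float)
    m, p = Z.shape
    if m <= 10 * p:
        raise ValueError(f"need more than {10 * p} rows to estimate covariance")
    trait_names = list(getattr(panel, "trait_names", None) or []) or None

    sigma = _cov_zero_mean(Z)
    prev_sel = None
    for _ in range(max_iter if iterate else 1):
        inv = np.linalg.inv(sigma)
        d = np.sqrt(np.einsum("ij,jk,ik->i", Z, inv, Z))
        sel = d < threshold
        if sel.sum() < 10 * p:
            raise ValueError(
                f"only {int(sel.sum())} SNPs below Mahalanobis threshold "
                f"{threshold}; increase the threshold"
            )
        sigma = _cov_zero_mean(Z[sel])
        if prev_sel is not None and np.array_equal(sel, prev_sel):
            break
        prev_sel = sel

    corr, sdev, W = _zca_cor_matrix(sigma)
    return WhiteningModel(
        sigma=sigma,
        corr=corr,
        sdev=sdev,
        W=W,
        n_null=int(prev_sel.sum()),
        mahalanobis_threshold=float(threshold),
        trait_names=trait_names,
    )


def zca_cor_whiten(panel, model: WhiteningModel):
    """Apply the ZCA-cor whitening transform to a panel.

    Returns an object of the same kind as the input: a new
    MultiTraitZPanel when given one, otherwise the transformed matrix.
    """
    Z = np.asarray(panel.Z if hasattr(panel, "Z") else panel, dtype=float)
    if Z.shape[1] != model.p:
        raise ValueError(
            f"panel has {Z.shape[1]} traits, model fitted for {model.p}"
        )
    names = list(getattr(panel, "trait_names", []) or [])
    if names and model.trait_names and names != list(model.trait_names):
        raise ValueError("trait ordering differs between panel and model")
    Zw = Z @ model.W.T
    if hasattr(panel, "Z"):
        return replace(panel, Z=Zw)
    return Zw
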