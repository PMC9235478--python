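"""Polar/hyperspherical transform of whitened z-score vectors.

A SNP's per-trait z-scores form a point in the p-dimensional trait space.
Its Euclidean norm ``r`` measures overall effect; the angle between the
point and the nearest trait axis measures sharedness.  All orthants are
folded on top of each other (absolute values), so the direction of effect
never matters downstream.

For two traits the folded angle lies in [0, pi/2] and is stretched by the
classical fourfold transform (4*theta mod 2*pi); for p traits the
nearest-axis angle lies in [0, arccos(1/sqrt(p))] and is stretched so its
maximum (the all-equal diagonal) maps to pi.  Either way the transformed
angle ``theta_trans`` lives in [0, pi]: 0 means trait-specific, pi means
perfectly shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PolarTable",
    "radius",
    "folded_angle_2d",
    "fourfold_transform",
    "nearest_axis_angle",
    "angle_norm_factor",
    "to_polar",
]


@dataclass
class PolarTable:
    """Per-SNP polar coordinates of a multi-trait z-score panel.

    Attributes
    ----------
    r : ndarray
        Distance of each SNP from the origin (>= 0).
    theta_raw : ndarray
        Folded nearest-axis angle in [0, arccos(1/sqrt(p))].
    theta_trans : ndarray
        Normalized angle in [0, pi]; the von Mises test statistic.
    axis_index : ndarray of int
        Trait index (0-based) used as the null direction for each SNP.
    p : int
        Number of traits.
    degenerate : ndarray of bool
        True for all-zero rows, whose angle is undefined (set to 0).
    variants : pandas.DataFrame or None
        Optional variant metadata carried along from the panel.
    """

    r: np.ndarray
    theta_raw: np.ndarray
    theta_trans: np.ndarray
    axis_index: np.ndarray
    p: int
    degenerate: np.ndarray
    variants: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.r.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (id column included when metadata is present)."""
        df = pd.DataFrame(
            {
                "r": self.r,
                "theta_raw": self.theta_raw,
                "theta_trans": self.theta_trans,
                "axis": self.axis_index,
                "degenerate_flag": self.degenerate,
            }
        )
        if self.variants is not None and "id" in self.variants:
            df.insert(0, "id", np.asarray(self.variants["id"]))
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def radius(zrow: np.ndarray) -> np.ndarray:
    """Euclidean norm of one z-score row (or of each row of a matrix)."""
    z = np.asarray(zrow, dtype=float)
    if z.ndim == 1:
        return float(np.sqrt(np.sum(z * z)))
    return np.sqrt(np.sum(z * z, axis=1))


def folded_angle_2d(zx, zy):
    """Quadrant-folded angle arctan(|zy|/|zx|) in [0, pi/2].

    The fold makes the angle invariant to the signs of both z-scores;
    (0, 0) is defined as 0 (such rows are flagged degenerate upstream).
    """
    return np.arctan2(np.abs(zy), np.abs(zx))


def fourfold_transform(theta):
    """Stretch a folded 2-trait angle to the full circle: 4*theta mod 2*pi."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > np.pi / 2 + 1e-12):
        raise ValueError("fourfold_transform expects angles in [0, pi/2]")
    out = np.mod(4.0 * theta, 2.0 * np.pi)
    return float(out) if out.ndim == 0 else out


def nearest_axis_angle(zrow: np.ndarray) -> tuple[float, int]:
    """Angle between a z-score row and its nearest trait axis.

    Works on absolute values (all orthants folded).  The nearest axis is
    the trait with the largest |z| (lowest index wins ties).  The angle is
    computed as atan2(norm of the remaining components, max |z|), which is
    algebraically arccos(max|z| / r) but stable near the axis.

    Returns
    -------
    (angle, axis_index) with angle in [0, arccos(1/sqrt(p))].
    """
    z = np.abs(np.asarray(zrow, dtype=float))
    if z.ndim != 1:
        raise ValueError("nearest_axis_angle expects a single row")
    axis = int(np.argmax(z))
    rest = np.sqrt(np.sum(z * z) - z[axis] ** 2)
    if z[axis] == 0.0:
        return 0.0, axis
    return float(np.arctan2(rest, z[axis])), axis


def angle_norm_factor(p: int) -> float:
    """Multiplier mapping the maximal nearest-axis angle to pi.

    The nearest-axis angle is largest on the all-equal diagonal, where it
    equals arccos(1/sqrt(p)); the factor pi / arccos(1/sqrt(p)) stretches
    the range to [0, pi] for every p.  At p=2 this reproduces the fourfold
    transform restricted to the folded half-quadrant (factor 4).
    """
    if p < 2:
        raise ValueError("angle normalization needs p >= 2")
    return float(np.pi / np.arccos(1.0 / np.sqrt(p)))


def _deviation_from_zero(angle):
    """Angular deviation of a circular angle in [0, 2*pi) from 0."""
    a = np.mod(angle, 2.0 * np.pi)
    return np.minimum(a, 2.0 * np.pi - a)


def to_polar(panel) -> PolarTable:
    """Convert a (whitened) multi-trait panel to polar coordinates.

    Parameters
    ----------
    panel : MultiTraitZPanel or ndarray
        m x p matrix of z-scores, ideally decorrelated.

    Notes
    -----
    For p = 2 the fourfold transform is applied and re-expressed as the
    deviation from 0 in [0, pi]; for p > 2 the nearest-axis angle is
    scaled by :func:`angle_norm_factor`.  Both constructions agree exactly
    at p = 2.
    """
    variants = None
    if hasattr(panel, "Z"):
        Z = np.asarray(panel.Z, dtype=float)
        variants = getattr(panel, "variants", None)
    else:
        Z = np.asarray(panel, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("panel must be an m x p matrix with p >= 2")
    m, p = Z.shape

    A = np.abs(Z)
    r = np.sqrt(np.sum(A * A, axis=1))
    axis = np.argmax(A, axis=1)
    amax = A[np.arange(m), axis]
    rest = np.sqrt(np.maximum(r * r - amax * amax, 0.0))
    degenerate = r == 0.0

    theta_raw = np.zeros(m)
    nz = ~degenerate
    theta_raw[nz] = np.arctan2(rest[nz], amax[nz])

    if p == 2:
        folded = np.arctan2(A[:, 1], A[:, 0])
        folded[degenerate] = 0.0
        theta_trans = _deviation_from_zero(np.mod(4.0 * folded, 2.0 * np.pi))
    else:
        theta_trans = theta_raw * angle_norm_factor(p)
    theta_trans[degenerate] = 0.0

    return PolarTable(
        r=r,
        theta_raw=theta_raw,
        theta_trans=theta_trans,
        axis_index=axis,
        p=p,
        degenerate=degenerate,
        variants=variants,
    )
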