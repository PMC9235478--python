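"""Von Mises null model for the sharedness angle.

Under the null hypothesis of a trait-specific effect the transformed
angle ``theta_trans`` concentrates at 0; under the alternative
(pleiotropy) it is pushed toward pi.  The null is modelled as a mean-zero
von Mises distribution whose concentration ``kappa`` depends on the
distance ``r``: strong effects pin the angle to the axis, weak effects
leave it nearly uniform.  Since no closed form for kappa(r) exists, the
curve is calibrated by simulating trait-specific SNPs at each distance
and fitting kappa by maximum likelihood; calibrated curves for p = 2..6
ship with the package and can be regenerated from the command line.

The tail probability P(Theta >= theta) is evaluated with a term-wise
series expansion of exp(kappa*cos t): each term has the closed-form
antiderivative

    int (k cos t)^j / j! dt
        = -cot(t) |sin t| (k cos t)^j
          2F1(1/2, (j+1)/2; (j+3)/2; cos^2 t) / Gamma(j+2)

(note -cot(t)|sin t| = -cos(t) on (0, pi)).  Summation stops when the
last added term falls below a user tolerance ``tol``.  The von Mises
normalization constant cancels in the tail ratio.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, hyp2f1, i0e, i1e

from .polar import PolarTable

__all__ = [
    "KappaCurve",
    "VonMisesNull",
    "vm_mle_kappa",
    "vm_tail_pvalue",
    "calibrate_kappa_curve",
    "kappa_lookup",
    "theta_pvalues",
    "builtin_curve",
    "simulate_trait_specific",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-8
DEFAULT_R_GRID = np.arange(0.5, 12.0 + 1e-9, 0.25)
DEFAULT_N_SIMS = 50_000
KAPPA_CAP = 1e6
_MAX_TERMS = 10_000


@dataclass(frozen=True)
class VonMisesNull:
    """Mean-zero von Mises null with concentration ``kappa``."""

    kappa: float
    tol: float = DEFAULT_TOL
    mu: float = 0.0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not (0 < self.tol <= 1e-4):
            raise ValueError("tol must be in (0, 1e-4]")


@dataclass
class KappaCurve:
    """Calibrated concentration kappa as a function of distance r.

    Lookup between grid points is piecewise linear; outside the grid the
    endpoint values are used (clamping).
    """

    r_grid: np.ndarray
    kappa_values: np.ndarray
    p: int
    n_sims: int
    seed: int

    def __post_init__(self):
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.kappa_values = np.asarray(self.kappa_values, dtype=float)
        if self.r_grid.shape != self.kappa_values.shape:
            raise ValueError("r_grid and kappa_values must have equal length")
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be strictly increasing")
        if np.any(~np.isfinite(self.kappa_values)) or np.any(self.kappa_values < 0):
            raise ValueError("kappa values must be finite and >= 0")

    def write_tsv(self, path) -> None:
        header = (
            f"# kappa calibration curve\n"
            f"# p={self.p}\n# n_sims={self.n_sims}\n# seed={self.seed}\n"
            "r\tkappa\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for r, k in zip(self.r_grid, self.kappa_values):
                fh.write(f"{float(r)!r}\t{float(k)!r}\n")

    @classmethod
    def read_tsv(cls, path_or_buf) -> "KappaCurve":
        meta = {"p": 0, "n_sims": 0, "seed": 0}
        rows = []
        if hasattr(path_or_buf, "read"):
            lines = path_or_buf.read().splitlines()
        else:
            with open(path_or_buf) as fh:
                lines = fh.read().splitlines()
        for line in lines:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, _, val = body.partition("=")
                    if key.strip() in meta:
                        meta[key.strip()] = int(val)
                continue
            if line.startswith("r\t"):
                continue
            a, b = line.split("\t")
            rows.append((float(a), float(b)))
        arr = np.array(rows)
        return cls(arr[:, 0], arr[:, 1], **meta)


def vm_mle_kappa(angles, mirrored: bool = True) -> float:
    """Maximum-likelihood concentration of a mean-zero von Mises.

    Parameters
    ----------
    angles : array-like
        Angular deviations in [0, pi].
    mirrored : bool
        When True (the usual case here) the deviations are mirrored to
        +/- theta before fitting, which forces the mean direction to 0;
        the mean resultant length then reduces to mean(cos theta).

    Notes
    -----
    Solves A(kappa) = Rbar with A = I1/I0 using the standard closed-form
    starting value (Fisher/Banerjee) refined by Newton steps.  The
    estimate is capped at 1e6 for degenerate, fully concentrated samples.
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("vm_mle_kappa needs at least one angle")
    # mirroring symmetrizes the sample; either way the resultant along the
    # zero direction is mean(cos).
    rbar = float(np.mean(np.cos(a)))
    if rbar <= 0.0:
        return 0.0
    if rbar >= 1.0 - 1e-12:
        logger.warning("all angles at 0: kappa capped at %.0e", KAPPA_CAP)
        return KAPPA_CAP
    r2 = rbar * rbar
    kappa = rbar * (2.0 - r2) / (1.0 - r2)
    for _ in range(50):
        A = i1e(kappa) / i0e(kappa)
        dA = 1.0 - A * A - A / kappa
        if dA <= 0:
            break
        step = (A - rbar) / dA
        kappa -= step
        if kappa <= 0:
            kappa = 1e-8
        if abs(step) < 1e-10 * (1.0 + kappa):
            break
        if kappa > KAPPA_CAP:
            logger.warning("kappa estimate capped at %.0e", KAPPA_CAP)
            return KAPPA_CAP
    return float(min(kappa, KAPPA_CAP))


def vm_tail_pvalue(theta, kappa, tol: float = DEFAULT_TOL):
    """P(angular deviation >= theta) under a mean-zero von Mises.

    Evaluates int_theta^pi exp(kappa cos t) dt / int_0^pi exp(kappa cos t) dt
    by term-wise summation of the series expansion of the exponent, each
    term integrated in closed form via the hypergeometric antiderivative
    (the j-th antiderivative term at angle t with c = cos t is
    ``-base_j * c**(j+1) * 2F1(1/2, (j+1)/2; (j+3)/2; c^2)`` with
    ``base_j = kappa**j / Gamma(j+2)``; at the endpoints c^2 = 1 the
    hypergeometric factor reduces to Gamma((j+3)/2)Gamma(1/2)/Gamma((j+2)/2)).
    Summation stops once the last added term of every partial sum is
    below ``tol`` in magnitude.

    Accepts scalars or arrays (broadcast together).

    Raises
    ------
    RuntimeError
        If the series has not converged after 10,000 terms.
    """
    th0, kp0 = np.asarray(theta, dtype=float), np.asarray(kappa, dtype=float)
    th, kp = np.broadcast_arrays(np.atleast_1d(th0), np.atleast_1d(kp0))
    shape = th.shape
    th = th.ravel().astype(float)
    kp = kp.ravel().astype(float)
    if np.any((th < -1e-12) | (th > np.pi + 1e-12)):
        raise ValueError("theta must lie in [0, pi]")
    if np.any(kp < 0):
        raise ValueError("kappa must be >= 0")
    if np.any(kp > 700):
        raise RuntimeError(
            "von Mises tail series overflows for kappa > 700 "
            f"(got kappa={float(np.max(kp)):g})"
        )
    th = np.clip(th, 0.0, np.pi)
    c = np.cos(th)

    num = np.zeros_like(th)  # F(pi) - F(theta)
    den = np.zeros_like(th)  # F(pi) - F(0)
    active = np.ones(th.shape, dtype=bool)
    logkp = np.where(kp > 0, np.log(np.where(kp > 0, kp, 1.0)), -np.inf)
    j = 0
    while active.any():
        if j >= _MAX_TERMS:
            idx = int(np.argmax(active))
            raise RuntimeError(
                "von Mises tail series did not converge after "
                f"{_MAX_TERMS} terms (kappa={kp[idx]:g}, theta={th[idx]:g})"
            )
        ka = kp[active]
        ca = c[active]
        if j == 0:
            base = np.ones_like(ka) / np.exp(gammaln(2))
        else:
            base = np.exp(j * logkp[active] - gammaln(j + 2))
        # endpoint hypergeometric value at z=1 (closed form, scalar per j)
        h1 = np.exp(
            gammaln((j + 3) / 2.0) + gammaln(0.5) - gammaln((j + 2) / 2.0)
        )
        t_pi = ((-1.0) ** j) * base * h1
        t_0 = -base * h1
        h = hyp2f1(0.5, (j + 1) / 2.0, (j + 3) / 2.0, ca * ca)
        t_th = -base * ca ** (j + 1) * h
        dnum = t_pi - t_th
        dden = t_pi - t_0
        num[active] += dnum
        den[active] += dden
        # terms decay only past the series peak at j ~ kappa
        done = (np.maximum(np.abs(dnum), np.abs(dden)) < tol) & (j >= ka)
        sub = np.flatnonzero(active)
        active[sub[done]] = False
        j += 1

    out = np.clip(num / den, 0.0, 1.0)
    if th0.ndim == 0 and kp0.ndim == 0:
        return float(out[0])
    return out.reshape(shape)


def _pava_nondecreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit."""
    level = list(y.astype(float))
    weight = [1.0] * len(level)
    i = 0
    while i < len(level) - 1:
        if level[i] > level[i + 1] + 1e-15:
            pooled = (level[i] * weight[i] + level[i + 1] * weight[i + 1]) / (
                weight[i] + weight[i + 1]
            )
            weight[i] += weight[i + 1]
            level[i] = pooled
            del level[i + 1], weight[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    return np.repeat(level, np.asarray(weight, dtype=int))


def simulate_trait_specific(p: int, mu: float, n: int, rng) -> np.ndarray:
    """Draw n trait-specific null SNPs in the whitened space.

    One trait carries the effect +/- mu plus unit normal noise; the other
    p-1 traits are pure unit normal.  The affected trait is the first
    column (the polar transform is permutation invariant).
    """
    Z = rng.standard_normal((n, p))
    signs = rng.choice([-1.0, 1.0], size=n)
    Z[:, 0] += signs * mu
    return Z


def _theta_trans_rows(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(r, theta_trans) of raw rows without building a PolarTable."""
    from .polar import to_polar

    pt = to_polar(Z)
    return pt.r, pt.theta_trans


def calibrate_kappa_curve(
    p: int,
    r_grid=None,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    min_bin_count: int = 500,
    isotonic: bool = True,
) -> KappaCurve:
    """Calibrate kappa(r) by simulation under the trait-specific null.

    For each grid distance r*, trait-specific SNPs are simulated with
    signal magnitude mu(r*) = sqrt(max(r*^2 - (p-1), 0)) so the expected
    distance matches r*; rows whose realized r falls in the bin around r*
    are retained, their transformed angles are fitted with
    :func:`vm_mle_kappa`, and the fit becomes the curve value.  Bins with
    fewer than ``min_bin_count`` retained rows are widened (with a
    warning) until populated.  Since a stronger effect always pins the
    angle more tightly to the axis, the concentration is non-decreasing
    in r; with ``isotonic=True`` (default) the fitted values are denoised
    by a least-squares monotone (pool-adjacent-violators) fit.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if r_grid is None:
        r_grid = DEFAULT_R_GRID
    r_grid = np.asarray(r_grid, dtype=float)
    if n_sims < 1000:
        raise ValueError("n_sims too small for a stable kappa fit")
    rng = np.random.default_rng(np.random.SeedSequence([seed, p]))
    spacing = np.min(np.diff(r_grid)) if r_grid.size > 1 else 0.5
    kappas = np.empty_like(r_grid)
    for i, rstar in enumerate(r_grid):
        mu = np.sqrt(max(rstar * rstar - (p - 1), 0.0))
        Z = simulate_trait_specific(p, mu, n_sims, rng)
        r, theta = _theta_trans_rows(Z)
        half = spacing / 2.0
        sel = np.abs(r - rstar) < half
        while sel.sum() < min_bin_count and half < 10 * spacing:
            half *= 2.0
            sel = np.abs(r - rstar) < half
            logger.warning(
                "kappa calibration bin at r*=%.2f widened to +/-%.2f "
                "(%d rows)", rstar, half, int(sel.sum()),
            )
        kappas[i] = vm_mle_kappa(theta[sel], mirrored=True)
    if isotonic:
        kappas = _pava_nondecreasing(kappas)
    return KappaCurve(r_grid, kappas, p=p, n_sims=n_sims, seed=seed)


def kappa_lookup(r, curve: KappaCurve):
    """Piecewise-linear interpolation of kappa at distance r (clamped)."""
    r = np.asarray(r, dtype=float)
    out = np.interp(r, curve.r_grid, curve.kappa_values)
    return float(out) if out.ndim == 0 else out


def builtin_curve(p: int) -> KappaCurve:
    """Load the pre-calibrated curve shipped with the package (p = 2..6)."""
    name = f"kappa_p{p}.tsv"
    ref = importlib.resources.files("polarpleio.data").joinpath(name)
    if not ref.is_file():
        raise FileNotFoundError(
            f"no builtin kappa curve for p={p}; run `polarpleio kappa-calibrate`"
        )
    with ref.open("r") as fh:
        return KappaCurve.read_tsv(fh)


def theta_pvalues(polar: PolarTable, curve: KappaCurve, tol: float = DEFAULT_TOL):
    """Per-SNP angle p-values p_theta under the kappa(r) null.

    Degenerate rows (r = 0) get p_theta = 1.
    """
    if curve.p != polar.p:
        raise ValueError(
            f"kappa curve calibrated for p={curve.p}, panel has p={polar.p}"
        )
    kap = kappa_lookup(polar.r, curve)
    pv = vm_tail_pvalue(polar.theta_trans, kap, tol=tol)
    pv = np.asarray(pv, dtype=float)
    pv[polar.degenerate] = 1.0
    return pv
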