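# Methods

## Model

For each SNP i and traits j = 1..p, the input is the z-score
z_ij = beta_ij / SE_ij, approximately N(0, 1) when the SNP has no effect
on trait j. Sample overlap and phenotypic correlation between studies
make the columns of the z matrix correlated even under the null, so the
panel is first decorrelated (below). The decorrelated row z_i is then
summarized by two polar coordinates:

- distance r_i = ||z_i||, measuring overall effect. Under the global
  null r_i is the norm of p independent standard normals, i.e. central
  chi with p degrees of freedom; `p_r = P(Chi_p >= r)`.
- angle theta_i, measuring sharedness. The row is folded into the
  positive orthant (absolute values), the nearest trait axis is taken as
  the null direction (the axis of the largest |z|), and the angle
  between the row and that axis is stretched by pi / arccos(1/sqrt(p))
  so its maximum — attained on the all-equal diagonal — is exactly pi.
  For p = 2 this reproduces the fourfold transform 4*theta mod 2*pi
  (expressed as deviation from 0 in [0, pi]): both trait axes map to 0
  and the diagonals to pi. The angle is computed as
  atan2(||z_perp||, max_j |z_j|), which is algebraically
  arccos(max|z|/r) but numerically stable near the axis.

The two hypotheses are tested separately and in sequence: stage 1 keeps
SNPs whose overall effect is significant (q_r < 0.05); stage 2 tests,
among those, whether the effect is shared rather than trait-specific
(q_theta < 0.05). The alternative of stage 1 alone ("affects at least
one trait") is deliberately insufficient for pleiotropy; only the
combination flags a SNP as shared.

A note on the angle normalization: stretching by pi / theta_max (rather
than 2*pi / theta_max) is the only choice consistent with the p = 2
fourfold construction — a 2*pi stretch would wrap the maximally shared
direction back onto the trait-specific null at 0 and make the test
blind to exactly the signal it seeks.

## The angle null and kappa calibration

Under the stage-2 null (trait-specific effect), theta concentrates at 0;
under the alternative it is pushed toward pi. The null is modelled as a
mean-zero von Mises distribution, treated as a circular (2-D) angle for
every p since the nearest-axis construction always lives in the 2-D
plane spanned by the row and its axis. No sin^(p-2) Jacobian is
introduced.

The concentration kappa is not free: a trait-specific SNP with a large
effect has a nearly axis-aligned row (kappa large), a weak one is almost
isotropic (kappa ~ 0). kappa(r) is calibrated by simulation: for each
grid distance r*, trait-specific rows are drawn as one coordinate
+/-mu(r*) + N(0,1) and the rest N(0,1), with mu(r*) =
sqrt(max(r*^2 - (p-1), 0)) so the realized distance matches r*; rows
whose realized r falls in the bin around r* (half the grid spacing,
widened if fewer than 500 rows land in it) are retained and their
transformed angles fitted by maximum likelihood. The MLE solves
A(kappa) = I1(kappa)/I0(kappa) = mean(cos theta) with the standard
closed-form start refined by Newton steps, capped at 1e6 for degenerate
samples. Binning on realized r (rather than on mu) matches how the
curve is used: the per-SNP lookup conditions on the observed r.

Because a stronger effect always concentrates the angle more, kappa(r)
is monotone non-decreasing; the fitted values are denoised with a
least-squares monotone (pool-adjacent-violators) fit before being
stored. Lookup between grid points is piecewise linear, clamped at the
grid ends.

Defaults: r grid 0.5 to 12 in steps of 0.25, 50,000 simulated rows per
grid point, series tolerance 1e-8. Calibrated curves for p = 2..6 are
bundled (seed 1729) and regenerable via `polarpleio kappa-calibrate`.

Calibration quality is judged by a uniformity oracle: p_theta of freshly
simulated trait-specific rows across the grid is uniform
(Kolmogorov–Smirnov statistic < 0.02 at n = 20,000 — the test suite
checks this). Concentration transfers across p only approximately (the
p = 3 curve runs ~20–30% below the p = 2 curve at matched r, because the
normalized p = 3 angle is more dispersed); per-p curves are therefore
calibrated and shipped rather than reusing p = 2 values.

## Tail probability of the angle

p_theta = P(Theta >= theta) under the mean-zero von Mises is the ratio
of integrals of exp(kappa cos t) over [theta, pi] and [0, pi] (the
normalization constant cancels). The integrand has no elementary
antiderivative; it is integrated term by term through the series of the
exponential, where the j-th term has the closed form

    int (kappa cos t)^j / j! dt
      = -cot(t) |sin t| (kappa cos t)^j
        2F1(1/2, (j+1)/2; (j+3)/2; cos^2 t) / Gamma(j+2)

(-cot(t)|sin t| = -cos(t) on (0, pi); at the endpoints cos^2 t = 1 the
hypergeometric factor reduces to Gamma((j+3)/2) Gamma(1/2) /
Gamma((j+2)/2)). Summation stops when the last added term of every
partial sum is below `tol` (default 1e-8; terms only decay past
j ~ kappa, so convergence is additionally gated on j >= kappa). A term
cap of 10,000 raises a hard error rather than silently truncating, and
kappa > 700 is rejected before the series overflows double range —
far beyond any concentration the calibration produces (kappa stays
below ~15 over the default grid). The implementation was validated
against adaptive quadrature at machine precision over
kappa in {0.1, 1, 5, 20, 100}.

## Decorrelation

The null covariance Sigma of the z columns is estimated in two passes:
pass 1 uses all rows (zero mean — z-scores are centered under the
null); pass 2 re-estimates on rows whose Mahalanobis distance under the
pass-1 covariance is below 5 (the distance, not its square). An
optional flag iterates the filter to a fixed point. The whitening
matrix is ZCA-cor, W = P^{-1/2} V^{-1/2} (inverse symmetric square root
of the correlation matrix, then scale standardization), computed by
symmetric eigen-decomposition with eigenvalues floored at 1e-10. Among
all whitening transforms, ZCA-cor keeps each whitened component
maximally correlated with its original counterpart, so trait axes
retain their identity as far as possible.

The Mahalanobis filter is self-normalizing: a contaminating class of
fraction f inflates the pass-1 variance so that its own distance
settles near sqrt(1/f), hence the d < 5 cutoff can only exclude effect
classes rarer than ~4% of SNPs. This is the sparse-large-effect regime
of real GWAS panels; synthetic panels with dense strong effects should
use sparse class fractions (or skip whitening when traits are
uncorrelated).

## Multiple testing

q-values use Storey's estimator: pi0(lambda) = #{p > lambda} /
(m (1 - lambda)) on lambda = 0.05..0.95, smoothed by a cubic polynomial
and read off at lambda = 0.95, with fallback to pi0 = 1 whenever the
smoother leaves (0, 1] or fewer than 100 p-values are available;
q-values are the step-up cumulative minimum of pi0 * m * p_(i) / i.
`method="bh"` forces pi0 = 1 (Benjamini–Hochberg). q_theta is computed
strictly on the stage-1 survivors; p_theta is still reported for all
SNPs for diagnostics. Rows with r = 0 are flagged degenerate and given
p_theta = 1 — they can never pass stage 1.

## Synthetic data

The generator works on the z-score scale: each SNP's z-vector is its
true effect vector plus equicorrelated unit-variance Gaussian noise
(pairwise correlation rho, default 0.8). Classes: a fraction of SNPs
specific to each trait (one nonzero effect entry, random sign; default
10% per trait), a pleiotropic fraction (all entries nonzero, one
magnitude per SNP, independent signs; default 10%), remainder null.
Everything is deterministic given (seed, replicate) through named
substreams.

The default effect magnitude reproduces a small-cohort polygenic GWAS:
per-trait heritability h2 = 0.6 spread over all of a trait's causal
SNPs at sample size n = 549 gives per-SNP z noncentrality
sqrt(n h2 / M_causal) — about 0.18 at the desk-scale default of 50,000
SNPs, i.e. individual causal SNPs are nearly indistinguishable from
null. This is the regime in which the angle test's false positive rate
is a calibration measure. Power experiments instead use a fixed large
magnitude (e.g. 6).

Two false-positive-rate experiments are built in:

- `permuted`: fully null panels that retain the inter-trait correlation
  (the z-level analog of permuting phenotypes in pairs); the FPR of the
  distance test is the fraction of SNPs with p_r < 0.05. It reproduces
  the nominal 0.050 within Monte-Carlo error (20 x 50,000 SNPs).
- `specific`: three-class panels through the full pipeline; the FPR of
  the angle test is the fraction of ground-truth trait-specific SNPs
  with p_theta < 0.05. It lands near 0.055 — slightly above nominal,
  because the von Mises tail is an imperfect fit to the exact folded
  angle distribution at moderate distances (the exact null tail is
  heavier than the fitted von Mises tail, and effectively-null SNPs
  that reach moderate r by noise meet a kappa(r) calibrated for true
  effects of that size).

What the generator does *not* emulate: linkage disequilibrium between
SNPs (rows are independent), allele-frequency structure, genotype-level
sampling noise, or exact heritability bookkeeping. LD both correlates
neighboring test statistics and creates spuriously shared markers, so
false positive rates on real panels can sit somewhat above these
simulated values; passing tests here demonstrate the statistical
machinery, not robustness to LD. Locus clumping downstream exists
precisely to absorb LD-driven redundancy.

## Known limitations

- Whitening is a linear map applied to effects and noise alike: a
  strictly trait-specific effect vector (delta, 0) under strong null
  correlation rho is rotated off-axis (for rho = 0.8, by ~27 degrees),
  so *large* trait-specific effects in a highly correlated pair can be
  flagged shared. Decorrelation attenuates, but does not remove,
  vertical pleiotropy; at polygenic effect sizes the rotation is
  negligible.
- The von Mises null is an approximation to the exact conditional angle
  distribution; its tail miscalibration is the ~0.005 excess in the
  angle-test FPR above.
- Clumping is positional only (default window 5,000 kb, greedy by
  ascending q_theta); an LD table can be supplied to absorb distant
  partners but no reference panel is bundled.
- The trait count used to down-weight widely shared loci is derived
  from pairwise runs (the number of traits in whose pairwise results a
  locus lead appears), not from a joint run over all traits.
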