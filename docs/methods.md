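# Methods

## Model

`ergsurf` fits sampled ERG amplitudes (µV) with the additive model

```
Y_ijk = β₀ + b_i + f(t_ijk, FS_ij) + ε_ijk
```

- `t` — time from flash onset, ms (here roughly −20.5 to 31.2 ms: baseline,
  a-wave and the ascending limb of the b-wave);
- `FS` — flash strength, Troland-seconds (Td.s), 10 design levels from 12
  to 446;
- `b_i ~ N(0, σ_b²)` — a random intercept per recording unit;
- `ε_ijk ~ N(0, σ²)` — independent Gaussian working noise.

`f` is deliberately nonparametric: the point of the method is to let the
waveform shape deform freely with flash strength rather than impose a
functional form, and then to read group differences off the fitted surface.

### Basis and penalties

`f(t, FS)` is a tensor product of two marginal B-spline bases, built as the
row-wise Kronecker product of the marginal design matrices. Column order is
t-major (the FS basis index varies fastest). Defaults: cubic splines,
`k_t = 20` time basis functions and `k_fs = 8` flash-strength functions.
Time gets the larger basis because it must resolve the a-wave trough,
oscillatory-potential ripples and the b-wave rise inside a ~52 ms window;
FS has only 10 design levels, so its basis stays below 10. FS enters on its
raw Td.s scale by default, with an optional log₁₀ flag
(`ModelSpec.fs_log_scale`) since the design spaces flash strengths
multiplicatively.

Knots follow the P-spline convention: uniform spacing over the observed
data range with `degree` extra uniform knots beyond each end (not clamped).
This matters: each marginal carries an unweighted difference penalty
`λ βᵀDᵀD β` (order 2 by default), and only on uniform knots are the
B-spline coefficients of a polynomial themselves polynomial in the index,
making polynomials of degree < order *exactly* penalty-free. With clamped
boundary knots the Greville sites are non-uniform near the ends and even a
plane picks up penalty, which would bias the fit at high smoothing; the
test suite pins the uniform-knot behavior (a bilinear surface is
reproduced with zero RSS at any λ).

The two directional penalties are `S_t ⊗ I` and `I ⊗ S_fs` (anisotropic:
time and FS get separate weights). Only these two marginal directions are
penalized; no extra null-space penalty is applied.

### Identifiability and random effects

The smooth coexists with a free intercept, so one linear constraint —
fitted smooth values sum to zero over the fitting data, the standard
choice — is absorbed by an orthonormal Householder reparameterization
(dimension `k_t·k_fs − 1`). Absorbing (rather than dropping a column) keeps
the transformed penalties symmetric PSD.

Random intercepts enter as a one-hot indicator block with an identity ridge
penalty. This is the exact penalized-least-squares encoding of
`b_i ~ N(0, σ_b²)` with `λ_b = σ²/σ_b²`; after fitting,
`σ̂_b² = σ̂²/λ̂_b`. The unit is per subject by default (both eyes of a
subject share one effect, preventing pseudoreplication of paired eyes);
`random_effect_unit="per_eye"` gives each eye its own intercept.

### Fitting and smoothing selection

For fixed λ the coefficients solve the penalized normal equations
`(XᵀX + λ_t S_t + λ_fs S_fs + λ_b S_b) β = Xᵀy` by Cholesky, with an
explicit singularity error when the LAPACK reciprocal-condition estimate
falls to the edge of double precision (10⁻¹⁴ — a deliberately low floor,
because a benign huge ridge such as λ_b = 10¹² inflates the 1-norm
condition without harming the solve). The effective degrees of freedom are
`tr[(XᵀX + ΣλⱼSⱼ)⁻¹ XᵀX]`; the residual variance is `σ̂² = RSS/(n − edf)`.

All three weights minimize `GCV(λ) = n·RSS/(n − edf)²`, evaluated from
precomputed cross-products (each λ evaluation is O(p³), p ≲ 400): a 5-point
multi-start grid per axis on log₁₀λ ∈ [−6, 6], then Nelder–Mead from the
best grid point (tolerance 10⁻⁶ on log GCV). The returned point is never
worse than any grid evaluation, and the whole fit is deterministic given a
`ModelSpec`. Nelder–Mead may walk outside the initial box; that is
intentional (e.g. λ_b → ∞ when the data carry no between-unit variance).

Two properties of GCV worth knowing (both pinned by tests):

- With a truth in the penalty null space, GCV does *not* push λ to the
  upper bound; it tolerates a few effective parameters of noise-chasing
  because they barely move the criterion at large n. Null-space recovery is
  still exact in the λ→∞ limit.
- `λ_b` is well identified only when the data contain many units with a
  modest number of samples each. When every unit has hundreds of samples,
  shrinkage is negligible, the GCV profile in λ_b is flat on the left, and
  `σ̂_b = σ̂/√λ̂_b` becomes unstable (typically inflated). The
  variance-recovery and z-calibration experiments therefore use many-unit,
  thin-per-unit designs; for a fit at the full study scale, treat `σ̂_b`
  with caution (the surface itself is unaffected).

### Uncertainty

The coefficient covariance is the Bayesian posterior of the penalized fit,
`V = (XᵀX + ΣλⱼSⱼ)⁻¹ σ̂²` — the standard penalized-spline convention; no
correction for λ having been estimated. Population-level predictions
(`b_i = 0`) use the intercept + smooth sub-block of `V`:
`se(t,FS) = sqrt(xᵀ V x)`. A Monte-Carlo propagation test (50 000
coefficient draws) confirms the algebra to 1%.

Group comparisons fit each group separately and combine SEs in quadrature
(`se_diff² = se_A² + se_B²`), valid because the fits are independent. The
z-map `z = diff/se_diff` is a *qualitative* screen: cells are strongly
correlated through the smoother, and no multiplicity correction is applied.
In a calibrated null experiment (identical truths, 200 replicate group
pairs, 40 units/group), the pointwise |z| > 1.96 rate at a fixed interior
cell came out at ~4% — close to nominal, with smoothing bias and λ
variability accounting for the deviation.

No extrapolation anywhere: predictions, grids, derived waveforms and
difference surfaces are confined to the fitted (t, FS) rectangle
(difference grids to the intersection of the two rectangles), and
out-of-range requests raise a named error.

### Surface outputs

- Grids default to 200 (t) × 100 (FS) points over the fitted rectangle.
- Extrema are elementwise global min/max; exact ties break toward smaller
  t, then smaller FS.
- Contours come from marching squares (`skimage.measure.find_contours`) on
  the estimate matrix, with fractional grid indices mapped linearly onto
  the data axes; vertices bilinear-interpolate back to their level to
  ~10⁻⁹.
- Derived waveforms default to the nine flash strengths 15, 50, 75, 100,
  150, 200, 250, 300, 400 Td.s.

## Synthetic generator

`true_mean(t, FS)` is a minimal kinetic sketch with closed form:

```
A_a(FS)·g_a(t) + A_b(FS)·[ g_b(t) + ripple(t) ]
```

- `g_a` — negative Gaussian lobe centred at 12 ms (width 3 ms): the a-wave
  trough; depth saturates as `A_a(FS) = a_amp_max·FS/(FS + b_k)`
  (default ceiling 12 µV).
- `g_b` — positive Gaussian lobe centred at 28 ms (width 5 ms): the b-wave
  rise; amplitude follows the Naka–Rushton law
  `A_b(FS) = b_vmax·FSⁿ/(FSⁿ + b_kⁿ)` (defaults `b_vmax` 30 µV, `b_k` 80
  Td.s, `n` 1).
- `ripple` — a 120 Hz sinusoid, zero-phase at the trough, decaying with an
  8 ms time constant and smoothly gated to the ascending limb: the
  oscillatory potentials. Its amplitude scales with the same Naka–Rushton
  law (4 µV at ceiling).

Baseline (t ≤ −5 ms) contributions are below 1% of the lobe peaks. Subject
effects are i.i.d. N(0, σ_b²) with σ_b = 2 µV; sampling noise N(0, σ²)
with σ = 3 µV; time axis 100 evenly spaced samples on [−20.5, 31.2] ms;
flash series 12, 21, 35, 70, 113, 178, 251, 356, 446 plus 85 Td.s. The
default `DesignTable.study_default()` reproduces the published per-FS
waveform counts exactly (1736 control / 1300 ASD). Because two of the
control counts (178 at 70 and 446 Td.s) exceed two eyes × 88 participants,
the synthetic control cohort uses 89 subjects so that every waveform maps
to a distinct (subject, eye) pair; the ASD cohort uses 70. Group contrasts
for power/localization experiments are injected by scaling `b_vmax` only
(a pure b-wave deficit).

What the generator does *not* emulate: biophysically realistic
phototransduction kinetics, the photopic-hill *decline* at the highest
flash strengths (amplitudes here saturate monotonically), rod intrusion,
device filtering, artifacts, autocorrelated within-waveform noise, or the
slight per-recording jitter of real sampling rates (all waveforms share one
time axis, and the different background luminance of the 85 Td.s level is
ignored). Passing tests therefore demonstrate that the estimator recovers
surfaces of this qualitative shape under Gaussian noise — not that it is
robust to correlated noise or artifact structure in real recordings.

## Experiment sizes used by tests and the acceptance script

Chosen once, as the package's own scaled designs:

- surface recovery: 40 subjects/group, both eyes, full 100-sample
  waveforms, default `ModelSpec` (~80 000 rows, p = 200);
- σ_b recovery: 20 replicate cohorts of 80 single-eye subjects, 25 samples
  per waveform, `k_t=12, k_fs=6`, generating σ_b = 5 µV against σ = 8 µV;
- null z calibration: 200 replicate two-group cohorts of 40 single-eye
  subjects, 15 samples per waveform, `k_t=10, k_fs=5`, reference cell
  (t = 20 ms, FS = 150 Td.s);
- deficit localization: 40 single-eye subjects/group, 30 samples,
  `b_vmax` reduced 20% in one group.

## Known limitations

- GCV (mandated for smoothing selection) estimates variance components
  poorly in data-rich-per-unit designs — see above; REML would be the
  usual remedy and is out of scope.
- Posterior SEs ignore smoothing-parameter uncertainty; pointwise coverage
  is approximate (by ~±1–2% at nominal 95% in the calibration experiment).
- The z-map is pointwise; simultaneous bands and multiplicity control are
  deliberately not provided.
- Dense linear algebra caps practical coefficient counts at a few hundred
  (ample for `k_t·k_fs ≤ ~300` plus a few hundred units).
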