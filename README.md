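# ergsurf

Surface modelling of light-adapted electroretinogram (ERG) stimulus–response
series with penalized tensor-product spline GAMs.

A light-adapted ERG protocol records the retina's voltage response to brief
flashes over a series of flash strengths (here 10 levels spanning 12–446
Troland-seconds). The classical analysis reduces each waveform to a handful
of landmarks (a-wave trough, b-wave peak) and fits amplitude–intensity laws
such as the Naka–Rushton function to those landmarks. `ergsurf` instead
models the *whole* waveform region as a smooth surface over time and flash
strength:

```
Y_ijk = β₀ + b_i + f(t_ijk, FS_ij) + ε_ijk,
b_i ~ N(0, σ_b²),  ε_ijk ~ N(0, σ²)
```

where `Y_ijk` is the sampled amplitude (µV) for recording unit `i` at flash
strength level `j` and time point `k`, `b_i` is a random per-unit intercept
guarding against pseudoreplication of repeated recordings, and `f(t, FS)` is
a tensor-product P-spline surface (cubic B-splines on uniform knots, one
second-order difference penalty per direction, sum-to-zero constrained).
All three penalty weights — time smoothness, flash-strength smoothness, and
the ridge on the random effects (λ_b = σ²/σ_b²) — are selected jointly by
minimizing the generalized cross validation criterion
`GCV = n·RSS / (n − tr(A))²` over a log-scale multi-start grid followed by
Nelder–Mead refinement. Standard errors come from the Bayesian posterior
covariance of the penalized fit, `(XᵀX + Σ λⱼSⱼ)⁻¹ σ̂²`.

From one or two fitted models the package derives the outputs a reader of
such an analysis needs:

- **surface grids** — `f̂(t, FS) + β̂₀` with pointwise SEs on a rectangular grid;
- **difference surfaces** between two independently fitted groups, with SEs
  combined in quadrature, and the pointwise **z-score map** `z = diff/se`;
- **derived waveforms** at arbitrary in-range flash strengths (the model is
  continuous in FS, so 85 Td.s or 137 Td.s work equally well);
- **extrema** (a-wave trough / b-wave peak locations) and **contour
  polylines** (marching squares) as plain data tables.

A first-class synthetic generator (`ergsurf.synthetic`) emulates the
qualitative structure of light-adapted ERG waveforms — negative a-lobe near
12 ms, b-wave rise peaking near 28 ms, decaying oscillatory-potential
ripples on the ascending limb, Naka–Rushton amplitude growth, per-subject
offsets, Gaussian noise — with a closed-form true mean, so every stage of
the pipeline is testable against exact ground truth. Its default design
reproduces the published per-flash-strength waveform counts of the study
cohort (1736 control / 1300 ASD recordings).

## Worked example

```python
import numpy as np
import ergsurf as es

design = es.DesignTable.balanced(12)           # 12 subjects/group, both eyes
params = es.SyntheticParams(n_samples=50)
data, truth = es.generate_dataset(design, params, seed=1)

model = es.fit_gam(data.subset("control"), es.ModelSpec(k_t=14, k_fs=6))
t = np.linspace(params.t_start, params.t_end, 100)
fs = np.linspace(12, 446, 50)
print(es.recovery_error(model, truth, t, fs, "control"))
```

Running `python examples/01_simulate_and_fit.py` prints:

```
simulated 480 waveforms, 24000 samples
edf = 68.0, GCV = 9.035
sigma (noise) = 3.00 uV (truth 3.0)
sigma_b (between-subject) = 2.98 uV (truth 2.0)
surface RMSE vs truth = 0.55 uV (1.5% of the 35.4 uV true amplitude range)
```

The effective degrees of freedom (~68 of 203 coefficients) show GCV chose a
genuinely smooth surface; the residual SD matches the generating noise; and
the fitted surface tracks the true mean surface to 1.5% of its amplitude
range. The other examples (`examples/02`–`04`) locate the surface extrema
(trough at ~12 ms, peak at ~28 ms), extract contour polylines, build a
two-group z-map that localizes an injected b-wave deficit to the b-wave
time band, and derive modelled waveforms at nine flash strengths.

## Command line

The same pipeline is scriptable from a shell:

```sh
ergsurf simulate --config cfg.yaml --out sim/
ergsurf fit --input sim/waveforms.csv --group control --out fit/
ergsurf surface --model fit/model.json --out out/
ergsurf diff --model-a a/model.json --model-b b/model.json --out out/
ergsurf waveform --model fit/model.json --fs "15,50,75,100,150,200,250,300,400" --out out/
ergsurf contour --model fit/model.json --levels "-5,0,5,10,20" --out out/
```

All outputs are CSV/JSON; every CSV carries a `#` provenance line (version,
seed, config hash), and runs are byte-reproducible given config + seed.

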