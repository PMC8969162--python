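# Methods

## Model and estimation procedure

The package estimates a local interstitial flow velocity *v* (µm/s) and an
effective diffusion coefficient *k* (µm²/s) for dye transport across a vessel
wall from a normalized kymograph φ(r, t), under four assumptions:

1. transport is one-dimensional along the radial axis (the wall is far more
   heterogeneous radially than circumferentially or longitudinally, and the
   flow is driven radially by the transmural pressure gradient);
2. *v* and *k* are constant over the analysis window (minutes);
3. fluorescence intensity is linear in dye concentration, so the per-row
   normalized intensity can stand in for concentration;
4. the advection–diffusion balance ∂φ/∂t + v ∂φ/∂r − k ∂²φ/∂r² = 0 holds.

Discretizing with a forward difference in time (a), a forward difference in
radius (b) and a central second difference (c), then dividing by c, maps every
interior kymograph pixel onto a point (b′, a′) = (−b/c, a/c) that should fall
on the line a′ = v·b′ + k. Estimation is a straight-line fit:

- pixels with |c| below a curvature floor are dropped (the ratios blow up);
- pixels outside a diagonal band of the kymograph are dropped (the band,
  r ∈ [(2 r_EEL/t_end)·t − r_EEL, (2 r_EEL/t_end)·t], tracks the advancing
  front and removes the flat corners where differences are pure noise);
- remaining points are screened by Stahel–Donoho projection outlyingness;
- ordinary least squares of a′ on b′ gives v (slope) and k (intercept), with
  Pearson R and its two-sided t-test p as a quality gate (fits with
  non-significant R should not be trusted).

### Discretization bias (exact result)

On the polynomial field φ = (r − vt)² + 2kt with unit grid steps the pipeline
is exactly solvable: every (b′, a′) point satisfies
a′ = v·b′ + k + v(Δr + vΔt)/2. The slope is *exact*; the intercept carries a
positive offset v(Δr + vΔt)/2 from the one-sided differences. The same
first-order analysis holds for smooth fields (a ≈ φ_t + (Δt/2)φ_tt,
b ≈ φ_r + (Δr/2)φ_rr), so fitted diffusion coefficients are systematically
high by about v(Δr + vΔt)/2 — at Δr = 2.05 µm, Δt = 1 s and v = 0.4 µm/s this
is ≈ 0.49 µm²/s, comparable to k itself. Velocity estimates are unaffected to
first order. The recovery tests therefore hold v̂ to truth directly but
compare k̂ against the bias-corrected expectation.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| pixel size Δr (native) | 0.41 | µm/px | acquisition resolution, both axes |
| resampled frame step Δt | 1 | s | uniform clock for differencing |
| α | 0.005 | — | arrival threshold as a fraction of the dynamic range of the mean wall intensity |
| t_MA | 10 | s | trailing moving-average window for plateau detection |
| β | 1 | intensity/s | plateau threshold on the moving-average increment, in raw intensity units of the input (bit-depth dependent) |
| radial block factor | 5 | — | one-fifth reduction → analysis Δr = 2.05 µm |
| c_min | 1e-4 | 1/µm² | curvature floor on normalized intensity |
| SD quantile | 0.999 | — | χ²(df=2) quantile; cutoff = √χ²₀.₉₉₉ ≈ 3.72 on outlyingness |
| ε (normalization guard) | 1e-6 × range | intensity | rows with smaller plateau magnitude are excluded |

The analysis-window constants (α, t_MA, β) and the block factor are the
method's standard operating values; c_min, the SD quantile and ε are numerical
guards with no analogue in the lab procedure and are configurable.

## Numerical choices

- **Moving average**: trailing window of exactly t_MA samples inclusive of the
  current one; the average is undefined for the first t_MA − 1 samples, and
  t_end is the first time after t_start with two defined averages whose
  difference falls below β. Ties in the arrival threshold resolve to the
  earliest time; the threshold comparison is inclusive (≥).
- **Stahel–Donoho outlyingness**: max over projection directions of
  |projection − median| / (1.4826·MAD). For n ≤ 500 the direction set is all
  point-pair differences (exact for this criterion and fully deterministic);
  above that, 1000 random unit directions from a seeded generator. A direction
  with zero MAD assigns infinite outlyingness to points off the common median
  and zero to points on it, so a point displaced orthogonally off a perfectly
  collinear cloud is always caught. Points whose squared outlyingness exceeds
  the χ² quantile (df = dimension) are flagged.
- **Regression**: OLS of a′ on b′ even though both coordinates are noisy —
  this reproduces the method as practiced. A Deming mode (unit variance
  ratio) exists but is off by default.
- **Negative fitted k** is reported as-is with a warning rather than clamped.
- **Degenerate inputs**: constant fields and linear ramps have c ≡ 0 and yield
  zero usable samples → the fit raises instead of returning garbage; a
  zero-variance b′ scatter raises "degenerate scatter".
- **Drift correction**: whole-frame plain cross-correlation (not phase
  normalization) against a fixed reference frame; integer-pixel shifts by
  default with optional upsampled subpixel refinement. Pixels rolled in from
  outside the field of view are masked and excluded from all later averages.
- **Polar unwrapping**: the lamina circle comes from manually measured chord
  and camber via the sagitta relation; sampling is bilinear along
  constant-radius arcs with one-pixel arc-length steps at the fitted radius;
  out-of-grid samples are masked.
- **Temporal resampling**: linear interpolation between the two bracketing
  frames, clock rebased to the first frame, no extrapolation.
- **Order of operations**: crop to media → radial block-average → background
  subtraction → per-row normalization. θ-averaging happens before any of
  these, after the 1-s resampling.

## Per-layer analysis

Layer windows (EL1–3, SML1–3) are 5–10 native pixels (~2–4 µm) taken from
user annotations; automatic lamina segmentation is out of scope. Each window
is analysed at native radial resolution (a one-fifth reduction of a 5–10 px
window would leave fewer than the 3 rows the second difference needs), and —
a deliberate design choice — the arrival/plateau detection is rerun on the
window's own mean-intensity trace: the dye sweeps past an inner lamina long
before the whole wall saturates, and reusing the whole-media window would
leave inner windows dominated by post-transit plateau pixels whose gradient
ratios are pure noise (verified on two-zone synthetic fields, where it
collapses the fitted slope). When a window never plateaus before the parent
kymograph ends, its end time falls back to the parent's. The normalized
depth d of a window is taken at its midpoint. Elastic-lamina fits are flagged
low-confidence by default — dye binds preferentially in the laminas, which
violates the intensity–concentration assumption there — and only SML windows
enter the d–v radial trend (Pearson R with t-test).

## Synthetic data generator

The generator solves the same 1-D PDE forward — explicit first-order upwind
advection (CFL ≤ 1 enforced) split with Crank–Nicolson diffusion
(unconditionally stable), on a grid 4× finer than the native pixel grid to
avoid inverting the same discretization that is being fitted — then renders
an image stack: radial block-average to 0.41 µm pixels, linear sampling onto
a 3-second frame clock, replication across θ, multiplicative stripe gains at
elastic-lamina bands (emulating the extra dye binding), optional
depth-dependent attenuation toward the intimal side, a constant offset,
seeded Gaussian noise scaled to the amplitude, optional per-frame drift, and
integer quantization at the configured bit depth.

Boundary conditions (not part of the inverse problem and chosen to match the
experiment): lumen-side concentration held at 1 from the start of the
analysis (dye-filled lumen), adventitia-side zero gradient. A fully closed
(no-flux) variant exists for conservation checks; total concentration is then
conserved to 1e-10 relative. The default wall is 41 µm (≈100 native pixels)
with v = 0.4 µm/s, k = 0.4 µm²/s, 32 θ-columns, amplitude 1000 at 12-bit —
θ-width and amplitude are compute-scaled stand-ins for the 512-column
acquisition; tests that need acquisition-grade SNR (thin layer windows) raise
them to 512 columns and amplitude 3000, which is the realistic setting.

What the generator does **not** emulate: optical point-spread blurring,
depth-dependent scattering beyond the linear attenuation option, detector
shot-noise statistics (Gaussian only by default), wall viscoelastic motion,
and any θ- or z-heterogeneity. Passing recovery tests therefore demonstrate
correctness of the estimation chain under the stated transport model, not
robustness to every optical artifact of a real two-photon acquisition.

Presets: `aorta-40mmHg` (v = 0.23, k = 0.24) and `aorta-120mmHg`
(v = 0.40, k = 0.35) use group-mean transport parameters at those pressures
as realistic simulation settings; `pure-diffusion` uses a thinner (20.5 µm)
wall and a 16-bit dynamic range so that the plateau detector only fires once
diffusion has genuinely saturated the wall (see limitations); `null` (v = k
= 0) exercises the degenerate-field error path.

## Known limitations

- **Intercept bias**: k̂ is high by ≈ v(Δr + vΔt)/2 (see above). This is a
  property of the one-sided discretization, not of the implementation.
- **Diffusion-dominated truncation bias**: the analysis ends when the mean
  intensity plateaus (β). If transport is diffusion-dominated (Péclet number
  ≲ 10) the far wall is still unsaturated at that point, and the per-row
  normalization then divides by a radially varying profile g(r); this injects
  an effective spurious velocity ≈ 2k·|g′/g|. With flow-dominated transport
  (the regime the method targets) g is flat and the effect vanishes. The
  recovery grid's slowest corner (v = 0.05, k = 0.4, Pe ≈ 5) shows exactly
  this failure mode; the recovery checks report the median error across the
  grid, which absorbs it.
- **Thin-window attenuation**: 5–10 px layer windows estimate v with a
  low bias of up to ~20–30 % (short transit, narrow b′ leverage), strongest
  for the window nearest the IEL; ordering and trends across windows are
  reliable well before absolute values are.
- **Steel–Dwass asymptotics**: the asymptotic mode applies a half-step
  continuity correction before the studentized-range (df = ∞) lookup. Against
  the exact joint-permutation null at three groups of five, tail p-values
  (p ≲ 0.25) agree to ~0.01; mid-range p can deviate by up to ~0.04. The
  exact mode (full enumeration, feasible to ~2·10⁶ partitions) is preferred
  for small samples.
- **Post-hoc dataset exclusion** (e.g., non-significant a′–b′ correlation, or
  physically damaged tissue) is exposed as the `significant` flag on a fit,
  not automated: it is experimental judgment.

## Problem sizes used in tests and the acceptance script

Recovery runs use the default 41 µm wall at Δr = 2.05 µm and Δt = 1 s after
processing, over v ∈ {0.05, 0.2, 0.4, 0.6} µm/s × k ∈ {0.1, 0.4} µm²/s with
1 % noise (and a noiseless repeat); the pressure series uses
v ∈ {0.1, 0.2, 0.4, 0.6} at k = 0.3. Outlier-oracle checks use point sets of
8–20; the exact Steel–Dwass enumeration uses three groups of five (756 756
partitions). These sizes keep every check exact or statistically
well-resolved while running in seconds.
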