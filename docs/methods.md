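# Methods

## The line-FRAP recovery model

A line-FRAP experiment scans a high-intensity line across a supported lipid
bilayer, irreversibly bleaching fluorophores with a Gaussian dose profile of
peak `K0` and e⁻² radius `r0e` (µm), then measures the fluorescence of a
thin line ROI through an imaging PSF of e⁻² radius `r0c` as unbleached
molecules diffuse back in. For first-order irreversible bleaching and free
lateral diffusion with coefficient `D` (µm²/s), the normalized recovery has
the closed series form

    F(t)/F0 = Σ_{n≥0} (−K0)ⁿ/n! · r0e · (n·r0c² + r0e² + 8nDt)^(−1/2)

`linefrap.model.recovery_fraction` evaluates this sum with a recursive term
update (no factorials or powers are ever formed), stopping when the next
term falls below `rel_tol` (default 1e-10) times the partial sum or at
`n_max = 200` terms; non-convergence raises an error carrying the bound on
the truncation residual (the series is alternating). The series is an exact
consequence of the microscopic picture implemented in the simulator —
survival probability `exp(−K0·exp(−2y²/r0e²))`, one-dimensional diffusion
across the line, detection weight `exp(−2y²/r0c²)`; the term-by-term
Gaussian integrals reproduce the radicand `n·r0c² + r0e² + 8nDt` exactly.
The model predicts the line-averaged signal only; no profile along or
across the line is produced.

Mobile-fraction and multi-species recovery use

    F_obs(t) = F_post0 + k · (M(t) − M(0)),    M(t) = Σ_j w_j F(t; D_j)/F0

with the mixture weights `w_j` on the simplex and `k ∈ [0, 1]` the mobile
fraction. The printed form of the mobile-fraction relation in the
literature is self-referential (the same symbol on both sides); the
implementation adopts the standard reading — the right-hand recovery is
the model prediction, the left-hand side the observed signal, and `k`
scales only the recovering part — so `k = 0` freezes the signal at
`F_post0` and `k = 1` with `F_post0 = M(0)` reduces to the pure diffusion
model. The long-time plateau is `F_post0 + k(1 − M(0))`.

A first-order truncation `1 − K0·r0e/√(r0c² + r0e² + 8Dt)` is provided as
an analytic cross-check. Its leading neglected term is ≈K0²/2, so it is
accurate to ~1% only for `K0 ≤ 0.13` and ~2% at `K0 = 0.2` (measured
against the 50-digit reference); the docstring and tests state the measured
domain.

Units are µm, s and µm²/s throughout. Time zero is the first post-bleach
sample; bleaching is treated as instantaneous (no bleach-duration model, no
reversible photobleaching, no bleaching-during-imaging correction).

## Fitting

`fit_line_frap` minimizes unweighted least squares of the multi-component
model against a normalized curve, parameterized in `log10 D` with the
mixture weight, mobile fraction and `F_post0` free and the beam constants
(`K0, r0e, r0c`) fixed at calibration values by default (`K0` co-fittable
via `fix_beam=False`). Multi-start over a log-spaced grid of starting
coefficients ({0.1, 1, 10, 100} µm²/s, crossed over components) with a
deterministic seed-controlled jitter; the best objective wins, ties broken
by the smaller total |log D|. Standard errors come from the Gauss–Newton
curvature at the optimum; no bootstrap by default. Requires ≥ 8 post-bleach
samples for one component, ≥ 15 for two. A coefficient landing on the
`D_bounds` box sets a boundary flag; `k = 1` or `F_post0` at their natural
physical limits deliberately do not, since fully mobile specimens are the
common case.

Two-component decompositions of membrane + free-dye curves are weakly
identifiable when the membrane recovery is itself multi-scale (obstructed
diffusion): the optimizer can merge the dye with the fast membrane
timescale into a component below the classification threshold. Real
experiments resolve this with an independent calibration — free dye in
buffer is measured once and known to diffuse far faster than any membrane
probe. `FitOptions.fast_D_min` encodes that calibration by partitioning the
D range between the two components; `run_batch` applies it by default using
the classification threshold as the split. The unconstrained fit remains
the default for `fit_line_frap` itself and is what the parameter-recovery
tests exercise.

The empirical backend `fit_double_exponential` fits
`plateau − A1·e^(−λ1 t) − A2·e^(−λ2 t)` (rates positive, amplitudes
non-negative), initialized by log-linear regression on the tail and
multi-started over the fast-rate guess. Rate collapse (λ1/λ2 < 1.5) or an
amplitude collapse (< 1% of the recovery) flags the result
single-component; in the amplitude-collapse case the significant component
is reported first. `rates_to_diffusion` converts rates by the line-FRAP
timescale `D = λ·r0e²/8`, with the factor exposed for calibration. On
single-species closed-form curves the double exponential consistently puts
the diffusion timescale in the *faster* rate (conversion lands ≈18% low,
within a measured 30% band); the slow exponential tracks the t^(−1/2)
recovery tail and does not estimate D. Neither backend is presumed
canonical; they are compared in the tests.

Components with `D` above a configurable threshold (default 10 µm²/s,
between membrane-probe values of ~1 µm²/s and reported free-dye values of
tens of µm²/s) are labelled `free_dye` and excluded from membrane
statistics, mirroring the practice of neglecting the fast coefficient
attributed to unbound fluorophore in the buffer.

## Image pipeline

Stacks are (T, H, W) single-channel TIFFs (uint16 camera data; float32 for
noise-free synthetic references, since 16-bit quantization would destroy
float-precision round trips) with a JSON sidecar carrying
`frame_interval_s`, `pixel_size_um` and optionally the bleach frame and a
non-uniform time grid; missing metadata is an explicit error. Coordinates
are 0-based and row-major with half-open column ranges; the bleach line
lies along x, profiles vary along y; `bleach_frame_index` is the last
pre-bleach frame, and the generator applies the bleach at the acquisition
time of the next frame so the first post-bleach sample is exactly t = 0.

Extraction: `F_pre` is the mean background-subtracted ROI intensity over
all pre-bleach frames; post-bleach values are divided by it. Background is
the per-frame mean of a user-supplied far-field ROI. Optional photofading
correction divides each frame by a fading ROI's intensity relative to its
own pre-bleach mean; it is off by default (synthetic validation shows
plateau bias without it when fading is injected, so it is provided, but no
fading model is assumed in the data). Bleach-frame detection takes the
largest single-frame drop in ROI intensity (earliest on ties) and requires
it to exceed 3× the pre-drop frame-to-frame standard deviation.

`estimate_bleach_resolution` exploits that for irreversible Gaussian-dose
bleaching the *log* intensity ratio across the line is exactly Gaussian:
`−log(I_post/I_pre) = K0·exp(−2(y−y0)²/r0e²)`. Fitting in log space stays
accurate at deep bleaches where the intensity dip itself is visibly
non-Gaussian. The detection PSF broadens the estimate by ~2.5% at
`r0c/r0e = 0.25` (measured on the noise-free forward profile); the fit
quality (R²) is reported and degrades gracefully as the dose vanishes.

## Synthetic data

The simulator is the package's independent oracle: 2D Brownian particles in
a reflecting square box (side ≥ 10·r0e, ROI centered), per-axis step
variance `2·D·dt`. Species without obstacle interactions advance with a
single exact Gaussian increment per frame interval — Brownian increments
are exactly Gaussian at any lag, and coordinate folding reproduces the
reflected process at the frame times — so no sub-stepping error exists for
them. Membrane particles in a domain-carrying membrane are sub-stepped
(`dt ≤ r0e²/40D` enforced) and reflect off impermeable discs by mirroring
across the circle, with rejection as the fallback for doubly-blocked moves
(numba-compiled).

Gel/ordered domains are non-overlapping discs on a jittered square lattice
(one disc per cell, so point-in-domain lookups inspect a 3×3
neighbourhood); the realized area fraction equals the request exactly by
construction. Temperature enters only as a label mapped to a domain area
fraction — no lipid phase thermodynamics is modelled. Free dye diffuses in
the same 2D plane with a larger D rather than in 3D, a deliberate
flattening of the buffer compartment that keeps the oracle two-dimensional;
it ignores domains (it is not in the membrane).

Bleaching draws per-particle Bernoulli flags from the survival probability
`exp(−K0·exp(−2y²/r0e²))`; the probability itself is also returned and
serves as a variance-reduced expected-fluorescence weight.
`brute_force_recovery` measures the PSF-weighted ROI signal directly from
positions, normalized either per frame by the bleach-ignored control signal
(a control variate that cancels density shot noise; the pre-bleach mean is
exactly 1) or classically by the pre-bleach mean. Rendering bins particles
onto the pixel grid, convolves with a pixel-integrated Gaussian PSF of e⁻²
radius `r0c`, scales to photons per particle, and applies Poisson plus
Gaussian read noise with 16-bit clipping (saturation above 1% of pixels is
reported). Passing survival probabilities instead of flags renders the
bleach-ensemble expected image — the fully noise-free limit used for
ground-truth curves. Every stochastic operation is a pure function of
(config, seed); datasets regenerate bit-exactly.

### What the generator emulates — and does not

It reproduces the statistical structure the analysis assumes: a slow
labelled-lipid species plus a fast free-fluorophore species (the
paper-like default: D = 1 and 30 µm²/s, 20% of signal in the dye,
K0 = 0.5, r0e = 1 µm, r0c = 0.25 µm, 60 frames), an optional immobile
fraction, Gaussian line bleach, imaging PSF, Poisson detection, and
probe-excluding domains whose area fraction falls with nominal temperature
(0.35/0.20/0.05 at 22/30/38 °C in the trend scenario; 0.5/0.1 mixed within
every condition in the gel scenario). It does not emulate: 3D dye
diffusion in buffer, bleach duration or reversibility, stage drift,
partitioning of probe into ordered phases (domains are perfectly
excluding), membrane undulations, or detector nonlinearity. Passing tests
therefore validate the analysis chain under these idealizations, not
instrument-specific artifacts. No acquisition rate, bleach dose or laser
geometry is published for the motivating experiments; all scenario numbers
are declared fixture choices, not reconstructions.

## Condition-series analysis

`run_batch` fits every curve in a manifest (two components with the
free-dye partition by default), classifies components, aggregates the
weight-weighted mean of membrane components per curve, and reports
per-condition mean ± SD over line scans with n (SD only for n ≥ 2;
mean/SD over curves, not frames). Non-converged fits, fits with a
coefficient on the D bounds, and curves with no membrane component are
excluded with logged reasons; per-curve failures never abort a batch.

`trend_test` is descriptive: Kendall rank correlation between temperature
(ordinal) and per-curve membrane D, pooled across conditions, plus a flag
for strictly increasing per-condition means. The verdict is "increasing"
only when the means are monotone AND the correlation is positive AND
clearly distinguishable from zero (one-sided p < 0.01). The p-threshold is
a guard, not a headline test: with only three conditions, exchangeable data
produce accidentally monotone means about one time in six, and an
unguarded monotonicity rule would flag spurious trends. No p-value is
reported as a result.

## Desk-scale validation experiments (`linefrap.validation`)

Problem sizes were chosen once as the package's study conditions:

- Series reference: 50-term, 50-digit decimal summation straight from the
  factorial definition (independent of the recursive float path); 3×3×3
  grid of (K0, D, t).
- Simulator oracle: 10⁵ particles, 12 µm box, 20 post-bleach frames at
  0.2 s, K0 ∈ {0.1, 0.5} × D ∈ {0.3, 1, 3} µm²/s, variance-reduced
  survival weights and per-frame control normalization. Finite-box image
  effects at this geometry are below 10⁻³.
- Parameter recovery: 12 replicate curves at ~2% Poisson noise per point
  (2500 photons/point); K0 = 1 bleach depth (typical FRAP contrast);
  geometric grids 0.02–20 s (50 points, single component) and
  5·10⁻⁴–20 s (80 points, two components, so the 4 ms halftime of the
  fast species is sampled). Medians over replicates are reported.
- Condition series: 12 curves per condition, 60 000 particles per curve
  (48k membrane + 12k dye), K0 = 1, geometric post-bleach sampling
  2 ms–6 s, per-frame control normalization.
- Pipeline identity: 12 replicate noise-free stacks of 10⁶ particles in a
  10 µm box; extraction identity is checked per replicate and the averaged
  curve is fitted. A single acquisition carries ~2% D scatter purely from
  the realized particle configuration in the bleached region (measured;
  the ensemble mean is unbiased to < 0.1%), so replicate series are
  averaged before fitting exactly as in experimental practice.

## Numerical choices and degenerate inputs

- Series domain check: results outside (0, 1] beyond 10× the truncation
  tolerance raise an invalid-parameter error; sub-tolerance excursions
  above 1 are clipped. Nothing is silently clamped.
- Constant (no-recovery) curves raise a degeneracy error in the
  double-exponential backend rather than returning junk rates.
- Tie-breaks: bleach detection takes the earliest maximal drop; multi-start
  ties take the smaller total |log D|.
- Report bytes are deterministic (sorted keys, fixed float formatting) so
  identical manifests + seeds reproduce identical reports.

## Known limitations

- The closed-form model assumes free diffusion; in obstructed membranes the
  fitted D is an effective coefficient whose mapping to the domain fraction
  is qualitative (monotone), not quantitative.
- The free-dye constraint (`fast_D_min`) presumes the calibration is right;
  a genuinely intermediate membrane component faster than the threshold
  would be mislabelled.
- Mobile fraction and slow components trade off on short acquisitions; the
  plateau must be reasonably sampled for `k` to be identifiable.
- The rate-to-D conversion for the empirical backend is a convention with a
  measured ~18% systematic; use the closed-form backend for quantitative D.
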