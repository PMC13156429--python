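# Methods

## Signal model and stepwise fit

The diffusion-weighted signal is modeled as biexponential in the b-value:

    S(b) = S0 [ F exp(−b D*) + (1 − F) exp(−b D) ],

with `0 ≤ F ≤ 1` and `0 < D ≤ D*`. Fitting is segmented for robustness:

1. **Diffusion step.** For b ≥ 200 s/mm² the perfusion compartment has
   decayed to a few percent, so `ln S` is approximately linear in b. `D`
   and the extrapolated high-b intercept come from ordinary least squares
   on `ln S` restricted to those points — exact for monoexponential data.
2. **Perfusion step.** `(S0, F, D*)` are then estimated over *all*
   b-values by bounded trust-region nonlinear least squares
   (`scipy.optimize.least_squares`, method `trf`, analytic Jacobian) with
   `D` frozen. Bounds: `F ∈ [0, 1]`, `D ∈ [1e-5, 4e-3]` mm²/s,
   `D* ∈ [D, 0.5]` mm²/s (enforcing `D* > D`), `S0 ≥ 0`. Initialization:
   `S0` from the b = 0 sample, `F = 1 − S0_high/S0` clipped to `[0, 0.5]`
   (the step-1 intercept estimates the non-perfusion fraction), `D*` at its
   physiologic prior 10e-3 mm²/s. The perfusion step refits `S0` rather
   than pinning it to the b = 0 sample, so measurement noise at a single
   point cannot bias `F`.
3. **Refinement.** The residual perfusion tail at b ≥ 200 biases the
   one-pass `D` high by up to ~5 % relative (at `F ≈ 0.1`,
   `D* ≈ 10e-3`), which leaks into `F` and `D*`. `fit_ivim_map` therefore
   iterates: subtract the fitted perfusion compartment from the high-b
   signal, re-estimate `D`, and repeat the perfusion step (warm-started at
   the previous optimum). The iteration converges linearly (ratio ≈ 0.4
   at typical tissue contrast), so after `n_refinements = 3` passes an
   Aitken Δ² extrapolation of the last three `D` iterates jumps essentially
   to the fixed point before a closing perfusion fit. Because the
   contraction slows where `D*/D` contrast is poor (CSF-like voxels), a
   cheap residual check after the closing fit — re-estimate `D` once more
   and compare at 1e-4 relative — triggers up to three further cycles for
   those voxels only. With `n_refinements = 0` the plain two-step
   estimator is retained.

Goodness-of-fit is reported as nRMSE = RMS(residual) / mean(observed
signal over all b-values). The mean-signal normalizer makes the metric
invariant to a global intensity gain and comparable across voxels; range
normalization was the considered alternative and differs only by a
voxelwise constant factor for fixed b-sampling.

Non-converged voxels keep their initialization values, are flagged, and
are excluded from downstream calibration sums rather than zero-filled —
zeros would silently deflate the conversion factor.

Brain masking thresholds the b = 0 volume at 20 % of its 99th-percentile
intensity and keeps the largest connected component. Brain volume is the
voxel count times the voxel volume. A denoising hook (any
volume-to-volume transform) can be applied before fitting; the default is
identity.

## Calibration to absolute units

Vessel lumina are segmented on the velocity cine by pulsatility: the
lumen is the connected component around an arterial seed pixel of pixels
whose velocity-vs-cardiac-phase waveform has Pearson correlation ≥ 0.85
with the seed's waveform. Flow is the cycle mean of
Σ velocity × pixel-area over the lumen (cm/s·mm² = 0.6 mL/min), signed,
and tCBF is the sum over L/R internal carotid and vertebral arteries.
Normalized tCBF = tCBF / (brain volume × 1.06 g/mL) × 100, in
mL/100 g/min.

Assuming rCBF is linear in FD*, the conversion factor is taken as
normalized tCBF divided by the **brain-mean** FD* over converged voxels,
and the rCBF map is conversion × FD* voxelwise. This reading distributes
the measured total flow over voxels proportionally to FD*: the brain mean
of the calibrated map equals normalized tCBF exactly (a conservation
property asserted to 1e-10 in the tests), and any global gain in the DWI
signal chain cancels. Normalizing by the brain *sum* of FD* instead would
shrink every voxel by the voxel count and cannot yield physiologic
magnitudes; the calibration JSON records the adopted reading.

## ASL reference

The standard single-compartment pCASL model:

    rCBF = 6000 λ exp(PLD/T1b) / [2 α T1b (1 − exp(−τ/T1b))] · ΔM/S_PD

with λ = 0.9 mL/g, T1b = 1.65 s, PLD = 1.525 s, τ = 1.8 s, α = 0.85 by
default; all times are converted to seconds on ingestion (the 6000 factor
presumes seconds). At the defaults the scale factor is ≈ 7305
(mL/100 g/min per unit ΔM/S_PD). Negative voxel values (noise-driven) are
retained but flagged out of ROI statistics only when the PD signal is
non-positive, matching common ASL practice.

## Evaluation metrics

* Tissue ROIs: probability maps thresholded at 0.9 (inclusive).
* ROI statistics: mean and SD (n − 1) over valid voxels only; `n_voxels`
  is reported so exclusions are auditable.
* Jensen–Shannon divergence between voxel-value histograms on 64
  equal-width bins spanning 0–150 mL/100 g/min, log base 2 so the range
  is [0, 1]; samples outside the range are clipped into the edge bins,
  zero-count bins follow 0·log 0 = 0. Voxel-value histograms (not
  spatially binned maps) are compared.
* Bland–Altman: bias = mean(x − y), limits = bias ± 1.96 SD (n − 1).
* Spearman rank correlation with average ranks for ties (scipy).
* Scheme comparison: Friedman omnibus plus three pairwise Wilcoxon
  signed-rank tests with Bonferroni factor 3 (delegated to scipy).

## The phantom

A concentric-shell head at desk scale: CSF rim, gray-matter shell,
white-matter core on an ellipsoid, default 48×48×24 voxels of 2×2×6 mm
(~500 mL of brain; the test cohort uses 24×24×12, ~63 mL, to keep run
times in minutes). Tissue truth: D = 0.8/0.7/2.0 ×10⁻³ mm²/s and
F = 0.12/0.06/0.02 for GM/WM/CSF, D* = 10×10⁻³ mm²/s, modulated by a
smooth multiplicative texture field (15 % relative SD, the order of real
regional perfusion variability) so intra-tissue distributions have
realistic width. True rCBF is proportional to F·D* and scaled so the
brain mean equals the configured whole-brain perfusion (default
50 mL/100 g/min); the four vessel flows are the consistent split of the
implied tCBF (35/35/15/15 %).

**Bulk motion** is modeled as intravoxel/shot-to-shot phase dispersion
producing deterministic magnitude attenuation `exp(−σφ²/2)` with
`σφ = √b (c1 w1 σv + c2 w2 σa)`, where `(w1, w2)` are the residual
first/second gradient-moment weights of the scheme — (0,0) for
second-order compensation, (0,1) for first-order, (1,1) for none — and
`(σv, σa)` are per-voxel velocity/acceleration dispersions. Deep
(periventricular) tissue receives larger σa than cortex, making the
corruption spatially structured; after the scheme-independent part of the
attenuation is absorbed by the calibration's mean normalization, it is
exactly this structure that distorts the rCBF distribution. Magnitudes
(σv = 0.25 cm/s, σa = 1.0/2.5 cm/s² cortex/deep, c1 = 0.1, c2 = 0.03)
are set so uncompensated gradients show pronounced deep-tissue
hyperperfusion artifacts — strong enough to visibly degrade fitting and
destroy white-matter correlations — while staying short of saturating the
fit bounds over most of the brain. The model deliberately omits EPI
distortion, eddy currents, k-space effects, and scheme-dependent
diffusion times (truth is scheme-independent, a stated simplification).

**Noise** is Rician: complex Gaussian channels added to the clean signal,
magnitude taken per excitation, then NSA magnitudes averaged (matching
scanner averaging of magnitude reconstructions). The synthesized series
stands for a trace of three orthogonal directions, so a raw per-image SNR
of ~50 corresponds to a trace noise sigma of ~2/√3 ≈ 1.2 at a tissue
b = 0 signal of ~100 — the cohort default, with NSA = 2.

**Phase contrast**: each artery gets a 64×64 cine with a circular lumen
carrying a spatially uniform raised-cosine waveform whose cycle mean
reproduces that vessel's true flow exactly on any uniform phase grid;
only the cycle mean matters to tCBF, so the waveform shape is free. The
pixel area is auto-scaled so the ICA cycle-mean velocity sits at a
physiologic ~17 cm/s regardless of phantom scale (desk-scale flows
through real-size lumina would give sub-cm/s velocities that drown in
velocity noise). Background pixels carry zero-mean velocity noise;
values are clipped to venc = 80 cm/s with a warning.

**ASL**: the triplet is constructed to invert exactly — PD is flat in the
brain, control − label = rCBF·PD/K — with optional Gaussian noise.

What passing phantom tests do *not* show: robustness to real-data
features the phantom lacks (registration error, susceptibility
distortion, partial-volume mixtures beyond smoothing, arterial transit
effects, D* anisotropy, scheme-dependent diffusion times).

## The synthetic cohort

Eight subjects per study; per subject, whole-brain perfusion ~ N(50, 5)
mL/100 g/min, GM/WM perfusion fractions jittered 10 % relative, motion
dispersions scaled uniformly in [0.9, 1.3], independent noise seeds. Each
subject is analyzed under all three gradient schemes with a shared
phase-contrast tCBF. Before fitting, the DWI passes through the local-PCA
denoising hook (3³ patches, rank 4; see `mcdip.denoise`) mirroring the
denoise-then-fit structure of the analysis chain — without it,
white-matter FD* estimates are noise-dominated and scheme differences
drown. Gaussian smoothing was rejected for this role: at desk scale it
blurs the thin CSF rim into gray matter and inflates CSF's apparent
perfusion fraction several-fold, which corrupts the calibration mean;
patch-PCA suppresses noise without mixing voxel means across edges.
Reported per subject and scheme: WM/GM mean nRMSE over converged ROI
voxels, JSD between the calibrated rCBF map and ground truth per tissue,
and GM/WM mean rCBF. Expected pattern: corruption metrics order
second-order < first-order < uncompensated, and the correlation of
scheme-wise WM means with truth is highest for second-order compensation.

## Numerical choices and degenerate inputs

* Solver tolerances 1e-12 (ftol/xtol/gtol), max 300 function evaluations;
  non-convergence flags the voxel instead of raising.
* Geometric-mean trace: a zero in any direction maps the voxel to zero
  with a logged warning.
* Log-linear D estimates are clamped to the bounds; constant high-b
  signal lands on the lower bound.
* Pulsatility segmentation with a constant seed waveform, an empty brain
  mask, zero total FD*, or an all-zero b0 volume raise descriptive errors.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; cohort subject seeds derive from the base seed, and regenerating
  any phantom with the same (shape, seed, config) is bit-identical.

## Known limitations

* The motion model is phenomenological; its coupling constants are not
  calibrated to physical units of brain-tissue displacement.
* The calibration conserves the brain mean by construction, so any
  region-specific corruption redistributes flow between tissues rather
  than adding to it — GM means drop when WM FD* inflates. This mirrors
  the method's real behavior but means tissue means are not independent.
* Triexponential IVIM, Bayesian/spatially regularized fitting,
  multi-delay ASL, and phase-unwrapping beyond venc clipping are out of
  scope.
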