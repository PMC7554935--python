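# Methods

This note documents the models, numerical conventions and design choices
behind `xetof`, and what the synthetic validation studies do and do not
demonstrate.

## Uptake model and its assumptions

A voxel is modelled as a sum of independent one-compartment systems fed by a
common arterial input. After the saturation pulse the dissolved-phase
magnetization of compartment *c* follows

    dM_c/dt = (f_c/60)·m_a0·e^(−t/T1b) − k_c·M_c,  k_c = (f_c/60)/λ_c + 1/T1t_c

whose closed form is implemented in `kinetics.analytic_uptake` (with the
L'Hôpital limit form substituted when |k − 1/T1b| < 1e−10 s⁻¹, keeping the
solution continuous across the removable singularity). Assumptions: the
arterial input decays purely by blood T1 (no dispersion, no recirculation);
the hyperpolarized state is never regenerated; venous outflow carries
tissue-equilibrated xenon (the f/λ term); compartments do not exchange with
each other.

The short-time linearization `M ≈ (Σf/60)·m_a0·τ` upper-bounds the exact
solution and underestimates it by a relative ≈ (1/T1b + k)·τ/2 at delay τ;
an ordinary-least-squares slope over a delay window centered at τ̄ is biased
by ≈ −(1/T1b + k)·τ̄. With the literature defaults (T1b = 8 s, T1t = 16 s,
λ = 0.9) this is −4% at τ̄ = 0.2 s but ≈ −65% at the multi-second in vivo
delay presets — the known price of the linear model at long TOF, which
the method accepts in exchange for a three-point breath-hold protocol.
The validation studies therefore run at delays 0.1/0.2/0.3 s, inside the
regime where the model's own assumptions hold; the in vivo delay triples
are shipped as presets for realistic protocol simulation, not for unbiased
quantification.

Units: perfusion is stored in mL·mL⁻¹·min⁻¹ throughout; all kinetics run on
a seconds time base with a single explicit ÷60 conversion
(`kinetics.SECONDS_PER_MINUTE`), tested once.

### Calibration

The proportionality between an SNR slope and absolute perfusion is isolated
in one scalar, `s_arterial`: the SNR a voxel fully occupied by fresh
arterial blood would show. `F = 60·slope/s_arterial`. For simulated data
the ground-truth value is computable
(`phantom.arterial_reference_snr` = m_a0·w_DC/(σ_k·√(2−π/2)), where w_DC is
the flip-angle depletion weight of the central k-space line — the effective
amplitude of smooth image features — and the zero-padding amplitude factor
cancels between signal and noise). For real data it is a user-supplied
calibration constant.

## Synthetic-data generators

**Flow phantom** (`phantom.simulate_flow_curve`): a 3.175 mm ID tube with a
20 mm coil-sensitive length (chosen so the sensitive volume refills on the
1–2 s scale over the 5–10 mL/min pump range, reproducing the observed
early saturation of the fastest flow), plug or laminar velocity profile,
plateau signal `s_max`, additive Gaussian noise of 1% of `s_max` per point
(plateau SNR 100, matching visibly smooth measured curves). The laminar
closed form is the radial average of `min(v(r)·τ, L)` with
`v(r) = 2v̄(1−(r/R)²)`: equal to the plug curve until the axial spins exit
(τ = L/2v̄), then `1 − L/(4v̄τ)`, approaching the plateau only
asymptotically. What it does *not* emulate: Taylor dispersion, inflow T1
decay of the xenon-saturated saline, coil sensitivity profiles — so the
simulated plateau is sharper than a measured one.

**Brain phantom** (`phantom.brain_phantom`): an outer "cortex" ellipse of
gray matter (f = 0.55), a deep white-matter core (f = 0.22), and optionally
a posterior gray-matter patch with fractionally increased perfusion (the
"activation"). Values are literature-derived defaults, exposed in
`presets.KINETICS_PRESETS`. Masks are disjoint by construction and validated.

**Acquisition forward model** (`phantom.simulate_tof_series`): per-pixel
analytic uptake at each delay, centered unitary 2-D DFT, per-line depletion
weight `sin α · cos^j α` for the j-th acquired phase-encode line (linear or
centric ordering; the saturation pulse resets magnetization between
dynamics, so depletion acts within a dynamic only), plus seeded complex
Gaussian noise per k-space sample. Identical (phantom, acquisition, seed)
triples are bit-reproducible. Not modelled: off-resonance/chemical shift,
T2* decay during readout, motion, coil sensitivities.

## Reconstruction conventions

* DFT normalization is unitary (`norm="ortho"`); Parseval holds with unit
  constant and is pinned by a test.
* k-space is FFT-shift centered with DC at index N//2 on each (even) axis;
  zero-padding (default 20×20 → 32×32) inserts zeros symmetrically with any
  odd remainder on the high-frequency side, and pad∘crop is exact.
* Complex k-space noise makes magnitude backgrounds Rayleigh-distributed
  (std = σ·√(2−π/2)); SNR maps divide by the *plain* standard deviation of
  the chosen noise region — no Rayleigh correction by default, matching the
  plainly-described processing chain — with `rayleigh_correction=True`
  available to rescale to the per-component σ.
* Noise-region practice matters more than the correction: the truncated
  k-space of a sharp object leaks sinc/Gibbs sidelobes far into the
  background, and the depletion apodization smears signal along the
  phase-encode axis. In the 20×20 phantom the sidelobe std near the object
  equals the noise std at realistic SNR. The validation studies therefore
  estimate noise on four image-corner squares, from the first (shortest
  delay, lowest signal) dynamic, shared across the stack — the noise level
  is a property of the receive chain, not of the dynamic — and, for HDR
  pairs, pooled across the task and baseline scans of a session. The pooled
  estimate also cancels the common-mode scale error that per-scan estimates
  imprint on the task−baseline subtraction.

## Mapping

Pixel-wise ordinary least squares of SNR against τ, with intercept by
default (real saturation is imperfect and in vivo delay triples do not pass
through the origin); slope standard errors propagate from the fit residual
(n−2 dof; n−1 for the through-origin option). R² is NaN where the data are
constant. Negative slopes pass through unclipped and are flagged in the
perfusion map's quality layer — clipping would bias HDR subtraction. The
default fitting mask keeps pixels whose maximum SNR across dynamics exceeds
3 (configurable). HDR maps are the task-minus-baseline slope difference
(exactly antisymmetric); `localize_activation` thresholds at z·σ̂
(one-sided positive by default, since a stimulus response is a perfusion
increase; two-sided available) and is a display/localization utility, not a
multiple-comparison-controlled test.

The flow–slope analysis fits each recovery curve on the 200–700 ms
quasilinear window and reports the Pearson correlation between pump flow
rate and slope. Noiseless plug curves give r = 1 exactly; the laminar
default geometry gives r ≈ 0.989 (the fastest rate bends mildly within the
window).

## Validation studies and what they show

`studies.perfusion_recovery_study`: 20 independent noise realizations of
the brain phantom at 20×20/FA 20°/pad 32, delays 0.1/0.2/0.3 s, with the
k-space noise calibrated so the weakest TOF image has brain-mean SNR ≈ 10
(an alternative calibration targets slope-map SNR ≈ 10, the regime reported
for in vivo perfusion-weighted maps, which this study then reproduces at
9.8 ± 0.8). Compartment means are taken on 1-pixel-eroded masks to avoid
the sinc partial-volume rim. Typical recovery: gray −1%, white −8%
(white matter is small enough that apodization and ringing of neighbouring
structures bias its mean; documented worst case ≈ −10% noiseless).

`studies.hdr_localization_study`: task (+20% perfusion in the posterior
patch) vs baseline pairs, pooled noise normalization, *through-origin*
slope fits — the simulated saturation is ideal so the regression origin is
known, and with three delays the intercept-free fit cuts the slope variance
about sevenfold — thresholded one-sided at 2σ̂ (σ̂ from the HDR map's
corner background) inside the intersection of the two data-driven brain
masks. Mean Dice against the ground-truth patch ≈ 0.65 across 20 seeds.
With the intercept fit the per-pixel detection z is ≈ 1.4 and no threshold
reaches Dice 0.5 — three-point-with-intercept HDR mapping at map SNR ~10 is
underpowered for +20% effects, a genuine sensitivity limit of the protocol
worth knowing before designing experiments.

Because the generators share the package's own forward conventions, these
studies validate the *pipeline* (reconstruction, calibration, statistics),
not the biological fidelity of the model: passing them does not show that
real brains satisfy the one-compartment assumptions, that real noise
regions are artifact-free, or that scanner saturation is ideal.

## Numerical and degenerate-input choices

* Removable kinetics singularity: limit form below |k−1/T1b| < 1e−10 s⁻¹.
* SNR mapping raises an explicit `DegenerateNoiseError` when the noise
  region's std is zero or < 1e−12 of the image scale, instead of
  propagating infinities.
* Regions are 0-based half-open rectangles (`x0:x1,y0:y1`) or explicit
  masks, in reconstructed-image coordinates.
* NIfTI interchange: series as (x, y, dynamic) volumes at full
  float64/complex128 precision with a JSON sidecar (delays, seed,
  acquisition metadata); maps as 2-D volumes with units in the header
  description. `io.to_anatomical` is the documented left-right axis flip
  from the radiological convention.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the specs; CLI runs log a config hash, the seed and the package version.

## Known limitations

* The slope→perfusion calibration assumes `s_arterial` is known; absolute
  quantification is only as good as that constant.
* Long-delay (multi-second) protocols are systematically underestimated by
  the linear model (see above); use the analytic model for forward
  simulation but expect biased linear inversions there.
* The noise model is stationary complex Gaussian; structured artifacts
  (gas-phase leakage, motion, ghosting) are not simulated, and real noise
  regions must be chosen away from such artifacts.
* Single-slice projection imaging only; no coil-sensitivity, parallel
  imaging or compressed-sensing modelling.
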