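# Methods

This note records the models implemented, the assumptions behind them, the
defaults and why they were chosen, and what the synthetic-data tests do and
do not demonstrate about real data.

## Time-integrated speckle model and its generator

The flowmetry chain rests on the standard model of time-integrated dynamic
speckle with an exponentially decaying field correlation (Lorentzian
spectrum, Siegert relation):

    K²(x) = β (e^(−2x) − 1 + 2x) / (2x²),   x = T / τ_c.

`speckle_theory.contrast_squared` evaluates this with a series expansion
below x = 10⁻⁴ to avoid catastrophic cancellation; the static limit is
K → √β. The blood flow index BFI = 1/K² inherits its interpretation from
this form: for exposure ≫ τ_c, BFI ≈ x + ½ ∝ 1/τ_c.

The generator does **not** simulate electric fields. Each pixel draws its
integrated intensity from a gamma distribution with shape M = 1/K²(x, β)
and the requested mean: a gamma variate's σ/mean is exactly K, which is
statistically sufficient for every contrast-domain statistic the pipeline
computes, and orders of magnitude faster than phasor simulation. Speckle
grains are one pixel wide (independent pixels, the matched-sampling case)
and frames are independent realizations. Consequences:

- spatial contrast, BFI, relative-flow ratios, and their convergence with
  window and ROI size are faithfully reproduced (verified against the
  closed form to <2 % over x ∈ {0.1, 1, 10, 100});
- spatial speckle-grain correlation, frame-to-frame temporal correlation,
  camera shot/read noise, and static-scatterer mixtures are **not**
  modeled, so passing tests say nothing about robustness to those effects
  in real recordings.

β defaults to 1.0 (ideal coherence); real systems have β < 1 and the
parameter is exposed everywhere. Camera noise defaults are likewise
stand-ins, not calibrated values.

## Flowmetry defaults

- 7×7 contrast bin (odd window required); population standard deviation
  over the window; reflect padding at borders, with a masked-border option.
- BFI masked (NaN) where K < 10⁻³ to avoid division blow-ups.
- ROI traces use a 1-s sliding mean of per-frame BFI before baseline
  referencing; gaps (animal repositioning) stay NaN, never interpolated.
- In the occlusion-confirmation harness (`experiments.measure_occlusion_drops`)
  ROIs are eroded by the half-window (3 px) before averaging so that no
  measured pixel's contrast bin straddles two tissue classes; without this
  partial-volume control the vessel drop reads ~1 point low.

## Guidance automaton

The published protocol is operator-driven ("the branch disappearing in
real time"); the implementation replaces the operator with explicit
thresholds: occlusion = ≥80 % vessel BFI drop, confirmation additionally
requires >50 % drop in the supplied region, both debounced by a 5-s
persistence window (criteria must hold at every sample of the window; a
NaN sample satisfies nothing, so gaps freeze the automaton). After
occlusion the laser holds half power (0.3 mW) for 120 s, then switches
off; from off, recanalization (drop back below 50 %, debounced) re-arms
full power. The 50 % re-arm threshold prevents chatter around the 80 %
criterion. The persistence length is a design choice — the latency of the
human judgment it replaces is unknowable.

## Modified Beer–Lambert inversion

I₀ is the per-trial first-5-s mean, so slow drifts cancel per trial; the
model is the literal attenuation form I = I₀·exp(−Δμ_a·L) with a mean
pathlength L(λ), not the differential-pathlength partial-derivative form.
The 3-wavelength / 2-chromophore system is solved by ordinary least squares
via the pseudoinverse, with a condition-number guard (reject above 10⁶).
ΔHbT ≡ ΔHbO + ΔHbR by construction. Bundled extinction coefficients
(cm⁻¹ M⁻¹: 470 nm 33209/16156, 530 nm 40092/39036, 625 nm 741/5763) and
pathlengths (0.039/0.048/0.297 cm) are compiled literature values for
hemoglobin spectra and Monte-Carlo pathlength estimates in cortex; both
are plain configuration inputs, and every quantitative guarantee (exact
round trip at zero noise, r > 0.95 footprint recovery at 1 % noise over
20 trials) holds for whatever tables are supplied. The generator's
canonical response is exactly zero during the baseline window so the
per-trial referencing is lossless; real hemodynamics violate this, which
is one reason the round-trip bound is a software guarantee, not a claim
about in-vivo accuracy.

## Monte Carlo dosimetry

Standard weighted photon walk: exponential free paths with μ_t = μ_a + μ_s,
deposition of μ_a/μ_t per event, Henyey–Greenstein deflection, Russian
roulette below weight 10⁻⁴ (survival 1/10). Launch: photons start on a
uniform disc of the waist radius at the tissue surface (the pial focal
plane) with a radially diverging cone — tilt proportional to launch radius
up to the NA half-angle, refracted by n_rel — and lose the
normal-incidence Fresnel fraction at entry; the top boundary applies
angle-dependent unpolarized Fresnel reflection with total internal
reflection beyond the critical angle. Tissue defaults
(μ_a = 0.37 mm⁻¹, μ_s = 23 mm⁻¹, g = 0.89, n_rel = 1.37) are typical
murine-cortex values near 520 nm; because the photosensitizer's activation
threshold is not known in absolute units, `activation_depth` expresses it
as a fraction (default 0.1) of the focal-plane peak fluence, and
spot-size comparisons are asserted as orderings (NA 0.1 strictly shallower
than NA 0.02), never as absolute depths. Voxels are 5 µm by default on a
1 mm × 1 mm × 1.6 mm grid; the grid must contain one Rayleigh range, which
is what forces the 1.6-mm default depth (the NA 0.02 beam's Rayleigh range
is ~1.52 mm). Verified properties: weight conservation to 10⁻³ per photon
at 10⁵ photons, and exp(−μ_a z) depth deposition within 5 % over three
attenuation lengths in the scattering-free limit at 10⁶ photons.

Two waist conventions circulate for the same hardware: the diffraction
estimate w₀ = 0.61λ/NA (NA 0.1 → 60.8 µm Rayleigh range) and the
half-spot-diameter reading (15 µm → ~1.4 mm). Both are exposed —
`rayleigh_range` takes either an NA or an explicit waist — and neither is
silently preferred.

## OCT angiogram analysis

Angiograms are mean absolute repeat-to-repeat differences, averaged over
acquisitions (20 in the acquisition protocol; tests use fewer and verify
the 1/√n background-variance scaling instead). Segmentation thresholds the
slab at median + 3·(1.4826·MAD) of the included voxels — a robust
background-noise floor that tolerates the sparse bright flow voxels —
followed by removal of objects under 5 voxels (26-connectivity, so oblique
capillary segments survive). The surface-vessel footprint is the
depth-projected pial stratum thresholded at mean + 3 SD and dilated by
2 voxels. Density is the flowing-voxel fraction of included slab voxels;
ring profiles use half-open lateral annuli [r, r + 50 µm) from 100 to
300 µm (en-face distance only), normalized ring-wise to the baseline scan.
The 150-µm slab thickness is fixed; its top sits below the pial stratum
(default 60 µm) and is configurable because the true boundary depth varies.
Recovered density tracks phantom truth within ±10 % relative for capillary
fractions 0.02–0.10 at the default noise level. The phantom's capillaries
are straight 8-voxel segments with fully decorrelated repeat amplitudes —
real capillary tortuosity, partial-volume voxels, bulk-motion artifacts,
and depth-dependent OCT signal decay are not represented.

## Behavior scoring

Asymmetry is the percent change from baseline of the contralateral-use
*fraction* (first wall contacts during rears), not the raw count: fractions
cancel session length and normalize pre-existing paw preference, and a
post-stroke deficit reads negative. Count columns are also emitted for a
count-based reading. Paired t-tests compare each follow-up timepoint to
baseline; no multiple-testing correction by default (a Bonferroni option
exists). Degenerate sessions (zero rears, zero baseline contralateral use)
become flagged missing values, never exceptions.

## Orchestration

The pipeline config is a single YAML document validated by a strict schema
(unknown keys rejected by name); every random stage carries an explicit
seed, and the manifest records SHA-256 checksums of all outputs so a rerun
with the same config is verifiably identical. Report text is
timestamp-free, making regeneration byte-identical. The demonstration
problem sizes (256×256 px × 100 frames for speckle, 80×120×120-voxel
angiogram phantoms at 3-µm voxels, 10⁵–10⁶ Monte Carlo photons) were
chosen so that statistical tolerances (ROI sampling error ≪ the 2-point
acceptance band, MC bin errors < 5 %) are met with comfortable margin at
interactive run times; all sizes are parameters.

## Known limitations

- No registration or motion correction; stacks are assumed co-registered.
- Single-exposure spatial contrast only; no multi-exposure or temporal
  contrast estimators, no absolute flow calibration.
- MBLL omits scattering-change terms and CMRO₂ estimation.
- The Monte Carlo model is homogeneous single-layer tissue; no vascular
  absorbers, no photochemistry or thrombus-formation kinetics.
- OCT analysis starts from angiogram-ready volumes; spectral
  reconstruction, Doppler velocimetry, and vascular graph extraction are
  out of scope.
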