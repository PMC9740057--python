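# Methods

## Scope and design

The package reconstructs, as testable code, the quantitative arm of a
longitudinal VDA-response imaging study: relaxometry and DCE perfusion
mapping of three ROIs (contralateral brain as control, intracranial tumor,
extracranial tumor) at four timepoints (pre-treatment, 1 h, 8 h, 24 h after
treatment), paired intraindividual statistics, and histology
quantification. Because no raw animal data accompany such studies, a
digital phantom stands in for the scanner and the microscope: every
acquisition is forward-simulated from ground-truth presets, and every
analysis stage is validated by recovering those presets.

## Signal models

**Spoiled gradient echo (VFA and dynamic readout).**
S(α) = M0·sin α·(1−E1)/(1−E1·cos α), E1 = exp(−TR/T1). The VFA fitter uses
the classical linearisation — S/sin α regressed on S/tan α has slope E1 —
followed by a damped Gauss–Newton refinement of (T1, M0) on the nonlinear
model (default on). The linear estimator alone is noise-biased
(≈ +0.8 % median at SNR 50 in our simulations); refinement brings the
median signed error to < 0.1 %. Voxels whose slope leaves (0, 1), or whose
T1 leaves the plausibility gate (1, 10000) ms, are marked invalid rather
than clamped, so divergent fits never pollute ROI means.

**Multi-echo T2 and multi-b ADC.** Mono-exponential decays fitted by
weighted log-linear regression with weights S² — the correct first-order
weighting, since var(ln S) ≈ σ²/S². Nonpositive samples (possible under
noise at long TE / high b) are excluded point-wise, never clamped, because
clamping biases the slope; a voxel needs at least two usable samples.
Gates: T2 ∈ (1, 2000) ms, ADC ∈ [0, 0.01) mm²/s (a zero slope from a
constant signal is kept valid).

**Noise.** Rician on magnitude images: independent Gaussian noise of equal
σ on two quadrature channels, |S + n₁ + i·n₂|. A plain Gaussian option
exists for debugging. All generators are seeded.

## DCE conversion and metrics

With baseline relaxation rate R10 = 1/T10, the agent raises the rate to
R1(t) = R10 + r1·C(t). M0 is calibrated per voxel from the mean of the 20
pre-injection frames together with the fitted T10; each frame is then
solved for E1 = (1 − s)/(1 − s·cos α) with s = S/(M0 sin α), giving
R1 = −ln E1/TR and C = (R1 − R10)/r1. Frames whose signal exceeds the SPGR
ceiling are marked invalid; small negative concentrations from the noise
floor are carried signed. A first-order mode (C ∝ ΔS/S0) is provided for
sensitivity analysis only — it carries a systematic gain relative to the
full inversion and is tested for shape-proportionality, not equality.

**AUC.** The ROI metric is the trapezoidal area under the ROI-mean
concentration curve, anchored at C(0) = 0, linearly interpolated to window
edges that fall between samples, reported in mmol/L·min. Voxel-wise AUC
maps use the identical rule. Windows are 30 s and 300 s after injection.
The acquisition itself (80 post frames at 3.6 s, mid-frame timestamps)
spans only ≈ 288 s, so the 300 s window always exceeds the sampled
support; the integral is truncated at the last sample with a warning. For
bolus-shaped curves the unsampled 288–300 s tail is O(10⁻⁵ %) of the
integral, far below the 1 % recovery tolerance; `strict=True` restores a
hard error for windows past the support.

**T1 ratio.** Post-contrast T1 divided by pre-contrast T1, voxel-wise, on
independently fitted VFA maps. Defined in this direction so the ratio lies
below 1 under contrast uptake and rises toward 1 after vascular shutdown.

## The phantom

**Geometry.** Three disjoint ellipsoids (brain control, intracranial
tumor, extracranial tumor; labels 1–3) on an empty background, 0.5 mm
isotropic voxels, written as RAS NIfTI. The geometry is deliberately
schematic: the pipeline validates parameter recovery, not anatomy. The
seed jitters ROI centres by up to one voxel so cohort subjects differ.

**Tissue curve.** C(t) = A·t^k·exp(−t/b), a gamma-variate with smooth
uptake and exponential washout, chosen for its closed-form running
integral A·b^(k+1)·Γ(k+1)·P(k+1, t/b) (P the regularised lower incomplete
gamma), which serves as the exact oracle for every AUC test. Shape k = 2
is fixed; the time-scale b is solved by bracketing root-finding so the
AUC300/AUC30 ratio matches each preset (the ratio is amplitude-free and
strictly increasing in b), after which the amplitude follows linearly.
Sampled at 3.6 s, the trapezoid agrees with the closed form to ≲ 0.2 % for
slow washout and ≲ 0.9 % for the sharpest (intracranial) bolus — the only
recovery that approaches its 1 % band, and purely a discretisation effect.

**Presets.** Each timepoint state carries per-ROI T1, post-contrast (CE)
T1, T2, ADC, M0 and the AUC30/AUC300 pair; lesion-centric aliases
(`extracranial_pre`, `intracranial_1h`, …) resolve to the same four
states. Printed study values populate the tumor entries (e.g. pre
extracranial AUC30 0.067, AUC300 0.193, T2 128.2 ms, CE-T1 786.1 ms; pre
intracranial AUC30 0.058, AUC300 0.063, T2 111.5 ms, CE-T1 1020.9 ms; 1 h
extracranial AUC30 0.008 with true T1 ratio 0.429). Where a state needed a
value no table provides, the package fixes one literature-typical choice:
pre-contrast tumor T1s are derived from the CE-T1 and T1-ratio pairs
(786.1/0.429 ≈ 1832 ms, 1020.9/0.497 ≈ 2054 ms); ADCs are 0.7–1.2 ×10⁻³
mm²/s rising after treatment; the brain control stays constant across
timepoints (T1 1600 ms, T2 90 ms, ADC 0.75×10⁻³, small AUCs) as expected
behind an intact BBB; post-treatment AUC300s (0.030 extracranial 1 h,
0.055 intracranial 1 h) complete the washout states consistently with
their AUC30s. AUC values are carried in mmol/L·min by convention; only
internal consistency matters for recovery.

**Acquisition defaults.** TR 15 ms with flip angles
{2,3,4,5,7,9,12,15,20}°; 24 TEs uniform on 10–240 ms; b ∈ {0, 1000} s/mm²;
dynamic readout α = 15°, TR 15 ms; r1 = 3.5 L·mmol⁻¹·s⁻¹ (typical of
Gd-DOTA at 3 T). The counts mirror the acquisition design; the specific
lists are package choices and all are configurable through
`AcquisitionProtocol`. Injection occurs at the start of frame 20
(0-based); frames are stamped at mid-frame, so pre-injection frames carry
negative times.

**Histology fields.** Five-class categorical images (background, viable
nucleus, positive nucleus, necrosis, vessel lumen) at 0.5 µm/pixel,
emulating a segmented ×200 field; unstained stroma is background, so the
necrosis denominator is necrosis + nucleus pixels. Placement is by exact
count, not Bernoulli draws: exactly ⌊n·f + 0.5⌋ of n nuclei are positive
(pooled counts across several fields are allocated by largest remainder,
so the pooled rate is exact regardless of per-field rounding), the
necrosis block is painted with the pixel count that realises the requested
fraction (exactly, when the fraction is representable on the lattice —
e.g. 86.2 % = 431·29 necrosis pixels against 69 nuclei of 29 pixels), and
vessel lumina get exact pixel counts from their µm² areas. Nuclei sit on a
jittered grid with a guaranteed ≥ 2-pixel moat so instances never merge
under 4-connectivity. The fields reproduce none of the realities of
stain-based segmentation (colour deconvolution, touching nuclei,
out-of-focus debris); passing tests demonstrate the correctness of the
quantifiers on segmented input, not robustness of segmentation itself.

## Statistics

Paired comparisons follow the intraindividual design: Shapiro–Wilk on the
paired differences, then the two-sided paired t-test
t = mean(d)/(sd(d)/√n) with n−1 df. When normality fails (p < 0.05) the t
result is still reported, flagged, and a Wilcoxon signed-rank p is added
as a sensitivity column — the primary inference stays the t-test. Raw
p-values at α = 0.05 are primary; a Holm-adjusted column is emitted for
transparency but not used for flags. Degenerate inputs resolve to limits:
identical pairs give t = 0, p = 1; zero-variance nonzero differences give
t = ±∞, p = 0. Comparisons with fewer than three complete pairs are
skipped with a warning, and subjects missing a timepoint are dropped from
the affected comparisons only. Type-I calibration over 10⁴ simulated null
cohorts of 15 subjects (the study's cohort size) lands at 5.3 % rejection
with uniform p-values.

The periphery analysis splits a ROI into a core (iterative 6-connected
morphological erosion by the rim width) and the rim (ROI minus core); the
two partition the ROI exactly.

## Problem sizes

Recovery tests run at desk scale by choice: 24³–64³-voxel grids (a few
hundred to ~800 voxels per ROI), 100-frame dynamics, ~10³ noise-bias
voxels, 10⁴ null replicates, and ×200 fields of ~520² pixels. All
round-trip tolerances are set by the stages' numerics (float64 fits are
exact to ~10⁻⁹; trapezoidal AUC to < 1 %), not by the grid size, so larger
grids change nothing but runtime.

## Known limitations

- No k-space simulation, partial-volume effects, motion, or B1/B0
  inhomogeneity; the phantom tests the fitting chain, not acquisition
  physics. (Partial volume notably affects small-animal DWI in practice.)
- No pharmacokinetic modelling (Ktrans/ve) or arterial input function —
  the perfusion metrics are deliberately model-free.
- The concentration conversion assumes fast water exchange and a spatially
  uniform flip angle.
- Real histology requires a segmentation step upstream of the quantifiers.
- Registration between timepoints is assumed (exact in the phantom).
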