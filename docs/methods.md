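# Methods

## Problem setting

Dynamic contrast-enhanced MRI (DCE-MRI) quantifies microvascular physiology
by fitting a tracer-kinetic model to the tissue concentration of a
gadolinium-based contrast agent (GBCA) over time. Accurate kinetics need
fast sampling of the arterial first pass; clinically useful maps need high
spatial resolution. A dual-temporal-resolution (DTR) acquisition
interleaves a fast, low-spatial-resolution series (HT: Δt = 1.46 s,
2.5×2.5×5 mm³, TR/TE/α = 2.5 ms/0.696 ms/16°) with a slow,
high-spatial-resolution series (HS: Δt = 6.04 s, 1×1×2.5 mm³,
3.7 ms/0.925 ms/16°): fifty HT frames cover the bolus first pass, followed
by twelve interleaved HS/HT segment pairs. This package reconstructs such
data into high-spatial-resolution kinetic maps at low contrast dose, and
quantifies the accuracy of the approach by Monte Carlo simulation.

## Signal model

Both series are spoiled gradient-echo (SPGR) acquisitions with steady-state
signal

    S = M0 · sin α · (1 − E1) / (1 − cos α · E1),   E1 = exp(−TR · R1).

T2*/TE decay is neglected: with TE < 1 ms it is a constant factor absorbed
into M0. Native R1_0 is estimated from variable-flip-angle (VFA)
acquisitions (α = 2°, 6°, 12°, 16°) by the linearised regression of
S/sin α on S/tan α, optionally refined by one bounded nonlinear pass.
Voxels with a regression slope outside (0, 1) — including flat responses —
are flagged invalid rather than raising, so whole-volume mapping never
aborts. Concentration follows the linear relaxivity model
R1(t) = R1_0 + r1·C(t); the SPGR equation is inverted per frame with M0
estimated from the mean of the pre-contrast baseline frames. Negative
concentrations from noise are deliberately not clamped (clamping would bias
baseline noise upward); frames at or above the saturation bound M0·sin α
are set to a configurable ceiling (50 mM) and flagged. The relaxivity of
gadoterate at 1.5 T is not uniquely standardised; the default is
r1 = 4.2 s⁻¹ mM⁻¹ (configurable). All ratio- and round-trip-based results
are independent of this choice.

## Kinetic model and fitting

The extended Tofts model (ETM) gives the tissue concentration

    Ct(t) = vp·Cp(t) + Ktrans ∫₀ᵗ Cp(u) · exp(−(Ktrans/ve)(t−u)) du

with Ktrans the transfer constant (reported in min⁻¹, converted to s⁻¹
internally), vp the fractional plasma volume and ve the fractional
extravascular extracellular space. The convolution is evaluated by an
exponential-kernel recursion on a uniform internal grid (default the HT
frame interval, 1.46 s); the recursion is exact for a piecewise-linear
plasma input, and is implemented as a first-order IIR filter so a forward
evaluation costs microseconds. Samples at arbitrary (e.g. HS) times are
obtained by linear interpolation of the model curve rather than
re-integration — the dual-rate evaluation.

Fitting is bounded trust-region least squares (Ktrans ∈ [0, 5] min⁻¹,
vp ∈ [0, 1], ve ∈ [10⁻³, 1]; the physiological constraint vp + ve ≤ 1 is
available as an opt-in flag but off by default). The bolus arrival time
(BAT) is searched on a discrete grid (default 0–15 s in HT-interval steps);
at each BAT the plasma input is time-shifted with zero padding before
onset, and the fit is started from three presets spanning weakly to
strongly enhancing tissue. Residual ties are broken toward smaller BAT,
then smaller Ktrans, so results are reproducible. Goodness of fit is the
scaled fitting error

    SFE = sqrt( Σᵢ (Tᵢ − Aᵢ)² / Σᵢ Aᵢ² )

(A observed, T modelled), which is 0 for a perfect fit and 1 when the
modelled curve is identically zero; it is undefined (flagged) for an
all-zero observed curve.

## Plasma input

The vascular input function (VIF) is measured in the superior sagittal
sinus: given a vessel mask, voxels are ranked by their peak concentration
within a first-pass window (default 60 s) and the top n (default 10)
curves averaged. The full-duration input is built by concatenating all HT
segments (arterial block plus interleaved segments) by acquisition time.
No haematocrit correction is applied by default (an optional
Cp = Cb/(1−Hct) switch exists), keeping parity with the reconstruction
method as published.

For simulations, where no measured input exists, a population model is
used: a gamma-variate first pass (unit-peak shape x^s·exp(s(1−x)),
s = 3, onset 10 s, time-to-peak 10 s, amplitude 5 mM) plus a
recirculation/washout term w·(1−e^(−rt))·e^(−dt) (w = 1.2 mM,
r = 0.08 s⁻¹, d = 0.0015 s⁻¹), giving a ~5.7 mM peak near 20 s decaying
to ~1 mM — typical of a low-dose sagittal-sinus curve. Because the true
simulation input of the original experiments is not published, absolute
CNR values are reported but only orderings and correlations are asserted.

## Dual-resolution reconstruction

Per HS-grid voxel the pipeline: (1) takes the HT curve of the HT voxel
containing the HS voxel centre (nearest-neighbour block mapping; trilinear
optional), (2) converts both series to concentration, (3) concatenates the
HT arterial phase (up to the concatenation point, default 73 s = 50×1.46 s)
with the HS parenchymal frames after it, (4) computes the per-voxel
calibration ratio

    ratio = mean(first 5 HS frames) / mean(last 4 HT frames),

(5) multiplies the arterial phase by the ratio so the two phases join
smoothly, and (6) fits the ETM against the VIF. The ratio corrects the
partial-volume level difference between the two native resolutions. A
non-positive HT window mean leaves the ratio undefined; such voxels fall
back to ratio 1 and are flagged and counted in the QC report rather than
dropped, so maps stay dense. Per-voxel fit failures are likewise flagged
(NaN in the maps) and never abort the volume. Downstream summaries exclude
voxels with SFE > 0.5 and trim above the 99th percentile by default (both
configurable). The same machinery serves the single-injection low-dose
variant and the dual-injection variant that concatenates with a separate
full-dose HS series; only the source tag differs.

**Known limitation — junction-slope bias.** The two ratio windows are
centred ~20 s apart. The ratio therefore estimates the product of the
resolution scale factor and the tissue curve's drift across the junction.
For slowly equilibrating tumours (the reference vestibular-schwannoma
kinetics have ve = 0.5, i.e. 1/kep ≈ 115 s, so the curve is still rising
at 70–100 s) the drift is ~4 %, which propagates into a systematic ≈ +4 %
on Ktrans and vp even on noiseless data; ve is nearly unaffected
(≈ −0.6 %). This is a property of the published ratio definition, not of
its implementation here: forcing ratio = 1 on a synthetic voxel with
identical HT/HS scales recovers all three parameters to < 0.05 %. The bias
vanishes when the junction phases are locally flat.

## Monte Carlo engine

A tissue curve with known kinetics (reference truth Ktrans = 0.26 min⁻¹,
vp = 0.07, ve = 0.5) is sampled once on the dual-rate axis (50 HT arterial
frames then 60 HS parenchymal frames) and rendered to SPGR signal twice:
at the HT baseline level (371.1 a.u.) and at the HS baseline level
(84.4 a.u.). Rician noise s → sqrt((s+n₁)² + n₂²), n₁,n₂ ~ N(0, σ²),
σ = NL × baseline mean, is added at the level of each rendering:
NL_HT = 0.04 (= 15.2/371.1) and NL_HS = 0.15 (= 12.6/84.4) by default
(the alternative pairing 0.038/0.12 is selectable via config). Three
conditions are refitted per repetition: the HT-level rendering, the
HS-level rendering, and the mixed interleaved condition formed by
converting the noisy arterial portion of the first and the noisy
parenchymal portion of the second back to concentration and combining
them. The fitting VIF is noiseless (only the tissue curve is perturbed);
conversion uses the known M0 rather than re-estimating it per repetition.
Percent deviation PD = (measured − true)/true × 100 is accumulated per
parameter; the mean and SD of PD, the mean absolute PD (the accuracy
metric used for condition orderings) and the mean SFE are reported.
Non-convergent repetitions are excluded and counted.

No calibration-ratio rescaling is applied inside the simulation's mixed
condition: both phases share one concentration scale, the true ratio is 1,
and estimating it per repetition would only inject the 5-frame HS window
noise into the arterial phase (measured: Ktrans mean PD +5 %, SD PD 6.8 %
versus 1.8 % without). The simulation isolates noise effects; the
calibration belongs to the in vivo reconstruction path.

Because the synthetic curves have zero bolus-arrival offset and
truth-scale kinetics, the simulation fit uses a degenerate BAT grid {0}
and a single start, which keeps 10⁴-repetition experiments to about a
minute per condition on one CPU without changing the estimates.

The Ktrans sweep repeats the mixed condition at true Ktrans
0.05–0.35 min⁻¹ (step 0.05, vp/ve fixed) and tabulates per-point PD
statistics plus the HS parenchymal-phase contrast-to-noise ratio

    CNR = (max parenchymal SI − mean baseline SI) / SD baseline SI.

The scheme provides four pre-injection HS baseline frames (negative
times); because per-repetition SDs over so few frames are unstable, the
sweep pools baseline samples across repetitions and averages the
per-repetition parenchymal maxima. Pearson correlations of CNR against
the mean and the SD of the Ktrans PD summarise the accuracy–CNR
relationship over the seven sweep points.

## Synthetic phantom

The phantom generator emits a registered file set in a shared world space:
HT and HS 4-D series, optional higher-dose HS series (dose-scaled input
amplitude, ratio 4 ≈ 0.080/0.020 mmol/kg; no saturation modelling at the
higher dose), VFA stacks per grid, tumour/vessel masks, ground-truth
parameter maps and a JSON manifest (seed, config, frame times). Geometry
is an ellipsoidal tumour with uniform ETM kinetics and a full-length
cylindrical vessel carrying the population input, in a non-enhancing
background (R1_0: tissue 1.0 s⁻¹, blood 0.7 s⁻¹). Regions are painted
binary on the HS grid; the HT series is the partial-volume block average
of the HS-grid concentration field, so tumour-edge HT voxels carry
realistically diluted curves — the situation the calibration ratio is
designed to correct. Noise per series comes from independent children of
one seed, making outputs bit-identical for identical seeds. Grids default
to 0.25 of the full matrices so end-to-end runs take minutes; tests use
0.12 (tumour of ~50 HS voxels) to keep the suite fast. The phantom is
geometric, not anatomical: no motion, no B0/B1 effects, no registration
error, and noise is spatially independent — passing recovery tests
therefore validates the numerics and the reconstruction logic, not
robustness to those real-data effects.

## Problem sizes and tolerances

Default experiment sizes: 10,000 repetitions for the noise-condition
comparison (~1 min/condition), 2,000 repetitions per sweep point for
routine sweep runs (the published experiments used 10,000; the
correlations are stable well below that), 0.12-scale phantom for
end-to-end tests. Numerical tolerances: noiseless round trips are exact to
1e-9 (signal↔concentration) and 1e-6 (VFA); the forward model matches a
brute-force trapezoidal convolution oracle to 0.1 % on-grid; noiseless
ETM refits recover parameters to < 0.5 %.
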