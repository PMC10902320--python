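# legatos

Low-dose, dual-temporal-resolution DCE-MRI reconstruction and extended
Tofts kinetic mapping, with a Monte Carlo accuracy/CNR simulation engine
and a synthetic 4-D phantom generator.

## What problem this solves

Quantitative dynamic contrast-enhanced MRI (DCE-MRI) estimates
microvascular parameters — the transfer constant K^trans (min⁻¹), the
fractional plasma volume v_p and the fractional extravascular
extracellular space v_e — by fitting the extended Tofts model

    C_t(t) = v_p·C_p(t) + K^trans ∫₀ᵗ C_p(u) e^(−(K^trans/v_e)(t−u)) du

to tissue gadolinium concentration curves, driven by a vascular input
function C_p(t) measured in the superior sagittal sinus. Fast sampling is
needed during the bolus first pass; fine spatial detail is needed in the
maps. An interleaved acquisition provides both: a high-temporal (HT)
series (Δt = 1.46 s, 2.5×2.5×5 mm³) covers the arterial phase with fifty
frames, then twelve pairs of interleaved high-spatial (HS; Δt = 6.04 s,
1×1×2.5 mm³) and HT segments cover the parenchymal phase. Per HS voxel
the two phases are concatenated and the arterial phase is rescaled by the
calibration ratio

    ratio = mean(first 5 HS frames) / mean(last 4 HT frames)

which corrects the partial-volume level difference between the two native
resolutions, before fitting the model (with bolus-arrival-time search and
a scaled-fitting-error map). This enables 1×1×2.5 mm kinetic maps from a
single low dose (~3 ml) of contrast agent. The package is aimed at
researchers developing or validating such protocols: it implements the
reconstruction, the fitting, the simulation experiments that justify the
design, and a ground-truth phantom to test all of it.

## Worked example

Compare kinetic-parameter accuracy under noise resembling the HT series
(NL = SD/mean baseline = 15.2/371.1 ≈ 0.04), the HS series
(12.6/84.4 ≈ 0.15), and the mixed interleaved curve, refitting a
vestibular-schwannoma-like tumour curve (K^trans = 0.26 min⁻¹,
v_p = 0.07, v_e = 0.5) 2,000 times per condition:

```bash
legatos simulate noise --reps 2000 --seed 1 --out fig2.tsv
```

selected columns of `fig2.tsv`:

```
condition  mean_abs_pd_ktrans  mean_abs_pd_vp  mean_abs_pd_ve  mean_sfe
    NL_HT               0.693           1.118           0.376     0.028
    NL_HS               2.954           4.642           1.679     0.117
 NL_HT-HS               1.482           1.355           1.633     0.090
```

`mean_abs_pd_*` is the mean absolute percent deviation of each parameter
estimate from truth, and `mean_sfe` the mean scaled fitting error. The
interleaved condition (NL_HT-HS) is substantially more accurate than the
high-spatial noise level alone (NL_HS) for every parameter — the case for
the dual-resolution design: the clean arterial phase anchors v_p and
K^trans even when the parenchymal phase is noisy.

Other entry points (same pattern, `--help` for options):

```bash
legatos phantom --out phantom/ --seed 1          # synthetic acquisition
legatos vif --series phantom/ht.nii.gz --mask phantom/vessel_mask_ht.nii.gz \
    --vfa phantom/vfa_ht.nii.gz --times phantom/manifest.json --out vif.tsv
legatos fit --ht phantom/ht.nii.gz --hs phantom/hs.nii.gz \
    --vfa phantom/vfa_hs.nii.gz --mask phantom/tumour_mask.nii.gz \
    --vif vif.tsv --manifest phantom/manifest.json --out maps/
legatos simulate sweep --kt 0.05:0.35:0.05 --reps 2000 --seed 1 --out fig3.tsv
```

`fit` writes one NIfTI per parameter (ktrans, vp, ve, bat, sfe) on the HS
grid plus a QC summary (fractions of calibration-flagged and high-SFE
voxels). `simulate sweep` tabulates accuracy and the HS parenchymal-phase
contrast-to-noise ratio across true K^trans values and reports the
Pearson correlations between them.

Everything is also available as a library (`import legatos`); see
`docs/methods.md` for the model, the numerical choices and the known
limitations.

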