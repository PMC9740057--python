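# vdamri

Multiparametric MRI and histology analysis of tumor response to
vascular-disrupting agents (VDAs), validated end-to-end on a digital
rat-head phantom.

VDAs such as combretastatin A-4 phosphate collapse established tumor
vasculature within hours. In a rat model carrying simultaneous intracranial
and extracranial (facial) lesions of the same tumor, the intact or
partially intact blood–brain barrier limits both contrast-agent and drug
delivery to the intracranial lesion, so the two lesions respond very
differently — a difference that model-free perfusion MRI can quantify.
This package implements the quantitative imaging pipeline for that kind of
study, for imaging scientists who need every stage to be verifiable by
parameter recovery:

- **Relaxometry** — voxel-wise T1 from variable-flip-angle (VFA) spoiled
  gradient echo, S(α) = M0·sin α·(1−E1)/(1−E1·cos α) with
  E1 = exp(−TR/T1); T2 from 24-echo mono-exponential decay
  S(TE) = S0·exp(−TE/T2); ADC from multi-b DWI, S(b) = S0·exp(−b·ADC).
- **DCE perfusion** — conversion of a 100-frame dynamic series
  (20 pre-contrast + 80 post-contrast frames, Δt = 3.6 s) to contrast-agent
  concentration by inverting the SPGR equation with
  R1(t) = 1/T10 + r1·C(t), then the model-free metrics
  **AUC30** and **AUC300** (areas under the concentration–time curve over
  the first 30 s / 300 s since injection, surrogates of perfusion and of
  perfusion-plus-retention) and the **T1 ratio** (post-contrast T1 ÷
  pre-contrast T1; rises toward 1 as perfusion shuts down).
- **Longitudinal statistics** — ROI summaries across four timepoints
  (pre, 1 h, 8 h, 24 h), Shapiro–Wilk normality on paired differences,
  two-sided paired t-tests, tumor core/periphery splitting.
- **Histology quantification** — necrosis area fraction from H&E-like
  label masks, pooled Ki67/CD31 positive-cell rates over three ×200
  fields, mean CD31-delineated vessel cross-sectional area.
- **Digital phantom** — forward-simulates every acquisition (with Rician
  noise) and synthetic histology fields from ground-truth presets, so each
  analysis stage is tested by closed-loop parameter recovery.

## Worked example

Simulate the pre-treatment phantom, fit the T1 map, convert the dynamic
series to concentration, and integrate the extracranial-tumor curve:

```python
from vdamri import dce
from vdamri.phantom import (build_phantom, parameter_volumes,
                            simulate_dce_series, simulate_vfa_series)
from vdamri.protocol import AcquisitionProtocol
from vdamri.relaxometry import fit_t1_vfa

protocol = AcquisitionProtocol()
labels, truth = build_phantom((64, 64, 16), "extracranial_pre", seed=0)
vols = parameter_volumes(labels, truth)

vfa = simulate_vfa_series(vols["t1_ms"], vols["m0"], protocol)
t10, _ = fit_t1_vfa(vfa, protocol.tr_ms, mask=labels.labels > 0)

dyn = simulate_dce_series(labels, truth, protocol)
baseline, _ = dce.estimate_baseline(dyn)
conc, valid = dce.signal_to_concentration(dyn, baseline, t10.values, protocol,
                                          mask=t10.validity_mask)
roi = labels.roi_mask("extracranial_tumor")
curve = dce.roi_mean_curve(conc, valid, dyn, roi, "extracranial_tumor")
print(f"extracranial tumor: {roi.sum()} voxels")
print(f"peak concentration: {curve.conc_mM.max():.3f} mmol/L")
print(f"AUC30 = {dce.auc(curve, 30.0):.4f} mmol/L*min")
```

prints

```
extracranial tumor: 790 voxels
peak concentration: 0.217 mmol/L
AUC30 = 0.0669 mmol/L*min
```

i.e. the bolus peaks around 0.22 mmol/L in the well-perfused facial tumor
and the recovered AUC30 matches the preset ground truth of 0.067
mmol/L·min to 0.15 % (the residual is trapezoidal discretisation of the
3.6 s frame grid).

The same pipeline runs from the shell:

```sh
vdamri simulate --out run --seed 11 --subjects 3 --grid 64,64,16
vdamri analyze  --out run          # maps, roi_table.csv, comparisons.csv, report.md
vdamri histo    --out run --seed 11
```

`vdamri relaxometry` and `vdamri dce` run the individual stages;
`vdamri all` chains everything.

## Layout

```
src/vdamri/
  protocol.py      acquisition constants (TR, angles, TEs, b, frames, r1)
  phantom/         presets, geometry, MRI forward models, histology fields
  relaxometry.py   VFA T1, multi-echo T2, multi-b ADC fitters
  dce.py           SPGR inversion, AUC30/AUC300, T1 ratio
  cohort.py        ROI summaries, periphery split, paired statistics
  histoquant.py    necrosis fraction, positive rate, vessel areas
  pipeline.py      end-to-end orchestration (simulate/analyze/stats/histo)
  cli.py           `vdamri` command-line interface
docs/methods.md    model assumptions, parameter choices, limitations
```
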