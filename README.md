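# pcct-cardiac

Desk-scale simulation and analysis pipeline for **photon-counting
computed-tomography (PCCT) cardiac phenotyping in mice**: from a beating
digital thorax phantom, through energy-binned photon-counting acquisition,
projection-domain intrinsic cardiac gating, multi-channel iterative
reconstruction and K-edge material decomposition, to deep-learning left-
ventricle segmentation and cohort-level cardiac-function statistics.

It is aimed at preclinical imaging researchers who want a tested, fully
synthetic test bed for the algorithmic chain used in contrast-enhanced
cardiac micro-CT studies of atherosclerosis models (APOE2/3/4 and APOE
knockout mice on control or high-fat diet, with or without a humanized NOS2
background).

## What is inside

| stage | module | core idea |
|---|---|---|
| spectral phantom | `physics` | two-basis photoelectric/Compton attenuation with an iodine K-edge at 33.2 keV; beating LV (raised-cosine volume between DLVV and SLVV, 300–600 bpm); Ca/I cylinder detectability phantom |
| acquisition | `acquisition` | 80 kVp filtered-bremsstrahlung spectrum, 4 PCD bins (thresholds 25/34/50/60 keV), 100 Hz view rate, Poisson counting noise; Joseph projector with an exact adjoint |
| intrinsic gating | `gating` | heart rate and per-view cardiac phase from the difference between measured projections and reprojections of the ungated reconstruction — no ECG input |
| reconstruction | `recon` | FBP baseline and split-Bregman multi-channel recon solving `min_X Σ_{t,e} ½‖R X(t,e) − Y(t,e)‖² + λ(t,e)·Reg(X(t,e))` with bilateral spatial/temporal TV and a rank-sparse (nuclear-norm) term across energy bins |
| decomposition | `decomp` | per-voxel inversion `C = X M⁻¹` of a vial-calibrated sensitivity matrix, with orthogonal-subspace projection for non-negativity |
| detectability | `detectability` | CNR = (μ_signal − μ_background)/σ_background over the cylinder grid; Rose criterion CNR > 3 |
| segmentation | `segmentation` | compact numpy U-Net, loss = BCE + (1 − soft Dice), precision/recall-balanced threshold, Dice/precision/recall/AUC |
| phenotyping | `phenotyping` | SV = DLVV − SLVV, EF = 100·SV/DLVV, CO = SV·HR, CI = CO/weight; IQR age-outlier rule; factorial OLS + type-II ANOVA with Tukey post hocs, Cohen F, point-biserial correlation |
| orchestration | `pipeline`, `workflows`, `cli` | seeded end-to-end runs, JSON/CSV/NIfTI artifacts, `pcct-cardiac` CLI |

## Worked example

Simulate a 10 s scan (1000 views at 100 Hz) of a beating phantom and gate it
from the projections alone:

```bash
pcct-cardiac simulate --views 1000 --heart-rate 450 --seed 1 --out sino.npz
pcct-cardiac gate --sino sino.npz --out gating.json
```

```
wrote sino.npz: 1000 views, 4 bins, truth HR 450 bpm
heart rate 450.0 bpm -> gating.json
```

The full pipeline on one synthetic subject (truth ejection fraction 45%):

```python
from pcct_cardiac.workflows import e2e_subject_study
m = e2e_subject_study(seed=3)
print(m["results"])
```

```
{'heart_rate_bpm': 449.875, 'segmentation_threshold': 0.31,
 'dlvv_ml': 0.0394, 'slvv_ml': 0.0215, 'sv_ml': 0.0179,
 'ef_pct': 45.34, 'co_ml_min': 8.04, 'ci_ml_min_g': 0.268,
 'hr_bpm': 449.875}
```

The recovered heart rate is within 0.2 bpm of the configured 450 bpm, and
the ejection fraction (45.3%) is within half a percentage point of the
ground truth — diastolic and systolic LV volumes come from the U-Net
segmentation of the ten gated phase reconstructions.

Cohort bookkeeping against the packaged group-count table:

```python
from pcct_cardiac.phenotyping import load_cohort_counts, summarize_cohort
print(summarize_cohort(load_cohort_counts()).round(1))
```

```
  isoform  male  female  total  pct_hn  pct_hfd
0   APOE2    17      10     27    44.4     55.6
1   APOE3    23      19     42    47.6     66.7
2   APOE4    21      14     35    57.1     51.4
3      KO     9      10     19     NaN     52.6
```

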