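# vista-followup

Invasiveness prediction for lung nodules from **irregularly sampled
follow-up CT series**.

Most early lung adenocarcinomas are watched over years of CT follow-up
before resection. Whether a nodule is an invasive adenocarcinoma (IA) or a
pre-/minimally-invasive lesion (AAH/AIS/MIA) correlates with *per-day*
dynamics — volumetric growth rate and the speed of solid transformation —
but follow-up scans arrive on arbitrary, patient-specific schedules, so
sequence models that ignore the acquisition dates conflate "changed a lot"
with "was followed for long". This package implements **ViSTA**, a 3D CNN
patch encoder coupled to **SimTA** (Simple Temporal Attention): a causal
attention mechanism whose weight on an earlier scan decays exponentially
with elapsed time,

    a[j, i] = softmax over i ≤ j of  ( −softplus(λ) · (t_j − t_i) / τ ),

with learnable per-channel decay rates λ and a fixed time scale τ = 30
days. Rows are convex weights, later scans never receive less weight than
earlier ones, and only time *differences* matter. Around the model the
package provides:

* the classical **volume doubling time** baseline
  (`VDT = Δt·ln2 / ln(v₂/v₁)`, ranked by 1/VDT, 400-day or best-Youden
  cutoffs),
* **static CNN** baselines (first/last/all scans) and an interval-blind
  **CNN+LSTM**,
* a **synthetic nodule-growth simulator** (NIfTI + CSV manifests) whose
  schedule statistics and class structure emulate a published follow-up
  cohort, making every stage testable without clinical data,
* preprocessing (isotropic resampling, HU windowing, VOI-centred patches),
  an AdamW/cosine training harness, ROC/Youden evaluation with radiologist
  reference rows, and backpropagation saliency maps per time point.

Models are sklearn-style estimators (`fit` / `predict_proba` /
`decision_function` / `get_params`) over lists of `FollowUpSeries`; the
neural networks run on a small NumPy reverse-mode autodiff engine that is
gradient-checked against finite differences in the test suite.

## Worked example

```python
import numpy as np
from vista import (simulate_cohort, series_from_synthetic, simta_attention,
                   compute_vdt, VDTClassifier, evaluate_scorer)

# SimTA attention over three scans 30 days apart, decay 0.1/day:
w = simta_attention([0.0, 30.0, 60.0], rate=3.0, time_scale=30.0)
print(np.round(w[2], 4))          # -> [0.0024 0.0473 0.9503]

# Volume doubling time: 250 -> 400 mm^3 in 180 days
print(round(compute_vdt(250.0, 400.0, 180.0).vdt_days, 1))   # -> 265.5

# A synthetic cohort, scored by the size-based baseline:
cohort = [series_from_synthetic(s, patch_size=16)
          for s in simulate_cohort(80, seed=11)]
y = np.array([s.label == "IA" for s in cohort], dtype=int)
val, test = cohort[:30], cohort[30:]
clf = VDTClassifier(cutoff="youden").fit(val, y[:30])
rep = evaluate_scorer(clf.decision_function(test), y[30:],
                      clf.rule_.threshold)
print(round(rep.auc, 3), round(rep.sensitivity, 3))   # -> 0.548 0.571
```

The attention row shows the exponential-decay weighting: the current scan
dominates (0.95) and the scan 60 days back is nearly ignored (0.0024). The
doubling time 265.5 d < 400 d flags a fast-growing nodule. The VDT
baseline's test AUC of 0.548 on the synthetic cohort illustrates why
two-point volumetry is weak when invasiveness is also carried by solid
transformation and when short intervals amplify measurement noise — the
gap that the image-based sequence models are built to close.

Training the full model on a simulated study (writes a comparison table
and ROC figure):

```bash
vista simulate --n 351 --seed 42 --out data/
vista benchmark --out runs/ --seed 42
```

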