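# pdglove

Analysis pipeline for a multimodal sensor glove that quantifies hand
dysfunction in Parkinson's disease (PD).  The glove records three signal
families — finger bend angles, palm/finger contact force, and triaxial
hand acceleration — and this package turns them into three clinical
grades plus the statistics needed to compare those grades with a
clinician's:

* **Finger flexibility (F0–F4)** — bend channels are smoothed with an
  exponentially weighted average (EWA) filter, min–max normalized
  against the sensor's 0–180° range, and the maximum normalized bend
  over nine test gestures is binned into five grades refining the TAM
  range-of-motion standard (F0 worst).
* **Hand muscle strength (Lovett M0–M5)** — a population of maximum
  grip/pinch forces is partitioned by a from-scratch 1-D k-means
  (Lloyd's algorithm, k = 6): samples x⁽ⁱ⁾ are assigned to the nearest
  center, c⁽ʲ⁾ = argminⱼ‖x⁽ⁱ⁾ − μ⁽ʲ⁾‖², centers update to cluster means
  μ⁽ʲ⁾ = Σ_{x∈c⁽ʲ⁾} x / n_{c⁽ʲ⁾}.  Midpoints of adjacent sorted centers
  partition the force axis into six intervals mapped onto the Lovett
  grades; a subject's grade is the interval of their maximum force over
  four test actions.
* **Hand stability (tremor severity)** — the triaxial acceleration is
  fused into the combined acceleration a(k) = √(ax²+ay²+az²), filtered
  (median, window 5 → 3–8 Hz zero-phase Butterworth band-pass →
  adaptive scalar Kalman), and summarized as a 9-element feature vector
  (peak-to-peak, SD, RMS and their logarithms on the fused signal;
  dominant in-band frequency per axis).  A from-scratch 9-6-3
  back-propagation neural network (sigmoid hidden layer, softmax
  output, cross-entropy) classifies the vector into No / Mild / Severe
  tremor — the UPDRS static-tremor item 0 vs 1–2 vs 3–4.

Agreement with clinical ratings uses Cohen's kappa,
κ = (p_o − p_e)/(1 − p_e), with the large-sample null-variance Z
statistic, Z = κ / √( [p_e + p_e² − Σᵢ p_{i+} p_{+i}(p_{i+} + p_{+i})] /
(n(1 − p_e)²) ); test–retest reliability uses the intraclass
correlation coefficient (two-way, absolute agreement, single
measurement, with a 95% CI).

No public recordings of the glove exist, so `pdglove.synthetic`
generates all three signal families with known ground truth; every
pipeline stage is exercised end to end on generated data.  See
`docs/methods.md` for the models, parameter choices and limitations.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
from pdglove import (ContingencyTable, cohen_kappa,
                     simulate_dataset, bpnn_train, evaluate)

# agreement between system and clinician flexibility grades (12 subjects)
table = ContingencyTable(
    labels=["F2", "F3", "F4"],
    counts=[[2, 0, 0],     # rows: system grade
            [1, 1, 0],     # cols: clinician grade
            [0, 0, 8]],
)
res = cohen_kappa(table)
print(f"kappa={res.kappa:.3f}  Z={res.z:.3f}  p={res.p_value:.2e}  band={res.band}")

# synthetic tremor experiment: 120 windows, stratified 8:2 split
features, labels = simulate_dataset(120, (40, 40, 40), seed=0)
Xtr, Xte, ytr, yte = train_test_split(
    features.to_numpy(), labels, test_size=0.2, stratify=labels, random_state=0)
model = bpnn_train(Xtr, ytr, seed=0)
report = evaluate(model, Xte, yte)
print(f"test accuracy: {report.accuracy:.4f}")
```

Output:

```
kappa=0.833  Z=3.906  p=9.40e-05  band=excellent
test accuracy: 1.0000
```

The kappa of 0.833 (Z = 3.906 > 1.96, p < 0.01) says the system's
flexibility grades agree with the clinician's far beyond chance —
eleven of twelve subjects identically graded, one off by a single
grade — landing in the "excellent" band (κ > 0.8).  The synthetic
tremor classifier separates the three severity classes on its 24-window
held-out set because class amplitudes are separable by construction;
this validates the pipeline plumbing, not clinical performance.

A `pdglove` command-line tool wraps each stage (`simulate`,
`preprocess`, `extract-features`, `train`, `cv`, `evaluate`,
`fit-strength-model`, `assess-flexibility`, `assess-strength`,
`assess-tremor`, `agreement`, `run-assessment`); `pdglove --help`
lists them.

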