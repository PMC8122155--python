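# disqa

Calibrated per-residue quality assessment (QA) and QA-aware meta-prediction
of protein intrinsic disorder.

## The problem

Sequence-based predictors of intrinsically disordered regions (IDRs) emit a
per-residue disorder propensity and a binary call, but their accuracy varies
widely between proteins and between residues of the same protein. Modern QA
tools attach a per-residue confidence score to a disorder prediction, yet
those raw scores have no fixed meaning: a raw confidence of 0.6 from one
predictor may correspond to excellent predictions and from another to barely
better than random. `disqa` addresses two needs that follow:

1. **Interpretable QA.** Raw QA scores are mapped onto the Matthews
   correlation coefficient (MCC) scale. Residues of a labeled calibration
   set are pooled and sorted by raw QA; a window of *w* residues slides over
   the sorted list and the MCC of the binary calls inside each window is
   assigned to the window's median raw score. The resulting median line
   (with 25th/75th percentile bands) is a piecewise-linear mapping
   raw QA → expected MCC, so a mapped score of 0.8 literally reads "for
   residues with this confidence, predictions of this tool achieve
   MCC ≈ 0.8". The fitted line is deliberately not forced monotone.

2. **QA-aware meta-prediction.** Three base predictors' propensities
   `p₁,p₂,p₃` and their mapped QA scores `q₁,q₂,q₃` form a per-residue
   feature vector fed to a small sequence-labeling network (default: a
   two-layer bidirectional LSTM, 25 units per layer, over a 10-unit dense
   input layer, sigmoid per-residue output; trained with binary
   cross-entropy, learning rate 0.01 decayed 1 %/epoch for 50 epochs,
   dropout 0.5). The QA inputs identify which base prediction is failing at
   a residue so the network can repair it from the other two — a consensus
   without the QA columns cannot distinguish a failing majority from a
   failing minority. Logistic-regression and k-NN baselines share the
   prediction contract.

An evaluation suite implements the residue-level protocol used to validate
both parts: threshold-swept ROC-AUC and PR-AUC, MCC, expected-vs-actual MCC
agreement of QA scores (PCC/MAE/MSE over sorted windows), coverage-vs-MCC
curves for selective prediction with a resampling significance test
(Anderson–Darling normality gate, then paired t-test or Wilcoxon rank-sum),
and stratification of QA by IDR length class and distance to IDR termini.
Because executing third-party disorder predictors is out of scope, a
synthetic generator produces the study data: proteins with IDRs of
controlled length classes and prevalence, base predictors with
region-shaped errors (missed IDRs, boundary jitter, false segments,
per-predictor failure proteins), and raw QA streams whose correlation with
per-residue correctness is a single dial.

## Worked example

The whole study — simulate, calibrate, train, predict, re-calibrate the
meta output, evaluate — runs from one command:

```bash
disqa run-pipeline --seed 1 --out run/
```

which prints the held-out test evaluation

```
   base1  ROC-AUC 0.7652  MCC 0.5069
   base2  ROC-AUC 0.8762  MCC 0.6834
   base3  ROC-AUC 0.8692  MCC 0.6865
    meta  ROC-AUC 1.0000  MCC 0.9796
```

and writes `curve_*.json` (the fitted raw-QA→MCC mappings), a model bundle
`meta_model/`, `report.json` and a `manifest.json` recording seeds, splits
and artifact hashes. Each base predictor fails hard on its own third of the
proteins; its QA stream flags those residues, and the trained meta-model
uses that signal to out-rank every base (ROC-AUC 1.000 vs at best 0.876
here). The MCC values read directly against the calibrated QA scale: the
bases sit near the middle of their curves, the meta near the top.

The same stages are available piecewise (`disqa simulate`, `calibrate`,
`apply-qa`, `train-meta`, `predict`, `evaluate`, `compare`) and as library
functions:

```python
from disqa import build_curve, apply_curve, make_meta_scenario

sc = make_meta_scenario(seed=1)
track = sc.dataset.tracks[(sc.dataset.records[0].id, "base1")]
curve = build_curve(
    [(sc.dataset.tracks[(pid, "base1")], sc.dataset.record(pid).labels, pid)
     for pid in sc.calibration_ids],
    window_size=150,
)
track.mapped_qa = apply_curve(curve, track.raw_qa)
```

The pipeline refuses to fit a calibration curve on proteins that the
meta-model trains on (a `LeakageError`), and every stochastic stage derives
its seed from the run seed, so reruns are bit-identical.

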