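# Methods

This note records the models, numerical choices and limitations behind
`disqa`, in the order the pipeline runs them.

## Calibration of raw QA scores to the MCC scale

**Procedure.** Residues of a labeled calibration set are pooled across
proteins and sorted ascending by raw QA, with ties broken by (protein id,
position) so the sort is total and reruns identical. A window of
`window_size` residues slides over the sorted pool with stride
`ceil(window_size/10)` (stride 1 available for oracle checks; the final
window is always anchored at the end of the pool). Each window position
yields one MCC from the binary-call-vs-label contingency inside the window,
computed from cumulative sums so the cost is linear in the pool. The knot
placed for a window has x = the window's median raw QA (robust to ties,
which a "middle residue" rule is not), and its median/p25/p75 values are
the 50th/25th/75th percentiles of window MCCs over a neighborhood of 21
consecutive window positions centered there (clipped at the ends). Knots
sharing an x (heavy ties, e.g. a near-binary raw stream) are merged by the
median of each band, so a few windows straddling a regime boundary cannot
drag the merged knot. The curve also stores the dataset-level MCC of the
pool — the reference line for coverage analyses.

**Application** is piecewise-linear interpolation on the (x, median) knots,
clamped to the end knots outside their range and clipped to [−1, 1]. The
percentile bands are descriptive only. No smoothing and no isotonic
regression are applied: observed mappings are genuinely non-monotone in
places, and forcing monotonicity would erase exactly the information the
calibrated score is meant to carry.

**Degenerate cases.** MCC with a zero contingency marginal is defined as 0
(the usual convention) inside windows of the curve fit, where it is rare at
sensible window sizes; in the expected-vs-actual agreement analysis such
windows are instead *excluded*, because there the 0 convention would be
compared against a meaningful expectation and register as spurious error. A
constant raw-QA stream carries no ordering information and produces a
single-knot curve at the dataset MCC.

**Window size.** Default 2000 residues, validated as at most half the
pooled count. Two scales matter: the window must hold enough residues of
both classes for a stable MCC, and the pool should span at least ~10
windows so the 21-window percentile neighborhood stays local. At the
synthetic desk scale used in the tests (calibration pools of ~2.4 k
residues at 12 % disorder) the pipeline uses a 150-residue window; with a
too-large window the minority tail of the raw-QA distribution falls inside
a single window and the curve collapses to a constant.

## The meta-predictor

**Inputs.** Exactly three base predictors (an odd count breaks ties); per
residue the feature vector is [p₁, p₂, p₃, q₁, q₂, q₃] — propensities then
mapped QA — in a declared predictor order that is recorded with the trained
model and enforced at prediction time. Propensities rather than binary
calls are used (the calls are derivable by thresholding).

**Architectures.** Three variants, all ending in a per-residue sigmoid:
a position-wise feedforward stack (two hidden layers with dropout between
them); a recurrent variant (dense input layer, then two stacked LSTM
layers with dropout); and the default bidirectional variant (the same with
biLSTM layers, forward/backward states concatenated). The search grid spans
the 3 types × recurrent sizes {200, 100, 50, 25, 12, 6, 3}; the dense layer
scales as max(3, size/2) except the selected 25-unit design, whose dense
layer is pinned at 10. Selection trains every candidate on the same seeded
split and keeps the highest validation ROC-AUC, ties to the smaller
parameter count.

**Training.** Binary cross-entropy, 50 epochs, learning rate 0.01 with a
multiplicative 1 %/epoch decay, dropout 0.5, no class reweighting. The
networks are implemented directly in numpy with analytic backpropagation
(gate order i, f, g, o; forget-gate bias initialized to 1; Glorot-uniform
weights), verified against central finite differences in the test suite.
Updates are per protein — each sequence is one batch, so no padding or
masking is ever needed and no padded position can touch the loss. Gradients
are clipped to a global norm of 5. The optimizer is RMSprop (ρ = 0.9,
ε = 1e−7) by default, with plain and momentum SGD available: at this
learning-rate/epoch budget plain SGD stalls well short of the base
predictors, which defeats the purpose of a meta-model, and the choice of
optimizer family is otherwise open.

**Split and threshold.** Proteins (never residues — labels are strongly
autocorrelated along the chain) are split 80/20 into design and validation
subsets with the model seed. The binary threshold is chosen to maximize MCC
on the validation subset, scanning midpoints of the sorted unique scores
(subsampled to 512 candidates when denser; MCC varies smoothly in the
threshold). The validation ROC-AUC is recorded for model selection. If the
validation subset degenerates to one class, threshold and AUC bookkeeping
fall back to the design subset rather than failing the run.

**QA for the meta output.** The pipeline's final stage gives the meta
prediction its own calibrated QA track. The raw confidence stream is a
synthetic stand-in provider — the rescaled distance of the meta propensity
from its binary threshold, |p − t| / max(t, 1 − t) — behind a pluggable
interface, and is calibrated through exactly the same curve-fitting as any
other raw QA stream, on calibration proteins disjoint from the meta's
training proteins. The manifest flags the provider as a stand-in.

**Leakage rule.** Calibration proteins ∩ meta-training proteins = ∅ is
enforced (`LeakageError`), because a curve fitted on training proteins
would import label information into the meta features.

## Evaluation protocol

ROC-AUC is the threshold-swept trapezoidal area (equal to the normalized
Mann–Whitney U; an exhaustive pair-counting oracle checks this in the
tests), PR-AUC the step-wise interpolated area, both via scikit-learn.
Expected-vs-actual QA agreement sorts residues by mapped QA, windows them
as in calibration, and compares each window's mean mapped QA (the expected
MCC) with its measured MCC via PCC, MAE and MSE, excluding undefined-MCC
windows. Coverage curves report the MCC of the top-QA fraction of residues
over a coverage grid (ties at the cutoff broken by input order); subsets
containing one label class are recorded as undefined and skipped by the
significance scan. The marked coverage is the largest one whose MCC beats
the full-dataset MCC by at least 10 % (relative; an absolute mode exists)
with p < 0.001 under the resampling test; all qualifying coverages are also
returned, since "the" marker is ambiguous when many qualify.

Significance between two metric samples (each from 100 seeded subsamples of
50 % of residues, or of whole proteins for predictor-level comparisons)
uses an Anderson–Darling normality check on both samples at α = 0.05, then
a paired t-test if both pass and the Wilcoxon rank-sum test otherwise.
Identical samples short-circuit to p = 1 (the paired t statistic is 0/0
there). Degenerate subsamples are redrawn up to 10 times.

Predictor comparison emits, for a designated reference, per-competitor
metric differences, their medians, the relative ROC-AUC error reduction
(ref − best other)/(1 − best other), and the MCC gap to the second best.
QA stratification classifies disordered runs as short (<10), medium
(10–30) or long (>30 residues), reports mean mapped QA per class and for
ordered residues, and profiles mean QA against distance (0–20) from the
nearest IDR boundary residue.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, not
protein biophysics: sequences are uniform random standard residues (nothing
downstream predicts from sequence), and disorder labels are laid down as
non-overlapping, non-adjacent runs drawn from a short/medium/long mix
against a dataset-level budget, realizing a target disorder fraction within
10 % relative (default 6 %, the prevalence of large curated disorder
benchmarks, so MCC magnitudes and window behavior are realistic).

Base-predictor errors are *region-shaped*, the way real predictors fail:
a whole disordered run is missed with probability `miss_rate`; caught runs
have each boundary jittered by up to `boundary_blur` residues with a
probability scaling with the miss rate (so an error-free model stays
error-free), producing the terminus effect that the QA stratification
analysis then detects; false disordered segments are laid down over ordered
stretches at `overcall_rate`; optional independent per-residue flips sit on
top. Independent per-residue errors were rejected deliberately: an isolated
wrong residue inside a long disordered run is trivially repaired from
sequence context alone, which would let a recurrent consensus match the
QA-aware model and make the QA-ablation comparisons vacuous. Propensities
are drawn from class-conditional Beta shapes on either side of the 0.5
threshold (modes near 0.15/0.85, spread set by `propensity_noise`), so the
binary call always reflects the realized prediction and errors are as
confident as correct calls. Raw QA is
`informativeness × correctness + (1 − informativeness) × Uniform(0,1)`.

**The canonical meta scenario** (`make_meta_scenario`) fixes the study
conditions for the meta experiments: 60 proteins of length 100–220 at 12 %
disorder with a 0.3/0.5/0.2 length mix — disorder-richer than the dataset
default so the fixture contains ~50 IDR events; at 6 % it holds ~17, and
single missed runs then dominate subset-level AUCs. Three base predictors
(region miss 0.15, overcall 0.05, noise 0.45) each fail on their own third
of the proteins (rates ×3, making missed runs the majority there), thirds
pairwise disjoint and covering all proteins; QA informativeness 0.9.
Proteins split 15/30/15 into calibration/train/test, stratified by failure
set so every subset sees each predictor fail on the same share. Residues
where two predictors err together cannot be fixed by majority vote and the
failing pair is not identifiable from propensities alone — exactly the
signal the QA columns carry, which is what the meta-dominance and
QA-ablation properties in the test suite measure.

**What passing these tests does and does not show.** The synthetic world
has exchangeable proteins, known error processes and a QA stream correlated
with correctness by construction. Results demonstrate that the machinery is
correct and that the QA-repair mechanism works when its premises hold; they
say nothing about the accuracy of any real disorder predictor, for which
real base predictions and curated annotations would be required.

## Problem sizes and determinism

The test suite and the acceptance script run the full study at desk scale:
~10 k residues per scenario, 150-residue calibration windows, the default
biLSTM trained for its full 50 epochs (~35 s on one CPU), the QA ablation
over 5 seeds, and the 21-architecture grid for one epoch on a miniature
subset. Calibration-recovery checks use pools of 40–80 k residues at the
2000-residue default window. All randomness flows from explicit
`numpy.random.default_rng` seeds; training is single-threaded numpy, so
equal seeds give bit-identical models, thresholds and artifacts (the
pipeline manifest records stage seeds and artifact hashes to make this
checkable).

## Known limitations

- The raw-QA generator for real predictors is out of scope; raw QA is a
  pluggable input, and the meta output's own raw QA uses the
  threshold-margin stand-in described above.
- Exactly three base predictors are supported by design.
- The calibration curve is only as good as the calibration pool; pools
  under ~10 windows produce degenerate curves, which the window-size
  validation only partially guards (it enforces pool ≥ 2 windows).
- MCC-vs-coverage points where the selected subset is single-class are
  undefined rather than zero; downstream consumers must handle the gaps.
- Per-residue file formats are this package's own dialect (TSV with a
  named-column header, comma accepted on read); there is no standard for
  per-residue QA interchange.
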