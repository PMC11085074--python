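# Methods

## Pair-image featurization

For a candidate pair (TF *a*, gene *b*) with expression vectors
*x = expr(a)*, *y = expr(b)* over the same samples, the feature is the 2D
histogram `H[i, j] = #{s : x_s ∈ bin_i, y_s ∈ bin_j}` with equal-width
bins, half-open `[e_i, e_{i+1})` with the final bin closed, so the raw
counts always sum to the number of samples. Defaults and rationale:

* **bins = 32** per axis. 32 × 32 per modality; the stacked bulk +
  single-cell image is 64 × 32 (bulk block on top). The orientation
  convention — TF on the first axis, target on the second, bulk above
  single-cell — is arbitrary but fixed; the classifier learns whatever
  convention it is trained under, and the scanner enforces the same
  histogram configuration via a config digest stored with the model.
* **Bin ranges: per-gene min/max** within each modality. Expression
  dynamic ranges differ by orders of magnitude between genes, so global
  ranges would collapse most genes into a few bins. A degenerate range
  (constant gene) is widened to `[lo, lo+1]` with a warning. A
  consequence checked by tests: scaling a gene's values by any positive
  constant leaves its histogram unchanged.
* **Count transform: log10(1 + c)** entrywise, applied after binning.
  With thousands of cells and a few hundred bulk samples, raw cell
  counts would dominate the stacked image numerically; the log compresses
  both blocks onto comparable scales. Raw mode is kept for conservation
  checks.
* Expression is CPM/TPM-normalized (per-sample sum 10⁶; gene-length
  correction applied when lengths are supplied) and log10(1 + v)
  transformed before histogramming. The log is applied to **both**
  modalities by default: the transform matters most for sparse, skewed
  single-cell counts, but applying it to bulk as well keeps the two
  blocks of the stacked image on the same scale. A flag disables the bulk
  log for users who want raw TPM binning.

## Classifier

Six 3 × 3 same-padding convolutions (rectifier activations) with 2 × 2
max pooling after the 2nd, 4th and 6th, then flatten, two dense hidden
layers, and a single sigmoid output unit; trained with Adam (learning
rate 10⁻³, batch 32) on binary cross-entropy, with early stopping on the
AUROC of a 10 % stratified validation split (patience 5, max 50 epochs)
and restoration of the best-validation parameters. A 64 × 32 input pools
to 8 × 4 before flattening; inputs too small to survive three pools are
rejected at build time.

Filter widths (32, 32, 64, 64, 128, 128), dense widths (128, 64), kernel
and pool sizes, optimizer settings and stopping rules are all exposed in
`ModelConfig`. The layer inventory itself (6 conv / 3 pool / 2 dense /
sigmoid) is fixed.

The network is implemented directly in numpy (im2col convolutions, exact
analytic gradients — verified against central finite differences to
~10⁻⁹ relative error in the test suite) and driven by a single seeded
`numpy.random.Generator`, which makes training bit-reproducible for a
fixed seed on any platform. On desk-scale corpora (hundreds of pairs)
training takes seconds to a couple of minutes on one CPU.

`PairImageCNN` follows the scikit-learn estimator API (`fit`,
`predict`, `predict_proba`, `get_params`/`set_params`, fitted attributes
with trailing underscores), so it composes with sklearn pipelines and
model selection; the module-level `train` / `predict_scores` /
`cross_validate` functions are thin wrappers.

Metric definitions: TPR = TP/(TP+FN), FPR = FP/(FP+TN), precision =
TP/(TP+FP), recall = TPR, F1 = 2PR/(P+R); a 0/0 is *flagged* as
undefined (`None`), never silently coerced to 0 or raised. The decision
threshold is strict (`score > t`), so a score exactly at the threshold
counts negative. AUROC uses the rank (Mann–Whitney) formulation with
ties counted ½, checked exactly against an O(n²) concordant-pair oracle.

## Synthetic data generator

The generator emulates the one property the featurization depends on:
TF–target co-variation across both samples and cells, against a
background of independent genes.

* Per TF and per sample/cell, a latent log-activity
  `a ~ Normal(μ₀, σ₀)`; the TF's own log-mean is `a`, each of its
  targets' log-mean is `μ₀ + slope · (a − μ₀)`.
* Bulk value: `exp(log-mean + Normal(0, bulk_noise_sd))` — log-normal,
  TPM-like intensities.
* Single-cell value: negative-binomial (gamma–Poisson) with mean
  `exp(log-mean)` and size `sc_dispersion`, then zeroed with probability
  `dropout_rate` — sparse, over-dispersed, zero-inflated UMI-like
  counts.
* Decoys draw independent latent activities. Labels: every (TF,
  own-target) pair is positive; an equal number of (TF, decoy) pairs,
  sampled without replacement, are negative. Cross pairs (TF_i,
  target-of-TF_j) are excluded from negatives to keep labels
  unambiguous.

Defaults are the strong-signal study condition used by the evaluation
suite: 40 TFs × 5 targets + 200 decoys (400 labeled pairs), 200 bulk
samples, 500 cells, slope 2, bulk noise SD 0.2. The remaining values —
baseline log-mean 1.0 and log-SD 1.0 (single-cell means ≈ 0.4–20
counts), NB size 2 (strong over-dispersion), dropout 0.3 — were chosen
once as typical of root-tissue droplet data and are not tuned.

What the generator does **not** emulate: realistic gene counts or TF
family structure, batch effects, cell types and trajectories, shared
targets between TFs, indirect regulation, or the (much weaker)
signal-to-noise of real regulatory relationships. Passing tests
therefore demonstrate that the pipeline recovers planted joint-expression
structure under its stated noise model — not that it attains any
particular accuracy on real organisms' data, where reported AUROCs are
far below the near-perfect values seen here.

## Splitting and cross-validation

Train/test splitting is stratified by label (default 70/30, delegated to
scikit-learn's stratified splitter). Repeated k-fold (default 10-fold ×
20 repeats) shuffles once per repeat with a child seed spawned from the
master seed and slices the permutation into contiguous folds whose sizes
differ by ≤ 1. All splits are pure functions of (input, parameters,
seed). Negative sampling draws uniformly from TF × universe minus
positives and self-pairs.

## Network assembly

Scanning scores all TF × candidate pairs (self-pairs skipped) in chunks
of 1,000 images, so memory is bounded by the chunk, not the genome.
Two thresholding rules are provided because both appear in practice:
retaining the top fraction of edges by score (default 0.10; reports the
implied cutoff; ties at the boundary broken lexicographically by
(tf_id, target_id) so the retained set has *exactly* ⌈f·N⌉ edges and is
reproducible), and a strict fixed-score cutoff (`score > c`). Degree
summaries bin targets by regulator count (1–100, 101–1000, >1000) with
percentages over targets having ≥ 1 regulator.

## Validation statistics

* **Permutation overlap**: the null preserves each TF's out-degree and
  redraws its target set uniformly without replacement from the
  universe. Under this null, the per-TF overlap with a fixed reference
  set is exactly hypergeometric (population = universe, successes =
  reference targets in the universe, draws = out-degree), so the
  implementation samples each TF's per-permutation overlap from that
  distribution directly — an exact, vectorized realization of the null,
  not an approximation; the permutation mean converges to
  Σ_tf d_tf·r_tf/N, which the tests check at 2 % with 10,000
  permutations. The empirical p-value is the strictly-greater count over
  permutations (reported as `< 1/n` when zero); fold enrichment is
  observed/expected, flagged infinite when the expectation is zero.
  Overlap percentages are reported against the *comparable* reference
  edges — those whose TF appears in the predicted network at all.
* **Hypergeometric set overlap**: upper tail P(X ≥ k) via
  `scipy.stats.hypergeom.sf`, checked exactly against subset
  enumeration for small universes.
* **BH adjustment**: statsmodels' step-up implementation behind a
  validating wrapper; checked against the hand-computed
  [0.01, 0.02, 0.03, 0.04] → [0.04 × 4] example.

## GO-based function inference

Annotations are consumed as-is (GAF 2.x or a simplified 4-column TSV):
BP aspect only, evidence restricted to an experimental/curated whitelist
{EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC} (configurable), and 15 root/near-
root BP terms excluded everywhere. No ancestor propagation over the
ontology graph is performed — annotation files are used exactly as
provided; users wanting closure semantics should pre-propagate their
annotation table. Candidate terms per TF are those annotating ≥ 1 of its
targets (keeping the BH family small and well-defined), and BH adjustment
is per-TF, mirroring per-TF reporting. Recovery rate per term is
recovered-TFs / TFs-annotated-with-term; TFs without any known BP
annotation have all their enriched terms flagged fully novel.

## Numerical and design choices

* One-way transform state machine raw → per-million → log; re-normalizing
  or re-logging is rejected rather than silently applied.
* Gene identifiers match by exact string; no alias resolution.
* Sparse input follows the 1-based MatrixMarket coordinate convention
  with gene/barcode sidecars.
* All randomness flows through `numpy.random.Generator` objects seeded
  from explicit integer seeds; child seeds are spawned via
  `SeedSequence`, never reused across purposes.
* Evaluation problem sizes: the acceptance script and end-to-end tests
  use a reduced architecture (filters 8–32, dense 32/16, ≤ 12 epochs) on
  the 400-pair strong-signal condition and a 1,000-pair (500 held-out)
  null condition; these sizes give stable statistics (null AUROC
  standard error ≈ 0.026) while keeping a full run around a minute on
  one CPU.

## Known limitations

* The numpy classifier is CPU-only and desk-scale; genome-scale scans
  (10⁷ pairs) are streamable but slow compared to GPU frameworks.
* Negative labels are sampled, so an unknown fraction of "negatives" in
  real data are undiscovered true edges; this is accepted noise, as is
  conventional for supervised GRN inference.
* Histogram featurization discards sample identity; paired designs or
  pseudotime structure are not exploited.
* The permutation null preserves out-degree only; nulls preserving
  in-degree or co-expression structure would be stricter.
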