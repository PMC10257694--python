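# Methods

## Statistical model

A DIA search produces, per run, a table of candidate *peak groups*: for
every library precursor (modified sequence + charge), one or more
candidate chromatographic co-elutions, each described by 22 MS2-level
subscores (library correlation and dot product, co-elution and shape
cross-correlations, mass deviation, mutual information, signal-to-noise,
isotope agreement, b/y-series evidence, normalized RT deviation, ...).
Library entries are either *targets* or reversed/shuffled *decoys*.
Targets split further, invisibly, into *true targets* (precursor present
in the sample) and *false targets* (library entry absent — guaranteed
for an entrapment species, and the dominant case under search-space
mismatch).  The working assumption of target-decoy FDR estimation, which
this package inherits, is that false targets and decoys are
exchangeable: their subscore vectors follow the same null distribution.

### Label denoising

Each sample's targets are split into `k_folds` folds (default 10).  For
a held-out fold, an ensemble of `ensemble_size` (default 10) logistic
scorers is fitted on the remaining targets (label 1) and all decoys
(label 0), each member on its own full-size bootstrap resample with
per-bag feature standardization.  Members are L2-regularized logistic
regressions fitted by stochastic gradient descent with iterate averaging
(α = 1e-4, balanced class weights); averaging is used because the vote
below thresholds each member's probability, and single-pass SGD noise
near the threshold otherwise dominates the vote outcome.  A member's
vote on a held-out target is positive when its predicted probability is
≥ `vote_probability` (default 0.75; a probability exactly at the
threshold counts as positive).  A target is retained when the positive
vote fraction is ≥ `required_vote_fraction` (default 1.0 — unanimity).
Decoys pass through untouched: they are the negative training set and
the FDR yardstick, and filtering them would bias both.

### Classifiers

Two families, both trained on the pooled (denoised) tables with the
positive class weighted by #decoys/#targets:

* `svm` — linear hinge-loss SGD: L2 penalty, α = 1e-5, adaptive
  learning rate, early stopping on a 10% validation split.
* `gbt` — gradient-boosted trees: raw-logit ("logitraw") objective,
  log-loss evaluation metric, depth 6, learning rate 0.1, up to 200
  rounds with early stopping after 20 stagnant rounds, single-threaded
  histogram tree method for determinism.

The feature scaler (per-feature center/scale) is fitted on the training
pool and stored with the model.  The discriminant score (*DScore*) is
the untransformed decision margin — linear margin or raw tree logit —
because margins preserve the bimodal target/decoy score geometry that
density-based q-value estimation relies on; a squashed probability
saturates both modes.  For prediction the margin passes through the
logistic link and is thresholded at `probability_threshold`
(default 0.5; documented here because no canonical value exists for this
step).  Models serialize to a single JSON document (scaler arrays,
linear weights or the booster's JSON dump, provenance) and round-trip
bit-exactly.

### Prediction gating

Applying the model to a new sample flags each record as predicted-true
or predicted-false.  The *gated* set keeps the predicted-true targets
plus **all** decoys, whatever their own predictions.  Removing
predicted-false targets before FDR estimation is what makes the
procedure search-space-agnostic: the target score distribution loses its
null mode, while the untouched decoy set keeps the null calibrated.
Because decoys are never removed while some true-null targets are, the
resulting q-values are conservative (the realized FDP at q ≤ 0.01 sits
below 0.01 in the gated acceptance checks).

### q-values

At score threshold s, with D(s) and T(s) the decoy and target counts at
or above s:

    FDR(s) = D(s) / (T(s) + D(s))
    q(s)   = min over thresholds t ≤ s of FDR(t)

The q-value is the smallest estimated FDR of any acceptance region
containing s; the running minimum makes q monotone non-increasing in the
score.  The fraction-of-accepted denominator (T+D, not the classical
D/T) is used throughout, and no PIT/pi0 estimate ever re-weights the
decoys: with identical target and decoy score samples the raw FDR at the
minimum score is exactly D/(T+D).

Two estimators:

* **counting** — exact empirical tail counts; always available.
* **spline** — target and decoy scores are histogrammed on a fixed
  1000-bin grid spanning the pooled range padded by three bin widths;
  the cumulative histogram is interpolated by a monotone cubic (PCHIP),
  whose derivative is a non-negative density integrating to 1, and whose
  closed form supplies the tail integrals D(s), T(s) without quadrature
  error.  Raw FDR is evaluated at the requested scores only and
  monotonized over them, exactly as in counting, so the two estimators
  agree to ~0.002 in the q ≤ 0.1 region at 10,000 scores per class.
  Requires ≥ 50 scores per class; callers fall back to counting below
  that.

### Global rollup, matrix, evaluation

For peptide- or protein-level FDR, the highest-scoring (best-peakgroup)
record per group key across all samples represents the group; q-values
are estimated on the representative scores (spline when counts allow).
Protein groups are opaque keys — no protein inference is performed.

The quantitative matrix keeps a cell iff that sample's record passed the
precursor q cutoff, and a row iff its peptide and protein pass their
global cutoffs; absent cells stay absent (no zero imputation).
Evaluation metrics: *missingness* (absent/total cells), the
*entrapment FDR* curve (absent-species identifications over all
identifications per q cutoff), and *ratio validation* (fraction of rows
whose between-group log2 fold change is within a tolerance, default
±0.2, of the species' expected ratio; fold change computed as log2 of
the ratio of group means over present cells, with a mean-of-logs variant
available).  The "ratio FDR" curve reports the out-of-window fraction as
a function of the tolerance — the other conceivable definition
(decoy-derived FDR of the within-window set) is not implemented.

## The simulator

`gpscore.synthetic` emulates per-sample score tables, not raw signal.
Subscore vectors are 22-dimensional Gaussians with exchangeable
correlation 0.3 and unit variances; true targets' best peak groups are
shifted by `effect_size` (default 3.0 standardized units) on 12
designated informative features, while false targets, decoys, and
non-best candidates share the null.  A static library fixes each
precursor's truth label, species, baseline log2 intensity (N(14, 2²))
and true log2 fold change; per sample, intensities are log-normal around
the baseline (noise sd 0.1 log2 units by default) times an exact
power-of-two spike factor, with missing-at-random dropout.  One
precursor per peptide, five peptides per protein.  All randomness flows
from a single seed through spawned substreams, so output is
bit-reproducible.

Default condition sets used by the acceptance checks: matched library
π = 0.5; calibration experiment π = 0.3 with 5000 targets + 5000 decoys
per sample (30 samples: 20 train / 10 evaluate); search-space mismatch
π = 0.05 with the same null; two-species entrapment with a fully null
species at 50% of the library; spike-in design 2 groups × 10 replicates
with species log2FC {0, 2}.  These sizes run the whole suite on one CPU
in a few minutes.

What the simulator does *not* model — and hence what passing tests do
not show about real data: correlated, heavy-tailed, feature-specific
subscore distributions; retention-time drift and alignment error;
interference between co-eluting precursors; shared peptides across
protein groups; informative (intensity-dependent) missingness; and any
systematic difference between decoys and false targets, which is
precisely the exchangeability assumption the method stands on.

## Numerical and design choices

* Tie-breaks: equal DScores resolve to the lowest peakgroup rank, then
  input order; deterministic and stable everywhere (best-peakgroup
  selection, RT anchors).
* RT anchor bins are equal-width over the observed per-sample RT range
  of predicted-true targets; empty bins yield no anchor.
* Bootstrap bags are full-size (same size as the training partition,
  drawn with replacement) — the standard bagging contract; a bag that
  loses one class entirely is redrawn.
* Fold assignment, bootstrap draws, SGD shuffling, and per-sample
  simulation streams all derive from one master seed via
  `numpy.random.SeedSequence` spawning.
* Probabilities are thresholded raw (no calibration step) both in the
  denoiser vote and in prediction gating.
* Second-pass signal re-extraction of gated precursors (adaptive
  search-space re-querying) is out of scope: gating operates on the
  already-extracted table.  Reading raw spectra or chromatograms,
  spectral-library construction, normalization, protein-abundance
  inference, and differential expression are likewise out of scope.

## Known limitations

* The spline estimator's advantage over counting (smoothing sparse decoy
  tails) is modest at simulated sizes; both are exposed so callers can
  trade smoothness for exactness.
* Per-sample q-values annotate decoy records too (by interpolation on
  the target score axis) for diagnostics; only target q-values have the
  FDR interpretation.
* The global rollup assumes best-peakgroup tables as input; feeding it
  multi-candidate tables silently rolls up over candidates as well.
* With `required_vote_fraction < 1` the denoiser's retained-target count
  is no longer guaranteed monotone in `vote_probability`.
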