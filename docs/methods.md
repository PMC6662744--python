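# Methods

## Problem and model

`mircotrain` addresses pre-miRNA classification when almost no labelled
examples exist. A candidate hairpin can be judged from two nearly independent
*views*: its sequence/structure (the *de novo* view) and the pile-up pattern
of small RNA-seq reads mapping onto it (the *expression* view). Multi-view
co-training exploits this redundancy: each view's classifier labels the
unlabelled instances it is most confident about, and those instances — with
their *predicted* labels — augment the **other** view's training set. Because
the views err on different instances, each view receives information it could
not have extracted itself, and drift (a classifier amplifying its own
mistakes, the failure mode of self-training) is damped.

The iteration loop is:

1. fit each view's classifier on its current labelled training set
   (initially a seed of 5 positives + 5 negatives);
2. score each view's own unlabelled pool;
3. take each view's single most confident positive (argmax score) and
   negative (argmin score);
4. remove those instances from both pools and append them, with the donor's
   predicted labels, to the opposite view's training set;
5. repeat for a fixed number of iterations (default 11) or until the
   holdout learning curves plateau.

Only 1 positive + 1 negative are transferred per view per iteration: small
batches keep the pseudo-labels high-confidence, which is the mechanism that
controls drift.

Two controls bracket the method. *Self-training* is identical except picks
return to the donor's own training set (one view, no cross-talk). *Passive
learning* keeps the cross-view transfer and the training-set growth schedule
but draws transfers uniformly from the >50% (labelled positive) and <50%
(labelled negative) score strata instead of taking the extremes — it controls
for training-set size, isolating the value of confidence ranking. The
*no-learning* baseline is the seed-only classifier (any strategy with
`iterations=0`; the engine guarantees the three strategies produce
bit-identical iteration-0 models for a given seed).

### Interpretations where the procedure was underdetermined

* **Transfers leave both pools.** The iteration description only forces
  removal from the donor's pool; we also remove the instance from the
  recipient's pool, so nothing is simultaneously training data in one view
  and unlabelled in the other, and no instance can ping-pong between views.
  Donors pick sequentially within an iteration, with ids already claimed
  excluded, so an instance is transferred at most once.
* **No 0.5 gate on confident picks.** "Most confident positive" is the
  argmax score even if every pool score is below 0.5 (and symmetrically for
  negatives). Passive learning's empty-stratum case falls back to the
  extreme score and is flagged in the trace.
* **One shared holdout** (stratified 20%) evaluates both views at every
  iteration of one run.
* **Ties** in scores break lexicographically by instance id; all randomness
  (split, seed draw, forest seeding, passive draws) derives from one master
  seed through per-(view, iteration, purpose) sub-streams, so runs are
  bit-reproducible and the iteration-0 model is strategy-independent.

## Classifier

A 500-tree random forest (scikit-learn, otherwise default parameters) is the
default probabilistic classifier; positive-class `predict_proba` is the
score. Anything implementing `fit(X, y)` / `score(X) -> P(positive)` can be
substituted (the engine is classifier-agnostic; fast tests use smaller
forests, which changes nothing about the bookkeeping being tested).

## Combining the views

The combined classifier accepts, per instance, the predicted class of the
view with the larger confidence `|score − 0.5|`; confidence ties go to the
expression view (fixed, arbitrary). For PR analysis the combined ranking
score is the winning view's positive-class probability — a confident
negative winner yields a score near 0 and ranks low, a confident positive
winner near 1 and ranks high, which is the ordering a PR sweep needs. Only
the class decision was prescribed; this ranking rule is our choice.

## Evaluation protocol

Performance is the area under the precision–recall step curve (AUPRC) on the
holdout, computed by a descending-score threshold sweep with tied scores
grouped (equivalently, average precision). PR space is preferred over ROC
because candidate-hairpin screens are heavily imbalanced in practice. The
protocol repeats the full split → seed → learn cycle (default 100
repetitions; 30 in the in-repo acceptance run, 12 in the acceptance script —
the comparison directions are stable well below that) and reports mean ± sd
per strategy × view. Strategy differences are tested with one-way ANOVA
followed by Tukey HSD contrasts of co-training against each alternative
(α = 0.01); the combined classifier is compared with each view by a paired
t-test, paired by repetition (pairing by dataset would need multiple real
datasets). Zero-variance degenerate inputs short-circuit to F = 0, p = 1
with a flag rather than an error.

## Sequence view

Features computed per candidate (L = sequence length):

| family | definition |
|---|---|
| MFE | folding (pseudo-)energy of the candidate |
| AMFE | MFE / L × 100 |
| MFEI | AMFE / GC%, 0 if GC = 0 (logged) |
| GC_content | 100 × (#G + #C) / L |
| 32 triplets | for each 3-nt window: middle nucleotide × paired/unpaired pattern (brackets collapse to `(`), frequencies over L − 2 windows |
| 16 dinucleotides | overlapping 2-mer frequencies over L − 1 windows |
| robustness | mean base-pair distance (symmetric difference of pair sets) between the wild-type fold and each of the 3L single-point mutants, divided by L |

The robustness definition is an operationalization of the
structural-robustness family: lower values mean the fold survives point
mutation, a property of genuine pre-miRNA stems. It costs 3L folds per
candidate, so the featurizer exposes `include_robustness=False` for large
batches.

The folding backend is pluggable. The baseline is a Nussinov-style
base-pair-maximization dynamic program (AU/GC/GU pairs, hairpin loops ≥ 3
nt, energy = −pair count, deterministic traceback: unpaired preferred on
ties, then the smallest partner index). It is not a thermodynamic model —
its role is to make the pipeline self-contained and exactly testable against
exhaustive enumeration; an `RNAfold` (ViennaRNA) backend is provided where
real energies matter.

Feature subset selection follows the CFS principle: greedy forward search on
merit(S) = k·mean|r_cf| / sqrt(k + k(k−1)·mean|r_ff|), where r_cf is a
feature's Pearson correlation with the 0/1 label and r_ff the between-feature
correlation; search stops when no addition raises the merit. Forward
hill-climbing approximates Weka's best-first default; constant features get
zero correlations; name order breaks ties. The selected *set* depends on the
data supplied — no fixed feature list is hard-coded.

## Expression view

Eight read-stack/structure features (all percentages in [0, 100]):
percentage of paired nucleotides in the mature region; number of lower-stem
pairs (both partners outside mature ∪ star ∪ loop); percentage of all reads
inconsistent with Dicer processing; percentage of loop reads consistent;
percentage of all reads consistent; percentage of mature reads consistent;
percentage of star reads consistent; total precursor reads in reads per
million of the library.

A read stack is Dicer-consistent when its 5′ start lies within ±`tolerance`
(default 1 nt, configurable) of the annotated mature or star 5′ end. A stack
belongs to the region holding the majority of its span, ties resolved
mature > star > loop. Consistent% and inconsistent% are complements by
construction, so they sum to exactly 100 whenever reads exist.

When region annotations are absent they are inferred: mature = span of the
highest-count stack (ties: earlier start, then shorter span); star = the
pair-table partners of the mature positions shifted by the canonical 2-nt 3′
overhang; loop = the gap between the arm-proximal ends; everything outside
is lower stem. This is a heuristic stand-in for upstream annotation tools
and is deliberately simple and deterministic.

## Data labelling rules

Given candidate hairpins, a known-miRNA set, coding-alignment hits and a
functional-ncRNA set: a candidate matching a known miRNA (exact substring in
either direction after T→U normalization — a deterministic, dependency-free
reading of "matches a known miRNA"; mismatch-tolerant matching belongs to the
upstream aligner) is a positive; a non-matching candidate whose best coding
hit has ≤ 2 mismatches is a negative; ncRNAs are appended to the negatives so
classifiers cannot win by separating coding from non-coding. Everything else
is discarded. Redundancy filtering of inputs is assumed done upstream.

## Synthetic data

`gen_two_view` draws class-conditional Gaussians: informative dimensions
have class means ±sep/2 at unit within-class sd, noise dimensions are
standard normal, and the views are conditionally independent given the class
— the co-training premise in its cleanest form, with separability as an
explicit dial. Defaults (375 + 375 instances → a 600-instance 80% training
share; one informative dimension per view at separation 2.0, so `sep` *is*
the view's class separation; 5 noise dims per view) are the benchmark
conditions used by the acceptance checks — separable enough that confident
picks are usually right, hard enough that a 10-sample seed classifier has
real room to improve.

`gen_hairpins` emulates the upstream mapping output: positives are perfect
`stem_len` complementary stems around a random loop (defaults 25 + 8 → 58 nt
candidates), folded by the baseline folder, with `pos_consistency` (default
0.9) of their `reads_per_candidate` (default 100) reads stacked exactly at
the annotated mature/star 5′ ends (60/40 mature-heavy) and the rest
scattered; negatives are composition-matched shuffles (so GC content alone
cannot separate the classes) with arbitrary anchor annotations and
`neg_consistency` (default 0.1) anchored reads. Candidates carry their
generator annotations, and hidden truth is retained only for trace auditing.

What the simulators do *not* model: sequencing error, adapter artifacts,
multi-mapping reads, UMI structure, realistic expression dynamics, and real
hairpin thermodynamics. Passing tests therefore demonstrate that the
*machinery* behaves as specified under controlled class structure — not that
any particular AUPRC will be attained on real libraries.

## Numerical and scale choices

* The acceptance test runs the strategy comparison at 30 repetitions on the
  default Gaussian conditions with the default 500-tree forest; the
  acceptance script uses 12 repetitions. Both sizes were chosen as the
  package's own benchmark scale: the compared directions (co-training >
  no-learning, ≥ passive; combined ≥ best view) are stable at these sizes.
* AUPRC requires both classes in the holdout; single-class inputs raise.
* Pool exhaustion mid-run truncates the trace with a
  `status = "pool_exhausted"` flag instead of raising.
* The plateau stopping rule fires when every view's per-step AUPRC gain over
  the last `window` iterations stays below `epsilon`.
* Exact-equality claims in tests (frequency sums, percentage complements,
  oracle equivalence) hold to 1e-12 or exactly where the arithmetic is
  closed-form.

## Known limitations

* The baseline folder maximizes pair count, not stability; MFE-derived
  features from it are pseudo-energies. Use the ViennaRNA backend for
  thermodynamically meaningful MFE/AMFE/MFEI.
* The region-annotation heuristic assumes a single clean duplex; multi-loop
  or branched candidates get a best-effort annotation.
* `combine_predictions` assumes calibrated-ish scores; forests trained on
  ~30 instances are only roughly calibrated, which the confidence rule
  tolerates but does not correct.
* The statistical harness treats repetitions as exchangeable units; they
  share the underlying dataset, so p-values speak to seed/split variability,
  not across-dataset generality.
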