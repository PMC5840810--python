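# Methods

## Models

A **PFM** stores per-position base probabilities (columns sum to 1, base
order A, C, G, T). A **PWM** stores unbounded additive weights; a site of
the matrix width scores `Σᵢ w(bᵢ, i)`. The **adjacent-dinucleotide PWM**
stores 16 weights per adjacent position pair, first-base-major (AA, AC, …,
TT); column *i* covers site positions (*i*, *i*+1), so a matrix with *k*
pair columns scores sites of length *k*+1. A PFM used directly as a scorer
scores a site by its log probability.

Conversions are the two standard maps. Seeding: `w(b,i) = ln(p(b,i)/bg(b))`,
log-odds against a background (uniform by default). Reading a PWM back as a
PFM treats weights as energies: per-column softmax, stabilized by
subtracting the column maximum (shift invariance makes this exact). With a
uniform background the two maps are mutually inverse to within 1e-9, which
the tests check. The mono→dinuc embedding assigns each pair column the first
base's mono weight, plus the second base's weight in the last column;
consequently every site scores identically under both models (verified
exhaustively at widths ≤ 5), so dinucleotide training starts from exactly
the mono seed's ranking.

Reverse complementation of a model is defined by the identity
`score(rc(M), s) = score(M, rc(s))` for all sites `s`, implemented by
complement-permuting and reversing the matrix (for pair weights, pair
(x, y) at column *i* maps to (ȳ, x̄) at the mirrored column). It is an
involution and is tested against explicit sequence reversal on random
(matrix, site) pairs.

## Dataset preparation

Coordinates are 0-based half-open (BED convention). Each peak's
point-source is the narrowPeak summit (column 10 ≥ 0) when present, else
the interval midpoint (floor). The positive window of width *W* (default
100 bp) is `[p − W/2, p − W/2 + W)`; odd widths put the extra base right of
the point-source. The paired negative window starts `negative_offset` bp
(default 100; 5000 for the distal variant) after the positive window's end.
A pair is dropped whole if either window leaves the chromosome.

Each sequence is reduced to its single best site under the seed matrix:
every offset is scanned on both strands (minus-strand scores are computed
by scanning the reverse-complement model forward, which is exact), windows
containing ambiguous bases are skipped, and ties break to the smaller
offset, then the forward strand — a fixed order chosen for reproducibility.
Sequences with no ambiguity-free window raise rather than disappear
silently, leaving the decision to the caller. Best sites are identified
once with the seed and frozen; training never re-scans.

Cross-validation folds are assigned to positive/negative *pairs*: a seeded
shuffle followed by a round-robin deal, so fold sizes differ by at most one
pair, each fold's training set is the other *k*−1 folds (train:test =
(k−1):1), and a site and its matched control never straddle folds. The
small-training variant draws two disjoint random subsets of
`floor(fraction · n)` pairs each (default fraction 0.1), emulating training
sets no larger than the test set.

## Perceptron training

Training configuration: learning rate 0.01, maximum 500 epochs, patience 45
epochs without a new best training AUROC (None disables early stopping),
mode mono or dinuc, explicit seed. The learning rate is deliberately small
relative to the nats-scale log-odds seed so early epochs refine rather than
erase the seed; the remaining defaults bound runtime while leaving typical
problems converged well before the cap.

Each epoch: score all sites with the current matrix; misclassified sites
are the positives strictly below the best negative and the negatives
strictly above the worst positive (ties are not misclassified — note the
degenerate consequence that a dataset whose scores are all exactly tied,
e.g. a uniform seed on one-letter classes, is a fixed point); updates
(+lr on each misclassified positive's observed features, −lr on each
misclassified negative's) are applied sequentially in an rng-shuffled
order. Identification happens once at epoch start, so the update set is a
batch and the shuffle matters only for the reproducibility of the rng
stream. Training AUROC is recorded after every epoch; epoch 0 is the seed
itself, and the returned model is the best snapshot, so the result never
ranks worse than the seed on training data and the reported best is
monotone in the epoch budget at fixed seed.

No weight decay and no score normalization are applied: AUROC is invariant
under shifts and positive scalings of the score, so such terms would only
change the parameterization, not the objective.

## Metrics

AUROC uses the Mann–Whitney convention (tied positive/negative pairs count
one half), computed by rank sums but contractually identical to pair
counting — the tests compare against an O(n²) enumeration exactly. AUPRC is
non-interpolated average precision with tied scores grouped, so a threshold
can never split a tie group; matrix scores over short sites tie often, and
the convention changes exact values. Cross-validation reports per-fold
train and test AUROC/AUPRC with mean and standard deviation (n−1
denominator). The comparison report emits a per-model table formatted
`mean (sd)` to three decimals, per-model boxplots of the train−test gap
(the overfitting signature), and pairwise scatter plus sorted-difference
plots of per-dataset test scores; for a single dataset the table shows
fold statistics, for several it aggregates per-dataset means.

## Feature classifiers

The 4-bit encoding maps A→1000, T→0100, G→0010, C→0001 (bit order A, T, G,
C) and concatenates positions. Shape tracks carry 8 per-position structural
descriptors (HelT, MGW, ProT, Roll and their second-order variants) in a
fixed row order; they are consumed from files, never computed — structure
prediction from sequence is outside this package's scope. Normalization is
per-feature min–max fitted on training tracks only; test values are clamped
to [0, 1] and constant features map to 0.5. Feature vectors concatenate
blocks in the fixed order [matrix score][4-bit][shape] according to the
variant. The classifier is a contract — `fit(X, y, seed)` /
`predict_score` monotone in positive-class confidence — with scikit-learn's
gradient boosting as the named default adapter and a logistic adapter as a
linear baseline; hyperparameters are constructor configuration, not
constants.

## Synthetic data

The generator defines the study conditions under which the package is
validated. Ground-truth motifs are drawn per-column from a symmetric
Dirichlet; concentration 0.1 yields sharp, motif-like columns (mean column
maximum > 0.7), large concentrations approach uniform. Positive sequences
are i.i.d. background (specified GC content) with one site sampled from the
motif planted at a uniform random offset; negatives are pure background;
defaults are 500+500 sequences of 100 bp, matching the positive/negative
window protocol above. An optional first-order background adds same-base
persistence for stress tests. Adjacent-pair coupling reweights the joint
distribution of one dinucleotide by 16 log-weights and renormalizes —
with uniform marginals at the coupled columns this creates dependence that
is provably invisible to any mononucleotide matrix, which is what the
dinucleotide-advantage experiments exploit. Fabricated shape tracks are
base-dependent mean vectors plus Gaussian noise: synthetic stand-ins, not
physical predictions, reproducing only the property that structure encodes
sequence (so shape-only classifiers beat chance). Everything is
bit-reproducible from (configuration, seed), and the truth record suffices
to reconstruct every planted site.

What the generator does not emulate: peak-calling noise and mislocalized
summits, chromatin and repeat structure, GC-matched negative selection,
motif multi-occurrence within a peak, and real DNA-structure physics.
Passing tests therefore demonstrate the algorithmic contracts and the
statistical behaviour of the models under clean planted-signal conditions,
not performance on real ChIP-seq data.

## Validation experiment design

The acceptance checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` use three designed experiments; problem sizes were
chosen to give each experiment statistical power at desk scale.

*Parameter recovery.* Planted-motif data (width 8, concentration 0.1,
500+500 sequences of 100 bp); the trainer is seeded with a 60:40 mixture of
the truth and an independent random motif. A uniform blend would be useless
here: Pearson correlation is affine-invariant, so `0.5·truth + 0.5·0.25`
correlates with truth at r = 1 before any training. Because a Dirichlet(0.1)
draw occasionally yields several near-uniform columns (making the planted
motif intrinsically hard to localize regardless of method), recovery is
assessed as the mean over three generator draws: held-out AUROC ≥ 0.9 and
mean per-column Pearson r ≥ 0.8 between the softmax of the trained PWM and
the generating motif.

*Dinucleotide advantage.* Width-8 sites scored directly (sequence length =
width, forward strand) so scanning noise does not dilute the signal:
flanking columns Dirichlet(3.0) put the mono model near AUROC 0.8, columns
3–4 are uniform with diagonal pair coupling of +2.5 log-units, 300+300
pairs, an 80:20 split, 10 seeds. Under coupling the dinucleotide mode's
mean held-out AUROC exceeds mono's (≈ +0.06–0.09); without coupling the
mean gap is ≈ 0 (a small negative bias, within ±0.03, reflects the 16×
parameter count overfitting slightly at this sample size).

*Classifier comparisons.* Small planted datasets cross-validated with the
matrix models and boosted classifiers; with 150+150 sites the boosted
models show the large train−test gaps expected of high-capacity learners,
while the linear matrix models sit near the diagonal.

## Numerical and degenerate-input conventions

JASPAR counts are normalized `(c + p)/(Σc + 4p)` with Laplace pseudocount
p = 1 by default, guaranteeing positive probabilities for log-odds seeding;
seeding from a PFM with zeros raises with instructions to re-read with a
pseudocount. Scoring a site against a zero PFM entry yields −inf (ranking
still works); training forbids non-finite scores. Matrix serialization
writes repr-precision floats for bit-exact round trips. Sequences shorter
than the matrix width, empty classes, malformed matrices/BED lines, and
layout-mismatched feature vectors raise immediately with the offending
item named.

## Limitations

Only fixed-width, gapped-free motifs; only adjacent-pair dependence (no
longer-range couplings); negatives by positional offset only; no
significance testing of metric differences; shape features must be
precomputed externally. The perceptron maximizes a surrogate of AUROC by
error correction rather than the metric directly; with patience disabled it
is not guaranteed to converge on non-separable data, which is why the best
snapshot, not the final matrix, is returned.
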