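# Methods

This note documents the models and procedures implemented in `vesipred`,
the conventions chosen where the underlying method left details open, and
the limits of what the synthetic benchmarks demonstrate.

## Profiles and normalization

A PSSM is the L × 20 matrix of per-position log-odds substitution scores
produced by iterative PSI-BLAST search, with columns in the fixed order
`A R N D C Q E G H I L K M F P S T W V Y`. Only the 40-column ASCII dialect
is parsed: the first 20 numeric columns of each body row are the profile;
the weighted-percentage and information columns are discarded.

All feature encoders consume profiles normalized entry-wise by the logistic
function 1/(1+e^(−x)). Raw log-odds can be negative or sum to zero, which
would leave the transition-probability features (products divided by their
row sums) undefined; the logistic map confines entries to (0, 1) while
preserving order, so the consensus sequence (per-row argmax) is identical
before and after normalization. Whether the original feature definitions
intended raw or transformed scores is not specified anywhere we could
verify, so the logistic choice is a design decision of this package, flagged
explicitly by the `normalized` attribute; applying it twice is an error
rather than a silent compression.

## Feature encoders

**AATP (420).** Amino-acid composition (per-column mean, 20 values) plus
transition probability composition: T_ij = Σₖ P_{k,i} P_{k+1,j} over
consecutive row pairs, each source-residue row normalized to sum to one
(400 values). The flattening is row-major with the source residue outer. A
zero row normalizer emits 20 zeros — impossible after logistic
normalization, kept as defensive behaviour.

**Segmented pseudo-PSSM (380).** The profile is split at L1 = ⌊L/2⌋ into
two segments, and at L1 = ⌊L/3⌋ into three, with the remainder absorbed by
the last segment ("equal segments" with integer row counts force a
convention). Per segment and column: the segment mean (λ = 0) and the mean
squared difference of entries λ rows apart (λ = 1..4 for two segments,
1..2 for three). All lag windows stay inside their segment, which the
printed index bounds themselves imply. One printed summation bound for the
third segment's mean is an evident typographical slip (its upper bound
repeats L1); it is implemented as the third segment's rows, consistent with
the lag-difference line for the same segment. Output ordering is segment
outer, λ middle, column inner; the same convention applies below.

**Segmented autocovariance (280).** For the same segmentations, the lag-lg
autocovariance of each column around its own segment mean, lg = 1..4 (two
segments, 160 values) and lg = 1..2 (three segments, 120 values).

**Consensus-sequence features (40).** The consensus sequence is the
per-row argmax column, ties broken toward the lower column index for
determinism. CSAAC is its composition (counts / L). CSCM, the composition
moment, sums the 1-based positions at which each residue occurs and divides
by L(L−1), the standard composition-moment-vector normalizer.

The fused vector is AATP followed by CSP (420 + 700 = 1,120). The relative
block order is a fixed convention; nothing downstream depends on it. The
minimum profile length is L = 10, the smallest L for which every lag window
above is non-empty.

## Imbalance handling

ENN (edited nearest neighbours) removes a majority-class sample when its
k = 3 nearest neighbours — Euclidean on z-scored features, excluding
itself — fail the agreement rule (`all`: any disagreeing neighbour
triggers removal; `mode`: the neighbour majority must disagree). Minority
samples are never touched and nothing is synthesized, so the resulting
class ratio is a data outcome, not a parameter; deliberately, no ratio knob
is exposed. Random undersampling and SMOTE (uniform interpolation between a
minority point and one of its k = 5 minority neighbours) are provided as
alternatives; the combined and prototype-based methods are declared
interface hooks that raise `NotImplementedError`. Distances are computed on
z-scored features because the downstream pipeline standardizes features and
neighbour queries are scale-sensitive. When classes tie in size the
negative class is treated as the majority, matching the direction of
imbalance in the motivating problem.

Because oversamplers synthesize rows, plain k-fold cross-validation leaks
information from validation samples into training. `make_resampled_folds`
therefore applies the resampler to the k−1 training folds only; validation
folds are untouched original data and partition the input exactly once per
pass. The leakage property is asserted by id audit in the tests.

## MRMD feature selection

Each feature receives a relevance score (|Pearson r| with the binary
label; constant features score 0) and a distance score (mean Euclidean
distance between its z-scored column and every other column, rescaled to
[0, 1] by the maximum; duplicated features score low). `score_sum` ranks by
relevance + distance.

The five link-analysis methods aggregate three base orderings — relevance,
distance, and their sum — via a directed preference graph. An edge u → v
exists when v outranks u on at least one base ordering, and its weight is
the total score margin Σ max(0, s_v − s_u) over the three score vectors.
Margin weighting is deliberate: with ordinal (win-count) weights, the HITS
eigenvectors are captured by large blocks of near-indistinguishable noise
features, because the distance ordering roughly reverses the relevance
ordering and a hair's-breadth win counts as much as a decisive one. Margins
make the centrality mass track effect sizes, and all five methods then
recover planted informative features reliably.

Centralities: PageRank (damping 0.85), TrustRank (personalized PageRank
restarted at the top decile of features by relevance), LeaderRank (PageRank
on the graph augmented with a bidirectionally linked ground node), HITS
authority descending (`hits_a`), and HITS hub **ascending** (`hits_h`): a
feature's hub score aggregates the authority of the features that beat it,
so a low hub score marks a feature beaten rarely and only by weak margins.
All centralities are deterministic power iterations (tolerance 1e−9, max
200 iterations); ties are broken by relevance, then feature index. The
exact graph semantics of the original MRMD2.0 tool are not published in a
reproducible form; these constructions are this package's own, chosen for
determinism and validated by the planted-feature benchmarks.

`select_subset` evaluates a caller-supplied (typically cross-validated)
metric on top-k prefixes over a grid (default: every 10th dimension from
20) and returns the best k, ties preferring the smaller subset. When used
inside model assessment, ranking and selection are refitted on each
training split.

## Classifier and evaluation

XGBoost with: learning rate 0.1, 1,000 trees, depth 8, min_child_weight 1,
γ = 0, subsample 0.8, colsample_bytree 0.8, binary-logistic objective,
scale_pos_weight 0.6 (after ENN cleaning the training set remains mildly
majority-heavy, so positives are weighted slightly below parity). Training
is single-threaded by default with a fixed seed for bit-reproducibility.
Features are z-scored with population standard deviations fitted on
training data only; constant features store sd 1 and map to 0.

The metric suite reports ACC, Sens, Spec, Precision and MCC from the
confusion counts at threshold 0.5 (no tuned threshold). Two "AUC"-like
quantities are computed and labelled distinctly: `balanced_auc` =
(Sens + Spec)/2, the balanced accuracy at the operating threshold, which is
how the benchmark's printed AUC formula reads; and `roc_auc`, the
trapezoidal area under the empirical ROC from the continuous scores. When
scores are the binary predictions themselves the two coincide (two-point
ROC identity), which is asserted as a test invariant. Rates with an empty
denominator class are reported as NaN rather than silently zero; MCC
follows the standard 0-when-degenerate convention. Cross-validated reports
are means of per-fold metrics (not pooled confusions), averaged NaN-aware;
repeats r use seeds seed + r.

## Synthetic data generator

`simulate_profiles` emulates labeled PSSM profiles without running
PSI-BLAST. Raw scores are drawn i.i.d. normal (mean 0, sd 3), rounded and
clipped to [−10, 13] to match the magnitude range of real BLOSUM-scaled
log-odds. Two class effects are planted in positives: a mean shift
(default 2.0 log-odds units) on five designated columns, emulating
composition bias, and a transition bias (default 0.5) that forces
consecutive rows to share their argmax column by swapping the row maximum
into the previous argmax position — a swap preserves each row's value
multiset, so the effect is purely structural and is what the TPC and
consensus features detect. Default lengths are uniform on [30, 80],
generous relative to the L ≥ 10 encoder minimum while keeping desk-scale
runs fast. Generation is bit-reproducible from the seed.

What the generator does **not** emulate: positional autocorrelation from
real conservation patterns, column covariance structure from the genetic
code and substitution matrices, length–composition dependence, and
homology between sequences. Passing the pipeline benchmarks on this
generator therefore demonstrates the machinery (encoders, leakage-free
protocol, selection, classification) is correct and can recover planted
signal — it does not certify real-data performance, which depends on the
curated dataset and NR-derived profiles.

## Benchmark problem sizes

The shipped benchmarks use 200 + 200 profiles for the full-pipeline
signal/null cross-validation, 150 + 150 vs 50 + 50 for the holdout check,
and n = 500, d = 50 with 5 planted features at effect 1.5σ for selection
recovery — sizes chosen to exercise every stage at desk scale. Under the
signal conditions the planted effects are strong, so near-perfect metrics
are expected and observed; the null conditions must and do stay at chance
(ROC AUC within [0.4, 0.6]).

## Known limitations

* The tool consumes pre-computed PSSMs; the PSI-BLAST command template is
  documented but not executed, and NR is not bundled.
* RPSSM, DWT and SOMA encoders, the prototype/combined resamplers, and the
  recurrent-network baseline from the surrounding literature are out of
  scope.
* Published real-data figures (and the published selected subset sizes)
  are not reproducible without the original dataset and profiles.
* The MRMD graph construction is a faithful-in-spirit, deterministic
  reconstruction, not a port of MRMD2.0.
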