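# Methods

## The chance model being simulated

A QSAR search over a descriptor pool is an order statistic: the reported
training r² is the *maximum* over every model the search evaluated. Its
null distribution therefore depends on the whole search protocol — pool
size, variable budget, pool filtering — not just on the single-model null
(for which E[r²] = p/(n−1) with p predictors and n compounds). The package
estimates that null empirically: it re-runs the identical search on each of
N randomized tables and summarizes the per-set best scores as
mean (mh) ± k·SD for k ∈ {1, 2.3, 3}. The +2.3 SD bar is the customary
normal-theory shorthand for the 99th percentile; because best-of-search
distributions are right-skewed, `compare_to_chance` always reports the
empirical percentile alongside the normal-theory verdict, and verdicts use
strict inequality.

Three null generators are provided. y-scrambling permutes the response and
is the sharpest test of the response–descriptor link; x-scrambling permutes
each descriptor column independently (equivalently, pseudo-descriptors with
the `original` family), preserving marginals but destroying joint
structure; parametric pseudo-descriptors replace columns with i.i.d. draws
whose parameters are fitted to the originals by moments: uniform → (min,
max), normal → (mean, SD with n−1), Poisson → rate = mean, exponential →
rate = 1/mean, binomial → trials = round(max) clamped to ≥ 1,
p = mean/trials clamped to [0, 1]. The binomial reading is one defensible
parameterization of an otherwise unparameterized family; all fits use the
*original* column (never chained through earlier replicates).

## Randomness and reproducibility

All streams are MT19937 (Mersenne Twister). Replicate i of a plan uses a
stream seeded `master_seed + i`; within the chance harness the same stream
also feeds any engine randomness (genetic search, random member choice in
the intercorrelation filter), so a run is a pure function of
(table, plan, engine, master_seed) and repeat runs are bit-identical.
Permutations are explicit Fisher–Yates shuffles; identity permutations are
*not* rejected — rejection would bias the null, and their probability is
negligible for n ≥ 6. Multiple activity columns are permuted independently.

## Model engines

**Pool reduction.** Constant columns (sample variance < 1e-12) and
near-constant columns (modal value occupying > 95% of rows) are dropped;
then pairs with |Pearson r| above the threshold (default 0.90) repeatedly
lose one member, chosen at random, until no offending pair remains.

**Subset search.** The training r² of the OLS model on subset S reduces to
`c_yᵀ C⁻¹ c_y / Σy_c²` on centered cross-products (C = XcᵀXc,
c_y = Xcᵀy_c), so all C(p, k) systems with k ≤ max_vars are solved in one
batched call; exhaustive search over p = 89, k ≤ 3 (~125k subsets) takes
tens of milliseconds, and an exact batched leave-one-out q² over all
subsets (via deleted residuals) backs the optional `max-q2` collection
policy. Exhaustive enumeration refuses above 200,000 subsets and points to
the genetic method. The GA (an evolutionary stand-in for GFA-style model
selection) evolves fixed-size descriptor index sets — r² is monotone under
added variables, so the optimum always uses the full budget — with
population 100, 200 generations, tournament size 3, uniform crossover with
duplicate repair, mutation probability 0.1 (swap one descriptor), elitism
5, fitness = training r²; the size cap makes a parsimony penalty
unnecessary. All settings are configurable; the archive of every evaluated
subset guarantees the returned best never beats exhaustive enumeration
falsely.

**Trees.** A hand-written CART classifier (Gini impurity, depth-limited,
default 3) with fully deterministic tie-breaking: candidate thresholds are
midpoints of consecutive sorted unique values; ties prefer the lowest
feature index, then the lowest threshold; splits that do not reduce
impurity become leaves; majority ties predict label 0. The left branch
takes value ≤ threshold. scikit-learn's `DecisionTreeClassifier` serves as
an independent cross-check in the tests, not as the implementation, because
its tie-breaking is randomized.

**Degenerate inputs.** A scrambled set whose response is constant scores
r² = q² = 0 with a warning instead of aborting, keeping exactly N entries
per run. r² with SS_tot = 0 is defined as 0 (warned). Rank-deficient OLS
designs raise an error naming the dependent columns (QR with pivoting).

## Validation statistics

q² uses the PRESS convention with the full-training-set mean in the
denominator. Leave-one-out uses the exact closed form via deleted residuals
e_i/(1 − h_ii); leave-m-out enumerates **all** C(n, m) groups (1,330
triples at n = 21, m = 3) using the exact block-deletion identity
ê_T = (I − H_TT)⁻¹e_T, with each point's squared errors averaged over the
groups containing it before summation — an exhaustive rather than
partition-based reading of the procedure. Custom fitters force naive
per-fold refits.

The permutation-intercept experiment plots r² and q² of models refitted on
permuted responses against |Pearson corr(y, y_perm)|, augments the points
with the unpermuted anchor (1, true statistic), and reports the OLS
intercepts at zero correlation; the customary validity bars are 0.4 (R²int)
and 0.05 (Q²int). The |corr| x-axis and the anchor point are this package's
reading of an ambiguous convention and are stated here so results are
comparable.

cRp² = √(r²·(r² − Rr²)) takes the randomized-model mean Rr² as an explicit
argument rather than guessing which null it came from; it is NaN (warned)
when Rr² > r². rm² is implemented in the single observed-vs-predicted
orientation R²·(1 − √(R² − R0²)) and requires R² ≥ R0² ≥ 0 (NaN otherwise);
the averaged/delta variants of later formulations are out of scope. Note
that R0² (origin-forced, optimal slope) always upper-bounds the
identity-line R², so the R² fed to the Golbraikh–Tropsha ratio and to rm²
should be the squared observed-vs-predicted correlation, as in the original
formulations. rm² is monotone in R0² at fixed R², not in R² at fixed R0² —
the gap penalty outpaces the leading factor.

Classification metrics follow the count definitions exactly; any metric
with a zero denominator is NaN, and F1 is computed from counts as
2TP/(2TP + FP + FN). Reports round to 2 decimals (3 for regression);
internals keep full precision. Computing F1 instead from already-rounded
PREC/SENS — as some published tables do — can differ in the second decimal
for extreme count ratios; this package always computes from counts.

## File formats

CSV is RFC-4180-style: comma separator, mandatory header, '.' decimal
point, no locale handling; floats are written in shortest-repr form and
parsed with Python's exact float parser, so read(write(t)) == t bit-for-bit.
The SD-file layer is a pure text layer over V2000 records: molblocks are
opaque verbatim bytes, data items are recognized by `> <NAME>` headers
(trailing tokens ignored, names matched case-sensitively), multi-line
values are joined verbatim, and both LF and CRLF dialects round-trip
byte-identically when unmodified; only randomized numeric fields are
rewritten. Record ids come from the molblock title line, with `rec<k>`
synthesized for blank (or colliding) titles. Records missing a requested
activity field are a hard error naming the record, or are dropped when
skip-missing is enabled. Non-numeric data items are carried as passthrough
and written back verbatim. All records must share the first record's
numeric field schema. No chemistry perception is done — no valence or
aromaticity handling, no V3000.

## Synthetic data

Fixtures emulate the audit's canonical shapes: n = 21 compounds against
pools of 10–89 descriptors for regression, and 1:36 actives:decoys decks
(100:3600) for classification. Descriptors are standard normal, optionally
in equicorrelated blocks (default within-block r = 0.95, chosen to
exercise the 0.90 intercorrelation filter); the response is
y = Σβ·x_signal + N(0, σ²), so the population R² = βᵀΣβ/(βᵀΣβ + σ²) is
known exactly and recorded in `table.metadata` along with the true subset.
Classification decks shift the actives' means by β on the signal
descriptors. What the fixtures deliberately do **not** model: real
descriptor marginals (discrete counts, heavy tails, mixed scales),
descriptor–descriptor structure beyond equicorrelated blocks, and
activity-measurement error models. Passing the planted-signal tests
therefore shows the machinery is calibrated, not that any particular real
data set contains signal.

## Problem sizes used in the checks

The self-audit runs at desk scale chosen to keep the whole suite in a few
minutes on one CPU: 2,000 scrambles for the fixed-model null calibration
(3 standard errors around E[r²] = 3/20), 100 seeded pools of 12 descriptors
for genetic-vs-exhaustive agreement, 50 fixtures for the leave-one-out
oracle identity (1e-12), 200 replicates per pool size in {10, 49, 89} for
the selection effect, and 100 seeded harness runs of 300 sets each (pool
size 10, exhaustive ≤3-variable search) per condition for the
detection/false-alarm rates at the +2.3 SD bar. The published mhr²/mhq²
tables themselves are not reproduction targets: they depend on proprietary
descriptor calculations and a specific commercial GFA implementation.

## Known limitations

* The genetic engine is a generic subset GA, not a reimplementation of any
  commercial GFA (no spline terms, no lack-of-fit scoring); only its
  *oracle agreement* with exhaustive search is guaranteed and tested.
* `collect="max-q2"` is exact only with the exhaustive engine; with the
  genetic engine it would require q² as the fitness and is refused.
* Pseudo-descriptor columns are drawn independently; correlated null
  descriptors are out of scope.
* The harness is single-threaded by design — determinism per seed is the
  contract.
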