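# Methods

## Problem setting

Input is a data matrix `E ∈ R^{S×V}` (S samples, V features; for
somatic-variant cohorts, column `v` is one variant key chrom:pos:ref:alt
and `e_sv ∈ {0,1}` marks whether sample `s` carries it), plus the
complementary class indicators `c^p` and `c^n = 1 − c^p`. The goal is a
small feature subset that separates the two classes while carrying
variants associated with *either* class and little internal redundancy.

## Variant filtering

The filter treats annotation as upstream input (region, consequence,
population-database and COSMIC membership flags, tumor/normal FREQ,
Fisher's exact p — the fields an ANNOVAR-annotated VarScan2 table
provides). The three predicates are:

1. region ∈ {exonic, 3' UTR, 5' UTR} and consequence = nonsynonymous
   (synonymous and ambiguous calls removed);
2. not in gnomAD/ESP6500/ExAC, except records flagged in COSMIC, which
   are always kept;
3. tumor FREQ ≥ 10 (percent), matched-normal FREQ = 0 exactly, Fisher
   p ≤ 0.01. FREQ is the variant-supporting read fraction × 100.

The composite filter is a pure conjunction — step order affects only the
per-step counts reported, never the survivor set — and each step is
idempotent and monotone. Records with missing annotation fields are
dropped with a logged warning by default (`missing_policy="keep"` maps
them to "other"/False instead); a record with an absent normal-sample
FREQ cannot satisfy predicate 3. The per-record Fisher p is consumed,
not recomputed (a `fisher_exact_p` helper exists for tables that ship
raw read counts). The matrix encoding is binary presence by default;
`encoding="freq"` stores tumor FREQ instead. Both are accepted by the
correlation engines; binary is the default because it is the minimal
encoding and makes the feature–class correlation the phi coefficient.

## Correlations

Pearson correlation is computed directly from centered dot products;
Spearman is Pearson on average-rank transforms (scipy `rankdata`), an
identity that holds exactly under ties. Two conventions matter for
sparse binary columns:

* zero-variance vectors get correlation 0 (a constant feature is
  uninformative; NaN propagation would poison subset means);
* ties get average ranks — binary columns are almost entirely ties, so
  any other convention changes Spearman values materially.

## Merit

For a mask `x` with `n = |x|` selected features:

    r̄_ff = mean over ordered pairs i≠j of |ρ(e_i, e_j)|
    r̄_fc = mean over selected i of g(ρ(e_i, c))
    M(x; c) = n·r̄_fc / √(n + n(n−1)·r̄_ff)
    M_DCFS(x) = α·M(x; c^p) + (1−α)·M(x; c^n),  α ∈ [0,1]

Decisions embedded here, all configurable:

* **Negative-correlation policy.** Because `c^n = 1 − c^p`, signed
  Pearson gives `ρ(e, c^n) = −ρ(e, c^p)` identically, and a signed dual
  merit at α = 0.5 would be 0 for every subset. The default
  `g(r) = max(r, 0)` (clip_to_zero) lets each feature credit only the
  class it is positively associated with, which is the reading under
  which the dual objective does what it is for; `absolute` and `signed`
  are provided for sensitivity analysis.
* Feature–feature correlations enter as absolute values; otherwise the
  square root can receive a negative argument. This is the standard CFS
  convention.
* The pair/class sums run over selected features only, normalized by
  `n(n−1)` and `n`; correlating against masked-out all-zero columns is
  undefined and not attempted.
* Degenerate masks follow the formula's algebra: `M(∅) = 0`, and a
  singleton's merit is its transformed class correlation (denominator
  √1). Both arise routinely as swarm particles.

`MeritEngine` precomputes the V×V absolute-correlation block and the two
class-correlation vectors when V ≤ 4096 (subset evaluation then costs a
submatrix mean), and falls back to per-subset computation above that;
both paths apply identical arithmetic per pair.

## Monte-Carlo weighting

Per iteration `t ≤ T1`: draw a size φ uniformly from Φ, draw φ features
uniformly without replacement, compute `M_DCFS` of that submatrix, add
it to `w_val` of each drawn feature and increment their `w_num`. The
weight vector is `w = w_val / w_num`, and the top `D1` weights (ties
broken by ascending feature index) form the candidate set. Defaults are
Φ = {2,…,100} and T1 = 10⁶, both scaled down in tests and the
acceptance script.

Never-sampled features have unknown — not zero — importance: their
weight is NaN, they are excluded from ranking, and requesting more
candidates than were sampled raises an error advising a larger T1.
Subset draws are without replacement within an iteration and
independent across iterations; one seeded Generator drives the size and
feature draws in a fixed order, so a run is a pure function of
(matrix, parameters, seed).

## Binary particle swarm

Positions are masks over the D1 candidates. Per particle and dimension:

    v ← a·v + c1·r1·(pb − x) + c2·r2·(gb − x),  clamped to [v_min, v_max]
    x ← 1 if rand < 1/(1+e^(−v)) else 0

Defaults: T2 = 100 iterations, a = 0.5, c1 = c2 = 2, v ∈ [−6, 6],
P = 100 particles. Choices the update rule leaves open, fixed here:

* initialization: positions i.i.d. Bernoulli(0.5), velocities uniform
  on [v_min, v_max] (uninformative prior over subsets); the initial
  global best is the best initial particle;
* personal/global bests update on strict improvement — ties keep the
  incumbent, making runs stable and the global-best trace
  non-decreasing;
* per iteration the RNG emits r1, r2 and the position thresholds as
  three (P, D) particle-major blocks, in that order, so runs are
  bit-reproducible from the seed;
* empty-mask particles are legal and score whatever the fitness assigns
  (both shipped fitnesses assign 0) rather than being re-rolled;
* fitness values are memoized by mask — sound because the fitness is
  required to be pure, and the CV fitness keeps fold assignment a
  function of (labels, seed) only.

Two fitness factories are provided: the dual merit of the masked
submatrix, and mean F1 under stratified k-fold CV of a supplied
classifier. The end-to-end runner defaults to the CV-F1 fitness, which
mirrors the protocol behind the headline comparisons; `fitness: merit`
selects the pure filter variant.

## Evaluation

Accuracy = (TP+TN)/total; F1 = 2TP/(2TP+FP+FN), defined as 0 when
TP = FP = FN = 0. The k-fold harness (k = 10 default) uses stratified
folds — with imbalanced cohorts plain folds risk a class-free fold —
toggleable to plain k-fold. Reference classifiers: a linear-kernel SVM
(the default protocol classifier) and a small feed-forward network (512
and 256 rectifier units, batch 50, 100 epochs) behind the same
fit/predict contract; any conforming classifier can be injected.

## Synthetic cohorts

The generator plants structure directly in carrier probabilities:
positive-associated features carry at rate π0 + δ in the positive class
and π0 otherwise (negative-associated mirrored), redundant features are
bit-flipped copies (flip rate `noise_flip`) of planted sources, null
features are Bernoulli(π0) everywhere. δ directly controls the
population point-biserial correlation the merit consumes, which is why
effects are parameterized as probability gaps rather than odds ratios.
Default study conditions: 200 samples, balanced classes, π0 = 0.1,
δ = 0.6 — a strong-effect regime in which planted features are
recoverable at desk-scale T1.

What the generator does *not* emulate: read-level noise, mutation
spectra, per-gene clustering, linkage beyond the explicit redundant
copies, or the extreme sparsity (carrier rates ≪ 0.1) and
dimensionality (V > 10⁵) of real cohorts. Passing tests therefore
demonstrate correctness of the algorithms and their documented
selection behavior under controlled correlation structure — not
clinical performance on patient data.

A second generator emits annotated variant records with exact fractions
failing each filter step, giving the filter tests a closed-form
survivor count.

## Problem sizes used by tests and the acceptance script

Unit and acceptance tests run the weighting at T1 = 10³–10⁴ over
V ≤ 100 and the swarm at its default parameters over D1 ≤ 20, sizes at
which the planted-recovery and oracle-equivalence properties hold with
wide margins. `scripts/acceptance.py` uses a 300 × 400 cohort,
T1 = 5·10⁴, D1 = 30, and a 60-particle/60-iteration swarm with the
CV-F1 fitness; these are the package's chosen reference conditions for
a complete, reproducible desk-scale run of the protocol.

## Known limitations

* The clip policy makes α = 0.5 weigh classes symmetrically, but merits
  are not calibrated across classes with very unequal carrier rates;
  α is the knob for that.
* The weighting estimator is unbiased per subset but its Monte-Carlo
  error grows for features rarely co-sampled with informative ones;
  T1 ≫ V/min(Φ) iterations are needed before every weight is even
  defined (coupon-collector argument).
* BPSO is a metaheuristic: optimality is verified against exhaustive
  search only at oracle scale (D ≤ 12); at larger D the global best is
  a good subset, not a certificate.
* The CV-F1 fitness evaluates thousands of masks against the same
  folds; the resulting D2 set's CV score is mildly optimistic (selection
  bias). Held-out validation is out of scope here.
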