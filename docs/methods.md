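# Methods

## The model

A *filter* is a conjunction of exactly five closed descriptor intervals
on five distinct descriptors; a molecule passes iff all five of its
values lie inside. A *model* is a list of filters ranked by the Matthews
correlation coefficient (MCC) of the active/inactive split each filter
induces on the learning set, truncated to min(`max_filters` = 1000,
⌈`retain_fraction` = 0.2 × enumerated⌉). MCC with any zero factor under
the square root is defined as 0 — the standard convention for degenerate
confusion tables, and the value assigned to filters that pass nothing.

Screening assigns each molecule the normalised ensemble vote
`index = (Σ w_f δ_f) / Σ w_f ∈ [−1, +1]`, where δ_f is +1 if the molecule
passes filter *f* and −1 otherwise. The default weighting is unit
(`w_f = 1`), making the index exactly (passes − fails)/n; `mcc` and
`fscore` weightings are provided because both readings of the scoring
prose are defensible — they emphasise better-discriminating filters but
change none of the bounds. A molecule missing any model descriptor fails
hard rather than being partially scored; silent skipping would corrupt
the [−1, 1] semantics. The computed quotient is clamped at ±1 to absorb a
possible 1-ulp float overshoot under non-unit weights.

## Candidate ranges

The literature form of the algorithm treats "all ranges of each
descriptor" abstractly; a concrete discretisation has to be chosen. Per
descriptor, bin edges are the quantiles of the **active-class**
distribution (`n_bins` = 8 equal-frequency bins) and the candidates are
all contiguous unions of bins: n_bins·(n_bins+1)/2 = 36 closed intervals.
Actives define the relevant property region — decoys span the whole
space — and contiguous unions keep the candidate count quadratic, the
space enumerable, and guarantee that the full span [min, max] of the
actives is always among the candidates. A descriptor constant over the
actives contributes a single degenerate point range, flagged. Duplicate
quantile edges (heavily tied descriptors such as small integer counts)
are merged, so such descriptors contribute fewer candidates.

## Stochastic elimination

While the number of filter combinations (the degree-5 elementary
symmetric polynomial of per-descriptor range counts, computed exactly by
dynamic programming, never by enumeration) is at least
`exhaustive_threshold` = 10⁶, elimination rounds run with
`sample_size_t` = 10⁵ filters per round. Each sampled filter draws five
distinct descriptors uniformly, then one surviving range per descriptor
uniformly. Per-range statistics: observation count, mean MCC of the
filters containing the range, and membership counts in the top and
bottom deciles of the sampled score distribution (the t/10 highest- and
lowest-scoring sampled filters under a stable sort — a percentile-value
definition degenerates when a mass of filters ties at MCC 0).

Three elimination rules of increasing force are applied; a build starts
with the first and escalates permanently whenever a round eliminates
nothing:

1. **strict** — eliminate a range observed ≥ `min_observations` = 30
   times whose mean MCC lies strictly below the `elim_fraction` = 0.2
   quantile of observed range means, which is over-represented in the
   bottom decile and absent from the top decile. Conservative, protects
   under-sampled ranges; ties at the cut are never split. In practice it
   goes quiet once every range has been observed often enough to appear
   in *some* top-decile filter.
2. **mean** — the mean-MCC condition alone. When nothing lies strictly
   below the cut (the bottom of the histogram is one large tie, typically
   at exactly 0), the whole tied group is eliminated — tied ranges still
   share one fate.
3. **forced** — a fixed quota (⌈0.2 × observed⌉) of the worst observed
   ranges, deterministic lexicographic tie-break. Guarantees progress;
   reached only on pathologically tied catalogs.

A descriptor that loses its last range drops out of the catalog, but
never below `min_descriptors` (default: the filter size) surviving
descriptors; would-vanish descriptors beyond that floor are rescued by
keeping their best-mean range. If the space still cannot be brought below
the exhaustive threshold within `max_iterations` = 100 rounds the build
fails loudly rather than returning a partial ranking.

## Exhaustive phase and ranking

All remaining combinations are evaluated with bit-packed pass vectors
(uint64 words + popcount), blocked over descriptor subsets. Filters are
ordered by MCC descending with a lexicographic tie-break on the sequence
of (descriptor name, low, high); the flattened catalog index realises
that key ordering, so a `lexsort` over the index columns under −MCC gives
the exact ranking without materialising keys. Materialised filters carry
confusion counts and an MCC recomputed in exact integer arithmetic, so
equal confusion tables always serialize to bit-identical values. Model
JSON round-trips bit-exactly and contains no timestamps: identical seed
and inputs give hash-identical artifacts.

## Learning-set protocol

Curation applies, in fixed order: flagged assay comments; non-"="
qualifiers; potency worse than 100 µM; source confidence not above 7;
explicit exclusion lists (e.g. approved drugs); duplicate collapse
keeping the numerically largest (worst) value in nM; structural alerts
(a small reactive/mutagenic SMARTS list, configurable off). The order is
fixed for auditability — every dropped record cites exactly the first
applicable rule, and kept + dropped = input. An optional high-activity
threshold (default off) restricts to sub-10/100 nM actives.

Decoys are sampled uniformly without replacement from pool members whose
MW, clogP, HBA and HBD all lie within mean ± 2 SD of the actives (sample
SD, n−1). The target dilution is `ratio` = 100 decoys per active (1000:1
better approximates real screening odds but multiplies build cost); a
short pool returns everything eligible with a shortfall flag rather than
an error so small demonstration pools work.

Cross-validation is stratified 5-fold (class proportions per fold within
one molecule, by dealing each shuffled class round-robin); below 20
actives it switches to leave-one-out over the actives with decoys dealt
evenly alongside. Reported: the top filter's MCC averaged over folds
(and a top-5 variant), pooled ROC AUC over raw held-out indices
(rank-normalising per fold was considered and rejected as it discards
calibration differences), TPR/TNR at the index > 0 cutoff, and the
enrichment factor at a configurable top fraction (default 1 %). Cutoff
tables select molecules with index ≥ cutoff so that a cutoff of −1
selects everything; the classification rates above use strictly positive
indices.

ROC AUC delegates to scikit-learn (ties count ½); tests verify it against
an O(n²) pairwise-concordance oracle. Y-randomization places the observed
number of activities uniformly (without replacement within a replicate)
in the drug × target frame and reports the mean ± SD fraction landing on
predicted-positive cells over 1000 replicates.

## Synthetic fixtures

`generate_planted_fixture` emulates the actives-vs-diluted-decoys
geometry: decoys uniform over [0, 100] per descriptor; each planted box
occupies a disjoint block of five descriptors, is 10 units wide, and
every active is drawn Gaussian (σ = width/6, clipped) inside **every**
box, so with several boxes each planted filter still classifies
perfectly; decoys falling inside any box are resampled. The recorded
ground-truth filters carry the empirical active span per planted
descriptor — exactly the full-span candidate the catalog builder
produces, making "recovered exactly" a testable numeric equality. Label
noise relabels a fraction of the actives as decoys, leaving coordinates
untouched: the planted filters remain the best attainable classifiers
and the decoy class acquires the realistic contamination of unrecognised
actives sitting inside the activity box.

What the generator does **not** model: correlated descriptors, activity
cliffs, multi-modal actives, assay noise in the descriptor values, or any
real chemical-space structure. Passing tests on these fixtures therefore
demonstrates algorithmic correctness (recovery of a recoverable signal,
calibration under the null), not screening performance on real targets.
`generate_toy_smiles` provides arylpiperazine-like actives against small
aliphatic decoys purely to exercise the real descriptor path end to end.

## Problem sizes and determinism

Default study conditions for the recovery experiments are 100 actives +
10,000 decoys (the 100:1 dilution) over 20 descriptors; a build takes a
few seconds. Validation experiments (null cross-validation, oracle
comparisons) use smaller sets — 80 actives + 800 decoys and sub-10⁴
catalogs — chosen so the exhaustive oracle itself stays cheap. All
randomness flows through a single seeded `numpy` Generator per entry
point; every CLI run writes its resolved configuration next to its
outputs, and repeated runs are hash-identical.

## Known limitations

- The descriptor panel is an open-source approximation grouped into the
  seven conventional families; it does not reproduce any commercial
  panel, so absolute model quality on real data differs from published
  figures.
- Protonation uses two rules (deprotonate carboxylic acids, protonate
  basic aliphatic amines) for a single microspecies; no tautomer or
  microspecies enumeration.
- The strict elimination rule's decile conditions rarely fire at the
  default sampling density; the mean-MCC rule does most elimination work.
- Exactly five ranges per filter is assumed throughout the defaults;
  `filter_size` is configurable but untested beyond 5.
- Held-out actives can fall marginally outside training-fold ranges, so
  cross-validated AUC on separable fixtures is near-perfect, not exactly
  1.
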