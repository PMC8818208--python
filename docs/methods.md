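# Methods

## Model of the data

The unit of analysis is a hospital admission carrying (i) a phenotype
profile — a set of terms from a single-rooted `is_a` taxonomy — and (ii)
an opaque primary diagnosis code.  Two admissions form a *positive* pair
when their codes are equal.  Every similarity configuration is scored by
how well its all-pairs similarity matrix separates positive from negative
pairs (global AUROC) and how early each admission's first positive partner
appears in its per-admission ranking (MRR, A@k).

The taxonomy is treated as an asserted subsumption DAG: only `is_a` edges
are loaded, obsolete terms are removed at load time (terms orphaned by
obsolete parents are re-attached to their nearest live ancestor through the
obsolete chain, or to the root), and no description-logic reasoning is
performed.  Whether reasoner-inferred subsumptions would change results on
a real ontology is an open question this package does not address.

## Measures

Information content (all natural log; every downstream metric is
rank-based, so the base is immaterial):

| id | kind | formula |
|----|------|---------|
| `resnik` | corpus | −ln(|I(x)|/|I|), I(x) = annotation pairs on x or its descendants |
| `seco` | structural | 1 − ln(hypo(x)+1)/ln N |
| `zhou` | structural | k·seco(x) + (1−k)·ln(depth_max(x)+1)/ln(D+1), k = 0.5 |
| `sanchez` | structural | −ln((leaves(x)/subsumers(x) + 1)/(L + 1)) |
| `depth_max`, `depth_min` | structural | ln(depth+1)/ln(D+1) |

Corpus IC counts annotation *pairs* by default; a flag switches to
distinct-entity counting, since toolkits differ on this convention.  Terms
with zero closure frequency receive the finite ceiling −ln(1/(|I|+1)),
preserving "rarer ⇒ more informative" without infinities.  Corpus IC is
monotone non-decreasing from root to leaves along every edge; so are
`seco` and `depth_max`.  `depth_min` is only monotone on trees — a second
parent can provide a shorter root path — which is why the test suite
checks it on trees only.

Pairwise: Rada path similarity 1/(d+1) with d the undirected shortest
`is_a` path; Resnik IC(MICA), ties among equally informative common
ancestors broken toward the lexicographically smallest id for determinism;
ancestor-set Jaccard and Dice on inclusive ancestor closures.

Groupwise direct: raw-set Jaccard (no closure — the closure variant is
registered separately as `ui`), ancestor-union overlap `ui`, and GIC as
the ratio of summed IC over intersection vs union of the two ancestor
closures.  GIC returns 1 for identical closures and 0 (logged) when the
union carries zero total IC.  With a constant IC table GIC reduces exactly
to `ui`.

Groupwise indirect: the m×n pairwise matrix S is collapsed by MAX, MIN,
AVG (grand mean), BMA = ½(mean row-max + mean column-max) or BMM =
max(mean row-max, mean column-max).  For any matrix,
MIN ≤ AVG ≤ MAX and MIN ≤ BMA ≤ BMM ≤ MAX.  Identical inputs reach the
maximum for direct normalized measures and for MAX; AVG/MIN mix in
off-diagonal pairs and legitimately stay below 1.

Empty profiles: comparing against one empty profile scores 0 and is
logged; two empty profiles are an error.  Uncurated concept recognition
can genuinely produce empty profiles, so they must not silently poison a
sweep.

## Configuration enumeration

A roster of measure descriptors (id, level, needs_ic, needs_pairwise)
expands to: each direct groupwise measure (crossed with every IC when it
needs one), each indirect groupwise × each non-IC pairwise, and each
indirect groupwise × each IC-using pairwise × each IC.  Output order and
config ids are lexicographic over (groupwise, pairwise, ic), so sweeps and
reports are stable across runs.  The default registry expands to 53
configurations.

## Evaluation

AUC uses the midrank Mann–Whitney formulation,
P(score⁺ > score⁻) + ½P(equal), over all unordered admission pairs
(self-pairs excluded; symmetric matrices make ordered duplication
pointless).  Its 95% CI uses the Hanley–McNeil parametric standard error
with Q1 = A/(2−A), Q2 = 2A²/(1+A), clipped to [0, 1].  A@k's CI is the
Wald normal approximation.  These are the standard parametric choices; the
implementation keeps them behind `evaluate_auc`/`evaluate_rankings` so
alternatives (e.g. DeLong, Wilson) could be swapped in.

Per-admission rankings sort neighbours by descending score.  Ties are
resolved by a named policy: `id` (ascending admission id, the
deterministic default), `optimistic`, `pessimistic`, or `mid`
(fractional mid-rank).  MRR and A@k are tie-sensitive, so the policy is an
explicit parameter rather than an accident of sort stability.  A@k uses
cutoff min(k, n−1).  MRR-0 = MRR-NA · n_matchable/n holds identically by
construction; the suite asserts it to 1e-12.

`run_benchmark` isolates per-configuration failures: a bad configuration
produces a `failed` row with its reason and the sweep continues.  Results
stream to TSV one flushed row per configuration, and summary tables
average each metric by groupwise measure and by IC measure.

The dense engine (`SimilarityEngine`) precomputes the ancestor-closure
boolean matrix, per-(pairwise, IC) term-term score matrices over the
profile vocabulary, and closure membership per admission, so a 53-config
sweep over 150 admissions takes seconds.  The scalar measure functions
remain the reference semantics; the suite checks entry-level agreement
between the two routes at 1e-9.

## Synthetic generator

The generator emulates uncurated text-derived profiles at desk scale.
Parameters stated by the emulated setting: 1000 admissions, mean 44
annotations per admission (Poisson truncated at ≥1 — only the mean is
constrained; real dispersion is unknown), ubiquitous noise terms, and rare
diagnoses.  Parameters chosen here as realistic defaults, fixed once:

- `n_terms = 500`, `max_children = 8`, `multi_parent_prob = 0.2`: a
  desk-scale stand-in for a clinical phenotype ontology with multiple
  inheritance; each term attaches to an earlier term, giving
  depth/branching heterogeneity.
- `n_diseases = 100`, `disease_profile_size = 30`: diagnosis diversity
  high enough that, with the Zipf-weighted (1/rank) diagnosis draw and
  `min_admissions_per_diagnosis = 1`, tail diagnoses occur exactly once —
  producing the unmatchable admissions that separate MRR-0 from MRR-NA.
- `noise_fraction = 0.5`, `noise_skew = 1.5`, `n_common_noise_terms = 20`,
  `noise_pool_fraction = 0.4`: 40% of the vocabulary is reserved as a
  noise pool disjoint from every disease profile, sampled with
  rank^(−1.5) weights so a ~20-term head appears in nearly every profile
  while a long tail appears rarely.  Reserving the pool up front keeps
  noise terms free of diagnostic signal by construction at any disease
  count.

Everything is driven by `numpy.random.default_rng(seed + fixed offsets)`;
identical specs give byte-identical TSV/OBO outputs.

What the generator does *not* model: string-level concept-recognition
errors, note-category structure, correlated comorbidities, annotation-count
overdispersion, and ontology-aware noise (noise terms are drawn
independently of the hierarchy).  Passing benchmarks on this data
therefore validates the *pipeline* — formula fidelity, estimator
correctness, calibration, and the qualitative behaviour of measure
families under exact-match-dominated noise — not clinical performance on
real notes.

On these synthetics, exact-match measures (Jaccard, GIC) are near-ceiling
because same-diagnosis profiles share many literal terms; MAX/MIN
aggregation saturates on shared noise and sits at or near chance; AVG
retains signal but is diluted by the noise block of the pairwise matrix.
The AVG-and-GIC-above-MAX/MIN ordering is stable across seeds, while the
absolute AVG AUC fluctuates by ±0.07–0.09 between seeds at n = 100, so
statistical checks on it average over a block of consecutive seeds.

## Problem sizes

Tests and the acceptance script run scaled-down instances chosen as the
package's own benchmark sizes: toy fixtures for formula checks, 50-term
random DAGs for oracle equivalence, 100-admission benchmarks for
calibration and ordering properties (12 consecutive seeds for stochastic
means), and a 150-admission full-roster sweep in the acceptance script.
The full-scale 1000-admission generator default is exercised for the
annotation-rate statistics, where no similarity matrices are needed.

## Known limitations

- Only `is_a` semantics; no relation types, no reasoning.
- The exact formulas behind some named measures in other toolkits are not
  published; the registry documents the formulas used here and is
  extensible without touching the benchmark engine.
- Wall-clock comparison of measures is out of scope.
- Hanley–McNeil and Wald CIs are asymptotic; at very small n they can be
  wide or clipped.
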