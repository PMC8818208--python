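# phenosim

Benchmarking ontology-based semantic-similarity configurations for
comparing patient phenotype profiles.

## The problem

When concept recognition is run over clinical narrative, every hospital
admission acquires a *phenotype profile*: the set of ontology terms (for
example Human Phenotype Ontology classes) mentioned in its notes.  Ranking
admissions by profile similarity supports "patient-like-me" retrieval and
differential diagnosis — but there are dozens of ways to define that
similarity, built from three interchangeable parts:

- an **information content** (IC) measure giving each term a specificity
  weight, either from annotation frequency, IC(x) = −ln p(x) with
  p(x) = |I(x)|/|I| over the annotation corpus, or from ontology structure
  alone (Seco, Zhou, Sánchez, depth-based);
- a **pairwise** term-term measure, e.g. Rada path similarity
  1/(dist(x,y)+1), Resnik IC(MICA(x,y)), or ancestor-set Jaccard/Dice;
- a **groupwise** set-to-set measure, either *direct* (raw-set Jaccard,
  ancestor-union overlap, the IC-weighted GIC ratio
  Σ<sub>t∈Â∩B̂</sub>IC(t) / Σ<sub>t∈Â∪B̂</sub>IC(t)) or *indirect*
  (MAX/MIN/AVG/BMA/BMM aggregation of the full pairwise score matrix).

`phenosim` enumerates every valid (groupwise, pairwise, IC) combination,
computes the all-pairs similarity matrix per configuration over a set of
labelled admissions, and evaluates how well each configuration predicts
*shared primary diagnosis*, via global AUROC over admission pairs
(Mann–Whitney formulation, Hanley–McNeil 95% CI), mean reciprocal rank of
the first same-diagnosis admission (MRR-0 counts unmatchable admissions as
zero, MRR-NA excludes them; the two always satisfy
MRR-0 = MRR-NA · n_matchable/n), and top-ten accuracy A@10 (Wald CI).

Because real clinical datasets are access-restricted, the package includes
a fully seeded synthetic generator that emulates the statistical shape of
uncurated text-derived profiles: ~44 annotations per admission, half
diagnosis-driven signal and half noise drawn from a Zipf-skewed pool whose
top terms appear in nearly every profile (the "pain"/"allergies" artefact),
and a skewed diagnosis distribution that leaves some admissions with no
possible match.

## Worked example

`examples/benchmark_sweep.py` generates 100 synthetic admissions over 25
diseases with half-noise profiles and evaluates eight representative
configurations:

```
        config_id   auc  mrr0  mrrna  a10  n_matchable
          jaccard 1.000 1.000  1.000 1.00          100
               ui 0.999 0.995  0.995 1.00          100
       gic+resnik 0.999 0.995  0.995 1.00          100
         gic+seco 1.000 0.995  0.995 1.00          100
avg+resnik+resnik 0.662 0.287  0.287 0.51          100
bma+resnik+resnik 0.982 0.964  0.964 1.00          100
         max+rada 0.500 0.133  0.133 0.21          100
         min+rada 0.397 0.175  0.175 0.28          100

Pearson r between AUC and A@10 across configs: 0.987 (p = 6e-06)
```

Reading the table: exact-match measures (Jaccard, GIC) solve this synthetic
task nearly perfectly because same-diagnosis profiles share many literal
terms; best-match averaging (BMA) is close behind; plain averaging retains
signal but is diluted by the noise block of the pairwise matrix; MAX and
MIN aggregation saturate on ubiquitous noise terms and stay at or below
chance (AUC 0.5).  `n_matchable` is the number of admissions with at least
one same-diagnosis partner, the denominator behind MRR-NA.

The other examples show the individual layers:
`examples/toy_taxonomy_similarity.py` (hand-checkable seven-term taxonomy)
and `examples/information_content_methods.py` (corpus vs structural IC on
noisy profiles).

## Command line

```bash
phenosim synth --out data --seed 5 --n-admissions 200        # synthetic dataset
phenosim enumerate                                           # list all configs
phenosim run --obo data/ontology.obo --profiles data/profiles.tsv \
             --diagnoses data/diagnoses.tsv --out results
```

`run` writes `results/results.tsv` incrementally (one row per
configuration, so interrupted sweeps keep their partial results) plus
summary tables grouped by groupwise measure and by IC measure.  Input
formats are two-column TSV (`admission_id<TAB>term_id`,
`admission_id<TAB>code`) and OBO 1.2/1.4 flat files; only `is_a` edges are
used and obsolete terms are filtered at load.

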