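"""Synthetic ontologies, disease profiles and noisy admission profiles.

The generator emulates the statistical shape of uncurated text-derived
phenotype profiles over a clinical ontology: each hospital admission gets a
primary diagnosis, a Poisson-sized term set (mean 44 annotations per
admission by default) mixing *signal* terms drawn from its diagnosis's
phenotype profile with *noise* terms drawn from a Zipf-skewed pool that a
handful of ubiquitous terms dominate — the way concept recognition over
clinical notes keeps re-annotating generic mentions such as "pain" or
"allergies".  Diagnosis frequencies are themselves skewed, so with
``min_admissions_per_diagnosis = 1`` some diagnoses occur exactly once and
their admissions have no possible same-diagnosis match (which is what
separates MRR-0 from MRR-NA downstream).

Everything is fully determined by the seed: the same
:class:`SyntheticSpec` yields byte-identical TSV/OBO outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .benchmark import LabeledAdmission
from .ic import AnnotationCorpus
from .ontology import OntologyGraph
from .similarity import PhenotypeProfile

__all__ = [
    "SyntheticSpec",
    "partition_terms",
    "generate_ontology",
    "generate_disease_profiles",
    "generate_admissions",
    "generate_benchmark",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance.

    Defaults describe the emulated study conditions: 1000 admissions with a
    mean of 44 annotations each, half of every profile diagnosis-driven and
    half noise, over a 500-term ontology with 100 diseases of 30 phenotype
    terms each.
    """

    seed: int = 0
    n_terms: int = 500
    max_children: int = 8
    multi_parent_prob: float = 0.2
    n_diseases: int = 100
    disease_profile_size: int = 30
    n_admissions: int = 1000
    mean_terms_per_admission: float = 44.0
    noise_fraction: float = 0.5
    n_common_noise_terms: int = 20
    noise_skew: float = 1.5
    noise_pool_fraction: float = 0.4
    min_admissions_per_diagnosis: int = 1

    def __post_init__(self) -> None:
        positive = {
            "n_terms": self.n_terms,
            "max_children": self.max_children,
            "n_diseases": self.n_diseases,
            "disease_profile_size": self.disease_profile_size,
            "n_admissions": self.n_admissions,
            "mean_terms_per_admission": self.mean_terms_per_admission,
            "n_common_noise_terms": self.n_common_noise_terms,
            "min_admissions_per_diagnosis": self.min_admissions_per_diagnosis,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError(f"noise_fraction must lie in [0, 1], got {self.noise_fraction}")
        if not 0.0 <= self.multi_parent_prob <= 1.0:
            raise ValueError(f"multi_parent_prob must lie in [0, 1], got {self.multi_parent_prob}")
        if self.noise_skew < 0:
            raise ValueError(f"noise_skew must be >= 0, got {self.noise_skew}")
        if not 0.0 <= self.noise_pool_fraction < 1.0:
            raise ValueError(
                f"noise_pool_fraction must lie in [0, 1), got {self.noise_pool_fraction}"
            )
        if self.min_admissions_per_diagnosis * self.n_diseases > self.n_admissions:
            raise ValueError(
                "min_admissions_per_diagnosis * n_diseases exceeds n_admissions"
            )


def _term_id(i: int) -> str:
    return f"T:{i:07d}"


def generate_ontology(spec: SyntheticSpec) -> OntologyGraph:
    """Random single-rooted is_a DAG.

    Terms are created in order; each non-root term attaches to one earlier
    term with fewer than ``max_children`` children (its primary parent) and,
    with probability ``multi_parent_prob``, to a second earlier term, giving
    the DAG the multiple-inheritance flavour of real phenotype ontologies.
    """
    rng = np.random.default_rng(spec.seed)
    parents: dict[str, set[str]] = {_term_id(0): set()}
    child_count = np.zeros(spec.n_terms, dtype=int)
    for i in range(1, spec.n_terms):
        eligible = np.flatnonzero(child_count[:i] < spec.max_children)
        if eligible.size == 0:  # every earlier term saturated; root absorbs
            eligible = np.array([0])
        primary = int(rng.choice(eligible))
        ps = {primary}
        if i > 1 and rng.random() < spec.multi_parent_prob:
            extra = int(rng.integers(0, i))
            ps.add(extra)
        parents[_term_id(i)] = {_term_id(p) for p in ps}
        for p in ps:
            child_count[p] += 1
    return OntologyGraph(parents)


def partition_terms(g: OntologyGraph, spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Split non-root terms into a dedicated noise pool and a disease pool.

    The noise pool (a ``noise_pool_fraction`` share of the vocabulary, at
    least ``n_common_noise_terms``) is reserved before disease profiles are
    sampled, so noise terms never carry diagnostic signal — the synthetic
    counterpart of field-name artefacts that concept recognition tags in
    every note regardless of the patient's condition.
    """
    rng = np.random.default_rng(spec.seed + 1)
    terms = np.array(sorted(g.terms - {g.root}))
    shuffled = rng.permutation(terms)
    k = min(
        max(spec.n_common_noise_terms, int(round(spec.noise_pool_fraction * terms.size))),
        max(terms.size - 1, 0),
    )
    return np.sort(shuffled[:k]), np.sort(shuffled[k:])


def generate_disease_profiles(
    g: OntologyGraph, spec: SyntheticSpec, disjoint: bool = False
) -> dict[str, frozenset[str]]:
    """Phenotype profile (term set) per disease.

    Each disease samples ``disease_profile_size`` terms from the disease
    pool (non-root terms outside the reserved noise pool).  With
    ``disjoint=True`` profiles are pairwise disjoint (the perfect-signal
    fixture used to validate the evaluation stack); this requires
    ``n_diseases * disease_profile_size`` distinct pool terms.
    """
    rng = np.random.default_rng(spec.seed + 3)
    _, pool = partition_terms(g, spec)
    if spec.disease_profile_size > pool.size:
        raise ValueError("disease_profile_size exceeds available disease-pool terms")
    profiles: dict[str, frozenset[str]] = {}
    if disjoint:
        need = spec.n_diseases * spec.disease_profile_size
        if need > pool.size:
            raise ValueError(
                f"disjoint profiles need {need} non-root terms, only {pool.size} available"
            )
        chosen = rng.choice(pool, size=need, replace=False)
        for d in range(spec.n_diseases):
            block = chosen[d * spec.disease_profile_size : (d + 1) * spec.disease_profile_size]
            profiles[_disease_id(d)] = frozenset(block)
    else:
        for d in range(spec.n_diseases):
            profiles[_disease_id(d)] = frozenset(
                rng.choice(pool, size=spec.disease_profile_size, replace=False)
            )
    return profiles


def _disease_id(d: int) -> str:
    return f"D{d:04d}"


def _diagnosis_assignment(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    """Skewed diagnosis draw honouring the per-diagnosis minimum.

    The first ``min * n_diseases`` admissions cover every disease the
    required number of times; the rest draw diseases with Zipf-like weights
    (prevalence ~ 1/rank), so tail diagnoses stay rare.
    """
    codes = [_disease_id(d) for d in range(spec.n_diseases)]
    assigned: list[str] = codes * spec.min_admissions_per_diagnosis
    remaining = spec.n_admissions - len(assigned)
    weights = 1.0 / np.arange(1, spec.n_diseases + 1)
    weights /= weights.sum()
    assigned.extend(rng.choice(codes, size=remaining, p=weights))
    order = rng.permutation(len(assigned))
    return [assigned[i] for i in order]


def generate_admissions(
    g: OntologyGraph,
    diseases: dict[str, frozenset[str]],
    spec: SyntheticSpec,
) -> tuple[list[LabeledAdmission], AnnotationCorpus]:
    """Labelled noisy admission profiles plus the self-referential IC corpus.

    Profile sizes follow a Poisson law (mean ``mean_terms_per_admission``)
    truncated at 1.  A fraction ``noise_fraction`` of each profile comes
    from the reserved noise pool (see :func:`partition_terms`), weighted by
    rank^(-noise_skew) so the first ``n_common_noise_terms`` dominate — and
    the rest is sampled from the admission's disease profile.  The returned
    corpus maps every admission to its own profile, so corpus IC estimated
    from it down-weights ubiquitous noise terms.
    """
    if not diseases:
        raise ValueError("empty disease map")
    rng = np.random.default_rng(spec.seed + 2)
    diagnoses = _diagnosis_assignment(spec, rng)

    disease_terms = frozenset().union(*diseases.values())
    reserved, _ = partition_terms(g, spec)
    noise_pool = np.array([t for t in reserved if t not in disease_terms])
    if noise_pool.size == 0 and spec.noise_fraction > 0:
        raise ValueError("no terms left for the noise pool; reduce disease coverage")
    ranks = np.arange(1, noise_pool.size + 1, dtype=float)
    noise_weights = ranks ** (-spec.noise_skew)
    noise_weights /= noise_weights.sum()

    admissions: list[LabeledAdmission] = []
    corpus: dict[str, frozenset[str]] = {}
    for i, code in enumerate(diagnoses):
        size = max(1, int(rng.poisson(spec.mean_terms_per_admission)))
        n_noise = int(round(spec.noise_fraction * size))
        n_signal = size - n_noise
        signal_pool = np.array(sorted(diseases[code]))
        terms: set[str] = set()
        if n_signal > 0:
            take = min(n_signal, signal_pool.size)
            terms |= set(rng.choice(signal_pool, size=take, replace=False))
        if n_noise > 0 and noise_pool.size > 0:
            take = min(n_noise, noise_pool.size)
            terms |= set(rng.choice(noise_pool, size=take, replace=False, p=noise_weights))
        if not terms:  # noise_fraction rounding can empty tiny profiles
            terms = {str(rng.choice(signal_pool))}
        aid = f"A{i:05d}"
        profile = PhenotypeProfile(aid, frozenset(terms))
        admissions.append(LabeledAdmission(aid, profile, code))
        corpus[aid] = profile.terms
    return admissions, AnnotationCorpus(corpus)


def generate_benchmark(
    spec: SyntheticSpec, disjoint_diseases: bool = False
) -> tuple[OntologyGraph, dict[str, frozenset[str]], list[LabeledAdmission], AnnotationCorpus]:
    """Convenience wrapper: ontology, disease map, admissions and corpus."""
    g = generate_ontology(spec)
    diseases = generate_disease_profiles(g, spec, disjoint=disjoint_diseases)
    admissions, corpus = generate_admissions(g, diseases, spec)
    return g, diseases, admissions, corpus
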