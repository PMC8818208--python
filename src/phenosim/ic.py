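"""Information-content measures: corpus-frequency and structural.

The corpus measure is the classic annotation-frequency IC: with I the full
multiset of (entity, term) annotation pairs and I(x) the subset whose term
is x or one of its descendants, p(x) = |I(x)|/|I| and IC(x) = -ln p(x).

The structural measures require no corpus and score a term by its position
in the taxonomy alone:

- ``seco``      : 1 - ln(hypo(x)+1)/ln N, hypo = exclusive descendants
- ``zhou``      : k*seco(x) + (1-k)*ln(max_depth(x)+1)/ln(D+1)
- ``sanchez``   : -ln( (leaves(x)/subsumers(x) + 1) / (L + 1) )
- ``depth_max`` : ln(max_depth(x)+1)/ln(D+1)
- ``depth_min`` : ln(min_depth(x)+1)/ln(D+1)

where N is the term count, D the maximum depth of the ontology and L the
total leaf count.  All logarithms are natural; every downstream evaluation
metric is rank-based and therefore invariant to the base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .ontology import OntologyGraph, OntologyError

__all__ = [
    "AnnotationCorpus",
    "ICTable",
    "corpus_ic",
    "structural_ic",
    "STRUCTURAL_IC_METHODS",
]

STRUCTURAL_IC_METHODS = ("seco", "zhou", "sanchez", "depth_max", "depth_min")


@dataclass(frozen=True)
class AnnotationCorpus:
    """Entity -> term-set map over which corpus IC probabilities are estimated."""

    annotations: Mapping[str, frozenset[str]]

    @classmethod
    def from_dict(cls, d: Mapping[str, set[str] | frozenset[str]]) -> "AnnotationCorpus":
        return cls({e: frozenset(ts) for e, ts in d.items()})

    @property
    def n_annotations(self) -> int:
        """Total annotation-pair count |I|."""
        return sum(len(ts) for ts in self.annotations.values())

    def validate_against(self, g: OntologyGraph) -> None:
        unknown = {t for ts in self.annotations.values() for t in ts} - g.terms
        if unknown:
            raise OntologyError(
                f"corpus annotates terms absent from the ontology: {sorted(unknown)[:5]}"
            )


@dataclass(frozen=True)
class ICTable:
    """Per-term information content values (nats) for one method."""

    method: str
    values: Mapping[str, float] = field(repr=False)

    def __getitem__(self, term: str) -> float:
        return self.values[term]

    def __contains__(self, term: str) -> bool:
        return term in self.values


def corpus_ic(
    g: OntologyGraph,
    corpus: AnnotationCorpus,
    count_entities: bool = False,
) -> ICTable:
    """Annotation-frequency IC over the subsumption closure.

    Parameters
    ----------
    count_entities:
        By default |I(x)| counts annotation *pairs*.  With this flag each
        entity contributes at most once per term closure (distinct-entity
        counting), an alternative convention some toolkits use.

    Terms never annotated (directly or via descendants) get the finite
    ceiling IC = -ln(1/(|I|+1)), just above the largest observed IC, so that
    "rarer implies more informative" survives without infinities.
    """
    if not corpus.annotations or corpus.n_annotations == 0:
        raise OntologyError("corpus IC requires a nonempty annotation corpus")
    corpus.validate_against(g)

    counts: dict[str, float] = dict.fromkeys(g.terms, 0)
    if count_entities:
        for ts in corpus.annotations.values():
            closure = frozenset().union(*(g.ancestors(t) for t in ts))
            for a in closure:
                counts[a] += 1
        total = len(corpus.annotations)
    else:
        for ts in corpus.annotations.values():
            for t in ts:
                for a in g.ancestors(t):
                    counts[a] += 1
        total = corpus.n_annotations

    unseen = -math.log(1.0 / (total + 1))
    values = {
        t: (-math.log(c / total) + 0.0 if c > 0 else unseen) for t, c in counts.items()
    }
    return ICTable(method="resnik_entities" if count_entities else "resnik", values=values)


def structural_ic(g: OntologyGraph, method: str, zhou_k: float = 0.5) -> ICTable:
    """Structure-only IC by one of the registered term-specificity formulas."""
    if method not in STRUCTURAL_IC_METHODS:
        raise OntologyError(
            f"unknown structural IC method {method!r}; valid: {STRUCTURAL_IC_METHODS}"
        )
    if not 0.0 <= zhou_k <= 1.0:
        raise OntologyError(f"zhou weight k must be in [0, 1], got {zhou_k}")
    stats = g.term_stats()
    n_terms = len(g)
    d_max = g.max_depth
    n_leaves = g.n_leaves
    log_n = math.log(n_terms) if n_terms > 1 else 1.0
    log_d = math.log(d_max + 1) if d_max > 0 else 1.0

    def seco(t: str) -> float:
        return 1.0 - math.log(stats[t].n_descendants + 1) / log_n

    def depth_max(t: str) -> float:
        return math.log(stats[t].max_depth + 1) / log_d

    def depth_min(t: str) -> float:
        return math.log(stats[t].min_depth + 1) / log_d

    formulas = {
        "seco": seco,
        "zhou": lambda t: zhou_k * seco(t) + (1 - zhou_k) * depth_max(t),
        "sanchez": lambda t: -math.log(
            (stats[t].n_leaves_below / stats[t].n_subsumers + 1) / (n_leaves + 1)
        ),
        "depth_max": depth_max,
        "depth_min": depth_min,
    }
    f = formulas[method]
    return ICTable(method=method, values={t: f(t) for t in g.terms})
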