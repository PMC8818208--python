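"""Pairwise term-term and groupwise profile-profile similarity measures.

Measures fall into three levels, mirroring how semantic-measures toolkits
organise them:

- *pairwise*: similarity between two single terms (Rada path similarity,
  Resnik MICA-IC, ancestor-set Jaccard/Dice);
- *groupwise-direct*: set-to-set similarity defined without a pairwise
  measure (raw-set Jaccard, ancestor-union intersection, graph information
  content GIC);
- *groupwise-indirect*: an aggregator (MAX / MIN / AVG / BMA / BMM) applied
  to the full pairwise score matrix between the two term sets.

Every measure is registered with a :class:`MeasureDescriptor` so a benchmark
sweep can enumerate valid (groupwise, pairwise, IC) combinations without
special-casing individual measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np

from .ic import ICTable
from .ontology import OntologyError, OntologyGraph

__all__ = [
    "PhenotypeProfile",
    "MeasureDescriptor",
    "sim_rada",
    "sim_resnik_pw",
    "sim_ancestor_overlap",
    "gw_jaccard",
    "gw_gic",
    "gw_ui",
    "gw_indirect",
    "AGGREGATORS",
    "default_roster",
    "registry_table",
]

log = logging.getLogger(__name__)

AGGREGATORS = ("max", "min", "avg", "bma", "bmm")


@dataclass(frozen=True)
class PhenotypeProfile:
    """The set of ontology terms annotated to one admission."""

    admission_id: str
    terms: frozenset[str]

    @classmethod
    def make(cls, admission_id: str, terms: Iterable[str]) -> "PhenotypeProfile":
        return cls(admission_id, frozenset(terms))


@dataclass(frozen=True)
class MeasureDescriptor:
    """Registry entry: what a measure is and what it needs."""

    id: str
    level: str  # "ic" | "pairwise" | "groupwise-direct" | "groupwise-indirect"
    needs_ic: bool = False
    needs_pairwise: bool = False

    def __post_init__(self) -> None:
        levels = {"ic", "pairwise", "groupwise-direct", "groupwise-indirect"}
        if self.level not in levels:
            raise ValueError(f"invalid measure level {self.level!r}")
        if self.needs_pairwise and self.level != "groupwise-indirect":
            raise ValueError(f"{self.id}: only indirect groupwise measures take a pairwise measure")


# ---------------------------------------------------------------------------
# pairwise measures
# ---------------------------------------------------------------------------


def sim_rada(g: OntologyGraph, x: str, y: str) -> float:
    """Path similarity 1/(d+1) with d the shortest is_a path between x and y."""
    return 1.0 / (g.shortest_path_length(x, y) + 1)


def sim_resnik_pw(g: OntologyGraph, x: str, y: str, ic: ICTable) -> float:
    """IC of the most informative common ancestor of x and y."""
    _, value = g.mica(x, y, ic.values)
    return value


def sim_ancestor_overlap(g: OntologyGraph, x: str, y: str, variant: str = "jaccard") -> float:
    """Jaccard or Dice overlap of the two terms' inclusive ancestor sets."""
    xa = g.ancestors(x)
    ya = g.ancestors(y)
    inter = len(xa & ya)
    if variant == "jaccard":
        return inter / len(xa | ya)
    if variant == "dice":
        return 2.0 * inter / (len(xa) + len(ya))
    raise OntologyError(f"unknown ancestor-overlap variant {variant!r}")


# ---------------------------------------------------------------------------
# direct groupwise measures
# ---------------------------------------------------------------------------


def _check_profiles(a: PhenotypeProfile, b: PhenotypeProfile) -> bool:
    """Shared empty-profile policy: both empty is an error, one empty scores 0."""
    if not a.terms and not b.terms:
        raise OntologyError(
            f"cannot compare two empty profiles ({a.admission_id}, {b.admission_id})"
        )
    if not a.terms or not b.terms:
        log.warning(
            "empty profile in comparison (%s, %s); similarity set to 0",
            a.admission_id,
            b.admission_id,
        )
        return False
    return True


def gw_jaccard(a: PhenotypeProfile, b: PhenotypeProfile) -> float:
    """Jaccard index over the raw annotated term sets (no ancestor closure)."""
    if not _check_profiles(a, b):
        return 0.0
    return len(a.terms & b.terms) / len(a.terms | b.terms)


def _closure(g: OntologyGraph, profile: PhenotypeProfile) -> frozenset[str]:
    return frozenset().union(*(g.ancestors(t) for t in profile.terms))


def gw_ui(g: OntologyGraph, a: PhenotypeProfile, b: PhenotypeProfile) -> float:
    """Union-intersection overlap of the profiles' ancestor closures."""
    if not _check_profiles(a, b):
        return 0.0
    ca, cb = _closure(g, a), _closure(g, b)
    return len(ca & cb) / len(ca | cb)


def gw_gic(g: OntologyGraph, a: PhenotypeProfile, b: PhenotypeProfile, ic: ICTable) -> float:
    """Graph information content: IC-weighted closure overlap.

    Ratio of summed IC over the intersection versus the union of the two
    ancestor closures.  A union carrying zero total IC scores 0 by
    convention (and is logged), since no term distinguishes the profiles.
    """
    if not _check_profiles(a, b):
        return 0.0
    ca, cb = _closure(g, a), _closure(g, b)
    if ca == cb:
        return 1.0
    union_ic = sum(ic[t] for t in ca | cb)
    if union_ic == 0.0:
        log.warning(
            "GIC union carries zero total IC for (%s, %s); returning 0",
            a.admission_id,
            b.admission_id,
        )
        return 0.0
    return sum(ic[t] for t in ca & cb) / union_ic


# ---------------------------------------------------------------------------
# indirect groupwise aggregation
# ---------------------------------------------------------------------------


def aggregate(matrix: np.ndarray, aggregator: str) -> float:
    """Collapse an m x n pairwise score matrix to one groupwise score."""
    if aggregator == "max":
        return float(matrix.max())
    if aggregator == "min":
        return float(matrix.min())
    if aggregator == "avg":
        return float(matrix.mean())
    row_best = matrix.max(axis=1).mean()
    col_best = matrix.max(axis=0).mean()
    if aggregator == "bma":
        return float((row_best + col_best) / 2.0)
    if aggregator == "bmm":
        return float(max(row_best, col_best))
    raise OntologyError(f"unknown aggregator {aggregator!r}; valid: {AGGREGATORS}")


def gw_indirect(
    g: OntologyGraph,
    a: PhenotypeProfile,
    b: PhenotypeProfile,
    pairwise: str,
    aggregator: str,
    ic: Optional[ICTable] = None,
) -> float:
    """Aggregate a pairwise measure over all term pairs of two profiles."""
    if not _check_profiles(a, b):
        return 0.0
    fn = _pairwise_fn(g, pairwise, ic)
    ta, tb = sorted(a.terms), sorted(b.terms)
    matrix = np.array([[fn(x, y) for y in tb] for x in ta])
    return aggregate(matrix, aggregator)


def _pairwise_fn(
    g: OntologyGraph, pairwise: str, ic: Optional[ICTable]
) -> Callable[[str, str], float]:
    needs_ic = pairwise in {"resnik"}
    if needs_ic and ic is None:
        raise OntologyError(f"pairwise measure {pairwise!r} requires an IC table")
    if pairwise == "rada":
        return lambda x, y: sim_rada(g, x, y)
    if pairwise == "resnik":
        return lambda x, y: sim_resnik_pw(g, x, y, ic)
    if pairwise == "anc_jaccard":
        return lambda x, y: sim_ancestor_overlap(g, x, y, "jaccard")
    if pairwise == "anc_dice":
        return lambda x, y: sim_ancestor_overlap(g, x, y, "dice")
    raise OntologyError(f"unknown pairwise measure {pairwise!r}")


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def default_roster() -> list[MeasureDescriptor]:
    """All registered IC, pairwise and groupwise measures."""
    return [
        MeasureDescriptor("resnik", "ic"),
        MeasureDescriptor("seco", "ic"),
        MeasureDescriptor("zhou", "ic"),
        MeasureDescriptor("sanchez", "ic"),
        MeasureDescriptor("depth_max", "ic"),
        MeasureDescriptor("depth_min", "ic"),
        MeasureDescriptor("rada", "pairwise"),
        MeasureDescriptor("resnik", "pairwise", needs_ic=True),
        MeasureDescriptor("anc_jaccard", "pairwise"),
        MeasureDescriptor("anc_dice", "pairwise"),
        MeasureDescriptor("jaccard", "groupwise-direct"),
        MeasureDescriptor("ui", "groupwise-direct"),
        MeasureDescriptor("gic", "groupwise-direct", needs_ic=True),
        MeasureDescriptor("max", "groupwise-indirect", needs_pairwise=True),
        MeasureDescriptor("min", "groupwise-indirect", needs_pairwise=True),
        MeasureDescriptor("avg", "groupwise-indirect", needs_pairwise=True),
        MeasureDescriptor("bma", "groupwise-indirect", needs_pairwise=True),
        MeasureDescriptor("bmm", "groupwise-indirect", needs_pairwise=True),
    ]


def registry_table(roster: Optional[list[MeasureDescriptor]] = None):
    """Measure registry as a DataFrame (id, level, needs_ic, needs_pairwise)."""
    import pandas as pd

    roster = default_roster() if roster is None else roster
    return pd.DataFrame(
        [
            {
                "id": m.id,
                "level": m.level,
                "needs_ic": m.needs_ic,
                "needs_pairwise": m.needs_pairwise,
            }
            for m in roster
        ]
    )
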