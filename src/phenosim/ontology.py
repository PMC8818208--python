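"""Subsumption taxonomy: loading, traversal and common-ancestor queries.

The ontology is modelled as a rooted directed acyclic graph over term
identifiers whose only edge type is ``is_a`` (child -> parent subsumption).
All similarity and information-content machinery in this package is defined
on this structure alone; other relationship types present in an OBO file
(``part_of`` etc.) are deliberately ignored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import cached_property
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "OntologyGraph",
    "TermStats",
    "read_obo",
    "OntologyError",
]

VIRTUAL_ROOT = "VIRTUAL:ROOT"


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown terms."""


@dataclass(frozen=True)
class TermStats:
    """Structural support values for a single term.

    Depths are edge counts relative to the root (root depth 0);
    ``n_descendants`` is exclusive, ``n_subsumers`` counts inclusive
    ancestors (so the root has exactly 1), and ``n_leaves_below`` counts a
    leaf term as its own leaf descendant.
    """

    term: str
    min_depth: int
    max_depth: int
    n_descendants: int
    n_leaves_below: int
    n_subsumers: int


class OntologyGraph:
    """Rooted is_a DAG with cached traversal queries.

    Parameters
    ----------
    parents:
        Map from term id to its set of direct is_a parents.  Exactly one
        term must be parentless; it becomes the root.
    """

    def __init__(self, parents: Mapping[str, Iterable[str]]):
        down = nx.DiGraph()  # edges parent -> child
        for term, ps in parents.items():
            down.add_node(term)
            for p in ps:
                down.add_edge(p, term)
        unknown = set(down.nodes) - set(parents)
        if unknown:
            raise OntologyError(
                f"parent terms missing from term set: {sorted(unknown)[:5]}"
            )
        if not nx.is_directed_acyclic_graph(down):
            cycle = [u for u, _ in nx.find_cycle(down)]
            raise OntologyError(f"is_a cycle detected: {' -> '.join(cycle)}")
        roots = [t for t in down.nodes if down.in_degree(t) == 0]
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one parentless term, found {len(roots)}: "
                f"{sorted(roots)[:5]}"
            )
        self.root: str = roots[0]
        self._down = down
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(down.predecessors(t)) for t in down.nodes
        }

    # -- basic container protocol -------------------------------------------

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._down.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._down

    def __len__(self) -> int:
        return self._down.number_of_nodes()

    def children(self, term: str) -> frozenset[str]:
        self._check(term)
        return frozenset(self._down.successors(term))

    def _check(self, term: str) -> None:
        if term not in self._down:
            raise OntologyError(f"unknown term: {term!r}")

    # -- traversal -----------------------------------------------------------

    @cached_property
    def _ancestor_sets(self) -> dict[str, frozenset[str]]:
        """Inclusive transitive is_a closure per term, via topological DP."""
        closure: dict[str, frozenset[str]] = {}
        for term in nx.topological_sort(self._down):
            acc: set[str] = {term}
            for p in self.parents[term]:
                acc |= closure[p]
            closure[term] = frozenset(acc)
        return closure

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        """Transitive is_a closure of *term*; always contains the root."""
        self._check(term)
        anc = self._ancestor_sets[term]
        return anc if include_self else anc - {term}

    def descendants(self, term: str, include_self: bool = False) -> frozenset[str]:
        self._check(term)
        desc = nx.descendants(self._down, term)
        if include_self:
            desc = desc | {term}
        return frozenset(desc)

    @cached_property
    def _undirected(self) -> nx.Graph:
        return self._down.to_undirected(as_view=True)

    def shortest_path_length(self, x: str, y: str) -> int:
        """Minimum number of is_a edges between *x* and *y*.

        Edges may be traversed in either direction (the conventional
        undirected reading of taxonomic path distance).
        """
        self._check(x)
        self._check(y)
        return nx.shortest_path_length(self._undirected, x, y)

    def path_lengths_from(self, term: str) -> dict[str, int]:
        """Undirected is_a path lengths from *term* to every term (one BFS)."""
        self._check(term)
        return dict(nx.single_source_shortest_path_length(self._undirected, term))

    def common_ancestors(self, x: str, y: str) -> frozenset[str]:
        return self.ancestors(x) & self.ancestors(y)

    def mica(self, x: str, y: str, ic: Mapping[str, float]) -> tuple[str, float]:
        """Most informative common ancestor under the IC table *ic*.

        Ties are broken toward the lexicographically smallest term id so that
        the result is deterministic.
        """
        common = self.common_ancestors(x, y)
        missing = [t for t in common if t not in ic]
        if missing:
            raise OntologyError(
                f"IC table lacks common ancestors: {sorted(missing)[:5]}"
            )
        best = min(common, key=lambda t: (-ic[t], t))
        return best, ic[best]

    # -- structural statistics ----------------------------------------------

    @cached_property
    def _stats(self) -> dict[str, TermStats]:
        down = self._down
        order = list(nx.topological_sort(down))
        min_depth = {self.root: 0}
        max_depth = {self.root: 0}
        for t in order:
            for c in down.successors(t):
                d = min_depth[t] + 1
                if c not in min_depth or d < min_depth[c]:
                    min_depth[c] = d
                d = max_depth[t] + 1
                if c not in max_depth or d > max_depth[c]:
                    max_depth[c] = d
        # descendant and leaf counts by reverse-topological set union; the
        # DAG may share descendants between parents, so counts use sets.
        desc: dict[str, set[str]] = {}
        leaves: dict[str, set[str]] = {}
        for t in reversed(order):
            ds: set[str] = set()
            lv: set[str] = set()
            for c in down.successors(t):
                ds |= desc[c]
                ds.add(c)
                lv |= leaves[c]
            if down.out_degree(t) == 0:
                lv = {t}
            desc[t] = ds
            leaves[t] = lv
        return {
            t: TermStats(
                term=t,
                min_depth=min_depth[t],
                max_depth=max_depth[t],
                n_descendants=len(desc[t]),
                n_leaves_below=len(leaves[t]),
                n_subsumers=len(self._ancestor_sets[t]),
            )
            for t in order
        }

    def term_stats(self) -> dict[str, TermStats]:
        """Depth, descendant, leaf and subsumer counts for every term."""
        return dict(self._stats)

    @property
    def max_depth(self) -> int:
        """Longest root-to-term path length over the whole ontology."""
        return max(s.max_depth for s in self._stats.values())

    @property
    def n_leaves(self) -> int:
        return sum(1 for t in self._down.nodes if self._down.out_degree(t) == 0)


def _is_obsolete(data: Mapping) -> bool:
    flag = data.get("is_obsolete", False)
    if isinstance(flag, str):
        return flag.lower() == "true"
    return bool(flag)


def read_obo(source: str | IO[str], allow_virtual_root: bool = False) -> OntologyGraph:
    """Load an OBO flat file into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas and their ``id``/``is_a``/``is_obsolete`` tags are
    honoured; every other relationship and stanza type is ignored.  Obsolete
    terms are removed.  A term whose parents are all obsolete is re-attached
    to its nearest non-obsolete ancestors reachable through obsolete is_a
    chains, or to the root when no such ancestor exists.

    Parameters
    ----------
    source:
        Path, OBO text, or an open text stream.
    allow_virtual_root:
        When the file declares several parentless terms, insert a synthetic
        root above them instead of raising.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    full = obonet.read_obo(source, ignore_obsolete=False)

    obsolete = {t for t, d in full.nodes(data=True) if _is_obsolete(d)}
    live = set(full.nodes) - obsolete
    if not live:
        raise OntologyError("no non-obsolete terms in OBO input")

    def is_a_parents(t: str) -> list[str]:
        return [v for _, v, k in full.out_edges(t, keys=True) if k == "is_a"]

    def resolve(parent: str, seen: set[str]) -> set[str]:
        """Nearest non-obsolete ancestors of an obsolete parent."""
        if parent in seen:
            return set()
        seen.add(parent)
        out: set[str] = set()
        for gp in is_a_parents(parent):
            if gp in obsolete:
                out |= resolve(gp, seen)
            elif gp in live:
                out.add(gp)
        return out

    parents: dict[str, set[str]] = {}
    had_is_a: dict[str, bool] = {}
    orphaned: list[str] = []  # lost every parent to obsolete chains
    for t in live:
        raw = is_a_parents(t)
        had_is_a[t] = bool(raw)
        ps: set[str] = set()
        for p in raw:
            if p in obsolete:
                ps |= resolve(p, set())
            elif p in live:
                ps.add(p)
        parents[t] = ps - {t}
        if raw and not parents[t]:
            orphaned.append(t)

    root_candidates = sorted(t for t in live if not had_is_a[t])
    if len(root_candidates) == 0:
        raise OntologyError("no parentless term: cannot determine a root")
    if len(root_candidates) > 1:
        if not allow_virtual_root:
            raise OntologyError(
                f"multiple parentless terms {root_candidates[:5]}; "
                "pass allow_virtual_root=True to join them under a synthetic root"
            )
        parents[VIRTUAL_ROOT] = set()
        for t in root_candidates:
            parents[t] = {VIRTUAL_ROOT}
        root = VIRTUAL_ROOT
    else:
        root = root_candidates[0]
    for t in orphaned:
        parents[t] = {root}
    return OntologyGraph(parents)
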