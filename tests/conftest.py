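"""Shared fixtures: a hand-checkable toy taxonomy and brute-force oracles.

The toy taxonomy used throughout (root r; a,b under r; c,d under a;
e under b; f under c) is small enough that every closure, path and count
can be verified by eye, and the toy corpus {P1:{f}, P2:{d}, P3:{e},
P4:{c,e}} gives corpus-IC values computable by hand.

The oracle helpers deliberately re-derive graph quantities from the raw
parent map with naive algorithms (recursive closure, queue-based BFS),
independently of the package's networkx-backed implementation.
"""

from collections import deque

import numpy as np
import pytest

from phenosim import AnnotationCorpus, OntologyGraph, corpus_ic

TOY_PARENTS = {
    "r": set(),
    "a": {"r"},
    "b": {"r"},
    "c": {"a"},
    "d": {"a"},
    "e": {"b"},
    "f": {"c"},
}

TOY_CORPUS = {"P1": {"f"}, "P2": {"d"}, "P3": {"e"}, "P4": {"c", "e"}}


@pytest.fixture(scope="session")
def toy_graph() -> OntologyGraph:
    return OntologyGraph(TOY_PARENTS)


@pytest.fixture(scope="session")
def toy_corpus() -> AnnotationCorpus:
    return AnnotationCorpus.from_dict(TOY_CORPUS)


@pytest.fixture(scope="session")
def toy_ic(toy_graph, toy_corpus):
    return corpus_ic(toy_graph, toy_corpus)


# ---------------------------------------------------------------------------
# independent oracles over a raw parent map
# ---------------------------------------------------------------------------


def oracle_ancestors(parents: dict, term: str) -> set:
    """Inclusive ancestor closure by naive recursion over the parent map."""
    out = {term}
    for p in parents[term]:
        out |= oracle_ancestors(parents, p)
    return out


def oracle_descendants(parents: dict, term: str) -> set:
    return {t for t in parents if term in oracle_ancestors(parents, t)} - {term}


def oracle_shortest_path(parents: dict, x: str, y: str) -> int:
    """Breadth-first search over the undirected edge set."""
    adj: dict[str, set] = {t: set() for t in parents}
    for t, ps in parents.items():
        for p in ps:
            adj[t].add(p)
            adj[p].add(t)
    seen = {x: 0}
    queue = deque([x])
    while queue:
        u = queue.popleft()
        if u == y:
            return seen[u]
        for v in adj[u]:
            if v not in seen:
                seen[v] = seen[u] + 1
                queue.append(v)
    raise AssertionError(f"no path between {x} and {y}")


def oracle_mica(parents: dict, x: str, y: str, ic: dict) -> float:
    """Max IC over the enumerated common-ancestor set."""
    common = oracle_ancestors(parents, x) & oracle_ancestors(parents, y)
    return max(ic[t] for t in common)


def oracle_corpus_ic(parents: dict, annotations: dict) -> dict:
    """-ln of descendant-closure annotation frequency, by direct counting."""
    total = sum(len(ts) for ts in annotations.values())
    out = {}
    for t in parents:
        below = oracle_descendants(parents, t) | {t}
        count = sum(1 for ts in annotations.values() for u in ts if u in below)
        out[t] = (
            -np.log(count / total) if count else -np.log(1.0 / (total + 1))
        )
    return out


def make_random_parents(rng: np.random.Generator, n_terms: int, multi_parent_prob: float = 0.3) -> dict:
    """Random single-rooted parent map, independent of the synthetic module."""
    parents = {"t000": set()}
    for i in range(1, n_terms):
        ps = {int(rng.integers(0, i))}
        if i > 1 and rng.random() < multi_parent_prob:
            ps.add(int(rng.integers(0, i)))
        parents[f"t{i:03d}"] = {f"t{p:03d}" for p in ps}
    return parents


@pytest.fixture
def random_parents_factory():
    return make_random_parents
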