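"""Shared fixtures: tiny hand-built ontologies, corpora and oracle helpers.

The oracle helpers recompute quantities from first principles (path
enumeration, definition-level sums, naive transitive closure) and stay
independent of the library code paths they are used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from semgo.ontology import AnnotationCorpus, GafRecord, OntologyGraph, parse_obo


def obo_text(stanzas: list[tuple[str, str, list[str]]], extra: str = "") -> str:
    """Render (term, namespace, parents) stanzas as OBO text."""
    lines = ["format-version: 1.2", ""]
    for term, ns, parents in stanzas:
        lines += ["[Term]", f"id: {term}", f"name: {term}", f"namespace: {ns}"]
        lines += [f"is_a: {p}" for p in parents]
        lines.append("")
    return "\n".join(lines) + extra


def graph_from_stanzas(stanzas) -> OntologyGraph:
    return parse_obo(obo_text(stanzas))


MF = "molecular_function"


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """root <- mid <- leaf, one namespace."""
    return graph_from_stanzas([
        ("GO:0000001", MF, []),
        ("GO:0000002", MF, ["GO:0000001"]),
        ("GO:0000003", MF, ["GO:0000002"]),
    ])


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """leaf with two parents p1, p2, both under root."""
    return graph_from_stanzas([
        ("GO:0000001", MF, []),
        ("GO:0000002", MF, ["GO:0000001"]),
        ("GO:0000003", MF, ["GO:0000001"]),
        ("GO:0000004", MF, ["GO:0000002", "GO:0000003"]),
    ])


def corpus_from_counts(graph: OntologyGraph, counts: dict[str, int]) -> AnnotationCorpus:
    """Corpus whose records cite each term the given number of times."""
    records = []
    i = 0
    aspect = {"molecular_function": "F", "biological_process": "P",
              "cellular_component": "C"}
    for term, n in counts.items():
        for _ in range(n):
            i += 1
            records.append(
                GafRecord(f"OBJ{i}", term, "IEA", aspect[graph.namespace_of(term)])
            )
    return AnnotationCorpus.from_records(records, graph)


# ---------------------------------------------------------------------------
# Oracles (independent recomputations)
# ---------------------------------------------------------------------------


def ancestors_by_path_enumeration(graph: OntologyGraph, term: str) -> set[str]:
    """Reflexive ancestor set by exhaustive upward path enumeration."""
    seen = {term}
    stack = [term]
    while stack:
        t = stack.pop()
        for parent in graph.graph.successors(t):
            seen.add(parent)
            stack.append(parent)
    return seen


def ic_oracle(graph: OntologyGraph, corpus: AnnotationCorpus, term: str) -> float:
    """IC from the definition, counting descendants one by one."""
    count = sum(
        corpus.direct_count.get(d, 0)
        for d in graph.terms
        if term in ancestors_by_path_enumeration(graph, d)
    )
    if count == 0:
        return math.log(corpus.total) + 1e-6
    return -math.log(count / corpus.total)


def lin_oracle(graph, corpus, t1, t2) -> float:
    common = ancestors_by_path_enumeration(graph, t1) & ancestors_by_path_enumeration(graph, t2)
    ic1, ic2 = ic_oracle(graph, corpus, t1), ic_oracle(graph, corpus, t2)
    if ic1 + ic2 == 0:
        return 1.0 if t1 == t2 else 0.0
    return min(1.0, 2 * max(ic_oracle(graph, corpus, g) for g in common) / (ic1 + ic2))


def slim_w_oracle(graph: OntologyGraph, weights: dict[str, float]) -> dict[str, float]:
    """Cumulative weights from the definition: W(g) sums w_j over input
    terms g_j whose enumerated ancestor set contains g."""
    slim = set()
    for t in weights:
        slim |= ancestors_by_path_enumeration(graph, t)
    return {
        g: sum(
            w for t, w in weights.items()
            if g in ancestors_by_path_enumeration(graph, t)
        )
        for g in slim
    }


def single_linkage_oracle(items: list[str], similar) -> list[frozenset[str]]:
    """Connected components under `similar` via naive closure iteration."""
    clusters = [{t} for t in items]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(clusters)), 2):
            if any(similar(a, b) for a in clusters[i] for b in clusters[j]):
                clusters[i] |= clusters[j]
                del clusters[j]
                changed = True
                break
    return sorted((frozenset(c) for c in clusters), key=min)


def random_dag_stanzas(rng: np.random.Generator, n: int, ns: str = MF):
    """Random layered DAG stanzas: term i>0 picks parents among 0..i-1."""
    stanzas = [("GO:0000001", ns, [])]
    for i in range(1, n):
        term = f"GO:{i + 1:07d}"
        k = int(rng.integers(1, min(i, 2) + 1))
        idx = sorted(rng.choice(i, size=k, replace=False))
        stanzas.append((term, ns, [f"GO:{j + 1:07d}" for j in idx]))
    return stanzas
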