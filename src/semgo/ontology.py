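"""Gene Ontology graph, annotation counts, information content and Lin similarity.

The ontology is a directed acyclic graph of GO terms partitioned into three
namespaces (molecular_function, biological_process, cellular_component).
Edges point child -> parent along ``is_a`` and, optionally, ``part_of``
relations.  An annotation corpus (GAF-style records) supplies term occurrence
counts, from which the Resnik information content

    IC(t) = -log( cumulative_count(t) / total_records )

is derived; ``cumulative_count`` counts records citing the term or any of its
descendants.  Lin similarity between two terms of the same namespace is

    sim(t1, t2) = 2 * max_{a in S(t1,t2)} IC(a) / (IC(t1) + IC(t2))

where S is the set of common subsumers (common ancestors, reflexive).
"""

from __future__ import annotations

import io
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence, TextIO

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")

#: GAF column 9 aspect letters to namespace names.
ASPECT_TO_NAMESPACE = {
    "F": "molecular_function",
    "P": "biological_process",
    "C": "cellular_component",
}

#: Relationship types traversed when building the DAG.
DEFAULT_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Raised for structural problems in an ontology or its queries."""


class OboParseError(OntologyError):
    """Raised when an OBO stream cannot be parsed."""


class GafParseError(ValueError):
    """Raised when a GAF stream cannot be parsed."""


# ---------------------------------------------------------------------------
# Ontology graph
# ---------------------------------------------------------------------------


@dataclass
class OntologyGraph:
    """The GO DAG with namespace partitions and ancestor closure queries.

    ``graph`` holds child -> parent edges restricted to the accepted relation
    types; obsolete terms are excluded from the graph but remembered in
    ``obsolete``; ``alt_ids`` maps secondary identifiers to their primary
    term.
    """

    graph: nx.DiGraph
    namespace: dict[str, str]
    roots: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)
    obsolete: frozenset[str] = frozenset()
    _anc_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph or term in self.alt_ids

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def resolve(self, term: str) -> str:
        """Map an identifier (primary or alt_id) to its primary term."""
        if term in self.graph:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise OntologyError(f"unknown term: {term!r}")

    def namespace_of(self, term: str) -> str:
        return self.namespace[self.resolve(term)]

    def root_of(self, term: str) -> str:
        return self.roots[self.namespace_of(term)]

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(self.resolve(term)))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(self.resolve(term)))

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor closure of ``term``, including the term itself.

        This is the subsumer set {g : term -> g has a path}, reflexive so
        that a term subsumes itself.
        """
        t = self.resolve(term)
        cached = self._anc_cache.get(t)
        if cached is None:
            # edges run child -> parent, so graph-descendants are ancestors
            cached = frozenset(nx.descendants(self.graph, t)) | {t}
            self._anc_cache[t] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        """Descendant closure of ``term``, including the term itself."""
        t = self.resolve(term)
        return frozenset(nx.ancestors(self.graph, t)) | {t}

    def terms_in_namespace(self, namespace: str) -> set[str]:
        return {t for t, ns in self.namespace.items() if ns == namespace}


def parse_obo(
    source: TextIO | str,
    *,
    include_part_of: bool = True,
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 stream (or text) into an :class:`OntologyGraph`.

    Obsolete terms are excluded from the graph; ``alt_id`` identifiers are
    recorded so they resolve to their primary term; relationship types other
    than ``is_a``/``part_of`` are ignored (``part_of`` only when
    ``include_part_of``).
    """
    if isinstance(source, str):
        text = source
    else:
        text = source.read()
    _prevalidate_obo(text)
    try:
        multigraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - obonet internal failures
        raise OboParseError(f"OBO parse failure: {exc}") from exc
    if multigraph.number_of_nodes() == 0:
        raise OboParseError("OBO stream contains no [Term] stanzas")

    relations = {"is_a"} | ({"part_of"} if include_part_of else set())
    obsolete = {
        t for t, data in multigraph.nodes(data=True)
        if str(data.get("is_obsolete", "")).lower() == "true"
    }

    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for term, data in multigraph.nodes(data=True):
        if term in obsolete:
            continue
        ns = data.get("namespace")
        if ns is None:
            raise OboParseError(f"term {term} has no namespace")
        if ns not in NAMESPACES:
            raise OboParseError(f"term {term} has unknown namespace {ns!r}")
        graph.add_node(term)
        namespace[term] = ns
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    for child, parent, rel in multigraph.edges(keys=True):
        if rel not in relations:
            continue
        if child in obsolete or parent in obsolete:
            continue
        if parent not in graph:
            continue
        graph.add_edge(child, parent)

    if not nx.is_directed_acyclic_graph(graph):
        raise OboParseError("ontology contains a relationship cycle")

    roots: dict[str, str] = {}
    for ns in sorted(set(namespace.values())):
        ns_terms = [t for t in graph.nodes if namespace[t] == ns]
        ns_roots = [t for t in ns_terms if graph.out_degree(t) == 0]
        if len(ns_roots) != 1:
            raise OboParseError(
                f"namespace {ns} has {len(ns_roots)} roots, expected exactly 1"
            )
        roots[ns] = ns_roots[0]

    for child, parent in graph.edges:
        if namespace[child] != namespace[parent]:
            raise OboParseError(
                f"edge {child}->{parent} crosses namespaces"
            )

    return OntologyGraph(
        graph=graph,
        namespace=namespace,
        roots=roots,
        alt_ids=alt_ids,
        obsolete=frozenset(obsolete),
    )


def _prevalidate_obo(text: str) -> None:
    """Cheap line-level sanity pass so parse errors can name the line."""
    in_term = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(f"line {lineno}: malformed stanza header {raw!r}")
            in_term = line == "[Term]"
            continue
        if in_term and ":" not in line:
            raise OboParseError(f"line {lineno}: malformed tag line {raw!r}")


# ---------------------------------------------------------------------------
# GAF records and the annotation corpus
# ---------------------------------------------------------------------------


class GafRecord(NamedTuple):
    object_id: str
    go_id: str
    evidence: str
    aspect: str


def parse_gaf(source: TextIO | str) -> list[GafRecord]:
    """Parse GAF 2.x text into records (columns 2, 5, 7, 9).

    Comment lines start with ``!``.  Rows with fewer than 9 columns raise a
    :class:`GafParseError` naming the line.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    records = []
    for lineno, raw in enumerate(source, start=1):
        if not raw.strip() or raw.startswith("!"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise GafParseError(
                f"line {lineno}: GAF row has {len(fields)} columns, expected >= 9"
            )
        records.append(
            GafRecord(
                object_id=fields[1],
                go_id=fields[4],
                evidence=fields[6],
                aspect=fields[8],
            )
        )
    return records


def gaf_term_map(
    records: Iterable[GafRecord],
    graph: OntologyGraph,
    *,
    exclude_evidence: Sequence[str] = (),
) -> dict[str, set[str]]:
    """Map each annotated object to its set of (primary) GO terms."""
    excluded = set(exclude_evidence)
    out: dict[str, set[str]] = {}
    for rec in records:
        if rec.evidence in excluded:
            continue
        if rec.go_id not in graph:
            logger.warning("GAF term %s not in ontology; record skipped", rec.go_id)
            continue
        out.setdefault(rec.object_id, set()).add(graph.resolve(rec.go_id))
    return out


@dataclass
class AnnotationCorpus:
    """Term occurrence counts backing information content.

    ``direct_count[t]`` is the number of annotation records citing ``t``;
    ``cumulative_count[t]`` adds the direct counts of all descendants of
    ``t``; ``total`` is the number of records kept from the corpus.
    """

    direct_count: Counter
    cumulative_count: Counter
    total: int

    @classmethod
    def from_records(
        cls,
        records: Iterable[GafRecord],
        graph: OntologyGraph,
        *,
        exclude_evidence: Sequence[str] = (),
        count_duplicates: bool = True,
    ) -> "AnnotationCorpus":
        """Build counts from GAF records.

        With ``count_duplicates`` (default) every record counts; otherwise
        only distinct (object, term) pairs do.
        """
        excluded = set(exclude_evidence)
        direct: Counter = Counter()
        seen: set[tuple[str, str]] = set()
        total = 0
        for rec in records:
            if rec.evidence in excluded:
                continue
            if rec.go_id not in graph:
                logger.warning(
                    "GAF term %s not in ontology; not counted", rec.go_id
                )
                continue
            term = graph.resolve(rec.go_id)
            if not count_duplicates:
                key = (rec.object_id, term)
                if key in seen:
                    continue
                seen.add(key)
            direct[term] += 1
            total += 1
        cumulative: Counter = Counter()
        for term, n in direct.items():
            for anc in graph.ancestors(term):
                cumulative[anc] += n
        return cls(direct_count=direct, cumulative_count=cumulative, total=total)

    @classmethod
    def from_gaf(
        cls,
        source: TextIO | str,
        graph: OntologyGraph,
        **kwargs,
    ) -> "AnnotationCorpus":
        return cls.from_records(parse_gaf(source), graph, **kwargs)


# ---------------------------------------------------------------------------
# Information content and semantic similarity
# ---------------------------------------------------------------------------

#: Added to the IC cap used for corpus-unseen terms, keeping them strictly
#: more informative than a once-seen term while staying finite.
UNSEEN_IC_EPSILON = 1e-6


def information_content(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    term: str,
    *,
    log_base: float = math.e,
) -> float:
    """Resnik information content -log(cumulative_count/total).

    Terms never seen in the corpus (cumulative count 0) receive the finite
    cap -log(1/total) + epsilon instead of infinity.
    """
    if corpus.total <= 0:
        raise OntologyError("annotation corpus is empty (total = 0)")
    t = graph.resolve(term)
    count = corpus.cumulative_count.get(t, 0)
    if count == 0:
        return -math.log(1.0 / corpus.total, log_base) + UNSEEN_IC_EPSILON
    return max(0.0, -math.log(count / corpus.total, log_base))


def resnik_shared_ic(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    t1: str,
    t2: str,
    *,
    log_base: float = math.e,
) -> float:
    """Highest information content among the common subsumers of t1 and t2."""
    a, b = graph.resolve(t1), graph.resolve(t2)
    if graph.namespace[a] != graph.namespace[b]:
        raise OntologyError(
            f"terms {a} and {b} belong to different namespaces"
        )
    common = graph.ancestors(a) & graph.ancestors(b)
    return max(
        information_content(corpus, graph, g, log_base=log_base) for g in common
    )


def lin_similarity(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    t1: str,
    t2: str,
    *,
    log_base: float = math.e,
) -> float:
    """Lin similarity 2*shared_IC/(IC(t1)+IC(t2)), in [0, 1].

    When both terms carry zero information (root-equivalent), the ratio is
    undefined; identical terms score 1 and distinct ones 0 so that roots
    never attract other terms into a group.
    """
    a, b = graph.resolve(t1), graph.resolve(t2)
    ic1 = information_content(corpus, graph, a, log_base=log_base)
    ic2 = information_content(corpus, graph, b, log_base=log_base)
    denom = ic1 + ic2
    if denom == 0.0:
        return 1.0 if a == b else 0.0
    shared = resnik_shared_ic(graph, corpus, a, b, log_base=log_base)
    return min(1.0, 2.0 * shared / denom)
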