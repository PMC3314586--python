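"""Core scoring engine: slim construction, filtering, grouping, Total Score.

For each protein and namespace the weighted input terms are propagated to the
namespace root, keeping only terms on a root path of some input term (the
per-protein "GO slim").  Every slim term g accumulates

    W(g) = sum of w_i over input terms g_i that g subsumes (ancestor-or-self)

so reconstructed ancestors carry exactly the mass of the input terms below
them and W(root) equals the total input weight.  Terms are then filtered by

    Z(g)  = (W(g) - Wbar) / sigma        (Wbar = W(root)/|slim|, population
                                          sigma of the W values over the slim)
    GrS(k) = sum of InC over group k      (InC(g) = W(g)/W(root))

where groups are single-linkage clusters of input terms under Lin similarity,
and the survivors are ranked by the Total Score

    TS(g) = IC(g) * InC_nc(g) * (InC_nc(g)/GrS_nc(k)) * w_g

with InC_nc(g) = w_g/W(root) the non-cumulative internal confidence and
GrS_nc the group sum of InC_nc.  Within each group the member with the
highest TS is the group representative.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .evidence import WeightedTermSet
from .ontology import (
    AnnotationCorpus,
    OntologyGraph,
    information_content,
    lin_similarity,
)


class EngineError(ValueError):
    pass


@dataclass
class EngineConfig:
    """Thresholds and conventions of the scoring stage.

    sim_threshold   Lin similarity at or above which two input terms are
                    linked into the same group (single linkage).
    z_threshold     minimum Z over cumulative weights for a term to survive.
    grs_threshold   minimum (cumulative) Group Score of a term's group.
    ts_threshold    minimum Total Score for a term to be reported.
    wbar_over       population for Wbar's denominator: "slim" (all slim
                    terms) or "input" (retrieved terms only).
    sigma_over      weights entering sigma: "cumulative" (W over the slim)
                    or "input" (raw input w_i).
    representatives_only   report only each group's best-scoring member.
    log_base        logarithm base for information content.
    """

    sim_threshold: float = 0.7
    z_threshold: float = 0.0
    grs_threshold: float = 0.2
    ts_threshold: float = 0.0
    wbar_over: str = "slim"  # "slim" | "input"
    sigma_over: str = "cumulative"  # "cumulative" | "input"
    representatives_only: bool = False
    log_base: float = math.e


@dataclass
class GoSlim:
    """Per-protein, per-namespace slim: input terms plus their root paths."""

    protein: str
    namespace: str
    root: str
    input_weights: dict[str, float]
    slim_terms: frozenset[str]
    W: dict[str, float]
    Z: dict[str, float]
    mean_weight: float
    sigma: float

    @property
    def input_terms(self) -> set[str]:
        return set(self.input_weights)

    @property
    def root_weight(self) -> float:
        return self.W.get(self.root, 0.0)

    def is_empty(self) -> bool:
        return not self.input_weights


@dataclass
class TermGroup:
    """A single-linkage cluster of input terms with its group scores."""

    id: int
    members: frozenset[str]
    GrS: float
    GrS_nc: float


@dataclass
class ScoredAnnotation:
    """One reported term with every intermediate quantity of its score."""

    protein: str
    term: str
    namespace: str
    w: float
    W: float
    InC: float
    InC_nc: float
    IC: float
    Z: float
    group_id: int
    GrS: float
    GrS_nc: float
    TS: float
    is_representative: bool


def build_goslim(
    wts: WeightedTermSet | Mapping[str, float],
    graph: OntologyGraph,
    *,
    protein: str = "",
    config: EngineConfig | None = None,
) -> GoSlim:
    """Propagate input-term weights to the root, building the per-protein slim.

    All input terms must belong to a single namespace (split upstream).  The
    slim is exactly the union of the input terms' ancestor closures; W(g)
    sums the weights of the input terms g subsumes, so W(root) conserves the
    total input mass.  Z standardises W over the slim; with zero spread
    (e.g. a single input term) Z is defined as 0 everywhere.
    """
    cfg = config or EngineConfig()
    if isinstance(wts, WeightedTermSet):
        weights = dict(wts.weights)
        protein = protein or wts.protein
    else:
        weights = dict(wts)
    weights = {graph.resolve(t): w for t, w in weights.items()}
    if not weights:
        return GoSlim(protein, "", "", {}, frozenset(), {}, {}, 0.0, 0.0)

    namespaces = {graph.namespace_of(t) for t in weights}
    if len(namespaces) != 1:
        raise EngineError(
            f"input terms span namespaces {sorted(namespaces)}; split first"
        )
    namespace = namespaces.pop()
    root = graph.roots[namespace]

    W: dict[str, float] = {}
    for term, w in weights.items():
        for anc in graph.ancestors(term):
            W[anc] = W.get(anc, 0.0) + w
    slim_terms = frozenset(W)

    if cfg.wbar_over == "input":
        mean_weight = W[root] / len(weights)
    else:
        mean_weight = W[root] / len(slim_terms)
    if cfg.sigma_over == "input":
        pool = np.array(list(weights.values()), dtype=float)
    else:
        pool = np.array([W[t] for t in sorted(slim_terms)], dtype=float)
    sigma = float(np.std(pool))  # population std
    # guard against last-ulp noise when all weights are equal
    if sigma <= 1e-12 * float(np.max(np.abs(pool))):
        sigma = 0.0

    if sigma > 0:
        Z = {t: (W[t] - mean_weight) / sigma for t in slim_terms}
    else:
        Z = {t: 0.0 for t in slim_terms}

    return GoSlim(
        protein=protein,
        namespace=namespace,
        root=root,
        input_weights=weights,
        slim_terms=slim_terms,
        W=W,
        Z=Z,
        mean_weight=mean_weight,
        sigma=sigma,
    )


def internal_confidence(slim: GoSlim, term: str) -> float:
    """Cumulative internal confidence W(t)/W(root); 1 at the root."""
    if slim.root_weight <= 0:
        raise EngineError("slim has zero root weight")
    if term not in slim.slim_terms:
        raise EngineError(f"term {term} not in slim")
    return slim.W[term] / slim.root_weight


def noncumulative_internal_confidence(slim: GoSlim, term: str) -> float:
    """Non-cumulative internal confidence w_t/W(root); 0 for reconstructed
    ancestors that were not themselves input terms."""
    if slim.root_weight <= 0:
        raise EngineError("slim has zero root weight")
    if term not in slim.slim_terms:
        raise EngineError(f"term {term} not in slim")
    return slim.input_weights.get(term, 0.0) / slim.root_weight


def group_by_similarity(
    slim: GoSlim,
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    *,
    sim_threshold: float = 0.7,
    log_base: float = math.e,
) -> list[TermGroup]:
    """Single-linkage clustering of the slim's input terms by Lin similarity.

    Two terms share a group iff they are connected by a chain of pairs with
    similarity >= threshold.  Group ids are assigned in order of each
    group's lexicographically smallest member, so the partition is
    deterministic and independent of input order.
    """
    terms = sorted(slim.input_terms)
    parent = {t: t for t in terms}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            if lin_similarity(graph, corpus, a, b, log_base=log_base) >= sim_threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[str, set[str]] = {}
    for t in terms:
        clusters.setdefault(find(t), set()).add(t)

    groups = []
    for gid, rep in enumerate(sorted(clusters)):
        members = clusters[rep]
        grs = sum(internal_confidence(slim, m) for m in members)
        grs_nc = sum(noncumulative_internal_confidence(slim, m) for m in members)
        groups.append(
            TermGroup(id=gid, members=frozenset(members), GrS=grs, GrS_nc=grs_nc)
        )
    return groups


def filter_terms(
    slim: GoSlim,
    groups: Sequence[TermGroup],
    *,
    z_threshold: float = 0.0,
    grs_threshold: float = 0.2,
) -> set[str]:
    """Input terms surviving both filters: Z(t) >= z and GrS(group) >= grs.

    Discards isolated low-weight branches; an empty survivor set is a legal
    outcome (the protein simply receives no annotation in this namespace).
    """
    group_of = {m: g for g in groups for m in g.members}
    return {
        t
        for t in slim.input_terms
        if slim.Z[t] >= z_threshold and group_of[t].GrS >= grs_threshold
    }


def total_score(
    slim: GoSlim,
    group: TermGroup,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    term: str,
    *,
    log_base: float = math.e,
) -> float:
    """Total Score IC * InC_nc * (InC_nc/GrS_nc) * w for a surviving term."""
    if group.GrS_nc <= 0:
        raise EngineError(f"group {group.id} has zero non-cumulative score")
    ic = information_content(corpus, graph, term, log_base=log_base)
    inc_nc = noncumulative_internal_confidence(slim, term)
    w = slim.input_weights[term]
    return ic * inc_nc * (inc_nc / group.GrS_nc) * w


def score_namespace(
    slim: GoSlim,
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    config: EngineConfig,
) -> list[ScoredAnnotation]:
    """Group, filter and score one protein/namespace slim."""
    if slim.is_empty() or slim.root_weight <= 0:
        return []
    groups = group_by_similarity(
        slim, graph, corpus,
        sim_threshold=config.sim_threshold, log_base=config.log_base,
    )
    survivors = filter_terms(
        slim, groups,
        z_threshold=config.z_threshold, grs_threshold=config.grs_threshold,
    )
    group_of = {m: g for g in groups for m in g.members}

    scored = []
    for term in sorted(survivors):
        group = group_of[term]
        ts = total_score(
            slim, group, corpus, graph, term, log_base=config.log_base
        )
        if ts < config.ts_threshold:
            continue
        scored.append(
            ScoredAnnotation(
                protein=slim.protein,
                term=term,
                namespace=slim.namespace,
                w=slim.input_weights[term],
                W=slim.W[term],
                InC=internal_confidence(slim, term),
                InC_nc=noncumulative_internal_confidence(slim, term),
                IC=information_content(corpus, graph, term, log_base=config.log_base),
                Z=slim.Z[term],
                group_id=group.id,
                GrS=group.GrS,
                GrS_nc=group.GrS_nc,
                TS=ts,
                is_representative=False,
            )
        )
    # deterministic rank: TS desc, IC desc, term id asc
    scored.sort(key=lambda a: (-a.TS, -a.IC, a.term))
    best_in_group: dict[int, ScoredAnnotation] = {}
    for ann in scored:
        if ann.group_id not in best_in_group:
            best_in_group[ann.group_id] = ann
            ann.is_representative = True
    if config.representatives_only:
        scored = [a for a in scored if a.is_representative]
    return scored


def annotate(
    term_sets: Mapping[str, WeightedTermSet] | Iterable[WeightedTermSet],
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    config: EngineConfig | None = None,
) -> list[ScoredAnnotation]:
    """Run the full engine over per-protein weighted term sets.

    Namespaces are processed independently; output is sorted by protein,
    then TS descending (ties: IC descending, term id ascending).
    """
    cfg = config or EngineConfig()
    if isinstance(term_sets, Mapping):
        term_sets = term_sets.values()
    out: list[ScoredAnnotation] = []
    for wts in sorted(term_sets, key=lambda s: s.protein):
        by_ns: dict[str, dict[str, float]] = {}
        for term, w in wts.weights.items():
            by_ns.setdefault(graph.namespace_of(term), {})[term] = w
        for ns in sorted(by_ns):
            slim = build_goslim(
                by_ns[ns], graph, protein=wts.protein, config=cfg
            )
            out.extend(score_namespace(slim, graph, corpus, cfg))
    return out


OUTPUT_COLUMNS = (
    "protein", "term", "namespace", "TS", "IC", "InC", "InC_nc",
    "Z", "w", "W", "group_id", "GrS", "GrS_nc", "is_representative",
)


def write_annotations(annotations: Iterable[ScoredAnnotation], out: TextIO) -> None:
    """Write scored annotations as a TSV with a header row."""
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(OUTPUT_COLUMNS)
    for a in annotations:
        writer.writerow([
            a.protein, a.term, a.namespace,
            f"{a.TS:.6g}", f"{a.IC:.6g}", f"{a.InC:.6g}", f"{a.InC_nc:.6g}",
            f"{a.Z:.6g}", f"{a.w:.6g}", f"{a.W:.6g}",
            a.group_id, f"{a.GrS:.6g}", f"{a.GrS_nc:.6g}",
            int(a.is_representative),
        ])
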