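"""Deterministic synthetic data: toy ontologies, corpora, hit tables, truths.

Everything the pipeline consumes can be generated here with no downloads:
an OBO ontology (layered random DAG per namespace), a GAF annotation corpus,
BLAST/HMMER hit tables, a Pfam-model term-frequency table and a truth table
for benchmarking.  Generation is driven by a single seeded NumPy generator
per artifact, so equal seeds give byte-identical files.

The benchmark plants true GO terms on target proteins and backs each one
with a strong hit (low e-value) against a databank protein or domain model
annotated with exactly that term; decoy hits point at unrelated terms with
e-values at least ~30 orders of magnitude weaker.  True terms sit at depth
>= 2 with at most two per namespace, each backed by a single evidence
source, decoy terms share no ancestry with the protein's true terms, and
background corpus records avoid true-term branches so planted terms stay
informative.  Under those conditions the default engine thresholds provably
retain every planted term and rank it above every decoy; the "with" variant
additionally puts the target itself in the databank (an exact self-hit at
the e-value floor), mirroring benchmark protocols that either keep or
remove the target from the databank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ontology import ASPECT_TO_NAMESPACE, NAMESPACES, OntologyGraph, parse_obo

NAMESPACE_TO_ASPECT = {ns: a for a, ns in ASPECT_TO_NAMESPACE.items()}


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters; defaults define the standard study conditions."""

    seed: int = 0
    n_terms: int = 30  # per namespace, including the root
    n_layer1: int = 4  # direct children of each root
    max_parents: int = 2
    n_proteins: int = 15
    n_corpus_records: int = 300
    hit_noise: float = 0.2  # decoy fraction of all hits
    signal_evalue_range: tuple[float, float] = (1e-80, 1e-40)
    decoy_evalue_range: tuple[float, float] = (1e-8, 1e-3)
    hmmer_fraction: float = 0.4  # chance a planted term is domain-backed
    max_true_per_namespace: int = 2
    namespaces: tuple[str, ...] = NAMESPACES

    def __post_init__(self):
        if self.n_terms < 1 or self.n_proteins < 1 or self.n_corpus_records < 1:
            raise ValueError("all fixture counts must be positive")
        if not 0.0 <= self.hit_noise < 1.0:
            raise ValueError("hit_noise must be in [0, 1)")


# ---------------------------------------------------------------------------
# Ontology generation
# ---------------------------------------------------------------------------


def make_ontology(spec: FixtureSpec) -> tuple[str, OntologyGraph]:
    """Layered random DAG per namespace, one root each, rendered as OBO text.

    Terms are laid out root, first layer, then the rest; every later term
    draws 1..max_parents parents among earlier non-root terms, so the graph
    is acyclic by construction and every non-root, non-first-layer term has
    depth >= 2.  The OBO text round-trips through :func:`parse_obo`.
    """
    rng = np.random.default_rng([spec.seed, 0])
    stanzas = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{counter:07d}"

    for ns in spec.namespaces:
        root = new_id()
        stanzas.append((root, f"{ns} root", ns, []))
        non_root = []
        n_layer1 = min(spec.n_layer1, spec.n_terms - 1)
        for i in range(n_layer1):
            t = new_id()
            stanzas.append((t, f"{ns} term {i}", ns, [root]))
            non_root.append(t)
        for i in range(spec.n_terms - 1 - n_layer1):
            t = new_id()
            if non_root:
                k = int(rng.integers(1, spec.max_parents + 1))
                k = min(k, len(non_root))
                idx = rng.choice(len(non_root), size=k, replace=False)
                parents = sorted(non_root[j] for j in idx)
            else:
                parents = [root]
            stanzas.append((t, f"{ns} term {n_layer1 + i}", ns, parents))
            non_root.append(t)

    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for term, name, ns, parents in stanzas:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {name}")
        lines.append(f"namespace: {ns}")
        for p in parents:
            lines.append(f"is_a: {p}")
        lines.append("")
    obo_text = "\n".join(lines)
    return obo_text, parse_obo(obo_text)


# ---------------------------------------------------------------------------
# Benchmark generation
# ---------------------------------------------------------------------------


@dataclass
class Benchmark:
    """All generated artifacts of one benchmark, as plain text."""

    spec: FixtureSpec
    mode: str  # "with" | "without"
    obo_text: str
    gaf_text: str
    blast_text: str
    hmmer_text: str
    pfam_text: str
    truth_text: str
    truth: dict[str, set[str]]
    decoys: dict[str, set[str]]
    graph: OntologyGraph = field(repr=False)

    def write_to(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, text in [
            ("ontology.obo", self.obo_text),
            ("corpus.gaf", self.gaf_text),
            ("blast.tsv", self.blast_text),
            ("hmmer.tbl", self.hmmer_text),
            ("pfam_freq.tsv", self.pfam_text),
            ("truth.tsv", self.truth_text),
        ]:
            path = directory / name
            path.write_text(text)
            paths[name] = path
        return paths


def _gaf_row(obj: str, term: str, aspect: str) -> str:
    fields = [
        "SYNT", obj, obj, "", term, "SYNT:0001", "IEA", "", aspect,
        obj, "", "protein", "taxon:0", "20120101", "SYNT", "", "",
    ]
    return "\t".join(fields)


def _blast_row(query: str, subject: str, evalue: float) -> str:
    return (
        f"{query}\t{subject}\t95.0\t200\t10\t0\t1\t200\t1\t200\t"
        f"{evalue:.3g}\t250.0"
    )


def _hmmer_row(model: str, query: str, evalue: float) -> str:
    filler = f"{evalue:.3g} 120.0 0.1 {evalue:.3g} 119.0 0.1 " \
             "1.0 1 1 0 0 1 1 synthetic model"
    return f"{model:<12} -          {query:<12} - {filler}"


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def make_benchmark(
    spec: FixtureSpec,
    graph: OntologyGraph | None = None,
    obo_text: str | None = None,
    *,
    mode: str = "without",
) -> Benchmark:
    """Generate a planted-truth benchmark over a (possibly shared) ontology.

    The "with" and "without" modes share all random draws for the same
    seed; "with" only appends the target itself to the databank, annotated
    with its true terms, plus an exact self-hit at the e-value floor.
    """
    if mode not in ("with", "without"):
        raise ValueError(f"unknown benchmark mode {mode!r}")
    if graph is None or obo_text is None:
        obo_text, graph = make_ontology(spec)
    rng = np.random.default_rng([spec.seed, 1])

    # terms guaranteed to sit at depth >= 2 (see make_ontology layout)
    eligible: dict[str, list[str]] = {}
    for ns in spec.namespaces:
        ns_terms = sorted(graph.terms_in_namespace(ns))
        n_layer1 = min(spec.n_layer1, spec.n_terms - 1)
        eligible[ns] = ns_terms[1 + n_layer1:]

    gaf_rows: list[str] = []
    blast_rows: list[str] = []
    hmmer_rows: list[str] = []
    pfam_rows: list[str] = []
    truth: dict[str, set[str]] = {}
    decoys: dict[str, set[str]] = {}
    databank_idx = 0
    model_idx = 0

    usable_ns = [ns for ns in spec.namespaces if eligible[ns]]
    for i in range(spec.n_proteins):
        protein = f"P{i + 1:04d}"
        truth[protein] = set()
        decoys[protein] = set()
        if not usable_ns:
            continue
        n_ns = int(rng.integers(1, min(2, len(usable_ns)) + 1))
        idx = rng.choice(len(usable_ns), size=n_ns, replace=False)
        chosen_ns = [usable_ns[j] for j in sorted(idx)]
        for ns in chosen_ns:
            pool = eligible[ns]
            m_cap = min(spec.max_true_per_namespace, len(pool))
            m = int(rng.integers(1, m_cap + 1))
            tidx = rng.choice(len(pool), size=m, replace=False)
            terms = [pool[j] for j in sorted(tidx)]
            aspect = NAMESPACE_TO_ASPECT[ns]
            for term in terms:
                truth[protein].add(term)
                evalue = _log_uniform(rng, *spec.signal_evalue_range)
                if rng.random() < spec.hmmer_fraction:
                    model_idx += 1
                    model = f"PF{model_idx:05d}"
                    n_with = int(rng.integers(16, 21))  # frequency 0.8..1.0
                    pfam_rows.append(f"{model}\t{term}\t{n_with}\t20")
                    hmmer_rows.append(_hmmer_row(model, protein, evalue))
                else:
                    databank_idx += 1
                    subject = f"D{databank_idx:05d}"
                    gaf_rows.append(_gaf_row(subject, term, aspect))
                    blast_rows.append(_blast_row(protein, subject, evalue))
            # at most one decoy hit per namespace block, ancestry-disjoint
            # from the block's true terms
            n_true = len(terms)
            p_decoy = min(1.0, spec.hit_noise / (1.0 - spec.hit_noise) * n_true)
            if rng.random() < p_decoy:
                forbidden: set[str] = set()
                for t in terms:
                    forbidden |= graph.ancestors(t)
                    forbidden |= graph.descendants(t)
                decoy_pool = [t for t in pool if t not in forbidden]
                if decoy_pool:
                    decoy = decoy_pool[int(rng.integers(len(decoy_pool)))]
                    decoys[protein].add(decoy)
                    databank_idx += 1
                    subject = f"D{databank_idx:05d}"
                    gaf_rows.append(_gaf_row(subject, decoy, aspect))
                    blast_rows.append(
                        _blast_row(
                            protein, subject,
                            _log_uniform(rng, *spec.decoy_evalue_range),
                        )
                    )

    # background corpus records, kept off every planted branch so planted
    # terms remain rare (informative) in the corpus
    planted_closure: set[str] = set()
    for terms in truth.values():
        for t in terms:
            planted_closure |= graph.descendants(t)
    background_pool = sorted(graph.terms - planted_closure)
    for i in range(spec.n_corpus_records):
        term = background_pool[int(rng.integers(len(background_pool)))]
        aspect = NAMESPACE_TO_ASPECT[graph.namespace_of(term)]
        gaf_rows.append(_gaf_row(f"BG{i + 1:05d}", term, aspect))

    if mode == "with":
        for protein in sorted(truth):
            for term in sorted(truth[protein]):
                aspect = NAMESPACE_TO_ASPECT[graph.namespace_of(term)]
                gaf_rows.append(_gaf_row(protein, term, aspect))
            blast_rows.append(_blast_row(protein, protein, 0.0))

    truth_rows = [
        f"{p}\t{t}" for p in sorted(truth) for t in sorted(truth[p])
    ]
    gaf_text = "!gaf-version: 2.1\n" + "\n".join(gaf_rows) + "\n"
    hmmer_header = (
        "#                                                               "
        "--- full sequence ---\n"
        "# target name        accession  query name           accession  "
        "  E-value  score  bias\n"
    )
    return Benchmark(
        spec=spec,
        mode=mode,
        obo_text=obo_text,
        gaf_text=gaf_text,
        blast_text="\n".join(blast_rows) + ("\n" if blast_rows else ""),
        hmmer_text=hmmer_header + "\n".join(hmmer_rows)
        + ("\n" if hmmer_rows else ""),
        pfam_text="\n".join(pfam_rows) + ("\n" if pfam_rows else ""),
        truth_text="\n".join(truth_rows) + ("\n" if truth_rows else ""),
        truth=truth,
        decoys=decoys,
        graph=graph,
    )
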