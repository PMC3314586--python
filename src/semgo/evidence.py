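"""Turn BLAST/HMMER hit tables into per-protein weighted GO-term sets.

A BLAST hit against an annotated database protein transfers that protein's
GO terms to the query with weight

    w = -log10(evalue)                                  (sequence evidence)

while a HMMER hit against a Pfam-like model transfers the model's GO terms
with the frequency-damped weight

    w = -log10(evalue) * f(n_with_term / n_total)       (domain evidence)

where f is a logistic curve rewarding terms frequent among the model's
member proteins and penalising sparse, likely spurious ones.  Contributions
from several hits to the same (protein, term) pair are summed by default.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)


class HitParseError(ValueError):
    """Raised for malformed rows in hit tables, naming the line."""


class WeightError(ValueError):
    """Raised for invalid weighting inputs (bad e-values, frequencies)."""


#: E-values of 0.0 reported by search tools are clamped here before taking
#: the log, capping a single hit's weight at 180.
DEFAULT_EVALUE_FLOOR = 1e-180
#: Hits weaker than this e-value are dropped on parse.
DEFAULT_EVALUE_CEILING = 1e-3

_GO_ID_RE = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class Hit:
    """One search hit: query protein vs database subject at some e-value."""

    query: str
    subject: str
    evalue: float
    source: str  # "blast" | "hmmer"

    def __post_init__(self):
        if not self.query or not self.subject:
            raise WeightError("hit query and subject must be non-empty")
        if self.evalue < 0:
            raise WeightError(f"negative e-value {self.evalue}")
        if self.source not in ("blast", "hmmer"):
            raise WeightError(f"unknown hit source {self.source!r}")


@dataclass(frozen=True)
class PfamTermFrequency:
    """How often a GO term occurs among the proteins of one Pfam-like model."""

    model: str
    term: str
    n_with_term: int
    n_total: int

    def __post_init__(self):
        if self.n_total <= 0:
            raise WeightError(f"model {self.model}: n_total must be positive")
        if not 0 <= self.n_with_term <= self.n_total:
            raise WeightError(
                f"model {self.model}: n_with_term {self.n_with_term} outside "
                f"[0, {self.n_total}]"
            )

    @property
    def frequency(self) -> float:
        return self.n_with_term / self.n_total


class PfamFrequencyTable:
    """Model -> [(term, frequency record)] lookup built from a TSV."""

    def __init__(self, entries: Iterable[PfamTermFrequency] = ()):
        self._by_model: dict[str, dict[str, PfamTermFrequency]] = {}
        for e in entries:
            self._by_model.setdefault(e.model, {})[e.term] = e

    def __contains__(self, model: str) -> bool:
        return model in self._by_model

    def terms_for(self, model: str) -> dict[str, PfamTermFrequency]:
        return self._by_model.get(model, {})

    @classmethod
    def from_tsv(cls, source: TextIO | str) -> "PfamFrequencyTable":
        """Read a (model, GO id, n_with_term, n_total) TSV."""
        if isinstance(source, str):
            source = io.StringIO(source)
        entries = []
        for lineno, raw in enumerate(source, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.split()
            if len(fields) != 4:
                raise HitParseError(
                    f"line {lineno}: expected 4 columns, got {len(fields)}"
                )
            model, term, n_with, n_total = fields
            if not _GO_ID_RE.match(term):
                raise HitParseError(f"line {lineno}: malformed GO id {term!r}")
            try:
                entries.append(
                    PfamTermFrequency(model, term, int(n_with), int(n_total))
                )
            except (ValueError, WeightError) as exc:
                raise HitParseError(f"line {lineno}: {exc}") from exc
        return cls(entries)


@dataclass
class WeightedTermSet:
    """Per-protein weighted GO terms: the input to the scoring engine."""

    protein: str
    weights: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, list[Hit]] = field(default_factory=dict)

    def add(
        self,
        term: str,
        weight: float,
        hit: Hit | None = None,
        *,
        aggregation: str = "sum",
    ) -> None:
        if weight <= 0:
            raise WeightError(f"non-positive weight {weight} for term {term}")
        if aggregation == "sum":
            self.weights[term] = self.weights.get(term, 0.0) + weight
        elif aggregation == "max":
            self.weights[term] = max(self.weights.get(term, 0.0), weight)
        else:
            raise WeightError(f"unknown aggregation {aggregation!r}")
        if hit is not None:
            self.provenance.setdefault(term, []).append(hit)

    @property
    def total_weight(self) -> float:
        return sum(self.weights.values())

    def __len__(self) -> int:
        return len(self.weights)


# ---------------------------------------------------------------------------
# Hit-table parsers
# ---------------------------------------------------------------------------


def _subject_accession(raw: str) -> str:
    """Extract the accession from UniProt-style 'sp|P12345|NAME' subjects."""
    if "|" in raw:
        parts = raw.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return raw


def parse_blast_tabular(
    source: TextIO | str,
    *,
    evalue_ceiling: float = DEFAULT_EVALUE_CEILING,
) -> list[Hit]:
    """Parse BLAST tabular output (outfmt 6, >= 12 columns) into hits.

    A minimal 3-column dialect (query, subject, evalue) is accepted as well.
    Rows with e-value above ``evalue_ceiling`` are dropped.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    hits = []
    for lineno, raw in enumerate(source, start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split()
        if len(fields) >= 12:
            query, subject, ev_field = fields[0], fields[1], fields[10]
        elif len(fields) == 3:
            query, subject, ev_field = fields
        else:
            raise HitParseError(
                f"line {lineno}: expected 3 or >=12 columns, got {len(fields)}"
            )
        try:
            evalue = float(ev_field)
        except ValueError as exc:
            raise HitParseError(
                f"line {lineno}: non-numeric e-value {ev_field!r}"
            ) from exc
        if evalue > evalue_ceiling:
            continue
        hits.append(Hit(query, _subject_accession(subject), evalue, "blast"))
    return hits


def parse_hmmer_tabular(
    source: TextIO | str,
    *,
    evalue_ceiling: float = DEFAULT_EVALUE_CEILING,
) -> list[Hit]:
    """Parse HMMER tblout (hmmscan orientation: target = model, query = protein).

    Uses the full-sequence e-value (column 5); the model accession (column 2)
    is preferred over the model name when present.  Duplicate (query, model)
    rows keep the smallest e-value.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    best: dict[tuple[str, str], float] = {}
    for lineno, raw in enumerate(source, start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split()
        if len(fields) < 5:
            raise HitParseError(
                f"line {lineno}: expected >=5 columns, got {len(fields)}"
            )
        target_name, target_acc, query = fields[0], fields[1], fields[2]
        model = target_acc if target_acc != "-" else target_name
        # Pfam accessions carry a version suffix (PF00001.21)
        model = model.split(".")[0]
        try:
            evalue = float(fields[4])
        except ValueError as exc:
            raise HitParseError(
                f"line {lineno}: non-numeric e-value {fields[4]!r}"
            ) from exc
        if evalue > evalue_ceiling:
            continue
        key = (query, model)
        if key not in best or evalue < best[key]:
            best[key] = evalue
    return [Hit(q, m, ev, "hmmer") for (q, m), ev in best.items()]


def parse_weighted_terms(source: TextIO | str) -> dict[str, WeightedTermSet]:
    """Parse a consensus TSV (protein, GO id, weight) into weighted term sets.

    Duplicate (protein, term) rows are summed; non-positive weights and
    malformed GO ids are row-level errors.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    out: dict[str, WeightedTermSet] = {}
    for lineno, raw in enumerate(source, start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split()
        if len(fields) != 3:
            raise HitParseError(
                f"line {lineno}: expected 3 columns, got {len(fields)}"
            )
        protein, term, w_field = fields
        if not _GO_ID_RE.match(term):
            raise HitParseError(f"line {lineno}: malformed GO id {term!r}")
        try:
            weight = float(w_field)
        except ValueError as exc:
            raise HitParseError(
                f"line {lineno}: non-numeric weight {w_field!r}"
            ) from exc
        if weight <= 0:
            raise HitParseError(f"line {lineno}: non-positive weight {weight}")
        out.setdefault(protein, WeightedTermSet(protein)).add(term, weight)
    return out


# ---------------------------------------------------------------------------
# Weighting
# ---------------------------------------------------------------------------


def blast_weight(
    evalue: float,
    *,
    evalue_floor: float = DEFAULT_EVALUE_FLOOR,
) -> float:
    """Weight of a sequence-similarity hit: -log10(evalue), floored."""
    ev = max(evalue, evalue_floor)
    if ev <= 0:
        raise WeightError(f"e-value {evalue} not positive after flooring")
    return -math.log10(ev)


def logistic_reward(
    freq: float,
    *,
    steepness: float = 10.0,
    midpoint: float = 0.5,
) -> float:
    """Logistic curve 1/(1+exp(-steepness*(freq-midpoint))) on [0, 1]."""
    if not 0.0 <= freq <= 1.0:
        raise WeightError(f"frequency {freq} outside [0, 1]")
    return 1.0 / (1.0 + math.exp(-steepness * (freq - midpoint)))


def hmmer_weight(
    evalue: float,
    ptf: PfamTermFrequency,
    *,
    evalue_floor: float = DEFAULT_EVALUE_FLOOR,
    steepness: float = 10.0,
    midpoint: float = 0.5,
) -> float:
    """Weight of a domain hit: -log10(evalue) * logistic(term frequency)."""
    return blast_weight(evalue, evalue_floor=evalue_floor) * logistic_reward(
        ptf.frequency, steepness=steepness, midpoint=midpoint
    )


@dataclass
class WeightingConfig:
    """Knobs of the evidence-weighting stage."""

    evalue_floor: float = DEFAULT_EVALUE_FLOOR
    evalue_ceiling: float = DEFAULT_EVALUE_CEILING
    logistic_steepness: float = 10.0
    logistic_midpoint: float = 0.5
    aggregation: str = "sum"  # "sum" | "max"
    exclude_self_hits: bool = False


def map_and_merge(
    hits: Iterable[Hit],
    protein_terms: Mapping[str, set[str]],
    ptf_table: PfamFrequencyTable,
    graph: OntologyGraph,
    config: WeightingConfig | None = None,
) -> dict[str, WeightedTermSet]:
    """Transfer GO terms from hit subjects to queries with summed weights.

    BLAST subjects are looked up in ``protein_terms`` (a GAF-derived object
    -> terms map); HMMER subjects in the Pfam frequency table.  Unresolvable
    subjects and terms missing from the ontology are skipped with a warning.
    """
    cfg = config or WeightingConfig()
    out: dict[str, WeightedTermSet] = {}
    # sort for order-independent output regardless of hit-list permutation
    for hit in sorted(hits, key=lambda h: (h.query, h.source, h.subject, h.evalue)):
        if cfg.exclude_self_hits and hit.subject == hit.query:
            continue
        contributions: list[tuple[str, float]] = []
        if hit.source == "blast":
            terms = protein_terms.get(hit.subject)
            if terms is None:
                logger.warning(
                    "BLAST subject %s has no GO annotation; hit skipped",
                    hit.subject,
                )
                continue
            w = blast_weight(hit.evalue, evalue_floor=cfg.evalue_floor)
            contributions = [(t, w) for t in sorted(terms)]
        else:
            if hit.subject not in ptf_table:
                logger.warning(
                    "HMMER model %s absent from frequency table; hit skipped",
                    hit.subject,
                )
                continue
            for term, ptf in sorted(ptf_table.terms_for(hit.subject).items()):
                w = hmmer_weight(
                    hit.evalue,
                    ptf,
                    evalue_floor=cfg.evalue_floor,
                    steepness=cfg.logistic_steepness,
                    midpoint=cfg.logistic_midpoint,
                )
                if w > 0:
                    contributions.append((term, w))
        wts = out.setdefault(hit.query, WeightedTermSet(hit.query))
        for term, w in contributions:
            if term not in graph:
                logger.warning(
                    "term %s not in ontology; contribution dropped", term
                )
                continue
            wts.add(graph.resolve(term), w, hit, aggregation=cfg.aggregation)
    return {p: wts for p, wts in out.items() if len(wts)}
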