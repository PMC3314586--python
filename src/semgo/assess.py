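"""Protein-centric precision/recall benchmarking with sliding score threshold.

For each target protein the predicted terms with score strictly above a
threshold t are compared against the benchmark (true) terms:

    PR_p(t) = TP / (TP + FP)        RC_p(t) = TP / (TP + FN)

Two matching protocols are provided.  Method m1 compares the term sets as
given (exact matches only).  Method m2 first propagates both sets to the
namespace root, so a prediction that is merely an ancestor or close relative
of a true term earns partial credit through the shared path — closely
related rather than completely wrong.  Precision is averaged only over
proteins that have at least one prediction at t ("if a protein has no
annotated term, its precision is not calculated"); recall is averaged over
the whole pool, so unannotated proteins still count their false negatives.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

from .engine import ScoredAnnotation
from .ontology import OntologyGraph, parse_gaf


class AssessError(ValueError):
    pass


@dataclass
class BenchmarkRecord:
    """One protein's true terms and scored predictions."""

    protein: str
    true_terms: frozenset[str]
    predicted: tuple[tuple[str, float], ...]

    def predicted_above(self, t: float) -> set[str]:
        return {term for term, score in self.predicted if score > t}

    @property
    def max_score(self) -> float:
        return max((s for _, s in self.predicted), default=0.0)


@dataclass
class PRCurve:
    """Averaged precision/recall at each threshold of an ascending grid."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    n_scored: np.ndarray  # proteins with >=1 prediction at each threshold

    def write_tsv(self, out: TextIO) -> None:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(["threshold", "precision", "recall", "n_scored"])
        for t, p, r, n in zip(
            self.thresholds, self.precision, self.recall, self.n_scored
        ):
            writer.writerow([f"{t:.6g}", f"{p:.6g}", f"{r:.6g}", int(n)])


def _propagate(terms: Iterable[str], graph: OntologyGraph, include_roots: bool) -> set[str]:
    out: set[str] = set()
    for t in terms:
        out |= graph.ancestors(t)
    if not include_roots:
        out -= set(graph.roots.values())
    return out


def confusion_at_threshold(
    record: BenchmarkRecord,
    t: float,
    mode: str,
    graph: OntologyGraph | None = None,
    *,
    include_roots: bool = True,
) -> tuple[int, int, int]:
    """(TP, FP, FN) for one protein at score threshold t (strict >).

    Mode "m1" compares term sets exactly; "m2" replaces both the predicted
    and the true set by the union of their ancestor closures before the set
    arithmetic, giving partial credit along shared root paths.
    """
    if mode not in ("m1", "m2"):
        raise AssessError(f"unknown assessment mode {mode!r}")
    predicted = record.predicted_above(t)
    true = set(record.true_terms)
    if mode == "m2":
        if graph is None:
            raise AssessError("mode m2 requires the ontology graph")
        predicted = _propagate(predicted, graph, include_roots)
        true = _propagate(true, graph, include_roots)
    tp = len(predicted & true)
    fp = len(predicted - true)
    fn = len(true - predicted)
    return tp, fp, fn


def pr_curve(
    records: Sequence[BenchmarkRecord],
    mode: str,
    graph: OntologyGraph | None = None,
    *,
    n_points: int = 100,
    include_roots: bool = True,
) -> PRCurve:
    """Sweep thresholds from 0 to the maximum observed score.

    Precision at t averages over proteins with at least one prediction
    above t; recall averages over all proteins in the pool.
    """
    if not records:
        raise AssessError("no benchmark records")
    t_max = max(r.max_score for r in records)
    thresholds = np.linspace(0.0, t_max, n_points)
    precision = np.zeros(n_points)
    recall = np.zeros(n_points)
    n_scored = np.zeros(n_points, dtype=int)
    for i, t in enumerate(thresholds):
        pr_vals = []
        rc_vals = []
        for rec in records:
            tp, fp, fn = confusion_at_threshold(
                rec, t, mode, graph, include_roots=include_roots
            )
            if tp + fp > 0:
                pr_vals.append(tp / (tp + fp))
            rc_vals.append(tp / (tp + fn) if tp + fn > 0 else 0.0)
        precision[i] = float(np.mean(pr_vals)) if pr_vals else 0.0
        recall[i] = float(np.mean(rc_vals))
        n_scored[i] = len(pr_vals)
    return PRCurve(thresholds, precision, recall, n_scored)


def records_by_namespace(
    records: Sequence[BenchmarkRecord],
    graph: OntologyGraph,
    namespace: str | None,
) -> list[BenchmarkRecord]:
    """Restrict records to one namespace (``None`` pools all three).

    Proteins left with no true terms in the namespace are dropped, since
    they cannot contribute to recall averaging.
    """
    if namespace is None:
        return [r for r in records if r.true_terms]
    out = []
    for r in records:
        true = frozenset(
            t for t in r.true_terms if graph.namespace_of(t) == namespace
        )
        pred = tuple(
            (t, s) for t, s in r.predicted if graph.namespace_of(t) == namespace
        )
        if true:
            out.append(BenchmarkRecord(r.protein, true, pred))
    return out


# ---------------------------------------------------------------------------
# Record construction from files / engine output
# ---------------------------------------------------------------------------


def records_from_annotations(
    annotations: Iterable[ScoredAnnotation],
    truth: dict[str, set[str]],
) -> list[BenchmarkRecord]:
    """Pair engine output with a truth table (protein -> true terms)."""
    preds: dict[str, list[tuple[str, float]]] = {p: [] for p in truth}
    for a in annotations:
        if a.protein in preds:
            preds[a.protein].append((a.term, a.TS))
    return [
        BenchmarkRecord(p, frozenset(truth[p]), tuple(preds[p]))
        for p in sorted(truth)
        if truth[p]
    ]


def parse_predictions_tsv(source: TextIO | str) -> dict[str, list[tuple[str, float]]]:
    """Read a (protein, GO id, score) TSV of predictions."""
    if isinstance(source, str):
        source = io.StringIO(source)
    out: dict[str, list[tuple[str, float]]] = {}
    for lineno, raw in enumerate(source, start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split()
        if len(fields) != 3:
            raise AssessError(
                f"line {lineno}: expected 3 columns, got {len(fields)}"
            )
        protein, term, score_field = fields
        try:
            score = float(score_field)
        except ValueError as exc:
            raise AssessError(
                f"line {lineno}: non-numeric score {score_field!r}"
            ) from exc
        if score < 0:
            raise AssessError(f"line {lineno}: negative score {score}")
        out.setdefault(protein, []).append((term, score))
    return out


def parse_truth(source: TextIO | str) -> dict[str, set[str]]:
    """Read true terms from a 2-column TSV (protein, GO id) or a GAF."""
    if not isinstance(source, str):
        source = source.read()
    first_data = next(
        (l for l in source.splitlines() if l.strip() and not l.startswith("!")),
        "",
    )
    out: dict[str, set[str]] = {}
    if len(first_data.split("\t")) >= 9:
        for rec in parse_gaf(source):
            out.setdefault(rec.object_id, set()).add(rec.go_id)
        return out
    for lineno, raw in enumerate(source.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split()
        if len(fields) != 2:
            raise AssessError(
                f"line {lineno}: expected 2 columns, got {len(fields)}"
            )
        out.setdefault(fields[0], set()).add(fields[1])
    return out


def build_records(
    predictions: dict[str, list[tuple[str, float]]],
    truth: dict[str, set[str]],
) -> list[BenchmarkRecord]:
    return [
        BenchmarkRecord(
            p, frozenset(truth[p]), tuple(predictions.get(p, []))
        )
        for p in sorted(truth)
        if truth[p]
    ]
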