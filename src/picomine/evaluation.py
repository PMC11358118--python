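"""Entity-level scoring: precision/recall/F1, strict and relaxed span
matching, per-element reports, and Cohen's kappa for annotation QC.

Strict matching requires identical (element, start, end).  Relaxed matching
tolerates boundary redundancy — trailing or leading characters around the
gold mention that do not change its reading: a prediction counts if it
*contains* the gold interval and its surplus length stays within a
tolerance, ``max(tol_abs, tol_frac * len(gold))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Document, EntitySpan, TagSchema


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Counts and P/R/F1
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN tallies.  TN is unused by entity-level PRF but kept so a
    full 2x2 prediction table can be represented."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass
class PrfScores:
    precision: float
    recall: float
    f1: float
    #: set when a zero denominator forced a score to 0
    degenerate: bool = False


def compute_prf(counts: ConfusionCounts) -> PrfScores:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); zero denominators
    yield 0 with the degenerate flag raised."""
    degenerate = False
    if counts.tp + counts.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0.0:
        return PrfScores(precision, recall, 0.0, True)
    f1 = 2 * precision * recall / (precision + recall)
    return PrfScores(precision, recall, f1, degenerate)


# ---------------------------------------------------------------------------
# Span matching
# ---------------------------------------------------------------------------


@dataclass
class MatchConfig:
    """Matching mode and the relaxed-mode redundancy tolerances (characters)."""

    mode: str = "strict"
    tol_abs: int = 10
    tol_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "relaxed"):
            raise EvaluationError(f"mode must be strict or relaxed, got {self.mode!r}")
        if self.tol_abs < 0 or self.tol_frac < 0:
            raise EvaluationError("tolerances must be non-negative")


def _spans_match(gold: EntitySpan, pred: EntitySpan, config: MatchConfig) -> bool:
    if gold.element != pred.element:
        return False
    if config.mode == "strict":
        return gold.start == pred.start and gold.end == pred.end
    if not (pred.start <= gold.start and gold.end <= pred.end):
        return False
    surplus = (pred.end - pred.start) - (gold.end - gold.start)
    return surplus <= max(config.tol_abs, config.tol_frac * (gold.end - gold.start))


def match_spans(
    gold: list[EntitySpan], pred: list[EntitySpan], config: MatchConfig
) -> ConfusionCounts:
    """Greedy one-to-one matching in document order.

    Each gold span, taken left to right, pairs with the first unused matching
    prediction.  Matched pairs are TP, leftover predictions FP, leftover gold
    FN.
    """
    used = [False] * len(pred)
    pred_ordered = sorted(range(len(pred)), key=lambda i: (pred[i].start, pred[i].end))
    tp = 0
    for g in sorted(gold, key=lambda s: (s.start, s.end)):
        for i in pred_ordered:
            if not used[i] and _spans_match(g, pred[i], config):
                used[i] = True
                tp += 1
                break
    return ConfusionCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


# ---------------------------------------------------------------------------
# Corpus-level evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    per_element: dict[str, PrfScores]
    micro: PrfScores
    counts: dict[str, ConfusionCounts]
    mode: str

    def as_dict(self) -> dict:
        def prf(s: PrfScores) -> dict:
            return {"precision": s.precision, "recall": s.recall, "f1": s.f1,
                    "degenerate": s.degenerate}

        return {
            "mode": self.mode,
            "micro": prf(self.micro),
            "per_element": {e: prf(s) for e, s in self.per_element.items()},
            "counts": {
                e: {"tp": c.tp, "fp": c.fp, "fn": c.fn}
                for e, c in self.counts.items()
            },
        }

    def render(self) -> str:
        """Aligned text table: one row per element plus the micro average."""
        rows = [f"{'element':<16} {'P':>7} {'R':>7} {'F1':>7}   TP   FP   FN"]
        for elem, s in self.per_element.items():
            c = self.counts[elem]
            rows.append(
                f"{elem:<16} {s.precision:7.3f} {s.recall:7.3f} {s.f1:7.3f} "
                f"{c.tp:4d} {c.fp:4d} {c.fn:4d}"
            )
        s = self.micro
        rows.append(f"{'micro':<16} {s.precision:7.3f} {s.recall:7.3f} {s.f1:7.3f}")
        return "\n".join(rows)


def evaluate_extraction(
    gold_docs: list[Document],
    pred_spans: dict[str, list[EntitySpan]],
    config: MatchConfig,
    schema: TagSchema,
) -> EvaluationReport:
    """Score predicted spans against gold annotations, per element and pooled.

    ``pred_spans`` maps doc_id to predicted evidence spans in document
    coordinates; a list of pipeline records (anything with ``doc_id`` and a
    ``spans()`` method) is also accepted and reduced to its coarse mention
    spans.  The micro average pools TP/FP/FN across all elements and
    documents.
    """
    if isinstance(pred_spans, list):
        pred_spans = {r.doc_id: r.spans() for r in pred_spans}
    gold_ids = {d.doc_id for d in gold_docs}
    missing = set(pred_spans) - gold_ids
    if missing:
        raise EvaluationError(f"predictions for unknown doc ids: {sorted(missing)}")

    elements = [e for e in schema.element_of.values() if e is not None]
    element_order = list(dict.fromkeys(elements))
    counts = {e: ConfusionCounts() for e in element_order}
    for doc in gold_docs:
        gold = doc.gold_spans(schema)
        pred = pred_spans.get(doc.doc_id, [])
        for elem in element_order:
            g = [s for s in gold if s.element == elem]
            p = [s for s in pred if s.element == elem]
            counts[elem] = counts[elem] + match_spans(g, p, config)

    micro = ConfusionCounts()
    for c in counts.values():
        micro = micro + c
    return EvaluationReport(
        per_element={e: compute_prf(c) for e, c in counts.items()},
        micro=compute_prf(micro),
        counts=counts,
        mode=config.mode,
    )


# ---------------------------------------------------------------------------
# Inter-annotator agreement
# ---------------------------------------------------------------------------


@dataclass
class KappaResult:
    observed_agreement: float
    expected_agreement: float
    kappa: float
    #: chance agreement is 1 and observed agreement is not: kappa undefined
    degenerate: bool = False


def cohens_kappa(table) -> KappaResult:
    """Cohen's kappa for two raters from a 2x2 (or KxK) contingency table.

    ``table[i][j]`` counts items rater A put in class i and rater B in class
    j.  kappa = (p_o - p_e) / (1 - p_e) with p_o the diagonal mass and p_e
    the chance agreement implied by the marginals.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise EvaluationError("contingency table must be square")
    if (t < 0).any():
        raise EvaluationError("contingency counts must be non-negative")
    total = t.sum()
    if total == 0:
        raise EvaluationError("contingency table is empty")
    p_o = np.trace(t) / total
    p_e = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / total**2
    if p_e == 1.0:
        # all mass in one class for both raters
        if p_o == 1.0:
            return KappaResult(p_o, p_e, 1.0)
        return KappaResult(p_o, p_e, float("nan"), degenerate=True)
    return KappaResult(float(p_o), float(p_e), float((p_o - p_e) / (1 - p_e)))


def qc_sample_size(n_items: int, fraction: float = 0.1) -> int:
    """Size of the random sample drawn for annotation quality control
    (e.g. 10% of 24,244 labeled items -> 2,424)."""
    if n_items < 0 or not (0.0 < fraction <= 1.0):
        raise EvaluationError("need n_items >= 0 and fraction in (0, 1]")
    return int(round(n_items * fraction))


def _truncate2(x: float) -> float:
    # percentages are truncated, not rounded, to two decimals — the
    # convention consistency reports in this literature use when quoting
    # cell proportions (72.0297% is quoted as 72.02%)
    return np.floor(x * 100 + 1e-9) / 100


def agreement_proportions(table) -> tuple[float, float]:
    """Percent of items both raters called accurate / both called ambiguous,
    for a 2x2 table ordered (accurate, ambiguous); truncated to 2 decimals."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise EvaluationError("agreement proportions need a 2x2 table")
    total = t.sum()
    if total == 0:
        raise EvaluationError("contingency table is empty")
    return (float(_truncate2(t[0, 0] / total * 100)),
            float(_truncate2(t[1, 1] / total * 100)))
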