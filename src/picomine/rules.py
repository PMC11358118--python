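"""The PATTERN rule-set layer: regex refinement of coarse evidence spans.

A rule set is an ordered family ``PATTERN = {Pattern1, Pattern2, ...}`` of
element-keyed regular expressions.  Each rule carries an *action*:

``match``
    keep the matched value (the named group ``v`` if the pattern declares
    one, else the whole match);
``judge``
    a boolean gate: a candidate span must satisfy the pattern or it is
    vetoed (dropped) — judges never produce values;
``split``
    emit one value per named capture group, e.g. separating treatment-arm
    and control-arm counts from one sentence.

In the hybrid pipeline the labeler's spans are computed first and each span
is handed to the rules of its element in priority order; the first matching
match/split rule wins.  A span no rule matches passes through unchanged with
``rule_id="fallback"`` — boundary redundancy does not make a mention
useless, so unmatched spans are kept rather than discarded.  The rule-only
baseline instead scans every sentence of the raw text with every rule,
which is cheap but over-matches (no model anchoring) and misses phrasings
outside the pattern inventory.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources

from .corpus import (
    Document,
    ElementRegistry,
    EntitySpan,
    default_registry,
    split_sentences,
)


class RuleError(ValueError):
    pass


ACTIONS = ("match", "judge", "split")


# ---------------------------------------------------------------------------
# Rule set
# ---------------------------------------------------------------------------


@dataclass
class RulePattern:
    rule_id: str
    element: str
    pattern: str
    action: str
    priority: int = 0

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise RuleError(
                f"rule {self.rule_id!r}: action must be one of {ACTIONS}, "
                f"got {self.action!r}"
            )
        try:
            self.compiled = re.compile(self.pattern)
        except re.error as exc:
            raise RuleError(
                f"rule {self.rule_id!r}: pattern does not compile: {exc}"
            ) from exc
        if self.action == "split" and not self.compiled.groupindex:
            raise RuleError(
                f"rule {self.rule_id!r}: split rules need at least one named group"
            )


@dataclass
class RuleSet:
    rules: list[RulePattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise RuleError(f"duplicate rule ids: {sorted(dupes)}")
        self.rules = sorted(self.rules, key=lambda r: (r.element, r.priority,
                                                       r.rule_id))
        self._by_element: dict[str, list[RulePattern]] = {}
        for r in self.rules:
            self._by_element.setdefault(r.element, []).append(r)

    def __len__(self) -> int:
        return len(self.rules)

    def for_element(self, element: str) -> list[RulePattern]:
        return self._by_element.get(element, [])

    def validate_registry(self, registry: ElementRegistry) -> None:
        for r in self.rules:
            if r.element not in registry:
                raise RuleError(
                    f"rule {r.rule_id!r} targets unknown element {r.element!r}"
                )


def compile_ruleset(path, registry: ElementRegistry | None = None) -> RuleSet:
    """Load a JSON rule file: an array of
    {"rule_id", "element", "pattern", "action", "priority"} objects."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    ruleset = RuleSet([RulePattern(
        rule_id=r["rule_id"], element=r["element"], pattern=r["pattern"],
        action=r["action"], priority=int(r.get("priority", 0))) for r in raw])
    if registry is not None:
        ruleset.validate_registry(registry)
    return ruleset


def starter_ruleset(registry: ElementRegistry | None = None) -> RuleSet:
    """The packaged starter rules, co-designed with the synthetic templates."""
    ref = resources.files("picomine.data") / "starter_rules.json"
    with resources.as_file(ref) as path:
        return compile_ruleset(path, registry or default_registry())


# ---------------------------------------------------------------------------
# Numeric parsing (D-level values)
# ---------------------------------------------------------------------------

_CN_DIGITS = {"〇": 0, "一": 1, "二": 2, "三": 3, "四": 4,
              "五": 5, "六": 6, "七": 7, "八": 8, "九": 9}


def parse_numeric(value: str):
    """Parse Arabic digits or simple Chinese numerals; None when unparseable.

    Chinese support covers the additive-positional forms up to the hundreds
    (〇一二三四五六七八九十百), e.g. 六十 -> 60, 一百二十 -> 120.  Mixed or
    vague expressions (约百余) yield None; this function never raises.
    """
    s = value.strip()
    if not s:
        return None
    if re.fullmatch(r"[0-9]+", s):
        return int(s)
    if re.fullmatch(r"[0-9]+\.[0-9]+", s):
        return float(s)
    if not re.fullmatch(r"[〇一二三四五六七八九十百]+", s):
        return None
    return _parse_cn(s)


def _parse_cn(s: str):
    total = 0
    current = 0
    seen_unit = False
    for ch in s:
        if ch in _CN_DIGITS:
            if current:
                return None  # two digits in a row (e.g. 三五) is not a number
            current = _CN_DIGITS[ch]
        elif ch == "十":
            current = 1 if current == 0 else current
            total += current * 10
            current = 0
            seen_unit = True
        elif ch == "百":
            if current == 0:
                return None  # bare 百 / 约百余 style
            total += current * 100
            current = 0
            seen_unit = True
    total += current
    if not seen_unit and len(s) > 1:
        # digit runs like 一二三 are enumerations, not numbers
        return None
    return total if total > 0 or s == "〇" else None


# ---------------------------------------------------------------------------
# Refined values and records
# ---------------------------------------------------------------------------


@dataclass
class RefinedValue:
    """A fine-grained evidence value extracted from (or passed through) a
    coarse span.  ``numeric`` is filled for D-level elements when the value
    parses; ``start``/``end`` locate the value in document coordinates."""

    element: str
    raw_span: EntitySpan
    value: str
    start: int
    end: int
    numeric: float | int | None = None
    rule_id: str = "fallback"

    def as_dict(self) -> dict:
        return {"value": self.value, "numeric": self.numeric,
                "start": self.start, "end": self.end, "rule_id": self.rule_id,
                "raw_start": self.raw_span.start, "raw_end": self.raw_span.end}


@dataclass
class PicosRecord:
    """Structured per-document output: element id -> refined values."""

    doc_id: str
    elements: dict[str, list[RefinedValue]] = field(default_factory=dict)
    provenance: str = "model+rules"

    def add(self, value: RefinedValue) -> None:
        self.elements.setdefault(value.element, []).append(value)

    def spans(self) -> list[EntitySpan]:
        """The coarse mention spans, deduplicated (split rules emit several
        values from one raw span).  This is what span-level evaluation uses."""
        seen: set[tuple[str, int, int]] = set()
        out: list[EntitySpan] = []
        for values in self.elements.values():
            for v in values:
                key = (v.raw_span.element, v.raw_span.start, v.raw_span.end)
                if key not in seen:
                    seen.add(key)
                    out.append(v.raw_span)
        return out

    def as_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "provenance": self.provenance,
            "elements": {e: [v.as_dict() for v in vs]
                         for e, vs in sorted(self.elements.items())},
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), ensure_ascii=False, sort_keys=True)


def write_records(records: list[PicosRecord], path) -> None:
    """One JSON object per line, one line per document."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_record_spans(path) -> dict[str, list[EntitySpan]]:
    """Load the coarse spans back from a record file, keyed by doc id."""
    out: dict[str, list[EntitySpan]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            spans = []
            seen = set()
            for elem, values in obj["elements"].items():
                for v in values:
                    raw = v.get("raw_start", v["start"]), v.get("raw_end", v["end"])
                    key = (elem, *raw)
                    if key not in seen:
                        seen.add(key)
                        spans.append(EntitySpan(elem, raw[0], raw[1]))
            out[obj["doc_id"]] = spans
    return out


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------


def _make_value(element: str, span_or_none, level: str, value: str,
                start: int, end: int, rule_id: str) -> RefinedValue:
    numeric = parse_numeric(value) if level == "D" else None
    return RefinedValue(element=element, raw_span=span_or_none, value=value,
                        start=start, end=end, numeric=numeric, rule_id=rule_id)


def apply_rules_to_span(
    span: EntitySpan, ruleset: RuleSet, registry: ElementRegistry | None = None
) -> list[RefinedValue]:
    """Refine one coarse span with its element's rules.

    Rules run in (priority, rule_id) order.  Judge rules gate: the span text
    must satisfy them or the span is vetoed and nothing is emitted.  The
    first matching match/split rule produces the refined value(s).  If no
    producing rule matches, the raw span passes through as a fallback value.
    """
    registry = registry or default_registry()
    level = registry.level_of(span.element)
    text = span.text
    for rule in ruleset.for_element(span.element):
        if rule.action == "judge":
            if not rule.compiled.search(text):
                return []  # vetoed
            continue
        m = rule.compiled.search(text)
        if m is None:
            continue
        if rule.action == "match":
            grp = "v" if "v" in rule.compiled.groupindex else 0
            return [_make_value(span.element, span, level, m.group(grp),
                                span.start + m.start(grp), span.start + m.end(grp),
                                rule.rule_id)]
        values = []
        for name in rule.compiled.groupindex:
            if m.group(name) is None:
                continue
            values.append(_make_value(span.element, span, level, m.group(name),
                                      span.start + m.start(name),
                                      span.start + m.end(name), rule.rule_id))
        if values:
            return values
    return [_make_value(span.element, span, level, text,
                        span.start, span.end, "fallback")]


def rules_only_extract(
    text: str, ruleset: RuleSet, registry: ElementRegistry | None = None,
    doc_id: str = "",
) -> PicosRecord:
    """Rule-set baseline: scan every sentence of the raw text with every rule.

    Sentences are split on 。；！？.  For each (sentence, element) pair the
    first producing rule that matches emits values for all its occurrences.
    Judge rules are span gates and do not apply without a model span.  The
    emitted raw spans cover the matched value region, so strict evaluation
    credits the baseline exactly where its patterns align with the gold
    annotation.
    """
    registry = registry or default_registry()
    record = PicosRecord(doc_id=doc_id, provenance="rules-only")
    for offset, sentence in split_sentences(text):
        for element in (e.id for e in registry):
            level = registry.level_of(element)
            for rule in ruleset.for_element(element):
                if rule.action == "judge":
                    continue
                matches = list(rule.compiled.finditer(sentence))
                if not matches:
                    continue
                for m in matches:
                    if rule.action == "match":
                        grp = "v" if "v" in rule.compiled.groupindex else 0
                        groups = [grp]
                    else:  # split
                        groups = [g for g in rule.compiled.groupindex
                                  if m.group(g) is not None]
                    for g in groups:
                        start = offset + m.start(g)
                        end = offset + m.end(g)
                        raw = EntitySpan(element, start, end, m.group(g), level)
                        record.add(_make_value(element, raw, level, m.group(g),
                                               start, end, rule.rule_id))
                break  # first matching rule wins for this sentence+element
    return record


def hybrid_extract(
    document: Document,
    model,
    ruleset: RuleSet,
    registry: ElementRegistry | None = None,
) -> PicosRecord:
    """Model-then-rules pipeline: the labeler proposes coarse spans, the rule
    layer refines each one to its fine-grained value.  Deterministic for
    fixed inputs."""
    registry = registry or model.registry
    spans = model.predict_segments([document])[0]
    record = PicosRecord(doc_id=document.doc_id, provenance="model+rules")
    for span in spans:
        if span.element not in registry:
            continue
        span = EntitySpan(span.element, span.start, span.end,
                          document.text[span.start:span.end],
                          registry.level_of(span.element))
        for value in apply_rules_to_span(span, ruleset, registry):
            record.add(value)
    return record


def model_only_extract(
    document: Document, model, registry: ElementRegistry | None = None
) -> PicosRecord:
    """Labeler spans reported as-is (no rule refinement)."""
    registry = registry or model.registry
    record = PicosRecord(doc_id=document.doc_id, provenance="model-only")
    for span in model.predict_segments([document])[0]:
        level = registry.level_of(span.element) if span.element in registry else ""
        raw = EntitySpan(span.element, span.start, span.end,
                         document.text[span.start:span.end], level)
        record.add(_make_value(span.element, raw, level, raw.text,
                               raw.start, raw.end, "model"))
    return record
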