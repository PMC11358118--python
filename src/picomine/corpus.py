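"""Annotation schema, document segmentation, BIO tagging and corpus file I/O.

The extraction targets are ten PICOS evidence elements of randomized
controlled trial reports (participant count, age, source, diagnostic
criteria, therapy, adverse effects, shedding number, missing data, blinding,
randomization).  Each element carries an *output level* describing the
granularity of its value: A = long sentence, B = short sentence, C = phrase,
D = number.

Text is tokenized per Unicode character (the norm for Chinese NER; no word
segmentation), cut into segments of at most 128 characters, and labeled with
a BIO scheme: ``B-<elem>`` on the first character of a mention, ``I-<elem>``
inside it, ``O`` elsewhere.  Offsets are 0-based, half-open, in code points.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger(__name__)

#: Sentence-final punctuation used as preferred segmentation cut points and
#: as sentence delimiters for rule-only scanning.
SENTENCE_PUNCT = "。；！？"  # 。 ； ！ ？

DEFAULT_MAX_LEN = 128

PICOS_CATEGORIES = ("Population", "Intervention/Comparison", "Outcome", "StudyDesign")
LEVELS = ("A", "B", "C", "D")


class CorpusError(ValueError):
    """Raised for schema violations and malformed corpus files."""


# ---------------------------------------------------------------------------
# Element registry and tag schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvidenceElement:
    """One extraction target: id, PICOS category and output level."""

    id: str
    picos_category: str
    level: str

    def __post_init__(self) -> None:
        if self.picos_category not in PICOS_CATEGORIES:
            raise CorpusError(f"unknown PICOS category {self.picos_category!r}")
        if self.level not in LEVELS:
            raise CorpusError(f"level must be one of {LEVELS}, got {self.level!r}")


_DEFAULT_ELEMENTS = [
    # id, category, level.  Level census: A=1, B=4, C=2, D=3.
    ("pop_number", "Population", "D"),
    ("pop_age", "Population", "C"),
    ("pop_source", "Population", "B"),
    ("pop_diagnosis", "Population", "A"),
    ("therapy", "Intervention/Comparison", "B"),
    ("out_adverse", "Outcome", "C"),
    ("out_shedding", "Outcome", "D"),
    ("des_missing", "StudyDesign", "D"),
    ("des_blind", "StudyDesign", "B"),
    ("des_random", "StudyDesign", "B"),
]

# The extended preset distinguishes treatment-arm and control-arm mentions of
# the five elements that are reported per arm, giving 15 entity labels and a
# 31-tag BIO inventory.
_ARM_SPLIT = ("pop_number", "pop_age", "therapy", "out_adverse", "out_shedding")


@dataclass
class ElementRegistry:
    """Ordered collection of evidence elements defining the label space."""

    elements: list[EvidenceElement]
    name: str = "default"

    def __post_init__(self) -> None:
        ids = [e.id for e in self.elements]
        if len(set(ids)) != len(ids):
            raise CorpusError("element ids must be unique within a registry")
        self._by_id = {e.id: e for e in self.elements}

    def __contains__(self, element_id: str) -> bool:
        return element_id in self._by_id

    def __iter__(self):
        return iter(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def get(self, element_id: str) -> EvidenceElement:
        try:
            return self._by_id[element_id]
        except KeyError:
            raise CorpusError(f"unknown element id {element_id!r}") from None

    def level_of(self, element_id: str) -> str:
        return self.get(element_id).level

    def tag_schema(self) -> "TagSchema":
        return TagSchema.from_registry(self)


def default_registry() -> ElementRegistry:
    """The ten-element schema (21 BIO tags)."""
    return ElementRegistry(
        [EvidenceElement(i, c, l) for i, c, l in _DEFAULT_ELEMENTS], name="default"
    )


def extended_registry() -> ElementRegistry:
    """Arm-resolved schema: 15 entity labels, hence 31 BIO tags."""
    elements = []
    for i, c, l in _DEFAULT_ELEMENTS:
        if i in _ARM_SPLIT:
            elements.append(EvidenceElement(f"{i}_t", c, l))
            elements.append(EvidenceElement(f"{i}_c", c, l))
        else:
            elements.append(EvidenceElement(i, c, l))
    return ElementRegistry(elements, name="extended")


_PRESETS = {"default": default_registry, "extended": extended_registry}


def registry_preset(name: str) -> ElementRegistry:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise CorpusError(
            f"unknown registry preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def load_registry(path) -> ElementRegistry:
    """Read a registry from a YAML file: list of {id, picos_category, level}."""
    with open(path, encoding="utf-8") as fh:
        spec = yaml.safe_load(fh)
    elements = [
        EvidenceElement(e["id"], e["picos_category"], e["level"])
        for e in spec["elements"]
    ]
    return ElementRegistry(elements, name=spec.get("name", "custom"))


@dataclass
class TagSchema:
    """The BIO tag inventory induced by a registry: {O} ∪ {B-e, I-e}."""

    tags: list[str]
    element_of: dict[str, str | None]

    @classmethod
    def from_registry(cls, registry: ElementRegistry) -> "TagSchema":
        tags = ["O"]
        element_of: dict[str, str | None] = {"O": None}
        for elem in registry:
            for prefix in ("B", "I"):
                tag = f"{prefix}-{elem.id}"
                tags.append(tag)
                element_of[tag] = elem.id
        return cls(tags=tags, element_of=element_of)

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag in self.element_of

    def index(self, tag: str) -> int:
        try:
            return self.tags.index(tag)
        except ValueError:
            raise CorpusError(f"unknown tag {tag!r}") from None

    def check(self, tag: str) -> None:
        if tag not in self.element_of:
            raise CorpusError(f"unknown tag {tag!r}")


# ---------------------------------------------------------------------------
# Spans, segments, documents
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntitySpan:
    """An evidence mention: element id, half-open offsets, surface text, level."""

    element: str
    start: int
    end: int
    text: str = ""
    level: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(f"invalid span offsets [{self.start}, {self.end})")
        if self.text and len(self.text) != self.end - self.start:
            raise CorpusError(
                f"span text length {len(self.text)} != end-start "
                f"({self.end - self.start}) for element {self.element}"
            )

    def shifted(self, offset: int) -> "EntitySpan":
        return EntitySpan(self.element, self.start + offset, self.end + offset,
                          self.text, self.level)


@dataclass
class LabeledSegment:
    """A ≤128-character slice of a document with parallel BIO tags.

    The unit of labeler training and prediction.  ``tags`` is None for
    unlabeled text awaiting prediction.
    """

    doc_id: str
    chars: str
    tags: list[str] | None = None

    def __post_init__(self) -> None:
        if self.tags is not None and len(self.tags) != len(self.chars):
            raise CorpusError(
                f"segment of doc {self.doc_id!r}: {len(self.chars)} chars "
                f"but {len(self.tags)} tags"
            )

    def __len__(self) -> int:
        return len(self.chars)


@dataclass
class Document:
    """A full article: id (NUMBER_YEAR_AUTHOR_TITLE form), text, segments.

    Segmentation is a partition: the concatenated segment chars reconstruct
    ``text`` exactly, so segment base offsets are cumulative lengths.
    """

    doc_id: str
    text: str
    segments: list[LabeledSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.segments and "".join(s.chars for s in self.segments) != self.text:
            raise CorpusError(
                f"doc {self.doc_id!r}: segments do not reconstruct the text"
            )

    def segment_offsets(self) -> list[int]:
        offsets, pos = [], 0
        for seg in self.segments:
            offsets.append(pos)
            pos += len(seg)
        return offsets

    def gold_spans(self, schema: TagSchema) -> list[EntitySpan]:
        """Document-coordinate spans decoded from the segments' gold tags."""
        spans: list[EntitySpan] = []
        for off, seg in zip(self.segment_offsets(), self.segments):
            if seg.tags is None:
                continue
            spans.extend(s.shifted(off) for s in tags_to_spans(seg.tags, schema,
                                                               text=seg.chars))
        return spans


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_document(text: str, max_len: int = DEFAULT_MAX_LEN) -> list[str]:
    """Cut ``text`` into pieces of at most ``max_len`` characters.

    Cut points prefer the last sentence-final punctuation (。；！？) at or
    before the length limit; failing that the text is cut hard at max_len.
    The pieces concatenate back to the input exactly.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    pieces: list[str] = []
    pos = 0
    n = len(text)
    while pos < n:
        window = text[pos:pos + max_len]
        if pos + max_len >= n:
            pieces.append(window)
            break
        cut = _last_punct_cut(window)
        pieces.append(window[:cut])
        pos += cut
    return pieces


def _last_punct_cut(window: str) -> int:
    for i in range(len(window) - 1, -1, -1):
        if window[i] in SENTENCE_PUNCT:
            return i + 1
    return len(window)


def segment_with_spans(
    text: str,
    spans: list[EntitySpan],
    max_len: int = DEFAULT_MAX_LEN,
) -> list[str]:
    """Segment labeled text without splitting any gold span.

    When the preferred cut would fall strictly inside a gold annotation, the
    cut moves back to the span's start so the mention stays whole in the next
    segment.  Only applicable when gold offsets are known (corpus building);
    at prediction time no gold exists and plain :func:`segment_document`
    applies.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    starts = sorted((s.start, s.end) for s in spans)
    pieces: list[str] = []
    pos = 0
    n = len(text)
    while pos < n:
        if pos + max_len >= n:
            pieces.append(text[pos:])
            break
        window = text[pos:pos + max_len]
        cut = pos + _last_punct_cut(window)
        adjusted = _avoid_span_split(cut, pos, starts)
        if adjusted <= pos:  # span longer than the window: forced hard cut
            logger.warning("gold span longer than max_len=%d split at %d", max_len, cut)
            adjusted = cut
        pieces.append(text[pos:adjusted])
        pos = adjusted
    return pieces


def _avoid_span_split(cut: int, seg_start: int, spans: list[tuple[int, int]]) -> int:
    for start, end in spans:
        if start < cut < end:
            return start if start > seg_start else cut
    return cut


# ---------------------------------------------------------------------------
# Span <-> tag conversion
# ---------------------------------------------------------------------------


def spans_to_tags(spans: list[EntitySpan], length: int, schema: TagSchema) -> list[str]:
    """Render non-overlapping spans as a BIO tag sequence of ``length``."""
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise CorpusError(
                f"overlapping spans: ({a.start},{a.end},{a.element}) and "
                f"({b.start},{b.end},{b.element})"
            )
    tags = ["O"] * length
    for span in ordered:
        if span.end > length:
            raise CorpusError(
                f"span ({span.start},{span.end}) exceeds sequence length {length}"
            )
        schema.check(f"B-{span.element}")
        tags[span.start] = f"B-{span.element}"
        for i in range(span.start + 1, span.end):
            tags[i] = f"I-{span.element}"
    return tags


def tags_to_spans(
    tags: list[str], schema: TagSchema, text: str | None = None
) -> list[EntitySpan]:
    """Decode a BIO sequence into spans (inverse of :func:`spans_to_tags`).

    An I-tag with no compatible predecessor opens a new span as if it were a
    B-tag; the repair is logged, mirroring the usual CoNLL convention.
    """
    spans: list[EntitySpan] = []
    start = None
    element = None

    def flush(end: int) -> None:
        nonlocal start, element
        if start is not None:
            surface = text[start:end] if text is not None else ""
            spans.append(EntitySpan(element, start, end, surface))
        start, element = None, None

    for i, tag in enumerate(tags):
        schema.check(tag)
        elem = schema.element_of[tag]
        if tag == "O":
            flush(i)
        elif tag.startswith("B-"):
            flush(i)
            start, element = i, elem
        else:  # I- continues the open span, or repairs a dangling I as a B
            if element != elem:
                flush(i)
                logger.debug("repaired dangling I-%s at position %d", elem, i)
                start, element = i, elem
    flush(len(tags))
    return spans


def validate_tags(tags: list[str], schema: TagSchema) -> list[int]:
    """Positions of illegal BIO transitions (I after O, I after another element)."""
    violations = []
    prev_elem: str | None = None
    for i, tag in enumerate(tags):
        schema.check(tag)
        if tag.startswith("I-") and schema.element_of[tag] != prev_elem:
            violations.append(i)
        prev_elem = schema.element_of[tag] if tag != "O" else None
    return violations


# ---------------------------------------------------------------------------
# Corpus file I/O (CoNLL-style two-column dialect)
# ---------------------------------------------------------------------------

_DOC_HEADER = "###DOC "


def write_bio_corpus(docs: list[Document], path) -> None:
    """Write documents in the two-column dialect.

    One ``char<TAB>tag`` per line, a blank line between segments, and a
    separator line ``###DOC <doc_id>`` before each document.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for doc in docs:
            fh.write(f"{_DOC_HEADER}{doc.doc_id}\n")
            for si, seg in enumerate(doc.segments):
                if si > 0:
                    fh.write("\n")
                tags = seg.tags if seg.tags is not None else ["O"] * len(seg)
                for ch, tag in zip(seg.chars, tags):
                    fh.write(f"{ch}\t{tag}\n")


def read_bio_corpus(path, schema: TagSchema) -> list[Document]:
    """Parse the two-column dialect back into documents.

    ``read(write(docs))`` is the identity on valid corpora.  Malformed lines
    and unknown tags raise :class:`CorpusError` with the 1-based line number.
    """
    docs: list[Document] = []
    doc_id: str | None = None
    seg_chars: list[str] = []
    seg_tags: list[str] = []
    segments: list[LabeledSegment] = []

    def flush_segment() -> None:
        if seg_chars:
            segments.append(
                LabeledSegment(doc_id, "".join(seg_chars), list(seg_tags))
            )
            seg_chars.clear()
            seg_tags.clear()

    def flush_doc() -> None:
        nonlocal segments
        if doc_id is not None:
            flush_segment()
            text = "".join(s.chars for s in segments)
            docs.append(Document(doc_id, text, segments))
            segments = []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith(_DOC_HEADER):
                flush_doc()
                doc_id = line[len(_DOC_HEADER):]
            elif line == "":
                flush_segment()
            else:
                if doc_id is None:
                    raise CorpusError(f"line {lineno}: content before any ###DOC header")
                parts = line.split("\t")
                if len(parts) != 2 or len(parts[0]) != 1:
                    raise CorpusError(
                        f"line {lineno}: expected 'char<TAB>tag', got {line!r}"
                    )
                ch, tag = parts
                if tag not in schema:
                    raise CorpusError(f"line {lineno}: unknown tag {tag!r}")
                seg_chars.append(ch)
                seg_tags.append(tag)
    flush_doc()
    return docs


def split_sentences(text: str) -> list[tuple[int, str]]:
    """Sentence pieces with their start offsets, split after 。；！？."""
    out = []
    start = 0
    for m in re.finditer(f"[{SENTENCE_PUNCT}]", text):
        out.append((start, text[start:m.end()]))
        start = m.end()
    if start < len(text):
        out.append((start, text[start:]))
    return out
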