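"""Seeded generator of synthetic Chinese RCT paragraphs with gold labels.

Each document interleaves evidence sentences — rendered from element-keyed
templates with typed slots (counts, age ranges, institution names, therapy
phrases, criteria sentences) — with distractor sentences drawn from a fixed
neutral pool.  Some distractors are deliberate *traps*: phrasings that rule
patterns over-match but that carry no gold annotation, reproducing the
precision deficit of rule-only extraction.  Optional perturbations emulate
two real-data nuisances: OCR-like character substitution outside gold
spans, and span-boundary redundancy (trailing characters glued onto a
mention) used to contrast strict with relaxed matching.

Three independent RNG streams (document structure, slot values, noise) are
spawned from the master seed so that, e.g., changing the noise rate does
not reshuffle document structure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .corpus import (
    Document,
    ElementRegistry,
    EntitySpan,
    LabeledSegment,
    TagSchema,
    default_registry,
    segment_with_spans,
    spans_to_tags,
)
from .rules import PicosRecord, RefinedValue, parse_numeric


class GeneratorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Slot grammar
# ---------------------------------------------------------------------------

_HOSPITALS = ["北京中医药大学附属医院", "浙江省中医院", "广州市第一人民医院",
              "上海中医药大学附属曙光医院", "成都中医药大学附属医院"]
_DISEASES = ["糖尿病", "冠心病", "脑卒中", "类风湿关节炎", "骨关节炎",
             "慢性阻塞性肺疾病", "心力衰竭"]
_THERAPIES = ["桂枝汤加减", "针灸联合推拿", "补阳还五汤", "电针治疗",
              "参苓白术散", "益气活血汤"]
_DRUGS = ["二甲双胍", "硝苯地平", "布洛芬", "常规西药"]
_ADVERSE = ["恶心", "皮疹", "头晕", "腹泻", "乏力"]
_BOOKS = ["中药新药临床研究指导原则", "中医病证诊断疗效标准", "内科学"]
_BLINDS = ["双盲", "单盲"]
_RANDOM_METHODS = ["随机数字表法", "区组随机化方法", "计算机产生的随机序列"]
_AUTHORS = ["王", "李", "张", "刘", "陈", "杨", "赵", "黄"]

#: substitution alphabet for OCR-like noise (common characters an OCR pass
#: confuses into the text)
CONFUSION_ALPHABET = "的了在是有这中大来上个到说们为和你地出道也时年得就那要下以生会自着去之过家学对"


def _render_slot(name: str, rng: np.random.Generator, ctx: dict) -> str:
    if name == "n_total":
        return str(int(rng.integers(40, 201)))
    if name == "n_arm":
        return str(int(rng.integers(20, 101)))
    if name == "n_small":
        return str(int(rng.integers(0, 10)))
    if name == "age_lo":
        lo = int(rng.integers(18, 61))
        ctx["age_lo"] = lo
        return str(lo)
    if name == "age_hi":
        lo = ctx.get("age_lo", int(rng.integers(18, 61)))
        hi = lo + int(rng.integers(5, 31))
        ctx["age_hi"] = hi
        return str(hi)
    if name == "age_mean":
        lo = ctx.get("age_lo", 30)
        hi = ctx.get("age_hi", lo + 20)
        return str(int(rng.integers(lo, hi + 1)))
    if name == "hosp":
        return str(rng.choice(_HOSPITALS))
    if name == "disease":
        return str(rng.choice(_DISEASES))
    if name == "therapy_name":
        return str(rng.choice(_THERAPIES))
    if name == "drug":
        return str(rng.choice(_DRUGS))
    if name == "ae_list":
        pair = rng.choice(len(_ADVERSE), size=2, replace=False)
        return "、".join(_ADVERSE[i] for i in pair)
    if name == "book":
        return str(rng.choice(_BOOKS))
    if name == "blind_kind":
        return str(rng.choice(_BLINDS))
    if name == "random_method":
        return str(rng.choice(_RANDOM_METHODS))
    raise GeneratorError(f"unknown template slot {{{name}}}")


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


@dataclass
class Template:
    """One sentence pattern: element id, output level, text with ``{slot}``
    placeholders and a single ``[[...]]`` gold region."""

    element: str
    level: str
    text: str

    def render(self, rng: np.random.Generator) -> tuple[str, int, int]:
        """Fill slots; returns (sentence, gold_start, gold_end)."""
        ctx: dict = {}
        out: list[str] = []
        pos = 0
        gold_start = gold_end = -1
        token = re.compile(r"\[\[|\]\]|\{(\w+)\}")
        for m in token.finditer(self.text):
            out.append(self.text[pos:m.start()])
            pos = m.end()
            cur = sum(len(p) for p in out)
            if m.group(0) == "[[":
                gold_start = cur
            elif m.group(0) == "]]":
                gold_end = cur
            else:
                out.append(_render_slot(m.group(1), rng, ctx))
        out.append(self.text[pos:])
        sentence = "".join(out)
        if not (0 <= gold_start < gold_end <= len(sentence)):
            raise GeneratorError(
                f"template for {self.element} lacks a valid [[...]] gold region")
        return sentence, gold_start, gold_end


@dataclass
class TemplateBank:
    templates: dict[str, list[Template]]
    distractors: list[str]
    traps: list[str]

    def check_covers(self, elements: list[str]) -> None:
        missing = [e for e in elements if not self.templates.get(e)]
        if missing:
            raise GeneratorError(f"template bank has no templates for: {missing}")


def load_template_bank(path, registry: ElementRegistry) -> TemplateBank:
    """Read a YAML template bank; element levels come from the registry
    (templates for elements outside the registry are ignored)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    templates: dict[str, list[Template]] = {}
    for entry in raw.get("templates", []):
        elem = entry["element"]
        if elem not in registry:
            continue
        templates.setdefault(elem, []).append(
            Template(elem, registry.level_of(elem), entry["text"]))
    return TemplateBank(
        templates=templates,
        distractors=list(raw.get("distractors", [])),
        traps=list(raw.get("traps", [])),
    )


def builtin_template_bank(registry: ElementRegistry,
                          variant: str = "default") -> TemplateBank:
    name = "templates.yaml" if variant == "default" else "templates_ascii.yaml"
    ref = resources.files("picomine.data") / name
    with resources.as_file(ref) as path:
        return load_template_bank(path, registry)


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults describe the desk-scale corpus all end-to-end checks run on:
    500 documents, each element present with probability 0.8, about three
    distractor sentences per document (one third of the pool are rule
    traps), and mild OCR-like substitution noise (1% of non-gold
    characters).  Boundary redundancy is off in the corpus itself; it is a
    prediction-side perturbation (see :func:`inject_redundancy`).
    """

    n_docs: int = 500
    seed: int = 0
    elements_per_doc: float | dict[str, float] = 0.8
    distractor_rate: float = 3.0
    ocr_noise_rate: float = 0.01
    redundancy_rate: float = 0.0
    k_max: int = 5
    template_bank: str | None = None  # path to YAML; None = built-in bank
    max_len: int = 128

    def __post_init__(self) -> None:
        if self.n_docs < 0:
            raise GeneratorError("n_docs must be >= 0")
        probs = (self.elements_per_doc.values()
                 if isinstance(self.elements_per_doc, dict)
                 else [self.elements_per_doc])
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise GeneratorError("inclusion probabilities must be in [0, 1]")
        if not (0.0 <= self.ocr_noise_rate <= 1.0):
            raise GeneratorError("ocr_noise_rate must be in [0, 1]")
        if not (0.0 <= self.redundancy_rate <= 1.0):
            raise GeneratorError("redundancy_rate must be in [0, 1]")
        if self.k_max < 1:
            raise GeneratorError("k_max must be >= 1")

    def inclusion_prob(self, element: str) -> float:
        if isinstance(self.elements_per_doc, dict):
            return self.elements_per_doc.get(element, 0.0)
        return self.elements_per_doc


def _fill_trap_slots(text: str, rng: np.random.Generator) -> str:
    ctx: dict = {}
    return re.sub(r"\{(\w+)\}", lambda m: _render_slot(m.group(1), rng, ctx), text)


def _doc_id(idx: int, rng: np.random.Generator) -> str:
    year = 1995 + int(rng.integers(0, 26))
    author = str(rng.choice(_AUTHORS))
    disease = str(rng.choice(_DISEASES))
    return f"{idx:04d}_{year}_{author}某_{disease}临床观察"


def generate_corpus(
    config: GeneratorConfig,
    registry: ElementRegistry | None = None,
) -> tuple[list[Document], list[PicosRecord]]:
    """Generate documents with gold BIO tags plus gold structured records.

    Deterministic given ``config.seed``.  Every gold span's offsets address
    its rendered slot in the final document text, under all noise settings.
    """
    registry = registry or default_registry()
    if config.template_bank is None:
        bank = builtin_template_bank(registry)
    else:
        bank = load_template_bank(config.template_bank, registry)
    enabled = [e.id for e in registry if config.inclusion_prob(e.id) > 0]
    bank.check_covers(enabled)

    ss = np.random.SeedSequence(config.seed)
    structure_rng, slot_rng, noise_rng = (np.random.default_rng(c)
                                          for c in ss.spawn(3))
    pool = [(t, False) for t in bank.distractors] + [(t, True) for t in bank.traps]

    docs: list[Document] = []
    records: list[PicosRecord] = []
    for idx in range(config.n_docs):
        doc_id = _doc_id(idx + 1, structure_rng)
        sentences: list[tuple[str, EntitySpan | None]] = []
        for elem in registry:
            if structure_rng.random() >= config.inclusion_prob(elem.id):
                continue
            variants = bank.templates[elem.id]
            template = variants[int(structure_rng.integers(0, len(variants)))]
            sentence, g0, g1 = template.render(slot_rng)
            span = EntitySpan(elem.id, g0, g1, sentence[g0:g1], elem.level)
            sentences.append((sentence, span))
        if pool:
            n_distract = int(structure_rng.poisson(config.distractor_rate))
            for _ in range(n_distract):
                text, is_trap = pool[int(structure_rng.integers(0, len(pool)))]
                if is_trap:
                    text = _fill_trap_slots(text, slot_rng)
                sentences.append((text, None))
        order = structure_rng.permutation(len(sentences))

        text_parts: list[str] = []
        spans: list[EntitySpan] = []
        offset = 0
        for i in order:
            sentence, span = sentences[i]
            if span is not None:
                spans.append(span.shifted(offset))
            text_parts.append(sentence)
            offset += len(sentence)
        text = "".join(text_parts)
        if config.ocr_noise_rate > 0:
            text = _noise_text(text, spans, config.ocr_noise_rate, noise_rng)
            spans = [EntitySpan(s.element, s.start, s.end,
                                text[s.start:s.end], s.level) for s in spans]
        docs.append(_build_document(doc_id, text, spans, registry, config.max_len))
        records.append(_gold_record(doc_id, spans, registry))
    return docs, records


def _build_document(doc_id: str, text: str, spans: list[EntitySpan],
                    registry: ElementRegistry, max_len: int) -> Document:
    schema = registry.tag_schema()
    pieces = segment_with_spans(text, spans, max_len)
    segments = []
    offset = 0
    for piece in pieces:
        local = [s.shifted(-offset) for s in spans
                 if offset <= s.start and s.end <= offset + len(piece)]
        segments.append(LabeledSegment(
            doc_id, piece, spans_to_tags(local, len(piece), schema)))
        offset += len(piece)
    return Document(doc_id, text, segments)


def _gold_record(doc_id: str, spans: list[EntitySpan],
                 registry: ElementRegistry) -> PicosRecord:
    record = PicosRecord(doc_id=doc_id, provenance="gold")
    for span in spans:
        numeric = parse_numeric(span.text) if span.level == "D" else None
        record.add(RefinedValue(
            element=span.element, raw_span=span, value=span.text,
            start=span.start, end=span.end, numeric=numeric, rule_id="gold"))
    return record


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------


def _noise_text(text: str, spans: list[EntitySpan], rate: float,
                rng: np.random.Generator) -> str:
    protected = np.zeros(len(text), dtype=bool)
    for s in spans:
        protected[s.start:s.end] = True
    chars = list(text)
    hit = rng.random(len(text)) < rate
    n_alpha = len(CONFUSION_ALPHABET)
    for i in np.nonzero(hit & ~protected)[0]:
        repl = CONFUSION_ALPHABET[int(rng.integers(0, n_alpha))]
        if repl == chars[i]:  # always substitute: step to the next letter
            repl = CONFUSION_ALPHABET[(CONFUSION_ALPHABET.index(repl) + 1) % n_alpha]
        chars[i] = repl
    return "".join(chars)


def inject_ocr_noise(document: Document, rate: float, seed: int) -> Document:
    """Substitute non-gold-span characters with probability ``rate`` from the
    confusion alphabet.  Gold offsets (and gold surface text) are preserved;
    segment boundaries and tags are unchanged."""
    if not (0.0 <= rate <= 1.0):
        raise GeneratorError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    schema_spans: list[EntitySpan] = []
    offset = 0
    boundaries = []
    for seg in document.segments:
        boundaries.append((offset, offset + len(seg)))
        offset += len(seg)
    if document.segments:
        # schema inferred from the tags actually present in the document
        tags_present = sorted({t for s in document.segments
                               for t in (s.tags or []) if t != "O"})
        element_of = {t: t[2:] for t in tags_present}
        element_of["O"] = None
        schema = TagSchema(tags=["O"] + tags_present, element_of=element_of)
        schema_spans = document.gold_spans(schema)
    noised = _noise_text(document.text, schema_spans, rate, rng)
    segments = [LabeledSegment(document.doc_id, noised[b0:b1],
                               seg.tags if seg.tags is None else list(seg.tags))
                for (b0, b1), seg in zip(boundaries, document.segments)]
    return Document(document.doc_id, noised, segments)


def inject_redundancy(
    docs: list[Document],
    gold_spans: dict[str, list[EntitySpan]],
    rate: float,
    k_max: int,
    seed: int,
) -> tuple[dict[str, list[EntitySpan]], dict]:
    """Perturb gold spans into a synthetic prediction set with boundary
    redundancy: selected spans gain 1..k_max trailing characters (clipped at
    the text end).

    Returns the prediction spans per doc and bookkeeping
    ``{"n_spans", "n_selected", "n_extended", "n_clipped_unchanged"}`` — a
    selected span at the text end may be unable to extend and then stays
    identical to gold.
    """
    if k_max < 1:
        raise GeneratorError("k_max must be >= 1")
    rng = np.random.default_rng(seed)
    by_id = {d.doc_id: d for d in docs}
    out: dict[str, list[EntitySpan]] = {}
    stats = {"n_spans": 0, "n_selected": 0, "n_extended": 0,
             "n_clipped_unchanged": 0}
    for doc_id, spans in gold_spans.items():
        text = by_id[doc_id].text
        perturbed = []
        for span in spans:
            stats["n_spans"] += 1
            new_end = span.end
            if rng.random() < rate:
                stats["n_selected"] += 1
                k = int(rng.integers(1, k_max + 1))
                new_end = min(span.end + k, len(text))
                if new_end == span.end:
                    stats["n_clipped_unchanged"] += 1
                else:
                    stats["n_extended"] += 1
            perturbed.append(EntitySpan(span.element, span.start, new_end,
                                        text[span.start:new_end], span.level))
        out[doc_id] = perturbed
    return out, stats
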