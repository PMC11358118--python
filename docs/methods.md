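# Methods

## Task and model

picomine extracts ten PICOS evidence elements from Chinese randomized
controlled trial (RCT) reports: participant count, age distribution,
participant source, diagnostic criteria (Population); therapy
(Intervention/Comparison); adverse effects, shedding number (Outcome);
missing data, blinding, randomization (Study design).  Each element has an
*output level* describing the granularity of its value — A: long sentence,
B: short sentence, C: phrase, D: number.  The default level assignment is
A = {pop_diagnosis}, B = {pop_source, therapy, des_blind, des_random},
C = {pop_age, out_adverse}, D = {pop_number, out_shedding, des_missing};
it is configurable per registry.

Extraction is a two-stage hybrid:

1. **Sequence labeler.**  Characters (no word segmentation — standard for
   Chinese clinical NER) are labeled with a BIO scheme over the element
   inventory (21 tags for the 10-element registry; 31 for the "extended"
   preset that distinguishes treatment-arm and control-arm mentions of the
   five per-arm elements, giving 15 entity labels).  The model is a
   character-embedding + bidirectional LSTM + linear-chain CRF.  For a
   segment of length L, tag sequence t scores

       score(t) = T[START, t1] + Σi E[i, ti] + Σi T[ti, ti+1] + T[tL, STOP]

   and training minimises the conditional negative log-likelihood
   `log Z − score(t_gold)`, with `log Z` from the forward algorithm in log
   space (max-shift stabilised) and its gradient from forward-backward
   marginals.  Decoding is Viterbi with ties broken toward the lowest tag
   index, so output is deterministic.  BIO constraints (no O→I, no I across
   elements, no START→I) are applied as a −∞ mask on transitions, so decoded
   sequences are always well formed.

2. **Rule refinement.**  An ordered, element-keyed family of regular
   expressions (`PATTERN = {Pattern1, Pattern2, …}`) turns each coarse span
   into a fine value.  Rule actions are *match* (keep the match, or its
   named group `v`), *judge* (a boolean gate: spans failing the pattern are
   vetoed), and *split* (one value per named group, e.g. separating
   treatment-arm from control-arm counts).  Rules run in (priority,
   rule_id) order; the first producing rule wins; a span no rule matches
   passes through with `rule_id="fallback"` — boundary redundancy does not
   make a mention useless, so unmatched spans are kept rather than dropped.
   D-level values are additionally parsed to numbers (Arabic digits plus
   simple Chinese numerals up to the hundreds).

A *rules-only* baseline scans every sentence (split on 。；！？) of the raw
text with every producing rule; judge rules are span gates and do not apply
there.  This mode over-matches (no model anchoring) and misses phrasings
outside the pattern inventory, which is exactly the precision/recall
profile that motivates the hybrid.

## Corpus conventions

Text is cut into segments of ≤128 characters; cuts prefer the last
sentence-final punctuation in the window and otherwise fall back to a hard
cut.  When gold annotations are available (corpus building), a cut that
would land inside a gold span is moved back to the span start so mentions
stay trainable; at prediction time no gold exists and hard cuts stand.
Offsets are 0-based, half-open, in code points.  Corpus files use a
CoNLL-style two-column dialect (`char<TAB>tag`, blank line between
segments, `###DOC <doc_id>` separator; doc ids follow the
NUMBER_YEAR_AUTHOR_TITLE form); read∘write is byte-identical.

## Training defaults

Embedding 32, hidden 64 per direction, AdamW (lr 5e-3, decoupled weight
decay 0.01, biases and transitions exempt), batch 16 padded to the batch
maximum with masked positions excluded from loss and from state updates
(right-padding must not leak into the reverse LSTM pass), gradient-norm
clip 5, 8 epochs, segment-level 9:1 train/held-out split by seeded
shuffle.  These sizes were chosen so a CPU-only run on the default
synthetic corpus converges comfortably (held-out strict entity F1 > 0.99
by epoch 3) while the whole pipeline stays in a few minutes; they are not
claimed to be anyone else's settings.  Training is bit-deterministic given
the config seed, and checkpoints reload to bit-identical predictions.

The pretrained-transformer variant of this architecture is supported only
as an *external encoder adapter*: any callable mapping a segment's
characters to fixed-dimension per-character vectors can replace the
embedding+BiLSTM stack, in which case only the emission projection and CRF
are trained.  No pretrained weights are shipped; the default encoder works
fully offline.

## Evaluation

Entity-level precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
harmonic mean; zero denominators yield 0 with a degenerate flag.  Matching
is greedy one-to-one in document order, per element.  *Strict* requires
identical (element, start, end).  *Relaxed* operationalises
redundancy-tolerant reading: the prediction must contain the gold interval
and its surplus length must not exceed max(tol_abs, tol_frac·|gold|),
defaults tol_abs = 10 characters, tol_frac = 0.5.  Relaxed TP therefore
dominates strict TP on any input.  Headline scores are micro-averages
(pooled counts); per-element tables are reported alongside.

Annotation QC uses Cohen's kappa on a two-rater 2×2
(accurate/ambiguous) table, κ = (p_o − p_e)/(1 − p_e).  Cell proportions
are *truncated* (not rounded) to two decimals, the convention consistency
reports in this literature use when quoting such percentages.  If chance
agreement p_e = 1, κ is defined as 1 when p_o = 1 and flagged degenerate
otherwise.

## Synthetic corpus: what it emulates and what it does not

The generator emulates the shape of the real task with no downloads:
paragraphs mixing evidence sentences (element-keyed Chinese templates with
typed slots — counts, age ranges, hospital names, therapy phrases,
criteria sentences; D slots render numerals) and distractor sentences from
a fixed neutral pool.  One third of the distractor pool are *traps*:
phrasings that starter rules over-match (e.g. an enrolment count inside a
citation of earlier work) but that the labeler can reject from context.
Optional OCR-like noise substitutes non-gold characters from a confusion
alphabet (default rate 0.01, roughly two characters per document);
boundary redundancy is a prediction-side perturbation that extends gold
spans rightward by 1–5 characters.  Default conditions: 500 documents,
per-element inclusion probability 0.8, Poisson(3) distractors per
document.  Three RNG streams (structure, slots, noise) are spawned from
the master seed, so changing the noise rate does not reshuffle document
structure.

Templates and the starter ruleset (25 rules, ≥2 per element) are
co-designed: every D-level template is covered by a rule (rule-only recall
1.0 on counts in noise-free corpora), while one therapy phrasing is
deliberately outside the inventory to exercise the fallback path and the
rule-only recall gap.  An ASCII-transliterated template bank is included
for terminals without CJK fonts; it is for display and interface testing
only and is not rule-covered.

What passing on this corpus does **not** show: robustness to the
heterogeneity of real journal prose (the templates are far more regular
than real writing, so absolute F1 here is much higher than any real-corpus
figure), to OCR segmentation damage beyond character substitution, or to
document layouts; and the 113-rule scale of a production rule base is not
reproduced — only the formalism and a starter set.

## Numerical and design choices

- CRF oracle tolerance 1e-8 against exhaustive enumeration (instances
  L ≤ 5, K ≤ 5); the implementation agrees to ~1e-14.
- Masked transitions behave as −∞ in all scoring; their parameters receive
  zero gradient.
- Viterbi tie-break: lowest tag index at every backtracking step.
- Judge rules are veto-only gates; they do not re-classify an element.
- Rule-only scanning works on sentences, not 128-character segments, since
  rules are meant for paragraphs and sentences of raw text.
- Span-level evaluation of pipeline records uses the coarse mention spans
  (deduplicated when a split rule emits several values from one span), so
  hybrid and model-only modes are scored on the same footing.
- Degenerate inputs: empty text segments decode to no spans; an empty
  corpus or a single segment refuses to train (no held-out split); spans
  longer than the segment limit fall back to a hard cut with a warning.

## Known limitations

Absolute scores on the synthetic corpus are near-ceiling by construction
and say nothing about real-corpus accuracy; the labeler is a single-layer
BiLSTM without pretraining; Chinese numeral parsing stops at the hundreds
(fine for trial-size counts); relaxed matching only tolerates surplus
around a contained gold span, not partial overlap; and the extended
(arm-resolved) preset ships templates but no dedicated starter rules, so
rule-backed refinement there requires a user rule file.
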