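# picomine

Hybrid neural + rule extraction of PICOS evidence elements from Chinese
randomized-controlled-trial (RCT) text.

Systematic reviews and clinical guidelines need structured facts out of
trial reports — how many participants, their age and source, the
diagnostic criteria, the therapy, adverse events, dropout and missing-data
counts, blinding and randomization design.  Reading these out of Chinese
(including traditional Chinese medicine) RCT articles by hand is slow and
narrow.  picomine implements the two-stage pipeline that automates it:

1. a **character-level BiLSTM-CRF sequence labeler** tags coarse evidence
   mentions with a BIO scheme over ten elements (four output levels:
   A long sentence / B short sentence / C phrase / D number), scoring a tag
   sequence as `T[START,t1] + Σ E[i,ti] + Σ T[ti,ti+1] + T[tL,STOP]`,
   trained by conditional NLL (forward algorithm) and decoded by Viterbi
   under BIO constraints;
2. a **rule-set layer** `PATTERN = {Pattern1, Pattern2, …}` of
   element-keyed regular expressions with *match*, *judge* (veto) and
   *split* actions refines each span to its fine-grained value (numbers
   parsed for D-level elements), with unmatched spans passed through
   rather than lost.

Around the pipeline sit entity-level evaluation (precision/recall/F1 with
strict and boundary-redundancy-tolerant relaxed matching, Cohen's kappa
for annotation QC) and a seeded synthetic-corpus generator that makes
every stage trainable and testable offline.  The whole stack — LSTM
backpropagation, CRF forward-backward, AdamW — is plain numpy/scipy.

See `docs/methods.md` for the model, the matching criteria, and what the
synthetic corpus does and does not demonstrate.

## Worked example

```sh
picomine generate --seed 7 --n-docs 200 --out corpus.bio
picomine train    --corpus corpus.bio --seed 7 --out model.npz
picomine extract  --mode hybrid --model model.npz --in corpus.bio --out pred.jsonl
picomine evaluate --gold corpus.bio --pred pred.jsonl --mode strict
```

The train step prints the final epoch's summary:

```
{"epochs": 8, "train_nll": 0.016801277885273875, "heldout_f1": 0.9874213836477987}
```

`heldout_f1` is strict entity-level F1 on the 10% of segments held out of
training — the labeler has essentially learned the synthetic tagging task.
Evaluation prints a per-element table:

```
== strict matching ==
element                P       R      F1   TP   FP   FN
pop_number         1.000   1.000   1.000  166    0    0
pop_age            1.000   1.000   1.000  153    0    0
pop_source         1.000   1.000   1.000  166    0    0
pop_diagnosis      0.994   0.994   0.994  170    1    1
therapy            1.000   1.000   1.000  162    0    0
out_adverse        1.000   1.000   1.000  153    0    0
out_shedding       1.000   1.000   1.000  169    0    0
des_missing        1.000   1.000   1.000  162    0    0
des_blind          0.994   0.994   0.994  164    1    1
des_random         1.000   1.000   1.000  145    0    0
micro              0.999   0.999   0.999
```

Each row pools true positives / false positives / false negatives for one
element over the corpus; `micro` pools them across elements.  A record in
`pred.jsonl` maps elements to refined values with provenance, e.g.

```json
{
  "doc_id": "0001_2002_赵某_冠心病临床观察",
  "elements": {
    "pop_number": [
      {"value": "149", "numeric": 149, "start": 116, "end": 119,
       "rule_id": "fallback", "raw_start": 116, "raw_end": 119}
    ],
    "des_random": [
      {"value": "采用区组随机化方法将患者分为两组", "numeric": null,
       "start": 153, "end": 169, "rule_id": "des_random_method_grouping",
       "raw_start": 153, "raw_end": 169}
    ]
  }
}
```

— the participant count was parsed to the number 149, and the
randomization description was matched and bounded by a named rule.  The
annotation-QC helper works straight from a 2×2 two-rater table:

```sh
picomine kappa --counts 1746,118,56,504
{"kappa": 0.806, "observed_agreement": 0.928..., "expected_agreement": 0.630...,
 "both_accurate_pct": 72.02, "both_ambiguous_pct": 20.79}
```

The same machinery is available as a library
(`picomine.train_labeler`, `picomine.hybrid_extract`,
`picomine.evaluate_extraction`, `picomine.generate_corpus`, …).

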