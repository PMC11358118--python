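# ASCII-transliterated template bank for terminals without CJK fonts.
# Same slot grammar and markup as templates.yaml; the starter ruleset does
# NOT target these phrasings, so rule-dependent checks use the default bank.
templates:
  - element: pop_number
    text: "zongji naru huanzhe [[{n_total}]] li, suiji fenwei liangzu. "
  - element: pop_age
    text: "huanzhe nianling [[{age_lo}-{age_hi} sui]]. "
  - element: pop_source
    text: "[[bingli laiyuan yu zhongyi yiyuan menzhen]]. "
  - element: pop_diagnosis
    text: "[[zhenduan biaozhun canzhao linchuang zhinan bing jingguo quezhen]]. "
  - element: therapy
    text: "[[zhiliao zu caiyong zhenjiu zhiliao]]. "
  - element: out_adverse
    text: "chuxian [[exin, pizhen]] deng buliang fanying. "
  - element: out_shedding
    text: "tuoluo [[{n_small}]] li. "
  - element: des_missing
    text: "shifang [[{n_small}]] li. "
  - element: des_blind
    text: "[[caiyong shuangmang sheji]]. "
  - element: des_random
    text: "[[caiyong suiji shuzi biao fa fenzu]]. "
distractors:
  - "liangzu jixian ziliao kebi. "
  - "shuju fenxi shiyong tongji ruanjian wancheng. "
traps: []
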