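# Sentence templates for the synthetic RCT-paragraph generator.
#
# [[...]] delimits the gold evidence span; {name} slots are filled by the
# slot grammar in picomine.synthetic.  Elements suffixed _t/_c serve the
# arm-resolved "extended" registry preset.
templates:
  - element: pop_number
    text: "本研究共纳入患者[[{n_total}]]例，随机分为两组。"
  - element: pop_number
    text: "共收治{disease}患者[[{n_total}]]例。"
  - element: pop_age
    text: "患者年龄[[{age_lo}～{age_hi}岁]]，平均年龄{age_mean}岁。"
  - element: pop_age
    text: "两组患者年龄均在[[{age_lo}～{age_hi}岁]]之间。"
  - element: pop_source
    text: "[[病例来源于{hosp}门诊及住院部]]。"
  - element: pop_source
    text: "[[研究对象均来自{hosp}]]，知情同意后入组。"
  - element: pop_diagnosis
    text: "[[诊断标准参照《{book}》中{disease}的相关标准，并经临床检查确诊]]。"
  - element: pop_diagnosis
    text: "[[所有患者均符合《{book}》制定的{disease}诊断标准]]。"
  - element: therapy
    text: "[[治疗组采用{therapy_name}治疗，对照组给予{drug}治疗]]。"
  - element: therapy
    text: "[[治疗组在对照组基础上加用{therapy_name}]]。"
  - element: therapy
    # phrasing outside the starter rule inventory: exercises the fallback
    # path and the rule-only recall deficit
    text: "[[观察组予{therapy_name}，对照组口服{drug}]]。"
  - element: out_adverse
    text: "治疗期间治疗组出现[[{ae_list}]]等不良反应。"
  - element: out_adverse
    text: "部分患者出现[[{ae_list}]]等轻度不良反应。"
  - element: out_shedding
    text: "研究过程中治疗组脱落[[{n_small}]]例。"
  - element: out_shedding
    text: "共有[[{n_small}]]例患者中途退出研究。"
  - element: des_missing
    text: "随访期间失访[[{n_small}]]例，其余资料完整。"
  - element: des_missing
    text: "数据缺失[[{n_small}]]例。"
  - element: des_blind
    text: "[[本试验采用{blind_kind}设计]]，受试者与评价者均不知晓分组。"
  - element: des_blind
    text: "[[评价过程实行{blind_kind}法]]。"
  - element: des_random
    text: "[[采用{random_method}将患者分为两组]]。"
  - element: des_random
    text: "[[按{random_method}分组]]，两组基线资料可比。"
  # arm-resolved variants (extended preset)
  - element: pop_number_t
    text: "治疗组纳入患者[[{n_arm}]]例。"
  - element: pop_number_c
    text: "对照组纳入患者[[{n_arm}]]例。"
  - element: pop_age_t
    text: "治疗组年龄[[{age_lo}～{age_hi}岁]]。"
  - element: pop_age_c
    text: "对照组年龄[[{age_lo}～{age_hi}岁]]。"
  - element: therapy_t
    text: "[[治疗组采用{therapy_name}治疗]]。"
  - element: therapy_c
    text: "[[对照组给予{drug}治疗]]。"
  - element: out_adverse_t
    text: "治疗组出现[[{ae_list}]]等不良反应。"
  - element: out_adverse_c
    text: "对照组出现[[{ae_list}]]等不良反应。"
  - element: out_shedding_t
    text: "治疗组脱落[[{n_small}]]例。"
  - element: out_shedding_c
    text: "对照组脱落[[{n_small}]]例。"

# Distractor sentences carry no gold annotation.  The trap sentences are
# phrased so that rule patterns over-match them (the rule-only baseline's
# precision deficit) while the labeler can use wider context to ignore them.
distractors:
  - "数据分析使用统计软件完成。"
  - "两组基线资料比较差异无统计学意义。"
  - "本文对研究结果进行了讨论。"
  - "表中列出了各项观察指标。"
  - "结果与国内外相关报道基本一致。"
  - "作者声明无利益冲突。"
traps:
  - "文献报道类似研究曾纳入受试者{n_total}例。"
  - "会议摘要报道患者{n_total}例的初步结果。"
  - "有报道称治疗组采用{therapy_name}后症状改善。"
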