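[
  {"rule_id": "pop_number_judge_digit", "element": "pop_number", "pattern": "[0-9〇一二三四五六七八九十百]", "action": "judge", "priority": 0},
  {"rule_id": "pop_number_split_arms", "element": "pop_number", "pattern": "治疗组(?P<n_t>[0-9]+)例[，,]对照组(?P<n_c>[0-9]+)例", "action": "split", "priority": 5},
  {"rule_id": "pop_number_enroll", "element": "pop_number", "pattern": "纳入(?:患者|受试者)?(?P<v>[0-9]+)例", "action": "match", "priority": 10},
  {"rule_id": "pop_number_patients", "element": "pop_number", "pattern": "患者(?P<v>[0-9]+)例", "action": "match", "priority": 20},
  {"rule_id": "pop_age_judge_range", "element": "pop_age", "pattern": "[0-9]+～[0-9]+岁", "action": "judge", "priority": 0},
  {"rule_id": "pop_age_prefixed", "element": "pop_age", "pattern": "年龄(?:均在)?(?P<v>[0-9]+～[0-9]+岁)", "action": "match", "priority": 10},
  {"rule_id": "pop_age_bare_range", "element": "pop_age", "pattern": "(?P<v>[0-9]+～[0-9]+岁)", "action": "match", "priority": 20},
  {"rule_id": "pop_source_cases_from", "element": "pop_source", "pattern": "(?P<v>病例来源于[^，。；]*)", "action": "match", "priority": 10},
  {"rule_id": "pop_source_subjects_from", "element": "pop_source", "pattern": "(?P<v>研究对象均来自[^，。；]*)", "action": "match", "priority": 20},
  {"rule_id": "pop_diagnosis_reference", "element": "pop_diagnosis", "pattern": "(?P<v>诊断标准参照《[^》]*》[^。；]*)", "action": "match", "priority": 10},
  {"rule_id": "pop_diagnosis_conform", "element": "pop_diagnosis", "pattern": "(?P<v>[^。；，]*符合《[^》]*》[^。；]*标准)", "action": "match", "priority": 20},
  {"rule_id": "therapy_treatment_adopt", "element": "therapy", "pattern": "(?P<v>治疗组采用[^。；]*)", "action": "match", "priority": 10},
  {"rule_id": "therapy_addon", "element": "therapy", "pattern": "(?P<v>治疗组在对照组基础上加用[^。；，]*)", "action": "match", "priority": 20},
  {"rule_id": "out_adverse_occurred", "element": "out_adverse", "pattern": "出现(?P<v>[^。；，]*?)等(?:轻度)?不良反应", "action": "match", "priority": 10},
  {"rule_id": "out_adverse_bare", "element": "out_adverse", "pattern": "(?P<v>[^。；，]*?)等不良反应", "action": "match", "priority": 20},
  {"rule_id": "out_shedding_judge_digit", "element": "out_shedding", "pattern": "[0-9〇一二三四五六七八九十百]", "action": "judge", "priority": 0},
  {"rule_id": "out_shedding_dropout", "element": "out_shedding", "pattern": "脱落(?P<v>[0-9]+)例", "action": "match", "priority": 10},
  {"rule_id": "out_shedding_withdraw", "element": "out_shedding", "pattern": "(?P<v>[0-9]+)例患者中途退出", "action": "match", "priority": 20},
  {"rule_id": "des_missing_judge_digit", "element": "des_missing", "pattern": "[0-9〇一二三四五六七八九十百]", "action": "judge", "priority": 0},
  {"rule_id": "des_missing_lost", "element": "des_missing", "pattern": "失访(?P<v>[0-9]+)例", "action": "match", "priority": 10},
  {"rule_id": "des_missing_absent", "element": "des_missing", "pattern": "(?:数据)?缺失(?P<v>[0-9]+)例", "action": "match", "priority": 20},
  {"rule_id": "des_blind_design", "element": "des_blind", "pattern": "(?P<v>(?:本试验)?采用[单双]盲设计)", "action": "match", "priority": 10},
  {"rule_id": "des_blind_assessment", "element": "des_blind", "pattern": "(?P<v>评价过程实行[单双]盲法)", "action": "match", "priority": 20},
  {"rule_id": "des_random_method_grouping", "element": "des_random", "pattern": "(?P<v>采用(?:随机数字表法|区组随机化方法|计算机产生的随机序列)将患者分为两组)", "action": "match", "priority": 10},
  {"rule_id": "des_random_by_method", "element": "des_random", "pattern": "(?P<v>按(?:随机数字表法|区组随机化方法|计算机产生的随机序列)分组)", "action": "match", "priority": 20}
]
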