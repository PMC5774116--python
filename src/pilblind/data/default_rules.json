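{
  "fd": ["sham", "placebo", "fake", "dummy", "inactive needle"],
  "dd": ["different", "control", "group one", "group two", "group 1", "group 2", "non-traditional", "not typical", "test"],
  "fd_escalation": ["non-acupoint", "non-acupoints", "away from true points", "non-penetrating", "does not penetrate", "not penetrate the skin", "blunt needle"]
}
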