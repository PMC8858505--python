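# Worked example: source subgroup -2% (95% CI -8 to 4), target +7%
# (95% CI -10 to 24), borrowing weight 0.78 under the planning design.
planning:
  n_target: 85
  n_source: 707
  p_fail: 18
  ltfu: 0.10
  margin: 10
analysis:
  target:
    estimate: 7
    ci_lower: -10
    ci_upper: 24
  source:
    estimate: -2
    ci_lower: -8
    ci_upper: 4
  weight: 0.78
reporting:
  scale: percent
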