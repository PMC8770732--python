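# DEMO clock models with made-up coefficients, for exercising the pipeline.
# The published 2-CpG and 4-CpG pyrosequencing clocks are defined by
# coefficients in their original sources; transcribe those here to run the
# real models.  Layout: predicted age = intercept + sum coef * m(site)^power.
models:
  - id: demo2
    intercept: 102.0
    terms:
      - {site: ELOVL2_6, coef: 1.1}
      - {site: ASPA_1, coef: -1.6}
  - id: demo4
    intercept: 38.0
    valid_age_range: [0, 101]
    terms:
      - {site: ELOVL2_6, coef: 0.9}
      - {site: ASPA_1, coef: -0.65}
      - {site: EDARADD_1, coef: -0.5}
      - {site: PDE4C_1, coef: 0.85}
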