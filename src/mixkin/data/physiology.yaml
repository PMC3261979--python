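# Chemical-independent rat physiology baselines.
# Units: flows mL/min, volumes mL, enzyme totals nmol.
# Rich-flow fraction and poorly-perfused volume are derived, not set:
#   rich fraction = 1 - sum of other fractions
#   poor volume   = 0.9 * body volume - sum of other tissue volumes
alveolar_ventilation: 62.5
cardiac_output: 62.5
flow_fractions:
  liver: 0.25
  fat: 0.09
  poor: 0.15
body_volume: 250.0
tissue_volumes:
  liver: 10.0
  fat: 17.5
  rich: 12.5
enzyme_totals:
  CYP2E1: 20.9   # 2.09e-5 mmol expressed in nmol
  CYPX: 1.16     # 1.16e-6 mmol, similar to hepatic CYP2B1
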