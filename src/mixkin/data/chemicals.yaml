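# Chemical-dependent baselines for the BTEX constituents.
# partitions: blood_air is the blood/air partition coefficient P_art;
# liver/fat/poor/rich are tissue/blood partition coefficients.
# k3_baseline is the literature-derived catalysis constant (min^-1) used
# before calibration; posterior_mode holds the calibrated maximum-posterior
# values (k1 min^-1 nmol^-1, k2 and k3 min^-1, blood_air dimensionless)
# together with the calibrated physiology (alveolar_ventilation and
# cardiac_output mL/min, fat_volume mL), shared across chemicals.
benzene:
  molecular_weight: 78.11
  partitions: {blood_air: 15.0, liver: 1.13, fat: 33.3, poor: 1.0, rich: 1.13}
  k3_baseline: 13.54
  posterior_mode: {k1: 39.0, k2: 1040.0, k3: 7.8, blood_air: 15.4}
toluene:
  molecular_weight: 92.14
  partitions: {blood_air: 18.0, liver: 4.64, fat: 56.7, poor: 1.54, rich: 4.64}
  k3_baseline: 10.38
  posterior_mode: {k1: 26.0, k2: 2900.0, k3: 12.0, blood_air: 17.2}
ethylbenzene:
  molecular_weight: 106.17
  partitions: {blood_air: 42.7, liver: 1.96, fat: 36.4, poor: 0.61, rich: 1.41}
  k3_baseline: 13.7
  posterior_mode: {k1: 94.0, k2: 22000.0, k3: 17.0, blood_air: 40.3}
m_xylene:
  molecular_weight: 106.17
  partitions: {blood_air: 46.0, liver: 1.97, fat: 40.4, poor: 0.91, rich: 1.97}
  k3_baseline: 10.32
  posterior_mode: {k1: 61.0, k2: 6800.0, k3: 18.0, blood_air: 48.5}
posterior_mode_physiology:
  alveolar_ventilation: 78.0
  cardiac_output: 90.0
  fat_volume: 12.0
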