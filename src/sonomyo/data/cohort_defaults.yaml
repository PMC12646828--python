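# Default cohort specification: per-sex means/SDs of the
# morphofunctional variables and the orthant-derived default
# correlations. Loading this file reproduces CohortSpec().
correlations:
  fatit_pct|pennation_deg: -0.39
  mit_pct|fatit_pct: -0.39
  mit_pct|pennation_deg: 0.39
  rfmt_cm|rfma_cm2: 0.93
male_fraction: 0.4559505409582689
moments:
  female:
    age:
    - 63.48
    - 16.72
    arm_circ_cm:
    - 23.75
    - 3.89
    asmi:
    - 5.51
    - 0.86
    bmi:
    - 21.7
    - 5.17
    calf_circ_cm:
    - 31.24
    - 3.91
    fatit_pct:
    - 39.71
    - 6.49
    handgrip_kg:
    - 17.71
    - 7.34
    height_m:
    - 1.58
    - 0.06
    mit_pct:
    - 45.35
    - 9.85
    pct_weight_loss:
    - 8.0
    - 5.0
    pennation_deg:
    - 4.9
    - 2.69
    reactance_ohm:
    - 52.92
    - 12.7
    resistance_ohm:
    - 633.53
    - 109.05
    rfma_cm2:
    - 2.72
    - 0.94
    rfmt_cm:
    - 0.9
    - 0.26
    sft_cm:
    - 0.98
    - 0.47
  male:
    age:
    - 66.44
    - 14.47
    arm_circ_cm:
    - 25.63
    - 3.18
    asmi:
    - 6.82
    - 1.42
    bmi:
    - 23.69
    - 4.41
    calf_circ_cm:
    - 32.71
    - 4.09
    fatit_pct:
    - 38.78
    - 7.81
    handgrip_kg:
    - 26.7
    - 9.13
    height_m:
    - 1.7
    - 0.07
    mit_pct:
    - 47.98
    - 11.66
    pct_weight_loss:
    - 8.0
    - 5.0
    pennation_deg:
    - 5.79
    - 2.89
    reactance_ohm:
    - 48.54
    - 11.21
    resistance_ohm:
    - 539.01
    - 94.69
    rfma_cm2:
    - 3.56
    - 1.21
    rfmt_cm:
    - 1.08
    - 0.31
    sft_cm:
    - 0.53
    - 0.27
n_total: 647
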