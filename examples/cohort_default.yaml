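# Default synthetic cohort: 153 people, ages 0-101 drawn from the banded
# age-by-sex design (81+ oversampled, predominantly female), four-site
# panel with noise calibrated to realistic single-site age correlations.
n: 153
seed: 0
age_sampler:
  type: bands
  bands:
    - {lo: 0, hi: 20, n_female: 13, n_male: 11}
    - {lo: 21, hi: 40, n_female: 12, n_male: 12}
    - {lo: 41, hi: 60, n_female: 12, n_male: 13}
    - {lo: 61, hi: 80, n_female: 14, n_male: 11}
    - {lo: 81, hi: 101, n_female: 45, n_male: 10}
# sites omitted -> calibrated four-site default panel
# (ASPA_1, EDARADD_1, ELOVL2_6, PDE4C_1)
sex_offset: 0.0
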