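# Default generating distributions for the two-group lymph-node cohort
# (23 benign vs 45 metastatic retropharyngeal nodes).  Diffusion
# parameters are per-group normal mean/SD in canonical units (D-type in
# um^2/ms, mu in um, exponents dimensionless); size/morphology fields
# are category frequencies.  MiAD categories are [6,8), [8,10) and
# [10,20] mm; maximum-axial-diameter categories are [6,10), [10,20) and
# [20,30) mm.
benign:
  label: benign
  n: 23
  params:
    adc:        {mean: 0.655, sd: 0.063}
    ddc_sem:    {mean: 0.721, sd: 0.073}
    alpha_sem:  {mean: 0.685, sd: 0.047}
    d_froc:     {mean: 0.631, sd: 0.065}
    beta_froc:  {mean: 0.714, sd: 0.071}
    mu_froc:    {mean: 3.235, sd: 0.291}
    d_ctrw:     {mean: 0.782, sd: 0.084}
    alpha_ctrw: {mean: 0.694, sd: 0.110}
    beta_ctrw:  {mean: 0.821, sd: 0.027}
  miad_counts: [13, 9, 1]
  maad_counts: [6, 17, 0]
  homogeneous_count: 16
  well_defined_count: 20
  male_count: 12
  age: {mean: 53.5, sd: 10.6}
metastatic:
  label: metastatic
  n: 45
  params:
    adc:        {mean: 0.615, sd: 0.068}
    ddc_sem:    {mean: 0.622, sd: 0.077}
    alpha_sem:  {mean: 0.748, sd: 0.044}
    d_froc:     {mean: 0.559, sd: 0.061}
    beta_froc:  {mean: 0.789, sd: 0.040}
    mu_froc:    {mean: 3.461, sd: 0.278}
    d_ctrw:     {mean: 0.688, sd: 0.074}
    alpha_ctrw: {mean: 0.649, sd: 0.082}
    beta_ctrw:  {mean: 0.889, sd: 0.040}
  miad_counts: [21, 8, 16]
  maad_counts: [20, 24, 1]
  homogeneous_count: 29
  well_defined_count: 35
  male_count: 31
  age: {mean: 56.4, sd: 13.2}
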