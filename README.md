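# dwinode

Non-Gaussian diffusion-MRI model comparison for lymph-node
characterization.

Metastatic spread of nasopharyngeal carcinoma is routinely staged
through the retropharyngeal lymph nodes, which are hard to biopsy;
multi-b-value diffusion-weighted imaging (DWI) offers a non-invasive
readout of tissue microstructure.  `dwinode` implements the full
quantitative chain used to ask whether diffusion heterogeneity
separates benign from metastatic nodes: four forward signal models and
their voxel-wise inverse problem, a synthetic cohort/phantom generator
matched to the published group summaries (23 benign vs 45 metastatic
nodes), and the diagnostic-statistics battery (group tests, ROC/Youden,
DeLong, logistic regression, ICC).

## The four signal models

For a normalized decay S(b)/S(0) over b-values 0–3 ms/µm²
(0–3,000 s/mm²):

| model | signal | parameters |
|---|---|---|
| mono-exponential | exp(−b·ADC) | ADC (µm²/ms) |
| stretched-exponential (SEM) | exp(−(b·DDC)^α) | DDC (µm²/ms), α |
| fractional-order calculus (FROC) | exp(−D·µ^{2(β−1)}·(γG_dδ)^{2β}·(Δ−((2β−1)/(2β+1))δ)) | D (µm²/ms), β, µ (µm) |
| continuous-time random walk (CTRW) | E_α(−(b·D)^β) | D (µm²/ms), α, β |

E_α is the one-parameter Mittag-Leffler function (implemented here on
the decay branch with ≤1e−8 absolute error).  The heterogeneity
exponents α, β ∈ (0, 1] equal 1 for pure Gaussian diffusion; all four
models collapse onto the mono-exponential in that limit.  Fitting
follows the two-stage clinical convention: for FROC/CTRW, D is first
estimated from the low-b sub-protocol (b ≤ 1 ms/µm²) by log-linear
regression, then the shape parameters are fit over all b with D fixed
(Levenberg–Marquardt with bound-preserving reparameterization and
seeded multi-start).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (no patient data are required):

```
python analysis/01_simulate_cohort.py      # cohort CSV + DWI phantom
python analysis/02_fit_phantom.py          # nine parameter maps + ROI means
python analysis/03_group_statistics.py     # group comparison tables
python analysis/04_diagnostic_performance.py  # ROC / logistic / DeLong
python analysis/05_replication_frequency.py   # significance pattern over 200 cohorts
```

`03_group_statistics.py` prints, for the default seed:

```
            benign_mean  benign_sd  metastatic_mean  metastatic_sd          test  statistic       p
adc              0.6502     0.0538           0.6254         0.0617  mann_whitney     2.1518  0.0314
ddc_sem          0.7373     0.0759           0.6174         0.0697     student_t     6.5126  0.0000
...
beta_ctrw        0.8225     0.0291           0.8971         0.0402     student_t    -7.9054  0.0000
```

i.e. benign nodes show higher diffusivities (ADC, DDC, D_FROC, D_CTRW)
and metastatic nodes higher heterogeneity exponents — large effects for
the SEM/FROC/CTRW shape parameters, a modest one for conventional ADC.
`04_diagnostic_performance.py` reports the per-parameter ROC table
(β_CTRW is the strongest single marker, AUC ≈ 0.94 on this draw; the
combined β_CTRW + node-size logistic model reaches AUC ≈ 0.94 with
Youden index 0.80) and the DeLong comparison of the combined model
against each single parameter.  `05_replication_frequency.py` shows
how often each parameter would replicate p < 0.05 across 200 fresh
cohorts at the published effect sizes (≈1.0 for the heterogeneity
exponents, ≈0.6 for ADC — the replicate frequency is simply the
statistical power).

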