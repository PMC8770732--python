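# pyroclock

Small-panel CpG-methylation epigenetic clocks and the accuracy-evaluation
pipeline used to validate them on cross-sectional cohorts.

Epigenetic clocks predict an individual's age from DNA methylation levels at
selected CpG sites. Pyrosequencing-based clocks use only a handful of sites
(typically 2–4, in genes such as *ELOVL2*, *ASPA*, *EDARADD* and *PDE4C*),
which makes them cheap and fast enough for routine use — but their accuracy
must be re-validated per population and, critically, per age range: errors
that look small in adults (18–80 y) can triple in the oldest group, where
methylation drift slows and clocks systematically under-predict age.

`pyroclock` provides, for anyone validating such a clock:

* **Clock application** — models of the form
  `X′ = intercept + Σᵢ cᵢ · mᵢ^pᵢ`, where `mᵢ` is percent methylation at
  site *i*, read from a YAML config and applied to sample CSVs.
* **Accuracy metrics** — the standard validation statistics on paired
  chronological (`X`) and predicted (`X′`) ages:
  * MAD = `Σ|Xᵢ − Xᵢ′| / n` (mean absolute difference, years),
  * SEE = `√(Σ(Xᵢ − Xᵢ′)² / (n − 2))` (standard error of the estimate),
  * PCP(t) = `100·k/n`, the percent of samples with `|Xᵢ − Xᵢ′| ≤ t`
    (thresholds 5, 7.5, 10 y by convention; the boundary counts),
  * R² = squared Pearson correlation of `X` and `X′` (always in [0, 1]).
* **Stratified evaluation** — metrics per age group (young 0–17, adult
  18–80, old 81+) and sex; two-sided Mann–Whitney rank-sum comparisons of
  delta age (`X′ − X`) between strata; MAD/SEE dynamics over cumulative age
  ranges `[min, t]`.
* **A synthetic cohort generator** — per-site methylation linear in age with
  Gaussian noise, drawn over a 153-person banded age-by-sex design spanning
  0–101 y, with optional drift attenuation past a knot age (~80 y) that
  reproduces old-age under-prediction. Noise is calibrated analytically so
  single-site age correlations land at realistic values (|r| ≈ 0.79–0.94).
  Its `matched_clock` is the exact inverse of the noiseless generator, which
  makes the whole pipeline testable against closed-form expectations.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort; outputs land in `results/`.

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_site_regressions.py
python analysis/03_predict_ages.py
python analysis/04_stratified_accuracy.py
python analysis/05_error_dynamics.py
python analysis/06_attenuation_study.py --seed 1
```

With `--seed 1` this prints (abridged):

```
ASPA_1       slope -0.148 %/y   r -0.832   R^2 0.692
ELOVL2_6     slope +0.568 %/y   r +0.947   R^2 0.897
...
young  all  n= 24  MAD  5.11  SEE  6.93  R^2 0.373  PCP5  58.3%
adult  all  n= 71  MAD  6.28  SEE  7.69  R^2 0.819  PCP5  45.1%
old    all  n= 58  MAD  7.77  SEE 10.08  R^2 0.452  PCP5  39.7%
all    all  n=153  MAD  6.66  SEE  8.47  R^2 0.933  PCP5  45.1%
...
MAD: range-to-80 5.98 y -> full range 6.66 y
attenuation: old delta below adult in 100.0% of replicates; p<0.01 in 94.5%
```

Reading this: each site's methylation tracks age strongly (ELOVL2-class
r ≈ 0.95); the equal-weight matched clock then predicts age with a ~6.7 y
mean error over the full 0–101 range; the pooled R² (0.93) far exceeds any
within-stratum R² because restricting the age range shrinks the age variance
against a fixed error floor; and when drift attenuation past age 80 is
switched on, the old group's predicted ages fall below their chronological
ages in every replicate and the cumulative MAD curve climbs once the range
passes 80 — the signature pattern of small-panel clocks in the oldest old.

The same pipeline is available as a CLI
(`pyroclock simulate | predict | evaluate | dynamics`); run any subcommand
with `--help`. Example clock configs (with clearly labelled demo
coefficients — published clock coefficients must be transcribed from their
original sources) are in `examples/`.

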