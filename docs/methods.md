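# Methods

## The model

A small-panel epigenetic clock maps percent methylation at a few named CpG
sites to a predicted age:

```
X′ = intercept + Σᵢ cᵢ · mᵢ^pᵢ ,   mᵢ ∈ [0, 100] %
```

with integer powers `pᵢ ≥ 1` (published pyrosequencing clocks are linear,
`pᵢ = 1`, but the term form admits polynomial variants without special
casing). `pyroclock` evaluates such clocks; it deliberately does **not**
train them — coefficients are user-supplied configuration, because published
clock coefficients belong to their original sources and a validation study
takes them as given.

## Accuracy statistics

All statistics act on paired chronological/predicted ages `(X, X′)` of a
stratum:

* **MAD** `= Σ|Xᵢ−Xᵢ′|/n`. This is the *mean* absolute difference — the
  conventional clock-error summary despite the recurring "median absolute
  deviation" naming confusion in the literature; a genuinely median-based
  statistic is exposed separately as `median_absolute_error`.
* **SEE** `= √(Σ(Xᵢ−Xᵢ′)²/(n−2))`. The `n−2` denominator is the
  two-parameter regression convention, so SEE needs `n ≥ 3` and always
  satisfies `SEE = RMSE·√(n/(n−2)) ≥ MAD`.
* **PCP(t)** `= 100·k/n`, `k = #{i : |Xᵢ−Xᵢ′| ≤ t}`. The boundary is
  included ("within *t* years" means ≤). Thresholds default to 5/7.5/10 y.
* **R²** is the squared Pearson correlation of `X` with `X′`, bounded in
  [0, 1]. The alternative — residual R² about the identity line — can go
  negative for badly biased strata and is *not* what validation studies
  tabulate; near-zero stratum values then simply mean "no correlation left
  inside this narrow age band". This is also why pooled R² always exceeds
  within-stratum R²: restricting the range shrinks age variance against a
  fixed error floor.

Degenerate inputs raise typed errors rather than returning NaN: empty
vectors everywhere, `n < 3` for SEE, constant vectors for R².

## Stratified evaluation

Age groups default to young [0, 17], adult [18, 80], old [81, 101] in
inclusive whole years, membership by `floor(age)`; ages beyond the last
bound join the last group (an open-ended oldest band). Reports are produced
for every (group ∪ all) × (sex ∪ all) stratum; samples with unparseable sex
count only toward pooled strata, so per-sex n's may sum to less than the
pooled n. Strata too small for SEE or R² omit the value and carry a flag
rather than failing the whole report.

**Delta-age comparisons.** Strata are independent groups of individuals, so
"the Wilcoxon test" is implemented as the two-sample rank-sum
(Mann–Whitney U), two-sided: exact null distribution when
`n_a + n_b ≤ 20` with no ties, otherwise the normal approximation with
midranks and tie correction. The signed-rank variant is available via
`paired=True` for matched designs. p-values are reported raw — multiple
small-stratum tests are few and exploratory here; apply your own correction
if you run many.

**Dynamics.** `metric_dynamics` recomputes MAD or SEE over cumulative
ranges `[min_age, t]` with the lower bound fixed at the cohort minimum and
`t` on a configurable grid (default 1 y) that always ends exactly at the
cohort maximum, so the final point equals the global metric. Early points
with too few samples are flagged null instead of reported; the early part
of any such curve is noisy because single outliers dominate small cumulative
samples.

## The synthetic cohort generator

The generator emulates the structure a validation cohort analysis assumes,
not any particular dataset:

* **Ages and sex** come from a banded design: five bands (0–20, 21–40,
  41–60, 61–80, 81+) with per-band female/male cell counts
  13/11, 12/12, 12/13, 14/11, 45/10 — a 153-person cross-section spanning
  0–101 y with the oldest band oversampled and predominantly female, as
  real human cohorts at that age are. Cells are drawn multinomially with
  these weights; ages are continuous uniform within `[lo, hi+1)` so
  `floor(age)` reproduces band membership. A uniform sampler is available
  for designed experiments (e.g. adult-only ranges).
* **Methylation** at site *i* for age *a* is
  `baseline + b·min(a, knot) + λ·b·max(0, a−knot) + N(0, σ)`, clipped to
  [0, 100] with clipping counted on the returned cohort. No knot means pure
  linearity. Noise is homoscedastic per site — the simplest structure
  consistent with evaluating a linear-regression-style clock.
* **Default panel**: ASPA_1 (−0.15 %/y), EDARADD_1 (−0.18 %/y), ELOVL2_6
  (+0.55 %/y), PDE4C_1 (+0.30 %/y), directions per the known age biology of
  each locus. σ is **derived, not tuned**: for a target single-site age
  correlation r, `σ = |b|·sd(age)·√(1/r² − 1)` with sd(age) ≈ 30.7 y
  computed analytically from the banded design. Targets are 0.94 (ELOVL2),
  0.88 (PDE4C), −0.84 (EDARADD), −0.79 (ASPA) — the realistic range for
  these assays, anchored at the strong-ELOVL2 / weaker-ASPA extremes. Under
  these defaults clipping occurs in far fewer than 0.1% of draws (0 of 612
  at n = 153).
* **Reproducibility**: one master seed per cohort; ages/sex and each site's
  noise consume independent sub-streams spawned deterministically from it,
  so adding a site never perturbs the others.
* **`matched_clock`** inverts the noiseless generator below the knot: one
  site gives `X′ = (m − baseline)/b`; several give the equal-weight average
  of single-site inversions. It is the natural reference clock for
  parameter-recovery tests: with σ = 0 it recovers age exactly; with noise,
  its error is exactly `N(0, Σ(σᵢ/bᵢ)²/k²)`, so MAD converges to the
  folded-normal mean `s·√(2/π)` and SEE to `s·√(n/(n−2))` where `s` is that
  error sd — closed forms the test suite checks at n = 20,000.

### What the generator does and does not emulate

It reproduces: linear age trends with realistic correlation strengths, the
banded 0–101 age structure, old-age drift attenuation (knot 80 y, slope
factor λ, default scenario λ = 0.3) and its consequences (negative old-group
delta age, MAD/SEE growth past 80), and optional per-sex offsets. It does
**not** emulate heteroscedastic assay noise, batch effects, bisulfite
conversion artefacts, inter-site noise correlation, or mortality selection —
so passing tests demonstrate the *pipeline's* correctness and the
qualitative age-range phenomena, not the error magnitudes of any real assay.

A quantitative sanity check: the calibrated four-site matched clock has an
error sd of ≈ 9.2 y over the full range, in line with what real four-site
clocks achieve over 0–101 cohorts; its adult-range MAD (~6 y) is modestly
worse than the ~4–5 y of regression-fitted clocks, as expected for an
equal-weight inversion rather than a fitted combination.

## Numerical and design choices

* Equal-weight inversion (not precision weighting) in `matched_clock`: it is
  the simplest exactly-invertible reference; precision weighting would
  improve noise but lose the "algebraic inverse" role the tests rely on.
* Validation bounds: ages in [0, 130] (age 0 is a legitimate cohort member),
  methylation in [0, 100]; every malformed CSV cell is reported with its row
  number in one error — rows are never silently dropped.
* Samples missing a site required by a clock are excluded from that clock's
  predictions with a logged count; imputation would bias MAD downward.
* A clock's `valid_age_range` triggers a warning, never clipping, so
  systematic out-of-range behaviour stays measurable.
* Site naming is canonical `GENE_ordinal` (`ELOVL2_6`); concatenated
  spellings (`ELOVL26`) are accepted as panel aliases when reading CSVs.
* Floats are written with `repr` and read with round-trip parsing, making
  sample/prediction CSV round-trips bit-identical; report CSVs round-trip at
  6 significant digits.
* Simulation-study sizes (200 replicates for the comparison studies, 500 for
  design calibration, n = 20,000 for the closed-form laws) were chosen so
  Monte-Carlo error is well inside the asserted tolerances while the whole
  suite stays interactive.

## Known limitations

* The replication path against a real cohort (per-site correlations, Table-2
  style adult MAD/SEE) requires the user to supply the deposited data and
  transcribed clock coefficients; the package ships only demo coefficients.
* `evaluate_strata` reports every stratum independently; it does not model
  covariance between overlapping strata (pooled vs per-group), so
  significance comparisons across rows are informal.
* With the paper-realistic noise calibration, the attenuation scenario's
  qualitative effect (old-group under-prediction) is essentially certain,
  but per-replicate guarantees involving MAD ordering hold only with ~98–99%
  probability at n = 50/50 — single-replicate exceptions are expected
  occasionally.
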