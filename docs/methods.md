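# Methods

## Problem and model

The package treats a hospital's emergency case mix as a rank-frequency
distribution: diagnosis categories ordered by how often they cause an
admission. Two parametric descriptions of the decay of frequency with rank
are supported.

**Exponential decay.** Frequency at 1-based rank x is modelled as
f(x) = b₀e^(−b₁x). b₀ has the units of the fitted frequencies (admissions
per year, or per 100,000 inhabitants per year on the normalized scale); b₁
is a dimensionless decay rate per rank. The fit is plain nonlinear least
squares against the ranked mean frequencies. The rank index is 1-based: with
a 0-based index the top diagnosis would be forced to equal b₀ exactly, which
is not what a decay law means. This convention is recorded in every fit
output.

**Pareto power law.** Frequencies x ≥ k are modelled by the density
f(x | α, k, C) = Cαk^α / x^(α+1). The tail exponent is estimated by the
closed-form maximum-likelihood estimator α̂ = n / Σ log(xᵢ/k̂) with
k̂ = min(xᵢ) — k̂ is pinned to the sample minimum because no observation can
lie below the scale parameter, so α is the single free shape parameter.
A sample with all values equal makes Σ log = 0 and α unidentifiable; this is
a hard error, not an infinite estimate.

**Rank-size mapping.** The Pareto density lives on the frequency axis while
the exponential lives on the rank axis. To compare them (and to generate
Pareto-law synthetic data) the package uses the quantile rank-size mapping:
the category at rank r of n is placed at the upper r/n tail of the law,
x_r = k·(n/r)^(1/α). This reduces to the classic Zipf profile x ∝ 1/r at
α = 1, leaves the smallest category exactly at k (so k̂ = min recovers the
true scale), and makes α̂ approximately recover a generating α. The scale
constant C — which the power-law density leaves unconstrained when used as a
shape template rather than a normalized density — is fixed operationally:
C matches the fitted rank-size curve's total to the observed total, so the
fitted curve is directly overlayable and scoreable on the rank grid.

**Model comparison.** Both fitted curves are evaluated on the profile's rank
grid and scored by residual sum of squares (default) or Gaussian-error AIC.
Each model carries two free parameters on this grid (b₀, b₁ vs α, C), and
the counts are recorded in the comparison output. Exact ties prefer the
exponential, with a logged note. Both fits must have been produced on the
same scale as the profile (per-100k rates or raw counts); mixing scales is a
contract error.

## Prediction intervals

"Reproducible from year to year" is quantified two ways. Per category, the
n annual frequencies give a two-sided t prediction interval for one future
year: mean ± t(1−(1−level)/2, n−1) · s · √(1 + 1/n), with s the sample
standard deviation. This is the standard frequentist PI for a single future
observation under approximate normality of annual frequencies; the lower
bound is clipped at zero because frequencies are non-negative. Intervals are
computed on the same scale that is displayed (normalized per 100k by
default; a flag switches to raw counts). With a single observed year the
interval degenerates to zero width at the mean. Across categories, the
Spearman rank correlation between every pair of yearly orderings summarizes
ordering stability; a year with fully tied counts has no ordering and its
pairs are reported as NaN and excluded from the min/mean.

## Preprocessing conventions

* Truncation normalizes every code to the 3-character category rather than
  literally dropping one character: "length − 1" would map an already
  3-character code to an invalid 2-character string, while the analysis is
  category-level by design.
* Chapter grouping is by first letter (A and B merged into one
  infectious-disease group); C and D are deliberately separate entities, so
  the grouping is *not* the official ICD-10 letter-range chapter partition.
  Every non-Z first letter is its own group; exclusion lists beyond Z are
  configurable rather than hard-coded.
* Z-chapter discharges are excluded as non-emergencies before any counting.
* Malformed codes are dropped with a logged warning by default; a strict
  mode aborts instead. Both behaviours are deterministic and the counts of
  retained / Z-excluded / malformed records always sum to the input count.
* The surgical/medical duty-roster split ships as an editable YAML because
  it encodes local hospital routine, not medicine: chapter-level entries
  with category-level overrides, unmapped categories labelled `unassigned`
  with a warning.

## Synthetic data: what it emulates and what it does not

The generator emulates a six-year registry extract: per-category annual
counts follow the configured law, optionally scaled by a per-year trend
factor (default 1.0), with Poisson draws modelling year-to-year arrival
noise, plus a Z-chapter contamination stream sized so the Z share of the
whole stream equals `z_fraction`. Category labels are deterministic
ICD-10-shaped strings over the letters A–Y, so preprocessing runs unmodified.
With noise off, counts are the expected values rounded half-to-even with a
floor of one admission — the floor keeps every configured category present,
at the cost that a decaying law's integer counts can no longer reproduce the
real-valued law exactly (recovery through the full pipeline is then
rounding-limited at roughly the 10⁻³ relative level; machine-precision
end-to-end recovery holds when expected counts are integers, e.g. a flat
law).

Annual Poisson totals are an assumption, not an observed property of
emergency arrivals; the generator makes no attempt to model age/sex
structure, comorbidity, readmission clustering, seasonality, or triage.
Passing tests therefore demonstrate the correctness of the statistical
machinery under a known law with independent Poisson noise — not that real
admission streams follow either law, which is exactly the empirical question
the ranked profiles and fits are meant to answer on real extracts.

The study-scale configuration used by `scripts/acceptance.py` mirrors the
cohort the method is designed for: years 2015–2020, a constant catchment
population of 315,000, and Z contamination of ≈2.7% (5,778 of 213,801
admissions). Cohorts of that shape do not pin down the number of distinct
categories or the true law parameters, so those are fixed once at
n_categories = 400 and b₁ = 0.1 (the canonical decay-rate magnitude for
emergency case mixes), with b₀ = 3646 chosen so the expected annual non-Z
volume matches (213,801 − 5,778)/6.

## Numerical choices

* Exponential fit: `scipy.optimize.least_squares` with bounds b₀ > 0,
  b₁ ≥ 0, relative tolerances 10⁻⁸, at most 10⁴ evaluations (all recorded in
  the fit result). The optimizer starts from the conventional (1000, 0.1);
  a second start seeded by log-linear regression of log f on rank is also
  tried and the lower-SSE solution kept — a single fixed start is not
  reliable across the whole b₀ ∈ [1, 10⁴], b₁ ∈ [0.01, 1] range. The start
  actually used is recorded. Non-convergence returns the best iterate with
  `converged=False`.
* Standard errors: `error_model="constant"` gives the classic homoscedastic
  s²(JᵀJ)⁻¹ covariance; `error_model="poisson"` gives the model-based
  covariance (JᵀJ)⁻¹ Jᵀ diag(μ̂) J (JᵀJ)⁻¹ with per-point variance equal to
  the fitted mean, which is the calibrated choice when the fitted values
  are counts with Poisson variation (residual-based sandwich estimators are
  too noisy at 50 ranks to give honest 3σ coverage).
* Ranking ties are broken lexicographically by category code, for
  reproducibility.
* Display truncation keeps the minimal top-rank prefix whose cumulative
  share of mean admissions reaches the coverage fraction; attainment uses ≥,
  so an exactly-attaining category is included. A flag switches the basis
  from share-of-admissions to share-of-category-count, since "omit the least
  frequent 20%" is ambiguous between the two readings.
* Vital-few extraction uses the same ≥ attainment rule; the
  community-diagnosis flag is operationalized as top-10 share ≥ 0.8, the
  only quantitative form of that criterion in use.
* The pipeline manifest contains versions, seed, config hash and record
  counts but no timestamps, so identical configuration and seed give
  byte-identical outputs; stage timings go to the stderr log only.

## Known limitations

* No age/sex standardization, trend or joinpoint analysis, readmission
  deduplication, or multi-morbidity handling; counts are workload, not
  incidence.
* Codes are validated lexically (letter + two digits + optional detail),
  not against the official ICD-10 catalogue; no ICD-9/ICD-11 conversion.
* No alternative heavy-tail families (lognormal, stretched exponential) and
  no data-driven choice of the Pareto threshold k — k̂ is the sample minimum
  by definition here.
* The Pareto goodness-of-fit comparison is a curve-fit score on the rank
  grid, not a formal hypothesis test of power-law membership.
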