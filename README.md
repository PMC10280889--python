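# emergepi

Rank-frequency analysis of emergency hospital admissions, for emergency
physicians, hospital planners and health-services researchers who need to
answer a practical question: **is the local emergency case mix predictable
enough to plan duty-roster competence around it?**

Given multi-year admission records — one row per admission with an ICD-10
main discharge diagnosis and the year — the package builds the "sorted
histogram" of emergency epidemiology: diagnosis categories ranked by their
across-year mean frequency per 100,000 catchment inhabitants, each with a
95% prediction interval for a future year. It then asks which law the decay
of frequency with rank follows, and extracts the *vital few* — the minimal
set of high-volume diagnoses a duty roster must competently cover.

## The model

Preprocessing follows the conventions of emergency-epidemiology practice:

* codes are truncated to the 3-character ICD-10 **category** (`I21.0 → I21`;
  the 4th character only encodes detail);
* categories are grouped by **capital letter**, with the infectious-disease
  letters A and B merged into one `A/B` group;
* **Z-chapter** discharges (factors influencing health status) are excluded
  as non-emergencies;
* categories are optionally split into **surgical** vs **medical**
  duty-roster arms via an editable YAML mapping.

Two candidate laws are fitted to frequency `f` against 1-based rank `x`:

* exponential decay, by nonlinear least squares (initial values
  b₀ = 1000, b₁ = 0.1):

  f(x) = b₀ e^(−b₁ x)

* the Pareto power law over frequency x ≥ k,

  f(x | α, k, C) = C α k^α / x^(α+1),

  with the closed-form maximum-likelihood tail exponent
  α̂ = n / Σᵢ log(xᵢ / k̂) and k̂ = min(xᵢ). For comparison on the rank
  axis, the fitted Pareto is re-expressed through its quantile rank-size
  profile x_r = k (n/r)^(1/α).

The models are compared by residual sum of squares on the rank grid (AIC
optional). Per-category 95% prediction intervals use the t-based interval
for one future annual observation, mean ± t₀.₉₇₅,ₙ₋₁ · s · √(1 + 1/n),
clipped at zero.

The cumulative coverage curve identifies the minimal top-rank prefix
covering a target share (default 80%) of admissions, and reports whether the
ten most frequent categories alone cover ≥ 80% — the classic
community-diagnosis ("pure Pareto", 80/20) criterion.

Because hospital registries cannot be shipped, the package includes a
first-class synthetic generator producing multi-year admission streams with
a known ground-truth law (exponential or Pareto), Poisson year-to-year
noise, and a configurable Z-chapter contamination fraction — so the entire
pipeline is testable end to end.

## Worked example

```python
from emergepi import GroundTruthLaw, SimulationConfig, PipelineConfig, run_pipeline

law = GroundTruthLaw(family="exponential", n_categories=120, b0=1200.0, b1=0.1)
sim = SimulationConfig(
    law=law,
    years=list(range(2015, 2021)),
    population_per_year={y: 315_000.0 for y in range(2015, 2021)},
    z_fraction=0.027,
    noise="poisson",
    seed=7,
)
manifest = run_pipeline(PipelineConfig(output_dir="demo_out", simulate=sim, seed=7))

counts = manifest["counts"]
print(f"admissions: {counts['input']}, Z-excluded: {counts['z_excluded']}, "
      f"retained: {counts['retained']}")
overall = next(s for s in manifest["scopes"] if s["scope"] == "all")
print(f"categories: {overall['n_categories']}, preferred law: {overall['preferred_model']}")
print(f"vital few (80% of admissions): {overall['n_vital_few']} categories, "
      f"top-10 share: {overall['top10_share']:.1%}")
print(f"year-to-year rank stability (mean Spearman): {overall['rank_stability_mean']:.3f}")
```

prints

```
admissions: 70326, Z-excluded: 1930, retained: 68396
categories: 93, preferred law: exponential
vital few (80% of admissions): 17 categories, top-10 share: 63.1%
year-to-year rank stability (mean Spearman): 0.971
```

Reading the output: of 70,326 simulated admissions over six years, 1,930
carried a Z-chapter code and were excluded. The ranked profile of the
remaining 68,396 is better described by the exponential law (as it should
be — that is the generating law), the ordering of diagnoses is highly
reproducible from year to year (mean pairwise Spearman ρ = 0.971), and 17
of 93 observed categories already cover 80% of the case load. The top-10
share of 63.1% falls short of the 80% community-diagnosis criterion —
expected for a whole-hospital case mix, which is broader than any single
specialty's.

The pipeline writes `frequency_table.csv`, `ranked_profile.csv`,
`fits.json`, `comparison.json`, `vital_few.csv` and a reproducibility
`manifest.json` into the output directory, with per-chapter-group and
per-roster-arm results under `scopes/`.

The same analysis is available from the shell:

```bash
emergepi simulate --n-categories 120 --b0 1200 --seed 7 --z-fraction 0.027 --out stream.csv
emergepi analyze --input stream.csv --population 315000 --outdir analysis/
emergepi fit --profile analysis/ranked_profile.csv --out fits.json
emergepi vital-few --profile analysis/ranked_profile.csv --outdir vf/
emergepi run-all --config pipeline.yaml
```

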