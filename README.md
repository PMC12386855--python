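# sitdemog

Demographic efficacy analysis for sterile-insect-technique (SIT / boosted-SIT)
cage trials against container-breeding mosquitoes. The package implements the
full analysis pipeline for a 5-treatment × 4-replicate semi-field design
(control, SIT 1:1, SIT 5:1, and the pyriproxyfen-boosted variants):

- **`trial_model`** — domain types, CSV/YAML schemas and validation for the
  four trial tables (cohorts, interval-censored stage events, trap-water
  concentrations, design layout).
- **`synthetic_data`** — a seeded synthetic-trial generator with
  competitiveness-consistent hatch suppression, a two-stage daily
  competing-risk chain observed only at examination days, logit-scale
  between-cage overdispersion, and zero-augmented / outlier-contaminated
  water concentrations with a log-logistic emergence-inhibition curve
  anchored at EI50 = 0.20 and EI95 = 0.67 ppb.
- **`demography`** — aggregation of interval-censored events and the
  corrected emergence probability
  `Pa = n_meta / (e_meta − (l_death + n_death)/2)`.
- **`bayes_binomial`** — Bayesian mixed-effect binomial logistic regression
  (treatment fixed effect + observation-level random intercept) with a
  built-in deterministic slice-within-Gibbs sampler (numba-accelerated),
  posterior draw matrices per cage-cohort, treatment aggregation, credible
  summaries, and separation / Hauck–Donner diagnostics.
- **`efficacy`** — sterile-male competitiveness (Fried index), the
  hatch × emergence posterior product, relative risks of adult emergence
  with 95% credible intervals, and the posterior simulation test for
  efficacy loss between boosted and non-boosted arms.
- **`pyriproxyfen_glm`** — zero-augmented (hurdle) gamma regression with a
  log link for trap-water concentrations, likelihood-ratio and Wald tests,
  and robust outlier flagging.
- **`quality_control`** — rearing-quality hatch / flight-test escape
  probabilities against the 0.70 threshold.
- **`pipeline` / `cli`** — end-to-end orchestration with a single-seed
  substream policy; identical seeds give byte-identical JSON reports.

## Command line

```sh
sit-demog simulate --seed 1 --out trial/              # write the four tables
sit-demog fit --table trial/cohorts.csv --response hatch \
    --draws 10000 --seed 1 --out hatch                # posterior .npz + .json
sit-demog fit --table trial/cohorts.csv --response emergence \
    --draws 10000 --seed 1 --out emergence
sit-demog efficacy --hatch hatch.npz --emergence emergence.npz --out eff.json
sit-demog water --table trial/water.csv --model "~ s2f" --out water.json
sit-demog qc --table qc.csv --out qc.json
sit-demog report --data-dir trial/ --seed 1 --out report/   # analyze a dataset
sit-demog all --seed 1 --out run/                     # simulate + everything
```

`sit-demog all` writes `report.json` (machine-readable, full precision) and
`report.txt` (rounded, treatments ordered most-to-least effective) plus the
simulated data tables.

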