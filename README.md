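# addikit

Scoring and validation toolkit for the Autoinflammatory Disease Damage Index
(ADDI) — the damage instrument for the four main monogenic autoinflammatory
diseases (FMF, CAPS, TRAPS, MKD): 18 items in 8 capped categories, maximum
total 27 points.

The package provides:

- **`addikit.instrument`** — the canonical instrument as data (bundled
  `addi_v1.yaml`): categories with point caps, graded/ungraded items,
  applicability markers (paediatric-only, female-relevant), YAML/JSON
  serialization and a JSON Schema for third-party validation.
- **`addikit.scoring`** — the scoring engine: damage-eligibility filtering
  (≥ 6 months' presence, not attributed to ongoing disease activity, onset
  after disease onset), glossary-faithful measurement graders (GFR
  thresholds, urine protein ratios, growth criteria, audiometry, ocular and
  bone-density rules), category capping and total computation. Evidence can
  be asserted (a grade label) or measured (raw clinical values).
- **`addikit.psychometrics`** — one-way random-effects ICC (single
  measures, absolute agreement) for the observer-nested-within-subject
  design with unbalanced groups and F-pivot 95% CIs; Cronbach's alpha with
  interitem correlation matrices; Spearman rank correlation with Fisher or
  bootstrap CIs; per-case mean aggregation.
- **`addikit.synthetic_data`** — a synthetic study simulator: case sets
  with per-disease item prevalence profiles (every item represented a
  configurable minimum number of times), nested rater-group allocation, a
  misclassification rater model, PGA damage/activity scales, and bisection
  calibration of the noise scale to a target ICC.
- **`addikit.pipeline`** — the full validation analysis on a rating table:
  reliability at overall / per-disease / per-category / per-item
  granularity, PGA reliability, construct validity on per-case means, and
  interitem redundancy screening (> 0.7 flags).
- **`addikit.cli`** — the `addi` command.

## CLI

```sh
# dump the canonical instrument (yaml | json | schema)
addi instrument-dump --format yaml

# score case records (JSON or flat CSV)
addi score cases.json --out scores/

# simulate a full synthetic validation study (110 cases, 11 groups x 4 raters)
addi simulate --seed 42 --out study/

# ... optionally calibrated to a target reliability
addi simulate --seed 42 --target-icc 0.85 --out study/

# run the reliability / construct-validity analysis
addi validate study/ratings.csv --out report/
```

Every command writes a `manifest.json` (inputs with SHA-256 hashes, seeds,
config echo, tool version). Exit codes: `0` success, `2` input validation
failure, `3` design/calibration infeasibility. All outputs are plain
CSV/JSON/YAML.

`addi simulate` accepts a YAML config with `design:`, `rater_model:` and
`calibration:` sections mirroring the `StudyDesign`, `RaterModel` and
`calibrate_noise_to_icc` parameters; `addi validate --config` accepts
`min_raters`, `ci_alpha`, `redundancy_threshold`, `spearman_method`,
`spearman_seed` and `pga_reliability_gate`.

## Notes

- The rating design nests raters within case blocks, so raters are not
  crossed with cases; the one-way random-effects ICC(1) is the only
  identifiable model, and consistency/absolute-agreement coincide in it.
  Negative ICC estimates are reported unclipped.
- Per-disease reliability is computed on total scores; per-item reliability
  is computed across all diseases.
- The simulator's prevalence profiles and rater misclassification model are
  synthetic stand-ins chosen for plausibility; they are labelled as such in
  the ground-truth output and make no epidemiological claims.
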