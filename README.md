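# emobias

Analysis pipeline for perceptual bias in two-alternative (happy/angry)
emotion judgments of morphed faces.

Given trial-level judgment tables on a signed morph continuum (angry
negative, happy positive) and participant metadata (social-anxiety group,
questionnaire scores), the package runs the full analysis chain:

1. **I/O & validation** (`emobias.io`) — schema-checked CSV trial and
   participant tables; structured JSON + CSV reports.
2. **Quality control** (`emobias.qc`) — inclusion rules: ≥ 30 valid
   (non-omitted) trials, and consistent judgments at the ±80% extremes
   (≥ 75% "happy" at +80, ≤ 25% "happy" at −80); auditable exclusion
   ledger.
3. **Psychometric fitting** (`emobias.psychometric`) — binomial
   maximum-likelihood fit of a cumulative-normal function per participant
   (deterministic grid initialization + bounded Nelder-Mead), yielding the
   point of subjective equality (PSE, the morph level judged happy and
   angry equally often) and the slope of the function at the PSE, plus
   deviance goodness of fit and optional bootstrap CIs.
4. **Group inference** (`emobias.inference`) — skew/kurtosis screens,
   square-root transform, Levene's variance test, Student/Welch two-sample
   t-tests with a Levene gate, pooled-SD Cohen's d.
5. **Moderation analysis** (`emobias.moderation`) — two-step hierarchical
   OLS regression of PSE (and slope) on group, centered negative affect,
   and their interaction, with HC3 robust standard errors, ΔR² F-change,
   standardized β, and simple slopes at ±1 SD of the moderator.
6. **Synthetic observers** (`emobias.simulate`) — guess/lapse-augmented
   cumulative-normal observers and whole cohorts with a known
   group × negative-affect structure, so every stage can be verified
   against ground truth.

## CLI

```sh
# full reproducible run on a simulated cohort
emobias run --config examples/run.yaml --seed 1 --out out/

# or stage by stage
emobias simulate --config examples/cohort.yaml --seed 1 --out data/
emobias qc       --trials data/trials.csv --out qc_ledger.csv
emobias fit      --trials data/trials.csv --qc qc_ledger.csv --out fits.csv
emobias analyze  --fits fits.csv --participants data/participants.csv --out out/
emobias report   --report out/report.json
```

Outputs: `report.json` (complete structured report, deterministic for a
given config + seed), CSV side tables (`fits.csv`, `qc_ledger.csv`,
`group_tests.csv`, `moderation.csv`, `simple_slopes.csv`) and a
`manifest.json`. Exit codes: 0 success, 1 stage failure, 2 usage error.

## Data formats

Trial table (CSV): `participant_id,trial_index,morph_level,face_id,response`
with `morph_level ∈ {−80,−40,−20,−10,0,10,20,40,80}` and
`response ∈ {happy, angry, omitted}`.

Participant table (CSV):
`participant_id,sa_status,bfne_s,dass_depression,panas_pa,panas_na,age,gender`
with `sa_status ∈ {HSA, LSA}` consistent with the BFNE-S cutoffs
(HSA ≥ 25, LSA ≤ 12); empty fields mean missing.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests for the model
invariants, and `tests/test_acceptance.py` with one test per acceptance
criterion (parameter recovery, grid-oracle dominance of the MLE,
moderation type-I calibration, simple-slope power pattern, QC boundary
semantics). The full run takes ~2 minutes on one CPU.

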