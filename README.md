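# catex — catastrophic healthcare expenditure analysis

`catex` is a Python toolkit for the standard health-financing question: *what
share of households is financially devastated by paying for care out of
pocket, and which household characteristics drive that risk?*  It implements
the WHO capacity-to-pay methodology for **catastrophic healthcare
expenditure (CHE)** together with the regression stage used to study its
determinants, and ships a synthetic household-survey generator with known
ground-truth effects so every step can be validated end to end.  It is aimed
at health economists and epidemiologists analysing household expenditure
microdata — in particular surveys of households caring for a person with a
mental disorder, the setting its defaults emulate.

## The statistic

For each household *h* with annualized total expenditure THE<sub>h</sub>,
food expenditure food<sub>h</sub>, and out-of-pocket health spending
OOP<sub>h</sub> (consultations + hospitalizations + medicines + diagnostic
tests + transport):

1. **Equivalized size** — eq<sub>h</sub> = size<sub>h</sub><sup>β</sup>,
   β = 0.56, converting members into equivalent adults.
2. **Poverty line** — *pl* = mean of food<sub>h</sub>/eq<sub>h</sub> over
   households whose food share food<sub>h</sub>/THE<sub>h</sub> lies in the
   45th–55th percentile window of the sample.
3. **Subsistence expenditure** — SE<sub>h</sub> = *pl* · eq<sub>h</sub>.
4. **Capacity to pay** — PC<sub>h</sub> = THE<sub>h</sub> − SE<sub>h</sub>;
   if negative (household below estimated subsistence), the poverty line is
   replaced by the household's own food spending:
   PC<sub>h</sub> = THE<sub>h</sub> − food<sub>h</sub>.
5. **CHE flag** — CHE<sub>h</sub> = 1 iff OOP<sub>h</sub>/PC<sub>h</sub> ≥ z
   (closed boundary), headline threshold z = 0.30, with a sensitivity sweep
   over z ∈ {0.10, 0.20, 0.30, 0.40}.
6. **Incidence** — E = 100 · Σ CHE<sub>h</sub> / N, with a Wilson 95% CI.

The determinants stage fits a logistic regression of CHE<sub>h</sub> on
household covariates (income, hospitalization and medicine spending in
1000-peso units, household size, patient sex and employment, caregiver
missed work days), reports **average marginal effects** so coefficients read
as probability changes, and fits the **linear probability model** (OLS, HC1
robust errors) alongside — defensible because CHE prevalence is mid-range.
Bidirectional stepwise selection on Wald p-values and Pearson chi-square
subgroup tests complete the stage.

## Worked example

```python
from catex import ScenarioConfig, annualize, decompose, sensitivity_analysis, simulate_households

ds = annualize(simulate_households(ScenarioConfig()))   # 387 households
pl, dec = decompose(ds)
print(pl.value_per_eq_adult, dec["substitution_applied"].mean())
print(sensitivity_analysis(ds))
```

prints (see `examples/02_che_statistic.py`):

```
poverty line: 12,937 MXN/year per equivalent adult (39 reference households)
substitution rule applied to 10.1% of households (spending below estimated subsistence)

incidence by threshold (share of households whose OOP health
spending reaches the given fraction of capacity to pay):
  z = 10%:  75.5%  [Wilson 95% CI 70.9, 79.5]
  z = 20%:  53.5%  [Wilson 95% CI 48.5, 58.4]
  z = 30%:  36.4%  [Wilson 95% CI 31.8, 41.3]
  z = 40%:  24.3%  [Wilson 95% CI 20.3, 28.8]
```

The poverty line is the estimated annual subsistence cost per equivalent
adult; about one household in ten spends below its estimated subsistence
level, so its capacity to pay falls back to non-food spending; and 36% of
these simulated households devote at least 30% of their capacity to pay to
out-of-pocket care — catastrophic spending under the headline definition.
Incidence falls monotonically as the threshold rises.

The other scripts in `examples/` walk through simulation
(`01_simulate_survey.py`), the regression stage with AME-vs-OLS comparison
and stepwise selection (`03_determinants.py`), incidence calibration and
counterfactual ground truth (`04_calibration_and_ground_truth.py`), and the
orchestrated pipeline (`05_full_pipeline.py`).  A thin CLI wraps the same
functions:

```bash
catex simulate --n 387 --seed 1 --out survey.csv
catex che survey.csv --outdir che_out
catex determinants survey.csv --stepwise --outdir det_out
catex run --scenario examples/paper_like_scenario.yaml --outdir run_out
```

## Layout

- `src/catex/io_model.py` — survey schema, CSV validation, annualization,
  currency conversion
- `src/catex/che_core.py` — the CHE statistic (poverty line → capacity to
  pay → flags → incidence)
- `src/catex/determinants.py` — logit + AME, linear probability model,
  stepwise selection, chi-square tests
- `src/catex/synthetic_data.py` — scenario generator, incidence
  calibration, Monte-Carlo ground truth
- `src/catex/pipeline.py`, `src/catex/cli.py` — orchestration and the
  command line
- `docs/methods.md` — modelling assumptions, parameter defaults, numerical
  choices, and known limitations
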