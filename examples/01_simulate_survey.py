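"""Simulate a study-scale household survey and write it as CSV.

The default scenario emulates 387 households caring for a psychiatric
outpatient: lognormal monthly income averaging ~US$338, 74% male patients,
a diagnosis mix led by schizophrenia, and five out-of-pocket (OOP) spending
components with mass at zero and right-skewed positive amounts.
"""

from pathlib import Path

from catex import ScenarioConfig, convert_currency, oop_total, simulate_households, write_survey

cfg = ScenarioConfig()
ds = simulate_households(cfg)

outdir = Path("scratch/examples")
outdir.mkdir(parents=True, exist_ok=True)
write_survey(ds, outdir / "survey.csv")

frame = ds.frame
usd = convert_currency(frame["income"], ds.convention, "USD")
print(f"households simulated:        {ds.n}")
print(f"mean monthly income:         US${usd.mean():.1f} (sd {usd.std():.1f})")
print(f"male patients:               {frame['patient_sex'].eq('male').mean():.0%}")
print(f"median monthly OOP spending: {oop_total(frame).median():.0f} MXN")
print(f"households with any OOP:     {(oop_total(frame) > 0).mean():.0%}")
print(f"wrote {outdir / 'survey.csv'}")
# Each row is one household: money aggregates, the five OOP components,
# and patient/caregiver covariates, all monthly MXN as surveyed.
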