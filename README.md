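# pahrisk

Dietary exposure and cancer-risk assessment for polycyclic aromatic
hydrocarbons (PAHs) in food, built around fish-surveillance data. The
package takes per-sample analyte concentration tables (or published group
summaries), collapses the 16 priority PAHs to a benzo[a]pyrene-equivalent
concentration via toxicity equivalency factors, converts it to an estimated
daily intake, and propagates input uncertainty into an incremental lifetime
cancer risk with a seeded Monte Carlo engine. It is aimed at food-safety
and exposure-assessment practitioners who need the full chain — descriptive
statistics, EU-limit compliance, risk percentiles — reproducible from a
single seed.

## The model

For an analyte profile `C_i` (µg/kg wet weight) and TEFs `TEF_i`
(benzo[a]pyrene ≡ 1):

```
BEC  = Σ_i C_i · TEF_i                        [µg BaP-eq / kg]
EDI  = BEC_mg · IR · (EF · ED) / (BW · AT)    [mg / kg bw / day]
ILCR = EDI · SF                               [dimensionless]
```

with IR the fish intake (kg/day), EF the exposure frequency (days/year),
ED the exposure duration (years), BW the body weight (kg), AT the averaging
time (days; lifetime for carcinogens) and SF the oral slope factor
(7.3 (mg/(kg·day))⁻¹ for BaP). ILCR below 10⁻⁶ is negligible, between
10⁻⁶ and 10⁻⁴ acceptable, above 10⁻⁴ of concern.

Because per-fish raw data for the calibration survey were never released,
the package ships the survey's published per-group summary statistics
(mean/median/min/max/SD for 16 analytes × 5 fish species × 4 cooking
methods) as fixtures, plus a synthetic-data generator that moment-matches
truncated-normal (or lognormal/uniform/triangular) distributions to any
summary row and draws reproducible per-sample tables from them.

## Worked example

```python
import pahrisk as pr

table2 = pr.load_fixture("table2_all")          # pooled published summary
medians = {r["analyte"]: r["median"] for _, r in table2.iterrows()
           if r["analyte"] in pr.CANONICAL}

res = pr.bec(medians, pr.builtin_tef())         # TEF collapse
params = pr.ExposureParameters.adults()         # IR 20 g/day, BW 70 kg, ...
e = pr.edi(pr.to_mg_per_kg(res.total), params)
print(f"BEC  = {res.total:.4f} ug/kg")
print(f"EDI  = {e:.3e} mg/kg bw/day")
print(f"ILCR = {pr.ilcr_from_edi(e, params.SF):.3e}")
```

prints

```
BEC  = 2.6569 ug/kg
EDI  = 7.591e-07 mg/kg bw/day
ILCR = 5.542e-06
```

i.e. the pooled median profile is worth ≈ 2.66 µg/kg of pure BaP
(dibenz[a,h]anthracene and BaP dominate, 47.8% and 37.6% of the total),
the lifetime-averaged adult dose is ≈ 7.6 × 10⁻⁷ mg/kg bw/day — far below
the WHO 10 ng/kg bw/day BaP screening value — and the deterministic adult
ILCR of ≈ 5.5 × 10⁻⁶ sits in the acceptable band. The probabilistic
version, `pr.default_simulation(seed=1, iterations=10_000)`, gives an
adult 95th-percentile ILCR of ≈ 9.9 × 10⁻⁶ (children ≈ 4.9 × 10⁻⁵), both
classified acceptable.

The same pipeline is available from the shell:

```
pahrisk bec                     # BEC breakdown of the pooled fixture
pahrisk run --seed 1 --out out/ # full report bundle (CSV + JSON + log)
pahrisk generate --fixture table3_by_species --n 3 --seed 1 --out synth.csv
```

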