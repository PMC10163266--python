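# dustrisk

Health-risk and ecological-impact assessment of heavy-metal-laden dust, for
environmental scientists studying dust storms in arid regions. Given a
per-site table of element concentrations in settled dust (mg/kg), a daily
PM₂.₅/PM₁₀ series from a monitoring station, and inhalation toxicity
reference values, the package computes the US EPA inhalation risk chain per
site and receptor class (adult, child aged 2–6), plus an endpoint
characterization of the particles' environmental impact.

## The model

Inhalation is taken as the dominant exposure route during dust events. For
each element *i* the average daily intake is

    ADI_i = C_i · (C_PM10 / 1000) · InhR · EF · ED / (BW · AT · 10⁶)   [mg/kg-day]

where C_i is the element concentration in dust (mg/kg) and C_PM10 the
exposure-point concentration of PM₁₀ (µg/m³) — by default the one-sided
Student-t 95% upper confidence limit of the series mean, the "reasonable
maximum exposure" convention. Non-carcinogenic risk uses the reference dose
RfD_i = RfC_i · InhR/BW, the hazard quotient HQ_i = ADI_i/RfD_i, and the
hazard index HI = Σ HQ_i (HI > 1 flags risk). Carcinogenic risk uses the
inhalation unit risk: CR_i = ADI_i · IUR_i · 10³ · BW/InhR, summed over
carcinogens, with bands at 10⁻⁶ (acceptable) and 10⁻⁴ (tolerable ceiling).
Total chromium is speciated 1:6 into Cr(VI):Cr(III) before any risk
computation, so the hexavalent fraction is 1/7 of measured Cr.

Endpoint characterization multiplies each sample's elemental inventory
(per 1 g of particles, emitted to air) by endpoint characterization factors
and aggregates into five categories — human carcinogenic and
non-carcinogenic toxicity (DALY), freshwater/marine/terrestrial ecotoxicity
(species.yr) — and two endpoint totals.

Two assessment conventions are built in: `strict` applies the equations
above literally per receptor; `replicate` reproduces the internal
child/adult ratios of published site tables from this study design
(HI ratio 4.44, CR ratio 11.97) by fixing RfD and the BW/InhR factor at
their adult values and averaging the child's carcinogenic intake over its
non-carcinogenic averaging time. See `docs/methods.md` for why both exist.

A seeded synthetic-campaign generator (`dustrisk.synthgen`) produces
crustal-dominated log-normal compositions over multiple sites and spiky PM
series with dust-event days, so the whole pipeline is testable without any
field data.

## Worked example

```python
import dustrisk as dr

comp, pm = dr.generate_campaign(dr.default_config(seed=1))  # 11 sites, 150 days
s = dr.summarize_guideline_exceedance(pm)
print(f"PM10 days above WHO guideline: {s.exceed_days_pm10}/{s.n_days}")
results = dr.InhalationRiskModel(comp, pm, mode="replicate").fit()
print(results.summary())
```

prints (abridged):

```
PM10 days above WHO guideline: 111/150
mode: replicate    EPC method: t_ucl95
C_PM10 (exposure-point): 102.1 ug/m3  (n=150)
thresholds: HI > 1; CR bands at 1e-06 / 0.0001
sample receptor    hi cr_total hi_band      cr_band
    D1    adult  3.02 1.61e-05    risk    tolerable
    D1    child  13.4 0.000193    risk unacceptable
    ...
    D8    adult  0.79 6.32e-06 no_risk    tolerable
   D11    child  6.33 0.000113    risk unacceptable
```

Most of the campaign's PM₁₀ days exceed the WHO 24-h guideline (45 µg/m³);
the exposure-point concentration is 102 µg/m³. Hazard indices above 1 flag
non-carcinogenic risk — children exceed it at every site because the
replicate convention scales their intake by (InhR/BW)_child/(InhR/BW)_adult
= 4.44. Total cancer risks all exceed the 10⁻⁶ acceptability level; several
child values pass the 10⁻⁴ tolerable ceiling. The note columns of the full
summary list elements skipped for missing reference values — they are never
silently zeroed.

The same workflow is available from the shell:

```sh
dustrisk simulate --seed 1 -o campaign/
dustrisk risk --composition campaign/composition.csv --pm campaign/pm_series.csv \
              --mode replicate -o report.csv
dustrisk impact --composition campaign/composition.csv -o impacts.csv
```

Bundled toxicity reference values and characterization factors are
demonstration snapshots (see the headers of `src/dustrisk/data/*.csv`);
supply your own tables for regulatory work.

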