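# Methods

## Scope and model

The package assesses inhalation exposure to heavy metals carried by dust,
per sampling site and receptor class, and characterizes the endpoint
environmental impact of the particles. The exposure model treats whole-PM₁₀
mass as the carrier of whole-dust metal concentrations: the intake equation
multiplies the element's concentration in settled dust (mg/kg) by the PM₁₀
exposure-point concentration with no size-fraction partitioning of the
metals. Dermal and ingestion routes are out of scope, as is any
source-apportionment or atmospheric transport modeling.

Pipeline order matters and is fixed: exposure-point concentration →
chromium speciation → per-element daily intake (both averaging-time kinds)
→ hazard quotients/index and cancer risks/total → classification.

## Exposure-point concentration

The "reasonable maximum exposure" concentration of PM₁₀ is estimated once
per campaign from the station series and shared across sites (the study
design this emulates used a single station for all sites). The default
estimator is the one-sided Student-t 95% UCL of the arithmetic mean,
mean + t₀.₉₅,ₙ₋₁·s/√n — the baseline recommendation for approximately
normal data; `mean` and `max` are exposed as alternatives and the method
used is recorded in every report. The estimator is undefined at n < 2
(no dispersion estimate) and equals the mean in the zero-variance limit.
More elaborate UCL families (Chebyshev, bootstrap-t, land-H) are deliberate
non-goals; for the strongly skewed series the generator produces, the
t-UCL is mildly anti-conservative, which is documented rather than patched.

## Chromium speciation

Toxicity differs so sharply between Cr(VI) and Cr(III) that total-Cr has no
reference entry of its own in the bundled table. Total chromium is split by
a fixed Cr(VI):Cr(III) ratio, default 1:6 (hexavalent fraction 1/7),
configurable per run. The split conserves mass by constructing Cr(III) as
the remainder.

## Risk equations and boundary conventions

* RfD = RfC · InhR/BW; HQ = ADI_nc/RfD; HI = exact sum of HQs.
* CR = ADI_ca · IUR · 10³ · BW/InhR; total CR = exact sum over carcinogens.
* HI classification is strict: risk iff HI > 1. Cancer-risk bands are
  inclusive at both edges: acceptable iff CR ≤ 10⁻⁶ ("at or lower than"),
  tolerable iff CR ≤ 10⁻⁴, unacceptable above. All thresholds are
  configurable through `Thresholds`.
* Elements lacking an RfC are omitted from HI, those lacking an IUR from
  CR — always with a logged, counted warning carried in the report, because
  silent zeros would bias HI/CR downward invisibly.
* Sums use compensated summation (`math.fsum`) so the report invariants
  HI = Σ HQ and CR_total = Σ CR hold exactly, independent of element order.

## The two assessment modes

In `strict` mode each receptor uses its own parameters throughout. Two
algebraic consequences follow and are property-tested: BW and InhR cancel
between the intake and cancer-risk formulas, leaving the closed form
CR = C_i·C_PM10·EF·ED·IUR/(AT_ca·10⁶); and whenever AT_nc = ED·365 (true of
both bundled receptors) ED cancels too, making HQ identical for every
receptor. Literal application therefore predicts equal adult and child HI,
and child CR = ED_c/ED_a = 6/26 of adult CR.

Published site tables from this study design show a different, internally
exact structure: HI_child/HI_adult ≈ 4.44 = (InhR/BW)_c/(InhR/BW)_a and
CR_child/CR_adult ≈ 11.97 at every site. `replicate` mode reproduces that
convention: one adult-derived RfD and one adult BW/InhR factor are applied
to every receptor, and each non-reference receptor's carcinogenic intake is
averaged over its non-carcinogenic averaging time (2190 d for the child)
while the adult keeps the 70-year averaging time. With those choices the
two ratios are exactly 40/9 = 4.444… and
(12.5·6·80·25550)/(15·2190·15·26) = 11.9658…, matching every published row
pair within print precision. This is an inference from the tables'
structure, not a claim about the original authors' intent; neither mode is
labeled "correct", and reports echo which one produced them.

## Endpoint characterization

For each impact category c, impact_c = Σ_i C_i·m·10⁻⁹·CF_{i,c}, where m is
the particle mass basis in grams (default 1) and 10⁻⁹ converts
mg/kg·g to kg emitted. The emission compartment is fixed to air. The two
human categories (DALY) and three ecotoxicity categories (species.yr) sum
exactly into the two endpoint totals. In realistic compositions the
freshwater and marine contributions sit ~3 orders of magnitude below the
terrestrial one, so at 3-significant-figure display the ecological total
coincides with the terrestrial value; the implementation always sums all
three. Characterization factors are input data: the bundled set only has
field-plausible magnitudes (it is labeled non-authoritative in the file
header) because real endpoint factor tables are externally licensed
artifacts, and midpoint-to-endpoint derivation is a non-goal.

## Reference data

Exposure defaults are the US EPA residential values: adult
InhR 15 m³/d, EF 350 d/y, ED 26 y, BW 80 kg, AT 9490/25550 d; child (2–6 y)
InhR 12.5, ED 6, BW 15, AT 2190/25550. The bundled RfC/IUR table is a
pinned, dated snapshot with a provenance column, because screening-level
toolkits are living resources and reproducibility across revisions requires
freezing; any element can be overridden from a user CSV. Below-LOD
concentration cells default to LOD/2 substitution (the common
risk-assessment convention; `zero` and `keep` policies are available), and
the below-LOD flag survives ingest.

## Synthetic campaign generator

The generator emulates the statistical structure the analysis assumes, not
any particular measured dataset. Element concentrations are log-normal —
the standard model for strictly positive, right-skewed environmental
concentrations — with a geometric mean and GSD per element and a
multiplicative offset per site; the default panel is crustal-dominated
(Fe/Ca/Al/K/Mg at 1–6% levels, trace metals at 0.3–600 mg/kg, GSD 1.4–2.0)
over 11 sites in five cities with offsets 0.8–1.3, one composite sample per
site. The PM model draws log-normal baseline days (geometric means
40/55 µg/m³ for PM₂.₅/PM₁₀, GSD 1.6) and multiplies dust-event days
(Bernoulli p = 0.2 over a 150-day campaign) by a factor of 4, which yields
campaign means near 57/89 µg/m³ with maxima several hundred µg/m³ and most
days above the WHO 24-h guidelines — the regime of an arid-basin dust
season. PM₂.₅ is clipped to PM₁₀ per day after event scaling.

Seeding contract: each element (and the PM block) draws from an independent
stream derived from the root seed and a hash of its name, so adding or
removing an element never perturbs the other streams. What the generator
does **not** emulate: temporal/spatial autocorrelation, correlated element
enrichment from shared sources, seasonal PM trends, measurement error and
censoring beyond an explicit below-LOD flag. Tests passing on generated
data therefore demonstrate the arithmetic chain and its invariances, not
calibration against field campaigns.

## Numerical and testing choices

Hand-checkable oracle values are frozen into the unit tests (e.g. the
t-UCL of {1,2,3} via a t-table, the intake of 100 mg/kg at 100 µg/m³ for
the adult profile); vectorized results are required to match a
longhand-arithmetic oracle to 10⁻¹² relative error on random inputs, and
the strict-mode cancellations to the same tolerance. The acceptance script
uses small problem sizes — 100 random oracle points, one 11-site × 20-element
× 150-day campaign, n = 500 for distributional recovery (within three
standard errors of the configured log-mean) — chosen as the smallest sizes
at which the statistical checks are stable.

## Known limitations

Bundled toxicity and characterization values are demonstration snapshots;
site risk numbers computed with them are not comparable to assessments made
with other reference tables, although mode ratios, classifications relative
to thresholds and all structural invariants are table-independent. No
Monte-Carlo uncertainty propagation, no age-integrated lifetime weighting
across receptors, no dermal/ingestion routes.
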