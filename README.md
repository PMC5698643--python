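# grousepheno

Climate–phenology–demography analysis for boreal forest grouse.

Long-term August brood surveys of capercaillie (*Tetrao urogallus*) and
black grouse (*T. tetrix*) are a standard instrument for monitoring
reproduction in Fennoscandian forests.  A central question for such series
is how warming springs move the onset of the boreal growing season, and
whether grouse breeding success tracks, ignores, or suffers from that
shift (the phenological "mismatch" question).  `grousepheno` implements
the full analysis chain as a tested, reusable pipeline for ecologists
working with daily weather series, lek-derived breeding dates and
pointing-dog survey records — plus a synthetic-data generator that
emulates such a study system end to end, so every stage can be exercised
and validated at desk scale.

## What it computes

**Phenological onsets** from a daily station series (lapse-rate adjusted
to the site): snow-free date (first snow score 0), frost-free date (first
day the centred 7-day mean of t_min exceeds 0 °C), and the "arrival of
summer" as the day the growing-degree-day sum GDD₅ (base 5 °C) reaches
200 — the point where bilberry shoot growth, host of the caterpillars
young chicks eat, is complete.

**Breeding windows** per species-year, anchored on capercaillie peak
mating: hatch = mating + 38 d, incubation 26 d; black-grouse dates lag by
+5/+8/+6 d (mating / incubation start / hatch).  Windows: 8 weeks
pre-hatch, 4 weeks pre-incubation, incubation, 4 weeks post-hatch.

**Demographic indices** from pooled survey blocks: breeding success
(chicks/female) = brood frequency (broods/females) × brood size
(chicks/brood), an identity the code maintains exactly.

**The regression battery**: OLS year trends with total change Δ = β × span
and an AIC comparison against AR(1)/AR(2) error structures; normalized
(β/mean) and log-ratio interspecific comparisons; slope-difference tests
t = (β₁−β₂)/√(se₁²+se₂²); temperature responses of each index over each
window; partial regressions controlling for √rodents and ln fox (β_p from
the multiple regression, r_p from residual-on-residual, equal by
Frisch–Waugh); lagged summer-temperature checks.

**Mismatch analysis**: the offset hatch − GDD₅=200 date per species-year,
with first/second-order polynomial fits of breeding success on the offset,
AICc model selection, and the optimum offset −b₁/(2b₂) for concave fits.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

```python
from grousepheno import SimulationConfig, simulate_bundle, run_study, response_battery
from grousepheno.pipeline import mismatch_analysis

bundle = simulate_bundle(SimulationConfig(), seed=11)   # 38-year synthetic study
tables = run_study(bundle)

print(tables.phenology.head(3).round(1).to_string(index=False))
row = response_battery(tables).query(
    "species=='capercaillie' and response=='brood_frequency' and window=='pre_inc4'"
).iloc[0]
print(f"cap brood frequency ~ pre-incubation t_min: "
      f"beta={row.beta:.3f} r={row.r:.2f} p={row.p:.3f} beta_p={row.beta_partial:.3f}")
print(mismatch_analysis(tables)[lambda d: d.selected].round(3).to_string(index=False))
```

prints

```
 year  snow_free_doy  frost_free_doy  gdd200_doy
 1979          108.0           111.0       157.0
 1980          104.0           107.0       159.0
 1981          100.0           105.0       147.0
cap brood frequency ~ pre-incubation t_min: beta=0.035 r=0.43 p=0.007 beta_p=0.035
     species  order    b0    b1     b2    r2     p  selected  optimum_offset
black_grouse      2 1.901 0.046 -0.003 0.135 0.080      True           8.809
capercaillie      1 1.315 0.013    NaN 0.024 0.356      True             NaN
```

Reading it: in this realisation spring arrives around day 100–110 and
summer (GDD₅ = 200) in early June; capercaillie brood frequency rises by
0.035 per °C of pre-incubation minimum temperature (r = 0.43, p = 0.007),
essentially unchanged after controlling for rodents and fox (β_p = 0.035) —
the temperature signal is not a predator-cycle artefact.  Any single
38-year realisation is noisy; replicate-averaged behaviour is what the
tests and the acceptance script characterise.

A command-line interface mirrors the stages
(`grousepheno simulate | phenology | windows | metrics | trends |
mismatch`); each command reads the documented CSV formats and writes
result tables to a directory.

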