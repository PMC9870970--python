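# crustpam

Analysis pipeline for **continuous chlorophyll *a* fluorescence monitoring
of biocrust-forming lichens under simulated warming**.

Biocrust lichens are poikilohydric: they are metabolically active only
while their thallus holds water, so *how long* conditions permit activity
— not just how favourable they are — drives their carbon balance.
Pulse-amplitude-modulated (PAM) fluorometry probes this continuously: a
weak measuring light records steady-state fluorescence `Ft` and a ~1 s
saturating flash records maximal fluorescence `Fm`, giving the PSII
quantum-use efficiency

```
φ_PSII = (Fm − Ft) / Fm
```

called **Yield** when measured in the light (PAR > 0) and **Fv/Fm** in
darkness. `crustpam` turns 30-minute monitoring records (lichen surface
temperature, relative moisture, PAR, `Ft`, `Fm`) from control and
open-top-chamber (OTC) warmed microcosms into:

1. **processed records** — instrument noise filtering (`Ft ≥ 10`,
   `Fm ≥ 50` units), efficiency computation, diurnal/nocturnal split at
   PAR = 0, and an activity flag at efficiency ≥ 0.1;
2. **daily statistics** — % activity per sensor × date × period, the
   variant restricted to photosynthesis-permitting light (PAR ≥ 70
   µmol m⁻² s⁻¹), microclimate means, activity-conditioned temperature,
   and positive-only efficiency means;
3. **mixed-effects inference** — treatment × season binomial GLMMs on
   (active, total) record counts and Gaussian LMMs on daily means, all
   with a microcosm random intercept, Tukey-style single-step contrasts
   and compact letter displays, plus per season × period GLMMs linking
   activity to temperature or moisture and their treatment interactions.

A seeded **synthetic campaign generator** reproduces the statistical
structure of the reference field design — 6 sensors (3 control /
3 warming), 48 records/day for the 247-day autumn-to-spring campaign,
diel and seasonal temperature and PAR cycles, rain and early-morning dew
wetting with temperature-accelerated exponential drying, and
hydration-gated fluorescence — so every downstream stage is testable
without any field data. The random-intercept binomial GLMM is estimated
in-house by adaptive Gauss–Hermite quadrature (verified against
`lme4::glmer` in the test suite) because no maximum-likelihood
implementation exists in the scientific Python stack.

## Worked example

```sh
python analysis/01_simulate_campaign.py --seed 1
python analysis/02_process_fluorescence.py
python analysis/03_daily_activity.py
python analysis/04_mixed_models.py
```

The drivers print, for seed 1:

```
campaign: 2016-09-21 .. 2017-05-25 = 247 days
6 sensors x 247 days x 48 records/day -> 71136 records
...
2964 period summaries over 1482 sensor-days
  warming - control, mean_temperature (diurnal): +2.14 degC
  warming - control, mean_temperature (nocturnal): +0.12 degC
  warming - control, mean_moisture (diurnal): -5.25 %
  warming - control, mean_moisture (nocturnal): +3.36 %
  diurnal activity deficit, autumn: -4.44 % points
  diurnal activity deficit, winter: -2.57 % points
  diurnal activity deficit, spring: -9.12 % points
```

The recovered diurnal surface-temperature difference matches the
configured mean chamber offset (2.3 °C); nights are nearly unwarmed
(0.2 °C), as passive OTCs behave. Warming lowers diurnal % activity in
every season, and the deficit is largest in spring, when warm, bright
conditions make the thalli dry fastest and heat stress suppresses PSII
efficiency — the mechanism the pipeline is designed to quantify. Tables
behind these numbers land under `results/`.

The same stages are available as a CLI
(`crustpam simulate|process|summarize|model|run`); `crustpam run
--config run.yaml --seed 1 --out results/run` executes everything and
writes a manifest with the config hash and output checksums
(byte-identical on rerun). Field exports with different column names are
read via a column mapping
(`read_monitoring_csv(path, column_map={"temperature_c": "Temp"})`).

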