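# Methods

## The measurement and its processing

Each 30-minute record from one sensor head holds lichen surface
temperature `T` (°C), relative moisture `M` (%) at the thallus, incident
PAR (µmol m⁻² s⁻¹), and the saturation-pulse fluorescence pair: the
steady-state signal `Ft` under a weak modulated measuring light and the
maximal signal `Fm` during a ~1 s, 4000 µmol m⁻² s⁻¹ actinic flash.

Processing applies three rules, in order:

1. **Noise filter.** Readings below the instrument's basal-noise floors
   (`Ft < 10` or `Fm < 50` units) are emitted by dry, inactive thalli;
   such records keep no efficiency value. The floors are inclusive: a
   reading exactly at the threshold passes.
2. **Efficiency.** Retained pairs give the PSII quantum-use efficiency
   `φ = (Fm − Ft)/Fm`, clamped below at 0, hence always in `[0, 1)`.
   This is the standard saturation-pulse form and the only one
   compatible with the instrument's documented 0–0.8 output range; the
   variant with `Ft` in the denominator, which appears in some write-ups
   and is unbounded above, is selectable as
   `efficiency_formula="ft_denominator"` for fidelity experiments but is
   not the default. The value is labelled Yield when PAR > 0 and Fv/Fm
   when PAR = 0; the arithmetic is identical, only the physiological
   reading differs.
3. **Activity flag.** Efficiencies below 0.1 are treated as unclear —
   plausible instrument drift rather than real hydration — and marked
   inactive (the threshold itself passes). A record failing either rule
   is *inactive, not missing*: it stays in the daily denominator, since
   % activity is defined over all records available that day.

Days are split into diurnal (PAR strictly above 0) and nocturnal periods
by the measured light, not clock time. Daily summaries per
sensor × date × period report record/active counts, % activity, the
variant counting only records with PAR ≥ 70 µmol m⁻² s⁻¹ (the light
level that permits net photosynthesis in this system) in **both**
numerator and denominator — i.e. the fraction of
photosynthesis-permitting time actually used; the alternative
normalisation over all records is available via `par_variant="all"` —
microclimate means, mean temperature over active records only, and the
mean of strictly positive efficiencies (the daily Yield / Fv/Fm
convention). A sensor-day-period with no records yields no row rather
than a fabricated zero, so models never see artificial 0 % days.
Seasons default to astronomical boundaries (autumn 21 Sep–20 Dec,
winter 21 Dec–20 Mar, spring 21 Mar–20 Jun) and are configurable, since
meteorological conventions would shift days near 1 Dec / 1 Mar.

## Inference

The design is repeated daily measures on six microcosms (one sensor
each), so every model carries a microcosm random intercept.

- **% activity** is modelled as binomial counts (active, total) with a
  logit link — a percentage with a known denominator is binomial
  information, and modelling the counts keeps the weighting. The
  random-intercept binomial GLMM is estimated by maximum likelihood with
  **adaptive Gauss–Hermite quadrature** (15 nodes; each group's
  integrand recentred at its posterior mode and rescaled by the local
  curvature). At a zero variance estimate the likelihood collapses
  exactly to the ordinary GLM. Optimisation is L-BFGS-B over
  (β, σ ≥ 0), ftol 1e-9; standard errors come from the numerical
  observed information; Wald tests use the normal reference.
  Non-convergence and separation are flagged on the result, never
  silent. The estimator matches `lme4::glmer` (nAGQ = 15) to ~1e-5 on
  test fixtures.
- **Daily means** (microclimate, Yield, Fv/Fm) use Gaussian LMMs
  (statsmodels MixedLM, ML). When the random variance hits the zero
  boundary the profiled information is singular and the optimizer's
  GLS step can be unreliable, so the fit falls back to the exact
  boundary solution — ordinary least squares — and is flagged
  `singular random variance`.
- **Post-hoc contrasts** over treatment × season cell means use
  single-step multiplicity adjustment against the max-|z| distribution
  of the full contrast vector under its fitted covariance (the
  Tukey-contrast construction for mixed models, as in R multcomp),
  evaluated by a fixed-seed Monte-Carlo sample (200 000 draws) so
  results are reproducible; Holm is available as a covariance-free
  fallback. A compact letter display is built by insert-and-absorb;
  adjusted p-values are floored at the raw p.
- **Activity ~ microclimate** models are one binomial GLMM per
  season × period with fixed part Intercept + covariate +
  covariate × treatment; the interaction asks whether warming-grown
  thalli respond to microclimate differently. Daily covariates are
  averaged over all records of the period, not activity-qualified ones.

## The synthetic campaign generator

The generator emulates the *statistical structure* of the reference
experiment — it is a stochastic emulator, not a calibrated
micrometeorological model. Defaults (all exposed on `SimConfig`):

- **Design**: 3 control + 3 warming sensors, 48 records/day,
  21 Sep 2016 – 25 May 2017 (247 days).
- **PAR**: zero outside a seasonal dawn–dusk window (day length
  12 ± 2.9 h over the year, mid-latitude), a sine-power hump peaking at
  the seasonal clear-sky maximum (1200/900/1800 µmol m⁻² s⁻¹ for
  autumn/winter/spring) times a shared daily cloudiness factor in
  [0.25, 1].
- **Temperature**: seasonal means 12/6/17 °C with a 12 °C diel swing
  peaking at 14:00, a shared daily weather anomaly (sd 2.5 °C) and
  sensor noise (sd 0.6 °C). Warming sensors add the chamber offset
  while PAR > 0 — mean 2.3 °C, modulated by season
  (×0.75/0.45/1.95, diurnal-record-weighted mean ≈ 1), since passive
  OTCs heat most under strong sun — and 0.2 °C at night.
- **Wetting and drying**: at most one rain event per day
  (probability 0.30/0.30/0.25 by season, uniform time of day,
  saturating) plus pre-dawn dew (probability 0.35, reaching water
  status 0.55 — dew is brief and sub-saturating). The latent water
  status decays exponentially with e-folding time 10 h at 15 °C,
  shortened by ×3.5 per +10 °C (a Q10-style evapotranspiration law);
  the thallus counts as hydrated above 0.25. This one-parameter decay
  is the simplest structure that reproduces quick-and-short dew
  activity and the warming-accelerated morning dry-down.
- **Moisture**: a dry baseline (30 %) anti-coupled to the control-basis
  temperature anomaly, pulled toward 92 % in proportion to water
  status, with the chamber moisture offsets (−4.75 % by day, +3.16 %
  by night) on warming sensors, clipped to [0, 100].
- **Fluorescence**: hydrated steps draw `Fm` around 800 units
  (sd 20); the target efficiency is 0.6 (healthy Fv/Fm) at PAR = 0,
  declines as `exp(−7·10⁻⁴·PAR)`, and above 23 °C is suppressed by
  `exp(−1.0·(T − 23))` (heat stress); `Ft = Fm·(1 − φ)` plus measuring
  noise (sd 5). Dry steps emit floor readings strictly below the noise
  thresholds. Small persistent per-sensor offsets (0.1 °C, 1 %,
  0.015 Fv/Fm) give the random intercepts something real to absorb.
- **Reproducibility**: every stream is keyed by purpose and sensor off
  the single seed, so identical configs give byte-identical campaigns
  and structural parameters can be varied under matched noise (this is
  what makes the warming-monotonicity property testable pathwise).

With these defaults the campaign reproduces the structure the analysis
assumes: recovered diurnal/nocturnal warming offsets within ±0.3 °C of
2.3/0.2 °C, warming-lower diurnal activity in every season with the
largest deficit in spring (drying plus heat stress), near-unwarmed
nights, and nocturnal efficiency recovering the configured healthy
Fv/Fm. Dropout is off by default; a `dropout_rate` reproduces
incomplete campaigns (real deployments lose a handful of records to
start-up and outages, so readers must tolerate incomplete days).

What the generator does **not** emulate — and hence what passing tests
do not show about field data: no energy balance or radiative transfer
inside chambers, no soil-water uptake pathway, no autocorrelated
multi-day weather regimes, no freezing physiology (activity is not
suppressed at sub-zero temperatures), no instrument drift or
re-calibration, and wetting amplitudes/rates are order-of-magnitude
choices, not site estimates. Conclusions about estimator correctness
(oracle equivalences, recovery, type-I calibration) transfer to real
data; effect *sizes* do not.

## Verification experiments

The mixed-model layer is verified by simulation at fixed problem sizes,
chosen so that each check's sampling error is well inside its stated
tolerance: GLMM ≡ GLM and LMM ≡ OLS on boundary-variance data
(agreement to 1e-4); recovery of a −1.0 logit treatment effect at
30 sensors × 100 days (±0.2) and of a +2.0 Gaussian effect on
500 sensor-days with group sd 0.2 (±0.3); and the Wald type-I error of
the GLMM treatment test over 200 null replicates at 30 sensors ×
10 days, expected near the nominal 5 % (the normal-reference Wald test
is mildly anticonservative at few groups, which is why the null design
uses 30). Pipeline/oracle equivalence runs 50 seeded reduced campaigns
(2 sensors × 20 days) against independent per-record Python loops. The
reduced sizes keep the whole suite and the acceptance script within a
few minutes on one CPU while leaving the checks' power intact.

## Known limitations

- Wald inference with 6 microcosms is optimistic; the paper-scale
  design has few groups and no degrees-of-freedom correction
  (Kenward–Roger-style) is implemented.
- The GLMM supports a single random intercept — no random slopes,
  temporal autocorrelation, or crossed effects; the LMM inherits
  MixedLM's capabilities but the pipeline only requests intercepts.
- `summarize_campaign` loops over sensor-day groups in Python; at the
  reference scale (~3 000 groups) this costs under a second, but very
  large deployments would want a vectorised rewrite.
- The season rule must cover every campaign date; campaigns crossing
  into summer need an explicit extended rule.
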