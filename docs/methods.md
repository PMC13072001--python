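# Methods

## Scope and model

`sowcal` implements the computational chain of a respiration-chamber
balance trial on gestating sows: open-circuit indirect calorimetry, total
collection of feces and urine, the DE/ME/NE energy cascade with
retained-energy partition, difference-method ingredient energies, and
composition-based NE prediction equations. The packaged fixtures transcribe
the published ten-barley trial tables (composition; diet formulations with
28.9% substitution; per-diet energy balance; per-barley energy values) and
serve both as worked inputs and as regression anchors for the statistics.

## Calorimetry

Gas records carry *differential* volume fractions (exhaust minus inlet,
sign such that O₂ depletion and CO₂/CH₄ enrichment are positive) so that
concentration × flow integrates directly to consumption/production.
Integration is trapezoidal over half-open windows; it is exact for traces
that are piecewise linear between samples, which is also how the synthetic
generator emits them. Assumptions and their knobs:

- **Steady-state open circuit, no washout/lag correction.** A chamber
  volume × concentration derivative term is not modelled; at the study's
  sampling cadence and 24 h windows the transient contribution is
  negligible, but step changes at feeding would be smeared. Known
  limitation.
- **Reference conditions.** Volumes are taken as already reduced to a
  common temperature/pressure by the analyser. No STP correction is
  applied by default; the Brouwer coefficients themselves can be
  overridden via `Constants.with_overrides` if a correction is needed.
- **Coverage.** Sampling gaps > 10 min (configurable) and window spans
  below 98% raise `DataQualityWarning`; the fasting window requires 90%
  coverage before FHP is computed at all. Negative integrated volumes
  (calibration drift) are flagged and returned, never clipped.

Heat production is the Brouwer equation with coefficients 16.18, 5.02,
2.17, 5.99 kJ per L or g; the CH₄ and urinary-N terms subtract. FHP
integrates the 8 h overnight fasting window (22:00–06:00), applies the
Brouwer equation with the fasting-day urinary N prorated by window length
(8/24), scales the window total ×3 to a daily rate, and divides by
BW^0.75. The ×3 extrapolation is linear because the overnight window is
taken as representative of fasting metabolism; both the proration and the
inclusion of the urinary-N term are configurable
(`fasting_scale_to_day`, `include_un_in_fhp`).

## Balance arithmetic

Percentages live on the 0–100 scale throughout (as feed tables print
them); energies are kJ internally, MJ at I/O boundaries. Fecal records
carry fresh mass, DM% and GE per kg fecal DM; urinary energy is recorded
directly per day. Methane energy uses 39.54 kJ/L (enthalpy of combustion
of CH₄) — the conversion constant is configurable since reported trials
rarely print it. Retained protein energy uses N × 6.25 × 23.86 kJ/g.
Apparent digestibility may legitimately fall below zero for fiber
fractions at low inclusion (endogenous losses exceed the marginal
contribution); such values are flagged with a warning and never clipped.
NE is computed as (RE + FHP) normalised to DM intake; on the published
basal column (RE 111, FHP 348 kJ/kg^0.75/d, BW 215.78 kg, DMI 2.11 kg/d)
this lands at 12.25 MJ/kg DM versus the printed 12.23 — a 0.2%
discrepancy attributable to rounding of the printed inputs.

Published N-balance rows are treatment means whose components do not close
(intake − feces − urine ≠ retention); the closure identity is therefore
asserted only on synthetic data, where it holds by construction.

## Difference method

r is the as-fed inclusion of the test ingredient (0.289) applied to
DM-basis energies; the small DM mismatch between the ingredient and the
replaced basal fraction is a documented approximation (an exact-DM r can
be recomputed from `DietFormulation` and the DM contents when needed). The
mineral premix, identical in all diets and contributing ~0 GE, is treated
as part of the basal fraction. Per-sow differences are averaged and the
ME/DE, NE/ME ratios formed from the averaged energies; ratios above 100%
— possible because the 1/r error amplification (≈4.3× at r = 0.289) can
push a noisy ME above DE — are tolerated with a warning. Published
ingredient values cannot be reproduced from the published diet means by
the plain formula (the study used per-sow values with unstated basis
corrections), so difference-method exactness is validated on synthetic
data instead.

## Statistics

Correlations are Pearson r with two-sided p from t = r√((n−2)/(1−r²)).
OLS fits report R², RMSE = √(SSE/(n−k−1)) and the overall-F p; rank
deficiency raises naming the dependent columns. Stepwise selection mirrors
SAS PROC REG STEPWISE: smallest partial-F p enters below SLENTRY, worst
term leaves above SLSTAY, deterministic with ties broken by candidate
order; visited models are ranked (significant at 0.05, R² descending,
RMSE ascending). Defaults are SLENTRY = SLSTAY = 0.15, the SAS default.

On the real ten-barley panel the best equation (NE on ADF and TDF,
R² = 0.66, RMSE = 0.91) is a **suppression pair**: ADF alone has entry
p = 0.17 and TDF is weaker still, so forward entry at 0.15 never starts;
at 0.20/0.20 the search terminates at exactly {ADF, TDF}. The package's
panel-analysis helper (`table_statistics`) therefore uses 0.20 as its
analysis choice for this panel, documented here; the fit statistics of the
final equation do not depend on the threshold. The computed overall-F p of
that equation is 0.022. No multiplicity correction is applied. A second
published equation (NE from ME and CP) has printed coefficients that
over-predict NE several-fold under any sign convention and is excluded
from the regression anchors.

Conclusions-level CVs of the composition panel (e.g. 14.17% for CP) are
not reproducible from the ten tabulated samples under either variance
denominator (the original candidate set had eleven samples); they are not
asserted anywhere.

## Synthetic trial generator

The generator defines the study conditions and inverts the analysis
exactly:

- Sows: BW ~ N(213, 17.8) kg (clipped to 150–280), FHP ~ N(360, 10)
  kJ/kg^0.75/d, fed RQ ~ U[0.93, 1.00], fasted RQ ~ U[0.76, 0.83].
- Feeding: DM intake set so ME intake is exactly 544 kJ/kg BW^0.75/d.
- Diets: basal DE/ME/NE = 15.62/14.37/12.23 MJ/kg DM; test diets are
  mixtures (1−r)·basal + r·ingredient at r = 0.289. Ingredient truths:
  NE ~ U[7.85, 11.85] MJ/kg DM, NE/ME ~ U[0.62, 0.81],
  ME/DE ~ U[0.87, 0.99]; compositions uniform within the observed
  per-analyte ranges with TDF = IDF + SDF enforced.
- Losses: GE digestibility ~ U[0.82, 0.88] fixes feed GE; methane
  0.7–1.0% of DE; the remaining DE−ME gap is urinary energy (5–8% of DE).
  Fecal N 8–10 g/d, urinary N 2.5–3.3 g/d.
- Gas traces: per-minute (configurable) constant differential
  concentrations obtained by inverting the Brouwer equation jointly with
  the target RQ; the fasting window is 22:00–06:00 and its inversion uses
  the same urinary N and proration the analysis applies, so at zero noise
  every stage round-trips to floating precision. Noise is multiplicative
  lognormal with mean exactly 1 (σ² = ln(1+cv²)), keeping recovery
  unbiased; default CVs are 2% (gas), 3% (fecal), 5% (urine), 1% (GE
  assay).
- Seeding: one trial seed split into ingredient/sow/noise substreams, so
  enlarging the roster never perturbs ingredient draws; identical seeds
  give byte-identical output files.

What the generator does **not** emulate: circadian THP structure (feeding
peaks, activity), chamber washout dynamics, gestation-stage drift in FHP,
multi-period crossover allocation (each simulated sow serves one period),
and analyte-level digestibility differences between diets. Passing
recovery tests therefore validate the arithmetic chain and its noise
propagation, not robustness to those real-data features.

## Numerical choices and problem sizes

Trapezoidal integration; half-open windows with the closing sample just
inside; strict timestamp monotonicity per sow enforced at read time.
Energy comparisons in tests use absolute tolerances of 1e−9 (exact
algebra), 0.02 MJ/kg DM (noiseless end-to-end), and Monte-Carlo bands
derived from binomial/χ² error for rate and SD assertions. Simulation
problem sizes were chosen to keep the suite quick on a single core while
leaving comfortable Monte-Carlo margins: 200 replicates for the noisy
recovery experiment (gas traces at 15 min resolution, where integration
is still exact for the constant-rate traces), 60 replicates for stepwise
recovery at the study noise level (σ = 0.9 MJ/kg DM, the RMSE of the
published equation), 300 replicates for the null-entry cross-check
against an independent per-replicate oracle.

## Known limitations

- FHP extrapolation from 8 h is linear; if fasting metabolism drifts
  overnight the ×3 scaling biases FHP accordingly.
- The DE/ME cascade attributes the whole DE−ME gap to urine + methane;
  skin/scurf losses are ignored, as in the underlying convention.
- Stepwise inference p-values are not selection-adjusted; equations from
  n = 10 panels are descriptive, not confirmatory.
- The difference method assumes energy additivity of the basal and test
  fractions; associative digestion effects between barley fiber and the
  basal diet would violate it and are not modelled.
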