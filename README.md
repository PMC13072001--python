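# sowcal

Indirect-calorimetry energy evaluation of feed ingredients for gestating
sows: from respiration-chamber gas exchange and total-collection balance
data to digestible (DE), metabolizable (ME) and net energy (NE) values,
difference-method ingredient energies, and NE prediction equations.

## Who this is for

Swine nutritionists and energy-metabolism researchers who run (or simulate)
respiration-chamber balance trials and need the full computational chain —
gas integration, heat production, digestibility, the DE→ME→NE cascade,
ingredient-level energy by substitution, and composition-based prediction
equations — as tested, composable Python functions rather than spreadsheet
arithmetic.

## The model

**Heat production.** Whole-animal heat output comes from the Brouwer
equation on daily gas volumes (L) and urinary nitrogen (g):

    THP (kJ) = 16.18 VO₂ + 5.02 VCO₂ − 2.17 VCH₄ − 5.99 UN

Fasting heat production (FHP) uses the overnight 22:00–06:00 window of the
fasting day, scaled linearly to 24 h and normalised by metabolic body
weight BW^0.75.

**Energy cascade** per sow-period (energies MJ/kg dietary DM, rates
kJ/kg BW^0.75/d):

    DE  = (GE intake − fecal GE) / DMI
    ME  = DE − (urinary GE + 39.54 kJ/L × VCH₄) / DMI
    RE  = ME intake − THP
    REP = retained N × 6.25 × 23.86 / BW^0.75,   REL = RE − REP
    NE  = (RE + FHP) × BW^0.75 / DMI

**Difference method.** When a test ingredient replaces a fraction r of the
basal diet (r = 0.289 in the reference trial),

    e_ingredient = (e_test − (1 − r) e_basal) / r

for each of DE/ME/NE, with noise amplified by √(1+(1−r)²)/r ≈ 4.3 at
r = 0.289.

**Prediction equations.** Pearson correlation of ingredient NE with the
analyte panel (CP, NDF, ADF, ash, EE, starch, IDF/SDF/TDF, hemicellulose =
NDF − ADF), then SAS-style stepwise regression (partial-F entry/stay
thresholds) ranked by significance, R² and RMSE.

A synthetic-trial generator (`sowcal.synthetic`) simulates the whole study
— sows near 213 kg fed at 544 kJ ME/kg BW^0.75/d, minute-level chamber
traces built by inverting the Brouwer equation against target RQ and heat
— so every stage is testable by parameter recovery.

## Worked example

The packaged ten-barley panel (composition in `sowcal/data/barley10.csv`,
energy values in `barley_energy.csv`) drives the prediction-equation
workflow:

```python
from sowcal import table_statistics
corr, models, direct = table_statistics()
print(models[0].equation(), models[0].r2, models[0].rmse)
```

Running `python examples/04_prediction_equations.py` prints:

```
fiber-fraction correlations (Pearson r):
  r(hemicellulose, ndf) = 0.99
  r(idf, tdf) = 0.97
  r(adf, idf) = 0.94

best stepwise equation:
  ne_mj_kg_dm = 4.33 - 3.92 adf + 1.24 tdf
  R2 = 0.66, RMSE = 0.91 MJ/kg DM, p = 0.022
```

ADF (negative) and TDF (positive) jointly index how much of the fiber
fraction is lignified versus fermentable; alone neither correlates
strongly with NE (a suppression pair — see `docs/methods.md`). The other
examples under `examples/` walk through heat production, the energy
cascade (the basal diet lands at NE = 12.25 MJ/kg DM from RE = 111 and
FHP = 348 kJ/kg^0.75/d), the difference method, and a noiseless synthetic
trial whose ingredient energies are recovered to floating precision.

A thin CLI mirrors the library: `sowcal simulate`, `sowcal run`,
`sowcal stats corr`, `sowcal stats stepwise`.

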