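"""Correlations and NE prediction equations from the packaged barley panel.

Loads the ten-barley composition and energy tables, prints the strong
fiber-fraction correlations, and builds the stepwise NE prediction equation.
"""

from sowcal import table_statistics

corr, models, direct = table_statistics()

print("fiber-fraction correlations (Pearson r):")
for a, b in [("hemicellulose", "ndf"), ("idf", "tdf"), ("adf", "idf")]:
    print(f"  r({a}, {b}) = {corr.r.loc[a, b]:.2f}")

best = models[0]
print("\nbest stepwise equation:")
print(f"  {best.equation()}")
print(f"  R2 = {best.r2:.2f}, RMSE = {best.rmse:.2f} MJ/kg DM, p = {best.p_value:.3f}")
# ADF enters with a negative sign (lignified fiber depresses energy value)
# and TDF positive: jointly they index the digestible vs indigestible split
# of the fiber fraction. Alone, neither correlates strongly with NE - a
# classic suppression pair, which is why the entry threshold is 0.20 here.
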