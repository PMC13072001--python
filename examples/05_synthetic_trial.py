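"""Simulate a noiseless trial and recover every ground truth.

Generates a basal group plus two test-ingredient groups, runs the whole
analysis pipeline, and compares recovered ingredient energies with the
generator's truths.
"""

from sowcal import make_ground_truth, simulate_trial, run_balance, ingredient_values
from sowcal.synthetic import NoiseSpec

truth = make_ground_truth(n_ingredients=2, n_sows=6, seed=3,
                          noise=NoiseSpec(0, 0, 0, 0))
data = simulate_trial(truth, sows_per_diet=2, resolution_min=5)

results = run_balance(data.sow_periods, data.gas, data.collections)
values = ingredient_values(
    results,
    {d: "Basal" for d in data.assignments if d != "Basal"},
    truth.substitution_rate,
    data.assignments,
)

print(f"{'ingredient':14s} {'true NE':>8s} {'recovered':>10s}")
for v in values:
    t = truth.ingredients[v.ingredient_id]
    print(f"{v.ingredient_id:14s} {t.ne:8.3f} {v.ne:10.3f}")
# With all noise CVs at zero the pipeline inverts the generator exactly:
# recovered DE/ME/NE agree with the truths to floating precision, which
# validates every stage from gas integration to the difference method.
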