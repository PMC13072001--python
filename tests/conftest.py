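import warnings

import pytest

from sowcal import io as sowcal_io
from sowcal.pipeline import ingredient_values, run_balance
from sowcal.synthetic import NoiseSpec, make_ground_truth, simulate_trial


@pytest.fixture(scope="session")
def barley_comps():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sowcal_io.load_barley_composition()


@pytest.fixture(scope="session")
def barley_frame(barley_comps):
    """Composition and energy values of the ten barleys, one row each."""
    comp = sowcal_io.composition_frame(barley_comps)
    energy = sowcal_io.load_barley_energy()
    return comp.join(energy[["de_mj_kg_dm", "me_mj_kg_dm", "ne_mj_kg_dm"]])


@pytest.fixture(scope="session")
def diet_energy():
    return sowcal_io.load_diet_energy()


@pytest.fixture(scope="session")
def noiseless_trial():
    """Small zero-noise trial: basal + 2 ingredients, 2 sows per diet."""
    truth = make_ground_truth(
        n_ingredients=2, n_sows=6, seed=3, noise=NoiseSpec(0, 0, 0, 0)
    )
    return simulate_trial(truth, sows_per_diet=2, resolution_min=5)


@pytest.fixture(scope="session")
def noiseless_results(noiseless_trial):
    return run_balance(
        noiseless_trial.sow_periods, noiseless_trial.gas, noiseless_trial.collections
    )


def recover_ingredients(data, results):
    substitution = {d: "Basal" for d in data.assignments if d != "Basal"}
    return ingredient_values(
        results, substitution, data.truth.substitution_rate, data.assignments
    )
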