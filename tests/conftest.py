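import pytest

import ruamkit as rk


@pytest.fixture(scope="session")
def round2_space():
    return rk.default_space()


@pytest.fixture(scope="session")
def minimal_config():
    return {
        "version": "minimal",
        "populations": {
            "NAID": {
                "variables": [{"name": "v", "levels": ["only"]}],
                "treatments": [{"name": "t"}],
            }
        },
    }


@pytest.fixture(scope="session")
def toy_config():
    # 2 variables x (2, 3) levels, 2 treatments -> 6 scenarios, 12 indications
    return {
        "version": "toy",
        "populations": {
            "IDA": {
                "variables": [
                    {"name": "a", "levels": ["a1", "a2"]},
                    {"name": "b", "levels": ["b1", "b2", "b3"]},
                ],
                "treatments": [{"name": "t1"}, {"name": "t2"}],
            }
        },
    }


@pytest.fixture(scope="session")
def toy_space(toy_config):
    return rk.build_scenario_space(toy_config)


@pytest.fixture(scope="session")
def classified_round(round2_space):
    """One noisy synthetic round of the full space, classified."""
    truth = rk.plant_truth(round2_space, seed=101, category_mix=(0.4, 0.3, 0.25, 0.05))
    table = rk.generate_ratings(
        truth, rk.RaterModel(noise_sd=0.5), panel_size=16, seed=102
    )
    results = rk.classify_all(table)
    return truth, table, results
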