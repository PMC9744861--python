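import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo_config():
    """Small but complete simulation configuration used across tests."""
    from occutrend.synthetic import SimulationConfig

    return SimulationConfig(n_zones=9, n_squares_per_zone=15, n_years=21,
                            start_year=1980, n_species_per_group=(6, 4, 3),
                            rng_seed=5)


@pytest.fixture(scope="session")
def demo_world(demo_config):
    """Landscape, drivers, species, truth and records generated once."""
    from occutrend import synthetic as syn

    frame = syn.generate_landscape(demo_config)
    raw = syn.generate_driver_trajectories(demo_config)
    driver_table, scaling = syn.derive_driver_table(raw, demo_config)
    species = syn.generate_species(demo_config)
    truth = syn.simulate_occupancy_dynamics(frame, driver_table, species, demo_config)
    obs = syn.simulate_visits_and_records(truth, frame, demo_config)
    return {"config": demo_config, "frame": frame, "raw": raw,
            "driver_table": driver_table, "scaling": scaling,
            "species": species, "truth": truth, "records": obs["records"],
            "projects": obs["projects"], "experts": obs["expert_observers"]}
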