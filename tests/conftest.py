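import numpy as np
import pandas as pd
import pytest

from trophicniche import diet, isotopes, synthetic


@pytest.fixture(scope="session")
def two_archetype_config():
    return synthetic.DietSimConfig(
        n_scats_per_species={"harbour": 60, "grey": 40},
        cluster_archetypes=[
            ("flatfish", np.array([0.55, 0.25, 0.05, 0.05, 0.05, 0.05]), 60.0),
            ("pelagic", np.array([0.02, 0.03, 0.05, 0.10, 0.70, 0.10]), 60.0),
        ],
        species_cluster_weights={
            "harbour": np.array([0.9, 0.1]),
            "grey": np.array([0.4, 0.6]),
        },
        seed=17,
    )


@pytest.fixture(scope="session")
def scat_dataset(two_archetype_config):
    parts, truth = synthetic.simulate_scats(two_archetype_config)
    return parts, truth


@pytest.fixture(scope="session")
def composition_matrix(scat_dataset):
    parts, _ = scat_dataset
    masses = diet.reconstruct_table(parts, synthetic.toy_allometry_table())
    return diet.build_composition_matrix(masses)


@pytest.fixture(scope="session")
def isotope_truth():
    return {
        "harbour": synthetic.SpeciesIsotopeTruth(
            mu=[-15.5, 16.5],
            omega=[[0.3, 0.05], [0.05, 0.2]],
            sigma=[[0.15, 0.02], [0.02, 0.1]],
            n_individuals=10,
        ),
        "grey": synthetic.SpeciesIsotopeTruth(
            mu=[-15.0, 17.5],
            omega=[[0.2, 0.0], [0.0, 0.8]],
            sigma=[[0.15, 0.0], [0.0, 0.1]],
            n_individuals=10,
        ),
    }


@pytest.fixture(scope="session")
def whisker_series(isotope_truth):
    cfg = synthetic.IsotopeSimConfig(
        species=isotope_truth, segments_range=(10, 10), seed=11
    )
    return synthetic.simulate_whiskers(cfg)


@pytest.fixture(scope="session")
def fast_fit_config():
    # reduced chain lengths keep the suite inside the CI budget
    return isotopes.FitConfig(chains=2, iterations=900, warmup=400, seed=5)


@pytest.fixture(scope="session")
def whisker_fit(whisker_series, fast_fit_config):
    return isotopes.fit_hierarchical_model(whisker_series, config=fast_fit_config)


@pytest.fixture()
def tiny_scat_parts():
    """Three-part scat: one otolith pair plus one unpaired bone."""
    return pd.DataFrame(
        {
            "scat_id": ["s1"] * 3,
            "species": ["harbour"] * 3,
            "date": pd.to_datetime(["2010-05-01"] * 3),
            "taxon": ["Merlangius merlangus"] * 3,
            "structure": ["otolith", "otolith", "parasphenoid"],
            "structure_class": ["paired", "paired", "unpaired"],
            "measurable": [True, True, False],
            "measurement_mm": [4.0, 4.0, np.nan],
            "measurement_kind": ["otolith length"] * 3,
        }
    )
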