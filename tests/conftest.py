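import numpy as np
import pandas as pd
import pytest

from amreml.pedigree import pedigree_from_frame
from amreml.simulate import (SimulationConfig, TraitArchitecture,
                             simulate_dataset)


@pytest.fixture(scope="session")
def toy_ped_frame():
    """Ten animals over three generations with one inbred mating (animal
    10 is the offspring of full sibs 5 x 6, so F_10 = 0.25) and dams with
    repeated recorded progeny (pe identifiable)."""
    rows = [
        # animal, sire, dam, generation, sex
        ("1", "0", "0", 0, "M"),
        ("2", "0", "0", 0, "F"),
        ("3", "0", "0", 0, "F"),
        ("4", "0", "0", 0, "M"),
        ("5", "1", "2", 1, "M"),
        ("6", "1", "2", 1, "F"),
        ("7", "4", "3", 1, "F"),
        ("8", "4", "3", 1, "M"),
        ("9", "1", "3", 1, "F"),
        ("10", "5", "6", 2, "M"),
    ]
    return pd.DataFrame(rows, columns=["animal", "sire", "dam",
                                       "generation", "sex"])


@pytest.fixture(scope="session")
def toy_ped(toy_ped_frame):
    return pedigree_from_frame(toy_ped_frame)


@pytest.fixture(scope="session")
def toy_data(toy_ped):
    """Records on the eight non-founder-sire animals (fixed values)."""
    rows = [
        ("5", "2", 1, 10.3), ("6", "2", 1, 12.1), ("7", "3", 1, 9.4),
        ("8", "3", 1, 11.8), ("9", "3", 1, 10.9), ("10", "6", 2, 13.0),
        ("1", "0", 0, 9.9), ("2", "0", 0, 10.6),
    ]
    return pd.DataFrame(rows, columns=["animal", "dam", "generation", "T"])


def small_architecture(**kw):
    base = dict(name="T", sigma2_a=3.0, sigma2_c=1.5, sigma2_e=6.0,
                mean=50.0, generation_levels=(49.0, 50.5, 51.0),
                hatch_levels=(49.5, 50.5), sex_gap=2.0)
    base.update(kw)
    return TraitArchitecture(**base)


@pytest.fixture(scope="session")
def sim_small():
    """One reusable simulated dataset: 3 generations, ~360 records."""
    cfg = SimulationConfig(
        n_sires=12, dams_per_sire=4, progeny_per_dam=5, n_generations=3,
        n_hatches=2, selected_males=18, selected_females=50,
        selection_trait="T", traits={"T": small_architecture()})
    return simulate_dataset(cfg, seed=2024)
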