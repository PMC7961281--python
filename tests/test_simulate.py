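import numpy as np
import pandas as pd
import pytest

from amreml.pedigree import (additive_relationship, inbreeding_coefficients,
                             pedigree_from_frame)
from amreml.simulate import (SimulationConfig, SimulationError,
                             TraitArchitecture, default_architectures,
                             simulate_breeding_values, simulate_dataset,
                             simulate_phenotypes, single_trait_config,
                             truncation_select)

from conftest import small_architecture


def tiny_config(**kw):
    base = dict(n_sires=8, dams_per_sire=3, progeny_per_dam=4,
                n_generations=3, n_hatches=2, selected_males=12,
                selected_females=30, selection_trait="T",
                traits={"T": small_architecture()})
    base.update(kw)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# reproducibility and structure
# ---------------------------------------------------------------------------

def test_same_seed_is_bit_identical():
    a = simulate_dataset(tiny_config(), seed=5)
    b = simulate_dataset(tiny_config(), seed=5)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    pd.testing.assert_frame_equal(a.truths, b.truths)
    assert a.pedigree.ids == b.pedigree.ids


def test_different_seed_differs():
    a = simulate_dataset(tiny_config(), seed=5)
    b = simulate_dataset(tiny_config(), seed=6)
    assert not a.phenotypes["T"].equals(b.phenotypes["T"])


def test_design_counts():
    cfg = tiny_config()
    sim = simulate_dataset(cfg, seed=1)
    per_gen = cfg.n_sires * cfg.dams_per_sire * cfg.progeny_per_dam
    gens = sim.phenotypes.groupby("generation").size()
    assert list(gens.index) == [1, 2, 3]
    assert (gens == per_gen).all()
    # founders are unrecorded
    assert (sim.pedigree.generation == 0).sum() == cfg.n_sires + cfg.n_dams
    assert sim.pedigree.n == cfg.n_sires + cfg.n_dams + 3 * per_gen
    assert set(sim.phenotypes["hatch"]) <= set(range(1, cfg.n_hatches + 1))


def test_female_only_trait_missing_for_males():
    arch = {"T": small_architecture(),
            "P": small_architecture(name="P", sigma2_c=0.0, sex_gap=0.0,
                                    female_only=True)}
    sim = simulate_dataset(tiny_config(traits=arch), seed=3)
    males = sim.phenotypes["sex"] == "M"
    assert sim.phenotypes.loc[males, "P"].isna().all()
    assert sim.phenotypes.loc[~males, "P"].notna().all()
    assert sim.phenotypes["T"].notna().all()


def test_truncation_select_hand_case():
    df = pd.DataFrame({
        "animal": ["a", "b", "c", "d", "e", "f"],
        "sex": ["M", "M", "M", "F", "F", "F"],
        "T": [3.0, 5.0, 4.0, 2.0, 2.0, 9.0],
    })
    males, females = truncation_select(df, "T", 2, 2)
    assert males == ["b", "c"]
    assert females == ["f", "d"]      # tie at 2.0 broken by id


def test_truncation_select_shortfall_raises():
    df = pd.DataFrame({"animal": ["a"], "sex": ["M"], "T": [1.0]})
    with pytest.raises(SimulationError, match="candidates"):
        truncation_select(df, "T", 2, 0)


def test_mate_avoidance_keeps_first_cohorts_noninbred(caplog):
    """Avoiding mates with a shared parent or grandparent means every
    generation-2 animal (whose grandparents are unrelated founders) has
    F = 0.  The design leaves enough unrelated candidates that the rule
    never needs to be relaxed."""
    cfg = tiny_config(n_sires=10, dams_per_sire=3, progeny_per_dam=8,
                      n_generations=2, selected_males=30,
                      selected_females=60)
    with caplog.at_level("WARNING"):
        sim = simulate_dataset(cfg, seed=11)
    assert "relaxed" not in caplog.text
    F = inbreeding_coefficients(sim.pedigree)
    assert np.all(F[sim.pedigree.generation == 2] == 0.0)


def test_config_validation():
    with pytest.raises(SimulationError, match="selection trait"):
        tiny_config(selection_trait="missing").validate()
    with pytest.raises(SimulationError, match="both sexes"):
        tiny_config(traits={"T": small_architecture(female_only=True)}
                    ).validate()
    with pytest.raises(SimulationError, match="sires"):
        tiny_config(selected_males=4).validate()
    with pytest.raises(SimulationError, match="negative variance"):
        TraitArchitecture("X", sigma2_a=-1.0, sigma2_e=1.0)
    with pytest.raises(SimulationError, match="sigma_am"):
        TraitArchitecture("X", sigma2_a=1.0, sigma2_m=1.0, sigma_am=2.0,
                          sigma2_e=1.0)


def test_default_architectures_complete():
    arch = default_architectures()
    assert set(arch) == {"SL6", "BW0", "BW2", "BW4", "BW6", "ASM",
                         "BW20", "BW40", "EP40", "EW40"}
    sl6 = arch["SL6"]
    assert sl6.sigma2_a == pytest.approx(5.371)
    assert sl6.sigma2_c == pytest.approx(1.144)
    assert sl6.sigma2_e == pytest.approx(25.742)
    assert arch["BW0"].sigma2_m > 0
    cfg = single_trait_config("SL6")
    cfg.validate()
    assert list(cfg.traits) == ["SL6"]


# ---------------------------------------------------------------------------
# gene-dropping correctness
# ---------------------------------------------------------------------------

def drop_cov_pedigree():
    return pedigree_from_frame(pd.DataFrame(
        [("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2"),
         ("4", "1", "2"), ("5", "3", "4"), ("6", "3", "4"),
         ("7", "5", "6"), ("8", "1", "0")],
        columns=["animal", "sire", "dam"]))


def test_gene_drop_covariance_matches_a():
    """Empirical covariance of replicate gene drops equals sigma2_a * A,
    including the inflated diagonal of inbred animals."""
    ped = drop_cov_pedigree()
    cfg = single_trait_config(
        "T", TraitArchitecture("T", sigma2_a=1.0, sigma2_e=1.0))
    R = 4000
    draws = np.empty((R, ped.n))
    for k in range(R):
        draws[k] = simulate_breeding_values(ped, cfg, seed=k)["a_T"]
    emp = draws.T @ draws / R
    A = additive_relationship(ped)
    # MC error of a covariance entry is ~ sqrt((1+a_ij^2)/R) ~ 0.022
    assert np.max(np.abs(emp - A)) <= 0.12
    i7 = ped.id_index["7"]
    assert emp[i7, i7] == pytest.approx(A[i7, i7], abs=0.12)
    assert A[i7, i7] > 1.2  # the case actually exercises inbreeding


def test_mendelian_sampling_variance_within_families():
    """a - 0.5 (a_s + a_d) has variance d_i * sigma2_a = 0.5 sigma2_a for
    non-inbred parents."""
    rows = [(str(i), "0", "0") for i in range(1, 401)]
    rows += [(str(400 + i), str(2 * i - 1), str(2 * i), )
             for i in range(1, 201)]
    ped = pedigree_from_frame(pd.DataFrame(
        [(a, s, d) for a, s, d in rows],
        columns=["animal", "sire", "dam"]))
    cfg = single_trait_config(
        "T", TraitArchitecture("T", sigma2_a=2.0, sigma2_e=1.0))
    tr = simulate_breeding_values(ped, cfg, seed=42).set_index("animal")
    a = tr["a_T"]
    founders = a[[str(i) for i in range(1, 401)]].to_numpy()
    assert founders.var() == pytest.approx(2.0, rel=0.2)
    resid = np.array([
        a[str(400 + i)] - 0.5 * (a[str(2 * i - 1)] + a[str(2 * i)])
        for i in range(1, 201)])
    assert resid.var() == pytest.approx(1.0, rel=0.3)
    assert abs(resid.mean()) < 0.3


def test_phenotype_variance_decomposition():
    """On a founder-parent design the phenotypic variance within one
    generation is close to sigma2_p."""
    arch = small_architecture(generation_levels=(), hatch_levels=(),
                              sex_gap=0.0)
    cfg = SimulationConfig(n_sires=25, dams_per_sire=4, progeny_per_dam=8,
                           n_generations=1, n_hatches=1,
                           selected_males=25, selected_females=100,
                           selection_trait="T", traits={"T": arch})
    sim = simulate_dataset(cfg, seed=17)
    y = sim.phenotypes["T"]
    assert y.var() == pytest.approx(arch.sigma2_p, rel=0.15)
    assert y.mean() == pytest.approx(arch.mean, abs=1.0)


def test_simulate_phenotypes_matches_truths():
    """Records produced for an existing pedigree use the supplied true
    values: regressing y on the true BV within a large family set gives a
    coefficient near 1."""
    sim = simulate_dataset(tiny_config(), seed=23)
    cfg = tiny_config()
    pheno = simulate_phenotypes(sim.pedigree, sim.truths, cfg, seed=99,
                                generations=[1, 2, 3])
    assert set(pheno["generation"]) == {1, 2, 3}
    merged = pheno.merge(sim.truths[["animal", "a_T"]], on="animal")
    # phenotypes are built on the supplied true BVs: regressing y on the
    # true BV gives a coefficient near 1 (fixed effects are independent)
    slope = np.polyfit(merged["a_T"], merged["T"], 1)[0]
    assert slope == pytest.approx(1.0, abs=0.35)
    resid_var = (merged["T"] - merged["a_T"]).var()
    assert resid_var < merged["T"].var()
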