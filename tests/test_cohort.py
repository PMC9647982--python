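"""Synthetic cohort generator: pedigree scheme, gene dropping, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from metabofe import (
    SimulationConfig,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
)
from metabofe.exceptions import ConfigurationError, ModelError
from metabofe.pedigree import UNKNOWN_PARENT


def test_zero_generations_yields_only_founders():
    cfg = SimulationConfig(n_founders_per_line=2, n_generations=0, n_phenotyped=None)
    ped = simulate_pedigree(cfg)
    assert len(ped) == 4
    assert (ped.df["sire"] == UNKNOWN_PARENT).all()
    assert (ped.df["dam"] == UNKNOWN_PARENT).all()


def test_pedigree_is_deterministic():
    cfg = SimulationConfig(n_founders_per_line=6, n_generations=2, offspring_per_dam=2)
    a = simulate_pedigree(cfg).df
    b = simulate_pedigree(cfg).df
    pd.testing.assert_frame_equal(a, b)


def test_mating_scheme_matches_hand_enumeration():
    # 10 founders/line, 2 dams/sire -> blocks of 3 -> 3 full blocks (1 spare);
    # 3 sires x 2 dams = 6 matings x 3 offspring = 18 offspring per line
    cfg = SimulationConfig(
        n_founders_per_line=10, n_generations=1, dams_per_sire=2, offspring_per_dam=3
    )
    ped = simulate_pedigree(cfg)
    assert len(ped) == 2 * (10 + 18)
    offspring = ped.df[ped.df["generation"] == 1]
    assert len(offspring) == 36
    for line in ("lean", "fat"):
        sub = offspring[offspring["line"] == line]
        assert sub["sire"].nunique() == 3
        assert sub["dam"].nunique() == 6
        # parents come from the same line's previous generation
        parents = set(sub["sire"]) | set(sub["dam"])
        prev = set(ped.df[(ped.df["generation"] == 0) & (ped.df["line"] == line)]["animal"])
        assert parents <= prev


def test_invalid_counts_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_founders_per_line=0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(dams_per_sire=0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(true_h2={"P0001": 1.5})
    with pytest.raises(ConfigurationError):
        SimulationConfig(true_rg={("P0001", "rfi"): 0.9, ("P0002", "rfi"): 0.8})  # non-PSD


def test_breeding_values_zero_variance_gives_zeros():
    cfg = SimulationConfig(n_founders_per_line=4, n_generations=1, offspring_per_dam=2)
    ped = simulate_pedigree(cfg)
    bv = simulate_breeding_values(ped, np.zeros((2, 2)), seed=1)
    assert np.all(bv == 0.0)


def test_breeding_values_reject_non_psd_covariance():
    cfg = SimulationConfig(n_founders_per_line=2, n_generations=0)
    ped = simulate_pedigree(cfg)
    with pytest.raises(ModelError):
        simulate_breeding_values(ped, np.array([[1.0, 2.0], [2.0, 1.0]]), seed=0)


def test_founder_breeding_values_match_target_variance_and_independence():
    cfg = SimulationConfig(n_founders_per_line=5000, n_generations=0, n_phenotyped=None)
    ped = simulate_pedigree(cfg)
    bv = simulate_breeding_values(ped, np.array([[1.0]]), seed=2).ravel()
    # chi-square bound at n = 10000: sd of the sample variance ~ sqrt(2/n)
    assert np.var(bv, ddof=1) == pytest.approx(1.0, abs=0.05)
    # founders are mutually independent: adjacent-founder correlation ~ 0
    assert abs(np.corrcoef(bv[:-1:2], bv[1::2])[0, 1]) < 0.05


def test_full_sib_breeding_value_correlation_is_half():
    # many replicate two-offspring families: corr(sib1, sib2) -> 0.5 for
    # univariate G = [1] (covariance A_sib,sib * sigma_a^2 = 0.5)
    cfg = SimulationConfig(
        n_founders_per_line=3000,
        n_generations=1,
        dams_per_sire=1,
        offspring_per_dam=2,
        n_phenotyped=None,
    )
    ped = simulate_pedigree(cfg)
    bv = simulate_breeding_values(ped, np.array([[1.0]]), seed=3).ravel()
    off = ped.df[ped.df["generation"] == 1]
    sib1 = bv[off.index[0::2]]
    sib2 = bv[off.index[1::2]]
    assert np.corrcoef(sib1, sib2)[0, 1] == pytest.approx(0.5, abs=0.04)


def test_all_variance_sources_off_gives_constant_baseline():
    cfg = SimulationConfig(
        n_founders_per_line=4,
        n_generations=1,
        offspring_per_dam=2,
        n_phenotyped=None,
        n_metabolites_pos=3,
        n_metabolites_neg=2,
        residual_sd=0.0,
        default_h2=0.0,
        fe_h2=0.0,
        baseline_mean=777.0,
        seed=4,
    )
    ped = simulate_pedigree(cfg)
    _, pos, neg = simulate_phenotypes(ped, cfg)
    assert np.all(pos.intensities.to_numpy() == 777.0)
    assert np.all(neg.intensities.to_numpy() == 777.0)


def test_phenotypes_deterministic_and_nonnegative(small_cohort):
    cfg, ped, phenotypes, pos, neg = small_cohort
    again_ph, again_pos, _ = simulate_phenotypes(ped, cfg)
    pd.testing.assert_frame_equal(phenotypes, again_ph)
    pd.testing.assert_frame_equal(pos.intensities, again_pos.intensities)
    assert pos.intensities.to_numpy().min() >= 0.0
    assert neg.intensities.to_numpy().min() >= 0.0


def test_line_and_sex_effects_shift_planted_features(small_cohort):
    _, _, phenotypes, pos, neg = small_cohort
    lines = phenotypes.set_index("bird_id").loc[pos.bird_ids, "line"]
    sexes = phenotypes.set_index("bird_id").loc[pos.bird_ids, "sex"]
    p1 = pos.intensities["P0001"]
    assert p1[lines.values == "fat"].mean() - p1[lines.values == "lean"].mean() > 300
    n1 = neg.intensities["N0001"]
    assert n1[lines.values == "fat"].mean() - n1[lines.values == "lean"].mean() < -300
    p2 = pos.intensities["P0002"]
    assert p2[sexes.values == "male"].mean() - p2[sexes.values == "female"].mean() > 50


def test_midparent_regression_recovers_heritability():
    # offspring-on-midparent slope estimates h2 when parents and offspring are
    # phenotyped under the same variances
    cfg = SimulationConfig(
        n_founders_per_line=600,
        n_generations=1,
        dams_per_sire=1,
        offspring_per_dam=1,
        n_phenotyped=None,
        phenotype_generations="all",
        n_metabolites_pos=1,
        n_metabolites_neg=1,
        true_h2={"P0001": 0.6},
        seed=6,
    )
    ped = simulate_pedigree(cfg)
    phenotypes, pos, _ = simulate_phenotypes(ped, cfg)
    values = pos.intensities["P0001"]
    df = ped.df.set_index("animal")
    off = df[df["generation"] == 1]
    mid = 0.5 * (values.loc[off["sire"]].to_numpy() + values.loc[off["dam"]].to_numpy())
    child = values.loc[off.index].to_numpy()
    slope = np.polyfit(mid, child, 1)[0]
    assert slope == pytest.approx(0.6, abs=0.1)


def test_configured_rfi_correlation_is_realized_generatively():
    # with r_g configured, the phenotypic correlation between the metabolite
    # and the RFI deviation approaches r_g * sqrt(h2_m * h2_fe)
    from metabofe.feed_efficiency import fit_rfi

    cfg = SimulationConfig(
        n_founders_per_line=2000,
        n_generations=0,
        n_phenotyped=None,
        phenotype_generations="all",
        n_metabolites_pos=1,
        n_metabolites_neg=1,
        true_h2={"P0001": 0.5},
        true_rg={("P0001", "rfi"): 0.8},
        seed=7,
    )
    ped = simulate_pedigree(cfg)
    phenotypes, pos, _ = simulate_phenotypes(ped, cfg)
    _, traits = fit_rfi(phenotypes)
    r_expected = 0.8 * np.sqrt(0.5 * cfg.fe_h2)
    r_obs = np.corrcoef(pos.intensities["P0001"], traits["rfi_g"])[0, 1]
    assert r_obs == pytest.approx(r_expected, abs=0.05)


def test_yaml_round_trip(tmp_path):
    cfg = SimulationConfig(true_rg={("P0001", "rfi"): 0.4}, true_h2={"P0001": 0.3})
    cfg.to_yaml(tmp_path / "cfg.yaml")
    back = SimulationConfig.from_yaml(tmp_path / "cfg.yaml")
    assert back == cfg
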