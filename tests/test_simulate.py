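"""Synthetic herd generator: pedigree structure, gene dropping, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import wssgwas as w
from wssgwas.kinship import build_G
from wssgwas.simulate import (
    lactation_stage_class,
    simulate_genotypes,
    simulate_marker_map,
    simulate_pedigree,
    simulate_phenotypes,
)


def _cfg(**kw):
    return w.SimulationConfig(**kw)


# ------------------------------------------------------------------ pedigree
def test_founders_only():
    ped = simulate_pedigree(_cfg(n_founders=10, n_generations=0))
    assert ped.n == 10
    assert (ped.table["sire"] == 0).all() and (ped.table["dam"] == 0).all()


def test_invalid_config_rejected():
    with pytest.raises(ValidationError):
        _cfg(n_founders=1)
    with pytest.raises(ValidationError):
        _cfg(n_generations=-1)
    with pytest.raises(ValidationError):
        _cfg(sigma2_e=-0.1)
    with pytest.raises(ValidationError):
        _cfg(maf_low=0.3, maf_high=0.2)
    with pytest.raises(ValidationError):
        _cfg(n_qtl=5, n_chromosomes=1, snps_per_chromosome=3)


def test_offspring_follow_parents_in_order():
    cfg = _cfg(n_founders=4, n_generations=2, n_per_generation=4, offspring_per_mating=2)
    ped = simulate_pedigree(cfg)
    rows = {a: i for i, a in enumerate(ped.ids)}
    nonfounders = ped.table[ped.table["sire"] > 0]
    for _, r in nonfounders.iterrows():
        assert rows[r["sire"]] < rows[r["animal"]]
        assert rows[r["dam"]] < rows[r["animal"]]


def test_simulation_deterministic_under_seed():
    cfg = _cfg(n_founders=12, n_generations=2, n_per_generation=20,
               n_chromosomes=1, snps_per_chromosome=15, rng_seed=42)
    d1 = w.simulate_dataset(cfg)
    d2 = w.simulate_dataset(cfg)
    pd.testing.assert_frame_equal(d1.pedigree.table, d2.pedigree.table)
    assert np.array_equal(d1.genotypes.X, d2.genotypes.X)
    pd.testing.assert_frame_equal(d1.phenotypes.records, d2.phenotypes.records)


# ------------------------------------------------------------- gene dropping
def test_monomorphic_transmission():
    """A child of two hom-reference parents is hom reference at that SNP."""
    cfg = _cfg(n_founders=10, n_generations=2, n_per_generation=20,
               n_chromosomes=1, snps_per_chromosome=30, rng_seed=1)
    ped = simulate_pedigree(cfg)
    mm = simulate_marker_map(cfg)
    geno = simulate_genotypes(ped, mm, cfg)
    X = geno.X
    for i in range(ped.n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s < 0 or d < 0:
            continue
        both_zero = (X[s] == 0) & (X[d] == 0)
        assert (X[i][both_zero] == 0).all()
        both_two = (X[s] == 2) & (X[d] == 2)
        assert (X[i][both_two] == 2).all()


def test_founder_allele_frequency_matches_target():
    """With 10,000 founders the observed frequency is binomially tight."""
    cfg = _cfg(n_founders=10000, n_generations=0, n_chromosomes=1,
               snps_per_chromosome=1, rng_seed=11)
    ped = simulate_pedigree(cfg)
    mm = simulate_marker_map(cfg)
    mm["founder_freq"] = 0.5
    geno = simulate_genotypes(ped, mm, cfg)
    assert abs(geno.allele_freq()[0] - 0.5) < 0.02


def test_expected_frequency_preserved_across_generations():
    """Drift is mean-zero: dropped frequencies track founder frequencies."""
    cfg = _cfg(n_founders=150, n_generations=2, n_per_generation=200,
               n_chromosomes=2, snps_per_chromosome=100, rng_seed=13)
    d = w.simulate_dataset(cfg)
    obs = d.genotypes.allele_freq()
    target = d.genotypes.marker_map["founder_freq"].to_numpy()
    assert np.all((obs >= 0) & (obs <= 1))
    assert abs(np.mean(obs - target)) < 0.01


@pytest.mark.parametrize("recombination", ["independent", "haldane"])
def test_parent_offspring_genomic_relationship(recombination):
    """Empirical VanRaden relationship of parent-offspring pairs is ~0.5."""
    cfg = _cfg(n_founders=200, n_generations=1, n_per_generation=300,
               n_chromosomes=2, snps_per_chromosome=200,
               recombination=recombination, rng_seed=17)
    ped = simulate_pedigree(cfg)
    mm = simulate_marker_map(cfg)
    geno = simulate_genotypes(ped, mm, cfg)
    G = build_G(geno).values
    pairs = [
        (i, ped.sire_idx[i]) for i in range(ped.n) if ped.sire_idx[i] >= 0
    ]
    rel = np.mean([G[i, s] for i, s in pairs])
    assert rel == pytest.approx(0.5, abs=0.05)


# --------------------------------------------------------------- phenotypes
def test_pure_residual_records():
    """With additive and pe variance off, records are iid noise at sigma2_e."""
    cfg = _cfg(n_founders=4000, n_generations=0, genotyped_fraction=0.0,
               sigma2_a=0.0, sigma2_pe=0.0, sigma2_e=0.25,
               thi_beta=0.0, fixed_effect_sd=0.0,
               n_farm_year=1, n_parity=1, n_stage=1, n_milking=1,
               records_per_animal=(2, 3), record_sex="all", rng_seed=19)
    ped = simulate_pedigree(cfg)
    phen = simulate_phenotypes(ped, None, cfg)
    y = phen.records["y"].to_numpy()
    assert len(y) >= 8000
    assert np.var(y) == pytest.approx(0.25, rel=0.05)
    assert np.allclose(phen.true_breeding_values, 0.0)


def test_within_animal_correlation_is_repeatability():
    cfg = _cfg(n_founders=3000, n_generations=0, sigma2_a=0.3, sigma2_pe=0.3,
               sigma2_e=0.4, thi_beta=0.0, fixed_effect_sd=0.0,
               records_per_animal=(2, 2), record_sex="all", rng_seed=23)
    ped = simulate_pedigree(cfg)
    phen = simulate_phenotypes(ped, None, cfg)
    wide = phen.records.assign(
        k=phen.records.groupby("animal").cumcount()
    ).pivot(index="animal", columns="k", values="y")
    r = np.corrcoef(wide[0], wide[1])[0, 1]
    assert r == pytest.approx(0.6, abs=0.05)


def test_thi_slope_recovered_by_ols():
    cfg = _cfg(n_founders=2500, n_generations=0, thi_beta=0.05,
               fixed_effect_sd=0.0, records_per_animal=(2, 2),
               record_sex="all", rng_seed=29)
    ped = simulate_pedigree(cfg)
    phen = simulate_phenotypes(ped, None, cfg)
    slope = np.polyfit(phen.records["thi"], phen.records["y"], 1)[0]
    assert slope == pytest.approx(0.05, abs=0.01)


def test_qtl_fraction_of_additive_variance(small_dataset):
    """QTL dosage effects carry their requested share of sigma2_a."""
    phen = small_dataset.phenotypes
    assert len(phen.qtl) == 1
    j = int(phen.qtl["snp_index"].iloc[0])
    alpha = float(phen.qtl["alpha"].iloc[0])
    z = small_dataset.genotypes.X[:, j].astype(float)
    v_qtl = np.var(z * alpha)
    assert v_qtl == pytest.approx(0.10 * phen.config.sigma2_a, rel=1e-6)


def test_qtl_without_genotypes_raises():
    cfg = _cfg(n_founders=10, n_generations=0, n_qtl=1, qtl_variance_fractions=[0.1])
    ped = simulate_pedigree(cfg)
    with pytest.raises(ValueError, match="genotypes"):
        simulate_phenotypes(ped, None, cfg)


def test_lactation_stage_classes():
    assert lactation_stage_class(1) == "1-50"
    assert lactation_stage_class(50) == "1-50"
    assert lactation_stage_class(51) == "51-100"
    assert lactation_stage_class(300) == "251-300"
    assert lactation_stage_class(301) == ">300"
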