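"""REML: likelihood correctness, oracles, identifiability, multi-trait."""

import warnings

import numpy as np
import pandas as pd
import pytest

import wssgwas as w
from wssgwas.design import ModelSpec, build_design
from wssgwas.reml import (
    MultiTraitVarianceComponents,
    VarianceComponents,
    genetic_correlation,
    heritability,
    multitrait_loglike,
    reml_estimate,
    reml_loglike,
    repeatability,
    round_table2,
)


def harville_loglike(design, K, vc):
    """Independent dense-V REML log-likelihood oracle (Harville form)."""
    Z, W, X, y = design.Za.toarray(), design.Wpe.toarray(), design.X, design.y
    n, p = X.shape
    V = vc.sigma2_a * Z @ K @ Z.T + vc.sigma2_pe * W @ W.T + vc.sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    b = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ b
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + r @ Vi @ r
        + (n - p) * np.log(2 * np.pi)
    )


@pytest.fixture(scope="module")
def tiny_model():
    cfg = w.SimulationConfig(
        n_founders=20, n_generations=1, n_per_generation=30,
        n_chromosomes=1, snps_per_chromosome=30, genotyped_fraction=0.5,
        rng_seed=3,
    )
    d = w.simulate_dataset(cfg)
    geno, _ = w.run_qc(d.observed_genotypes)
    m_ped = w.SingleStepRepeatabilityModel.from_dataframe(
        d.phenotypes.records, "y", d.pedigree
    )
    m_gen = w.SingleStepRepeatabilityModel.from_dataframe(
        d.phenotypes.records, "y", d.pedigree, genotypes=geno
    )
    return d, m_ped, m_gen


@pytest.mark.parametrize("theta", [(0.3, 0.1, 0.2), (0.05, 0.05, 0.4)])
def test_loglike_matches_dense_V_oracle(tiny_model, theta):
    """MME-based restricted logL equals the dense-V evaluation to 1e-6."""
    d, m_ped, m_gen = tiny_model
    vc = VarianceComponents(*theta)
    K = d.pedigree.relationship_matrix()
    assert reml_loglike(m_ped.design, m_ped.K_inv, vc) == pytest.approx(
        harville_loglike(m_ped.design, K, vc), abs=1e-6
    )
    # H-structured model: K = inverse of the assembled H^-1
    H = np.linalg.inv(m_gen.K_inv.toarray())
    assert reml_loglike(m_gen.design, m_gen.K_inv, vc) == pytest.approx(
        harville_loglike(m_gen.design, H, vc), abs=1e-6
    )


def test_reml_matches_statsmodels_random_intercept():
    """With unrelated animals (A=I) and the additive term pinned, the model
    is a plain random-intercept model; estimates must match MixedLM REML."""
    import statsmodels.api as sm

    cfg = w.SimulationConfig(
        n_founders=400, n_generations=0, sigma2_a=0.0, sigma2_pe=0.25,
        sigma2_e=0.5, thi_beta=0.02, fixed_effect_sd=0.0,
        n_farm_year=1, n_parity=1, n_stage=1, n_milking=1,
        records_per_animal=(2, 3), record_sex="all", rng_seed=37,
    )
    ped = w.simulate_pedigree(cfg)
    phen = w.simulate_phenotypes(ped, None, cfg)
    rec = phen.records
    spec = ModelSpec(trait="y", factors=[], covariates=["thi"])
    design = build_design(rec, spec, ped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vc = reml_estimate(
            design, ped.a_inverse(), fix_sigma2_pe=None, tol=1e-10,
            start=(1e-6, 0.2, 0.5),
        )
    # additive and pe are both animal-level iid here; only their sum is
    # identified, so compare sigma2_a + sigma2_pe with MixedLM's group var
    X = np.column_stack([np.ones(len(rec)), rec["thi"]])
    md = sm.MixedLM(rec["y"].to_numpy(), X, groups=rec["animal"].to_numpy())
    fit = md.fit(reml=True)
    assert vc.sigma2_a + vc.sigma2_pe == pytest.approx(
        float(np.asarray(fit.cov_re)[0, 0]), rel=1e-3
    )
    assert vc.sigma2_e == pytest.approx(float(fit.scale), rel=1e-3)


def test_pure_noise_recovers_residual_variance():
    """Simulated with sigma2_a = sigma2_pe = 0: residual estimate within 5%."""
    cfg = w.SimulationConfig(
        n_founders=800, n_generations=0, sigma2_a=0.0, sigma2_pe=0.0,
        sigma2_e=0.3, thi_beta=0.0, fixed_effect_sd=0.05,
        records_per_animal=(2, 3), record_sex="all", rng_seed=41,
    )
    ped = w.simulate_pedigree(cfg)
    phen = w.simulate_phenotypes(ped, None, cfg)
    design = build_design(phen.records, ModelSpec(), ped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vc = reml_estimate(design, ped.a_inverse(), tol=1e-6)
    assert vc.sigma2_e == pytest.approx(0.3, rel=0.05)
    # between-animal variance at truth 0 is sampling noise with
    # SE ~ sqrt(2/n_animals) * sigma2_e ~ 0.015; allow ~3 SE
    assert vc.sigma2_a + vc.sigma2_pe < 0.05


def test_single_record_pe_flagged_unidentifiable(tiny_model):
    d, m_ped, _ = tiny_model
    rec = d.phenotypes.records.drop_duplicates("animal")
    design = build_design(rec, ModelSpec(), d.pedigree)
    with pytest.warns(UserWarning, match="single record"):
        vc = reml_estimate(design, d.pedigree.a_inverse(), max_iter=30, tol=1e-4)
    assert not vc.pe_identifiable
    assert vc.pinned["sigma2_pe"]


def test_estimates_invariant_to_location_shift(tiny_model):
    d, m_ped, _ = tiny_model
    rec = d.phenotypes.records.copy()
    design0 = build_design(rec, ModelSpec(), d.pedigree)
    rec["y"] = rec["y"] + 100.0
    design1 = build_design(rec, ModelSpec(), d.pedigree)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vc0 = reml_estimate(design0, d.pedigree.a_inverse(), tol=1e-8)
        vc1 = reml_estimate(design1, d.pedigree.a_inverse(), tol=1e-8)
    assert vc0.sigma2_a == pytest.approx(vc1.sigma2_a, rel=1e-4)
    assert vc0.sigma2_e == pytest.approx(vc1.sigma2_e, rel=1e-4)


# --------------------------------------------------------------- ratios
def test_heritability_and_repeatability_formulas():
    vc = VarianceComponents(0.015, 0.03, 0.20)
    assert heritability(vc) == pytest.approx(0.015 / 0.245)
    assert repeatability(vc) == pytest.approx(0.045 / 0.245)
    full = VarianceComponents(1.0, 0.0, 0.0)
    assert heritability(full) == 1.0
    norec = VarianceComponents(0.2, 0.3, 0.0)
    assert repeatability(norec) == 1.0
    with pytest.raises(ValueError):
        heritability(VarianceComponents(0.0, 0.0, 0.0))


def test_round_half_away_from_zero():
    assert round_table2(0.0449) == 0.04
    assert round_table2(0.045) == 0.05
    assert round_table2(-0.125) == -0.13


# ----------------------------------------------------------- multi-trait
def test_multitrait_loglike_equals_sum_of_univariate(tiny_model):
    """Independent traits with block-diagonal covariances: joint logL adds."""
    d, m_ped, _ = tiny_model
    rng = np.random.default_rng(0)
    rec = d.phenotypes.records.copy()
    rec["y2"] = rng.normal(size=len(rec))
    design = build_design(rec, ModelSpec(), d.pedigree)
    Y = rec[["y", "y2"]].to_numpy()
    Ga, Gpe, R = np.diag([0.2, 0.3]), np.diag([0.1, 0.2]), np.diag([0.3, 0.5])
    ll = multitrait_loglike(Y, design, d.pedigree.a_inverse(), Ga, Gpe, R)
    l1 = reml_loglike(design, d.pedigree.a_inverse(), VarianceComponents(0.2, 0.1, 0.3))
    design2 = build_design(rec, ModelSpec(trait="y2"), d.pedigree)
    l2 = reml_loglike(design2, d.pedigree.a_inverse(), VarianceComponents(0.3, 0.2, 0.5))
    assert ll == pytest.approx(l1 + l2, abs=1e-8)


def test_genetic_correlation_edge_cases():
    vc = MultiTraitVarianceComponents(
        traits=["rt", "rr"],
        G_a=np.array([[0.015, 0.0], [0.0, 0.016]]),
        G_pe=np.eye(2) * 0.03,
        R=np.eye(2) * 0.2,
    )
    assert genetic_correlation(vc, "rt", "rr") == 0.0
    vc.G_a[0, 1] = vc.G_a[1, 0] = np.sqrt(0.015 * 0.016)
    assert genetic_correlation(vc, 0, 1) == pytest.approx(1.0)
    vc.G_a[0, 1] = vc.G_a[1, 0] = 2 * np.sqrt(0.015 * 0.016)
    with pytest.warns(UserWarning, match="clipping"):
        assert genetic_correlation(vc, 0, 1) == 1.0
    vc.G_a[0, 0] = 0.0
    with pytest.raises(ValueError):
        genetic_correlation(vc, 0, 1)


def _simulate_bivariate(ped, cfg, r_g, rng):
    """Two traits sharing pedigree with additive correlation r_g."""
    n = ped.n
    s2a, s2pe, s2e = cfg.sigma2_a, cfg.sigma2_pe, cfg.sigma2_e
    Ca = s2a * np.array([[1.0, r_g], [r_g, 1.0]])
    La = np.linalg.cholesky(Ca)
    F = ped.inbreeding()
    dvec = ped._mendelian_variance(F)
    u = np.zeros((n, 2))
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        mid = np.zeros(2)
        if s >= 0:
            mid += 0.5 * u[s]
        if d >= 0:
            mid += 0.5 * u[d]
        u[i] = mid + np.sqrt(dvec[i]) * (La @ rng.normal(size=2))
    rows = []
    for i in range(n):
        pe = rng.normal(0, np.sqrt(s2pe), size=2)
        for _ in range(2):
            e = rng.normal(0, np.sqrt(s2e), size=2)
            rows.append((ped.ids[i], *(u[i] + pe + e)))
    return pd.DataFrame(rows, columns=["animal", "y1", "y2"]), u


def test_bivariate_genetic_correlation_recovery():
    """Scaled-down parameter recovery: true r_g = 0.5 on a 700-animal herd
    (smaller than ideal for CI speed; tolerance widened accordingly)."""
    ests = []
    for seed in range(2):
        rng = np.random.default_rng(100 + seed)
        cfg = w.SimulationConfig(
            n_founders=300, n_generations=1, n_per_generation=400,
            sigma2_a=0.3, sigma2_pe=0.2, sigma2_e=0.5, record_sex="all",
            n_chromosomes=1, snps_per_chromosome=5, rng_seed=100 + seed,
        )
        ped = w.simulate_pedigree(cfg, seed=seed)
        rec, _ = _simulate_bivariate(ped, cfg, 0.5, rng)
        model = w.SingleStepRepeatabilityModel(
            rec, ModelSpec(trait="y1", factors=[], covariates=[]), ped
        )
        res = model.fit_multitrait(["y1", "y2"], max_iter=150)
        ests.append(res.genetic_correlation("y1", "y2"))
    mean_r = float(np.mean(ests))
    assert mean_r == pytest.approx(0.5, abs=0.25)
    assert all(r > 0 for r in ests)
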