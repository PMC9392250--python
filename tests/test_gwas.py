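"""Backsolved SNP effects, iterative weights, and the window variance scan."""

import numpy as np
import pandas as pd
import pytest

import wssgwas as w
from wssgwas.genotypes import GenotypeMatrix
from wssgwas.gwas import (
    SNPEffectSet,
    backsolve_snp_effects,
    significant_regions,
    snp_weights,
    window_variance_scan,
)
from wssgwas.kinship import blend_tune_G, build_G, inv_psd


def make_geno(X, chrom=None, pos=None):
    X = np.asarray(X, dtype=np.int8)
    m = X.shape[1]
    mm = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, int),
            "pos_bp": pos if pos is not None else np.arange(1, m + 1) * 1000,
        }
    )
    return GenotypeMatrix(ids=np.arange(1, X.shape[0] + 1), marker_map=mm, X=X)


# ------------------------------------------------------------- backsolve
def test_backsolve_zero_gebv_gives_zero_effects():
    rng = np.random.default_rng(0)
    geno = make_geno(rng.integers(0, 3, (10, 20)))
    G = build_G(geno)
    Gi = inv_psd(blend_tune_G(G, np.eye(10), 0.05).values)
    eff = backsolve_snp_effects(np.zeros(10), geno.centered(), None, Gi, G.meta["k"])
    assert np.allclose(eff.effects, 0.0)


def test_backsolve_hand_worked_fixture():
    """2 individuals, 1 SNP, genotypes {0,2}: u computable by 2x2 arithmetic."""
    geno = make_geno([[0], [2]])
    G = build_G(geno)  # [[2,-2],[-2,2]], k = 0.5
    Gs = blend_tune_G(G, np.eye(2), 0.05).values  # [[1.95,-1.9],[-1.9,1.95]]
    Gs_inv = np.linalg.inv(Gs)
    a = np.array([-1.0, 1.0])
    eff = backsolve_snp_effects(a, geno.centered(), None, Gs_inv, 0.5)
    # by hand: det = 1.95^2 - 1.9^2 = 0.1925; adj = [[1.95, 1.9], [1.9, 1.95]]
    # G*^-1 a = [-0.05, 0.05]/0.1925; z = [-1, +1] so z'G*^-1 a = 0.1/0.1925
    # u = (1/k) z'G*^-1 a = 2 * 0.1/0.1925 = 80/77
    assert eff.effects[0] == pytest.approx(80.0 / 77.0, abs=1e-10)


def test_backsolve_projection_identity_unblended():
    """alpha=0, M >= n, full-rank G: Z u reproduces the GEBV exactly.

    G must be built with external (founder) allele frequencies: centering by
    the observed frequencies zeroes the column sums and leaves G singular.
    """
    rng = np.random.default_rng(1)
    geno = make_geno(rng.integers(0, 3, (25, 60)))
    p = np.full(60, 0.5)
    G = build_G(geno, freqs=p)
    Gi = inv_psd(G.values)
    a = rng.normal(size=25)
    eff = backsolve_snp_effects(a, geno.centered(p), None, Gi, G.meta["k"])
    assert np.allclose(geno.centered(p) @ eff.effects, a, atol=1e-6)


def test_backsolve_dimension_mismatch():
    geno = make_geno([[0], [2]])
    with pytest.raises(ValueError, match="mismatch"):
        backsolve_snp_effects(np.zeros(3), geno.centered(), None, np.eye(2), 0.5)


# --------------------------------------------------------------- weights
def test_weight_formula_fixed_points():
    """|u| = 2 sd -> d=1; u=0 -> 1.125^-2; |u| = 6 sd capped at 5 -> 1.125^3
    (all pre-rescaling; the published rescale keeps sum(d) = M)."""
    # [1,-1,0x6]: sd = 0.5, so |u|/sd = 2 for the nonzero entries
    u8 = np.array([1.0, -1.0] + [0.0] * 6)
    w8 = snp_weights(u8)
    pre_nonzero, pre_zero = 1.125**0, 1.125**-2
    scale8 = 8 / (2 * pre_nonzero + 6 * pre_zero)
    assert w8[0] == pytest.approx(pre_nonzero * scale8, abs=1e-12)
    assert w8[2] == pytest.approx(pre_zero * scale8, abs=1e-12)
    assert pre_zero == pytest.approx(0.7901, abs=1e-4)

    # [1,-1,0x70]: sd = 1/6, ratio 6 -> capped at 5 -> exponent 3
    u72 = np.array([1.0, -1.0] + [0.0] * 70)
    w72 = snp_weights(u72, cap_sd=5.0)
    pre_cap = 1.125**3
    scale72 = 72 / (2 * pre_cap + 70 * pre_zero)
    assert w72[0] == pytest.approx(pre_cap * scale72, abs=1e-12)
    assert pre_cap == pytest.approx(1.4238, abs=1e-4)


def test_weights_sum_to_snp_count():
    rng = np.random.default_rng(2)
    for _ in range(5):
        u = rng.normal(size=200) * rng.uniform(0.1, 10)
        d = snp_weights(u)
        assert d.sum() == pytest.approx(200.0, abs=1e-8)
        assert (d > 0).all()


def test_constant_magnitude_effects_are_a_fixed_point():
    """Equal-|u| effects give identity weights, so iteration cannot move."""
    u = np.array([0.3, -0.3, 0.3, 0.3, -0.3])
    assert np.allclose(snp_weights(u), np.ones(5))


def test_zero_effects_warn_identity():
    with pytest.warns(UserWarning, match="zero"):
        d = snp_weights(np.zeros(10))
    assert np.array_equal(d, np.ones(10))


# --------------------------------------------------------- full iteration
def test_wssgwas_first_iteration_is_unweighted(small_dataset, small_fit):
    res1 = small_fit.wssgwas(n_iterations=1)
    res3 = small_fit.wssgwas(n_iterations=3)
    assert np.array_equal(res1.iterations[0].effects, res3.iterations[0].effects)
    assert np.array_equal(res3.weights[0], np.ones(res3.geno.n_snps))
    # weights used at each later iteration conserve sum(d) = M
    for d in res3.weights[1:]:
        assert d.sum() == pytest.approx(res3.geno.n_snps, abs=1e-8)


def test_wssgwas_gebv_table(small_fit):
    res = small_fit.wssgwas(n_iterations=1)
    assert set(res.gebv.columns) >= {"animal", "gebv", "genotyped"}
    assert len(res.gebv) == small_fit.model.pedigree.n


# ------------------------------------------------------------------ scan
def test_scan_zero_effects_zero_percentages():
    rng = np.random.default_rng(3)
    geno = make_geno(rng.integers(0, 3, (30, 25)))
    scan = window_variance_scan(np.zeros(25), geno, window_size=10, sigma2_a=0.015)
    assert (scan["pct_variance"] == 0).all()


def test_scan_matches_bruteforce_individual_loop():
    """Vectorized scan equals a per-individual, per-window Python loop."""
    rng = np.random.default_rng(4)
    geno = make_geno(
        rng.integers(0, 3, (40, 30)), chrom=[1] * 10 + [2] * 20
    )
    u = rng.normal(scale=0.01, size=30)
    s2a = 0.015
    scan = window_variance_scan(u, geno, window_size=10, step=1, sigma2_a=s2a)
    Zc = geno.centered()
    chrom = geno.marker_map["chrom"].to_numpy()
    expected = []
    for c in (1, 2):
        idx = np.flatnonzero(chrom == c)
        for s0 in range(len(idx) - 10 + 1):
            win = idx[s0 : s0 + 10]
            vals = [sum(Zc[i, j] * u[j] for j in win) for i in range(40)]
            expected.append(np.var(vals))
    assert len(scan) == len(expected)
    assert np.allclose(scan["var_window"], expected, atol=1e-8)
    assert np.allclose(scan["pct_variance"], 100 * np.array(expected) / s2a, atol=1e-8)
    # chromosome 1 has exactly 10 SNPs -> one full window
    assert (scan["chrom"] == 1).sum() == 1


def test_scan_analytic_linkage_equilibrium():
    """Independent HWE SNPs: window variance ~ sum 2p(1-p)u^2 within 10%."""
    rng = np.random.default_rng(5)
    n, m = 1000, 40
    p = rng.uniform(0.2, 0.8, m)
    X = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    geno = make_geno(X)
    u = rng.normal(scale=0.05, size=m)
    scan = window_variance_scan(u, geno, window_size=10, step=10, sigma2_a=1.0)
    phat = geno.allele_freq()
    for _, row in scan.iterrows():
        j0, j1 = int(row["start_index"]), int(row["end_index"]) + 1
        analytic = np.sum(2 * phat[j0:j1] * (1 - phat[j0:j1]) * u[j0:j1] ** 2)
        assert row["var_window"] == pytest.approx(analytic, rel=0.10)


def test_scan_short_chromosome_flagged():
    rng = np.random.default_rng(6)
    geno = make_geno(rng.integers(0, 3, (20, 16)), chrom=[1] * 12 + [2] * 4)
    scan = window_variance_scan(rng.normal(size=16), geno, window_size=10)
    short = scan[scan["chrom"] == 2]
    assert len(short) == 1
    assert short["short_window"].all()
    assert short["n_snps"].iloc[0] == 4
    assert not scan[scan["chrom"] == 1]["short_window"].any()


def test_scan_invariant_to_individual_permutation():
    rng = np.random.default_rng(7)
    geno = make_geno(rng.integers(0, 3, (50, 20)))
    u = rng.normal(size=20)
    s1 = window_variance_scan(u, geno, sigma2_a=1.0)
    perm = rng.permutation(50)
    s2 = window_variance_scan(u, geno.subset(rows=perm), sigma2_a=1.0)
    assert np.allclose(s1["pct_variance"], s2["pct_variance"], atol=1e-12)


# --------------------------------------------------------------- regions
def test_regions_empty_when_nothing_significant():
    scan = pd.DataFrame(
        {
            "chrom": [1, 1], "start_bp": [1, 2], "end_bp": [10, 11],
            "start_index": [0, 1], "end_index": [9, 10],
            "n_snps": 10, "var_window": 0.0, "pct_variance": [0.01, 0.02],
            "short_window": False,
        }
    )
    assert significant_regions(scan, 0.15).empty


def test_regions_merge_overlapping_windows():
    """Two windows sharing 9 SNPs merge into one region of 11 SNPs."""
    scan = pd.DataFrame(
        {
            "chrom": [1, 1, 2],
            "start_bp": [100, 200, 50],
            "end_bp": [1000, 1100, 900],
            "start_index": [0, 1, 20],
            "end_index": [9, 10, 29],
            "n_snps": 10,
            "var_window": 0.001,
            "pct_variance": [0.2, 0.3, 0.5],
            "short_window": False,
        }
    )
    regions = significant_regions(scan, 0.15)
    assert len(regions) == 2
    r1 = regions[regions["chrom"] == 1].iloc[0]
    assert (r1["start_index"], r1["end_index"]) == (0, 10)  # 11 SNPs
    assert r1["n_windows"] == 2
    assert r1["max_pct"] == pytest.approx(0.3)
    assert r1["sum_pct"] == pytest.approx(0.5)
    assert regions[regions["chrom"] == 2]["max_pct"].iloc[0] == pytest.approx(0.5)


def test_regions_respect_threshold_boundary():
    scan = pd.DataFrame(
        {
            "chrom": [1], "start_bp": [100], "end_bp": [1000],
            "start_index": [0], "end_index": [9], "n_snps": 10,
            "var_window": 0.001, "pct_variance": [0.15], "short_window": False,
        }
    )
    # "0.15% or more": the boundary window is significant
    assert len(significant_regions(scan, 0.15)) == 1
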