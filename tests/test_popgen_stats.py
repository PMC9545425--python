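"""Diversity and differentiation statistics against hand arithmetic,
independent re-derivations, and simulation expectations."""

import numpy as np
import pandas as pd
import pytest

from knotpop.io_core import MISSING, PopulationMap
from knotpop import popgen_stats as ps
from knotpop.scenario_engine import Event, Population, Scenario, population_map_for, simulate_genotypes

from conftest import make_matrix, random_matrix, split_popmap
from helpers import random_additive_matrix, wc_theta_oracle


def _single_pop(g):
    return PopulationMap({s: "all" for s in g.sample_ids})


# ------------------------------------------------------------------ diversity


def test_site_pi_hand_value_and_monomorphic():
    # 10 diploids, p = 0.5: pi = 2*10*10/(20*19)
    calls = np.zeros((10, 2), dtype=np.int8)
    calls[:5, 0] = 2
    g = make_matrix(calls)
    per_site, mean_pi = ps.site_pi(g, _single_pop(g), "all")
    assert per_site[0] == pytest.approx(200 / 380, abs=1e-12)
    assert per_site[1] == 0.0  # monomorphic
    assert mean_pi == pytest.approx(100 / 380)


def test_site_pi_excludes_sites_without_called_alleles():
    calls = np.full((5, 2), MISSING, dtype=np.int8)
    calls[0, 1] = 1  # one called het genotype: pi = 2*1*1/(2*1) = 1
    g = make_matrix(calls)
    per_site, mean_pi = ps.site_pi(g, _single_pop(g), "all")
    assert np.isnan(per_site[0])
    assert per_site[1] == pytest.approx(1.0)
    assert mean_pi == pytest.approx(1.0)  # fully-missing site excluded from the mean


def test_all_het_individual_has_negative_fis(rng):
    g = random_matrix(rng, 20, 200)
    calls = g.calls.copy()
    calls[0, :] = 1
    g = make_matrix(calls)
    h_obs, fis = ps.heterozygosity_fis(g, _single_pop(g), "all")
    assert fis[g.sample_ids[0]] < 0
    assert 0 < h_obs < 1


def test_mean_fis_near_zero_under_hwe(rng):
    n, m = 30, 10000
    p = rng.uniform(0.1, 0.9, m)
    calls = (rng.binomial(1, p, (n, m)) + rng.binomial(1, p, (n, m))).astype(np.int8)
    g = make_matrix(calls)
    _, fis = ps.heterozygosity_fis(g, _single_pop(g), "all")
    assert abs(fis.mean()) < 0.02


def test_tajimas_d_hand_arithmetic_n4():
    # one locus, one segregating site, 2 diploids (n=4 alleles), singleton
    calls = np.array([[1], [0]], dtype=np.int8)
    g = make_matrix(calls, locus_ids=["L1"], contigs=["L1"])
    d = ps.tajimas_d(g, _single_pop(g), "all")
    n = 4
    a1 = 1 + 1 / 2 + 1 / 3
    a2 = 1 + 1 / 4 + 1 / 9
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    pi = 2 * 1 * 3 / (4 * 3)
    expect = (pi - 1 / a1) / np.sqrt(e1 * 1)
    assert d["L1"] == pytest.approx(expect, rel=1e-12)
    assert e2 > 0  # sanity on the constants path


def test_tajimas_d_mean_near_zero_under_neutral_simulation():
    sc = Scenario("neutral", [Population("A", 10, 10000.0)], [])
    g = simulate_genotypes(sc, {}, 500, seed=11)
    pm = population_map_for(sc)
    d = ps.tajimas_d(g, pm, "A")
    assert len(d) > 400
    assert abs(d.mean()) < 0.15


# ----------------------------------------------------------------------- F_ST


def test_wc_fst_equals_independent_rederivation_on_100_datasets(rng):
    for _ in range(100):
        g = random_matrix(rng, 16, 30, missing_rate=0.05)
        pm = split_popmap(g, 2)
        rows_a = pm.indices_for("pop0", g)
        rows_b = pm.indices_for("pop1", g)
        theta = ps.wc_fst(g, pm, "pop0", "pop1")
        assert theta == pytest.approx(wc_theta_oracle(g, rows_a, rows_b), abs=1e-12)


def test_wc_fst_relabelled_sample_is_zero(rng):
    g = random_matrix(rng, 40, 200)
    pm = split_popmap(g, 2)
    # same sample relabelled: duplicate rows into two pops
    calls = np.vstack([g.calls[:20], g.calls[:20]])
    g2 = make_matrix(calls)
    pm2 = split_popmap(g2, 2)
    theta = ps.wc_fst(g2, pm2, "pop0", "pop1")
    # the unbiased estimator is slightly negative on identical relabelled
    # samples (~ -1/(2n-1)); negative estimates are retained, not clamped
    assert theta == pytest.approx(-1 / (2 * 20 - 1), abs=0.02)
    assert abs(theta) < 0.05


def test_wc_fst_fixed_difference_is_near_one():
    calls = np.zeros((40, 50), dtype=np.int8)
    calls[20:, :] = 2
    g = make_matrix(calls)
    theta = ps.wc_fst(g, split_popmap(g, 2), "pop0", "pop1")
    assert theta == pytest.approx(1.0, abs=1e-9)


def test_fst_tracks_drift_expectation():
    for t_over_2n in (0.01, 0.05, 0.1):
        n_e = 10000.0
        sc = Scenario(
            "split",
            [Population("A", 20, n_e), Population("B", 20, n_e)],
            [Event(kind="merge", time=t_over_2n * 2 * n_e, source="B", dest="A")],
        )
        g = simulate_genotypes(sc, {}, 5000, seed=int(1000 * t_over_2n))
        pm = population_map_for(sc)
        theta = ps.wc_fst(g, pm, "A", "B")
        assert theta == pytest.approx(1 - np.exp(-t_over_2n), abs=0.02)


def test_fst_bootstrap_degenerate_single_locus(rng):
    g = random_matrix(rng, 20, 4)
    g = make_matrix(g.calls, locus_ids=["L"] * 4, contigs=["L"] * 4)
    pm = split_popmap(g, 2)
    theta = ps.wc_fst(g, pm, "pop0", "pop1")
    lo, hi = ps.fst_bootstrap_ci(g, pm, "pop0", "pop1", n_boot=50, rng=rng)
    assert lo == pytest.approx(theta) and hi == pytest.approx(theta)


def test_fst_bootstrap_ci_width_shrinks_with_loci(rng):
    sc = Scenario(
        "split",
        [Population("A", 15, 5000.0), Population("B", 15, 5000.0)],
        [Event(kind="merge", time=500.0, source="B", dest="A")],
    )
    widths = {}
    for n_loci in (200, 800):
        g = simulate_genotypes(sc, {}, n_loci, seed=7)
        pm = population_map_for(sc)
        lo, hi = ps.fst_bootstrap_ci(g, pm, "A", "B", n_boot=200, rng=rng)
        assert lo <= ps.wc_fst(g, pm, "A", "B") <= hi
        widths[n_loci] = hi - lo
    ratio = widths[200] / widths[800]  # expect ~ sqrt(4) = 2
    assert 1.3 < ratio < 3.2


def test_fst_permutation_p_minimum_when_diverged(rng):
    calls = np.zeros((30, 40), dtype=np.int8)
    calls[15:, :] = 2
    g = make_matrix(calls)
    pm = split_popmap(g, 2)
    p = ps.fst_permutation_p(g, pm, "pop0", "pop1", n_perm=99, rng=rng)
    assert p == pytest.approx(1 / 100)


def test_fst_permutation_p_roughly_uniform_under_panmixia(rng):
    from scipy import stats as sstats

    pvals = []
    for k in range(40):
        g = random_matrix(np.random.default_rng(500 + k), 20, 60)
        pm = split_popmap(g, 2)
        pvals.append(
            ps.fst_permutation_p(g, pm, "pop0", "pop1", n_perm=199, rng=rng)
        )
    assert sstats.kstest(pvals, "uniform").pvalue > 0.005


# ------------------------------------------------------------------------ Nei


def test_nei_identical_and_opposite_fixed():
    calls = np.zeros((20, 10), dtype=np.int8)
    calls[10:, :] = 2
    g = make_matrix(calls)
    pm = split_popmap(g, 2)
    d = ps.nei_distance(g, pm, "minimum")
    assert d.loc["pop0", "pop1"] == pytest.approx(1.0)  # opposite fixation: Dm=1/site
    same = make_matrix(np.vstack([calls[:10], calls[:10]]))
    d0 = ps.nei_distance(same, split_popmap(same, 2), "minimum")
    assert d0.loc["pop0", "pop1"] == pytest.approx(0.0, abs=1e-12)


def test_nei_three_pop_hand_computation():
    # 2 sites; frequencies by construction: popA p=(1.0, 0.5), popB p=(0.5, 0.5), popC p=(0.0, 1.0)
    calls = np.array(
        [
            [2, 1], [2, 1],          # A
            [1, 0], [1, 2],          # B
            [0, 2], [0, 2],          # C
        ],
        dtype=np.int8,
    )
    g = make_matrix(calls)
    pm = PopulationMap({g.sample_ids[i]: "ABC"[i // 2] for i in range(6)})
    d = ps.nei_distance(g, pm, "minimum")

    def dm(px, py):
        jx = np.array([x**2 + (1 - x) ** 2 for x in px])
        jy = np.array([y**2 + (1 - y) ** 2 for y in py])
        jxy = np.array([x * y + (1 - x) * (1 - y) for x, y in zip(px, py)])
        return np.mean((jx + jy) / 2 - jxy)

    assert d.loc["A", "B"] == pytest.approx(dm([1, 0.5], [0.5, 0.5]), abs=1e-12)
    assert d.loc["A", "C"] == pytest.approx(dm([1, 0.5], [0, 1]), abs=1e-12)
    assert d.loc["B", "C"] == pytest.approx(dm([0.5, 0.5], [0, 1]), abs=1e-12)
    assert np.allclose(d.to_numpy(), d.to_numpy().T)
    assert (np.diag(d.to_numpy()) == 0).all()


def test_nei_standard_is_nonnegative_option(rng):
    g = random_matrix(rng, 20, 50)
    d = ps.nei_distance(g, split_popmap(g, 2), "standard")
    assert d.loc["pop0", "pop1"] >= 0


# ------------------------------------------------------------------- NJ trees


@pytest.mark.parametrize("n_taxa", [4, 6, 8])
def test_nj_recovers_additive_matrices_exactly(rng, n_taxa):
    labels = [f"T{i}" for i in range(n_taxa)]
    d = random_additive_matrix(rng, labels)
    tree = ps.nj_tree(d)
    tips = {t.name: t for t in tree.tips()}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            patristic = tips[a].distance(tips[b])
            assert patristic == pytest.approx(d.loc[a, b], abs=1e-10)


def test_nj_requires_three_taxa():
    d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError):
        ps.nj_tree(d)


def test_nj_bootstrap_high_support_for_strong_split():
    n_e = 2000.0
    sc = Scenario(
        "twopairs",
        [Population(lab, 8, n_e) for lab in ("A1", "A2", "B1", "B2")],
        [
            Event(kind="merge", time=200.0, source="A2", dest="A1"),
            Event(kind="merge", time=200.0, source="B2", dest="B1"),
            Event(kind="merge", time=4000.0, source="B1", dest="A1"),
        ],
    )
    g = simulate_genotypes(sc, {}, 1000, seed=3)
    pm = population_map_for(sc)
    tree, support = ps.nj_bootstrap(g, pm, n_boot=100, rng=np.random.default_rng(4))
    split = frozenset({"A1", "A2"})
    assert split in support
    assert support[split] > 95.0


# ------------------------------------------------------------------------- PCA


def test_pca_matches_direct_eigendecomposition(rng):
    g = random_matrix(rng, 15, 120)
    res = ps.pca(g, n_components=5)
    # oracle: SVD of the explicitly normalised matrix
    p = g.calls.mean(axis=0) / 2
    keep = (p > 0) & (p < 1)
    x = (g.calls[:, keep] - 2 * p[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores_oracle = u * s / np.sqrt(x.shape[1])
    for k in range(5):
        got = res.scores.iloc[:, k].to_numpy()
        want = scores_oracle[:, k]
        assert np.allclose(got, want, atol=1e-8) or np.allclose(got, -want, atol=1e-8)
    assert res.explained.sum() == pytest.approx(1.0)
    assert (np.diff(res.explained) <= 1e-12).all()


def test_pca_separates_divergent_groups(rng):
    calls = rng.binomial(2, 0.5, (20, 300)).astype(np.int8)
    calls[10:, :150] = np.clip(calls[10:, :150] + 1, 0, 2)
    g = make_matrix(calls)
    res = ps.pca(g)
    pc1 = res.scores["PC1"].to_numpy()
    gap = abs(pc1[:10].mean() - pc1[10:].mean())
    spread = pc1[:10].std() + pc1[10:].std()
    assert gap > spread  # sign-invariant separation


def test_pca_scores_are_orthogonal(rng):
    g = random_matrix(rng, 12, 200)
    res = ps.pca(g, n_components=6)
    s = res.scores.to_numpy()
    gram = s.T @ s
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8
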