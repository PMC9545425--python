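"""QC chain: threshold edges, brute-force recount oracles, HWE enumeration,
LD-prune post-conditions, PI-HAT relationship recovery, relatedness resolution."""

import itertools

import numpy as np
import pytest
from knotpop.io_core import MISSING, PopulationMap
from knotpop import variant_qc as vq

from conftest import make_matrix, random_matrix, split_popmap
from helpers import hwe_enumeration_oracle, population_pool


# ------------------------------------------------------------------ call rate


def test_call_rate_threshold_edges():
    # 100 samples; variant 0 called in 79, variant 1 in 80
    calls = np.zeros((100, 2), dtype=np.int8)
    calls[79:, 0] = MISSING
    calls[80:, 1] = MISSING
    g = make_matrix(calls)
    out, stage = vq.filter_call_rate(g, 0.80)
    assert out.n_variants == 1
    assert list(out.variant_meta["contig"]) == ["locus_00001"]
    assert stage.n_removed_variants == 1


def test_call_rate_matches_brute_force_recount(rng):
    g = random_matrix(rng, 50, 200, missing_rate=0.25)
    out, _ = vq.filter_call_rate(g, 0.8)
    expected = {
        g.variant_meta["contig"][j]
        for j in range(g.n_variants)
        if sum(g.calls[i, j] != MISSING for i in range(50)) / 50 >= 0.8
    }
    assert set(out.variant_meta["contig"]) == expected


# ------------------------------------------------------------------------ MAC


def test_mac_removes_low_count_and_monomorphic():
    # 172 diploids: variant 0 has minor count 9 (removed at 10), variant 1 has 10
    calls = np.zeros((172, 3), dtype=np.int8)
    calls[:9, 0] = 1
    calls[:10, 1] = 1
    g = make_matrix(calls)  # variant 2 monomorphic
    out, _ = vq.filter_mac(g, 10)
    assert list(out.variant_meta["contig"]) == ["locus_00001"]


def test_mac_matches_brute_force_tally(rng):
    g = random_matrix(rng, 30, 100, missing_rate=0.2)
    out, _ = vq.filter_mac(g, 5)
    expected = set()
    for j in range(g.n_variants):
        col = [g.calls[i, j] for i in range(30) if g.calls[i, j] != MISSING]
        alt = sum(col)
        minor = min(alt, 2 * len(col) - alt)
        if minor >= 5:
            expected.add(g.variant_meta["contig"][j])
    assert set(out.variant_meta["contig"]) == expected


def test_drop_indels():
    calls = np.zeros((4, 10), dtype=np.int8)
    flags = [j in (1, 4, 7) for j in range(10)]
    g = make_matrix(calls, is_indel=flags)
    out, stage = vq.drop_indels(g)
    assert out.n_variants == 7
    assert stage.n_removed_variants == 3
    out2, stage2 = vq.drop_indels(out)
    assert out2.n_variants == 7 and stage2.n_removed_variants == 0


# ------------------------------------------------------------------------ HWE


def test_hwe_extreme_and_monomorphic():
    assert vq.hwe_exact_test(0, 20, 0) < 1e-4
    assert vq.hwe_exact_test(20, 0, 0) == 1.0
    assert vq.hwe_exact_test(0, 0, 20) == 1.0


def test_hwe_small_example_matches_enumeration():
    assert vq.hwe_exact_test(3, 5, 2) == pytest.approx(hwe_enumeration_oracle(3, 5, 2), rel=1e-12)


def test_hwe_matches_enumeration_for_all_small_configs():
    # every genotype configuration with n <= 25 diploids (subsampled grid)
    for n in (4, 7, 11, 16, 25):
        for n_aa in range(0, n + 1, 3):
            for n_ab in range(0, n - n_aa + 1, 2):
                n_bb = n - n_aa - n_ab
                got = vq.hwe_exact_test(n_aa, n_ab, n_bb)
                want = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
                assert got == pytest.approx(want, rel=1e-10, abs=1e-12), (n_aa, n_ab, n_bb)


def test_hwe_filter_min_pops_rule(rng):
    # 7 populations x 10 diploids; variant 0 all-het (deviates) everywhere,
    # variant 1 at HWE.  min_pops=6 removes only variant 0.
    n_pops, per = 7, 10
    calls = np.empty((n_pops * per, 2), dtype=np.int8)
    calls[:, 0] = 1
    calls[:, 1] = rng.binomial(1, 0.5, n_pops * per) + rng.binomial(1, 0.5, n_pops * per)
    g = make_matrix(calls)
    pm = split_popmap(g, n_pops)
    out, stage = vq.hwe_filter(g, pm, alpha=0.05, min_pops=6)
    assert stage.n_removed_variants == 1
    assert list(out.variant_meta["contig"]) == ["locus_00001"]


def test_hwe_filter_five_of_seven_retained():
    # all-het deviation in exactly 5 of 7 populations -> retained at min_pops=6
    n_pops, per = 7, 12
    calls = np.zeros((n_pops * per, 1), dtype=np.int8)
    for p in range(5):
        calls[p * per : (p + 1) * per, 0] = 1
    # pops 5,6 monomorphic (p=1 by convention)
    g = make_matrix(calls)
    pm = split_popmap(g, n_pops)
    out, _ = vq.hwe_filter(g, pm, alpha=0.05, min_pops=6)
    assert out.n_variants == 1
    out6, _ = vq.hwe_filter(g, pm, alpha=0.05, min_pops=5)
    assert out6.n_variants == 0


def test_hwe_true_data_rarely_removed(rng):
    # HWE-true genotypes: per-variant removal needs p<0.05 in >=6 of 7 pops,
    # binomial tail ~ 2e-7, so 400 variants should keep everything.
    n_pops, per = 7, 15
    p = rng.uniform(0.2, 0.8, 400)
    calls = (
        rng.binomial(1, p, (n_pops * per, 400)) + rng.binomial(1, p, (n_pops * per, 400))
    ).astype(np.int8)
    g = make_matrix(calls)
    out, _ = vq.hwe_filter(g, split_popmap(g, n_pops), 0.05, 6)
    assert out.n_variants == 400


# ------------------------------------------------------------------ LD pruning


def test_ld_prune_removes_one_of_duplicated_pair(rng):
    base = random_matrix(rng, 40, 1)
    calls = np.repeat(base.calls, 2, axis=1)
    g = make_matrix(calls)
    out, stage = vq.ld_prune(g, r2_max=0.20, window=10, step=5)
    assert out.n_variants == 1
    assert stage.n_removed_variants == 1


def test_ld_prune_keeps_independent_snps(rng):
    g = random_matrix(rng, 200, 60)
    out, _ = vq.ld_prune(g, r2_max=0.20, window=20, step=5)
    assert out.n_variants >= 58  # ~0 removals expected among independent SNPs


def test_ld_prune_exhaustive_post_check(rng):
    # correlated blocks: duplicate every 3rd SNP with noise
    g = random_matrix(rng, 100, 40)
    calls = g.calls.copy()
    for j in range(0, 40, 3):
        k = (j + 1) % 40
        calls[:, k] = calls[:, j]
        flip = rng.random(100) < 0.05
        calls[flip, k] = np.clip(calls[flip, k] + 1, 0, 2)
    g = make_matrix(calls)
    window, r2_max = 15, 0.20
    out, _ = vq.ld_prune(g, r2_max=r2_max, window=window, step=5)
    kept = set(out.variant_meta["contig"])
    idx = [j for j in range(g.n_variants) if g.variant_meta["contig"][j] in kept]
    # exhaustive within-window recomputation on the retained set
    for a_pos, a in enumerate(idx):
        for b in idx[a_pos + 1 :]:
            if b - a >= window:
                continue
            r2 = vq._pairwise_r2(g.calls[:, a], g.calls[:, b])
            assert r2 <= r2_max + 1e-9, (a, b, r2)


def test_ld_prune_rejects_tiny_window(rng):
    with pytest.raises(ValueError):
        vq.ld_prune(random_matrix(rng, 10, 5), window=1)


# ----------------------------------------------------------------- missingness


def test_sample_missingness_threshold_edges():
    calls = np.zeros((3, 100), dtype=np.int8)
    calls[0, :26] = MISSING  # 26% -> removed at 0.25
    calls[1, :25] = MISSING  # 25% -> retained (> rule)
    g = make_matrix(calls)
    out, stage = vq.drop_samples(g, 0.25)
    assert out.sample_ids == g.sample_ids[1:]
    assert stage.n_removed_samples == 1


def test_missingness_matches_brute_force(rng):
    g = random_matrix(rng, 25, 80, missing_rate=0.3)
    miss = vq.individual_missingness(g)
    for i, s in enumerate(g.sample_ids):
        brute = sum(g.calls[i, j] == MISSING for j in range(80)) / 80
        assert miss[s] == pytest.approx(brute)


# --------------------------------------------------------------------- PI-HAT


def test_pihat_duplicate_unrelated_parent_offspring(rng):
    n_snps = 5000
    p, calls, hap1 = population_pool(rng, 12, n_snps)
    # child: one allele from parent 0, one random from the pool
    child = (hap1[0] + rng.binomial(1, p)).astype(np.int8)
    dup = calls[1].copy()
    all_calls = np.vstack([calls, child[None, :], dup[None, :]])
    g = make_matrix(all_calls)
    rm = vq.pihat(g)
    ids = g.sample_ids
    # unrelated draws from one frequency pool
    assert abs(rm.pihat[2, 3]) < 0.05
    assert abs(rm.pihat[0, 5]) < 0.05
    # parent-offspring ~ 0.5
    assert rm.pihat[0, 12] == pytest.approx(0.5, abs=0.05)
    # duplicated sample ~ 1
    assert rm.pihat[1, 13] == pytest.approx(1.0, abs=0.05)
    assert np.allclose(rm.pihat, rm.pihat.T)


def test_pihat_low_confidence_flag(rng):
    g = random_matrix(rng, 3, 40)
    rm = vq.pihat(g, min_pair_variants=50)
    assert rm.low_confidence[0, 1]


# ---------------------------------------------------------- resolve relatives


def _rm_from_edges(ids, edges):
    n = len(ids)
    m = np.zeros((n, n))
    np.fill_diagonal(m, 1.0)
    for a, b in edges:
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = 0.5
    return vq.RelatednessMatrix(ids, m, np.zeros((n, n), dtype=bool))


def test_resolve_related_single_pair_and_empty():
    rm = _rm_from_edges(["a", "b", "c"], [("a", "b")])
    assert len(vq.resolve_related(rm, 0.2)) == 1
    rm0 = _rm_from_edges(["a", "b", "c"], [])
    assert vq.resolve_related(rm0, 0.2) == set()


def test_resolve_related_triangle_matches_minimal_vertex_cover():
    ids = ["a", "b", "c", "d", "e"]
    edges = [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e")]
    rm = _rm_from_edges(ids, edges)
    removed = vq.resolve_related(rm, 0.2)
    # exhaustive minimum vertex cover on <=6 nodes
    best = min(
        (
            set(sub)
            for r in range(len(ids) + 1)
            for sub in itertools.combinations(ids, r)
            if all(a in sub or b in sub for a, b in edges)
        ),
        key=len,
    )
    assert len(removed) == len(best) == 3
    assert all(a in removed or b in removed for a, b in edges)


# ------------------------------------------------------------------ full chain


def test_run_qc_constructive_fixture(rng):
    """Engineer one known violation per filter and check the report."""
    n_pops, per = 7, 12
    n_samples = n_pops * per
    p = rng.uniform(0.3, 0.7, 60)
    calls = (
        rng.binomial(1, p, (n_samples, 60)) + rng.binomial(1, p, (n_samples, 60))
    ).astype(np.int8)
    flags = [False] * 60
    calls[: int(n_samples * 0.5), 0] = MISSING  # call rate 50% -> removed
    calls[:, 1] = 0
    calls[0, 1] = 1  # MAC 1 -> removed
    flags[2] = True  # indel -> removed
    calls[:, 3] = 1  # all-het in every pop -> HWE removal
    calls[:, 5] = calls[:, 4]  # duplicate pair -> LD removal
    g = make_matrix(calls, is_indel=flags)
    pm = split_popmap(g, n_pops)
    out, report = vq.run_qc(
        g, pm, {"min_mac": 2, "ld_window": 10, "max_missing": 0.25}
    )
    by_name = {st.name: st for st in report.stages}
    assert by_name["call_rate"].n_removed_variants == 1
    assert by_name["mac"].n_removed_variants == 1
    assert by_name["indels"].n_removed_variants == 1
    assert by_name["hwe"].n_removed_variants == 1
    assert by_name["ld_prune"].n_removed_variants == 1
    report.validate()
    # telescoping: initial minus all removals equals final
    assert report.stages[0].n_variants_before - sum(
        st.n_removed_variants for st in report.stages
    ) == out.n_variants == report.final_variants


def test_qc_report_rejects_inconsistent_chain():
    rep = vq.QcReport()
    rep.add(vq.QcStage("a", 100, 90, 10, 10))
    with pytest.raises(ValueError, match="chain"):
        rep.add(vq.QcStage("b", 95, 90, 10, 10))


def test_run_qc_rejects_unknown_config(rng):
    g = random_matrix(rng, 14, 10)
    with pytest.raises(ValueError, match="unknown"):
        vq.run_qc(g, split_popmap(g, 7), {"bogus": 1})
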