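"""F_IS, Weir–Cockerham F_ST, and f3/f4 block-jackknife statistics."""

import numpy as np
import pytest

import zebupop as z

from conftest import make_panel


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------


def test_fis_extreme_loci():
    # 5 AA + 5 aa: Ho=0, He=0.5 -> FIS=1; all-het locus: Ho=1 -> FIS=-1
    calls = np.column_stack([
        np.array([0] * 5 + [2] * 5),
        np.ones(10, dtype=int),
    ])
    panel = make_panel(calls)
    res = z.fis_nei(panel, "B1")
    np.testing.assert_allclose(res.per_locus, [1.0, -1.0])
    assert res.value == pytest.approx(0.0)


def test_fis_near_zero_under_hwe():
    cfg = z.SimConfig(seed=3, n_per_breed=50, n_markers=20000, breed_f=(0.05,))
    panel = z.balding_nichols_panel(cfg)
    res = z.fis_nei(panel, "BREED1")
    assert abs(res.value) < 0.02
    assert res.sd_loci > 0


def test_fis_monomorphic_only_rejected():
    panel = make_panel(np.zeros((4, 10), dtype=np.int8))
    with pytest.raises(z.ZebuPopError, match="polymorphic"):
        z.fis_nei(panel, "B1")


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST
# ---------------------------------------------------------------------------


def _wc_single_locus_oracle(g1, g2):
    """Independent brute-force evaluation of the 1984 a,b,c components."""
    n1, n2 = len(g1), len(g2)
    p1, p2 = sum(g1) / (2 * n1), sum(g2) / (2 * n2)
    h1 = sum(1 for g in g1 if g == 1) / n1
    h2 = sum(1 for g in g2 if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def test_wc_single_locus_matches_component_oracle():
    rng = np.random.default_rng(8)
    g1 = rng.binomial(2, 0.7, 10)
    g2 = rng.binomial(2, 0.3, 10)
    panel = make_panel(
        np.concatenate([g1, g2])[:, None], breeds=["A"] * 10 + ["B"] * 10
    )
    res = z.fst_weir_cockerham(panel, "A", "B")
    assert res.value == pytest.approx(_wc_single_locus_oracle(g1, g2), abs=1e-12)


def test_wc_multilocus_matches_locus_by_locus_aggregation():
    cfg = z.SimConfig(seed=44, n_per_breed=15, n_markers=300, breed_f=(0.1, 0.1))
    panel = z.balding_nichols_panel(cfg)
    res = z.fst_weir_cockerham(panel, "BREED1", "BREED2")
    # brute force: per-locus components summed explicitly
    i1 = panel.samples_in_breed("BREED1")
    i2 = panel.samples_in_breed("BREED2")
    num = den = 0.0
    for j in range(panel.n_markers):
        g1 = panel.calls[i1, j]
        g2 = panel.calls[i2, j]
        p1, p2 = g1.sum() / (2 * len(g1)), g2.sum() / (2 * len(g2))
        if (p1 == 0 and p2 == 0) or (p1 == 1 and p2 == 1):
            continue
        theta = _wc_single_locus_oracle(list(g1), list(g2))
        # re-derive components from the oracle pieces
        n1, n2 = len(g1), len(g2)
        h1 = (g1 == 1).mean()
        h2 = (g2 == 1).mean()
        r, nbar = 2, (n1 + n2) / 2
        nc = (2 * nbar - (n1**2 + n2**2) / (2 * nbar)) / 1
        pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
        a = (nbar / nc) * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - s2 / 2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    assert res.value == pytest.approx(num / den, abs=1e-12)


def test_wc_limits_fixed_difference_and_null_split():
    panel = make_panel(
        np.column_stack([
            np.array([2] * 30 + [0] * 30),
            np.array([0] * 30 + [2] * 30),
        ]),
        breeds=["A"] * 30 + ["B"] * 30,
    )
    assert z.fst_weir_cockerham(panel, "A", "B").value == pytest.approx(1.0)
    cfg = z.SimConfig(seed=45, n_per_breed=60, n_markers=20000, breed_f=(0.05,))
    one = z.balding_nichols_panel(cfg)
    relabeled = z.GenotypePanel(
        sample_ids=one.sample_ids,
        breed_labels=["H1"] * 30 + ["H2"] * 30,
        markers=one.markers,
        calls=one.calls,
    )
    assert abs(z.fst_weir_cockerham(relabeled, "H1", "H2").value) < 0.01


def test_wc_invariant_to_allele_label_swap(two_breed_panel):
    theta = z.fst_weir_cockerham(two_breed_panel, "BREED1", "BREED2").value
    flipped_calls = two_breed_panel.calls.copy()
    flipped_calls[:, ::3] = 2 - flipped_calls[:, ::3]  # swap labels at every 3rd locus
    flipped = z.GenotypePanel(
        sample_ids=two_breed_panel.sample_ids,
        breed_labels=two_breed_panel.breed_labels,
        markers=two_breed_panel.markers,
        calls=flipped_calls,
    )
    assert z.fst_weir_cockerham(flipped, "BREED1", "BREED2").value == pytest.approx(
        theta, abs=1e-12
    )


def test_fst_matrix_recovers_planted_ordering():
    cfg = z.SimConfig(seed=46, n_per_breed=50, n_markers=20000,
                      breed_f=(0.02, 0.05, 0.1, 0.2))
    panel = z.balding_nichols_panel(cfg)
    m = z.fst_matrix(panel)
    assert (m.values == m.values.T).all()
    # pairs with larger combined planted F show larger theta
    assert m.loc["BREED1", "BREED2"] < m.loc["BREED1", "BREED3"]
    assert m.loc["BREED1", "BREED3"] < m.loc["BREED1", "BREED4"]
    assert m.loc["BREED2", "BREED3"] < m.loc["BREED3", "BREED4"]


# ---------------------------------------------------------------------------
# f3 / f4
# ---------------------------------------------------------------------------


def test_f3_zero_for_identical_populations():
    rng = np.random.default_rng(5)
    p = rng.uniform(0.1, 0.9, 5000)
    res = z.f3(p, p, p, block_size=1000, correction=False)
    assert res.estimate == 0.0
    assert res.z == 0.0


def test_f3_negative_for_frequency_midpoint():
    # A exactly midway between diverged B and C:
    # (pA-pB)(pA-pC) = -((pB-pC)/2)^2 < 0
    rng = np.random.default_rng(6)
    pb = rng.uniform(0.1, 0.9, 10000)
    pc = np.clip(pb + rng.normal(0, 0.2, 10000), 0.01, 0.99)
    pa = (pb + pc) / 2
    res = z.f3(pa, pb, pc, block_size=1000, correction=False)
    expected = -np.mean(((pb - pc) / 2) ** 2)
    assert res.estimate == pytest.approx(expected, rel=1e-12)
    assert res.z < z.fstats.Z_ADMIXED and res.admixture_call


def test_f3_detects_simulated_admixture_at_study_scale(diverged_pools):
    # 50/50 admixed target with 35 blocks of 1000 SNPs -> Z < -3
    fi, ft = diverged_pools
    cfg = z.SimConfig(seed=61, n_markers=35000)
    fb = z.pool_freq_table(cfg, "indicine")
    fc = z.pool_freq_table(cfg, "taurine")
    adm = z.admix_individuals(fc, fb, np.full(20, 0.5), seed=62)
    pa = z.allele_frequencies(adm, "pooled").freq[0]
    res = z.f3(pa, fb.freq[0], fc.freq[0], block_size=1000, n_a=20)
    assert res.n_blocks == 35
    assert res.z < -3
    assert res.admixture_call


def test_f4_zero_when_a_equals_b():
    rng = np.random.default_rng(7)
    pa = rng.uniform(0.1, 0.9, 4000)
    pc = rng.uniform(0.1, 0.9, 4000)
    pd_ = rng.uniform(0.1, 0.9, 4000)
    res = z.f4(pa, pa, pc, pd_, block_size=1000)
    assert res.estimate == 0.0


def test_f4_null_calibration_on_tree_consistent_data():
    # ((A,B),(C,D)) without gene flow: |Z| < 3 in >= 19/20 replicates
    hits = 0
    reps = 20
    for rep in range(reps):
        rng = np.random.default_rng(900 + rep)
        anc = rng.uniform(0.1, 0.9, 20000)
        left = np.clip(anc + rng.normal(0, 0.05, anc.shape), 0.01, 0.99)
        right = np.clip(anc + rng.normal(0, 0.05, anc.shape), 0.01, 0.99)
        n = 2 * 30
        pa = rng.binomial(n, np.clip(left + rng.normal(0, 0.03, anc.shape), 0.01, 0.99)) / n
        pb = rng.binomial(n, np.clip(left + rng.normal(0, 0.03, anc.shape), 0.01, 0.99)) / n
        pc = rng.binomial(n, np.clip(right + rng.normal(0, 0.03, anc.shape), 0.01, 0.99)) / n
        pd_ = rng.binomial(n, np.clip(right + rng.normal(0, 0.03, anc.shape), 0.01, 0.99)) / n
        if abs(z.f4(pa, pb, pc, pd_, block_size=1000).z) < 3:
            hits += 1
    assert hits >= 19


def test_f4_z_grows_with_planted_gene_flow():
    rng = np.random.default_rng(77)
    anc = rng.uniform(0.1, 0.9, 30000)
    left = np.clip(anc + rng.normal(0, 0.08, anc.shape), 0.01, 0.99)
    right = np.clip(anc + rng.normal(0, 0.08, anc.shape), 0.01, 0.99)
    pa = np.clip(left + rng.normal(0, 0.03, anc.shape), 0.01, 0.99)
    pc = np.clip(right + rng.normal(0, 0.03, anc.shape), 0.01, 0.99)
    pd_ = np.clip(right + rng.normal(0, 0.03, anc.shape), 0.01, 0.99)
    zs = []
    for flow in (0.0, 0.2, 0.4):
        pb = (1 - flow) * np.clip(left + rng.normal(0, 0.03, anc.shape), 0.01, 0.99) + flow * pc
        zs.append(z.f4(pa, pb, pc, pd_, block_size=1000).z)
    # C->B flow makes (pA-pB)(pC-pD) systematically nonzero, growing with flow
    assert abs(zs[0]) < abs(zs[1]) < abs(zs[2])
    assert abs(zs[2]) > 3


def test_jackknife_se_matches_analytic_and_shrinks():
    # on iid data the jackknife SE of the mean should approach sigma/sqrt(m),
    # hence shrink ~2x when the homogeneous data (and block count) grow 4x
    rng = np.random.default_rng(88)
    sigma = 0.1
    for m in (16000, 64000):
        ses = [z.fstats._block_jackknife(rng.normal(0.01, sigma, m), 1000)[1]
               for _ in range(10)]
        assert np.mean(ses) == pytest.approx(sigma / np.sqrt(m), rel=0.15)


def test_jackknife_handles_short_trailing_block():
    rng = np.random.default_rng(89)
    x = rng.normal(0, 1.0, 10500)  # trailing block of 500 SNPs
    est, se, g = z.fstats._block_jackknife(x, 1000)
    assert g == 11
    assert est == pytest.approx(x.mean(), abs=1e-12)
    assert se == pytest.approx(1.0 / np.sqrt(10500), rel=0.5)
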