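"""Synthetic-panel generators: divergence, drift, admixture, relatives, ROH."""

import numpy as np
import pytest

import zebupop as z


# ---------------------------------------------------------------------------
# Balding–Nichols breeds
# ---------------------------------------------------------------------------


def test_bn_panel_deterministic_and_f_zero_degenerate():
    cfg = z.SimConfig(seed=4, n_per_breed=10, n_markers=500, breed_f=(0.0, 0.1))
    p1, t1 = z.balding_nichols_panel(cfg, return_truth=True)
    p2, t2 = z.balding_nichols_panel(cfg, return_truth=True)
    np.testing.assert_array_equal(p1.calls, p2.calls)
    # F=0 breed copies the ancestral frequencies exactly
    np.testing.assert_array_equal(t1["breed_freqs"]["BREED1"], t1["ancestral_p"])


def test_bn_breed_frequency_variance_tracks_f():
    # across-breed variance of breed frequencies approaches F p (1-p)
    cfg = z.SimConfig(
        seed=8, n_per_breed=2, n_markers=20000, breed_f=tuple([0.2] * 30),
        ancestral_freq_range=(0.5, 0.5),
    )
    _, truth = z.balding_nichols_panel(cfg, return_truth=True)
    stacked = np.stack(list(truth["breed_freqs"].values()))
    var = stacked.var(axis=0).mean()
    assert var == pytest.approx(0.2 * 0.25, rel=0.05)


@pytest.mark.parametrize("f", [0.05, 0.2])
def test_bn_fst_recovery(f):
    cfg = z.SimConfig(seed=11, n_per_breed=50, n_markers=20000, breed_f=(f, f))
    panel = z.balding_nichols_panel(cfg)
    theta = z.fst_weir_cockerham(panel, "BREED1", "BREED2").value
    assert theta == pytest.approx(f, abs=0.02)


# ---------------------------------------------------------------------------
# Wright–Fisher engine
# ---------------------------------------------------------------------------


def test_wf_deterministic_given_seed():
    traj = z.NeTrajectory(((1, 50),))
    kwargs = dict(n_sample=10, chrom_length_bp=2_000_000, n_chromosomes=1,
                  marker_density=2e-4, seed=3)
    a = z.wright_fisher_simulate(traj, **kwargs)
    b = z.wright_fisher_simulate(traj, **kwargs)
    np.testing.assert_array_equal(a.calls, b.calls)


def test_wf_heterozygosity_decay_matches_drift_expectation():
    # per-generation expected het decay factor is (1 - 1/(2Ne)); averaged over
    # many short, effectively unlinked chromosomes to tame drift correlation
    ne, gens = 50, 60
    traj = z.NeTrajectory(((gens, ne),))
    losses = []
    for seed in range(10):
        p = z.wright_fisher_simulate(
            traj, n_sample=ne, chrom_length_bp=50_000, n_chromosomes=20,
            marker_density=2e-3, seed=seed, burn_in=0, init_freq_range=(0.5, 0.5),
        )
        freq = z.allele_frequencies(p, "pooled").freq[0]
        h = 2 * freq * (1 - freq)
        losses.append(h.mean() / 0.5)
    expected = (1 - 1 / (2 * ne)) ** gens
    assert np.mean(losses) == pytest.approx(expected, rel=0.15)


def test_wf_small_ne_fixes_everything():
    traj = z.NeTrajectory(((300, 2),))
    p = z.wright_fisher_simulate(
        traj, n_sample=2, chrom_length_bp=1_000_000, n_chromosomes=1,
        marker_density=5e-4, seed=1, burn_in=0,
    )
    freq = z.allele_frequencies(p, "pooled").freq[0]
    het = 2 * freq * (1 - freq)
    assert het.mean() < 0.02


def test_wf_sved_expectation_at_known_ne():
    # Sved: E[r2_adj] at c=0.005 Morgan with Ne=100 is 1/(1+4*100*0.005) = 1/3
    vals = []
    for seed in range(62, 62 + 20):
        p = z.wright_fisher_simulate(
            z.NeTrajectory(((1, 100),)), n_sample=50, chrom_length_bp=4_000_000,
            n_chromosomes=1, marker_density=4e-4, seed=seed,
        )
        try:
            p = z.filter_markers_by_maf(p, min_maf=0.05)
        except z.EmptyResultError:  # a whole linked block can fix by drift
            continue
        pairs = z.pairwise_r2(p, max_dist_bp=600_000, min_dist_bp=400_000)
        if len(pairs) == 0:
            continue
        vals.append(float(np.mean(z.adjust_r2(pairs.r2, pairs.n))))
    assert len(vals) >= 10
    assert np.mean(vals) == pytest.approx(1 / 3, rel=0.25)


def test_wf_r2_decay_monotone_after_binning():
    frames = []
    for seed in range(10):
        p = z.wright_fisher_simulate(
            z.NeTrajectory(((1, 100),)), n_sample=50, chrom_length_bp=5_000_000,
            n_chromosomes=1, marker_density=4e-4, seed=100 + seed,
        )
        try:
            p = z.filter_markers_by_maf(p, min_maf=0.05)
        except z.EmptyResultError:
            continue
        frames.append(z.pairwise_r2(p, max_dist_bp=3_000_000))
    import pandas as pd

    pairs = pd.concat(frames, ignore_index=True)
    curve = z.ld_decay_curve(pairs, bin_width_bp=500_000, max_dist_bp=3_000_000)
    smooth = curve.mean_r2.rolling(3, center=True, min_periods=1).mean()
    assert (np.diff(smooth) <= 1e-3).all()


def test_wf_rejects_oversampling():
    with pytest.raises(z.ZebuPopError, match="cannot sample"):
        z.wright_fisher_simulate(
            z.NeTrajectory(((1, 10),)), n_sample=50, chrom_length_bp=1_000_000,
            n_chromosomes=1, marker_density=1e-4, seed=0,
        )


# ---------------------------------------------------------------------------
# admixture
# ---------------------------------------------------------------------------


def test_admix_q1_draws_from_pool_a(diverged_pools):
    fi, ft = diverged_pools
    panel = z.admix_individuals(ft, fi, np.ones(40), seed=6)
    observed = z.allele_frequencies(panel, "pooled").freq[0]
    # frequencies should track pool a, not pool b
    ca = np.corrcoef(observed, ft.freq[0])[0, 1]
    cb = np.corrcoef(observed, fi.freq[0])[0, 1]
    assert ca > 0.97 and ca > cb + 0.1


def test_admix_mismatched_marker_sets_rejected(diverged_pools):
    fi, ft = diverged_pools
    short = z.AlleleFreqTable(
        groups=fi.groups, freq=fi.freq[:, :100], n_alleles=fi.n_alleles[:, :100],
        markers=fi.markers.subset(np.arange(100)),
    )
    with pytest.raises(z.ConsistencyError):
        z.admix_individuals(short, ft, np.full(3, 0.5), seed=0)


# ---------------------------------------------------------------------------
# planted ROH and relatives
# ---------------------------------------------------------------------------


def test_plant_roh_identity_and_overlap_guard():
    cfg = z.SimConfig(seed=2, n_per_breed=3, n_markers=300, breed_f=(0.05,),
                      n_chromosomes=1)
    panel = z.balding_nichols_panel(cfg)
    unchanged = z.plant_roh(panel, [])
    np.testing.assert_array_equal(panel.calls, unchanged.calls)
    sid = panel.sample_ids[0]
    with pytest.raises(z.ConsistencyError, match="overlap"):
        z.plant_roh(panel, [(sid, "1", 1_000_000, 3_000_000),
                            (sid, "1", 2_000_000, 4_000_000)])


def test_plant_roh_outside_segment_untouched():
    cfg = z.SimConfig(seed=2, n_per_breed=3, n_markers=300, breed_f=(0.05,),
                      n_chromosomes=1, chrom_length_bp=30_000_000)
    panel = z.balding_nichols_panel(cfg)
    sid = panel.sample_ids[1]
    planted = z.plant_roh(panel, [(sid, "1", 5_000_000, 8_000_000)], seed=3)
    pos = np.asarray(panel.markers.position_bp)
    outside = (pos < 5_000_000) | (pos >= 8_000_000)
    i = panel.sample_ids.index(sid)
    np.testing.assert_array_equal(panel.calls[i, outside], planted.calls[i, outside])
    inside = ~outside
    assert (planted.calls[i, inside] != 1).all()  # all homozygous in segment


def test_inject_relatives_pedigree_expectation():
    cfg = z.SimConfig(seed=5, n_per_breed=60, n_markers=20000, breed_f=(0.05,))
    panel = z.balding_nichols_panel(cfg)
    bigger, truth = z.inject_relatives(panel, pairs=3, kinship="parent_offspring", seed=7)
    assert bigger.n_samples == panel.n_samples + 3
    grm = z.grm_vanraden(bigger)
    for parent, child, expected in truth:
        i, j = bigger.sample_ids.index(parent), bigger.sample_ids.index(child)
        assert grm.matrix[i, j] == pytest.approx(expected, abs=0.1)


def test_inject_relatives_full_sibs_and_identity():
    cfg = z.SimConfig(seed=6, n_per_breed=40, n_markers=20000, breed_f=(0.05,))
    panel = z.balding_nichols_panel(cfg)
    same, truth = z.inject_relatives(panel, pairs=0, kinship="full_sib", seed=1)
    assert same.n_samples == panel.n_samples and truth == []
    # sib relationship varies chromosome-by-chromosome; test the mean over
    # pairs, centering with founder-population frequencies so the estimated-p
    # shrinkage of relative-heavy panels does not bias the pedigree expectation
    bigger, truth = z.inject_relatives(panel, pairs=8, kinship="full_sib", seed=1)
    founder_freqs = z.allele_frequencies(panel, "pooled")
    grm = z.grm_vanraden(bigger, freqs=founder_freqs)
    vals = [
        grm.matrix[bigger.sample_ids.index(a), bigger.sample_ids.index(b)]
        for a, b, _ in truth
    ]
    assert np.mean(vals) == pytest.approx(0.5, abs=0.1)
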