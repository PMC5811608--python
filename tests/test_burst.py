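"""Burst search, PIE partition, corrections and stoichiometry gating."""

import numpy as np
import pytest

import protconf as pc
from protconf.burst import ACCEPTOR_EM, ACCEPTOR_EX, DONOR_EM, DONOR_EX

from conftest import make_stream


def brute_force_bursts(stream, window_ms=0.5, min_counts=35, region_threshold=10):
    """Independent O(n^2) windowed-count burst search."""
    t = stream.timestamps
    n = len(t)
    half = int(round(window_ms * 1e6 / 2))
    in_region = []
    for i in range(n):
        count = int(np.sum((t >= t[i] - half) & (t <= t[i] + half)))
        in_region.append(count >= region_threshold)
    # maximal runs, breaking on out-of-region photons or >= one window of silence
    runs = []
    i = 0
    while i < n:
        if not in_region[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and in_region[j + 1]
               and t[j + 1] - t[j] < 2 * half):
            j += 1
        runs.append([i, j + 1])
        i = j + 1
    merged = []
    for a, b in runs:
        if merged and t[a] - t[merged[-1][1] - 1] < 2 * half:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged if (b - a) > min_counts]


class TestFindBursts:
    def test_empty_stream(self):
        stream = make_stream([])
        assert pc.find_bursts(stream) == []

    def test_isolated_cluster_is_one_burst(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.integers(0, 400_000, 50))  # 50 photons in 0.4 ms
        t = np.unique(t)
        while len(t) < 50:
            t = np.unique(np.concatenate([t, t[-1:] + 1]))
        stream = make_stream(t + 20_000_000)  # >= 10 ms silence on both sides
        bursts = pc.find_bursts(stream)
        assert len(bursts) == 1
        assert bursts[0].n_photons == 50

    @pytest.mark.parametrize("n,expected", [(35, 0), (36, 1)])
    def test_min_counts_threshold_is_strict(self, n, expected):
        t = np.linspace(0, 400_000, n).astype(np.int64) + 10_000_000
        bursts = pc.find_bursts(make_stream(t))
        assert len(bursts) == expected

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # sparse background + a few dense clusters
        t_bg = rng.integers(0, int(2e8), 400)
        clusters = []
        for _ in range(rng.integers(1, 6)):
            t0 = rng.integers(0, int(2e8))
            clusters.append(t0 + rng.integers(0, 1_000_000, rng.integers(10, 120)))
        t = np.unique(np.concatenate([t_bg] + clusters))
        stream = make_stream(t)
        got = [(b.start, b.stop) for b in pc.find_bursts(stream)]
        assert got == brute_force_bursts(stream)

    def test_translation_and_padding_invariance(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.integers(0, 500_000, 60)).astype(np.int64)
        t = np.unique(t)
        base = [(b.start, b.stop) for b in pc.find_bursts(make_stream(t + 5_000_000))]
        shifted = [(b.start, b.stop)
                   for b in pc.find_bursts(make_stream(t + 905_000_000))]
        padded = [(b.start, b.stop)
                  for b in pc.find_bursts(make_stream(
                      np.concatenate([t + 5_000_000, [int(9e9)]])))]
        assert base == shifted
        assert base == padded

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            pc.find_bursts(make_stream([1, 2, 3]), window_ms=0)


class TestIntegrateBurst:
    def test_three_photon_tally(self):
        stream = make_stream(
            [10, 20, 30],
            channel=[DONOR_EM, ACCEPTOR_EM, ACCEPTOR_EM],
            excitation=[DONOR_EX, DONOR_EX, ACCEPTOR_EX],
        )
        c = pc.integrate_burst(stream, pc.Burst(0, 3, 10, 30))
        assert (c.f_dd, c.f_da, c.f_aa) == (1, 1, 1)

    def test_all_donor(self):
        stream = make_stream(np.arange(1, 21))
        c = pc.integrate_burst(stream, pc.Burst(0, 20, 1, 20))
        assert (c.f_dd, c.f_da, c.f_aa) == (20, 0, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tags_match_naive_tally(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        ch = rng.integers(0, 2, n)
        ex = rng.integers(0, 2, n)
        stream = make_stream(np.arange(1, n + 1), ch, ex)
        burst = pc.Burst(17, 131, 18, 131)
        c = pc.integrate_burst(stream, burst)
        sl = slice(17, 131)
        assert c.f_dd == sum((ch[sl] == DONOR_EM) & (ex[sl] == DONOR_EX))
        assert c.f_da == sum((ch[sl] == ACCEPTOR_EM) & (ex[sl] == DONOR_EX))
        assert c.f_aa == sum((ch[sl] == ACCEPTOR_EM) & (ex[sl] == ACCEPTOR_EX))
        assert c.f_d_aex == sum((ch[sl] == DONOR_EM) & (ex[sl] == ACCEPTOR_EX))

    def test_out_of_range_burst(self):
        stream = make_stream([1, 2, 3])
        with pytest.raises(IndexError):
            pc.integrate_burst(stream, pc.Burst(0, 4, 1, 4))


class TestComputeES:
    def test_no_acceptor_signal(self):
        p = pc.compute_es(pc.ChannelCounts(100, 0, 50), pc.CorrectionSet.neutral())
        assert p.e == 0.0
        assert p.s == pytest.approx(100 / 150)

    def test_hand_evaluated_corrections(self):
        # F_corr = 100 - 0.08*100 - 0.15*100 = 77
        p = pc.compute_es(pc.ChannelCounts(100, 100, 100),
                          pc.CorrectionSet(0.08, 0.15, 0.85))
        assert p.e == pytest.approx(77 / 162, abs=1e-12)
        assert p.s == pytest.approx(162 / 262, abs=1e-12)

    def test_default_corrections_are_calibrated_values(self):
        c = pc.CorrectionSet()
        assert (c.lk, c.de, c.gamma) == (0.08, 0.15, 0.85)

    def test_neutral_reduces_to_proximity_ratio(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            f_dd, f_da, f_aa = rng.integers(1, 300, 3)
            p = pc.compute_es(pc.ChannelCounts(f_dd, f_da, f_aa),
                              pc.CorrectionSet.neutral())
            assert p.e == pytest.approx(f_da / (f_da + f_dd))

    def test_zero_denominator_flagged_invalid(self):
        p = pc.compute_es(pc.ChannelCounts(0, 0, 10), pc.CorrectionSet.neutral())
        assert not p.valid


class TestStoichiometryGate:
    def test_keeps_mid_range_only(self):
        pts = [pc.ESPoint(0.5, s, pc.ChannelCounts(1, 1, 1)) for s in (0.1, 0.5, 0.9)]
        kept = pc.filter_stoichiometry(pts)
        assert [p.s for p in kept] == [0.5]

    def test_boundaries_inclusive(self):
        pts = [pc.ESPoint(0.5, s, pc.ChannelCounts(1, 1, 1))
               for s in (0.25, 0.75, 0.2499, 0.7501)]
        kept = pc.filter_stoichiometry(pts)
        assert [p.s for p in kept] == [0.25, 0.75]

    def test_invalid_gate_config(self):
        with pytest.raises(ValueError):
            pc.filter_stoichiometry([], s_min=0.8, s_max=0.2)

    def test_donor_only_species_removed(self):
        cfg = pc.SimConfig(duration_s=60, burst_rate=50, states=((1.0, 0.58),),
                           donor_only_fraction=0.30, acceptor_only_fraction=0.0,
                           seed=11)
        stream, truth = pc.simulate_photon_stream(cfg)
        bursts = pc.find_bursts(stream)
        match = truth.match_bursts(bursts)
        points = [pc.compute_es(pc.integrate_burst(stream, b)) for b in bursts]
        s = np.array([p.s for p in points])
        valid = np.array([p.valid for p in points])
        kept = valid & (s >= 0.25) & (s <= 0.75)
        dual = (match >= 0) & (truth.species[match] == 0)
        # gate retains dual-labelled bursts and rejects donor-only ones
        expected = dual.mean()
        assert kept.mean() == pytest.approx(expected, abs=0.03)
        assert np.mean(kept & ~dual) < 0.02


class TestRoundTrip:
    def test_corrected_e_recovers_truth(self, single_state_run):
        """Inverse corrections undo the embedded forward model: median
        corrected E within 3 standard errors of the configured E*."""
        cfg, stream, truth, df = single_state_run
        e = df.loc[df.kept_flag, "E"].to_numpy()
        se = e.std() / np.sqrt(len(e))
        assert abs(np.median(e) - 0.58) < max(3 * se, 0.005)

    def test_kept_table_columns(self, single_state_run):
        df = single_state_run[3]
        assert list(df.columns) == [
            "burst_id", "t_start_ns", "t_stop_ns", "n_photons",
            "F_DD", "F_DA", "F_AA", "E", "S", "kept_flag"]
        assert (df["n_photons"] > 35).all()
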