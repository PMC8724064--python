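"""DI, HMM segmentation, insulation, meta-profile, five-type classification."""

import numpy as np
import pandas as pd
import pytest

from calscope.contacts import ContactMap
from calscope.genome import BinnedGenome
from calscope.simulate import make_truth, simulate_hic
from calscope.tads import (STATE_DOWN, STATE_NONE, STATE_UP, TadSet, call_tads,
                           classify_tads, directionality_index, hmm_segment,
                           insulation_score, tad_genome_coverage,
                           tad_metaprofile, tads_from_states)


def balanced_map(genome, values, chrom="chr1"):
    return ContactMap(genome, {chrom: values}, {}, "balanced")


def brute_force_di(v, w):
    n = v.shape[0]
    di = np.zeros(n)
    for i in range(n):
        a = sum(v[i, j] for j in range(max(i - w, 0), i))
        b = sum(v[i, j] for j in range(i + 1, min(i + w + 1, n)))
        e = (a + b) / 2.0
        if e == 0 or a == b:
            continue
        di[i] = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
    return di


def brute_force_is(v, w):
    n = v.shape[0]
    out = np.full(n, np.nan)
    for i in range(w, n - w):
        block = [v[a, b] for a in range(i - w, i) for b in range(i + 1, i + w + 1)]
        out[i] = np.mean(block)
    mean = np.nanmean(out)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.isfinite(out) & (out > 0), np.log2(out / mean), np.nan)


class TestDirectionalityIndex:
    def test_hand_computed_value(self):
        # bin 1 sees A=10 upstream, B=30 downstream:
        # E=20, DI = +((10-20)^2/20 + (30-20)^2/20) = +10
        g = BinnedGenome(("chr1",), (120_000,), 40_000)
        v = np.array([[0.0, 10.0, 0.0],
                      [10.0, 0.0, 30.0],
                      [0.0, 30.0, 0.0]])
        di = directionality_index(balanced_map(g, v), window=80_000)
        assert di.di["chr1"][1] == pytest.approx(10.0)

    def test_zero_at_symmetry_center(self):
        g = BinnedGenome(("chr1",), (200_000,), 40_000)
        v = np.zeros((5, 5))
        v[2, 1] = v[1, 2] = 4.0
        v[2, 3] = v[3, 2] = 4.0
        di = directionality_index(balanced_map(g, v), window=80_000)
        assert di.di["chr1"][2] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        g = BinnedGenome(("chr1",), (4_000_000,), 40_000)  # 100 bins
        v = rng.random((100, 100)) * 10
        v = (v + v.T) / 2
        di = directionality_index(balanced_map(g, v), window=2_000_000)
        np.testing.assert_allclose(di.di["chr1"],
                                   brute_force_di(v, 50), atol=1e-10)

    def test_antisymmetry_under_reflection(self, rng):
        g = BinnedGenome(("chr1",), (2_400_000,), 40_000)  # 60 bins
        v = rng.random((60, 60))
        v = (v + v.T) / 2
        di = directionality_index(balanced_map(g, v), window=800_000)
        vr = v[::-1, ::-1]
        dir_ = directionality_index(balanced_map(g, vr), window=800_000)
        np.testing.assert_allclose(di.di["chr1"], -dir_.di["chr1"][::-1],
                                   atol=1e-10)

    def test_window_too_small_rejected(self, rng):
        g = BinnedGenome(("chr1",), (400_000,), 40_000)
        v = rng.random((10, 10))
        with pytest.raises(ValueError, match="window"):
            directionality_index(balanced_map(g, (v + v.T) / 2), window=40_000)


class TestHmmSegment:
    def _blocky_di(self, rng, n_blocks=20, block=10, scale=50.0, noise=0.1):
        di = []
        edges = []
        for k in range(n_blocks):
            sign = 1.0 if k % 2 == 0 else -1.0
            di.extend(sign * scale * (1 + rng.normal(0, noise, block)))
            edges.append((k + 1) * block)
        return np.asarray(di), edges[:-1]

    def test_block_edges_recovered(self, rng):
        di_vals, edges = self._blocky_di(rng)
        g = BinnedGenome(("chr1",), (len(di_vals) * 40_000,), 40_000)
        from calscope.tads import DITrack
        track = DITrack(genome=g, di={"chr1": di_vals}, window=2_000_000)
        states = hmm_segment(track, seed=0, n_restarts=5)["chr1"]
        changes = set(np.where(states[1:] != states[:-1])[0] + 1)
        hits = sum(any(abs(e - c) <= 1 for c in changes) for e in edges)
        assert hits / len(edges) >= 0.9

    def test_all_zero_di_is_single_none_state(self):
        g = BinnedGenome(("chr1",), (4_000_000,), 40_000)
        from calscope.tads import DITrack
        track = DITrack(genome=g, di={"chr1": np.zeros(100)}, window=2_000_000)
        states = hmm_segment(track, seed=0)["chr1"]
        assert (states == STATE_NONE).all()

    def test_determinism_under_seed(self, rng):
        di_vals, _ = self._blocky_di(rng, n_blocks=10)
        g = BinnedGenome(("chr1",), (len(di_vals) * 40_000,), 40_000)
        from calscope.tads import DITrack
        track = DITrack(genome=g, di={"chr1": di_vals}, window=2_000_000)
        s1 = hmm_segment(track, seed=7)["chr1"]
        s2 = hmm_segment(track, seed=7)["chr1"]
        assert (s1 == s2).all()

    def test_too_few_bins_rejected(self):
        g = BinnedGenome(("chr1",), (400_000,), 40_000)
        from calscope.tads import DITrack
        track = DITrack(genome=g, di={"chr1": np.ones(10)}, window=2_000_000)
        with pytest.raises(ValueError, match="50"):
            hmm_segment(track)


class TestTadsFromStates:
    def test_down_none_up_is_one_tad(self):
        g = BinnedGenome(("chr1",), (480_000,), 40_000)  # 12 bins
        states = {"chr1": np.array([STATE_DOWN] * 5 + [STATE_NONE] * 2
                                   + [STATE_UP] * 5)}
        tads = tads_from_states(states, g)
        assert len(tads) == 1
        assert tads.intervals.iloc[0]["start"] == 0
        assert tads.intervals.iloc[0]["end"] == 480_000  # bins 0..11

    def test_gap_at_least_400kb_is_unorganized(self):
        # two TADs separated by 11 'none' bins = 440 kb at 40-kb bins
        g = BinnedGenome(("chr1",), (40_000 * 31,), 40_000)
        states = {"chr1": np.array(
            [STATE_DOWN] * 5 + [STATE_UP] * 5 + [STATE_NONE] * 11
            + [STATE_DOWN] * 5 + [STATE_UP] * 5)}
        tads = tads_from_states(states, g)
        assert len(tads) == 2
        assert len(tads.boundaries) == 0
        assert len(tads.unorganized) == 1
        assert (tads.unorganized["end"] - tads.unorganized["start"]).iloc[0] == 440_000

    def test_short_gap_is_boundary(self):
        g = BinnedGenome(("chr1",), (40_000 * 25,), 40_000)
        states = {"chr1": np.array(
            [STATE_DOWN] * 5 + [STATE_UP] * 5 + [STATE_NONE] * 5
            + [STATE_DOWN] * 5 + [STATE_UP] * 5)}
        tads = tads_from_states(states, g)
        assert len(tads.boundaries) == 1
        length = (tads.boundaries["end"] - tads.boundaries["start"]).iloc[0]
        assert length == 200_000 and length < 400_000

    def test_empty_states_give_empty_tadset(self):
        g = BinnedGenome(("chr1",), (400_000,), 40_000)
        tads = tads_from_states({"chr1": np.array([], dtype="U15")}, g)
        assert len(tads) == 0


class TestInsulation:
    def test_uniform_matrix_is_zero(self):
        g = BinnedGenome(("chr1",), (2_000_000,), 40_000)
        v = np.full((50, 50), 2.0)
        ins = insulation_score(balanced_map(g, v), window=200_000)
        sc = ins.score["chr1"]
        assert np.allclose(sc[np.isfinite(sc)], 0.0)
        assert np.isnan(sc[:5]).all() and np.isnan(sc[-5:]).all()

    def test_matches_brute_force_oracle(self, rng):
        g = BinnedGenome(("chr1",), (2_400_000,), 40_000)  # 60 bins
        v = rng.random((60, 60)) + 0.5
        v = (v + v.T) / 2
        ins = insulation_score(balanced_map(g, v), window=200_000)
        np.testing.assert_allclose(ins.score["chr1"],
                                   brute_force_is(v, 5), atol=1e-10)

    def test_window_exceeding_chromosome_rejected(self, rng):
        g = BinnedGenome(("chr1",), (400_000,), 40_000)
        v = rng.random((10, 10))
        with pytest.raises(ValueError, match="exceeds"):
            insulation_score(balanced_map(g, (v + v.T) / 2), window=400_000)


class TestMetaprofile:
    def _is_track(self, genome, values):
        from calscope.tads import InsulationTrack
        return InsulationTrack(genome=genome, score={"chr1": values},
                               window=200_000)

    def test_identical_tads_average_to_single_profile(self):
        g = BinnedGenome(("chr1",), (4_000_000,), 40_000)
        base = np.tile([0.0, 1.0, 2.0, 1.0, 0.0], 20)
        ins = self._is_track(g, base.astype(float))
        tads = TadSet(intervals=pd.DataFrame(
            {"chrom": "chr1", "start": [400_000, 1_400_000],
             "end": [600_000, 1_600_000]}))
        prof = tad_metaprofile(ins, tads, n_points=9)
        single = tad_metaprofile(
            ins, TadSet(intervals=tads.intervals.iloc[[0]]), n_points=9)
        np.testing.assert_allclose(prof, single)

    def test_output_shape_contract(self):
        g = BinnedGenome(("chr1",), (4_000_000,), 40_000)
        ins = self._is_track(g, np.zeros(100))
        tads = TadSet(intervals=pd.DataFrame(
            {"chrom": ["chr1"], "start": [1_000_000], "end": [2_000_000]}))
        prof = tad_metaprofile(ins, tads, n_points=3)
        assert prof.shape == (3,)

    def test_boundary_minimum_mid_tad_maximum(self, rng):
        # planted TADs: IS low at boundaries, high inside
        g = BinnedGenome(("chr1",), (20_000_000,), 40_000)
        truth = make_truth(g, switch_fraction=0.0, tad_gap_prob=0.0, seed=3)
        (rep,) = simulate_hic(g, truth, compartment_contrast=1.0,
                              tad_boost=3.0, loop_boost=1.0, depth=3e6,
                              seed=4, n_replicates=1)
        from calscope.contacts import ice_normalize
        bal = ice_normalize(rep)
        ins = insulation_score(bal, window=400_000)
        tads = TadSet(intervals=truth.tad_intervals["FGSC"])
        prof = tad_metaprofile(ins, tads, n_points=101)
        # grid spans [-0.5, 1.5] TAD lengths: boundaries at points 25 and 75
        inner = np.nanmean(prof[40:60])
        assert prof[25] < inner and prof[75] < inner


class TestClassifyTads:
    def _ts(self, rows):
        return TadSet(intervals=pd.DataFrame(
            rows, columns=["chrom", "start", "end"]))

    def test_five_scenarios(self):
        ref = self._ts([("chr1", 0, 1_000_000),          # stable (shifted 10%)
                        ("chr1", 2_000_000, 3_000_000),  # split
                        ("chr1", 4_000_000, 4_500_000),  # merged (with sibling)
                        ("chr1", 4_500_000, 5_000_000),  # merged
                        ("chr1", 6_000_000, 7_000_000),  # unique
                        ("chr1", 8_000_000, 9_000_000)])  # reorganized
        other = self._ts([
            ("chr1", 100_000, 1_100_000),     # 10% shift: IoU 0.9/1.1 ~ 0.82
            ("chr1", 2_000_000, 2_500_000),   # split piece 1
            ("chr1", 2_500_000, 3_000_000),   # split piece 2
            ("chr1", 4_000_000, 5_000_000),   # covers both merged siblings
            ("chr1", 8_400_000, 9_600_000),   # partial: IoU 0.6/1.6 = 0.375
        ])
        out = classify_tads(ref, other)
        assert list(out["type"]) == ["stable", "split", "merged", "merged",
                                     "unique", "reorganized"]
        assert out["best_overlap"].iloc[0] == pytest.approx(0.9 / 1.1, abs=1e-9)

    def test_self_comparison_all_stable(self, rng):
        starts = np.arange(10) * 1_000_000
        ref = self._ts([("chr1", s, s + 800_000) for s in starts])
        out = classify_tads(ref, ref)
        assert (out["type"] == "stable").all()

    def test_types_exhaustive_and_exclusive(self, rng):
        # random interval sets: every reference TAD gets exactly one type
        def rand_set(seed):
            r = np.random.default_rng(seed)
            pos, rows = 0, []
            while pos < 18_000_000:
                ln = int(r.integers(400_000, 1_600_000))
                if r.random() > 0.2:
                    rows.append(("chr1", pos, pos + ln))
                pos += ln + int(r.integers(0, 200_000))
            return self._ts(rows)

        ref, other = rand_set(1), rand_set(2)
        out = classify_tads(ref, other)
        assert len(out) == len(ref.intervals)
        assert out["type"].isin(
            ["stable", "merged", "split", "reorganized", "unique"]).all()

    def test_overlapping_reference_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            self._ts([("chr1", 0, 1_000_000), ("chr1", 500_000, 1_500_000)])


class TestCoverage:
    def test_tiling_tads_cover_everything(self):
        g = BinnedGenome(("chr1",), (2_000_000,), 40_000)
        tads = TadSet(intervals=pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [0, 1_000_000],
             "end": [1_000_000, 2_000_000]}))
        assert tad_genome_coverage(tads, g) == 1.0

    def test_empty_set_covers_nothing(self):
        g = BinnedGenome(("chr1",), (2_000_000,), 40_000)
        tads = TadSet(intervals=pd.DataFrame(columns=["chrom", "start", "end"]))
        assert tad_genome_coverage(tads, g) == 0.0


def test_call_tads_recovers_planted_boundaries(rng):
    g = BinnedGenome(("chr1",), (20_000_000,), 40_000)
    truth = make_truth(g, switch_fraction=0.0, tad_gap_prob=0.0, seed=3)
    (rep1, rep2) = simulate_hic(g, truth, compartment_contrast=1.0,
                                tad_boost=3.0, loop_boost=1.0, depth=2e6,
                                seed=4)
    from calscope.contacts import ice_normalize
    bal = ice_normalize(rep1 + rep2)
    tads, _ = call_tads(bal, seed=5)
    bs = g.bin_size
    edges = set(tads.intervals["start"] // bs) | set(tads.intervals["end"] // bs)
    planted = truth.tad_boundaries("FGSC")
    recall = np.mean([
        any(abs(p["pos"] // bs - e) <= 1 for e in edges)
        for _, p in planted.iterrows()])
    assert recall >= 0.9
    # every emitted boundary is < 400 kb
    if len(tads.boundaries):
        assert ((tads.boundaries["end"] - tads.boundaries["start"])
                < 400_000).all()
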