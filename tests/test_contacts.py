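"""Matrix core: I/O, ICE balancing, O/E, correlation, p(s), QC statistics."""

import numpy as np
import pandas as pd
import pytest

from calscope.contacts import (ContactMap, MatrixIntegrityError,
                               MatrixStateError, cis_short_fraction,
                               contact_probability, correlation_matrix,
                               expected_by_distance, ice_normalize,
                               observed_over_expected, read_contact_map,
                               replicate_correlation, write_contact_map)
from calscope.genome import BinnedGenome

from conftest import random_raw_map


# ---------------------------------------------------------------------------
# triplet I/O
# ---------------------------------------------------------------------------

class TestTripletIO:
    def test_single_entry_is_symmetrized(self, tmp_path):
        g = BinnedGenome(("chr1",), (400_000,), 40_000)
        f = tmp_path / "m.matrix"
        f.write_text("4\t6\t7\n")  # 1-based: bins 3 and 5
        cmap = read_contact_map(f, g)
        assert cmap.values["chr1"][3, 5] == 7
        assert cmap.values["chr1"][5, 3] == 7
        assert cmap.state == "raw"

    def test_empty_file_gives_zero_map(self, tmp_path):
        g = BinnedGenome(("chr1",), (400_000,), 40_000)
        f = tmp_path / "m.matrix"
        f.write_text("")
        cmap = read_contact_map(f, g)
        assert cmap.values["chr1"].shape == (10, 10)
        assert not cmap.values["chr1"].any()

    def test_round_trip_random_map(self, tmp_path, rng, genome50):
        cmap = random_raw_map(genome50, rng)
        write_contact_map(cmap, tmp_path / "m.matrix", tmp_path / "m.bed")
        back = read_contact_map(tmp_path / "m.matrix", bed_path=tmp_path / "m.bed")
        assert back.genome == genome50
        np.testing.assert_array_equal(back.values["chr1"], cmap.values["chr1"])

    def test_malformed_line_names_line_number(self, tmp_path):
        g = BinnedGenome(("chr1",), (400_000,), 40_000)
        f = tmp_path / "m.matrix"
        f.write_text("1\t2\t3\nnot-a-bin\t2\t3\n")
        with pytest.raises(MatrixIntegrityError, match="line 2"):
            read_contact_map(f, g)

    def test_conflicting_duplicate_pair_rejected(self, tmp_path):
        g = BinnedGenome(("chr1",), (400_000,), 40_000)
        f = tmp_path / "m.matrix"
        f.write_text("2\t5\t3\n5\t2\t4\n")
        with pytest.raises(MatrixIntegrityError, match="conflicting"):
            read_contact_map(f, g)

    def test_out_of_range_bin_rejected(self, tmp_path):
        g = BinnedGenome(("chr1",), (400_000,), 40_000)
        f = tmp_path / "m.matrix"
        f.write_text("1\t99\t3\n")
        with pytest.raises(MatrixIntegrityError, match="out of range"):
            read_contact_map(f, g)


# ---------------------------------------------------------------------------
# ICE
# ---------------------------------------------------------------------------

class TestIce:
    def test_equal_marginals_is_fixed_point(self, genome50):
        # circulant matrix: every row has the same sum
        n = 50
        base = np.arange(1.0, n + 1.0)
        v = np.empty((n, n))
        for i in range(n):
            v[i] = np.roll(base, i)
        v = (v + v.T) / 2
        cmap = ContactMap(genome50, {"chr1": v}, {}, "raw")
        bal = ice_normalize(cmap, low_coverage_quantile=0.0)
        ratio = bal.values["chr1"][v > 0] / v[v > 0]
        assert np.allclose(ratio, ratio.flat[0])

    def test_lognormal_bias_removed(self, rng):
        g = BinnedGenome(("chr1",), (8_000_000,), 40_000)  # 200 bins
        n = 200
        bias = rng.lognormal(0.0, 0.6, n)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        lam = 500.0 / np.maximum(d, 1.0) * np.outer(bias, bias)
        up = np.triu(rng.poisson(lam)).astype(float)
        cmap = ContactMap(g, {"chr1": up + np.triu(up, 1).T}, {}, "raw")
        bal = ice_normalize(cmap)
        s = bal.values["chr1"].sum(axis=1)
        ok = ~bal.mask["chr1"]
        cv = s[ok].std() / s[ok].mean()
        assert cv < 1e-4
        assert bal.metadata["ice_converged"]

    def test_single_unmasked_bin_degenerate(self):
        g = BinnedGenome(("chr1",), (200_000,), 40_000)
        v = np.zeros((5, 5))
        v[2, 2] = 10.0
        cmap = ContactMap(g, {"chr1": v}, {}, "raw")
        bal = ice_normalize(cmap, low_coverage_quantile=0.0)
        assert bal.mask["chr1"].sum() == 4
        assert not bal.mask["chr1"][2]

    def test_all_masked_raises(self):
        g = BinnedGenome(("chr1",), (200_000,), 40_000)
        cmap = ContactMap.zeros(g)
        with pytest.raises(ValueError, match="all bins masked"):
            ice_normalize(cmap)

    def test_mass_scale_recorded_and_mean_marginal_one(self, rng, genome50):
        bal = ice_normalize(random_raw_map(genome50, rng))
        s = bal.values["chr1"].sum(axis=1)
        ok = ~bal.mask["chr1"]
        assert s[ok].mean() == pytest.approx(1.0, rel=1e-6)
        assert "ice_scale" in bal.metadata


# ---------------------------------------------------------------------------
# O/E and correlation
# ---------------------------------------------------------------------------

def brute_force_oe(v, mask):
    n = v.shape[0]
    out = np.zeros_like(v)
    for i in range(n):
        for j in range(n):
            if mask[i] or mask[j]:
                continue
            d = abs(i - j)
            vals = [v[a, a + d] for a in range(n - d)
                    if not (mask[a] or mask[a + d])]
            exp = np.mean(vals) if vals else 0.0
            out[i, j] = v[i, j] / exp if exp > 0 else 0.0
    return out


class TestObservedOverExpected:
    def test_distance_only_map_gives_ones(self, genome50):
        n = 50
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        v = 1.0 / (1.0 + d)
        cmap = ContactMap(genome50, {"chr1": v}, {}, "balanced")
        oe = observed_over_expected(cmap)
        assert np.allclose(oe.values["chr1"], 1.0)

    def test_matches_brute_force_oracle(self, rng):
        g = BinnedGenome(("chr1",), (1_600_000,), 40_000)  # 40 bins
        v = rng.random((40, 40))
        v = (v + v.T) / 2
        mask = np.zeros(40, dtype=bool)
        mask[[3, 17]] = True
        v[mask, :] = 0.0
        v[:, mask] = 0.0
        cmap = ContactMap(g, {"chr1": v}, {"chr1": mask}, "balanced")
        oe = observed_over_expected(cmap)
        np.testing.assert_allclose(oe.values["chr1"],
                                   brute_force_oe(v, mask), atol=1e-10)

    def test_masked_rows_stay_zero(self, rng, genome50):
        cmap = ice_normalize(random_raw_map(genome50, rng))
        cmap.mask["chr1"][7] = True
        cmap.apply_mask()
        oe = observed_over_expected(cmap)
        assert not oe.values["chr1"][7].any()

    def test_requires_balanced_state(self, rng, genome50):
        with pytest.raises(MatrixStateError):
            observed_over_expected(random_raw_map(genome50, rng))


class TestCorrelationMatrix:
    def _oe_map(self, genome, v, mask=None):
        n = v.shape[0]
        mask = np.zeros(n, dtype=bool) if mask is None else mask
        return ContactMap(genome, {"chr1": v}, {"chr1": mask},
                          "observed_over_expected")

    def test_matches_naive_pairwise_oracle(self, rng):
        g = BinnedGenome(("chr1",), (1_200_000,), 40_000)  # 30 bins
        v = rng.random((30, 30))
        v = (v + v.T) / 2
        corr = correlation_matrix(self._oe_map(g, v))
        expected = np.empty((30, 30))
        for i in range(30):
            for j in range(30):
                expected[i, j] = np.corrcoef(v[i], v[j])[0, 1]
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(corr.values["chr1"], expected, atol=1e-10)

    def test_entries_bounded_and_symmetric(self, rng, genome50):
        v = rng.random((50, 50))
        v = (v + v.T) / 2
        corr = correlation_matrix(self._oe_map(genome50, v))
        c = corr.values["chr1"]
        assert np.allclose(c, c.T)
        assert c.max() <= 1.0 and c.min() >= -1.0

    def test_constant_row_auto_masked(self, rng, genome50):
        v = rng.random((50, 50))
        v = (v + v.T) / 2
        v[5, :] = 2.0
        v[:, 5] = 2.0
        with pytest.warns(RuntimeWarning, match="constant"):
            corr = correlation_matrix(self._oe_map(genome50, v))
        assert corr.mask["chr1"][5]


# ---------------------------------------------------------------------------
# p(s)
# ---------------------------------------------------------------------------

class TestContactProbability:
    def test_uniform_matrix_constant_ps(self, genome50):
        v = np.full((50, 50), 3.0)
        cmap = ContactMap(genome50, {"chr1": v}, {}, "raw")
        ps = contact_probability(cmap)
        assert np.allclose(ps.probabilities, 1.0 / 49)

    def test_sums_to_one_and_scale_invariant(self, rng, genome50):
        cmap = random_raw_map(genome50, rng, decay=1.0)
        ps = contact_probability(cmap)
        assert ps.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        scaled = cmap.copy()
        scaled.values["chr1"] *= 7.5
        ps2 = contact_probability(scaled)
        np.testing.assert_allclose(ps.probabilities, ps2.probabilities)

    def test_decay_slope_recovered(self, rng):
        g = BinnedGenome(("chr1",), (40_000_000,), 40_000)  # 1000 bins
        n = 1000
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        lam = 2000.0 / np.maximum(d, 1.0)
        up = np.triu(rng.poisson(lam)).astype(float)
        cmap = ContactMap(g, {"chr1": up + np.triu(up, 1).T}, {}, "raw")
        slope = contact_probability(cmap).loglog_slope()
        assert slope == pytest.approx(-1.0, rel=0.10)

    def test_single_separation_map(self, genome50):
        v = np.zeros((50, 50))
        for i in range(49):
            v[i, i + 1] = v[i + 1, i] = 5.0
        cmap = ContactMap(genome50, {"chr1": v}, {}, "raw")
        ps = contact_probability(cmap)
        assert ps.probabilities[0] == pytest.approx(1.0)
        assert not ps.probabilities[1:].any()

    def test_empty_map_raises(self, genome50):
        with pytest.raises(ValueError, match="empty"):
            contact_probability(ContactMap.zeros(genome50))


# ---------------------------------------------------------------------------
# replicate correlation & cis fractions
# ---------------------------------------------------------------------------

class TestReplicateCorrelation:
    def test_self_correlation_is_one(self, rng, genome50):
        cmap = random_raw_map(genome50, rng, decay=1.0)
        assert replicate_correlation(cmap, cmap) == pytest.approx(1.0)

    def test_poisson_resampled_replicates_correlate(self, rng):
        g = BinnedGenome(("chr1",), (20_000_000,), 40_000)  # 500 bins
        n = 500
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        lam = 200.0 / np.maximum(d, 1.0)
        reps = []
        for _ in range(2):
            up = np.triu(rng.poisson(lam)).astype(float)
            reps.append(ContactMap(g, {"chr1": up + np.triu(up, 1).T}, {}, "raw"))
        assert replicate_correlation(reps[0], reps[1], 2_000_000) > 0.95

    def test_shuffled_replicate_decorrelates(self, rng):
        g = BinnedGenome(("chr1",), (20_000_000,), 40_000)
        m1 = random_raw_map(g, rng)
        perm = rng.permutation(500)
        v2 = m1.values["chr1"][np.ix_(perm, perm)]
        m2 = ContactMap(g, {"chr1": (v2 + v2.T) / 2}, {}, "raw")
        assert abs(replicate_correlation(m1, m2, 2_000_000)) < 0.1

    def test_mismatched_binning_raises(self, rng, genome50):
        other = BinnedGenome(("chr1",), (2_000_000,), 20_000)
        with pytest.raises(ValueError, match="binning"):
            replicate_correlation(random_raw_map(genome50, rng),
                                  random_raw_map(other, rng))


class TestCisShortFraction:
    def test_all_contacts_below_threshold(self):
        g = BinnedGenome(("chr1",), (100_000,), 10_000)
        v = np.zeros((10, 10))
        for i in range(9):
            v[i, i + 1] = v[i + 1, i] = 2.0  # separation 10 kb
        cmap = ContactMap(g, {"chr1": v}, {}, "raw")
        out = cis_short_fraction(cmap, [20_000])
        assert out["fraction"].iloc[0] == pytest.approx(1.0)

    def test_uniform_matrix_matches_pair_count(self, genome50):
        v = np.full((50, 50), 1.0)
        cmap = ContactMap(genome50, {"chr1": v}, {}, "raw")
        out = cis_short_fraction(cmap, [200_000])  # separations 1..4 bins
        n_under = sum(50 - d for d in range(1, 5))
        n_all = sum(50 - d for d in range(1, 50))
        assert out["fraction"].iloc[0] == pytest.approx(n_under / n_all)

    def test_monotone_in_threshold(self, rng, genome50):
        cmap = random_raw_map(genome50, rng, decay=1.0)
        out = cis_short_fraction(cmap, [80_000, 120_000, 200_000, 400_000])
        assert (np.diff(out["fraction"]) >= 0).all()

    def test_threshold_below_bin_size_warns_zero(self, rng, genome50):
        cmap = random_raw_map(genome50, rng)
        with pytest.warns(RuntimeWarning, match="below bin size"):
            out = cis_short_fraction(cmap, [10_000])
        assert out["fraction"].iloc[0] == 0.0


# ---------------------------------------------------------------------------
# cross-cutting invariants
# ---------------------------------------------------------------------------

def test_transform_chain_preserves_symmetry_and_mask(rng, genome50):
    cmap = random_raw_map(genome50, rng, decay=1.0)
    cmap.mask["chr1"][11] = True
    cmap.apply_mask()
    bal = ice_normalize(cmap)
    oe = observed_over_expected(bal)
    corr = correlation_matrix(oe)
    for m in (bal, oe, corr):
        assert m.check_symmetry()
        assert m.mask["chr1"][11]
        assert not m.values["chr1"][11].any()


def test_expected_by_distance_ignores_masked(rng):
    v = rng.random((20, 20))
    v = (v + v.T) / 2
    mask = np.zeros(20, dtype=bool)
    mask[4] = True
    exp = expected_by_distance(v, mask)
    d = 3
    manual = np.mean([v[a, a + d] for a in range(17)
                      if a != 4 and a + d != 4])
    assert exp[d] == pytest.approx(manual, abs=1e-12)


def test_replicate_merge_sums_counts(rng, genome50):
    m1 = random_raw_map(genome50, rng)
    m2 = random_raw_map(genome50, rng)
    merged = m1 + m2
    np.testing.assert_array_equal(
        merged.values["chr1"], m1.values["chr1"] + m2.values["chr1"])
    assert merged.state == "raw"
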