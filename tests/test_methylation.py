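"""Credible-difference statistics, DMC/DMR calling, region levels, profiles."""

import numpy as np
import pandas as pd
import pytest

from epistage import (GenomicInterval, MethylationMatrix, MethylationTrack,
                      anchored_profile, call_dmcs, credible_difference,
                      credible_difference_many, merge_dmcs_to_dmrs,
                      region_methylation)


def mc_credible_difference(case, ctl, level=0.95, n=1_000_000, seed=0):
    """Monte-Carlo oracle: sample the two Beta posteriors, take the
    equal-tailed interval of the difference, return the bound nearest zero
    capped at the raw pooled difference."""
    rng = np.random.default_rng(seed)
    x = rng.beta(case[0] + 0.5, case[1] - case[0] + 0.5, n)
    y = rng.beta(ctl[0] + 0.5, ctl[1] - ctl[0] + 0.5, n)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(x - y, [alpha, 1 - alpha])
    cdif = lo if lo > 0 else (hi if hi < 0 else 0.0)
    raw = case[0] / case[1] - ctl[0] / ctl[1]
    return np.sign(cdif) * min(abs(cdif), abs(raw))


def make_matrix(positions, meth, total, samples):
    sites = pd.DataFrame({"chrom": "chr1", "start": positions,
                          "end": np.asarray(positions) + 1})
    return MethylationMatrix(sites, np.asarray(meth), np.asarray(total), samples)


class TestCredibleDifference:
    def test_identical_groups_span_zero(self):
        assert credible_difference((5, 10), (5, 10)) == 0.0

    @pytest.mark.parametrize("case,ctl", [
        ((30, 30), (0, 30)),
        ((20, 40), (10, 40)),
        ((45, 50), (20, 100)),
        ((3, 60), (30, 60)),
    ])
    def test_matches_monte_carlo_oracle(self, case, ctl):
        got = credible_difference(case, ctl)
        want = mc_credible_difference(case, ctl)
        assert got == pytest.approx(want, abs=5e-3)

    def test_strong_separation_exceeds_threshold(self):
        assert credible_difference((30, 30), (0, 30)) > 0.20

    def test_antisymmetry_is_exact(self, rng):
        for _ in range(30):
            t1, t2 = rng.integers(5, 200, size=2)
            m1 = int(rng.integers(0, t1 + 1))
            m2 = int(rng.integers(0, t2 + 1))
            a = credible_difference((m1, t1), (m2, t2))
            b = credible_difference((m2, t2), (m1, t1))
            assert a == -b

    def test_magnitude_never_exceeds_raw_difference(self, rng):
        t1 = rng.integers(2, 300, size=200)
        t2 = rng.integers(2, 300, size=200)
        m1 = rng.integers(0, t1 + 1)
        m2 = rng.integers(0, t2 + 1)
        cdif = credible_difference_many(m1, t1, m2, t2)
        raw = m1 / t1 - m2 / t2
        assert (np.abs(cdif) <= np.abs(raw) + 1e-12).all()

    def test_converges_to_raw_difference_at_high_depth(self):
        depth = 100_000
        v = credible_difference((int(0.8 * depth), depth), (int(0.5 * depth), depth))
        assert abs(v - 0.3) < 0.01

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError, match="zero pooled total"):
            credible_difference((0, 0), (5, 10))


class TestCallDmcs:
    def test_threshold_is_inclusive_and_prefilter_consistent(self):
        # the caller must emit exactly the sites whose full credible
        # difference clears the cut, despite the raw-difference prefilter
        rng = np.random.default_rng(5)
        n = 300
        total = rng.integers(20, 60, size=(n, 8))
        level = np.tile(rng.uniform(0.1, 0.9, size=(n, 1)), (1, 8))
        level[:, :4] += rng.choice([0.0, 0.25], size=(n, 1))
        meth = rng.binomial(total, np.clip(level, 0, 1))
        samples = [f"c{i}" for i in range(4)] + [f"k{i}" for i in range(4)]
        mm = make_matrix(np.arange(n) * 10, meth, total, samples)
        stages = {s: ("IAC" if s.startswith("c") else "CTL") for s in samples}
        dmcs = call_dmcs(mm, stages, "IAC")
        full = credible_difference_many(
            meth[:, :4].sum(1), total[:, :4].sum(1),
            meth[:, 4:].sum(1), total[:, 4:].sum(1))
        expect = set(np.flatnonzero(np.abs(full) >= 0.20) * 10)
        assert set(dmcs["start"]) == expect

    def test_direction_matches_sign(self):
        total = np.full((2, 4), 50)
        meth = np.array([[48, 47, 2, 3], [1, 2, 46, 45]])
        samples = ["c1", "c2", "k1", "k2"]
        mm = make_matrix([100, 200], meth, total, samples)
        stages = {"c1": "AIS", "c2": "AIS", "k1": "CTL", "k2": "CTL"}
        dmcs = call_dmcs(mm, stages, "AIS")
        assert list(dmcs["direction"]) == ["hyper", "hypo"]

    def test_uncovered_sites_are_skipped(self):
        total = np.array([[0, 0, 10, 10], [10, 10, 10, 10]])
        meth = np.array([[0, 0, 10, 10], [10, 10, 0, 0]])
        mm = make_matrix([100, 200], meth, total, ["c1", "c2", "k1", "k2"])
        stages = {"c1": "IAC", "c2": "IAC", "k1": "CTL", "k2": "CTL"}
        dmcs = call_dmcs(mm, stages, "IAC")
        assert list(dmcs["start"]) == [200]


def oracle_dmrs(starts, min_dmcs, max_gap):
    """Independent O(n^2) oracle: enumerate every maximal valid window."""
    out = []
    n = len(starts)
    for i in range(n):
        for j in range(i, n):
            window = starts[i:j + 1]
            gaps_ok = all(b - a <= max_gap for a, b in zip(window, window[1:]))
            left_max = i == 0 or starts[i] - starts[i - 1] > max_gap
            right_max = j == n - 1 or starts[j + 1] - starts[j] > max_gap
            if gaps_ok and left_max and right_max and len(window) >= min_dmcs:
                out.append((window[0], window[-1] + 1, len(window)))
    return sorted(out)


class TestMergeDmcsToDmrs:
    @staticmethod
    def _frame(starts, direction="hyper", chrom="chr1"):
        return pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.asarray(starts) + 1, "direction": direction})

    def test_three_dmcs_within_gap_form_one_dmr(self):
        dmrs = merge_dmcs_to_dmrs(self._frame([100, 250, 400]))
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert (row.start, row.end, row.n_dmcs) == (100, 401, 3)

    def test_two_dmcs_are_not_enough(self):
        assert len(merge_dmcs_to_dmrs(self._frame([100, 250]))) == 0

    def test_gap_boundary(self):
        # gap of exactly 200 merges; 201 splits
        assert len(merge_dmcs_to_dmrs(self._frame([0, 200, 400]))) == 1
        assert len(merge_dmcs_to_dmrs(self._frame([0, 201, 402]))) == 0

    def test_unsorted_input_is_error(self):
        bad = self._frame([400, 100, 250])
        with pytest.raises(ValueError, match="sorted"):
            merge_dmcs_to_dmrs(bad)

    def test_directions_never_merge(self):
        df = pd.DataFrame({
            "chrom": "chr1", "start": [0, 50, 100, 150, 200, 250],
            "end": [1, 51, 101, 151, 201, 251],
            "direction": ["hyper", "hypo"] * 3})
        dmrs = merge_dmcs_to_dmrs(df)
        assert set(dmrs["direction"]) == {"hyper", "hypo"}
        assert (dmrs["n_dmcs"] == 3).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_run_scanner_oracle(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.unique(rng.integers(0, 20_000, size=500))
        dmrs = merge_dmcs_to_dmrs(self._frame(list(starts)))
        got = sorted(zip(dmrs.start, dmrs.end, dmrs.n_dmcs))
        assert got == oracle_dmrs(list(starts), 3, 200)
        # non-overlap within a direction
        for (_, e1, _), (s2, _, _) in zip(got, got[1:]):
            assert s2 >= e1


class TestRegionMethylation:
    def _matrix(self):
        total = np.array([[10, 10], [10, 20]])
        meth = np.array([[5, 0], [0, 10]])
        return make_matrix([100, 150], meth, total, ["a", "b"])

    def test_single_cpg_ratio(self):
        mm = self._matrix()
        lev = region_methylation(mm, [GenomicInterval("chr1", 100, 101)])
        assert lev.iloc[0]["a"] == 0.5

    def test_read_weighted_not_mean_of_ratios(self):
        total = np.array([[10], [10]])
        meth = np.array([[5], [0]])
        mm = make_matrix([100, 150], meth, total, ["a"])
        lev = region_methylation(mm, [GenomicInterval("chr1", 90, 200)])
        assert lev.iloc[0]["a"] == pytest.approx(5 / 20)

    def test_region_without_cpgs_is_absent(self):
        mm = self._matrix()
        lev = region_methylation(mm, [GenomicInterval("chr1", 500, 600)])
        assert lev.isna().all().all()

    def test_matches_direct_summation_oracle(self, rng):
        n, s = 40, 5
        pos = np.arange(n) * 7
        total = rng.integers(0, 30, size=(n, s))
        meth = rng.integers(0, total + 1)
        mm = make_matrix(pos, meth, total, [f"s{i}" for i in range(s)])
        regions = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 300)]
        got = region_methylation(mm, regions)
        for iv, (_, row) in zip(regions, got.iterrows()):
            member = (pos >= iv.start) & (pos < iv.end)
            ms, ts = meth[member].sum(0), total[member].sum(0)
            want = np.where(ts > 0, ms / np.maximum(ts, 1), np.nan)
            np.testing.assert_allclose(row.to_numpy(), want)


class TestAnchoredProfile:
    def test_uniform_methylation_gives_flat_profile(self):
        pos = np.arange(0, 4000, 100)
        total = np.full((len(pos), 2), 10)
        meth = np.full((len(pos), 2), 8)
        mm = make_matrix(pos, meth, total, ["a", "b"])
        prof = anchored_profile(mm, [GenomicInterval("chr1", 2000, 2001)],
                                flank=1000, bin_width=100)
        vals = prof.dropna()
        assert len(vals) > 0
        assert np.allclose(vals, 0.8)

    def test_single_cpg_lands_in_expected_bin(self):
        mm = make_matrix([1010], np.array([[5]]), np.array([[10]]), ["a"])
        prof = anchored_profile(mm, [GenomicInterval("chr1", 1000, 1001)],
                                flank=500, bin_width=100)
        assert prof.loc[0] == 0.5
        assert prof.drop(index=0).isna().all()

    def test_minus_strand_profile_is_mirrored(self):
        pos = np.array([900, 1100])
        total = np.full((2, 1), 10)
        meth = np.array([[2], [8]])
        mm = make_matrix(pos, meth, total, ["a"])
        plus = anchored_profile(mm, [GenomicInterval("chr1", 1000, 1001, "+")],
                                flank=300, bin_width=100)
        minus = anchored_profile(mm, [GenomicInterval("chr1", 1000, 1001, "-")],
                                 flank=300, bin_width=100)
        # the CpG 100 bp upstream on + (d=-100, level 0.2) sits 100 bp
        # downstream on - (d=+100), and vice versa for the 0.8 CpG
        assert plus.loc[-100] == minus.loc[100] == pytest.approx(0.2)
        assert plus.loc[100] == minus.loc[-100] == pytest.approx(0.8)
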