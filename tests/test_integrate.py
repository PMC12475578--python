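"""Correlation machinery, the srDMR-srDAR panel, and co-expression calls."""

import numpy as np
import pandas as pd
import pytest

from epistage import (CountMatrix, GenomicInterval, MethylationMatrix, Panel,
                      build_panel, classify_peak_correlations, coexpression,
                      intersect_intervals, kendall_tau, metric_correlations,
                      pearson_r, sample_level_correlation)


def brute_force_tau_b(x, y):
    """All-pairs concordant/discordant counting with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom if denom else np.nan


class TestKendallTau:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        assert kendall_tau(x, x)[0] == pytest.approx(1.0)

    def test_perfect_reversal(self):
        x = np.arange(10.0)
        assert kendall_tau(x, -x)[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_tied_vectors_match_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        x = rng.integers(0, 5, size=n).astype(float)
        y = rng.integers(0, 5, size=n).astype(float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            return
        got, _ = kendall_tau(x, y)
        assert got == pytest.approx(brute_force_tau_b(x, y))

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        t1, _ = kendall_tau(x, y)
        t2, _ = kendall_tau(np.exp(x), y**3)
        assert t1 == pytest.approx(t2)

    def test_constant_vector_is_undefined(self):
        tau, p = kendall_tau(np.ones(5), np.arange(5.0))
        assert np.isnan(tau) and np.isnan(p)


class TestPearson:
    def test_matches_covariance_oracle(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        r, _ = pearson_r(x, y)
        want = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(want)

    def test_toy_linear_pair(self):
        r, p = pearson_r([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r == pytest.approx(1.0)
        assert p < 0.05


class TestClassifyPeakCorrelations:
    def test_planted_negative_coupling_recovered(self, rng):
        n_peaks, n_s = 200, 20
        meth = rng.uniform(0.2, 0.8, (n_peaks, n_s))
        acc = 5 - 4 * meth + rng.normal(0, 0.15, (n_peaks, n_s))
        cols = [f"s{i}" for i in range(n_s)]
        calls = classify_peak_correlations(
            pd.DataFrame(acc, columns=cols), pd.DataFrame(meth, columns=cols))
        assert (calls["cls"] == "negative").mean() >= 0.95

    def test_independent_data_is_mostly_none(self, rng):
        n_peaks, n_s = 400, 20
        cols = [f"s{i}" for i in range(n_s)]
        calls = classify_peak_correlations(
            pd.DataFrame(rng.normal(size=(n_peaks, n_s)), columns=cols),
            pd.DataFrame(rng.uniform(size=(n_peaks, n_s)), columns=cols))
        assert (calls["cls"] == "none").mean() == pytest.approx(0.95, abs=0.04)

    def test_constant_accessibility_and_missing_meth(self):
        cols = list("abcd")
        acc = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4]], columns=cols)
        meth = pd.DataFrame([[0.1, 0.2, 0.3, 0.4],
                             [np.nan] * 4], columns=cols)
        calls = classify_peak_correlations(acc, meth)
        assert list(calls["cls"]) == ["none", "none"]
        assert list(calls["usable"]) == [True, False]


class TestSampleLevelCorrelation:
    def test_full_subsample_has_zero_sd(self, rng):
        acc = rng.normal(size=30)
        meth = rng.uniform(size=30)
        mean, sd = sample_level_correlation(acc, meth, 30, 10, rng)
        assert sd == 0.0

    def test_planted_negative_coupling(self, rng):
        meth = rng.uniform(size=100)
        acc = 1 - meth + rng.normal(0, 0.1, 100)
        mean, sd = sample_level_correlation(acc, meth, 50, 20, rng)
        assert mean < -0.5

    def test_too_few_peaks_is_error(self, rng):
        with pytest.raises(ValueError):
            sample_level_correlation([1.0, 2.0], [0.1, 0.2], 2, 5, rng)


def _toy_meth_matrix():
    pos = np.array([100, 150, 600, 650])
    total = np.full((4, 3), 10)
    meth = np.array([[1, 5, 9], [2, 5, 8], [9, 5, 1], [8, 5, 2]])
    sites = pd.DataFrame({"chrom": "chr1", "start": pos, "end": pos + 1})
    return MethylationMatrix(sites, meth, total, ["x", "y", "z"])


def _toy_acc(index):
    rngl = np.random.default_rng(0)
    df = pd.DataFrame(rngl.integers(50, 150, size=(len(index), 3)),
                      index=index, columns=["x", "y", "z"])
    return df


class TestBuildPanel:
    def _srdmrs(self):
        return pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [90, 580],
                             "end": [160, 700],
                             "category": ["hyper-AIS", "hypo-IAC"]})

    def test_disjoint_sets_give_empty_panel(self):
        srdars = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100],
                               "category": ["hyper-IAC"],
                               "feature": ["chr2:0-100"]})
        acc = CountMatrix(_toy_acc(["chr2:0-100"]))
        with pytest.warns(UserWarning, match="empty panel"):
            panel = build_panel(self._srdmrs(), srdars, _toy_meth_matrix(), acc)
        assert len(panel) == 0

    def test_single_overlap_yields_one_record_with_metrics(self):
        srdars = pd.DataFrame({"chrom": ["chr1"], "start": [140], "end": [200],
                               "category": ["hyper-AIS"],
                               "feature": ["chr1:140-200"]})
        acc = CountMatrix(_toy_acc(["chr1:140-200"]))
        panel = build_panel(self._srdmrs(), srdars, _toy_meth_matrix(), acc)
        assert len(panel) == 1
        # srDMR covers CpGs at 100+150; srDAR only the CpG at 150
        assert panel.srdmr_meth.iloc[0]["x"] == pytest.approx(3 / 20)
        assert panel.srdar_meth.iloc[0]["x"] == pytest.approx(2 / 10)
        assert panel.srdar_acc.notna().all().all()

    def test_pair_set_matches_intersection_oracle(self, rng):
        starts_a = rng.choice(5000, size=30, replace=False)
        starts_b = rng.choice(5000, size=30, replace=False)
        srdmrs = pd.DataFrame({"chrom": "chr1", "start": starts_a,
                               "end": starts_a + 80, "category": "hyper-AIS"})
        feats = [f"chr1:{s}-{s+60}" for s in starts_b]
        srdars = pd.DataFrame({"chrom": "chr1", "start": starts_b,
                               "end": starts_b + 60, "category": "hypo-IAC",
                               "feature": feats})
        acc = CountMatrix(_toy_acc(feats))
        panel = build_panel(srdmrs, srdars, _toy_meth_matrix(), acc)
        a = [GenomicInterval("chr1", int(s), int(s) + 80) for s in starts_a]
        b = [GenomicInterval("chr1", int(s), int(s) + 60) for s in starts_b]
        oracle = {(i, j) for i, j, _ in intersect_intervals(a, b)}
        got = set()
        for _, row in panel.records.iterrows():
            i = [f"chr1:{s}-{s+80}" for s in starts_a].index(row.srdmr_id)
            j = feats.index(row.srdar_id.replace("-", "-"))
            got.add((i, j))
        assert got == oracle


class TestMetricCorrelations:
    def _panel(self, srdmr, srdar, acc):
        idx = pd.RangeIndex(len(srdmr))
        cols = ["x", "y", "z"]
        rec = pd.DataFrame({"srdmr_id": "r", "srdmr_category": "c",
                            "srdar_id": "d", "srdar_category": "c",
                            "feature": "f"}, index=idx)
        return Panel(rec, pd.DataFrame(srdmr, index=idx, columns=cols),
                     pd.DataFrame(srdar, index=idx, columns=cols),
                     pd.DataFrame(acc, index=idx, columns=cols))

    def test_duplicated_metric_gives_unit_correlation(self, rng):
        m = rng.uniform(size=(10, 3))
        out = metric_correlations(self._panel(m, m, rng.normal(size=(10, 3))))
        np.testing.assert_allclose(out["r_srdmr_meth_vs_srdar_meth"], 1.0)

    def test_matches_direct_covariance_oracle(self, rng):
        a = rng.uniform(size=(12, 3))
        b = rng.uniform(size=(12, 3))
        c = rng.normal(size=(12, 3))
        out = metric_correlations(self._panel(a, b, c))
        want = np.corrcoef(a[:, 0], b[:, 0])[0, 1]
        assert out["r_srdmr_meth_vs_srdar_meth"].iloc[0] == pytest.approx(want)

    def test_degenerate_variance_is_absent(self, rng):
        a = np.full((5, 3), 0.4)
        out = metric_correlations(self._panel(a, rng.uniform(size=(5, 3)),
                                              rng.normal(size=(5, 3))))
        assert out["r_srdmr_meth_vs_srdar_meth"].isna().all()


class TestCoexpression:
    def test_identical_series_positive(self):
        cols = list("abcde")
        tf = pd.DataFrame([[1, 2, 3, 4, 5]], index=["TF1"], columns=cols)
        out = coexpression(tf, tf.rename(index={"TF1": "g1"}))
        assert out.iloc[0]["cls"] == "positive"
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_anticorrelated_with_noise(self, rng):
        cols = [f"s{i}" for i in range(12)]
        x = rng.normal(size=12)
        tf = pd.DataFrame([x], index=["TF1"], columns=cols)
        gene = pd.DataFrame([-x + rng.normal(0, 0.1, 12)], index=["g1"],
                            columns=cols)
        out = coexpression(tf, gene)
        assert out.iloc[0]["cls"] == "negative"

    def test_constant_expression_is_none(self):
        cols = list("abcd")
        tf = pd.DataFrame([[1, 1, 1, 1]], index=["TF1"], columns=cols)
        gene = pd.DataFrame([[1, 2, 3, 4]], index=["g1"], columns=cols)
        assert coexpression(tf, gene).iloc[0]["cls"] == "none"
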