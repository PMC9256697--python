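import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctc_concord.io_core import RunConfig, WindowCounts
from ctc_concord import cna
from ctc_concord.cna import (
    CNProfile,
    PurityFit,
    build_profile,
    categorize_cn,
    cbs_segment,
    cna_concordance,
    count_cnas,
    fit_purity_ploidy,
    normalize_ploidy,
    normalize_to_control,
)


def _wc(counts, chrom="chr1", width=10_000):
    n = len(counts)
    df = pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "count": np.asarray(counts, dtype=np.int64),
        }
    )
    return WindowCounts(df)


def _window_frame(values, chrom="chr1", masked=None):
    n = len(values)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "start": np.arange(n) * 10_000,
            "end": (np.arange(n) + 1) * 10_000,
            "log2": values,
            "masked": masked if masked is not None else [False] * n,
        }
    )


class TestNormalizeToControl:
    def test_identical_counts_give_zero_log2(self, cfg):
        wc = _wc([100] * 20)
        out = normalize_to_control(wc, wc, cfg)
        assert np.allclose(out["log2"], 0.0)

    def test_closed_form_on_constructed_counts(self, cfg):
        # sample doubled on half the genome; library scaling makes the
        # doubled half 4/3 of the control and the other half 2/3
        control = _wc([100] * 40)
        sample = _wc([200] * 20 + [100] * 20)
        out = normalize_to_control(sample, control, cfg)
        assert np.allclose(out["log2"][:20], np.log2(4 / 3))
        assert np.allclose(out["log2"][20:], np.log2(2 / 3))

    def test_zero_control_window_masked_not_infinite(self, cfg):
        control = _wc([100] * 10 + [0])
        sample = _wc([100] * 11)
        out = normalize_to_control(sample, control, cfg)
        assert bool(out["masked"].iloc[-1])
        assert np.isfinite(out["log2"][:10]).all()

    def test_mismatched_grids_rejected(self, cfg):
        with pytest.raises(ValueError, match="grid"):
            normalize_to_control(_wc([1] * 5), _wc([1] * 6), cfg)


class TestCbs:
    def test_noiseless_step_found_exactly(self, cfg):
        x = [0.0] * 25 + [1.0] * 25
        segs, wseg = cbs_segment(_window_frame(x), cfg,
                                 np.random.default_rng(0))
        assert len(segs) == 2
        assert segs.iloc[0]["n_windows"] == 25
        assert segs.iloc[1]["mean_log2"] == pytest.approx(1.0)
        assert (wseg[:25] == 0).all() and (wseg[25:] == 1).all()

    def test_interior_event_gives_three_segments(self, cfg):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.05, 120)
        x[40:80] += 1.0
        segs, _ = cbs_segment(_window_frame(x), cfg, np.random.default_rng(2))
        assert len(segs) == 3
        assert segs.iloc[1]["start"] == 40 * 10_000
        assert segs.iloc[1]["end"] == 80 * 10_000

    def test_constant_stretch_single_segment(self, cfg):
        segs, _ = cbs_segment(_window_frame([0.3] * 30), cfg,
                              np.random.default_rng(0))
        assert len(segs) == 1

    def test_masked_windows_excluded(self, cfg):
        x = [0.0] * 10 + [np.nan] * 3 + [0.0] * 10
        masked = [False] * 10 + [True] * 3 + [False] * 10
        segs, wseg = cbs_segment(_window_frame(x, masked=masked), cfg,
                                 np.random.default_rng(0))
        assert (wseg[10:13] == -1).all()
        assert segs["n_windows"].sum() == 20

    def test_segment_partition_preserves_global_mean(self, cfg):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.2, 300)
        x[100:200] += 0.8
        frame = _window_frame(x)
        segs, wseg = cbs_segment(frame, cfg, np.random.default_rng(4))
        assert (wseg >= 0).all()
        weighted = np.average(segs["mean_log2"], weights=segs["n_windows"])
        assert weighted == pytest.approx(x.mean(), abs=1e-9)


def _segments_from_cn(q_values, n_windows, rho, tau):
    R = (rho * np.asarray(q_values, dtype=float) + 2 * (1 - rho)) / (
        rho * tau + 2 * (1 - rho)
    )
    return pd.DataFrame(
        {
            "chrom": [f"chr{i+1}" for i in range(len(q_values))],
            "start": 0,
            "end": np.asarray(n_windows) * 10_000,
            "n_windows": n_windows,
            "mean_log2": np.log2(R),
        }
    )


class TestPurityFit:
    def test_pure_tumor_recovered_exactly(self, cfg):
        q = [2, 2, 3, 1, 6, 2]
        w = [300, 250, 60, 50, 20, 320]
        tau = np.average(q, weights=w)
        segs = _segments_from_cn(q, w, rho=1.0, tau=tau)
        fit, cn = fit_purity_ploidy(segs, cfg)
        assert fit.corrected and fit.rho == pytest.approx(1.0)
        assert np.allclose(np.round(cn), q)

    def test_low_purity_bulk_recovered(self, cfg):
        q = [2, 2, 3, 1, 6, 2, 4]
        w = [300, 250, 60, 50, 20, 290, 30]
        tau = np.average(q, weights=w)
        for rho in (0.2, 0.35, 0.5):
            segs = _segments_from_cn(q, w, rho=rho, tau=tau)
            fit, cn = fit_purity_ploidy(segs, cfg)
            assert fit.corrected
            assert fit.rho == pytest.approx(rho, abs=0.02)
            assert np.allclose(np.round(cn), q)

    def test_flat_diploid_flagged_degenerate(self, cfg):
        segs = _segments_from_cn([2, 2, 2], [300, 400, 300], rho=1.0, tau=2.0)
        fit, cn = fit_purity_ploidy(segs, cfg)
        assert not fit.corrected and fit.degenerate
        assert fit.rho == 1.0
        assert np.allclose(cn, 2.0)

    def test_too_few_segments_rejected(self, cfg):
        segs = _segments_from_cn([2, 3], [500, 500], rho=0.5, tau=2.05)
        with pytest.raises(ValueError, match="segments"):
            fit_purity_ploidy(segs, cfg)


class TestNormalizePloidy:
    def test_tetraploid_uniform_profile_maps_to_two(self):
        segs = pd.DataFrame({"n_windows": [500, 500], "mean_log2": [0.0, 0.0]})
        cn = normalize_ploidy(segs)  # pure route: recentred ratio
        assert np.allclose(cn, 2.0)

    def test_tau_two_is_identity(self):
        fit = PurityFit(rho=0.4, tau=2.0, objective=0.0)
        segs = pd.DataFrame({"n_windows": [500, 500], "mean_log2": [0.0, 0.1]})
        q = np.array([2.0, 3.0])
        assert np.allclose(normalize_ploidy(segs, fit, q), q)

    def test_triploid_with_gain_scales_by_two_thirds(self):
        fit = PurityFit(rho=1.0, tau=3.0, objective=0.0)
        segs = pd.DataFrame({"n_windows": [900, 100],
                             "mean_log2": [np.log2(1.0), np.log2(4 / 3)]})
        q = np.array([3.0, 4.0])
        out = normalize_ploidy(segs, fit, q)
        assert np.allclose(out, 2 * q / 3)


class TestCategorizeAndCount:
    @pytest.mark.parametrize(
        "cn,expected",
        [
            (4.5, "amp"),
            (2.0, "neutral"),
            (0.5, "deep_del"),
            (2.5, "neutral"),   # boundary: strict inequality
            (4.0, "gain"),      # boundary: strict inequality
            (1.5, "neutral"),
            (0.8, "del"),
            (1.2, "del"),
            (3.0, "gain"),
        ],
    )
    def test_thresholds(self, cfg, cn, expected):
        assert categorize_cn(cn, cfg) == expected

    def test_count_cnas(self, cfg):
        segs = pd.DataFrame({"category": ["neutral"] * 4})
        assert count_cnas(segs) == 0
        segs = pd.DataFrame(
            {"category": ["gain", "gain", "gain", "del", "del", "neutral"]})
        assert count_cnas(segs) == 5


def _profile_from_cn_vector(sid, values):
    n = len(values)
    windows = _window_frame([0.0] * n)
    segments = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 10_000,
            "end": (np.arange(n) + 1) * 10_000,
            "n_windows": 1,
            "mean_log2": 0.0,
            "cn": values,
            "category": "neutral",
        }
    )
    return CNProfile(sid, windows, segments, np.arange(n), None)


class TestConcordance:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(5)
        p = _profile_from_cn_vector("a", rng.uniform(1, 3, 50))
        rho, _, _ = cna_concordance([p, p])
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_rank_correlation_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(1, 3, 60)
        y = x + rng.normal(0, 0.5, 60)
        rho, _, _ = cna_concordance(
            [_profile_from_cn_vector("a", x), _profile_from_cn_vector("b", y)])
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["a", "b"] == pytest.approx(oracle, abs=1e-12)

    def test_too_few_shared_windows_rejected(self):
        a = _profile_from_cn_vector("a", np.ones(5))
        b = _profile_from_cn_vector("b", np.ones(5))
        with pytest.raises(ValueError, match="shared windows"):
            cna_concordance([a, b])

    def test_grid_mismatch_rejected(self):
        a = _profile_from_cn_vector("a", np.ones(30))
        b = _profile_from_cn_vector("b", np.ones(40))
        with pytest.raises(ValueError, match="grid"):
            cna_concordance([a, b])


class TestBuildProfile:
    def test_end_to_end_on_constructed_counts(self, cfg):
        rng = np.random.default_rng(7)
        n = 200
        control = _wc(rng.poisson(2000, n))
        expected = np.full(n, 2000.0)
        expected[60:120] *= 2.0  # a clean doubling
        sample = _wc(rng.poisson(expected))
        prof = build_profile("s", sample, control, cfg, correct_purity=False,
                             rng=np.random.default_rng(8))
        assert len(prof.segments) == 3
        cats = prof.segments["category"].tolist()
        assert cats[1] != "neutral"
        cn = prof.window_cn()
        assert np.nanmean(cn[60:120]) > 2.4
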