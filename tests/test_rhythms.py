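"""Tests for preprocessing, detrending, FFT-NLLS fitting and group statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from catackit.rhythms import (
    CosineComponent,
    GroupSummary,
    LuminescenceTrace,
    RhythmResult,
    analyze_trace,
    average_trace,
    chi_square_classes,
    classify,
    compare_groups,
    detrend,
    expression_level,
    fft_nlls,
    mann_whitney,
    preprocess,
    relative_amplitude_error,
    summarize_group,
    tamhane_t2,
    traces_from_frame,
    welch_anova,
)
from catackit.simulate import TraceSimSpec, simulate_traces


def cosine_trace(
    duration=168.0, dt=1.0, amp=50.0, period=24.0, phase=4.0, baseline=0.0,
    amp12=0.0, noise=0.0, seed=0, ld_head=0.0, tau=None,
):
    t = np.arange(0, duration, dt)
    y = baseline + amp * np.cos(2 * np.pi * (t - phase) / period)
    y = y + amp12 * np.cos(4 * np.pi * (t - phase) / period)
    if tau:
        y = y + 200 * np.exp(-t / tau)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, t.size)
    regime = np.where(t < ld_head, "LD", "DD")
    return LuminescenceTrace("fly", t, y, regime=regime)


class TestPreprocess:
    def test_trace_entirely_in_settling_head_flagged(self):
        tr = cosine_trace(duration=20.0)
        out = preprocess(tr)
        assert out.times.size == 0 and not out.fit_eligible

    def test_ld_head_and_settling_exclusion(self):
        tr = cosine_trace(duration=96.0, ld_head=12.0)
        out = preprocess(tr)
        assert out.times[0] >= 24.0
        assert (out.regime == "DD").all()

    def test_removed_samples_match_direct_enumeration(self):
        spec = TraceSimSpec(n_flies=1, seed=5)
        df, _ = simulate_traces(spec)
        tr = traces_from_frame(df)[0]
        out = preprocess(tr)
        expected = ((tr.times >= tr.times[0] + 24.0) & (tr.regime == "DD")).sum()
        assert out.times.size == expected


class TestDetrend:
    def test_constant_input_is_identically_zero(self):
        tr = LuminescenceTrace("f", np.arange(100.0), np.full(100, 42.0))
        assert np.allclose(detrend(tr).counts, 0.0, atol=1e-12)

    def test_linear_ramp_vanishes_away_from_edges(self):
        t = np.arange(100.0)
        tr = LuminescenceTrace("f", t, 3.0 * t + 7)
        out = detrend(tr).counts
        interior = (t >= 12) & (t <= t[-1] - 12)
        assert np.allclose(out[interior], 0.0, atol=1e-9)
        assert not np.allclose(out[~interior], 0.0)

    def test_cosine_attenuation_matches_dirichlet_kernel(self):
        """A centred discrete running mean scales a cosine by a computable
        factor: the detrended amplitude is (1 - D) with D the normalised
        Dirichlet kernel of the window."""
        period, window, dt = 24.0, 12.0, 1.0
        tr = cosine_trace(duration=120.0, dt=dt, amp=10.0, period=period)
        out = detrend(tr, window_h=window)
        n_half = int(window / 2 / dt)
        ks = np.arange(-n_half, n_half + 1)
        D = np.cos(2 * np.pi * ks / period).sum() / ks.size
        t = tr.times
        interior = (t >= window / 2) & (t <= t[-1] - window / 2)
        expected = (1 - D) * tr.counts[interior]
        assert np.allclose(out.counts[interior], expected, atol=1e-9)

    def test_too_short_trace_rejected(self):
        tr = LuminescenceTrace("f", np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError):
            detrend(tr)


class TestFftNlls:
    def test_noiseless_cosine_recovered_exactly(self):
        tr = cosine_trace(amp=50.0)
        res = fft_nlls(tr)
        assert res.classification == "rhythmic"
        assert res.circadian_period == pytest.approx(24.0, abs=1e-3)
        assert res.rae < 0.01
        circ = res.circadian_component
        assert circ.amplitude == pytest.approx(50.0, rel=1e-3)
        assert circ.phase == pytest.approx(4.0, abs=0.05)

    def test_two_component_signal_recovers_both_periods(self):
        tr = cosine_trace(amp=50.0, amp12=15.0, noise=5.0)
        res = fft_nlls(tr)
        periods = sorted(c.period for c in res.components)
        assert any(abs(p - 24.0) < 0.5 for p in periods)
        assert any(abs(p - 12.0) < 0.5 for p in periods)

    def test_time_shift_changes_only_phase(self):
        a = cosine_trace(amp=40.0, noise=3.0)
        b = LuminescenceTrace("f", a.times + 5.0, a.counts)
        ra, rb = fft_nlls(a), fft_nlls(b)
        assert rb.circadian_period == pytest.approx(ra.circadian_period, abs=0.01)
        assert rb.circadian_component.amplitude == pytest.approx(
            ra.circadian_component.amplitude, rel=0.01
        )
        T = ra.circadian_period
        expected = (ra.circadian_component.phase + 5.0) % T
        dp = abs(rb.circadian_component.phase - expected)
        assert min(dp, T - dp) < 0.1

    def test_count_scaling_leaves_rae_invariant(self):
        a = cosine_trace(amp=40.0, noise=5.0)
        b = LuminescenceTrace("f", a.times, 10.0 * a.counts)
        ra, rb = fft_nlls(a), fft_nlls(b)
        assert rb.rae == pytest.approx(ra.rae, rel=1e-6)
        assert rb.circadian_component.amplitude == pytest.approx(
            10 * ra.circadian_component.amplitude, rel=1e-6
        )

    def test_short_trace_returns_arrhythmic_failure(self):
        tr = cosine_trace(duration=40.0)
        res = fft_nlls(tr)
        assert res.fit_failed and res.classification == "arrhythmic"

    def test_rae_medians_nondecreasing_in_noise(self):
        medians = []
        for sd in (1.0, 5.0, 10.0, 20.0):
            spec = TraceSimSpec(n_flies=15, amp_24=50.0, noise_sd=sd, seed=17)
            df, _ = simulate_traces(spec)
            raes = [
                r.rae
                for r in (analyze_trace(t) for t in traces_from_frame(df))
                if r.rae is not None
            ]
            medians.append(np.median(raes))
        assert all(a <= b + 1e-9 for a, b in zip(medians, medians[1:]))

    def test_period_bias_small_at_moderate_noise(self):
        spec = TraceSimSpec(n_flies=15, amp_24=50.0, noise_sd=10.0, seed=23)
        df, _ = simulate_traces(spec)
        periods = [
            r.circadian_period
            for r in (analyze_trace(t) for t in traces_from_frame(df))
            if r.circadian_period is not None
        ]
        assert abs(np.mean(periods) - 24.0) < 0.2


class TestRaeAndClassification:
    def test_rae_definition(self):
        c = CosineComponent(period=24, amplitude=10, phase=0, amplitude_ci95_half_width=1)
        assert relative_amplitude_error(c) == pytest.approx(0.1)

    def test_zero_amplitude_propagates_to_arrhythmic(self):
        c = CosineComponent(period=24, amplitude=0, phase=0, amplitude_ci95_half_width=1)
        assert classify(relative_amplitude_error(c)) == "arrhythmic"

    @pytest.mark.parametrize(
        "rae,expected",
        [
            (0.69, "rhythmic"),
            (0.70, "weakly_rhythmic"),
            (1.00, "weakly_rhythmic"),
            (1.01, "arrhythmic"),
            (None, "arrhythmic"),
        ],
    )
    def test_classification_boundaries(self, rae, expected):
        assert classify(rae) == expected


class TestAverageTrace:
    def test_identical_traces_average_to_themselves(self):
        tr = cosine_trace(amp=30.0)
        mean, overlay, fit = average_trace([tr, tr, tr])
        assert np.allclose(mean.counts, np.interp(mean.times, tr.times, tr.counts))
        assert fit.circadian_period == pytest.approx(24.0, abs=0.01)

    def test_antiphase_traces_cancel(self):
        a = cosine_trace(amp=30.0, phase=0.0)
        b = cosine_trace(amp=30.0, phase=12.0)
        mean, _, fit = average_trace([a, b])
        assert np.abs(mean.counts).max() < 1e-9

    def test_cohort_average_amplitude_within_ten_percent(self):
        spec = TraceSimSpec(n_flies=26, amp_24=50.0, noise_sd=10.0, seed=31)
        df, _ = simulate_traces(spec)
        pre = [preprocess(t) for t in traces_from_frame(df)]
        det = [detrend(t) for t in pre]
        _, _, fit = average_trace(det)
        assert fit.circadian_component.amplitude == pytest.approx(50.0, rel=0.10)

    def test_disjoint_ranges_rejected(self):
        a = LuminescenceTrace("a", np.arange(0.0, 50.0), np.zeros(50))
        b = LuminescenceTrace("b", np.arange(60.0, 110.0), np.zeros(50))
        with pytest.raises(ValueError):
            average_trace([a, b])


def _result(cls, rae=None, period=None):
    r = RhythmResult(classification=cls, rae=rae)
    if period is not None:
        r.circadian_component = CosineComponent(
            period=period, amplitude=1, phase=0, amplitude_ci95_half_width=rae or 0
        )
    return r


class TestGroupSummary:
    def test_all_arrhythmic(self):
        s = summarize_group([_result("arrhythmic")] * 5)
        assert s.pct_arrhythmic == 100.0 and s.mean_rae is None

    def test_percentages_match_direct_tally(self):
        results = [
            _result("rhythmic", 0.3, 24.0),
            _result("rhythmic", 0.5, 23.0),
            _result("weakly_rhythmic", 0.8, 25.0),
            _result("arrhythmic"),
        ]
        s = summarize_group(results)
        assert (s.pct_rhythmic, s.pct_weakly_rhythmic, s.pct_arrhythmic) == (50, 25, 25)
        assert s.mean_rae == pytest.approx(np.mean([0.3, 0.5, 0.8]))
        assert s.mean_period == pytest.approx(24.0)
        assert s.sem_rae == pytest.approx(np.std([0.3, 0.5, 0.8], ddof=1) / math.sqrt(3))


class TestCompareGroups:
    def test_identical_groups_chi_square_zero(self):
        g = [_result("rhythmic", 0.3, 24.0)] * 10 + [_result("arrhythmic")] * 10
        chi2, p = chi_square_classes(g, g)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_chi_square_matches_textbook_formula(self):
        """2x3 table 10/5/5 vs 2/4/14 against a hand-computed statistic."""
        a = (
            [_result("rhythmic", 0.1, 24.0)] * 10
            + [_result("weakly_rhythmic", 0.8, 24.0)] * 5
            + [_result("arrhythmic")] * 5
        )
        b = (
            [_result("rhythmic", 0.1, 24.0)] * 2
            + [_result("weakly_rhythmic", 0.8, 24.0)] * 4
            + [_result("arrhythmic")] * 14
        )
        chi2, p = chi_square_classes(a, b)
        observed = np.array([[10, 5, 5], [2, 4, 14]], dtype=float)
        expected = (
            observed.sum(axis=1, keepdims=True)
            * observed.sum(axis=0, keepdims=True)
            / observed.sum()
        )
        manual = ((observed - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(manual)
        assert 0 < p < 1

    def test_empty_class_dropped_with_warning(self):
        a = [_result("rhythmic", 0.1, 24.0)] * 5
        b = [_result("weakly_rhythmic", 0.9, 24.0)] * 5
        with pytest.warns(UserWarning, match="dropped"):
            chi_square_classes(a, b)

    def test_welch_anova_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 12), (0.8, 2, 9), (0.2, 0.5, 15))]
        f, p = welch_anova(groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
            }
        )
        ref = pingouin.welch_anova(data=df, dv="y", between="g")
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_tamhane_t2_adjusts_upward_and_detects_shift(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.normal(0, 1, 20),
            "b": rng.normal(0, 1, 20),
            "c": rng.normal(3, 1, 20),
        }
        table = tamhane_t2(groups)
        assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()
        pc = table.set_index(["group_a", "group_b"])["p_adj"]
        assert pc[("a", "c")] < 0.001 and pc[("b", "c")] < 0.001
        assert pc[("a", "b")] > 0.05

    def test_dispatch(self):
        g = [_result("rhythmic", 0.3, 24.0)] * 4 + [_result("arrhythmic")] * 4
        assert compare_groups(g, g, "chi_square")[1] == pytest.approx(1.0)
        u, p = compare_groups([1, 2, 3], [1, 2, 3], "mann_whitney")
        assert p == pytest.approx(1.0)
        with pytest.raises(ValueError):
            compare_groups(g, g, "bogus")

    def test_power_mutant_versus_wild_type_rhythmicity(self):
        """Cohorts generated with and without a circadian component separate
        by the chi-square class comparison in nearly every replicate."""
        detected = 0
        n_rep = 25
        for rep in range(n_rep):
            wt_spec = TraceSimSpec(n_flies=8, amp_24=50.0, noise_sd=10.0, seed=1000 + rep)
            mt_spec = TraceSimSpec(n_flies=8, amp_24=0.0, amp_12=0.0, noise_sd=10.0, seed=2000 + rep)
            wt = [analyze_trace(t) for t in traces_from_frame(simulate_traces(wt_spec)[0])]
            mt = [analyze_trace(t) for t in traces_from_frame(simulate_traces(mt_spec)[0])]
            _, p = chi_square_classes(wt, mt)
            detected += p < 0.01
        assert detected >= 0.9 * n_rep


class TestExpressionLevel:
    @staticmethod
    def _flat_trace(fly, level, genotype=""):
        t = np.arange(0.0, 96.0)
        return LuminescenceTrace(
            fly, t, np.full(t.size, float(level)),
            regime=np.where(t < 12, "LD", "DD"), genotype=genotype,
        )

    def test_constant_traces_report_their_level(self):
        df = expression_level([self._flat_trace(f"f{i}", 100) for i in range(3)])
        assert (df["level"] == 100).all()

    def test_single_trace_identity(self):
        tr = cosine_trace(amp=10.0, baseline=100.0, ld_head=12.0)
        df = expression_level([tr])
        target = 12.0 + 6.0
        i = int(np.argmin(np.abs(tr.times - target)))
        assert df["level"].iloc[0] == tr.counts[i]

    def test_distinct_baselines_detected_by_mann_whitney(self, rng):
        high = [self._flat_trace(f"h{i}", 200 + rng.normal(0, 10), "hi") for i in range(20)]
        low = [self._flat_trace(f"l{i}", 100 + rng.normal(0, 10), "lo") for i in range(20)]
        df = expression_level(high + low)
        u, p = mann_whitney(
            df[df.genotype == "hi"]["level"], df[df.genotype == "lo"]["level"]
        )
        assert p < 0.001

    def test_fly_without_sample_near_target_excluded(self):
        t = np.array([0.0, 30.0, 60.0])
        tr = LuminescenceTrace("f", t, np.zeros(3), regime=np.array(["DD"] * 3))
        with pytest.warns(UserWarning, match="no sample"):
            df = expression_level([tr])
        assert df.empty
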