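"""Channel statistics: responsiveness, latency, ANOVA, Swidth, d-prime."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapecat import ChannelStats, synth, tuning
from shapecat.types import TrialDataset


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def swidth_oracle(r):
    """Direct evaluation of (n - sum(r_i)/max) / (n - 1) after rectification."""
    r = np.clip(np.asarray(r, float), 0, None)
    return (len(r) - r.sum() / r.max()) / (len(r) - 1)


def dprime_oracle(pref, nonpref):
    """Direct evaluation of the pooled-SD discriminability index."""
    s = np.sqrt((np.var(pref, ddof=1) + np.var(nonpref, ddof=1)) / 2)
    return (np.mean(pref) - np.mean(nonpref)) / s


def anova_ss_oracle(y, a, b):
    """Hand-computed sums of squares for a balanced two-way layout."""
    y, a, b = np.asarray(y, float), np.asarray(a), np.asarray(b)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_a = sum(
        (y[a == lv].size) * (y[a == lv].mean() - grand) ** 2 for lv in np.unique(a)
    )
    ss_b = sum(
        (y[b == lv].size) * (y[b == lv].mean() - grand) ** 2 for lv in np.unique(b)
    )
    ss_cells = sum(
        (y[(a == la) & (b == lb)].size)
        * (y[(a == la) & (b == lb)].mean() - grand) ** 2
        for la in np.unique(a)
        for lb in np.unique(b)
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_cells
    return ss_a, ss_b, ss_ab, ss_err, ss_total


# ---------------------------------------------------------------------------
# responsiveness
# ---------------------------------------------------------------------------


class TestResponsiveness:
    def test_corrected_threshold_is_alpha_over_channels(self, small_dataset):
        # 96 channels -> threshold 0.05 / 96; here we check the rule by
        # reconstructing the mask from the returned p-values
        data, _ = small_dataset
        mask, p = tuning.detect_responsive_mua(data)
        from shapecat.preprocess import _window_rate

        base = _window_rate(data, data.baseline_window).mean(axis=0)
        post = _window_rate(data, (50.0, 250.0)).mean(axis=0)
        expected = (p < 0.05 / data.n_channels) & (post > base)
        np.testing.assert_array_equal(mask, expected)

    def test_null_population_flags_almost_nothing(self, design54):
        flagged = 0
        for seed in range(5):
            spec = synth.PopulationSpec(
                n_channels=24,
                p_shape_only=0,
                p_category_only=0,
                p_interaction=0,
                p_responsive_only=0,
                trials_min=5,
                trials_max=5,
                seed=seed,
            )
            data, _ = synth.generate_trials(design54, spec)
            mask, _ = tuning.detect_responsive_mua(data)
            flagged += mask.sum()
        assert flagged <= 1  # corrected alpha makes false positives rare

    def test_suppressed_channel_not_responsive(self, design54):
        # strong *decrease* after onset: small p but no increase
        spec = synth.PopulationSpec(
            n_channels=4,
            p_shape_only=0,
            p_category_only=0,
            p_interaction=0,
            p_responsive_only=0,
            baseline_rate=40.0,
            trials_min=8,
            trials_max=8,
            seed=0,
        )
        data, _ = synth.generate_trials(design54, spec)
        post = data.bin_slice((0.0, 500.0))
        mua = data.mua.copy()
        mua[:, :, post] = 0  # silence after onset
        data2 = TrialDataset(
            mua, data.trial_table, data.design, data.bin_width_ms, data.t_start_ms
        )
        mask, p = tuning.detect_responsive_mua(data2)
        assert (p < 0.05 / 4).all()  # hugely significant difference
        assert not mask.any()  # but not an increase

    def test_hg_top_two_condition_ranking(self):
        # channel responsive to exactly one stimulus: its trials carry the
        # effect and must be selected by the descending post-power sort
        rng = np.random.default_rng(0)
        n_stim, n_per = 6, 8
        stim = np.repeat(np.arange(1, n_stim + 1), n_per)
        times = np.arange(-200.0, 400.0, 10.0)
        power = 1.0 + 0.05 * rng.normal(size=(len(stim), 1, len(times)))
        bump = (stim == 4)[:, None, None] & (times >= 50)[None, None, :]
        power += 2.0 * bump
        mask, p = tuning.detect_responsive_hg(power, times, stim)
        assert mask[0]
        # brute-force: condition 4 must be the top-ranked condition
        post = power[:, 0, times >= 50].mean(axis=1)
        means = [post[stim == s].mean() for s in range(1, n_stim + 1)]
        assert int(np.argmax(means)) + 1 == 4


# ---------------------------------------------------------------------------
# latency and window selection
# ---------------------------------------------------------------------------


class TestLatency:
    def _step_tc(self, onset_ms, gain=30.0, n_trials=40, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        starts = np.arange(-300.0, 500.0, 25.0)
        tc = rng.normal(0, sd, size=(n_trials, len(starts)))
        tc[:, starts >= onset_ms] += gain
        return tc, starts

    def test_step_at_100ms_recovered(self):
        tc, starts = self._step_tc(100.0)
        assert tuning.estimate_latency(tc, starts) == 100.0

    def test_flat_channel_returns_none(self):
        rng = np.random.default_rng(1)
        starts = np.arange(-300.0, 500.0, 25.0)
        tc = rng.normal(size=(30, len(starts)))
        assert tuning.estimate_latency(tc, starts) is None

    def test_two_isolated_bins_do_not_count(self):
        tc, starts = self._step_tc(100.0, gain=0.0)
        post = starts >= 0
        # inject exactly two separated significant bins
        tc[:, np.flatnonzero(post)[2]] += 30.0
        tc[:, np.flatnonzero(post)[6]] += 30.0
        assert tuning.estimate_latency(tc, starts) is None

    def test_latency_never_before_onset(self):
        tc, starts = self._step_tc(-200.0)  # effect spans the baseline too
        lat = tuning.estimate_latency(tc, starts)
        assert lat is not None and lat >= 0.0

    @pytest.mark.parametrize(
        "mean_latency,expected",
        [
            (65.0, (25.0, 225.0)),
            (123.0, (75.0, 275.0)),
            (186.0, (125.0, 325.0)),
            (113.0, (75.0, 275.0)),
        ],
    )
    def test_window_selection_rule(self, mean_latency, expected):
        """The four observed array latencies map to the documented windows."""
        assert tuning.select_analysis_window([mean_latency]) == expected

    def test_window_from_multiple_latencies_uses_mean(self):
        assert tuning.select_analysis_window([100.0, 146.0]) == (75.0, 275.0)

    def test_empty_latency_list_rejected(self):
        with pytest.raises(ValueError):
            tuning.select_analysis_window([])


# ---------------------------------------------------------------------------
# two-factor ANOVA
# ---------------------------------------------------------------------------


class TestAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        # 2 x 2 design, 3 trials per cell, fixed values
        a = np.repeat([1, 1, 2, 2], 3)
        b = np.tile(np.repeat([1, 2], 3), 2)
        y = np.array([3.0, 4.0, 5.0, 7.0, 8.0, 6.0, 1.0, 2.0, 3.0, 9.0, 8.0, 10.0])
        ss_a, ss_b, ss_ab, ss_err, ss_total = anova_ss_oracle(y, a, b)
        res = tuning.anova_shape_category(y, a, b)
        tab = res["anova_table"]
        assert tab.loc["C(shape)", "sum_sq"] == pytest.approx(ss_a, abs=1e-9)
        assert tab.loc["C(category)", "sum_sq"] == pytest.approx(ss_b, abs=1e-9)
        assert tab.loc["C(shape):C(category)", "sum_sq"] == pytest.approx(ss_ab, abs=1e-9)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(ss_err, abs=1e-9)
        assert res["eta2_shape"] == pytest.approx(ss_a / ss_total, abs=1e-12)

    def test_pure_shape_effect(self):
        a = np.repeat([1, 2, 3], 8)
        b = np.tile([1, 2], 12)
        y = a * 10.0 + np.random.default_rng(0).normal(0, 1e-6, size=24)
        res = tuning.anova_shape_category(y, a, b)
        assert res["p_shape"] < 1e-10
        assert res["eta2_shape"] > 0.999
        assert res["p_category"] > 0.05

    def test_eta2_components_sum_below_one(self, small_dataset):
        data, _ = small_dataset
        table = tuning.tuning_table(data)
        resp = table[table["responsive"]]
        total = resp[["eta2_shape", "eta2_category", "eta2_interaction"]].sum(axis=1)
        assert (total <= 1.0 + 1e-9).all()

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        a = np.repeat(np.arange(1, 4), 12)
        b = np.tile(np.repeat([1, 2], 6), 3)
        rejections = 0
        n_rep = 200
        Y = rng.normal(size=(len(a), n_rep))
        batch = tuning._twoway_type2_batch(Y, a, b)
        for term in ("shape", "category", "interaction"):
            rejections += (batch[f"p_{term}"] < 0.05).sum()
        rate = rejections / (3 * n_rep)
        assert 0.02 < rate < 0.09  # ~5% nominal

    def test_batch_matches_statsmodels_on_unbalanced_data(self):
        rng = np.random.default_rng(3)
        design = synth.generate_design(4, 3)
        stim = np.repeat(design.stimulus_ids, rng.integers(3, 7, design.n_stimuli))
        idx = np.searchsorted(design.stimulus_ids, stim)
        sh, ca = design.shape_types[idx], design.categories[idx]
        Y = rng.normal(size=(len(stim), 3)) + sh[:, None] * 0.5
        batch = tuning._twoway_type2_batch(Y, sh, ca)
        for ch in range(3):
            ref = tuning.anova_shape_category(Y[:, ch], sh, ca)
            for term in ("shape", "category", "interaction"):
                assert batch[f"p_{term}"][ch] == pytest.approx(ref[f"p_{term}"], abs=1e-10)
                assert batch[f"eta2_{term}"][ch] == pytest.approx(
                    ref[f"eta2_{term}"], abs=1e-10
                )

    def test_empty_cell_rejected(self):
        a = np.repeat([1, 2], 6)
        b = np.tile([1, 2], 6)
        keep = ~((a == 2) & (b == 2))
        with pytest.raises(ValueError, match="cell"):
            tuning.anova_shape_category(np.ones(keep.sum()), a[keep], b[keep])


class TestClassification:
    @pytest.mark.parametrize(
        "ps,pc,pi,expected",
        [
            (0.0001, 0.52, 0.65, "shape_only"),  # clean shape-selective site
            (0.06, 0.026, 0.0007, "interaction"),  # animal-exemplar site
            (0.00002, 0.46, 0.000, "interaction"),  # interaction + shape main
            (0.5, 0.5, 0.5, "responsive_only"),
            (0.5, 0.01, 0.5, "category_only"),
        ],
    )
    def test_rule(self, ps, pc, pi, expected):
        assert tuning.classify_selectivity(ps, pc, pi) == expected


# ---------------------------------------------------------------------------
# selectivity indices
# ---------------------------------------------------------------------------


class TestSwidth:
    def test_flat_gives_zero(self):
        assert tuning.selectivity_width(np.full(54, 7.0)) == pytest.approx(0.0)

    def test_single_responder_gives_one(self):
        r = np.zeros(54)
        r[10] = 5.0
        assert tuning.selectivity_width(r) == pytest.approx(1.0)

    def test_worked_example(self):
        assert tuning.selectivity_width([2.0, 1.0, 1.0]) == pytest.approx(0.5)

    def test_no_positive_response_undefined(self):
        with pytest.warns(UserWarning):
            assert tuning.selectivity_width([-1.0, -2.0, 0.0]) is None

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-10, max_value=100, allow_nan=False), min_size=2, max_size=60
        ).filter(lambda r: max(r) > 0)
    )
    def test_matches_oracle_and_bounds(self, r):
        val = tuning.selectivity_width(np.array(r))
        assert val == pytest.approx(swidth_oracle(r), abs=1e-12)
        assert -1e-12 <= val <= 1.0 + 1e-12

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        r = rng.random(54)
        a = tuning.selectivity_width(r)
        b = tuning.selectivity_width(3.7 * r)
        assert a == pytest.approx(b, abs=1e-12)


class TestDPrime:
    def test_equal_means_give_zero(self):
        s = ChannelStats(1.0, 1.0, 2.0, 3.0)
        assert tuning.d_prime(s) == 0.0

    def test_unit_case(self):
        s = ChannelStats(2.0, 1.0, 1.0, 1.0)
        assert tuning.d_prime(s) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = tuning.d_prime(ChannelStats(2.0, 1.0, 1.0, 1.0))
        b = tuning.d_prime(ChannelStats(4.0, 2.0, 4.0, 4.0))
        assert a == pytest.approx(b)

    def test_common_shift_invariance(self):
        a = tuning.d_prime(ChannelStats(2.0, 1.0, 1.5, 0.5))
        b = tuning.d_prime(ChannelStats(12.0, 11.0, 1.5, 0.5))
        assert a == pytest.approx(b)

    def test_zero_sigma_sentinel(self):
        assert np.isinf(tuning.d_prime(ChannelStats(2.0, 1.0, 0.0, 0.0)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_stim, n_tr = rng.integers(3, 10), rng.integers(3, 8)
        pt = rng.normal(2.0, 1.0, size=(n_stim, n_tr))
        stats_ = tuning.channel_stats(pt)
        pref = int(np.argmax(pt.mean(axis=1)))
        oracle = dprime_oracle(pt[pref], np.delete(pt, pref, axis=0).ravel())
        assert tuning.d_prime(stats_) == pytest.approx(oracle, abs=1e-12)

    def test_worst_stimulus_variant(self):
        pt = np.array([[5.0, 6.0], [1.0, 2.0], [3.0, 3.5]])
        stats_ = tuning.channel_stats(pt, nonpreferred="worst")
        assert stats_.mu_nonpref == pytest.approx(1.5)


# ---------------------------------------------------------------------------
# localizer contrast
# ---------------------------------------------------------------------------


class TestLocalizerContrast:
    def _tc(self, effect, n=30, seed=0):
        rng = np.random.default_rng(seed)
        starts = np.arange(-300.0, 500.0, 50.0)
        tc = rng.normal(size=(2 * n, 3, len(starts)))
        intact = np.arange(2 * n) < n
        window = (starts >= 100) & (starts < 400)
        tc[np.ix_(intact, [0, 1, 2], np.flatnonzero(window))] += effect
        return tc, starts, intact

    def test_window_centers_spaced_50ms(self):
        tc, starts, intact = self._tc(0.0)
        res = tuning.localizer_contrast_timecourse(tc, starts, 50.0, intact)
        np.testing.assert_allclose(np.diff(res["center_ms"]), 50.0)

    def test_null_rate_and_correction(self):
        hits_raw = hits_corr = total = 0
        for seed in range(12):
            tc, starts, intact = self._tc(0.0, seed=seed)
            raw = tuning.localizer_contrast_timecourse(tc, starts, 50.0, intact)
            corr = tuning.localizer_contrast_timecourse(
                tc, starts, 50.0, intact, correction="holm"
            )
            hits_raw += raw["significant"].sum()
            hits_corr += corr["significant"].sum()
            total += len(raw)
        assert hits_raw / total < 0.15  # ~5% nominal
        assert hits_corr / total < 0.02  # nearly none after correction

    def test_strong_effect_covers_its_span(self):
        tc, starts, intact = self._tc(5.0)
        res = tuning.localizer_contrast_timecourse(tc, starts, 50.0, intact)
        inside = res[(res["center_ms"] >= 150) & (res["center_ms"] <= 350)]
        assert inside["significant"].all()

    def test_single_condition_rejected(self):
        tc, starts, _ = self._tc(0.0)
        with pytest.raises(ValueError):
            tuning.localizer_contrast_timecourse(
                tc, starts, 50.0, np.ones(tc.shape[0], dtype=bool)
            )
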