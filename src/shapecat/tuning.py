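"""Channel-level statistics.

Responsiveness detection (Bonferroni-corrected baseline-vs-post ANOVA),
response latency from 25-ms bins, the analysis-window selection rule,
two-factor shape x category ANOVA with eta-squared effect sizes and Tukey
post-hocs, selectivity classification, the Swidth tuning-breadth index,
d-prime, and the intact-vs-scrambled localizer contrast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import _window_rate, compute_net_mua, net_timecourse
from .types import ChannelStats, TrialDataset

__all__ = [
    "detect_responsive_mua",
    "detect_responsive_hg",
    "estimate_latency",
    "select_analysis_window",
    "anova_shape_category",
    "classify_selectivity",
    "selectivity_width",
    "channel_stats",
    "d_prime",
    "localizer_contrast_timecourse",
    "tuning_table",
]


# ---------------------------------------------------------------------------
# responsiveness
# ---------------------------------------------------------------------------


def detect_responsive_mua(
    data: TrialDataset,
    post_window: tuple[float, float] = (50.0, 250.0),
    baseline: tuple[float, float] | None = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Visually responsive channels: significant rate *increase* after onset.

    Per channel, a one-way ANOVA compares per-trial mean baseline rates
    with per-trial mean post-stimulus rates; the threshold is Bonferroni
    corrected (``alpha / n_channels``) and the post mean must exceed the
    baseline mean. Returns ``(responsive_mask, p_values)``.
    """
    baseline = data.baseline_window if baseline is None else baseline
    if data.n_trials < 2:
        raise ValueError("responsiveness detection needs at least 2 trials")
    base = _window_rate(data, baseline)  # (trials, channels)
    post = _window_rate(data, post_window)
    n_ch = data.n_channels
    p = np.empty(n_ch)
    for ch in range(n_ch):
        p[ch] = stats.f_oneway(base[:, ch], post[:, ch]).pvalue
    p = np.nan_to_num(p, nan=1.0)  # constant inputs -> undecidable, not responsive
    increase = post.mean(axis=0) > base.mean(axis=0)
    return (p < alpha / n_ch) & increase, p


def detect_responsive_hg(
    power: np.ndarray,
    times_ms: np.ndarray,
    stimulus_of_trial: np.ndarray,
    post_window: tuple[float, float] = (50.0, 250.0),
    baseline: tuple[float, float] = (-200.0, 0.0),
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """High-gamma responsiveness using only the two preferred conditions.

    Because the band-power signal is noisier than spiking, conditions are
    ranked per channel by mean post-stimulus power and the baseline-vs-post
    ANOVA is restricted to trials of the two most preferred conditions;
    the corrected threshold and increase requirement are as for MUA.
    """
    stims = np.unique(stimulus_of_trial)
    if len(stims) < 2:
        raise ValueError("need at least 2 conditions")
    post_mask = (times_ms >= post_window[0]) & (times_ms < post_window[1])
    base_mask = (times_ms >= baseline[0]) & (times_ms < baseline[1])
    if not post_mask.any() or not base_mask.any():
        raise ValueError("windows outside the power time axis")
    post = power[:, :, post_mask].mean(axis=2)  # (trials, channels)
    base = power[:, :, base_mask].mean(axis=2)
    n_ch = power.shape[1]
    p = np.empty(n_ch)
    increase = np.empty(n_ch, dtype=bool)
    for ch in range(n_ch):
        cond_means = np.array(
            [post[stimulus_of_trial == s, ch].mean() for s in stims]
        )
        top2 = stims[np.argsort(cond_means)[::-1][:2]]
        sel = np.isin(stimulus_of_trial, top2)
        p[ch] = stats.f_oneway(base[sel, ch], post[sel, ch]).pvalue
        increase[ch] = post[sel, ch].mean() > base[sel, ch].mean()
    p = np.nan_to_num(p, nan=1.0)
    return (p < alpha / n_ch) & increase, p


# ---------------------------------------------------------------------------
# latency and analysis window
# ---------------------------------------------------------------------------


def estimate_latency(
    net_tc: np.ndarray,
    bin_starts_ms: np.ndarray,
    alpha: float = 0.05,
    n_consecutive: int = 3,
) -> float | None:
    """Response latency of one channel from its binned net time course.

    ``net_tc`` is (n_trials, n_bins) baseline-subtracted activity (25-ms
    bins by convention). Each post-onset bin is tested against zero across
    trials (two-sided one-sample t-test); the latency is the start of the
    first bin in the earliest run of ``n_consecutive`` significant bins,
    or None if no such run exists. Never earlier than the first post-onset
    bin.
    """
    if net_tc.ndim != 2 or net_tc.shape[0] < 2:
        raise ValueError("need a (n_trials, n_bins) array with >= 2 trials")
    post = bin_starts_ms >= 0
    if post.sum() < n_consecutive:
        raise ValueError(f"need at least {n_consecutive} post-stimulus bins")
    tc = net_tc[:, post]
    starts = bin_starts_ms[post]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_1samp(tc, 0.0, axis=0).pvalue
    sig = np.nan_to_num(p, nan=1.0) < alpha
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= n_consecutive:
            return float(starts[i - n_consecutive + 1])
    return None


def select_analysis_window(
    latencies_ms: list[float] | np.ndarray,
    bin_ms: float = 50.0,
    before_ms: float = 50.0,
    after_ms: float = 150.0,
) -> tuple[float, float]:
    """Analysis window from the mean response latency of an array.

    The mean latency is snapped to the nearest 50-ms bin center (25, 75,
    125, ... ms) and the window spans 50 ms before to 150 ms after that
    center: mean 123 ms -> center 125 -> [75, 275).
    """
    lats = np.asarray([l for l in np.atleast_1d(latencies_ms) if l is not None and not np.isnan(l)])
    if lats.size == 0:
        raise ValueError("no latencies to average")
    mean = lats.mean()
    # candidate centers 25, 75, 125, ... bracket the mean; take the nearer
    lower = np.floor(mean / bin_ms) * bin_ms + bin_ms / 2
    upper = lower + bin_ms
    center = lower if abs(mean - lower) <= abs(mean - upper) else upper
    return (float(center - before_ms), float(center + after_ms))


# ---------------------------------------------------------------------------
# two-factor ANOVA
# ---------------------------------------------------------------------------


def anova_shape_category(
    responses: np.ndarray,
    shape_labels: np.ndarray,
    category_labels: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Two-factor fixed-effects ANOVA with interaction for one channel.

    ``responses`` are per-trial net responses; labels give each trial's
    shape type and category. Type II sums of squares accommodate the mild
    imbalance of 10-19 trials per stimulus. Effect sizes are classical
    eta-squared (SS_effect / SS_total), so the three components sum to at
    most 1. Tukey HSD pairwise comparisons are run on the marginal means
    of each significant factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    y = np.asarray(responses, dtype=float)
    df = pd.DataFrame({"y": y, "shape": shape_labels, "category": category_labels})
    cells = df.groupby(["shape", "category"]).size()
    expected = df["shape"].nunique() * df["category"].nunique()
    if len(cells) < expected or (cells < 2).any():
        thin = [f"(shape={s}, category={c})" for (s, c), n in cells.items() if n < 2]
        missing_n = expected - len(cells)
        raise ValueError(
            f"need >= 2 trials in every (shape, category) cell; "
            f"{missing_n} empty cell(s), thin cells: {thin}"
        )
    model = smf.ols("y ~ C(shape) * C(category)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss = {
        "shape": float(table.loc["C(shape)", "sum_sq"]),
        "category": float(table.loc["C(category)", "sum_sq"]),
        "interaction": float(table.loc["C(shape):C(category)", "sum_sq"]),
    }
    out = {
        "p_shape": float(table.loc["C(shape)", "PR(>F)"]),
        "p_category": float(table.loc["C(category)", "PR(>F)"]),
        "p_interaction": float(table.loc["C(shape):C(category)", "PR(>F)"]),
        "eta2_shape": ss["shape"] / ss_total if ss_total > 0 else 0.0,
        "eta2_category": ss["category"] / ss_total if ss_total > 0 else 0.0,
        "eta2_interaction": ss["interaction"] / ss_total if ss_total > 0 else 0.0,
        "anova_table": table,
    }
    posthoc = {}
    if out["p_shape"] < alpha and df["shape"].nunique() > 1:
        posthoc["shape"] = pairwise_tukeyhsd(df["y"], df["shape"], alpha=alpha)
    if out["p_category"] < alpha and df["category"].nunique() > 1:
        posthoc["category"] = pairwise_tukeyhsd(df["y"], df["category"], alpha=alpha)
    out["tukey"] = posthoc
    return out


def _twoway_type2_batch(
    Y: np.ndarray, shape_labels: np.ndarray, category_labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized two-factor Type II ANOVA across many channels at once.

    ``Y`` is (n_trials, n_channels). Produces the same p-values and
    eta-squared components as :func:`anova_shape_category` (asserted in the
    test suite) by comparing residual sums of squares of nested
    least-squares fits, but solves all channels in one pass.
    """
    n = Y.shape[0]
    s_levels, s_idx = np.unique(shape_labels, return_inverse=True)
    c_levels, c_idx = np.unique(category_labels, return_inverse=True)
    S, C = len(s_levels), len(c_levels)

    def _onehot(idx: np.ndarray, k: int) -> np.ndarray:
        m = np.zeros((n, k))
        m[np.arange(n), idx] = 1.0
        return m[:, 1:]  # drop first level

    A = _onehot(s_idx, S)
    B = _onehot(c_idx, C)
    AB = (A[:, :, None] * B[:, None, :]).reshape(n, -1)
    one = np.ones((n, 1))

    def _sse(X: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        return (resid**2).sum(axis=0)

    sse_a = _sse(np.hstack([one, A]))
    sse_b = _sse(np.hstack([one, B]))
    sse_ab = _sse(np.hstack([one, A, B]))
    sse_full = _sse(np.hstack([one, A, B, AB]))
    ss = {
        "shape": sse_b - sse_ab,
        "category": sse_a - sse_ab,
        "interaction": sse_ab - sse_full,
    }
    df = {"shape": S - 1, "category": C - 1, "interaction": (S - 1) * (C - 1)}
    df_resid = n - S * C
    if df_resid <= 0:
        raise ValueError("need more than one trial per cell")
    mse = sse_full / df_resid
    ss_total = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    out: dict[str, np.ndarray] = {}
    for term in ss:
        f = (ss[term] / df[term]) / mse
        out[f"p_{term}"] = stats.f.sf(f, df[term], df_resid)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"eta2_{term}"] = np.where(ss_total > 0, ss[term] / ss_total, 0.0)
    return out


def classify_selectivity(
    p_shape: float, p_category: float, p_interaction: float, alpha: float = 0.05
) -> str:
    """Deterministic selectivity class from the three ANOVA p-values.

    A significant interaction dominates regardless of main effects; then a
    significant shape main effect alone gives ``shape_only``, a category
    main effect alone ``category_only``; anything else is
    ``responsive_only``.
    """
    if p_interaction < alpha:
        return "interaction"
    if p_shape < alpha and p_category >= alpha:
        return "shape_only"
    if p_category < alpha and p_shape >= alpha:
        return "category_only"
    return "responsive_only"


# ---------------------------------------------------------------------------
# selectivity indices
# ---------------------------------------------------------------------------


def selectivity_width(responses: np.ndarray) -> float | None:
    """Tuning-breadth index Swidth = (n - sum(r_i)/max) / (n - 1).

    Negative net responses are clipped to 0 first (the index presumes
    non-negative rates). 0 means equal response to every stimulus, 1 a
    single-stimulus responder. Returns None (with a warning) when the
    rectified maximum is zero.
    """
    r = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    n = r.size
    if n < 2:
        raise ValueError("Swidth needs at least 2 stimuli")
    mx = r.max()
    if mx <= 0:
        warnings.warn("channel has no positive response; Swidth undefined", stacklevel=2)
        return None
    return float((n - r.sum() / mx) / (n - 1))


def channel_stats(per_trial: np.ndarray, nonpreferred: str = "pooled") -> ChannelStats:
    """Preferred vs non-preferred statistics for one channel.

    ``per_trial`` is (n_stimuli, max_trials) NaN-padded. The preferred
    condition is the highest-mean stimulus; the non-preferred side is
    either all remaining trials pooled (default) or the single
    lowest-mean stimulus (``nonpreferred='worst'``).
    """
    pt = np.asarray(per_trial, dtype=float)
    means = np.nanmean(pt, axis=1)
    pref = int(np.nanargmax(means))
    pref_trials = pt[pref][~np.isnan(pt[pref])]
    if nonpreferred == "pooled":
        rest = np.delete(pt, pref, axis=0).ravel()
        non_trials = rest[~np.isnan(rest)]
    elif nonpreferred == "worst":
        worst = int(np.nanargmin(means))
        non_trials = pt[worst][~np.isnan(pt[worst])]
    else:
        raise ValueError("nonpreferred must be 'pooled' or 'worst'")
    if len(pref_trials) < 2 or len(non_trials) < 2:
        raise ValueError("need >= 2 trials per condition")
    return ChannelStats(
        mu_pref=float(pref_trials.mean()),
        mu_nonpref=float(non_trials.mean()),
        var_pref=float(pref_trials.var(ddof=1)),
        var_nonpref=float(non_trials.var(ddof=1)),
    )


def d_prime(stats_: ChannelStats) -> float:
    """Discriminability d' = (mu_pref - mu_nonpref) / pooled SD.

    The pooled SD is sqrt((var_pref + var_nonpref) / 2). A zero pooled SD
    means infinite separation and returns ``inf`` (sign following the mean
    difference).
    """
    sigma = stats_.sigma_pooled
    diff = stats_.mu_pref - stats_.mu_nonpref
    if sigma == 0:
        return float(np.sign(diff) * np.inf) if diff != 0 else 0.0
    return float(diff / sigma)


# ---------------------------------------------------------------------------
# localizer contrast
# ---------------------------------------------------------------------------


def localizer_contrast_timecourse(
    timecourses: np.ndarray,
    bin_starts_ms: np.ndarray,
    bin_width_ms: float,
    intact_mask: np.ndarray,
    window_ms: float = 100.0,
    step_ms: float = 50.0,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Sliding-window intact-vs-scrambled contrast.

    ``timecourses`` is (n_trials, n_channels, n_bins); responses are
    averaged over channels and over each 100-ms window (50% overlap) and
    the two conditions compared with a one-way ANOVA per window.
    ``correction='holm'`` additionally corrects across windows. Returns a
    frame with ``center_ms``, ``p``, ``p_corrected``, ``significant``.
    """
    intact_mask = np.asarray(intact_mask, dtype=bool)
    if intact_mask.all() or not intact_mask.any():
        raise ValueError("both conditions must be present")
    mean_tc = timecourses.mean(axis=1)  # (trials, bins)
    t0 = bin_starts_ms[0]
    t_end = bin_starts_ms[-1] + bin_width_ms
    centers, pvals = [], []
    start = t0
    while start + window_ms <= t_end + 1e-9:
        sel = (bin_starts_ms >= start - 1e-9) & (bin_starts_ms + bin_width_ms <= start + window_ms + 1e-9)
        vals = mean_tc[:, sel].mean(axis=1)
        res = stats.f_oneway(vals[intact_mask], vals[~intact_mask])
        centers.append(start + window_ms / 2)
        pvals.append(np.nan_to_num(res.pvalue, nan=1.0))
        start += step_ms
    p = np.asarray(pvals)
    if correction == "holm":
        from statsmodels.stats.multitest import multipletests

        _, p_corr, _, _ = multipletests(p, alpha=alpha, method="holm")
    elif correction == "none":
        p_corr = p
    else:
        raise ValueError("correction must be 'none' or 'holm'")
    return pd.DataFrame(
        {
            "center_ms": centers,
            "p": p,
            "p_corrected": p_corr,
            "significant": p_corr < alpha,
        }
    )


# ---------------------------------------------------------------------------
# channel summary table
# ---------------------------------------------------------------------------


def tuning_table(
    data: TrialDataset,
    epoch: tuple[float, float] = (50.0, 350.0),
    responsive_window: tuple[float, float] = (50.0, 250.0),
    latency_bin_ms: float = 25.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-row-per-channel summary of the full tuning analysis.

    Columns: ``channel`` (1-based), ``responsive``, ``latency_ms``,
    the three ANOVA p-values and eta-squared components,
    ``selectivity_class`` (NaN fields for non-responsive channels),
    ``s_width`` and ``d_prime``.
    """
    responsive, p_resp = detect_responsive_mua(data, responsive_window, alpha=alpha)
    crm = compute_net_mua(data, epoch=epoch)
    tc, tc_starts = net_timecourse(data, bin_width_ms=latency_bin_ms)
    stim_index = np.searchsorted(data.design.stimulus_ids, data.stimulus_of_trial)
    net_trials = (
        _window_rate(data, epoch) - _window_rate(data, data.baseline_window)
    )  # (trials, channels)
    batch = _twoway_type2_batch(
        net_trials, data.design.shape_types[stim_index], data.design.categories[stim_index]
    )
    rows = []
    for ch in range(data.n_channels):
        row: dict = {"channel": ch + 1, "responsive": bool(responsive[ch]), "p_responsive": p_resp[ch]}
        if responsive[ch]:
            row["latency_ms"] = estimate_latency(tc[:, ch, :], tc_starts, alpha=alpha)
            row.update(
                p_shape=batch["p_shape"][ch],
                p_category=batch["p_category"][ch],
                p_interaction=batch["p_interaction"][ch],
                eta2_shape=batch["eta2_shape"][ch],
                eta2_category=batch["eta2_category"][ch],
                eta2_interaction=batch["eta2_interaction"][ch],
                selectivity_class=classify_selectivity(
                    batch["p_shape"][ch],
                    batch["p_category"][ch],
                    batch["p_interaction"][ch],
                    alpha,
                ),
            )
            row["s_width"] = selectivity_width(crm.net[ch])
            try:
                row["d_prime"] = d_prime(channel_stats(crm.per_trial[ch]))
            except ValueError:
                row["d_prime"] = np.nan
        else:
            row.update(
                latency_ms=np.nan,
                p_shape=np.nan,
                p_category=np.nan,
                p_interaction=np.nan,
                eta2_shape=np.nan,
                eta2_category=np.nan,
                eta2_interaction=np.nan,
                selectivity_class="unresponsive",
                s_width=np.nan,
                d_prime=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)
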