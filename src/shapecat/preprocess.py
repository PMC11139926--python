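"""Raw trial tensors -> analysis substrates.

Net multi-unit responses (epoch minus baseline, spikes/s), cleaned
broadband field signals, baseline-normalized high-gamma power, z-scored
condition means, and peak-normalized localizer responses.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .types import ConditionResponseMatrix, TrialDataset

__all__ = [
    "compute_net_mua",
    "net_timecourse",
    "bandpass_filter",
    "reject_artifact_trials",
    "morlet_highgamma",
    "zscore_condition_means",
    "peak_normalize_localizer",
    "group_per_trial",
]


# ---------------------------------------------------------------------------
# net MUA
# ---------------------------------------------------------------------------


def _window_rate(data: TrialDataset, window: tuple[float, float]) -> np.ndarray:
    """Mean firing rate (Hz) per trial x channel inside ``window``."""
    sl = data.bin_slice(window)
    counts = data.mua[:, :, sl].sum(axis=2)
    duration_s = (sl.stop - sl.start) * data.bin_width_ms / 1000.0
    return counts / duration_s


def group_per_trial(
    values: np.ndarray, stimulus_of_trial: np.ndarray, stimulus_ids: np.ndarray
) -> np.ndarray:
    """Regroup per-trial values (n_trials, n_channels) into a NaN-padded
    (n_channels, n_stimuli, max_trials) tensor."""
    counts = [(stimulus_of_trial == sid).sum() for sid in stimulus_ids]
    max_trials = max(counts)
    n_channels = values.shape[1]
    out = np.full((n_channels, len(stimulus_ids), max_trials), np.nan)
    for j, sid in enumerate(stimulus_ids):
        idx = np.flatnonzero(stimulus_of_trial == sid)
        out[:, j, : len(idx)] = values[idx].T
    return out


def compute_net_mua(
    data: TrialDataset,
    epoch: tuple[float, float] = (50.0, 350.0),
    baseline: tuple[float, float] | None = None,
) -> ConditionResponseMatrix:
    """Net MUA response per trial: epoch rate minus baseline rate (spikes/s).

    Adding a constant rate to both baseline and epoch leaves the net
    response unchanged; a silent channel has net 0.
    """
    baseline = data.baseline_window if baseline is None else baseline
    net_trials = _window_rate(data, epoch) - _window_rate(data, baseline)
    per_trial = group_per_trial(net_trials, data.stimulus_of_trial, data.design.stimulus_ids)
    return ConditionResponseMatrix(
        net=np.nanmean(per_trial, axis=2),
        per_trial=per_trial,
        stimulus_ids=data.design.stimulus_ids,
        window=epoch,
        signal_kind="mua",
    )


def net_timecourse(
    data: TrialDataset,
    bin_width_ms: float | None = None,
    baseline: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-subtracted binned rate time course.

    Returns ``(net, bin_starts_ms)`` where ``net`` is (n_trials,
    n_channels, n_bins) in spikes/s, computed at ``bin_width_ms`` (which
    must be a multiple of the recorded bin width; default: recorded width).
    """
    baseline = data.baseline_window if baseline is None else baseline
    width = data.bin_width_ms if bin_width_ms is None else bin_width_ms
    factor = width / data.bin_width_ms
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"requested bin width {width} ms is not a multiple of the recorded "
            f"{data.bin_width_ms} ms"
        )
    factor = int(round(factor))
    n_bins = (data.n_bins // factor) * factor
    counts = data.mua[:, :, :n_bins].reshape(
        data.n_trials, data.n_channels, n_bins // factor, factor
    ).sum(axis=3)
    rate = counts / (width / 1000.0)
    base_rate = _window_rate(data, baseline)
    starts = data.t_start_ms + width * np.arange(n_bins // factor)
    return rate - base_rate[:, :, None], starts


# ---------------------------------------------------------------------------
# field-potential path
# ---------------------------------------------------------------------------


def bandpass_filter(
    x: np.ndarray,
    low_hz: float,
    high_hz: float,
    sfreq_hz: float,
    numtaps: int | None = None,
) -> np.ndarray:
    """Zero-phase FIR band-pass along the last axis.

    A linear-phase (symmetric) windowed-sinc kernel applied with 'same'
    alignment, so the output has the input's length and no group delay.
    """
    nyq = sfreq_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for sampling rate {sfreq_hz} Hz"
        )
    if numtaps is None:
        # ~3 cycles of the low edge, forced odd for exact symmetry
        numtaps = int(3 * sfreq_hz / low_hz) | 1
    taps = sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=sfreq_hz)
    x = np.asarray(x, dtype=float)
    pad = numtaps // 2
    padded = np.concatenate(
        [x[..., 1 : pad + 1][..., ::-1], x, x[..., -pad - 1 : -1][..., ::-1]], axis=-1
    )
    out = sps.oaconvolve(padded, taps.reshape((1,) * (x.ndim - 1) + (-1,)), mode="valid", axes=-1)
    return out


def reject_artifact_trials(lfp: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Keep-mask over trials based on broadband amplitude.

    A trial is flagged when its RMS amplitude (per channel, averaged over
    channels) exceeds the across-trial mean by more than ``k`` standard
    deviations. The mask is returned, never applied silently.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.shape[0] < 3:
        raise ValueError("artifact rejection needs at least 3 trials")
    rms = np.sqrt(np.mean(lfp**2, axis=-1))  # (trials, channels)
    summary = rms.mean(axis=1)
    mu, sd = summary.mean(), summary.std(ddof=1)
    if np.isinf(k):
        return np.ones(lfp.shape[0], dtype=bool)
    return summary <= mu + k * sd


def morlet_highgamma(
    lfp: np.ndarray,
    sfreq_hz: float,
    t_start_ms: float,
    band: tuple[float, float] = (60.0, 120.0),
    n_cycles: float = 7.0,
    freq_step: float = 1.0,
    baseline: tuple[float, float] = (-300.0, 0.0),
    edge_trim_ms: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-normalized band power via Morlet wavelets.

    The time-frequency power is computed at ``freq_step`` Hz steps across
    ``band`` with ``n_cycles``-cycle Morlet wavelets; per trial, channel
    and frequency, power is divided by its own mean over the baseline
    interval, then averaged over frequencies. ``edge_trim_ms`` is removed
    from both ends to discard filter edge artifacts.

    Returns ``(power, times_ms)`` with power (n_trials, n_channels,
    n_times) as a unitless ratio (1 = baseline level).
    """
    from mne.time_frequency import tfr_array_morlet

    lfp = np.asarray(lfp, dtype=float)
    nyq = sfreq_hz / 2.0
    if band[1] >= nyq:
        raise ValueError(f"band {band} exceeds Nyquist {nyq} Hz")
    n_samples = lfp.shape[-1]
    times_ms = t_start_ms + 1000.0 * np.arange(n_samples) / sfreq_hz
    base_mask = (times_ms >= baseline[0]) & (times_ms < baseline[1])
    if base_mask.sum() < n_cycles * sfreq_hz / band[0]:
        raise ValueError("baseline shorter than one wavelet at the lowest frequency")
    freqs = np.arange(band[0], band[1] + 1e-9, freq_step)
    power = tfr_array_morlet(
        lfp, sfreq_hz, freqs, n_cycles=n_cycles, output="power", zero_mean=True
    )  # (trials, channels, freqs, times)
    base = power[..., base_mask].mean(axis=-1, keepdims=True)
    norm = power / base
    ratio = norm.mean(axis=2)  # average over frequencies after normalization
    trim = int(round(edge_trim_ms / 1000.0 * sfreq_hz))
    if trim > 0:
        ratio = ratio[..., trim:-trim]
        times_ms = times_ms[trim:-trim]
    return ratio, times_ms


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------


def zscore_condition_means(net: np.ndarray) -> np.ndarray:
    """Z-score each channel's condition means across stimuli.

    After the transform every channel has mean 0 and SD 1 across the
    stimulus axis; zero-variance channels map to all-zeros with a warning.
    Idempotent: z-scoring twice equals z-scoring once.
    """
    net = np.asarray(net, dtype=float)
    if net.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 stimuli")
    mu = net.mean(axis=1, keepdims=True)
    sd = net.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{flat.sum()} constant channel(s) mapped to zeros in z-scoring",
            stacklevel=2,
        )
    sd[sd == 0] = 1.0
    out = (net - mu) / sd
    out[flat] = 0.0
    return out


def peak_normalize_localizer(
    timecourses: np.ndarray, intact_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Divide each channel's responses by the peak of its intact mean.

    ``timecourses`` is (n_trials, n_channels, n_bins) net activity and
    ``intact_mask`` flags intact-condition trials. Channels whose intact
    peak is not positive are flagged excluded (second return value) and
    left unscaled.
    """
    intact_mask = np.asarray(intact_mask, dtype=bool)
    if intact_mask.sum() == 0:
        raise ValueError("no intact trials")
    intact_mean = timecourses[intact_mask].mean(axis=0)  # (channels, bins)
    peaks = intact_mean.max(axis=1)
    excluded = peaks <= 0
    safe = np.where(excluded, 1.0, peaks)
    return timecourses / safe[None, :, None], excluded
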