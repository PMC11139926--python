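"""Synthetic multichannel recordings with controlled shape/category tuning.

The generator emulates the kind of data produced by a 96-channel
microelectrode array in shape-sensitive human visual cortex during a
factorial shape x category experiment: Poisson spike counts around
per-channel rate profiles, response latencies, an optional band-limited
(60-120 Hz) field signal carrying the same tuning, binary silhouette images
per stimulus, and behavioral shape/category dissimilarity models.

Channel classes
---------------
``shape_only``
    firing rate modulated by shape type only (graded tuning curve);
``category_only``
    rate modulated by semantic category only;
``interaction``
    rate driven by specific (shape, category) cells; two flavors exist --
    ``exemplar`` channels boost a few exemplars of a single category (the
    kind of channel that makes one category decodable), and ``cell``
    channels boost arbitrary cells so that shape preference differs between
    categories;
``responsive_only``
    a visual response with no stimulus tuning;
``unresponsive``
    baseline firing throughout.

All draws come from ``numpy.random.Generator`` objects derived from the
caller's seed; identical spec + seed gives bit-identical datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .types import RDM, StimulusDesign, TrialDataset

__all__ = [
    "PopulationSpec",
    "generate_design",
    "generate_silhouettes",
    "generate_behavioral_rdms",
    "generate_trials",
    "generate_localizer_trials",
]


# ---------------------------------------------------------------------------
# population specification
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    """Parameters of the simulated recording population.

    Class proportions default to the mix observed in the modeled recordings
    (16% shape-only, 3% category-only, 48% interaction, 10% responsive but
    untuned; the remainder unresponsive). Rates are in Hz; ``modulation``
    in [0, 1] scales tuning depth (0 = flat, 1 = full range).
    """

    n_channels: int = 96
    p_shape_only: float = 0.16
    p_category_only: float = 0.03
    p_interaction: float = 0.48
    p_responsive_only: float = 0.10
    baseline_rate: float = 5.0
    gain: float = 20.0
    modulation: float = 1.0
    fano_factor: float = 2.0
    latency_mean_ms: float = 120.0
    latency_jitter_ms: float = 25.0
    trials_min: int = 10
    trials_max: int = 19
    bin_width_ms: float = 25.0
    t_start_ms: float = -300.0
    t_stop_ms: float = 500.0
    interaction_cells: int = 3
    interaction_exemplar_frac: float = 0.5
    interaction_base: float = 0.3
    interaction_halo: float = 0.0
    dominant_category: int | None = None
    dominant_category_frac: float = 0.8
    dominant_category_gain: float = 0.2
    with_lfp: bool = False
    lfp_sfreq_hz: float = 1000.0
    lfp_noise_sd: float = 1.0
    lfp_hg_band: tuple[float, float] = (60.0, 120.0)
    lfp_hg_gain: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = (
            self.p_shape_only
            + self.p_category_only
            + self.p_interaction
            + self.p_responsive_only
        )
        if total > 1.0 + 1e-9:
            raise ValueError(f"class proportions sum to {total:.3f} > 1")
        if self.baseline_rate < 0 or self.gain < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.modulation <= 1.0):
            raise ValueError("modulation must lie in [0, 1]")
        if self.fano_factor < 1.0:
            raise ValueError("fano_factor must be >= 1 (1 = Poisson)")
        if not (1 <= self.trials_min <= self.trials_max):
            raise ValueError("invalid trials-per-stimulus range")

    @classmethod
    def category_preferring_array(
        cls, category: int = 2, **overrides
    ) -> "PopulationSpec":
        """Preset emulating an array whose interaction channels concentrate
        on exemplars of one category (the 'animals-preferring' profile).

        Shape-tuned plus interaction channels, no category-main-effect
        channels; most exemplar-flavor interaction channels prefer the
        given ``category``. This is the population profile in which object
        category is linearly decodable from the multichannel pattern even
        though no single channel carries a category main effect and the
        dissimilarity structure stays shape-dominated.
        """
        params = dict(
            p_shape_only=0.16,
            p_category_only=0.0,
            p_interaction=0.48,
            p_responsive_only=0.10,
            dominant_category=category,
        )
        params.update(overrides)
        return cls(**params)


# ---------------------------------------------------------------------------
# stimulus design
# ---------------------------------------------------------------------------

_CATEGORY_NAMES = (
    "minerals",
    "animals",
    "fruit_vegetables",
    "musical_instruments",
    "sports_articles",
    "tools",
)


def generate_design(n_shapes: int = 9, n_categories: int = 6, seed: int = 0) -> StimulusDesign:
    """Complete shape x category factorial design (default 9 x 6 = 54).

    Deterministic given ``seed`` (the seed currently only fixes the row
    order, which is the canonical shape-major order anyway).
    """
    if n_shapes < 1 or n_categories < 1:
        raise ValueError("n_shapes and n_categories must be positive")
    rows = []
    sid = 1
    for s in range(1, n_shapes + 1):
        for c in range(1, n_categories + 1):
            cname = _CATEGORY_NAMES[c - 1] if c <= len(_CATEGORY_NAMES) else f"category{c}"
            rows.append((sid, s, c, f"shape{s}_{cname}"))
            sid += 1
    table = pd.DataFrame(rows, columns=["stimulus_id", "shape_type", "category", "name"])
    return StimulusDesign(table)


# ---------------------------------------------------------------------------
# silhouettes
# ---------------------------------------------------------------------------


def _superellipse_mask(
    H: int,
    W: int,
    rx: float,
    ry: float,
    exponent: float,
    angle_deg: float,
) -> np.ndarray:
    """Binary mask of a rotated superellipse centered on the canvas.

    ``exponent`` 2 gives an ellipse, large exponents approach a rectangle;
    ``rx``/``ry`` are half-axes as fractions of the canvas half-size.
    """
    yy, xx = np.mgrid[0:H, 0:W]
    x = (xx - (W - 1) / 2) / (W / 2)
    y = (yy - (H - 1) / 2) / (H / 2)
    th = np.deg2rad(angle_deg)
    xr = x * np.cos(th) + y * np.sin(th)
    yr = -x * np.sin(th) + y * np.cos(th)
    with np.errstate(divide="ignore"):
        v = (np.abs(xr / rx)) ** exponent + (np.abs(yr / ry)) ** exponent
    return (v <= 1.0).astype(np.uint8)


# base (rx, ry, exponent, angle) per shape family; the last three families
# are elongated bars so aspect ratio varies strongly across shape types
_SHAPE_FAMILIES = [
    (0.55, 0.55, 2.0, 0.0),   # disc
    (0.65, 0.45, 2.0, 20.0),  # tilted ellipse
    (0.50, 0.50, 4.0, 0.0),   # rounded square
    (0.62, 0.40, 6.0, 0.0),   # rounded rectangle
    (0.45, 0.60, 2.8, 60.0),  # oblique blob
    (0.58, 0.35, 2.0, 90.0),  # upright ellipse
    (0.80, 0.16, 2.0, 0.0),   # horizontal bar (high aspect ratio)
    (0.85, 0.12, 6.0, 30.0),  # thin tilted bar
    (0.90, 0.10, 2.0, 75.0),  # near-vertical spike
]


def generate_silhouettes(
    design: StimulusDesign,
    H: int = 64,
    W: int = 64,
    perturbation: float = 0.06,
    seed: int = 0,
) -> StimulusDesign:
    """Attach a binary silhouette mask to every stimulus.

    Masks of the same shape type share a parametric base shape and differ
    only by a small seeded perturbation of its parameters (scaled by
    ``perturbation``), so a pixelwise dissimilarity matrix clusters by
    shape type. With ``perturbation=0`` same-shape-type masks are
    pixelwise identical.
    """
    if H < 16 or W < 16:
        raise ValueError("canvas must be at least 16 x 16 pixels")
    rng = np.random.default_rng(seed)
    masks: dict[int, np.ndarray] = {}
    n_fam = len(_SHAPE_FAMILIES)
    for _, row in design.table.iterrows():
        s = int(row["shape_type"])
        rx, ry, expo, ang = _SHAPE_FAMILIES[(s - 1) % n_fam]
        jitter = rng.uniform(-1.0, 1.0, size=4) * perturbation
        mask = _superellipse_mask(
            H,
            W,
            rx * (1 + jitter[0]),
            ry * (1 + jitter[1]),
            max(1.2, expo * (1 + jitter[2])),
            ang + 30.0 * jitter[3],
        )
        masks[int(row["stimulus_id"])] = mask
    return StimulusDesign(design.table.copy(), masks)


# ---------------------------------------------------------------------------
# behavioral model RDMs
# ---------------------------------------------------------------------------


def generate_behavioral_rdms(
    design: StimulusDesign,
    orthogonality: float = 0.2,
    seed: int = 0,
    within: float = 0.3,
    between: float = 1.0,
    noise_sd: float = 0.05,
) -> tuple[RDM, RDM]:
    """Behavioral-style shape and category dissimilarity models.

    Each model is a block structure -- low dissimilarity (``within``) for
    stimulus pairs sharing the grouping dimension, high (``between``)
    otherwise -- plus symmetric Gaussian rating noise. Because the factorial
    design makes same-shape pairs different-category and vice versa, the two
    models come out nearly orthogonal; ``orthogonality`` is the maximum
    acceptable magnitude of their off-diagonal correlation (a warning is
    emitted if the achieved value exceeds it).
    """
    if orthogonality > 0.2 + 1e-9:
        raise ValueError("orthogonality target magnitude must be <= 0.2")
    rng = np.random.default_rng(seed)

    def _block(labels: np.ndarray, stream: np.random.Generator) -> np.ndarray:
        same = labels[:, None] == labels[None, :]
        base = np.where(same, within, between).astype(float)
        noise = stream.normal(0.0, noise_sd, size=base.shape)
        noise = (noise + noise.T) / 2.0
        vals = np.clip(base + noise, 0.0, None)
        np.fill_diagonal(vals, 0.0)
        return vals

    shape_rdm = RDM(_block(design.shape_types, rng), design.stimulus_ids, "behavioral_shape")
    cat_rdm = RDM(_block(design.categories, rng), design.stimulus_ids, "behavioral_category")
    r = np.corrcoef(shape_rdm.triu_vector(), cat_rdm.triu_vector())[0, 1]
    if abs(r) > orthogonality:
        warnings.warn(
            f"achieved |corr(shape, category)| = {abs(r):.3f} exceeds target "
            f"{orthogonality}; returning best effort",
            stacklevel=2,
        )
    return shape_rdm, cat_rdm


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------


def _assign_classes(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    counts = {
        "shape_only": int(round(spec.p_shape_only * spec.n_channels)),
        "category_only": int(round(spec.p_category_only * spec.n_channels)),
        "interaction": int(round(spec.p_interaction * spec.n_channels)),
        "responsive_only": int(round(spec.p_responsive_only * spec.n_channels)),
    }
    total = sum(counts.values())
    if total > spec.n_channels:
        # trim the largest class to fit (rounding artifact)
        biggest = max(counts, key=counts.get)
        counts[biggest] -= total - spec.n_channels
    labels = (
        ["shape_only"] * counts["shape_only"]
        + ["category_only"] * counts["category_only"]
        + ["interaction"] * counts["interaction"]
        + ["responsive_only"] * counts["responsive_only"]
    )
    labels += ["unresponsive"] * (spec.n_channels - len(labels))
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    return labels


def _tuning_weights(n_levels: int, rng: np.random.Generator) -> np.ndarray:
    """Graded tuning weights in [0, 1] with min 0 and max 1."""
    w = rng.uniform(0.0, 1.0, size=n_levels)
    w = w - w.min()
    peak = w.max()
    if peak <= 0:
        w[rng.integers(n_levels)] = 1.0
        peak = 1.0
    return w / peak


def _channel_rate_profile(
    klass: str,
    design: StimulusDesign,
    spec: PopulationSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Per-stimulus response weight in [0, 1] plus ground-truth details."""
    n = design.n_stimuli
    m = spec.modulation
    info: dict = {}
    if klass == "unresponsive":
        return np.zeros(n), info
    if klass == "responsive_only":
        return np.ones(n), info
    if klass == "shape_only":
        w = _tuning_weights(design.n_shape_types, rng)
        info["preferred_shape"] = int(np.argmax(w) + 1)
        weights = w[design.shape_types - 1]
    elif klass == "category_only":
        w = _tuning_weights(design.n_categories, rng)
        info["preferred_category"] = int(np.argmax(w) + 1)
        weights = w[design.categories - 1]
    elif klass == "interaction":
        exemplar = rng.random() < spec.interaction_exemplar_frac
        k = min(spec.interaction_cells, n)
        if exemplar:
            # boost k exemplars (shapes) of a single category
            if (
                spec.dominant_category is not None
                and rng.random() < spec.dominant_category_frac
            ):
                cat = int(spec.dominant_category)
            else:
                cat = int(rng.integers(1, design.n_categories + 1))
            members = np.flatnonzero(design.categories == cat)
            boosted = rng.choice(members, size=min(k, len(members)), replace=False)
            info["flavor"] = "exemplar"
            info["preferred_category"] = cat
        else:
            boosted = rng.choice(n, size=k, replace=False)
            info["flavor"] = "cell"
        info["boosted_stimuli"] = np.sort(design.stimulus_ids[boosted]).tolist()
        # a broad base response with boosts on the preferred cells: real
        # interaction sites are visually responsive to most stimuli
        weights = np.full(n, spec.interaction_base)
        if exemplar and spec.interaction_halo > 0:
            # optional: exemplar-preferring sites respond weakly but
            # consistently to the *other* exemplars of their category (the
            # weak category main effect such sites can show alongside the
            # interaction)
            halo = spec.interaction_base + spec.interaction_halo * (
                1.0 - spec.interaction_base
            )
            weights[design.categories == info["preferred_category"]] = halo
        weights[boosted] = 1.0
    else:  # pragma: no cover
        raise ValueError(f"unknown channel class {klass!r}")
    return (1.0 - m) + m * weights, info


def _bandlimited_noise(
    n_samples: int, sfreq: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to ``band`` (FFT masking)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _overdispersed_counts(
    lam: np.ndarray, fano: float, rng: np.random.Generator
) -> np.ndarray:
    """Counts with mean ``lam`` and variance ``fano * lam``.

    ``fano == 1`` gives Poisson; above 1 a negative binomial
    (Gamma-Poisson mixture) with r = lam / (fano - 1), p = 1 / fano.
    """
    if fano <= 1.0 + 1e-12:
        return rng.poisson(lam)
    out = np.zeros(lam.shape, dtype=np.int64)
    pos = lam > 0
    r = lam[pos] / (fano - 1.0)
    out[pos] = rng.negative_binomial(r, 1.0 / fano)
    return out


def generate_trials(
    design: StimulusDesign, spec: PopulationSpec
) -> tuple[TrialDataset, pd.DataFrame]:
    """Simulate a recording session; returns the dataset and ground truth.

    Spike counts are Poisson per bin around a per-channel rate profile:
    baseline rate before the channel's latency, baseline + gain x weight
    afterwards, where the per-stimulus weight encodes the channel's class.
    When ``spec.with_lfp`` the continuous signal carries a band-limited
    amplitude increase with the same tuning, so the high-gamma path sees
    the same structure as the spiking path.

    The ground-truth table has one row per channel: ``channel`` (1-based),
    ``class``, ``latency_ms`` (NaN for unresponsive channels) and
    class-specific details (preferred shape/category, boosted stimuli).
    """
    if design.validate():
        raise ValueError("invalid stimulus design: " + "; ".join(design.validate()))
    rng = np.random.default_rng(spec.seed)
    classes = _assign_classes(spec, rng)

    n_bins = int(round((spec.t_stop_ms - spec.t_start_ms) / spec.bin_width_ms))
    bin_starts = spec.t_start_ms + spec.bin_width_ms * np.arange(n_bins)
    dt_s = spec.bin_width_ms / 1000.0

    # trials per stimulus in the configured range
    n_per_stim = rng.integers(spec.trials_min, spec.trials_max + 1, size=design.n_stimuli)
    stim_of_trial = np.repeat(design.stimulus_ids, n_per_stim)
    order = rng.permutation(len(stim_of_trial))
    stim_of_trial = stim_of_trial[order]
    n_trials = len(stim_of_trial)
    stim_index = np.searchsorted(design.stimulus_ids, stim_of_trial)

    # per-channel profiles and latencies
    weights = np.zeros((spec.n_channels, design.n_stimuli))
    gt_rows = []
    latencies = np.full(spec.n_channels, np.nan)
    for ch in range(spec.n_channels):
        w, info = _channel_rate_profile(classes[ch], design, spec, rng)
        weights[ch] = w
        if classes[ch] != "unresponsive":
            lat = rng.normal(spec.latency_mean_ms, spec.latency_jitter_ms)
            lat = max(0.0, round(lat / spec.bin_width_ms) * spec.bin_width_ms)
            latencies[ch] = lat
        gt_rows.append(
            {
                "channel": ch + 1,
                "class": classes[ch],
                "latency_ms": latencies[ch],
                "preferred_shape": info.get("preferred_shape", np.nan),
                "preferred_category": info.get("preferred_category", np.nan),
                "flavor": info.get("flavor", ""),
                "boosted_stimuli": ";".join(map(str, info.get("boosted_stimuli", []))),
            }
        )
    ground_truth = pd.DataFrame(gt_rows)

    # broad preference of the whole array for one category: a near-uniform
    # additive elevation across responsive channels. Being (almost) common
    # to all channels it barely moves pattern correlations, but it is a
    # linear-decoder feature that generalizes across shape types.
    if spec.dominant_category is not None and spec.dominant_category_gain > 0:
        dom = design.categories == spec.dominant_category
        responsive_ch = classes != "unresponsive"
        bump = spec.dominant_category_gain * rng.uniform(
            0.7, 1.3, size=spec.n_channels
        )
        weights[np.ix_(responsive_ch, dom)] += bump[responsive_ch][:, None]

    # rate tensor (channel, stimulus, bin) -> overdispersed counts per trial.
    # Cortical MUA counts are overdispersed relative to Poisson; a
    # Gamma-Poisson mixture with variance F * mean (F = fano_factor)
    # emulates that trial-to-trial excess variability.
    post = bin_starts[None, None, :] >= np.nan_to_num(latencies, nan=np.inf)[:, None, None]
    rates = spec.baseline_rate + spec.gain * weights[:, :, None] * post
    lam = (rates * dt_s)[:, stim_index, :].transpose(1, 0, 2)  # (trial, channel, bin)
    counts = _overdispersed_counts(lam, spec.fano_factor, rng)

    trial_table = pd.DataFrame(
        {"trial_id": np.arange(1, n_trials + 1), "stimulus_id": stim_of_trial}
    )

    lfp = None
    if spec.with_lfp:
        sf = spec.lfp_sfreq_hz
        n_samp = int(round((spec.t_stop_ms - spec.t_start_ms) / 1000.0 * sf))
        t_ms = spec.t_start_ms + 1000.0 * np.arange(n_samp) / sf
        lfp = np.empty((n_trials, spec.n_channels, n_samp))
        for tr in range(n_trials):
            si = stim_index[tr]
            for ch in range(spec.n_channels):
                base = spec.lfp_noise_sd * rng.standard_normal(n_samp)
                if not np.isnan(latencies[ch]) and weights[ch, si] > 0:
                    burst = _bandlimited_noise(n_samp, sf, spec.lfp_hg_band, rng)
                    envelope = (t_ms >= latencies[ch]).astype(float)
                    amp = spec.lfp_hg_gain * weights[ch, si]
                    base = base + amp * burst * envelope
                lfp[tr, ch] = base

    data = TrialDataset(
        mua=counts,
        trial_table=trial_table,
        design=design,
        bin_width_ms=spec.bin_width_ms,
        t_start_ms=spec.t_start_ms,
        baseline_window=(max(spec.t_start_ms, -300.0), 0.0),
        lfp=lfp,
        sfreq_hz=spec.lfp_sfreq_hz,
        lfp_t_start_ms=spec.t_start_ms,
    )
    return data, ground_truth


def generate_localizer_trials(
    n_trials: int,
    spec: PopulationSpec,
    seed: int = 0,
    intact_gain: float | None = None,
    scrambled_frac: float = 0.4,
) -> TrialDataset:
    """Localizer-style session: intact vs scrambled object images.

    ``n_trials`` is the count per condition; stimulus 1 is "intact",
    stimulus 2 "scrambled". On responsive channels the intact rate exceeds
    the scrambled rate by a configurable factor (``intact_gain`` defaults
    to ``spec.gain``; scrambled responses are ``scrambled_frac`` of it).
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials per condition")
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "stimulus_id": [1, 2],
            "shape_type": [1, 1],
            "category": [1, 2],
            "name": ["intact", "scrambled"],
        }
    )
    design = StimulusDesign(table)
    gain = spec.gain if intact_gain is None else intact_gain
    classes = _assign_classes(spec, rng)
    responsive = classes != "unresponsive"

    n_bins = int(round((spec.t_stop_ms - spec.t_start_ms) / spec.bin_width_ms))
    bin_starts = spec.t_start_ms + spec.bin_width_ms * np.arange(n_bins)
    dt_s = spec.bin_width_ms / 1000.0
    lat = np.full(spec.n_channels, np.nan)
    lat[responsive] = np.maximum(
        0.0,
        np.round(
            rng.normal(spec.latency_mean_ms, spec.latency_jitter_ms, responsive.sum())
            / spec.bin_width_ms
        )
        * spec.bin_width_ms,
    )
    post = bin_starts[None, :] >= np.nan_to_num(lat, nan=np.inf)[:, None]
    cond_gain = np.array([gain, gain * scrambled_frac])
    # rates (condition, channel, bin)
    rates = spec.baseline_rate + cond_gain[:, None, None] * post[None, :, :] * responsive[
        None, :, None
    ]
    stim = np.array([1, 2] * n_trials)
    counts = _overdispersed_counts(rates[stim - 1] * dt_s, spec.fano_factor, rng)
    trial_table = pd.DataFrame(
        {"trial_id": np.arange(1, len(stim) + 1), "stimulus_id": stim}
    )
    return TrialDataset(
        mua=counts,
        trial_table=trial_table,
        design=design,
        bin_width_ms=spec.bin_width_ms,
        t_start_ms=spec.t_start_ms,
        baseline_window=(max(spec.t_start_ms, -300.0), 0.0),
    )
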