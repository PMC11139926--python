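"""Domain types shared by every analysis stage.

Conventions used throughout the package:

* time is expressed in milliseconds relative to stimulus onset, and every
  window is half-open ``[start, end)`` so that abutting bins partition the
  axis without double counting;
* stimulus and channel indices are 1-based in files and reports and 0-based
  internally (converters live only in I/O);
* every stochastic operation takes an explicit seed or NumPy generator --
  there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "StimulusDesign",
    "TrialDataset",
    "ConditionResponseMatrix",
    "ChannelStats",
    "RDM",
    "DecodingResult",
]


class SchemaError(ValueError):
    """A container or table violates the documented layout."""


# ---------------------------------------------------------------------------
# stimulus design
# ---------------------------------------------------------------------------


@dataclass
class StimulusDesign:
    """A factorial stimulus set crossing shape type with semantic category.

    The canonical design is the 9 shape-type x 6 category cross of 54
    silhouette stimuli: each shape type contains exactly one exemplar of
    every category and vice versa, so the two dimensions are orthogonal.

    Parameters
    ----------
    table
        One row per stimulus with columns ``stimulus_id`` (1..N, contiguous),
        ``shape_type`` (1..S), ``category`` (1..C) and ``name``.
    silhouettes
        Optional mapping ``stimulus_id -> binary mask`` (H x W, 1 = figure).
    """

    table: pd.DataFrame
    silhouettes: Optional[dict[int, np.ndarray]] = None

    REQUIRED_COLUMNS = ("stimulus_id", "shape_type", "category", "name")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"stimulus table is missing columns {missing}")
        self.table = self.table.sort_values("stimulus_id").reset_index(drop=True)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_stimuli(self) -> int:
        return len(self.table)

    @property
    def stimulus_ids(self) -> np.ndarray:
        return self.table["stimulus_id"].to_numpy()

    @property
    def shape_types(self) -> np.ndarray:
        """Per-stimulus shape-type labels, aligned with ``stimulus_ids``."""
        return self.table["shape_type"].to_numpy()

    @property
    def categories(self) -> np.ndarray:
        return self.table["category"].to_numpy()

    @property
    def n_shape_types(self) -> int:
        return int(self.table["shape_type"].nunique())

    @property
    def n_categories(self) -> int:
        return int(self.table["category"].nunique())

    def labels_for(self, dimension: str) -> np.ndarray:
        """Per-stimulus labels for ``dimension`` ('shape' or 'category')."""
        if dimension == "shape":
            return self.shape_types
        if dimension == "category":
            return self.categories
        raise ValueError(f"unknown dimension {dimension!r}; use 'shape' or 'category'")

    def validate(self) -> list[str]:
        """Diagnostic report of violated design invariants (empty = valid).

        Checks that stimulus ids are unique and contiguous from 1 and that
        the (shape_type, category) pairs form a complete cross: every cell
        occupied exactly once.
        """
        report: list[str] = []
        ids = self.stimulus_ids
        if len(np.unique(ids)) != len(ids):
            report.append("duplicate stimulus_id values")
        expected = np.arange(1, len(ids) + 1)
        if not np.array_equal(np.sort(ids), expected):
            report.append("stimulus_id values are not contiguous from 1")
        shapes = np.unique(self.shape_types)
        cats = np.unique(self.categories)
        counts = self.table.groupby(["shape_type", "category"]).size()
        for s in shapes:
            for c in cats:
                n = counts.get((s, c), 0)
                if n == 0:
                    report.append(f"missing cell (shape_type={s}, category={c})")
                elif n > 1:
                    report.append(
                        f"duplicated cell (shape_type={s}, category={c}): {n} exemplars"
                    )
        if len(ids) != len(shapes) * len(cats):
            report.append(
                f"N={len(ids)} does not equal S x C = {len(shapes) * len(cats)}"
            )
        return report


# ---------------------------------------------------------------------------
# trial-resolved recordings
# ---------------------------------------------------------------------------


@dataclass
class TrialDataset:
    """Trial x channel x time recordings with per-trial stimulus labels.

    ``mua`` holds non-negative spike counts in abutting bins of
    ``bin_width_ms`` starting at ``t_start_ms``; ``lfp`` optionally holds a
    continuous field-potential stream sampled at ``sfreq_hz``.
    """

    mua: np.ndarray  # (n_trials, n_channels, n_bins) int
    trial_table: pd.DataFrame  # trial_id, stimulus_id
    design: StimulusDesign
    bin_width_ms: float = 50.0
    t_start_ms: float = -300.0
    baseline_window: tuple[float, float] = (-300.0, 0.0)
    lfp: Optional[np.ndarray] = None  # (n_trials, n_channels, n_samples)
    sfreq_hz: float = 1000.0
    lfp_t_start_ms: float = -300.0

    def __post_init__(self) -> None:
        self.mua = np.asarray(self.mua)
        if self.mua.ndim != 3:
            raise SchemaError("mua must be a trial x channel x bin array")
        if np.any(self.mua < 0):
            raise SchemaError("mua spike counts must be non-negative")
        for col in ("trial_id", "stimulus_id"):
            if col not in self.trial_table.columns:
                raise SchemaError(f"trial table is missing column {col!r}")
        if len(self.trial_table) != self.mua.shape[0]:
            raise SchemaError(
                f"trial table has {len(self.trial_table)} rows but mua has "
                f"{self.mua.shape[0]} trials"
            )
        known = set(self.design.stimulus_ids.tolist())
        unknown = set(self.trial_table["stimulus_id"].tolist()) - known
        if unknown:
            raise SchemaError(f"trial table references unknown stimulus_id {sorted(unknown)}")
        t0, t1 = self.time_range_ms
        b0, b1 = self.baseline_window
        if b0 < t0 or b1 > t1:
            raise SchemaError(
                f"time axis [{t0}, {t1}) does not cover baseline window [{b0}, {b1})"
            )
        if self.lfp is not None:
            self.lfp = np.asarray(self.lfp, dtype=float)
            if self.lfp.ndim != 3 or self.lfp.shape[0] != self.mua.shape[0]:
                raise SchemaError("lfp must be trial x channel x sample, same trials as mua")

    @property
    def n_trials(self) -> int:
        return self.mua.shape[0]

    @property
    def n_channels(self) -> int:
        return self.mua.shape[1]

    @property
    def n_bins(self) -> int:
        return self.mua.shape[2]

    @property
    def bin_starts_ms(self) -> np.ndarray:
        return self.t_start_ms + self.bin_width_ms * np.arange(self.n_bins)

    @property
    def time_range_ms(self) -> tuple[float, float]:
        return self.t_start_ms, self.t_start_ms + self.bin_width_ms * self.n_bins

    @property
    def stimulus_of_trial(self) -> np.ndarray:
        return self.trial_table["stimulus_id"].to_numpy()

    def bin_slice(self, window: tuple[float, float]) -> slice:
        """Index slice of the bins whose full extent lies inside ``window``."""
        start, end = window
        t0, t1 = self.time_range_ms
        if start < t0 or end > t1:
            raise ValueError(f"window [{start}, {end}) outside recorded axis [{t0}, {t1})")
        starts = self.bin_starts_ms
        i0 = int(np.searchsorted(starts, start - 1e-9))
        i1 = int(np.searchsorted(starts + self.bin_width_ms, end + 1e-9))
        if i1 <= i0:
            raise ValueError(f"window [{start}, {end}) contains no complete bin")
        return slice(i0, i1)

    def trials_per_stimulus(self) -> pd.Series:
        return self.trial_table.groupby("stimulus_id").size()


# ---------------------------------------------------------------------------
# condition responses and channel statistics
# ---------------------------------------------------------------------------


@dataclass
class ConditionResponseMatrix:
    """Per-channel, per-stimulus net responses (trial-resolved and averaged).

    ``per_trial`` is NaN-padded along the last axis because stimuli may have
    unequal trial counts; ``net`` is its NaN-mean and the substrate of the
    tuning and population analyses.
    """

    net: np.ndarray  # (n_channels, n_stimuli)
    per_trial: np.ndarray  # (n_channels, n_stimuli, max_trials), NaN-padded
    stimulus_ids: np.ndarray
    window: tuple[float, float]
    signal_kind: str = "mua"  # mua | high_gamma

    def __post_init__(self) -> None:
        recomputed = np.nanmean(self.per_trial, axis=2)
        if not np.allclose(recomputed, self.net, atol=1e-8, equal_nan=True):
            raise SchemaError("per-trial averages do not reproduce net responses")

    @property
    def n_channels(self) -> int:
        return self.net.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.net.shape[1]

    def trial_counts(self) -> np.ndarray:
        return (~np.isnan(self.per_trial[0])).sum(axis=1)


@dataclass
class ChannelStats:
    """Preferred vs non-preferred response statistics of one channel."""

    mu_pref: float
    mu_nonpref: float
    var_pref: float
    var_nonpref: float

    def __post_init__(self) -> None:
        if self.var_pref < 0 or self.var_nonpref < 0:
            raise ValueError("variances must be non-negative")

    @property
    def sigma_pooled(self) -> float:
        return float(np.sqrt((self.var_pref + self.var_nonpref) / 2.0))


# ---------------------------------------------------------------------------
# representational dissimilarity matrices
# ---------------------------------------------------------------------------

RDM_SOURCES = (
    "neural",
    "behavioral_shape",
    "behavioral_category",
    "silhouette",
    "aspect_ratio",
    "network_layer",
)


@dataclass
class RDM:
    """Labeled symmetric dissimilarity matrix over stimuli.

    Correlation-distance RDMs (``1 - r``) lie in [0, 2]; model RDMs
    (silhouette, aspect ratio, behavioral) are non-negative. The diagonal is
    identically zero and the matrix exactly symmetric.
    """

    values: np.ndarray
    labels: np.ndarray
    source: str = "neural"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("RDM must be square")
        if len(self.labels) != n:
            raise ValueError("label count must match RDM size")
        if self.source not in RDM_SOURCES:
            raise ValueError(f"unknown RDM source {self.source!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        # enforce exactly after the tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def triu_vector(self) -> np.ndarray:
        """Off-diagonal upper-triangle entries, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reordered(self, order: np.ndarray) -> "RDM":
        return RDM(self.values[np.ix_(order, order)], self.labels[order], self.source)


# ---------------------------------------------------------------------------
# decoding results
# ---------------------------------------------------------------------------


@dataclass
class DecodingResult:
    """Accuracy time courses and controls from the sliding-window decoder."""

    dimension: str  # shape | category
    window_centers_ms: np.ndarray
    fold_accuracies: np.ndarray  # (n_windows, n_folds)
    p_values: np.ndarray  # (n_windows,)
    significant: np.ndarray  # (n_windows,) bool
    chance_level: float
    onset_ms: Optional[float] = None
    confusion: Optional[np.ndarray] = None
    confusion_window_ms: Optional[tuple[float, float]] = None
    generalization: Optional[np.ndarray] = None  # (n_train_windows, n_test_windows)

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.fold_accuracies.mean(axis=1)

    def to_dict(self) -> dict:
        out = {
            "dimension": self.dimension,
            "window_centers_ms": self.window_centers_ms.tolist(),
            "mean_accuracy": self.mean_accuracy.tolist(),
            "fold_accuracies": self.fold_accuracies.tolist(),
            "p_values": self.p_values.tolist(),
            "significant": [bool(s) for s in self.significant],
            "chance_level": self.chance_level,
            "onset_ms": self.onset_ms,
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.tolist()
            out["confusion_window_ms"] = list(self.confusion_window_ms)
        if self.generalization is not None:
            out["generalization"] = self.generalization.tolist()
        return out

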