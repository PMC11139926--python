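"""Run configuration: every tunable constant of the pipeline in one place.

The defaults reproduce the analysis conventions of the study the package
models: 50-ms response bins, a [-300, 0) ms baseline, the 60-120 Hz
high-gamma band analyzed with 7-cycle Morlet wavelets, 100 split-half
iterations, 1000 RSA permutations, 100 arbitrary-grouping repetitions, and
10-fold cross-validated linear decoding in 100-ms windows stepped by 50 ms.

A serialized config plus the master seed fully reproduces a run: every
stochastic operation draws from a generator derived from the master seed
through a named substream (see :func:`AnalysisConfig.rng`).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    # --- time conventions (ms, half-open windows) ---
    bin_width_ms: float = 50.0
    baseline_window: tuple[float, float] = (-300.0, 0.0)
    epoch_window: tuple[float, float] = (50.0, 350.0)
    responsive_window: tuple[float, float] = (50.0, 250.0)
    latency_bin_ms: float = 25.0

    # --- statistics ---
    alpha: float = 0.05
    latency_alpha: float = 0.05

    # --- high-gamma path ---
    hg_band: tuple[float, float] = (60.0, 120.0)
    hg_n_cycles: float = 7.0
    hg_freq_step: float = 1.0
    hg_edge_trim_ms: float = 100.0
    lfp_bandpass: tuple[float, float] = (2.0, 300.0)
    artifact_sd: float = 2.0

    # --- representational analysis ---
    splithalf_iterations: int = 100
    rsa_permutations: int = 1000
    rsa_method: str = "spearman"  # spearman | pearson
    mds_restarts: int = 8
    max_clusters: int = 10

    # --- decoding ---
    decode_window_ms: float = 100.0
    decode_step_ms: float = 50.0
    decode_folds: int = 10
    svm_c: float = 1.0
    arbitrary_group_reps: int = 100
    cross_dimension_splits: int = 10

    # --- randomness ---
    seed: int = 0

    def rng(self, stream: str) -> np.random.Generator:
        """Generator for a named substream of the master seed.

        The substream key is a stable hash of the stream name, so adding new
        stages never perturbs the draws of existing ones.
        """
        digest = hashlib.sha256(stream.encode()).digest()
        key = int.from_bytes(digest[:4], "big")
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))

    def substream_seed(self, stream: str) -> int:
        """31-bit integer seed for APIs that want a plain seed."""
        return int(self.rng(stream).integers(0, 2**31 - 1))

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)

    def content_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_dict(data)


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
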