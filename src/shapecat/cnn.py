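"""Layerwise representational comparison through feature extractors.

Any object exposing named layers and a deterministic ``extract(image)``
method can be compared, layer by layer, against neural or behavioral RDMs.
The built-in extractors are a raw-pixel identity extractor and a small
deterministic oriented-filter bank (edge maps -> pooled maps -> global
orientation energies) that mimics the depth progression of a convolutional
network without requiring any pretrained weights. Real pretrained networks
can be plugged in by implementing the same interface with user-supplied
weights.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage, stats

from .types import RDM, StimulusDesign

__all__ = [
    "FeatureExtractor",
    "IdentityExtractor",
    "FilterBankExtractor",
    "layer_rdms",
    "correlate_layer_rdms",
]


@runtime_checkable
class FeatureExtractor(Protocol):
    """Named-layer feature extractor over single images."""

    layer_names: tuple[str, ...]

    def extract(self, image: np.ndarray) -> dict[str, np.ndarray]:
        """Flattened activation vector per layer for one image."""
        ...


class IdentityExtractor:
    """Single 'pixels' layer: the flattened image itself."""

    layer_names = ("pixels",)

    def extract(self, image: np.ndarray) -> dict[str, np.ndarray]:
        return {"pixels": np.asarray(image, dtype=float).ravel()}


class FilterBankExtractor:
    """Deterministic oriented-edge filter bank with pooling stages.

    Layers, shallow to deep:

    * ``edges`` -- rectified responses of oriented derivative-of-Gaussian
      filters at ``n_orientations`` angles, concatenated;
    * ``pooled`` -- the same maps block-averaged by ``pool`` (local
      position tolerance);
    * ``global`` -- one energy value per orientation (all position
      information discarded).

    Early layers retain pixel layout and so track silhouette similarity;
    the global layer only keeps orientation statistics.
    """

    def __init__(self, n_orientations: int = 4, sigma: float = 2.0, pool: int = 4):
        self.n_orientations = n_orientations
        self.sigma = sigma
        self.pool = pool
        self.layer_names = ("edges", "pooled", "global")

    def _edge_maps(self, image: np.ndarray) -> list[np.ndarray]:
        img = np.asarray(image, dtype=float)
        maps = []
        for k in range(self.n_orientations):
            theta = np.pi * k / self.n_orientations
            gx = ndimage.gaussian_filter(img, self.sigma, order=(0, 1))
            gy = ndimage.gaussian_filter(img, self.sigma, order=(1, 0))
            maps.append(np.abs(np.cos(theta) * gx + np.sin(theta) * gy))
        return maps

    def _block_pool(self, m: np.ndarray) -> np.ndarray:
        p = self.pool
        h, w = (m.shape[0] // p) * p, (m.shape[1] // p) * p
        return m[:h, :w].reshape(h // p, p, w // p, p).mean(axis=(1, 3))

    def extract(self, image: np.ndarray) -> dict[str, np.ndarray]:
        maps = self._edge_maps(image)
        pooled = [self._block_pool(m) for m in maps]
        return {
            "edges": np.concatenate([m.ravel() for m in maps]),
            "pooled": np.concatenate([m.ravel() for m in pooled]),
            "global": np.array([m.mean() for m in maps]),
        }


def layer_rdms(
    extractor: FeatureExtractor, design: StimulusDesign
) -> dict[str, RDM]:
    """Correlation-distance RDM (1 - Pearson) per extractor layer.

    Images come from the design's silhouettes; activation vectors of every
    stimulus pair are Pearson-correlated per layer.
    """
    if not design.silhouettes:
        raise ValueError("design carries no images")
    ids = design.stimulus_ids
    acts: dict[str, list[np.ndarray]] = {name: [] for name in extractor.layer_names}
    for i in ids:
        feats = extractor.extract(design.silhouettes[int(i)])
        for name in extractor.layer_names:
            acts[name].append(np.asarray(feats[name], dtype=float))
    out = {}
    for name, vecs in acts.items():
        mat = np.stack(vecs)  # (n_stim, n_nodes)
        sd = mat.std(axis=1)
        if np.any(sd == 0):
            bad = ids[np.flatnonzero(sd == 0)].tolist()
            raise ValueError(
                f"layer {name!r} has constant activations for stimuli {bad}; "
                "correlation undefined"
            )
        corr = np.corrcoef(mat)
        values = 1.0 - corr
        np.fill_diagonal(values, 0.0)
        out[name] = RDM(values, ids, "network_layer")
    return out


def correlate_layer_rdms(
    layers: dict[str, RDM],
    reference: RDM,
    method: str = "pearson",
) -> tuple[dict[str, float], str]:
    """Per-layer correlation with a reference RDM and the peak layer.

    Correlations are computed over the off-diagonal upper triangles; the
    peak layer is the argmax, ties broken by the earliest layer in the
    extractor's layer order.
    """
    rhos: dict[str, float] = {}
    ref = reference.triu_vector()
    for name, rdm in layers.items():
        if rdm.n != reference.n or not np.array_equal(rdm.labels, reference.labels):
            raise ValueError(f"layer {name!r} labels do not match the reference RDM")
        v = rdm.triu_vector()
        if method == "pearson":
            rhos[name] = float(np.corrcoef(v, ref)[0, 1])
        elif method == "spearman":
            rhos[name] = float(stats.spearmanr(v, ref).statistic)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
    peak = max(rhos, key=lambda k: (rhos[k], -list(rhos).index(k)))
    return rhos, peak
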