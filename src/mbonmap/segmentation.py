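"""Seed-constrained segmentation of transsynaptic label.

The central denoising step of the tracing pipeline: postsynaptic reporter
signal is trusted only where it is spatially continuous with the presynaptic
terminal field of the driver line.  Both channels are binarized, the
postsynaptic mask is decomposed into connected components (6-, 18- or
26-connectivity), and a component is retained iff it intersects the
presynaptic seed mask dilated by a small tolerance radius that absorbs
channel mis-registration without bridging genuine gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volio import RunConfig, VolumeImage

__all__ = ["SegmentationResult", "binarize", "seeded_components", "segment_brain"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SegmentationResult:
    """Retained postsynaptic mask plus per-component bookkeeping.

    ``components`` has one row per connected component of the *candidate*
    mask with columns (component_id, voxel_count, bbox z0..x1,
    touches_seed); the retained mask is the union of rows with
    touches_seed=True.
    """

    retained_mask: np.ndarray
    components: pd.DataFrame
    threshold_used: float
    connectivity: int
    dilation_radius: int
    seed_threshold_used: float | None = None

    @property
    def n_retained_voxels(self) -> int:
        return int(self.retained_mask.sum())


def binarize(vol: VolumeImage, method: str = "otsu", *,
             threshold: float | None = None,
             quantile: float | None = None) -> tuple[np.ndarray, float]:
    """Threshold one channel; returns (mask, threshold_used).

    method 'fixed' uses ``threshold``; 'quantile' uses the ``quantile``-th
    intensity quantile; 'otsu' maximizes between-class variance.  The mask
    is strictly ``data > threshold``.
    """
    data = np.asarray(vol.data, dtype=float)
    if data.size == 0:
        raise ValueError("empty volume")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method needs threshold=")
        t = float(threshold)
        lo, hi = data.min(), data.max()
        if not lo <= t <= hi:
            raise ValueError(f"threshold {t} outside intensity range [{lo}, {hi}]")
    elif method == "quantile":
        q = 0.99 if quantile is None else float(quantile)
        if not 0.0 <= q <= 1.0:
            raise ValueError("quantile must be in [0, 1]")
        t = float(np.quantile(data, q))
    elif method == "otsu":
        if data.min() == data.max():
            raise ValueError("constant volume: Otsu histogram is degenerate")
        t = float(threshold_otsu(data))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return data > t, t


def seeded_components(
    post_mask: np.ndarray,
    seed_mask: np.ndarray,
    connectivity: int = 26,
    dilation_radius: int = 1,
) -> SegmentationResult:
    """Retain the connected components of ``post_mask`` that touch the
    (dilated) ``seed_mask``.

    Dilation uses the Chebyshev ball (26-neighbourhood iterated), so a
    radius of r accepts components within r voxels of a seed voxel in the
    max-norm.  An empty seed mask retains nothing and warns.
    """
    post_mask = np.asarray(post_mask, dtype=bool)
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if post_mask.shape != seed_mask.shape:
        raise ValueError(
            f"shape mismatch: {post_mask.shape} vs {seed_mask.shape}")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")

    if not seed_mask.any():
        warnings.warn("empty seed mask: nothing retained", stacklevel=2)
        empty = pd.DataFrame(columns=[
            "component_id", "voxel_count", "z0", "y0", "x0", "z1", "y1", "x1",
            "touches_seed"])
        return SegmentationResult(np.zeros_like(post_mask), empty, np.nan,
                                  connectivity, dilation_radius)

    if dilation_radius > 0:
        seed = ndimage.binary_dilation(seed_mask, structure=_STRUCTURES[26],
                                       iterations=dilation_radius)
    else:
        seed = seed_mask

    labels, n = ndimage.label(post_mask, structure=_STRUCTURES[connectivity])
    touched = np.zeros(n + 1, dtype=bool)
    hit = np.unique(labels[seed])
    touched[hit[hit > 0]] = True

    counts = np.bincount(labels.ravel(), minlength=n + 1)
    slices = ndimage.find_objects(labels)
    rows = []
    for cid in range(1, n + 1):
        sl = slices[cid - 1]
        rows.append({
            "component_id": cid,
            "voxel_count": int(counts[cid]),
            "z0": sl[0].start, "y0": sl[1].start, "x0": sl[2].start,
            "z1": sl[0].stop, "y1": sl[1].stop, "x1": sl[2].stop,
            "touches_seed": bool(touched[cid]),
        })
    components = pd.DataFrame(rows, columns=[
        "component_id", "voxel_count", "z0", "y0", "x0", "z1", "y1", "x1",
        "touches_seed"])
    retained = touched[labels]
    return SegmentationResult(retained, components, np.nan, connectivity,
                              dilation_radius)


def segment_brain(
    presynaptic: VolumeImage,
    postsynaptic: VolumeImage,
    config: RunConfig | None = None,
) -> SegmentationResult:
    """Full per-brain segmentation: binarize both channels, then keep
    postsynaptic components continuous with the presynaptic terminals.

    Defaults: presynaptic seed threshold at the 99th intensity percentile
    (terminal fields are sparse and bright), postsynaptic threshold by Otsu,
    26-connectivity, 1-voxel dilation.
    """
    config = config or RunConfig()
    if presynaptic.shape != postsynaptic.shape:
        raise ValueError("channels must be congruent")
    seed_mask, seed_t = binarize(
        presynaptic, config.pre_threshold_method,
        threshold=config.pre_threshold_value
        if config.pre_threshold_method == "fixed" else None,
        quantile=config.pre_threshold_value
        if config.pre_threshold_method == "quantile" else None,
    )
    post_data = np.asarray(postsynaptic.data, dtype=float)
    if post_data.min() == post_data.max():
        # constant channel (e.g. all zero): nothing can be suprathreshold
        post_mask = np.zeros(postsynaptic.shape, dtype=bool)
        post_t = float(post_data.max())
    else:
        post_mask, post_t = binarize(
            postsynaptic, config.post_threshold_method,
            threshold=config.post_threshold_value,
            quantile=config.post_threshold_value
            if config.post_threshold_method == "quantile" else None,
        )
    result = seeded_components(post_mask, seed_mask,
                               connectivity=config.connectivity,
                               dilation_radius=config.dilation_radius)
    result.threshold_used = post_t
    result.seed_threshold_used = seed_t
    return result
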