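"""Two-channel co-localized soma counting.

Automates the blinded manual count of dopaminergic (TH⁺) somata that overlap
postsynaptic trans-Tango label: somata are detected per channel as local
maxima of a smoothed volume, restricted to one hemibrain and to the region
anterior to a stop coordinate (the protocerebral anterior lateral cluster
landmark, supplied as a coordinate because the landmark itself was
identified morphologically), and counted as co-localized via a maximum
one-to-one matching under a distance cap.  Counts per hemibrain are
summarized as mean ± SEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from skimage.feature import peak_local_max

from .volio import VolumeImage

__all__ = [
    "CellSet",
    "ColocSummary",
    "detect_somata",
    "filter_counting_window",
    "count_colocalized",
    "mean_sem",
    "summarize_counts",
]


@dataclass
class CellSet:
    channel: str                      # e.g. "TH" or "tango"
    centroids: np.ndarray             # (n, 3) voxel coords, (z, y, x)
    intensities: np.ndarray           # peak intensity per detection
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        if len(self.centroids) != len(self.intensities):
            raise ValueError("centroids and intensities differ in length")

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class ColocSummary:
    per_hemibrain_counts: list[int]
    mean: float
    sem: float                        # NaN when n = 1 (undefined, not 0)
    n: int


def detect_somata(
    vol: VolumeImage,
    expected_radius: float = 3.0,
    threshold: float | None = None,
    min_separation: float | None = None,
    channel: str = "",
) -> CellSet:
    """Local-maximum soma detection on a Gaussian-smoothed volume.

    Peaks below ``threshold`` (default: half the smoothed maximum) are
    dropped; maxima closer than ``min_separation`` (default: the expected
    radius) are merged to the brighter peak.
    """
    if expected_radius < 1:
        raise ValueError("expected_radius must be >= 1 voxel")
    if min_separation is None:
        min_separation = expected_radius
    data = np.asarray(vol.data, dtype=float)
    smoothed = gaussian_filter(data, sigma=expected_radius / 2.0)
    if threshold is None:
        threshold = 0.5 * float(smoothed.max())
    if smoothed.max() <= 0 or threshold <= 0:
        return CellSet(channel=channel, centroids=np.empty((0, 3)),
                       intensities=np.empty(0),
                       settings={"expected_radius": expected_radius,
                                 "threshold": threshold,
                                 "min_separation": min_separation})
    peaks = peak_local_max(
        smoothed,
        min_distance=max(1, int(math.ceil(min_separation))),
        threshold_abs=threshold,
        exclude_border=False,
    )
    intensities = smoothed[tuple(peaks.T)] if len(peaks) else np.empty(0)
    order = np.argsort(-intensities)
    return CellSet(
        channel=channel,
        centroids=peaks[order].astype(float),
        intensities=intensities[order],
        settings={"expected_radius": expected_radius, "threshold": threshold,
                  "min_separation": min_separation},
    )


def filter_counting_window(
    cells: CellSet,
    midline_x: float,
    side: str = "left",
    anterior_stop_z: float | None = None,
) -> CellSet:
    """Restrict detections to one hemibrain, anterior to the stop plane.

    Convention: anterior→posterior is increasing z; cells with
    z < ``anterior_stop_z`` are kept (the count stops at the PAL cluster).
    ``side`` 'left' keeps x < midline_x, 'right' keeps x >= midline_x.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if len(cells) == 0:
        return replace(cells)
    x = cells.centroids[:, 2]
    keep = x < midline_x if side == "left" else x >= midline_x
    if anterior_stop_z is not None:
        keep &= cells.centroids[:, 0] < anterior_stop_z
    return CellSet(channel=cells.channel, centroids=cells.centroids[keep],
                   intensities=cells.intensities[keep],
                   settings={**cells.settings, "midline_x": midline_x,
                             "side": side, "anterior_stop_z": anterior_stop_z})


def count_colocalized(th: CellSet, tango: CellSet, max_distance: float) -> int:
    """Size of a maximum one-to-one matching between the two centroid sets
    with pair distance <= ``max_distance``.

    One-to-one matching (rather than "any overlap") prevents a single
    bright soma in one channel from absorbing several cells of the other.
    Symmetric in its arguments and monotone in ``max_distance``.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    a, b = th.centroids, tango.centroids
    if len(a) == 0 or len(b) == 0:
        return 0
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    adj = csr_matrix((d <= max_distance).astype(np.int8))
    match = maximum_bipartite_matching(adj, perm_type="column")
    return int((match >= 0).sum())


def mean_sem(counts: list[float]) -> tuple[float, float]:
    """Mean and standard error; SEM is NaN (undefined) for n = 1."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one count")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else math.nan
    return mean, sem


def summarize_counts(per_hemibrain_counts: list[int]) -> ColocSummary:
    mean, sem = mean_sem(per_hemibrain_counts)
    return ColocSummary(per_hemibrain_counts=list(per_hemibrain_counts),
                        mean=mean, sem=sem, n=len(per_hemibrain_counts))
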