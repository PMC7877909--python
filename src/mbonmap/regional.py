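"""Regional distribution of retained postsynaptic signal.

Retained voxels are tallied against the labelled neuropil atlas (the source
analysis multiplies the segmented mask by 34 binary region masks), each
brain is normalized to a Z-score profile across its regions, per-line
profiles are assembled into a line × region heatmap matrix, and laminar /
LAL prevalence maps report, per stratum, the percentage of brains carrying
suprathreshold signal.

The Z-score is computed *within* one brain, across its regions:

    z_r = (s_r − mean_r' s_r') / sd_r' s_r'        (sample sd, n−1)

so a profile always has mean 0 and sample sd 1 and is invariant under a
positive rescaling of all sums (expression level) or addition of a common
constant.  The across-brain alternative (normalizing each region over
brains) is available via :func:`zscore_across_brains`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import SegmentationResult
from .volio import LabelAtlas

__all__ = [
    "RegionSignal",
    "RegionZProfile",
    "PrevalenceMap",
    "regional_signal",
    "zscore_profile",
    "zscore_across_brains",
    "assemble_heatmap",
    "laminar_prevalence",
    "render_heatmap",
]


@dataclass
class RegionSignal:
    brain_id: str
    line_id: str
    sums: dict[int, float]          # region id -> retained count / intensity sum
    outside_atlas: float = 0.0      # retained voxels with label 0
    mode: str = "count"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.sums.values()):
            raise ValueError("regional sums must be non-negative")


@dataclass
class RegionZProfile:
    brain_id: str
    line_id: str
    z: dict[int, float]             # region id -> Z-score within this brain


@dataclass
class PrevalenceMap:
    line_id: str
    percent: dict[str, float]       # stratum -> % of brains positive
    n_brains: int
    positivity_threshold: float     # voxels; mandatory provenance

    def __post_init__(self) -> None:
        if self.n_brains < 1:
            raise ValueError("need at least one brain")
        for k, v in self.percent.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"stratum {k!r}: percentage {v} outside [0, 100]")


def regional_signal(
    seg: SegmentationResult,
    atlas: LabelAtlas,
    mode: str = "count",
    intensity: np.ndarray | None = None,
    brain_id: str = "",
    line_id: str = "",
) -> RegionSignal:
    """Per-region totals of retained signal.

    mode 'count' tallies retained voxels per region label (the default: a
    binary segmented mask carries no meaningful intensity); 'intensity' sums
    the supplied intensity volume over retained voxels.  Voxels outside the
    atlas (label 0) are reported separately, never silently dropped.
    """
    mask = np.asarray(seg.retained_mask, dtype=bool)
    if mask.shape != atlas.labels.shape:
        raise ValueError("segmentation and atlas shapes differ")
    labels = atlas.labels[mask]
    if mode == "count":
        weights = None
    elif mode == "intensity":
        if intensity is None:
            raise ValueError("mode='intensity' needs the intensity volume")
        intensity = np.asarray(intensity, dtype=float)
        if intensity.shape != mask.shape:
            raise ValueError("intensity volume shape differs")
        weights = intensity[mask]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    max_label = int(atlas.labels.max())
    tall = np.bincount(labels.ravel(), weights=weights, minlength=max_label + 1)
    sums = {rid: float(tall[rid]) if rid <= max_label else 0.0
            for rid in atlas.region_ids}
    return RegionSignal(brain_id=brain_id, line_id=line_id, sums=sums,
                        outside_atlas=float(tall[0]), mode=mode)


def zscore_profile(rs: RegionSignal) -> RegionZProfile:
    """Within-brain Z-score across regions (sample sd, denominator n−1)."""
    rids = list(rs.sums)
    values = np.array([rs.sums[r] for r in rids], dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 regions")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "all regional sums equal: Z-score scale is degenerate")
    z = (values - values.mean()) / sd
    return RegionZProfile(brain_id=rs.brain_id, line_id=rs.line_id,
                          z={r: float(v) for r, v in zip(rids, z)})


def zscore_across_brains(signals: list[RegionSignal]) -> pd.DataFrame:
    """Alternative axis: normalize each region across brains.

    Returns a brain × region frame of Z-scores; regions with zero variance
    across brains are NaN.
    """
    if not signals:
        raise ValueError("no signals")
    df = pd.DataFrame([s.sums for s in signals],
                      index=[s.brain_id for s in signals])
    sd = df.std(ddof=1)
    out = (df - df.mean()) / sd
    out[sd.index[sd == 0]] = np.nan
    return out


def assemble_heatmap(
    profiles: list[RegionZProfile],
    region_order: list[int] | None = None,
) -> pd.DataFrame:
    """Line × region matrix of mean Z (brains of one line averaged).

    Line/region combinations with no contributing brain are NaN gaps, not
    zeros.  ``region_order`` defaults to the shared region-id order of the
    profiles (the atlas's anterior→posterior listing).
    """
    if not profiles:
        raise ValueError("no profiles")
    region_sets = {frozenset(p.z) for p in profiles}
    if len(region_sets) != 1:
        raise ValueError("profiles carry inconsistent region sets")
    if region_order is None:
        region_order = list(profiles[0].z)
    elif set(region_order) != set(profiles[0].z):
        raise ValueError("region_order does not match the profiles' regions")
    long = pd.DataFrame(
        [{"line_id": p.line_id, "region": r, "z": v}
         for p in profiles for r, v in p.z.items()])
    mat = long.pivot_table(index="line_id", columns="region", values="z",
                           aggfunc="mean")
    lines_in_order = list(dict.fromkeys(p.line_id for p in profiles))
    return mat.reindex(index=lines_in_order, columns=region_order)


def laminar_prevalence(
    per_brain: list[tuple[str, dict[str, float]]],
    positivity_threshold: float = 10.0,
    line_id: str = "",
) -> PrevalenceMap:
    """Percentage of brains with suprathreshold signal per stratum.

    ``per_brain`` holds (brain_id, stratum -> retained voxel count); strata
    must be consistent across brains.  A brain is positive in a stratum when
    its count is >= ``positivity_threshold`` voxels.
    """
    if not per_brain:
        raise ValueError("no brains")
    strata = list(per_brain[0][1])
    for bid, counts in per_brain:
        if set(counts) != set(strata):
            raise ValueError(f"brain {bid!r}: inconsistent strata")
    n = len(per_brain)
    percent = {
        s: 100.0 * sum(counts[s] >= positivity_threshold
                       for _, counts in per_brain) / n
        for s in strata
    }
    return PrevalenceMap(line_id=line_id, percent=percent, n_brains=n,
                         positivity_threshold=positivity_threshold)


def render_heatmap(matrix: pd.DataFrame, path=None, atlas: LabelAtlas | None = None):
    """Render the Z heatmap (diverging scale symmetric about 0).

    The matrix is the tested artifact; rendering is a side effect only.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(np.nanmax(np.abs(matrix.values))) or 1.0
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * matrix.shape[1]),
                                    max(3, 0.35 * matrix.shape[0])))
    im = ax.imshow(matrix.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    if atlas is not None:
        abbr = dict(zip(atlas.region_table["id"], atlas.region_table["abbreviation"]))
        ax.set_xticks(range(matrix.shape[1]),
                      [abbr.get(c, str(c)) for c in matrix.columns],
                      rotation=90, fontsize=6)
    else:
        ax.set_xticks(range(matrix.shape[1]),
                      [str(c) for c in matrix.columns], rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Z-score (within brain)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
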