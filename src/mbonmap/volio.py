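"""Volume containers and file I/O.

Registered confocal channels are represented as :class:`VolumeImage` (a 3D
scalar grid in ``(z, y, x)`` index order with per-axis spacing in micrometres)
and neuropil parcellations as :class:`LabelAtlas` (an integer label grid plus
a region table).  Volumes are stored on disk as NRRD (attached header, raw
encoding) or multi-page grayscale TIFF; tables as CSV.

The NRRD codec here is deliberately minimal: attached headers only, raw or
gzip encoding, little-endian scalar types.  Detached-header files
(``data file:`` field) are rejected.
"""

from __future__ import annotations

import gzip as _gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "VolumeImage",
    "LabelAtlas",
    "RunConfig",
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
]


@dataclass
class VolumeImage:
    """One fluorescence channel: 3D grid, (z, y, x) order, spacing in µm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive numbers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelAtlas:
    """Integer label grid plus region table (id, abbreviation, name).

    Every nonzero label present in the grid must appear in the region table
    exactly once; abbreviations are unique.  Label 0 is "outside atlas".
    """

    labels: np.ndarray
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer")
        if (self.labels < 0).any():
            raise ValueError("atlas labels must be non-negative")
        required = {"id", "abbreviation", "name"}
        if not required.issubset(self.region_table.columns):
            raise ValueError(f"region table needs columns {sorted(required)}")
        ids = self.region_table["id"]
        if ids.duplicated().any() or (ids <= 0).any():
            raise ValueError("region ids must be unique positive integers")
        if self.region_table["abbreviation"].duplicated().any():
            raise ValueError("region abbreviations must be unique")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(int(i) for i in ids)
        if missing:
            raise ValueError(f"labels present in grid but not in table: {sorted(missing)}")

    @property
    def region_ids(self) -> list[int]:
        return [int(i) for i in self.region_table["id"]]

    def mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id


@dataclass
class RunConfig:
    """Pipeline settings; round-trips losslessly through YAML."""

    pre_threshold_method: str = "quantile"
    pre_threshold_value: float = 0.99
    post_threshold_method: str = "otsu"
    post_threshold_value: float | None = None
    connectivity: int = 26
    dilation_radius: int = 1
    n_fsb_layers: int = 9
    activity_bin_width_s: float = 10.0
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be >= 0")
        if self.n_fsb_layers < 1:
            raise ValueError("n_fsb_layers must be >= 1")
        if self.activity_bin_width_s <= 0:
            raise ValueError("activity_bin_width_s must be > 0")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.__dict__, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def manifest(self, **extra) -> str:
        """JSON run manifest (config + free-form provenance entries)."""
        doc = {"config": self.__dict__, **extra}
        return json.dumps(doc, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# NRRD codec (attached header, raw/gzip encoding)

_NRRD_TYPES = {
    "uint8": np.uint8, "uchar": np.uint8,
    "uint16": np.uint16, "ushort": np.uint16,
    "int16": np.int16, "short": np.int16,
    "int32": np.int32, "int": np.int32,
    "uint32": np.uint32, "uint": np.uint32,
    "int64": np.int64, "uint64": np.uint64,
    "float": np.float32, "float32": np.float32,
    "double": np.float64, "float64": np.float64,
}
_NP_TO_NRRD = {
    np.dtype(np.uint8): "uint8", np.dtype(np.uint16): "uint16",
    np.dtype(np.int16): "int16", np.dtype(np.int32): "int32",
    np.dtype(np.uint32): "uint32", np.dtype(np.int64): "int64",
    np.dtype(np.uint64): "uint64", np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}


def _write_nrrd(vol: VolumeImage, path: Path) -> None:
    data = np.ascontiguousarray(vol.data)
    if data.dtype not in _NP_TO_NRRD:
        data = data.astype(np.float32)
    # NRRD sizes are fastest-axis-first; our memory order is (z, y, x) C-order,
    # so x varies fastest.
    sizes = " ".join(str(s) for s in data.shape[::-1])
    spacings = " ".join(repr(s) for s in vol.spacing[::-1])
    header = (
        "NRRD0004\n"
        f"# channel: {vol.channel_name}\n"
        f"type: {_NP_TO_NRRD[data.dtype]}\n"
        "dimension: 3\n"
        f"sizes: {sizes}\n"
        f"spacings: {spacings}\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(data.astype(data.dtype.newbyteorder("<"), copy=False).tobytes())


def _read_nrrd(path: Path) -> VolumeImage:
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.find(b"\n\n")
    if not raw.startswith(b"NRRD") or end < 0:
        raise ValueError(f"{path}: not an attached-header NRRD file")
    fields: dict[str, str] = {}
    channel = ""
    for line in raw[: end].decode("ascii", "replace").splitlines()[1:]:
        if line.startswith("# channel:"):
            channel = line.split(":", 1)[1].strip()
        if line.startswith("#") or ":" not in line:
            continue
        key, val = line.split(":", 1)
        fields[key.strip().lower()] = val.strip()
    if "data file" in fields or "datafile" in fields:
        raise ValueError(f"{path}: detached-header NRRD is not supported")
    if int(fields.get("dimension", 0)) != 3:
        raise ValueError(f"{path}: expected a 3D volume")
    dtype = _NRRD_TYPES.get(fields.get("type", ""))
    if dtype is None:
        raise ValueError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    sizes = [int(t) for t in fields["sizes"].split()]
    encoding = fields.get("encoding", "raw").lower()
    payload = raw[end + 2:]
    if encoding in ("gzip", "gz"):
        payload = _gzip.decompress(payload)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported encoding {encoding!r}")
    if fields.get("endian", "little") != "little":
        raise ValueError(f"{path}: only little-endian NRRD is supported")
    data = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<"))
    # sizes are fastest-first -> reverse to (z, y, x)
    shape = tuple(sizes[::-1])
    data = data[: int(np.prod(shape))].reshape(shape)
    spacing = (1.0, 1.0, 1.0)
    if "spacings" in fields:
        sp = [float(t) for t in re.split(r"[\s,]+", fields["spacings"]) if t]
        spacing = tuple(sp[::-1])
    return VolumeImage(data=data.copy(), spacing=spacing, channel_name=channel)


# ---------------------------------------------------------------------------
# TIFF

def _write_tiff(vol: VolumeImage, path: Path) -> None:
    zs, ys, xs = vol.spacing
    tifffile.imwrite(
        path,
        np.asarray(vol.data),
        imagej=True,
        resolution=(1.0 / xs, 1.0 / ys),
        metadata={"spacing": zs, "unit": "um", "axes": "ZYX",
                  "channel_name": vol.channel_name},
    )


def _read_tiff(path: Path) -> VolumeImage:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.imagej_metadata or {}
        page = tf.pages[0]
        zs = float(meta.get("spacing", 1.0))
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        xs = xres.value[1] / xres.value[0] if xres else 1.0
        ys = yres.value[1] / yres.value[0] if yres else 1.0
        channel = str(meta.get("channel_name", ""))
    if data.ndim == 2:
        raise ValueError(f"{path}: 2D image, expected a 3-D stack")
    return VolumeImage(data=data, spacing=(zs, ys, xs), channel_name=channel)


def write_volume(vol: VolumeImage, path: str | Path) -> Path:
    """Write a volume; format chosen by extension (.nrrd, .tif/.tiff)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".nrrd":
        _write_nrrd(vol, path)
    elif suffix in (".tif", ".tiff"):
        _write_tiff(vol, path)
    else:
        raise ValueError(f"unsupported volume format: {suffix!r}")
    return path


def read_volume(path: str | Path) -> VolumeImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".nrrd":
        return _read_nrrd(path)
    if suffix in (".tif", ".tiff"):
        return _read_tiff(path)
    raise ValueError(f"unsupported volume format: {suffix!r}")


def write_atlas(atlas: LabelAtlas, volume_path: str | Path,
                table_path: str | Path) -> tuple[Path, Path]:
    vp = write_volume(
        VolumeImage(atlas.labels.astype(np.int32), channel_name="atlas"),
        volume_path,
    )
    tp = Path(table_path)
    atlas.region_table.to_csv(tp, index=False)
    return vp, tp


def read_atlas(volume_path: str | Path, table_path: str | Path) -> LabelAtlas:
    vol = read_volume(volume_path)
    table = pd.read_csv(table_path)
    return LabelAtlas(labels=vol.data.astype(np.int64), region_table=table)
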