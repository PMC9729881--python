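"""Data interchange: canonical CSV tables, ImageJ point ROIs, run configs.

The canonical annotation format is a plain CSV with columns
``section_id, group, mark, x_um, y_um`` and the observation window declared
in ``# key=value`` comment lines at the top of the file.  ImageJ point-ROI
files (single ``.roi`` or a ``.zip`` ROI set, the format FIJI saves point
annotations in) can be imported as a convenience; coordinates are scaled
from pixels to µm by a mandatory scale factor and the y-axis flipped from
ImageJ's y-down convention when the image height is supplied.
"""

from __future__ import annotations

import io as _io
import struct
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .nuclei import FEATURE_NAMES, NucleusRecord
from .patterns import MarkedPointPattern, Window

__all__ = [
    "write_points_csv",
    "read_points_csv",
    "write_nuclei_csv",
    "read_nuclei_csv",
    "read_imagej_points",
    "write_imagej_points",
    "RunConfig",
    "load_run_config",
]

POINT_COLUMNS = ["section_id", "group", "mark", "x_um", "y_um"]


# ---------------------------------------------------------------------------
# canonical CSV


def write_points_csv(patterns, path) -> None:
    """Write one or more patterns (sharing a window) to the canonical CSV."""
    if isinstance(patterns, MarkedPointPattern):
        patterns = [patterns]
    w = patterns[0].window
    rows = []
    for p in patterns:
        for (x, y), m in zip(p.points, p.marks):
            rows.append((p.section_id, p.group, m, x, y))
    df = pd.DataFrame(rows, columns=POINT_COLUMNS)
    with open(path, "w") as fh:
        for key, val in (
            ("window_x_min", w.x_min),
            ("window_x_max", w.x_max),
            ("window_y_min", w.y_min),
            ("window_y_max", w.y_max),
        ):
            fh.write(f"# {key}={val!r}\n")
        df.to_csv(fh, index=False)


def read_points_csv(path, margin: float = 0.0) -> list[MarkedPointPattern]:
    """Read the canonical point CSV back into one pattern per section.

    If no window header is present the window is the joint bounding box of
    all points expanded by ``margin`` µm on every side.
    """
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
        fh.seek(pos)
        df = pd.read_csv(fh)
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"point CSV missing columns: {missing}")
    if {"window_x_min", "window_x_max", "window_y_min", "window_y_max"} <= meta.keys():
        window = Window(
            meta["window_x_min"],
            meta["window_x_max"],
            meta["window_y_min"],
            meta["window_y_max"],
        )
    else:
        window = Window(
            df.x_um.min() - margin,
            df.x_um.max() + margin,
            df.y_um.min() - margin,
            df.y_um.max() + margin,
        )
    out = []
    for sid, sub in df.groupby("section_id", sort=False):
        out.append(
            MarkedPointPattern(
                points=sub[["x_um", "y_um"]].to_numpy(),
                marks=sub["mark"].to_numpy(dtype=object),
                window=window,
                section_id=str(sid),
                group=str(sub["group"].iloc[0]),
            )
        )
    return out


NUCLEUS_COLUMNS = ["id", "x", "y", *FEATURE_NAMES, "true_class", "predicted_class"]


def write_nuclei_csv(records, path) -> None:
    rows = [
        {c: getattr(r, c) for c in NUCLEUS_COLUMNS}
        for r in records
    ]
    pd.DataFrame(rows, columns=NUCLEUS_COLUMNS).to_csv(path, index=False)


def read_nuclei_csv(path) -> list[NucleusRecord]:
    df = pd.read_csv(path)
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        pred = d.get("predicted_class")
        if pred is not None and (isinstance(pred, float) and np.isnan(pred)):
            d["predicted_class"] = None
        d["id"] = int(d["id"])
        d["touching_count"] = int(d["touching_count"])
        recs.append(NucleusRecord(**d))
    return recs


# ---------------------------------------------------------------------------
# ImageJ point ROIs (binary "Iout" format)

_ROI_MAGIC = b"Iout"
_ROI_TYPE_POINT = 10
_OPT_SUBPIXEL = 128


def _decode_roi(buf: bytes, name: str):
    if buf[:4] != _ROI_MAGIC:
        raise ValueError(f"{name}: not an ImageJ ROI (bad magic {buf[:4]!r})")
    roi_type = buf[6]
    if roi_type != _ROI_TYPE_POINT:
        return None  # caller warns and skips
    top, left, bottom, right, n = struct.unpack(">5h", buf[8:18])
    options = struct.unpack(">h", buf[50:52])[0]
    xs_i = np.frombuffer(buf, dtype=">i2", count=n, offset=64).astype(float) + left
    ys_i = np.frombuffer(buf, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    if options & _OPT_SUBPIXEL and len(buf) >= 64 + 4 * n + 8 * n:
        xs = np.frombuffer(buf, dtype=">f4", count=n, offset=64 + 4 * n).astype(float)
        ys = np.frombuffer(buf, dtype=">f4", count=n, offset=64 + 8 * n).astype(float)
    else:
        xs, ys = xs_i, ys_i
    return xs, ys


def read_imagej_points(
    path,
    scale_um_per_px: float,
    image_height_px: float | None = None,
) -> list[tuple[str, np.ndarray]]:
    """Point coordinates from an ImageJ ``.roi`` file or ``.zip`` ROI set.

    Returns ``[(name, (n, 2) array in µm), ...]`` preserving file order.
    Pixel coordinates are multiplied by ``scale_um_per_px``; when
    ``image_height_px`` is given the y-axis is flipped so that y increases
    upward (ImageJ stores y downward from the top-left corner).  Non-point
    ROIs are skipped with a warning; a corrupt magic number is an error.
    """
    import warnings

    path = Path(path)
    entries: list[tuple[str, bytes]] = []
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for name in zf.namelist():
                entries.append((Path(name).stem, zf.read(name)))
    else:
        entries.append((path.stem, path.read_bytes()))
    out = []
    for name, buf in entries:
        decoded = _decode_roi(buf, name)
        if decoded is None:
            warnings.warn(f"{name}: not a point ROI, skipped", stacklevel=2)
            continue
        xs, ys = decoded
        if image_height_px is not None:
            ys = image_height_px - ys
        out.append((name, np.column_stack([xs, ys]) * scale_um_per_px))
    return out


def write_imagej_points(xy_px: np.ndarray, path) -> None:
    """Write pixel coordinates as a sub-pixel ImageJ point ROI file."""
    xy = np.asarray(xy_px, dtype=float).reshape(-1, 2)
    n = len(xy)
    left, top = int(np.floor(xy[:, 0].min())), int(np.floor(xy[:, 1].min()))
    right, bottom = int(np.ceil(xy[:, 0].max())), int(np.ceil(xy[:, 1].max()))
    header = bytearray(64)
    header[:4] = _ROI_MAGIC
    struct.pack_into(">h", header, 4, 227)  # version
    header[6] = _ROI_TYPE_POINT
    struct.pack_into(">5h", header, 8, top, left, bottom, right, n)
    struct.pack_into(">h", header, 50, _OPT_SUBPIXEL)
    body = _io.BytesIO()
    body.write(bytes(header))
    body.write((xy[:, 0] - left).astype(">i2").tobytes())
    body.write((xy[:, 1] - top).astype(">i2").tobytes())
    body.write(xy[:, 0].astype(">f4").tobytes())
    body.write(xy[:, 1].astype(">f4").tobytes())
    Path(path).write_bytes(body.getvalue())


# ---------------------------------------------------------------------------
# run configuration


class LatticeSection(BaseModel):
    """Synthetic vascular sections for one group."""

    group: str
    n_sections: int = 4
    lattice_radius_r0: float = 100.0
    jitter_sd: float = 8.0
    portal_occupancy: str = "three_alternate"
    occupancy_fraction: float = 0.5
    window_width: float = 2000.0
    window_height: float = 2000.0


class SpatialConfig(BaseModel):
    correction: str = "isotropic"
    n_r: int = 128
    n_permutations: int = 999


class LobuleConfig(BaseModel):
    k_max: int = 6
    exclude_boundary: bool = False


class ClassifyConfig(BaseModel):
    n_hepatocyte: int = 1100
    n_binuclear: int = 60
    n_other: int = 700
    max_depth: int = 7
    min_samples_per_leaf: int = 1
    cv_folds: int = 5
    train_fraction: float = 0.70
    touching_distance: float = 12.0


class RunConfig(BaseModel):
    """Validated parameters for the end-to-end pipeline."""

    seed: int
    out_dir: str
    groups: list[LatticeSection] = Field(min_length=2)
    spatial: SpatialConfig = SpatialConfig()
    lobule: LobuleConfig = LobuleConfig()
    classify: ClassifyConfig = ClassifyConfig()


def load_run_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration.

    Validation errors name the offending field (pydantic semantics).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)
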