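"""Image and lineage file IO.

Images are plain TIFF: one multi-page 3D stack per time step, addressed by a
filename pattern containing a ``{t}`` field (and optionally ``{z}`` for
per-section series).  Intensities are read as floating point without any
rescaling; detection thresholds downstream are either absolute or fractions
of the per-frame maximum, never dependent on a load-time normalization.

Lineages are stored as plain CSV, one row per centre::

    id,t,x,y,z,mother_id,virtual

with ``mother_id = -1`` for roots and positions in physical µm written with
six decimal digits (the documented round-trip precision).  Gold-standard
files use the identical schema plus an optional ``curated`` column.
"""

from __future__ import annotations

import glob
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .model import Centre, Channel, LineageForest, TimeLapseDataset, VoxelGrid

__all__ = [
    "read_timelapse",
    "write_timelapse",
    "read_lineage",
    "write_lineage",
    "write_mask",
]

_POS_DECIMALS = 6


def _resolve_pattern(pattern: str, field: str) -> list[tuple[int, str]]:
    """Expand a ``{t}``-style pattern into sorted ``(index, path)`` pairs."""
    glob_pat = pattern.replace("{%s}" % field, "*")
    rx = re.compile(
        re.escape(pattern).replace(re.escape("{%s}" % field), r"(\d+)") + r"$"
    )
    out = []
    for path in glob.glob(glob_pat):
        m = rx.match(path)
        if m:
            out.append((int(m.group(1)), path))
    out.sort()
    return out


def read_timelapse(
    patterns: dict | str,
    spacing: tuple[float, float, float],
    dt_seconds: float,
) -> TimeLapseDataset:
    """Read a 3D+time dataset from per-timestep TIFF stacks.

    Parameters
    ----------
    patterns : str or dict
        Filename pattern with a ``{t}`` field, e.g. ``"frames/t{t}.tif"``;
        a bare string is taken as the nuclei channel, a dict maps channel
        names (``"nuclei"``, ``"membranes"``) to patterns.
    spacing : tuple
        ``(sz, sy, sx)`` voxel size in µm.
    dt_seconds : float
        Frame interval in seconds.
    """
    if isinstance(patterns, str):
        patterns = {Channel.NUCLEI: patterns}
    patterns = {Channel(k): v for k, v in patterns.items()}

    per_channel: dict[Channel, list[tuple[int, str]]] = {}
    for channel, pattern in patterns.items():
        found = _resolve_pattern(pattern, "t")
        if not found:
            raise FileNotFoundError(f"pattern {pattern!r} matched no files")
        indices = [t for t, _ in found]
        expected = list(range(indices[0], indices[0] + len(indices)))
        if indices != expected:
            missing = sorted(set(expected) - set(indices))[:1]
            gap = missing[0] if missing else indices[0]
            raise FileNotFoundError(
                f"pattern {pattern!r}: missing frame index {gap} "
                f"(found indices {indices[0]}..{indices[-1]})"
            )
        per_channel[channel] = found

    n = {ch: len(v) for ch, v in per_channel.items()}
    if len(set(n.values())) > 1:
        raise ValueError(f"channels have different frame counts: {n}")

    frames: list[dict[Channel, VoxelGrid]] = []
    shape_ref: tuple | None = None
    for t in range(next(iter(n.values()))):
        group = {}
        for channel, found in per_channel.items():
            values = np.asarray(tifffile.imread(found[t][1]), dtype=np.float64)
            if values.ndim == 2:
                values = values[None]
            if shape_ref is None:
                shape_ref = values.shape
            elif values.shape != shape_ref:
                raise ValueError(
                    f"frame {t} ({found[t][1]}): shape {values.shape} != {shape_ref}"
                )
            group[channel] = VoxelGrid(values, spacing=spacing, t=t, channel=channel)
        frames.append(group)
    return TimeLapseDataset(frames=frames, dt_seconds=dt_seconds)


def write_timelapse(dataset: TimeLapseDataset, out_dir, prefix: str = "frame"):
    """Write one multi-page TIFF per frame and channel; returns the patterns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patterns = {}
    for channel in dataset.frames[0]:
        pattern = str(out_dir / f"{prefix}_{channel.value}_t{{t}}.tif")
        for t, group in enumerate(dataset.frames):
            tifffile.imwrite(
                pattern.replace("{t}", f"{t:04d}"),
                group[channel].values.astype(np.float32),
                photometric="minisblack",
            )
        patterns[channel.value] = pattern
    return patterns


def write_lineage(forest: LineageForest, path, extra_columns: dict | None = None):
    """Serialize a lineage forest to CSV (see module docstring for schema)."""
    forest.validate()
    rows = []
    for c in sorted(forest.centres.values(), key=lambda c: (c.t, c.id)):
        m = forest.mother(c.id)
        rows.append(
            {
                "id": c.id,
                "t": c.t,
                "x": round(c.pos[0], _POS_DECIMALS),
                "y": round(c.pos[1], _POS_DECIMALS),
                "z": round(c.pos[2], _POS_DECIMALS),
                "mother_id": -1 if m is None else m,
                "virtual": int(c.virtual),
            }
        )
    df = pd.DataFrame(
        rows, columns=["id", "t", "x", "y", "z", "mother_id", "virtual"]
    )
    if extra_columns:
        for name, mapping in extra_columns.items():
            df[name] = [mapping.get(i, "") for i in df["id"]]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_lineage(path) -> LineageForest:
    """Read a lineage CSV back into a :class:`LineageForest` (exact inverse)."""
    df = pd.read_csv(path)
    required = {"id", "t", "x", "y", "z", "mother_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    if df["id"].duplicated().any():
        dup = int(df["id"][df["id"].duplicated()].iloc[0])
        raise ValueError(f"{path}: duplicate centre id {dup}")
    forest = LineageForest()
    for row in df.itertuples(index=False):
        forest.add_centre(
            Centre(
                id=int(row.id),
                t=int(row.t),
                pos=(float(row.x), float(row.y), float(row.z)),
                virtual=bool(getattr(row, "virtual", 0)),
            )
        )
    known = set(forest.centres)
    for row in df.itertuples(index=False):
        m = int(row.mother_id)
        if m == -1:
            continue
        if m not in known:
            raise ValueError(f"{path}: row id={int(row.id)} references unknown mother_id {m}")
        forest.add_link(m, int(row.id))
    return forest


def write_mask(mask: np.ndarray, path):
    """Write a binary/label mask as an 8-bit TIFF stack."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(mask).astype(np.uint8))
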