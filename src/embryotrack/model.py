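"""Core domain types shared by every reconstruction stage.

Conventions
-----------
* Image arrays are indexed ``(z, y, x)``, 0-based.
* Physical positions are ``(x, y, z)`` in micrometres, using the
  centre-of-voxel convention: the physical position of voxel index ``i``
  along an axis with spacing ``s`` is ``(i + 0.5) * s``.
* All inter-centre distances are computed in physical micrometres, so
  anisotropic voxel sizes are handled uniformly across modules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Channel",
    "VoxelGrid",
    "TimeLapseDataset",
    "Centre",
    "CentreSet",
    "LineageForest",
    "LineageError",
    "to_physical",
    "to_index",
]


class LineageError(ValueError):
    """Raised when a lineage forest violates its structural invariants."""


class Channel(str, enum.Enum):
    NUCLEI = "nuclei"
    MEMBRANES = "membranes"


def to_physical(index, spacing):
    """Map a ``(z, y, x)`` voxel index to an ``(x, y, z)`` position in µm.

    Uses the centre-of-voxel convention ``physical = (index + 0.5) * spacing``.
    Accepts a single index triple or an ``(n, 3)`` array of them.
    """
    idx = np.asarray(index, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    phys_zyx = (idx + 0.5) * sp
    return phys_zyx[..., ::-1]


def to_index(pos, spacing):
    """Inverse of :func:`to_physical`: ``(x, y, z)`` µm to nearest ``(z, y, x)`` index."""
    p = np.asarray(pos, dtype=float)[..., ::-1]
    sp = np.asarray(spacing, dtype=float)
    return np.floor(p / sp).astype(int)


@dataclass
class VoxelGrid:
    """One 3D scalar intensity field at a single time step.

    Parameters
    ----------
    values : ndarray
        3D array indexed ``(z, y, x)``; arbitrary nonnegative intensity units.
    spacing : tuple of float
        ``(sz, sy, sx)`` voxel size in µm; all components positive.
    t : int
        Time index, ≥ 0.
    channel : Channel
        Which fluorescence channel the grid holds.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    t: int = 0
    channel: Channel = Channel.NUCLEI

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")
        if self.t < 0:
            raise ValueError("time index must be >= 0")
        self.channel = Channel(self.channel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def physical_size(self) -> np.ndarray:
        """Box extent as ``(x, y, z)`` µm."""
        return (np.array(self.shape, dtype=float) * self.spacing)[::-1]

    def require_pde_size(self):
        if min(self.shape) < 3:
            raise ValueError(
                f"PDE operations need >= 3 voxels per axis, got shape {self.shape}"
            )

    def copy_with(self, values: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(values=values, spacing=self.spacing, t=self.t, channel=self.channel)


@dataclass
class TimeLapseDataset:
    """Ordered per-timestep channel groups plus the frame interval.

    ``frames[t]`` is a dict mapping :class:`Channel` to a :class:`VoxelGrid`.
    All frames must share spacing and per-channel shape, and time indices
    run consecutively from 0.
    """

    frames: list[dict[Channel, VoxelGrid]]
    dt_seconds: float

    def __post_init__(self):
        if self.dt_seconds <= 0:
            raise ValueError("dt_seconds must be > 0")
        if not self.frames:
            raise ValueError("dataset has no frames")
        ref = next(iter(self.frames[0].values()))
        for t, group in enumerate(self.frames):
            for grid in group.values():
                if grid.spacing != ref.spacing:
                    raise ValueError(
                        f"frame {t}: spacing {grid.spacing} != {ref.spacing}"
                    )
                if grid.shape != ref.shape:
                    raise ValueError(
                        f"frame {t}: shape {grid.shape} != {ref.shape}"
                    )
                if grid.t != t:
                    raise ValueError(f"frame {t} carries time index {grid.t}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return next(iter(self.frames[0].values())).spacing

    def channel_series(self, channel: Channel) -> list[VoxelGrid]:
        return [group[Channel(channel)] for group in self.frames]


@dataclass(frozen=True)
class Centre:
    """A detected (or virtual) nucleus centre.

    ``pos`` is ``(x, y, z)`` in physical µm.  ``virtual`` marks centres
    inserted by lineage repair rather than detected in the image.
    """

    id: int
    t: int
    pos: tuple[float, float, float]
    intensity: float = 0.0
    virtual: bool = False

    def __post_init__(self):
        object.__setattr__(self, "pos", tuple(float(p) for p in self.pos))
        if len(self.pos) != 3:
            raise ValueError("pos must be (x, y, z)")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass
class CentreSet:
    """All centres detected at one time step."""

    t: int
    centres: list[Centre] = field(default_factory=list)

    def __post_init__(self):
        for c in self.centres:
            if c.t != self.t:
                raise ValueError(f"centre {c.id} has t={c.t}, set has t={self.t}")

    def __len__(self) -> int:
        return len(self.centres)

    def __iter__(self) -> Iterator[Centre]:
        return iter(self.centres)

    def positions(self) -> np.ndarray:
        """``(n, 3)`` array of ``(x, y, z)`` µm positions."""
        if not self.centres:
            return np.zeros((0, 3))
        return np.array([c.pos for c in self.centres], dtype=float)


class LineageForest:
    """Nucleus centres over time plus mother→daughter links.

    The forest is a union of disjoint trees: links span exactly one frame,
    every centre has at most one mother and at most two daughters.  Mothers
    are stored as a daughter→mother map, which makes the single-mother
    constraint structural; the two-daughter constraint is checked by
    :meth:`validate` so that intermediate tracking states (e.g. raw
    nearest-neighbour initialization) can hold recorded violations.
    """

    def __init__(self, centres: Iterable[Centre] = (), links: Iterable[tuple[int, int]] = ()):
        self.centres: dict[int, Centre] = {}
        self._mother: dict[int, int] = {}
        self._daughters: dict[int, set[int]] = {}
        for c in centres:
            self.add_centre(c)
        for mother_id, daughter_id in links:
            self.add_link(mother_id, daughter_id)

    # -- construction -------------------------------------------------
    def add_centre(self, centre: Centre):
        if centre.id in self.centres:
            raise LineageError(f"duplicate centre id {centre.id}")
        self.centres[centre.id] = centre

    def remove_centre(self, centre_id: int):
        self.unlink(centre_id)
        for d in list(self._daughters.get(centre_id, ())):
            self.unlink(d)
        self._daughters.pop(centre_id, None)
        del self.centres[centre_id]

    def add_link(self, mother_id: int, daughter_id: int):
        if mother_id not in self.centres:
            raise LineageError(f"unknown mother id {mother_id}")
        if daughter_id not in self.centres:
            raise LineageError(f"unknown daughter id {daughter_id}")
        m, d = self.centres[mother_id], self.centres[daughter_id]
        if d.t != m.t + 1:
            raise LineageError(
                f"link {mother_id}->{daughter_id} spans t={m.t} to t={d.t}; "
                "links must span exactly one frame"
            )
        if daughter_id in self._mother:
            raise LineageError(f"centre {daughter_id} already has a mother")
        self._mother[daughter_id] = mother_id
        self._daughters.setdefault(mother_id, set()).add(daughter_id)

    def set_mother(self, daughter_id: int, mother_id: int | None):
        """Replace (or clear) a centre's mother link."""
        self.unlink(daughter_id)
        if mother_id is not None:
            self.add_link(mother_id, daughter_id)

    def unlink(self, daughter_id: int):
        m = self._mother.pop(daughter_id, None)
        if m is not None:
            self._daughters[m].discard(daughter_id)
            if not self._daughters[m]:
                del self._daughters[m]

    # -- queries ------------------------------------------------------
    def mother(self, centre_id: int) -> int | None:
        return self._mother.get(centre_id)

    def daughters(self, centre_id: int) -> frozenset[int]:
        return frozenset(self._daughters.get(centre_id, ()))

    def out_degree(self, centre_id: int) -> int:
        return len(self._daughters.get(centre_id, ()))

    @property
    def links(self) -> set[tuple[int, int]]:
        return {(m, d) for d, m in self._mother.items()}

    @property
    def n_links(self) -> int:
        return len(self._mother)

    @property
    def max_t(self) -> int:
        return max((c.t for c in self.centres.values()), default=-1)

    @property
    def min_t(self) -> int:
        return min((c.t for c in self.centres.values()), default=0)

    def centres_at(self, t: int) -> CentreSet:
        return CentreSet(t=t, centres=sorted(
            (c for c in self.centres.values() if c.t == t), key=lambda c: c.id))

    def roots(self) -> list[int]:
        return [cid for cid in self.centres if cid not in self._mother]

    def descendants(self, centre_id: int, max_frames: int | None = None) -> list[int]:
        """All ids reachable forward from ``centre_id`` (excluded), optionally
        limited to ``max_frames`` frames ahead."""
        t0 = self.centres[centre_id].t
        out, stack = [], [centre_id]
        while stack:
            cid = stack.pop()
            for d in self._daughters.get(cid, ()):
                if max_frames is not None and self.centres[d].t - t0 > max_frames:
                    continue
                out.append(d)
                stack.append(d)
        return out

    def divisions(self) -> list[int]:
        """Ids of mothers with exactly two daughters."""
        return [cid for cid, ds in self._daughters.items() if len(ds) == 2]

    # -- invariants ---------------------------------------------------
    def validate(self):
        """Raise :class:`LineageError` on any structural violation."""
        for d, m in self._mother.items():
            if self.centres[d].t != self.centres[m].t + 1:
                raise LineageError(f"link {m}->{d} does not span one frame")
        for cid, ds in self._daughters.items():
            if len(ds) > 2:
                raise LineageError(
                    f"centre {cid} has {len(ds)} daughters (max 2)"
                )
        # acyclicity is implied by links strictly increasing in t

    def copy(self) -> "LineageForest":
        f = LineageForest()
        f.centres = dict(self.centres)
        f._mother = dict(self._mother)
        f._daughters = {k: set(v) for k, v in self._daughters.items()}
        return f

    def __eq__(self, other) -> bool:
        if not isinstance(other, LineageForest):
            return NotImplemented
        return self.centres == other.centres and self._mother == other._mother

    def next_id(self) -> int:
        return max(self.centres, default=-1) + 1
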