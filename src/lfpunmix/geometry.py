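"""Core data containers and file I/O.

Coordinate convention (used uniformly across the package, see
:data:`COORDINATE_CONVENTION`): positions are in millimetres; ``x`` is
lateral distance from the midline, ``y`` runs along the anterior--posterior
axis, and ``z`` is depth below the cortical surface (0 at the surface,
positive downward).

Unit convention: mm / ms / mV / uA / uA/mm^3 / S/m.  With current in uA,
distance in mm and conductivity in S/m, the point-charge potential
``Q / (4 pi sigma r)`` comes out directly in mV, so the unit-consistency
factor is exactly 1 (see :data:`UNIT_FACTOR`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError

#: Human-readable statement of the shared coordinate convention.  Tests
#: assert against this constant so the convention cannot silently drift.
COORDINATE_CONVENTION = (
    "mm; x lateral from midline, y anterior-posterior, "
    "z depth below cortical surface (0 at surface, positive down)"
)

#: Conversion factor between (uA, mm, S/m) inputs and mV potentials.
#: uA/(S/m * mm) = 1e-6 A / (1e-3 S) = 1e-3 V = 1 mV, hence 1.0 exactly.
UNIT_FACTOR = 1.0

#: Relative tolerance for the uniform-sampling invariant of time axes.
_TIME_RTOL = 1e-9


@dataclass(frozen=True)
class Medium:
    """Infinite homogeneous volume conductor.

    Parameters
    ----------
    conductivity
        Extracellular conductivity sigma in S/m.  Must be positive.
    """

    conductivity: float = 0.3

    def __post_init__(self) -> None:
        if not np.isfinite(self.conductivity) or self.conductivity <= 0:
            raise ValidationError(
                f"conductivity must be a positive finite number, "
                f"got {self.conductivity!r}"
            )


@dataclass
class ElectrodeGrid:
    """Measurement geometry: channel ids, positions (mm) and broken flags.

    Broken channels are retained (never silently re-indexed) and dropped
    only at analysis time via :attr:`active_positions`.
    """

    channel_ids: list
    positions: np.ndarray  # (N, 3) mm
    broken: np.ndarray  # (N,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.broken = np.asarray(self.broken, dtype=bool)
        self.channel_ids = list(self.channel_ids)
        n = len(self.channel_ids)
        if self.positions.shape != (n, 3):
            raise ValidationError(
                f"positions must have shape ({n}, 3), got {self.positions.shape}"
            )
        if self.broken.shape != (n,):
            raise ValidationError(
                f"broken mask must have shape ({n},), got {self.broken.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("electrode positions must be finite")
        active = self.positions[~self.broken]
        if active.shape[0] < 1:
            raise ValidationError("grid must contain at least one active channel")
        uniq = np.unique(active.round(decimals=9), axis=0)
        if uniq.shape[0] != active.shape[0]:
            raise ValidationError("two active channels share identical coordinates")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(~self.broken))

    @property
    def active_positions(self) -> np.ndarray:
        """Positions of non-broken channels, (n_active, 3), mm."""
        return self.positions[~self.broken]

    @property
    def active_ids(self) -> list:
        return [c for c, b in zip(self.channel_ids, self.broken) if not b]

    def subset(self, keep: np.ndarray) -> "ElectrodeGrid":
        """Grid restricted to channels selected by boolean mask ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        return ElectrodeGrid(
            channel_ids=[c for c, k in zip(self.channel_ids, keep) if k],
            positions=self.positions[keep],
            broken=self.broken[keep],
        )


@dataclass
class Region:
    """Named union of axis-aligned cuboids, in mm.

    Each cuboid is a (2, 3) array ``[[xmin, ymin, zmin], [xmax, ymax, zmax]]``
    with strictly increasing bounds on every axis.
    """

    name: str
    cuboids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        boxes = []
        for box in self.cuboids:
            box = np.asarray(box, dtype=float)
            if box.shape != (2, 3):
                raise ValidationError(
                    f"cuboid must be a (2, 3) min/max array, got shape {box.shape}"
                )
            if not np.all(box[0] < box[1]):
                raise ValidationError(
                    f"cuboid of region {self.name!r} must satisfy min < max "
                    f"on all axes, got {box.tolist()}"
                )
            boxes.append(box)
        self.cuboids = boxes

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: point inside (boundary inclusive) any cuboid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        mask = np.zeros(pts.shape[0], dtype=bool)
        for box in self.cuboids:
            mask |= np.all((pts >= box[0]) & (pts <= box[1]), axis=1)
        return mask

    def bounding_box(self) -> np.ndarray:
        """Smallest single cuboid containing the region, (2, 3)."""
        if not self.cuboids:
            raise ValidationError(f"region {self.name!r} has no cuboids")
        lo = np.min([b[0] for b in self.cuboids], axis=0)
        hi = np.max([b[1] for b in self.cuboids], axis=0)
        return np.array([lo, hi])


@dataclass
class EvokedPotential:
    """Trial-averaged stimulus-locked potential on an electrode grid.

    ``values`` has one row per *active* channel of ``grid`` (mV); ``times``
    is in ms relative to the stimulus at t = 0 and must be strictly
    increasing and uniformly spaced.
    """

    grid: ElectrodeGrid
    times: np.ndarray  # (T,) ms
    values: np.ndarray  # (n_active, T) mV
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValidationError("times must be a 1-D array with >= 2 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=_TIME_RTOL, atol=0.0):
            raise ValidationError("times must be uniformly spaced")
        if self.values.shape != (self.grid.n_active, self.times.size):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"(n_active={self.grid.n_active}, n_times={self.times.size})"
            )
        if not np.isclose(self.sampling_rate, 1000.0 / dt[0], rtol=1e-6):
            raise ValidationError(
                f"sampling_rate {self.sampling_rate} Hz inconsistent with "
                f"time step {dt[0]} ms"
            )

    @property
    def dt(self) -> float:
        """Sample period in ms."""
        return float(self.times[1] - self.times[0])

    def channel_index(self, channel) -> int:
        """Row index of ``channel`` among active channels."""
        ids = self.grid.active_ids
        try:
            return ids.index(channel)
        except ValueError:
            raise KeyError(f"unknown active channel {channel!r}") from None

    def trace(self, channel) -> np.ndarray:
        return self.values[self.channel_index(channel)]


# ---------------------------------------------------------------------------
# CSV electrode geometry
# ---------------------------------------------------------------------------

_GRID_COLUMNS = ("channel", "x", "y", "z", "broken")


def read_electrode_grid(path) -> ElectrodeGrid:
    """Read an electrode geometry table.

    Expected CSV header: ``channel,x,y,z,broken`` with coordinates in mm
    and ``broken`` as 0/1.  Broken channels are retained but flagged;
    row order is preserved.
    """
    df = pd.read_csv(path)
    for col in _GRID_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"electrode table is missing column {col!r}")
    if len(df) == 0:
        raise ValidationError("electrode table contains no channels")
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pos)):
        raise FormatError("electrode coordinates must parse as finite numbers")
    return ElectrodeGrid(
        channel_ids=[str(c) for c in df["channel"]],
        positions=pos,
        broken=df["broken"].to_numpy().astype(bool),
    )


def write_electrode_grid(grid: ElectrodeGrid, path) -> None:
    df = pd.DataFrame(
        {
            "channel": grid.channel_ids,
            "x": grid.positions[:, 0],
            "y": grid.positions[:, 1],
            "z": grid.positions[:, 2],
            "broken": grid.broken.astype(int),
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HDF5 evoked potentials
# ---------------------------------------------------------------------------


def write_ep(ep: EvokedPotential, path) -> None:
    """Write an evoked potential to HDF5 (layout: /values, /times, /channels
    plus a /grid group so the file is self-contained)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=ep.values)
        f.create_dataset("times", data=ep.times)
        f.create_dataset(
            "channels", data=np.array([str(c) for c in ep.grid.active_ids], dtype="S")
        )
        g = f.create_group("grid")
        g.create_dataset(
            "channel_ids",
            data=np.array([str(c) for c in ep.grid.channel_ids], dtype="S"),
        )
        g.create_dataset("positions", data=ep.grid.positions)
        g.create_dataset("broken", data=ep.grid.broken.astype(np.uint8))
        f.attrs["sampling_rate_hz"] = ep.sampling_rate
        f.attrs["units_values"] = "mV"
        f.attrs["units_times"] = "ms"
        f.attrs["units_positions"] = "mm"


def read_ep(path) -> EvokedPotential:
    """Read an evoked potential written by :func:`write_ep`.

    Round-trips bit-exactly with :func:`write_ep`.
    """
    with h5py.File(path, "r") as f:
        for name in ("values", "times", "channels", "grid"):
            if name not in f:
                raise FormatError(f"EP file is missing dataset {name!r}")
        values = f["values"][()]
        times = f["times"][()]
        channels = [c.decode() for c in f["channels"][()]]
        g = f["grid"]
        grid = ElectrodeGrid(
            channel_ids=[c.decode() for c in g["channel_ids"][()]],
            positions=g["positions"][()],
            broken=g["broken"][()].astype(bool),
        )
        rate = float(f.attrs["sampling_rate_hz"])
    if values.ndim != 2 or values.shape[1] != times.shape[0]:
        raise FormatError(
            f"values shape {values.shape} does not match times length {times.shape[0]}"
        )
    if channels != [str(c) for c in grid.active_ids]:
        raise FormatError("channel list does not match active channels of the grid")
    return EvokedPotential(grid=grid, times=times, values=values, sampling_rate=rate)


# ---------------------------------------------------------------------------
# YAML / JSON configuration
# ---------------------------------------------------------------------------


def regions_from_mapping(spec) -> list:
    """Build :class:`Region` objects from a config mapping.

    Accepts ``{name: {cuboids: [[[xmin,ymin,zmin],[xmax,ymax,zmax]], ...]}}``
    or the shorthand ``{name: [[min],[max]]}`` for a single cuboid.
    """
    regions = []
    for name, body in spec.items():
        if isinstance(body, dict):
            cuboids = body["cuboids"]
        else:
            cuboids = [body]
        regions.append(Region(name=name, cuboids=cuboids))
    return regions


def load_config(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) pipeline configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("configuration file must contain a mapping")
    return cfg
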