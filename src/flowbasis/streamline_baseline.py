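"""Streamline (tracer) prediction baseline on a lattice velocity field.

The carrier fluid is known only at the nodes of a unit-spacing regular grid;
trilinear interpolation supplies the velocity between nodes. A cell is then
modeled as a massless tracer: one recording stride ahead, its predicted
position is

    x_p = x_c + stride * y_i,

where ``y_i`` is the interpolated fluid velocity at the current center and
``stride`` converts the field's time unit to the recording stride (default
100: snapshots are taken every 1000 simulation steps of 0.1 time units).

Because a cell has finite extent in the thin channel direction, its membrane
samples fluid above and below the center, where a parabolic profile is slower
than at the mid-plane. The z-weighted variant therefore mixes the fluid
velocity at the center and at +/-1 length unit in z with weights proportional
to the membrane-node counts (30 of 141 nodes near the center plane, 55.5
effective nodes each for the upper and lower planes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .trajectory_data import TrajectoryDataset

_FIELD_HEADER = "# flowbasis field v"
FIELD_FORMAT_VERSION = 1


class DomainError(ValueError):
    """A query point lies outside the lattice grid."""


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


@dataclass
class LatticeVelocityField:
    """Fluid velocities on a unit-spacing regular grid with a solid mask.

    ``velocities`` has shape (nx, ny, nz, 3); ``solid_mask`` marks wall and
    obstacle nodes, which always carry zero velocity (no-slip). ``meta`` holds
    free-form provenance (solver residuals, fixture parameters).
    """

    origin: np.ndarray
    velocities: np.ndarray
    solid_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.solid_mask = np.asarray(self.solid_mask, dtype=bool)
        if self.velocities.ndim != 4 or self.velocities.shape[-1] != 3:
            raise ValueError("velocities must have shape (nx, ny, nz, 3)")
        if self.solid_mask.shape != self.velocities.shape[:3]:
            raise ValueError("solid_mask shape must match the grid")
        if not np.isfinite(self.velocities).all():
            raise ValueError("field velocities must be finite")
        if self.solid_mask.any() and np.abs(self.velocities[self.solid_mask]).max() > 0:
            raise ValueError("solid nodes must carry zero velocity")
        self._interp: Optional[RegularGridInterpolator] = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.velocities.shape[:3]

    @property
    def upper_corner(self) -> np.ndarray:
        return self.origin + np.asarray(self.shape) - 1.0

    def _interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            axes = [self.origin[d] + np.arange(self.shape[d]) for d in range(3)]
            self._interp = RegularGridInterpolator(
                axes, self.velocities, method="linear", bounds_error=True
            )
        return self._interp


def interpolate_velocity(field: LatticeVelocityField, p) -> np.ndarray:
    """Trilinear interpolation of the fluid velocity at point(s) ``p``.

    Accepts a single 3-vector or an (M, 3) array. Raises :class:`DomainError`
    outside the grid's convex hull.
    """
    pts = np.asarray(p, dtype=float)
    single = pts.ndim == 1
    try:
        out = field._interpolator()(pts.reshape(-1, 3))
    except ValueError as exc:
        raise DomainError(f"point outside the lattice grid: {exc}") from None
    return out[0] if single else out


def tracer_step(field: LatticeVelocityField, x_c, stride: float = 100.0) -> np.ndarray:
    """One-stride tracer prediction: ``x_p = x_c + stride * u(x_c)``."""
    x_c = np.asarray(x_c, dtype=float)
    return x_c + stride * interpolate_velocity(field, x_c)


@dataclass(frozen=True)
class ZWeighting:
    """Membrane-extent weighting of fluid velocities above/at/below the center.

    Defaults reflect a 141-node membrane discretization: 30 nodes near the
    center plane and 55.5 effective nodes at each of the planes one length
    unit above and below; the normalized weights sum to exactly 1.
    """

    upper: float = 55.5
    center: float = 30.0
    lower: float = 55.5
    offset: float = 1.0

    @property
    def total(self) -> float:
        return self.upper + self.center + self.lower

    @property
    def normalized(self) -> tuple[float, float, float]:
        t = self.total
        return (self.upper / t, self.center / t, self.lower / t)


def weighted_cell_velocity(
    field: LatticeVelocityField, center, weighting: ZWeighting | None = None
) -> np.ndarray:
    """Cell velocity as the z-weighted mix of three interpolated fluid velocities."""
    if weighting is None:
        weighting = ZWeighting()
    c = np.asarray(center, dtype=float)
    off = np.zeros_like(c)
    off[..., 2] = weighting.offset
    wu, wc, wl = weighting.normalized
    return (
        wu * interpolate_velocity(field, c + off)
        + wc * interpolate_velocity(field, c)
        + wl * interpolate_velocity(field, c - off)
    )


@dataclass
class BaselineErrorReport:
    """Mean one-stride tracer prediction error over a dataset."""

    mean_error: float
    relative_error_pct: float
    mean_step_displacement: float
    n_predictions: int
    n_cells: int


def mean_prediction_error(
    dataset: TrajectoryDataset,
    field: LatticeVelocityField,
    stride: float = 100.0,
    weighting: ZWeighting | None = None,
    *,
    period_x: float | None = None,
) -> BaselineErrorReport:
    """Mean distance between recorded and tracer-predicted next positions.

    For every consecutive record pair within a trajectory, the tracer (or
    z-weighted) prediction is launched from the earlier position and compared
    with the later one; the mean Euclidean distance over all such pairs is the
    mean error. The relative error divides it by the mean recorded step
    displacement. ``period_x`` enables minimum-image distance along x for
    periodic channels.
    """
    starts: list[np.ndarray] = []
    nexts: list[np.ndarray] = []
    n_cells = 0
    for cid, idx in dataset.cells():
        if len(idx) < 2:
            raise ValueError(f"cell {cid!r} has fewer than 2 snapshots")
        n_cells += 1
        pos = dataset.positions[idx]
        starts.append(pos[:-1])
        nexts.append(pos[1:])
    if n_cells == 0:
        raise ValueError("empty dataset")
    x_c = np.vstack(starts)
    x_true = np.vstack(nexts)
    if weighting is None:
        u = interpolate_velocity(field, x_c)
    else:
        u = np.vstack([weighted_cell_velocity(field, p, weighting) for p in x_c])
    x_p = x_c + stride * u
    diff = x_true - x_p
    if period_x is not None:
        diff[:, 0] -= period_x * np.round(diff[:, 0] / period_x)
    err = np.linalg.norm(diff, axis=1)
    step_disp = x_true - x_c
    if period_x is not None:
        step_disp[:, 0] -= period_x * np.round(step_disp[:, 0] / period_x)
    mean_step = float(np.linalg.norm(step_disp, axis=1).mean())
    e_bar = float(err.mean())
    rel = 100.0 * e_bar / mean_step if mean_step > 0 else float("inf")
    return BaselineErrorReport(
        mean_error=e_bar,
        relative_error_pct=rel,
        mean_step_displacement=mean_step,
        n_predictions=len(err),
        n_cells=n_cells,
    )


def write_field(field: LatticeVelocityField, path) -> None:
    """Write a field as text: header plus one node per line, x-fastest order."""
    nx, ny, nz = field.shape
    lines = [
        f"{_FIELD_HEADER}{FIELD_FORMAT_VERSION}",
        f"# shape: {nx} {ny} {nz}",
        "# origin: " + " ".join(_fmt(v) for v in field.origin),
    ]
    for key, val in sorted(field.meta.items()):
        lines.append(f"# meta {key}: {val}")
    lines.append("# columns: i j k ux uy uz solid")
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                u = field.velocities[i, j, k]
                lines.append(
                    f"{i} {j} {k} {_fmt(u[0])} {_fmt(u[1])} {_fmt(u[2])} "
                    f"{int(field.solid_mask[i, j, k])}"
                )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_field(path) -> LatticeVelocityField:
    """Read a field written by :func:`write_field`."""
    meta: dict = {}
    shape = origin = None
    header_rows = 0
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith(_FIELD_HEADER):
            raise ValueError(f"{path}: not a flowbasis field file")
        version = first[len(_FIELD_HEADER):]
        if version != str(FIELD_FORMAT_VERSION):
            raise ValueError(f"{path}: unsupported field format version {version}")
        header_rows = 1
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            body = line[1:].strip()
            if body.startswith("shape:"):
                shape = tuple(int(v) for v in body.split(":", 1)[1].split())
            elif body.startswith("origin:"):
                origin = [float(v) for v in body.split(":", 1)[1].split()]
            elif body.startswith("meta "):
                key, _, val = body[5:].partition(":")
                meta[key.strip()] = val.strip()
    if shape is None or origin is None:
        raise ValueError(f"{path}: missing shape/origin header")
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None,
        names=["i", "j", "k", "ux", "uy", "uz", "solid"],
        float_precision="round_trip",
    )
    nx, ny, nz = shape
    if len(df) != nx * ny * nz:
        raise ValueError(f"{path}: expected {nx * ny * nz} node rows, got {len(df)}")
    vel = np.empty((nx, ny, nz, 3))
    solid = np.empty((nx, ny, nz), dtype=bool)
    i = df["i"].to_numpy()
    j = df["j"].to_numpy()
    k = df["k"].to_numpy()
    vel[i, j, k, 0] = df["ux"].to_numpy()
    vel[i, j, k, 1] = df["uy"].to_numpy()
    vel[i, j, k, 2] = df["uz"].to_numpy()
    solid[i, j, k] = df["solid"].to_numpy().astype(bool)
    return LatticeVelocityField(origin=origin, velocities=vel, solid_mask=solid, meta=meta)
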