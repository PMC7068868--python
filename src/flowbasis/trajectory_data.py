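"""Trajectory datasets: per-cell, per-snapshot cell-center positions and velocities.

A dataset is a bag of records ``(cell_id, snapshot_index, position, velocity)``
stored column-wise. Positions are in channel length units (1 unit = 1 um in the
lattice system used throughout); velocities are displacements per snapshot
interval, so trajectory integration with ``dt = 1`` is unit-consistent.

Files are UTF-8 delimited text (comma or tab, auto-detected) with ``#``-prefixed
metadata lines at the top, a mandatory header row naming the columns
``cell_id, step, x, y, z, vx, vy, vz``, and one record per line. Floats are
serialized with 17 significant digits so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

COLUMNS = ("cell_id", "step", "x", "y", "z", "vx", "vy", "vz")

_FORMAT_LINE = "# flowbasis trajectory v1"


class DatasetParseError(ValueError):
    """A trajectory file could not be parsed (message names the line)."""


class DatasetValidationError(ValueError):
    """A dataset violates a structural invariant."""


class CellRecord(NamedTuple):
    cell_id: str
    snapshot_index: int
    position: np.ndarray
    velocity: np.ndarray


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


@dataclass
class TrajectoryDataset:
    """Column-wise collection of cell-center records.

    Parameters
    ----------
    cell_ids : array of str, shape (n,)
    steps : int array, shape (n,)
        Snapshot indices (one unit = one recording stride).
    positions, velocities : float arrays, shape (n, 3)
    bounding_box : float array, shape (2, 3)
        Inclusive [min; max] corners. Computed from the data when omitted.
    channel_id : free-text label (e.g. ``A50a``).
    snapshot_interval : physical duration of one snapshot (metadata only).
    """

    cell_ids: np.ndarray
    steps: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    bounding_box: np.ndarray | None = None
    channel_id: str = ""
    snapshot_interval: float = 1.0

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        if self.bounding_box is None:
            if len(self.positions):
                self.bounding_box = np.vstack(
                    [self.positions.min(axis=0), self.positions.max(axis=0)]
                )
            else:
                self.bounding_box = np.zeros((2, 3))
        self.bounding_box = np.asarray(self.bounding_box, dtype=float).reshape(2, 3)

    @property
    def n_records(self) -> int:
        return len(self.steps)

    def cells(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield ``(cell_id, row_indices)`` in order of first appearance."""
        order: dict[str, list[int]] = {}
        for i, cid in enumerate(self.cell_ids):
            order.setdefault(cid, []).append(i)
        for cid, idx in order.items():
            yield cid, np.asarray(idx, dtype=np.intp)

    def records(self) -> Iterator[CellRecord]:
        for i in range(self.n_records):
            yield CellRecord(
                self.cell_ids[i], int(self.steps[i]),
                self.positions[i].copy(), self.velocities[i].copy(),
            )

    def validate(self) -> None:
        """Raise :class:`DatasetValidationError` on any invariant violation."""
        if not np.isfinite(self.positions).all() or not np.isfinite(self.velocities).all():
            raise DatasetValidationError("non-finite position or velocity component")
        lo, hi = self.bounding_box
        if len(self.positions) and (
            (self.positions < lo - 1e-12).any() or (self.positions > hi + 1e-12).any()
        ):
            raise DatasetValidationError("record position outside bounding_box")
        seen = set(zip(self.cell_ids, self.steps.tolist()))
        if len(seen) != self.n_records:
            raise DatasetValidationError("(cell_id, snapshot_index) pairs are not unique")
        for cid, idx in self.cells():
            d = np.diff(self.steps[idx])
            if len(d) and ((d != 1).any()):
                raise DatasetValidationError(
                    f"cell {cid!r}: snapshot indices not consecutive within a passage"
                )


def read_dataset(path, delimiter: str | None = None) -> TrajectoryDataset:
    """Read a trajectory file.

    ``#`` metadata/comment lines may appear anywhere; the first non-comment line
    must be the header. Raises :class:`DatasetParseError` naming the offending
    line on malformed rows and :class:`DatasetValidationError` on non-finite
    values.
    """
    meta: dict[str, str] = {}
    data_lines: list[tuple[int, str]] = []
    header: str | None = None
    header_lineno = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta.setdefault(key.strip(), val.strip())
                continue
            if header is None:
                header = line
                header_lineno = lineno
            else:
                data_lines.append((lineno, line))
    if header is None:
        raise DatasetParseError(f"{path}: no header row found")
    if delimiter is None:
        delimiter = "\t" if "\t" in header else ","
    names = tuple(h.strip() for h in header.split(delimiter))
    if names != COLUMNS:
        raise DatasetParseError(
            f"{path}: line {header_lineno}: header must declare columns "
            f"{', '.join(COLUMNS)} (got {', '.join(names)})"
        )

    n = len(data_lines)
    cell_ids = np.empty(n, dtype=object)
    steps = np.empty(n, dtype=np.int64)
    numeric = np.empty((n, 6), dtype=float)
    if n:
        body = io.StringIO("\n".join(line for _, line in data_lines))
        try:
            df = pd.read_csv(
                body, sep=delimiter, names=COLUMNS, header=None,
                dtype={"cell_id": str}, na_values=[], keep_default_na=False,
                float_precision="round_trip",
            )
            steps[:] = pd.to_numeric(df["step"]).to_numpy()
            for j, col in enumerate(("x", "y", "z", "vx", "vy", "vz")):
                numeric[:, j] = pd.to_numeric(df[col].to_numpy())
        except (ValueError, pd.errors.ParserError):
            # slow path: locate the offending line for the diagnostic
            for lineno, line in data_lines:
                parts = line.split(delimiter)
                if len(parts) != len(COLUMNS):
                    raise DatasetParseError(
                        f"{path}: line {lineno}: expected {len(COLUMNS)} fields, "
                        f"got {len(parts)}"
                    ) from None
                for part in parts[1:]:
                    try:
                        float(part)
                    except ValueError:
                        raise DatasetParseError(
                            f"{path}: line {lineno}: cannot parse {part!r} as a number"
                        ) from None
            raise
        cell_ids[:] = df["cell_id"].to_numpy(dtype=object)
        if not np.isfinite(numeric).all():
            bad = int(np.argwhere(~np.isfinite(numeric).all(axis=1))[0, 0])
            raise DatasetValidationError(
                f"{path}: line {data_lines[bad][0]}: non-finite value"
            )

    bbox = None
    if "bounding_box" in meta:
        vals = [float(v) for v in meta["bounding_box"].split()]
        bbox = np.asarray(vals, dtype=float).reshape(2, 3)
    return TrajectoryDataset(
        cell_ids=cell_ids,
        steps=steps,
        positions=numeric[:, :3],
        velocities=numeric[:, 3:],
        bounding_box=bbox,
        channel_id=meta.get("channel_id", ""),
        snapshot_interval=float(meta.get("snapshot_interval", 1.0)),
    )


def write_dataset(dataset: TrajectoryDataset, path) -> None:
    """Write a dataset as comma-delimited text with a ``#`` metadata header."""
    lo, hi = dataset.bounding_box
    lines = [
        _FORMAT_LINE,
        f"# channel_id: {dataset.channel_id}",
        f"# snapshot_interval: {_fmt(dataset.snapshot_interval)}",
        "# bounding_box: " + " ".join(_fmt(v) for v in (*lo, *hi)),
        "# velocity unit: length per snapshot interval",
        ",".join(COLUMNS),
    ]
    p = dataset.positions
    v = dataset.velocities
    for i in range(dataset.n_records):
        lines.append(
            f"{dataset.cell_ids[i]},{int(dataset.steps[i])},"
            f"{_fmt(p[i, 0])},{_fmt(p[i, 1])},{_fmt(p[i, 2])},"
            f"{_fmt(v[i, 0])},{_fmt(v[i, 1])},{_fmt(v[i, 2])}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def split_periodic_passages(
    dataset: TrajectoryDataset, axis: int, period: float
) -> TrajectoryDataset:
    """Cut trajectories at periodic wrap jumps along ``axis``.

    Channels are periodic in the flow direction: a cell leaving at one end
    re-enters at the other, producing a coordinate jump of about one period
    between consecutive snapshots. Whenever consecutive records of one cell
    jump by more than ``period / 2`` along ``axis``, the trajectory is cut and
    the tail becomes a fresh trajectory (``<cell_id>#p<k>``), so that each
    passage through the channel counts as a separate cell. No record is
    dropped and the record order is preserved.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis!r}")
    if not period > 0:
        raise ValueError("period must be positive")
    new_ids = np.array(dataset.cell_ids, dtype=object, copy=True)
    half = period / 2.0
    for cid, idx in dataset.cells():
        coord = dataset.positions[idx, axis]
        cuts = np.nonzero(np.abs(np.diff(coord)) > half)[0]
        for k, c in enumerate(cuts, start=1):
            start = idx[c + 1]
            end = idx[-1]
            tail = idx[(idx >= start) & (idx <= end)]
            new_ids[tail] = f"{cid}#p{k}"
    return replace(dataset, cell_ids=new_ids)


def assemble_training_vectors(
    dataset: TrajectoryDataset,
) -> tuple[np.ndarray, np.ndarray]:
    """Return the dataset as unordered ``(x, y)`` training pairs.

    The mutual relations between records (the fact that they form trajectories)
    are deliberately discarded: each record is one independent (position,
    velocity) sample. For a complete rectangular recording of ``n_cells`` cells
    over ``n_snapshots`` snapshots the pair count is their product.
    """
    return dataset.positions.copy(), dataset.velocities.copy()
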