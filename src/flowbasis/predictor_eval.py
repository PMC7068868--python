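"""Trajectory prediction and error metrics for a trained basis system.

Whole trajectories are generated by iterating the velocity prediction,

    x_{n+1} = x_n + y'(x_n) * dt,

with dt = 1 snapshot interval by default (velocities are stored as
displacement per snapshot, so no unit conversion is involved). Local accuracy
is measured by the relative error of each velocity prediction,

    RE_i = ||y_i - y_p(x_i)|| / ||y_i|| * 100 [%],

averaged into the mean relative error (MRE), optionally after trimming the
samples with the largest absolute prediction error ||y - y_p|| — those are
outlier-like records dominated by short-term membrane oscillations rather
than by the carrier flow. Global accuracy is the per-iteration deviation
between recorded trajectories and predictions launched from the same initial
positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .basis_model import BasisSystem, predict_velocities, predict_velocity
from .trajectory_data import TrajectoryDataset

DEFAULT_RETENTIONS = (0.999, 0.99, 0.90, 0.50)


@dataclass
class PredictedTrajectory:
    """Positions produced by iterated velocity prediction.

    ``positions[0]`` is the initial position. ``completed`` is False when the
    trajectory left the model bounding box (plus margin) before reaching the
    requested number of steps; ``positions`` then holds only the steps taken.
    """

    positions: np.ndarray
    dt: float
    requested_steps: int
    completed: bool = True

    @property
    def initial_position(self) -> np.ndarray:
        return self.positions[0]

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1


@dataclass
class ErrorSummary:
    """MRE of velocity predictions on one test set, full and trimmed."""

    n_compared: int
    mre_full: float
    mre_trimmed: dict[float, float]
    trim_mode: str = "absolute"
    n_zero_excluded: int = 0


@dataclass
class DeviationCurve:
    """Per-iteration spread of ||reference - predicted|| across paired trajectories."""

    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n_active: np.ndarray

    def to_delimited(self) -> str:
        lines = ["iteration\tmean\tmin\tmax\tn_active"]
        for i in range(len(self.mean)):
            lines.append(
                f"{i}\t{self.mean[i]:.10g}\t{self.min[i]:.10g}"
                f"\t{self.max[i]:.10g}\t{int(self.n_active[i])}"
            )
        return "\n".join(lines) + "\n"


def predict_trajectory(
    model: BasisSystem,
    x0,
    n_steps: int,
    dt: float = 1.0,
    *,
    bounding_box: np.ndarray | None = None,
    margin: float = 5.0,
) -> PredictedTrajectory:
    """Advect a point through the learned velocity field.

    Integration stops early if the position leaves ``bounding_box`` (default:
    the basis-position bounding box) by more than ``margin`` length units —
    outside the data support the model has nothing to say.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    if not dt > 0:
        raise ValueError("dt must be positive")
    x0 = np.asarray(x0, dtype=float).reshape(3)
    if bounding_box is None:
        bounding_box = model.bounding_box
    lo = bounding_box[0] - margin
    hi = bounding_box[1] + margin
    out = [x0.copy()]
    x = x0.copy()
    completed = True
    for step in range(n_steps):
        v = predict_velocity(model, x)
        if not np.isfinite(v).all():
            raise FloatingPointError(
                f"non-finite predicted velocity at step {step} (position {x})"
            )
        x = x + v * dt
        if (x < lo).any() or (x > hi).any():
            completed = False
            break
        out.append(x.copy())
    return PredictedTrajectory(
        positions=np.asarray(out), dt=dt, requested_steps=n_steps, completed=completed
    )


#: scale-free rest threshold: a record whose speed is below this fraction of
#: the dataset's median speed counts as a zero-velocity record. Cells parked
#: at stagnation faces produce arbitrarily small finite speeds for which the
#: relative error is as meaningless as for an exact zero.
REST_FRACTION = 0.01


def local_error_summary(
    model: BasisSystem,
    test: TrajectoryDataset,
    retentions: Sequence[float] = DEFAULT_RETENTIONS,
    trim_mode: str = "absolute",
    speed_floor: float | None = None,
) -> ErrorSummary:
    """Trimmed mean-relative-error of velocity predictions on a test set.

    Records are treated as independent (position, velocity) samples. Records
    of cells at rest — speed exactly zero, or below ``speed_floor``, which
    defaults to ``REST_FRACTION`` times the median recorded speed — are
    excluded (RE is undefined at rest) and counted in ``n_zero_excluded``.
    For each retention fraction r the ``ceil((1 - r) * n)`` samples with the
    largest absolute error ``||y - y_p||`` (``trim_mode="absolute"``) or the
    largest RE (``trim_mode="relative"``) are dropped before averaging.
    """
    if test.n_records == 0:
        raise ValueError("empty test set")
    if trim_mode not in ("absolute", "relative"):
        raise ValueError(f"trim_mode must be 'absolute' or 'relative', got {trim_mode!r}")
    y = test.velocities
    speed = np.linalg.norm(y, axis=1)
    if speed_floor is None:
        moving = speed[speed > 0]
        speed_floor = REST_FRACTION * float(np.median(moving)) if len(moving) else 0.0
    keep = speed > speed_floor
    n_zero = int((~keep).sum())
    if not keep.any():
        raise ValueError("all test records have zero velocity; RE is undefined")
    x = test.positions[keep]
    y = y[keep]
    speed = speed[keep]
    y_p = predict_velocities(model, x)
    abs_err = np.linalg.norm(y - y_p, axis=1)
    re = abs_err / speed * 100.0
    n = len(re)
    rank_key = abs_err if trim_mode == "absolute" else re
    order = np.argsort(rank_key, kind="stable")
    re_sorted = re[order]  # ascending by trim key; tail gets dropped
    trimmed: dict[float, float] = {}
    for r in retentions:
        if not 0 < r <= 1:
            raise ValueError(f"retention fractions must be in (0, 1], got {r}")
        drop = math.ceil((1.0 - r) * n)
        kept = re_sorted[: n - drop] if drop else re_sorted
        trimmed[r] = float(kept.mean()) if len(kept) else float("nan")
    return ErrorSummary(
        n_compared=n,
        mre_full=float(re.mean()),
        mre_trimmed=trimmed,
        trim_mode=trim_mode,
        n_zero_excluded=n_zero,
    )


def trajectory_deviation(
    model: BasisSystem,
    reference: TrajectoryDataset,
    dt: float = 1.0,
    *,
    margin: float = 5.0,
    period_x: float | None = None,
) -> DeviationCurve:
    """Deviation curves between recorded trajectories and paired predictions.

    Each reference trajectory is matched by a prediction starting from its
    first recorded position and iterated for exactly its recorded length.
    Per-iteration mean/min/max are taken over trajectories still active at
    that iteration (long enough, and not yet escaped from the model bounding
    box plus ``margin``). For channels periodic in x, pass ``period_x`` so
    predicted positions wrap and deviations use the minimum-image x distance.
    """
    trajs = []
    for _, idx in reference.cells():
        if len(idx) < 2:
            raise ValueError("every reference trajectory needs at least 2 snapshots")
        trajs.append(reference.positions[idx])
    m = len(trajs)
    lengths = np.array([len(t) for t in trajs])
    horizon = int(lengths.max())
    cur = np.array([t[0] for t in trajs])
    active = np.ones(m, dtype=bool)
    bbox = model.bounding_box
    lo = bbox[0] - margin
    hi = bbox[1] + margin
    mean = np.full(horizon, np.nan)
    mn = np.full(horizon, np.nan)
    mx = np.full(horizon, np.nan)
    n_active = np.zeros(horizon, dtype=int)
    for it in range(horizon):
        alive = active & (lengths > it)
        if alive.any():
            ref = np.array([trajs[i][it] for i in np.nonzero(alive)[0]])
            diff = cur[alive] - ref
            if period_x is not None:
                diff[:, 0] -= period_x * np.round(diff[:, 0] / period_x)
            dev = np.linalg.norm(diff, axis=1)
            mean[it] = dev.mean()
            mn[it] = dev.min()
            mx[it] = dev.max()
            n_active[it] = int(alive.sum())
        step = active & (lengths > it + 1)
        if not step.any():
            active &= lengths > it + 1
            continue
        v = predict_velocities(model, cur[step])
        nxt = cur[step] + v * dt
        if period_x is not None:
            nxt[:, 0] = np.mod(nxt[:, 0], period_x)
        cur[step] = nxt
        escaped = ((nxt < lo) | (nxt > hi)).any(axis=1)
        idx_step = np.nonzero(step)[0]
        active[idx_step[escaped]] = False
        active &= lengths > it + 1
    return DeviationCurve(mean=mean, min=mn, max=mx, n_active=n_active)


_ROW_LABELS = {
    1.0: "MRE",
    0.999: "MRE for top 99.9% of results",
    0.99: "MRE for top 99% of results",
    0.90: "MRE for top 90% of results",
    0.50: "MRE for top 50% of results",
}


def _retention_label(r: float) -> str:
    if r in _ROW_LABELS:
        return _ROW_LABELS[r]
    return f"MRE for top {100 * r:g}% of results"


@dataclass
class ComparisonTable:
    """Grid of :class:`ErrorSummary` for every (model, test set) pair."""

    model_labels: list[str]
    testset_labels: list[str]
    summaries: dict[tuple[str, str], ErrorSummary]
    retentions: tuple[float, ...]

    def columns(self) -> list[tuple[str, str]]:
        return [(m, t) for m, t in zip(self.model_labels, self.testset_labels)]

    def to_text(self) -> str:
        """Aligned human-readable table, one column per (model, test) pair."""
        cols = self.columns()
        rows: list[tuple[str, list[str]]] = [
            ("Training set", [m for m, _ in cols]),
            ("Testing set", [t for _, t in cols]),
            ("No. of compared velocities",
             [str(self.summaries[c].n_compared) for c in cols]),
            ("MRE", [f"{self.summaries[c].mre_full:.1f}" for c in cols]),
        ]
        for r in self.retentions:
            rows.append((
                _retention_label(r),
                [f"{self.summaries[c].mre_trimmed[r]:.1f}" for c in cols],
            ))
        label_w = max(len(lbl) for lbl, _ in rows)
        col_w = [
            max(len(rows[i][1][j]) for i in range(len(rows)))
            for j in range(len(cols))
        ]
        out = []
        for lbl, vals in rows:
            cells = "  ".join(v.rjust(col_w[j]) for j, v in enumerate(vals))
            out.append(f"{lbl.ljust(label_w)}  {cells}")
        return "\n".join(out) + "\n"

    def to_delimited(self) -> str:
        lines = ["model\ttestset\tn_compared\tmre_full\t"
                 + "\t".join(f"mre_top_{100 * r:g}pct" for r in self.retentions)]
        for c in self.columns():
            s = self.summaries[c]
            vals = [c[0], c[1], str(s.n_compared), f"{s.mre_full:.10g}"]
            vals += [f"{s.mre_trimmed[r]:.10g}" for r in self.retentions]
            lines.append("\t".join(vals))
        return "\n".join(lines) + "\n"


def cross_compare(
    models: Mapping[str, BasisSystem],
    testsets: Mapping[str, TrajectoryDataset],
    retentions: Sequence[float] = DEFAULT_RETENTIONS,
    trim_mode: str = "absolute",
    *,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> ComparisonTable:
    """Evaluate every requested (model, test set) pair.

    By default the full product of models and test sets is evaluated; pass
    ``pairs`` to restrict/order the columns (e.g. one trained channel against
    its held-out set and against perturbed-geometry sets).
    """
    if not models or not testsets:
        raise ValueError("need at least one model and one test set")
    if pairs is None:
        pairs = [(m, t) for m in models for t in testsets]
    summaries = {
        (m, t): local_error_summary(models[m], testsets[t], retentions, trim_mode)
        for m, t in pairs
    }
    return ComparisonTable(
        model_labels=[m for m, _ in pairs],
        testset_labels=[t for _, t in pairs],
        summaries=summaries,
        retentions=tuple(retentions),
    )
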