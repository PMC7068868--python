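"""The system-of-bases learner.

The model is a set of N six-component basis vectors, each pairing a reference
position ``a_i`` with a reference velocity ``b_i``. Similarity between a query
position x and basis i is a Gaussian radial kernel

    s_i(x) = exp(-k * ||x - a_i||^2),

with shape constant ``k > 0`` (larger k localizes each basis). The predicted
velocity is the convex combination of the velocity parts with the normalized
similarities as weights:

    y'(x) = sum_i s'_i(x) * b_i,   s'_i = s_i / sum_j s_j.

Training is unsupervised and online, one random sample (x, y) per iteration:
the position of the single most similar basis (the winner) moves toward x by a
learning rate eta (winner-take-all, Kohonen style; all other positions stay
put), and every velocity part takes a stochastic-gradient (LMS) step

    b_i <- b_i + eta * (y - y'(x)) * s'_i(x).

All randomness flows through numpy's PCG64 generator (``default_rng``), so a
seed fully determines initialization and the sample draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

FORMAT_VERSION = 1
_HEADER_PREFIX = "# flowbasis basis-system v"

#: if the similarity sum falls below this floor (query far outside the data
#: support, all kernels underflow) prediction falls back to the nearest basis.
SIMILARITY_SUM_FLOOR = 1e-300


class ModelFormatError(ValueError):
    """A model file is unreadable, truncated, or of an unsupported version."""


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


@dataclass
class TrainingLog:
    iterations: int = 0
    epochs: float = 0.0
    seed: int | None = None
    source: str = ""
    schedule: str = "interleaved"


@dataclass
class WeightVector:
    """Similarities of one query position to every basis.

    ``raw`` values lie in (0, 1]; ``normalized`` weights are non-negative and
    sum to 1; ``winner_index`` attains the maximum of ``raw`` (ties broken by
    lowest index).
    """

    raw: np.ndarray
    normalized: np.ndarray
    winner_index: int


@dataclass
class BasisSystem:
    """N basis vectors (positions ``a``, velocities ``b``) plus hyperparameters."""

    positions: np.ndarray
    velocities: np.ndarray
    shape_constant: float
    learning_rate: float
    training_log: TrainingLog = field(default_factory=TrainingLog)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        self.validate()

    @property
    def n_bases(self) -> int:
        return len(self.positions)

    @property
    def bounding_box(self) -> np.ndarray:
        """[min; max] corners of the basis positions."""
        return np.vstack([self.positions.min(axis=0), self.positions.max(axis=0)])

    def validate(self) -> None:
        if self.n_bases < 1:
            raise ValueError("a basis system needs at least one basis")
        if len(self.velocities) != self.n_bases:
            raise ValueError("positions and velocities must have equal length")
        if not (np.isfinite(self.positions).all() and np.isfinite(self.velocities).all()):
            raise ValueError("basis components must be finite")
        if not self.shape_constant > 0:
            raise ValueError(f"shape_constant must be > 0, got {self.shape_constant}")
        if not 0 < self.learning_rate < 1:
            raise ValueError(f"learning_rate must be in (0, 1), got {self.learning_rate}")


def _as_xy(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, tuple) and len(pairs) == 2:
        x, y = pairs
        x = np.asarray(x, dtype=float).reshape(-1, 3)
        y = np.asarray(y, dtype=float).reshape(-1, 3)
    else:
        arr = np.asarray([(p, v) for p, v in pairs], dtype=float)
        x = arr[:, 0, :].reshape(-1, 3) if len(arr) else np.empty((0, 3))
        y = arr[:, 1, :].reshape(-1, 3) if len(arr) else np.empty((0, 3))
    if len(x) != len(y):
        raise ValueError("positions and velocities must pair up")
    return x, y


def init_bases(
    pairs, n_bases: int, seed: int, *, k: float = 1.0, eta: float = 0.1,
    source: str = "",
) -> BasisSystem:
    """Initialize a basis system from ``n_bases`` distinct training samples.

    Sampling is without replacement via ``default_rng(seed).choice``; the same
    seed always yields the same system.
    """
    x, y = _as_xy(pairs)
    if n_bases > len(x):
        raise ValueError(
            f"n_bases={n_bases} exceeds the {len(x)} available training pairs"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(x), size=n_bases, replace=False)
    return BasisSystem(
        positions=x[idx].copy(),
        velocities=y[idx].copy(),
        shape_constant=k,
        learning_rate=eta,
        training_log=TrainingLog(seed=seed, source=source),
    )


def similarities(model: BasisSystem, x) -> WeightVector:
    """Raw and normalized Gaussian similarities of ``x`` to every basis."""
    x = np.asarray(x, dtype=float).reshape(3)
    d = model.positions - x
    dist2 = np.einsum("ij,ij->i", d, d)
    raw = np.exp(-model.shape_constant * dist2)
    winner = int(np.argmin(dist2))  # == argmax(raw); lowest index on ties
    total = raw.sum()
    if total < SIMILARITY_SUM_FLOOR:
        normalized = np.zeros(model.n_bases)
        normalized[winner] = 1.0
    else:
        normalized = raw / total
    return WeightVector(raw=raw, normalized=normalized, winner_index=winner)


def predict_velocity(model: BasisSystem, x) -> np.ndarray:
    """Predicted velocity at ``x``: convex combination of basis velocities."""
    w = similarities(model, x)
    return w.normalized @ model.velocities


def predict_velocities(
    model: BasisSystem, points, *, chunk: int = 4096
) -> np.ndarray:
    """Vectorized :func:`predict_velocity` over an (M, 3) array of queries."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    out = np.empty_like(pts)
    a = model.positions
    k = model.shape_constant
    for start in range(0, len(pts), chunk):
        block = pts[start:start + chunk]
        d2 = (
            np.einsum("ij,ij->i", block, block)[:, None]
            - 2.0 * block @ a.T
            + np.einsum("ij,ij->i", a, a)[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        raw = np.exp(-k * d2)
        total = raw.sum(axis=1)
        low = total < SIMILARITY_SUM_FLOOR
        if low.any():
            nearest = np.argmin(d2[low], axis=1)
            raw[low] = 0.0
            raw[np.nonzero(low)[0], nearest] = 1.0
            total[low] = 1.0
        out[start:start + chunk] = (raw / total[:, None]) @ model.velocities
    return out


def update_winner_position(model: BasisSystem, x) -> BasisSystem:
    """Move the winning basis position toward ``x`` by the learning rate.

    Only the single most similar basis moves; every other position and all
    velocity parts are untouched. Modifies ``model`` in place and returns it.
    """
    x = np.asarray(x, dtype=float).reshape(3)
    w = similarities(model, x)
    eta = model.learning_rate
    model.positions[w.winner_index] += eta * (x - model.positions[w.winner_index])
    return model


def update_velocities(model: BasisSystem, x, y) -> BasisSystem:
    """One LMS step of every basis velocity toward reproducing ``y`` at ``x``.

    The shared residual is ``E = y - y'(x)``; basis i takes the step
    ``eta * E * s'_i(x)``. Positions are untouched. In-place; returns ``model``.
    """
    x = np.asarray(x, dtype=float).reshape(3)
    y = np.asarray(y, dtype=float).reshape(3)
    w = similarities(model, x)
    residual = y - w.normalized @ model.velocities
    model.velocities += model.learning_rate * np.outer(w.normalized, residual)
    return model


def train(
    pairs,
    n_bases: int,
    k: float,
    eta: float,
    n_iterations: int,
    seed: int,
    *,
    schedule: str = "interleaved",
    phase_split: float = 0.5,
    source: str = "",
) -> BasisSystem:
    """Train a basis system on (position, velocity) pairs.

    Initialization samples ``n_bases`` pairs without replacement; each of the
    ``n_iterations`` online steps then draws one pair uniformly with
    replacement and applies the winner-position update followed by the
    velocity LMS update on the same sample (``schedule="interleaved"``, the
    default). ``schedule="two_phase"`` instead spends the first
    ``phase_split`` fraction of iterations on position updates only and the
    remainder on velocity updates only. Deterministic given ``seed``.
    """
    if schedule not in ("interleaved", "two_phase"):
        raise ValueError(f"unknown schedule {schedule!r}")
    x, y = _as_xy(pairs)
    if len(x) == 0:
        raise ValueError("training requires at least one (x, y) pair")
    model = init_bases((x, y), n_bases, seed, k=k, eta=eta, source=source)
    a = model.positions
    b = model.velocities
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    draws = rng.integers(0, len(x), size=n_iterations)
    n_pos = n_iterations if schedule == "interleaved" else int(round(phase_split * n_iterations))
    floor = SIMILARITY_SUM_FLOOR
    for t in range(n_iterations):
        j = draws[t]
        xs = x[j]
        ys = y[j]
        d = a - xs
        dist2 = np.einsum("ij,ij->i", d, d)
        w = np.argmin(dist2)
        do_pos = (schedule == "interleaved") or (t < n_pos)
        do_vel = (schedule == "interleaved") or (t >= n_pos)
        if do_pos:
            a[w] += eta * (xs - a[w])
            if do_vel:
                dw = a[w] - xs
                dist2[w] = dw @ dw
        if do_vel:
            s = np.exp(-k * dist2)
            total = s.sum()
            if total < floor:
                sp = np.zeros(len(s))
                sp[np.argmin(dist2)] = 1.0
            else:
                sp = s / total
            residual = ys - sp @ b
            b += eta * sp[:, None] * residual[None, :]
    model.training_log = TrainingLog(
        iterations=n_iterations,
        epochs=n_iterations / len(x),
        seed=seed,
        source=source,
        schedule=schedule,
    )
    return model


def save_model(model: BasisSystem, path) -> None:
    """Write a basis system as versioned, full-precision text."""
    log = model.training_log
    lines = [
        f"{_HEADER_PREFIX}{FORMAT_VERSION}",
        f"# n_bases: {model.n_bases}",
        f"# k: {_fmt(model.shape_constant)}",
        f"# eta: {_fmt(model.learning_rate)}",
        f"# iterations: {log.iterations}",
        f"# epochs: {_fmt(log.epochs)}",
        f"# seed: {'none' if log.seed is None else log.seed}",
        f"# schedule: {log.schedule}",
        f"# source: {log.source}",
        "# columns: a1 a2 a3 b1 b2 b3",
    ]
    for i in range(model.n_bases):
        row = (*model.positions[i], *model.velocities[i])
        lines.append(" ".join(_fmt(v) for v in row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> BasisSystem:
    """Read a model written by :func:`save_model`. Round-trips exactly."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(_HEADER_PREFIX):
        raise ModelFormatError(f"{path}: not a flowbasis basis-system file")
    version = lines[0][len(_HEADER_PREFIX):].strip()
    if version != str(FORMAT_VERSION):
        raise ModelFormatError(
            f"{path}: unsupported format version {version} (expected {FORMAT_VERSION})"
        )
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            key, _, val = ln[1:].partition(":")
            meta[key.strip()] = val.strip()
        else:
            parts = ln.split()
            if len(parts) != 6:
                raise ModelFormatError(f"{path}: malformed basis row {ln!r}")
            rows.append([float(v) for v in parts])
    n = int(meta["n_bases"])
    if len(rows) != n:
        raise ModelFormatError(
            f"{path}: truncated model file ({len(rows)} rows, expected {n})"
        )
    arr = np.asarray(rows, dtype=float).reshape(n, 6)
    seed_s = meta.get("seed", "none")
    return BasisSystem(
        positions=arr[:, :3],
        velocities=arr[:, 3:],
        shape_constant=float(meta["k"]),
        learning_rate=float(meta["eta"]),
        training_log=TrainingLog(
            iterations=int(meta.get("iterations", 0)),
            epochs=float(meta.get("epochs", 0.0)),
            seed=None if seed_s == "none" else int(seed_s),
            source=meta.get("source", ""),
            schedule=meta.get("schedule", "interleaved"),
        ),
    )
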