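"""Synthetic channel flows and advected cell trajectories.

These fixtures emulate the structure of cell-resolved channel-flow
simulations at desk scale, replacing the lattice-Boltzmann/immersed-boundary
machinery with analytic and grid-solved steady fields:

* ``plane_slit`` — flow between two plates a few length units apart (the flat
  slit channel, default 126 x 44 x 3.5): the classical parabolic profile
  u(z) = f z (h - z) / (2 rho nu), uniform in x and y.
* ``box_duct`` — fully developed laminar flow in a rectangular duct with four
  no-slip walls (the open box channel, default 100 x 40 x 40): the classical
  Fourier-series solution, truncated at a configurable number of odd modes.
* ``slit_obstacle_channel`` — the flat channel with obstacle strips forming
  slits: a depth-averaged (Hele-Shaw style) in-plane flow obtained by
  relaxing the streamfunction Laplace problem on the mid-plane (periodic in
  x, constant streamfunction on walls and obstacles), then extruded in z
  with the parabolic plane profile normalized to the open inlet.

Cells are massless points seeded uniformly in fluid space (with a wall margin
reflecting their finite thickness) and advected with RK4 through
``lag_factor * field``; their centers are recorded every snapshot, with the
recorded velocity taken as the finite difference of consecutive positions.
Optional zero-mean Gaussian noise on the recorded velocities emulates the
outlier-like membrane-oscillation fluctuations of a deformable cell model; a
"stiff-cell" variant halts cells at the entry of slits narrower than a
threshold, emulating rigid cells that cannot squeeze through and block them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
import numpy as np

from .streamline_baseline import LatticeVelocityField, interpolate_velocity
from .trajectory_data import TrajectoryDataset, split_periodic_passages

#: default channel-A-like slit layout, bottom -> top along y (widths in length
#: units). Slits alternate with obstacle strips; the widths sum to the channel
#: width. Removing the middle obstacle merges 5.8 + 5.3 + 4.7 = 15.8 into one
#: free corridor; the wide 10.0 slit sits at the top.
CHANNEL_A_SLITS = (4.0, 5.8, 4.7, 10.0)
CHANNEL_A_OBSTACLES = (7.1, 5.3, 7.1)
#: x-extent of the obstacle strips in the default layout.
CHANNEL_A_OBSTACLE_X = (55.0, 71.0)

GEOMETRIES = ("plane_slit", "box_duct", "slit_obstacle_channel")


@dataclass
class FlowFixtureSpec:
    """Parameters of one synthetic channel and its trajectory recording.

    Defaults follow the flat slit channel: 126 x 44 x 3.5 length units, force
    density 6e-4, kinematic viscosity 1.5, density 1 (the box duct uses
    100 x 40 x 40 with force density 1e-4). ``lag_factor`` scales the carrier
    field to emulate cells traveling slower than the fluid; ``noise_sd`` is
    the standard deviation of the Gaussian perturbation added to recorded
    velocities; ``stiff_threshold`` (a slit width) enables the stiff-cell
    variant. ``seed_margin`` keeps cell centers away from walls by half a
    cell thickness.
    """

    geometry: str = "plane_slit"
    dimensions: tuple[float, float, float] = (126.0, 44.0, 3.5)
    force_density: float = 6e-4
    kinematic_viscosity: float = 1.5
    density: float = 1.0
    slits: tuple[float, ...] = CHANNEL_A_SLITS
    obstacle_widths: tuple[float, ...] = CHANNEL_A_OBSTACLES
    obstacle_x: tuple[float, float] = CHANNEL_A_OBSTACLE_X
    n_cells: int = 50
    n_snapshots: int = 500
    noise_sd: float = 0.0
    lag_factor: float = 1.0
    seed: int = 0
    seed_margin: float = 1.15
    snapshot_stride: float = 100.0
    rk4_substeps: int = 10
    stiff_threshold: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}")
        if min(self.dimensions) <= 0:
            raise ValueError("dimensions must be positive")
        if self.kinematic_viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")
        if not 0 < self.lag_factor <= 1:
            raise ValueError(f"lag_factor must be in (0, 1], got {self.lag_factor}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.obstacle_widths) != len(self.slits) - 1:
            raise ValueError("need exactly one obstacle strip between consecutive slits")

    def slit_intervals(self) -> list[tuple[float, float]]:
        """(y_low, y_high) of each slit opening, bottom -> top."""
        out = []
        y = 0.0
        for i, w in enumerate(self.slits):
            out.append((y, y + w))
            y += w
            if i < len(self.obstacle_widths):
                y += self.obstacle_widths[i]
        return out

    def obstacle_intervals(self) -> list[tuple[float, float]]:
        """(y_low, y_high) of each obstacle strip, bottom -> top."""
        out = []
        y = 0.0
        for i, w in enumerate(self.slits):
            y += w
            if i < len(self.obstacle_widths):
                out.append((y, y + self.obstacle_widths[i]))
                y += self.obstacle_widths[i]
        return out


def remove_middle_obstacle(spec: FlowFixtureSpec) -> FlowFixtureSpec:
    """Geometry variant with the middle obstacle strip removed.

    The two slits around it merge with the freed strip into one wide corridor
    (with the default layout: 5.8 + 5.3 + 4.7 = 15.8 length units).
    """
    n = len(spec.obstacle_widths)
    if n == 0:
        raise ValueError("no obstacles to remove")
    mid = n // 2
    slits = list(spec.slits)
    obstacles = list(spec.obstacle_widths)
    merged = slits[mid] + obstacles[mid] + slits[mid + 1]
    new_slits = slits[:mid] + [merged] + slits[mid + 2:]
    new_obstacles = obstacles[:mid] + obstacles[mid + 1:]
    return dataclasses.replace(
        spec, slits=tuple(new_slits), obstacle_widths=tuple(new_obstacles)
    )


def channel_a_spec(**overrides) -> FlowFixtureSpec:
    """Flat slit channel with obstacles: 126 x 44 x 3.5, force density 6e-4."""
    base = dict(
        geometry="slit_obstacle_channel",
        dimensions=(126.0, 44.0, 3.5),
        force_density=6e-4,
        label="slitA",
    )
    base.update(overrides)
    return FlowFixtureSpec(**base)


def channel_b_spec(**overrides) -> FlowFixtureSpec:
    """Open box duct: 100 x 40 x 40, force density 1e-4."""
    base = dict(
        geometry="box_duct",
        dimensions=(100.0, 40.0, 40.0),
        force_density=1e-4,
        label="ductB",
    )
    base.update(overrides)
    return FlowFixtureSpec(**base)


def plane_slit_spec(**overrides) -> FlowFixtureSpec:
    """Obstacle-free flat slit: 126 x 44 x 3.5, force density 6e-4."""
    base = dict(
        geometry="plane_slit",
        dimensions=(126.0, 44.0, 3.5),
        force_density=6e-4,
        label="planeA",
    )
    base.update(overrides)
    return FlowFixtureSpec(**base)


# --------------------------------------------------------------------------
# analytic profiles


def plane_poiseuille_profile(z, h: float, f: float, rho: float, nu: float):
    """u_x(z) = f z (h - z) / (2 rho nu) between plates at z = 0 and z = h."""
    z = np.asarray(z, dtype=float)
    return np.where((z < 0) | (z > h), 0.0, f * z * (h - z) / (2.0 * rho * nu))


def plane_poiseuille_umax(spec: FlowFixtureSpec) -> float:
    """Closed-form mid-gap maximum f h^2 / (8 rho nu)."""
    h = spec.dimensions[2]
    return spec.force_density * h * h / (
        8.0 * spec.density * spec.kinematic_viscosity
    )


def duct_profile(y, z, width: float, height: float, f: float, rho: float,
                 nu: float, n_terms: int = 50):
    """Series solution of laminar flow in a rectangular duct (no-slip walls).

    ``y`` in [0, width], ``z`` in [0, height]; the series runs over odd modes
    along y and converges rapidly (each term decays like 1/n^3).
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    a = width / 2.0
    b = height / 2.0
    yc = y - a
    zc = z - b
    u = np.zeros(np.broadcast(yc, zc).shape)
    for m in range(n_terms):
        n = 2 * m + 1
        beta = n * np.pi / (2.0 * a)
        u = u + ((-1.0) ** m / n**3) * (
            1.0 - np.cosh(beta * zc) / np.cosh(beta * b)
        ) * np.cos(beta * yc)
    return (16.0 * a * a * f / (rho * nu * np.pi**3)) * u


# --------------------------------------------------------------------------
# Poisson relaxation (shared by the slit channel and the duct cross-check)


def solve_poisson_2d(
    fluid_mask: np.ndarray,
    source: float,
    spacing: float = 1.0,
    *,
    periodic_x: bool = False,
    tol: float = 1e-10,
    max_iter: int = 200_000,
    omega: float | None = None,
    fixed: np.ndarray | None = None,
) -> tuple[np.ndarray, float, int]:
    """Solve  -laplace(u) = source  on the fluid nodes.

    Non-fluid nodes hold the Dirichlet values given by ``fixed`` (zero when
    omitted). Red/black successive over-relaxation, vectorized; the first
    array axis may be periodic. Convergence is declared when the largest
    nodal update in one full sweep drops below ``tol``. Returns
    ``(u, last_max_update, sweeps)`` and raises ``RuntimeError`` when
    ``max_iter`` sweeps do not converge.
    """
    nx, ny = fluid_mask.shape
    if omega is None:
        omega = 2.0 / (1.0 + np.sin(np.pi / max(nx, ny)))
    if periodic_x and nx % 2 == 1:
        omega = 1.0  # checkerboard coloring is inconsistent across an odd wrap
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    colors = [((ii + jj) % 2 == c) & fluid_mask for c in (0, 1)]
    u = np.zeros((nx, ny))
    if fixed is not None:
        u[~fluid_mask] = fixed[~fluid_mask]
    h2s = spacing * spacing * source

    def neighbor_sum(u):
        s = np.zeros_like(u)
        if periodic_x:
            s += np.roll(u, 1, axis=0) + np.roll(u, -1, axis=0)
        else:
            s[1:, :] += u[:-1, :]
            s[:-1, :] += u[1:, :]
        s[:, 1:] += u[:, :-1]
        s[:, :-1] += u[:, 1:]
        return s

    for sweep in range(1, max_iter + 1):
        max_update = 0.0
        for color in colors:
            s = neighbor_sum(u)
            new = (1.0 - omega) * u + (omega / 4.0) * (s + h2s)
            delta = np.abs(new[color] - u[color])
            if len(delta):
                max_update = max(max_update, float(delta.max()))
            u[color] = new[color]
        if max_update < tol:
            return u, max_update, sweep
    raise RuntimeError(
        f"Poisson relaxation did not converge in {max_iter} sweeps "
        f"(last max update {max_update:.3e} > tol {tol:.3e})"
    )


# --------------------------------------------------------------------------
# field builders


def _grid_axes(spec: FlowFixtureSpec) -> tuple[int, int, int]:
    lx, ly, lz = spec.dimensions
    return int(np.ceil(lx)) + 1, int(np.ceil(ly)) + 1, int(np.ceil(lz)) + 1


def plane_poiseuille_field(spec: FlowFixtureSpec) -> LatticeVelocityField:
    """Sample the plane-Poiseuille profile onto the unit grid.

    The slit is idealized as infinite plates: only the z = 0 plane and nodes
    at or beyond z = h are solid; there are no side walls.
    """
    if spec.geometry != "plane_slit":
        raise ValueError("plane_poiseuille_field requires geometry='plane_slit'")
    nx, ny, nz = _grid_axes(spec)
    h = spec.dimensions[2]
    zs = np.arange(nz, dtype=float)
    prof = plane_poiseuille_profile(
        zs, h, spec.force_density, spec.density, spec.kinematic_viscosity
    )
    vel = np.zeros((nx, ny, nz, 3))
    vel[:, :, :, 0] = prof[None, None, :]
    solid = np.zeros((nx, ny, nz), dtype=bool)
    solid[:, :, zs <= 0] = True
    solid[:, :, zs >= h] = True
    vel[solid] = 0.0
    return LatticeVelocityField(
        origin=np.zeros(3), velocities=vel, solid_mask=solid,
        meta={"geometry": "plane_slit", "force_density": spec.force_density},
    )


def duct_flow_field(spec: FlowFixtureSpec, n_terms: int = 50) -> LatticeVelocityField:
    """Sample the rectangular-duct series solution onto the unit grid."""
    if spec.geometry != "box_duct":
        raise ValueError("duct_flow_field requires geometry='box_duct'")
    if n_terms < 10:
        raise ValueError("n_terms must be at least 10")
    nx, ny, nz = _grid_axes(spec)
    _, w, h = spec.dimensions
    ys = np.arange(ny, dtype=float)
    zs = np.arange(nz, dtype=float)
    u = duct_profile(
        ys[:, None], zs[None, :], w, h,
        spec.force_density, spec.density, spec.kinematic_viscosity, n_terms,
    )
    solid2d = (ys[:, None] <= 0) | (ys[:, None] >= w) | (zs[None, :] <= 0) | (zs[None, :] >= h)
    u = np.where(solid2d, 0.0, u)
    vel = np.zeros((nx, ny, nz, 3))
    vel[:, :, :, 0] = u[None, :, :]
    solid = np.broadcast_to(solid2d[None, :, :], (nx, ny, nz)).copy()
    return LatticeVelocityField(
        origin=np.zeros(3), velocities=vel, solid_mask=solid,
        meta={"geometry": "box_duct", "n_terms": n_terms},
    )


def slit_obstacle_field(
    spec: FlowFixtureSpec, solver_tol: float = 1e-9
) -> LatticeVelocityField:
    """Grid-solved steady flow for the flat channel with obstacle slits.

    The in-plane flow is treated the way depth-averaged (Hele-Shaw) flow in a
    thin gap behaves: a streamfunction psi solves the Laplace equation on the
    (x, y) mid-plane (periodic in x) with constant Dirichlet values on the
    walls (0 and 1) and on each obstacle (its upstream flux allocation), so
    the in-plane field (u, v) = (dpsi/dy, -dpsi/dx) is divergence-free,
    streamlines never enter the obstacles, and each slit carries the flux
    squeezed between its bounding obstacle values — every cross-section
    carries the same total flux (the continuity requirement holds by
    construction, well within the 2% contract). The in-plane field,
    normalized to the open inlet column, is extruded in z with the parabolic
    plane-Poiseuille profile: without obstacles the construction degenerates
    exactly to the plane-slit solution. In-plane obstacle boundaries are
    free-slip (the no-slip z-confinement dominates a thin channel); solid
    nodes still carry zero velocity.
    """
    if spec.geometry != "slit_obstacle_channel":
        raise ValueError("slit_obstacle_field requires geometry='slit_obstacle_channel'")
    lx, ly, h = spec.dimensions
    nx = int(round(lx))           # periodic x: node lx duplicates node 0
    ny = int(np.ceil(ly)) + 1
    nz = int(np.ceil(h)) + 1
    xs = np.arange(nx, dtype=float)
    ys = np.arange(ny, dtype=float)
    fluid = np.ones((nx, ny), dtype=bool)
    fluid[:, ys <= 0] = False
    fluid[:, ys >= ly] = False
    x0, x1 = spec.obstacle_x
    in_x = (xs >= x0) & (xs <= x1)
    psi_fixed = np.zeros((nx, ny))
    psi_fixed[:, ys >= ly] = 1.0
    # flux allocation: in a depth-limited gap every slit has in-plane
    # resistance inversely proportional to its width, so the slits share the
    # total flux in proportion to their widths — removing an obstacle hands
    # the merged corridor the combined (larger) share and redistributes the
    # approach flow globally
    total_w = sum(spec.slits)
    if total_w <= 0:
        raise ValueError("an obstacle blocks an entire cross-section; no through-flow")
    below = np.cumsum(spec.slits)
    for k, (y0, y1) in enumerate(spec.obstacle_intervals()):
        in_y = (ys >= y0) & (ys <= y1)
        fluid[np.ix_(in_x, in_y)] = False
        psi_fixed[np.ix_(in_x, in_y)] = below[k] / total_w
    if (~fluid).all(axis=1).any():
        raise ValueError("an obstacle blocks an entire cross-section; no through-flow")
    psi, residual, sweeps = solve_poisson_2d(
        fluid, 0.0, periodic_x=True, tol=solver_tol, fixed=psi_fixed
    )
    ux = np.gradient(psi, axis=1)
    vy = -(np.roll(psi, -1, axis=0) - np.roll(psi, 1, axis=0)) / 2.0
    # in-plane correction: the centered-difference node sum misses the
    # boundary half-cells next to walls and obstacles, so rescale every
    # contiguous fluid run of each column to carry exactly the
    # streamfunction flux through it; column fluxes then telescope to the
    # same total everywhere (the discrete continuity proxy becomes exact)
    for i in range(nx):
        col_fluid = fluid[i]
        j = 1
        while j < ny:
            if not col_fluid[j]:
                j += 1
                continue
            j0 = j
            while j < ny and col_fluid[j]:
                j += 1
            j1 = j - 1
            target = psi[i, min(j1 + 1, ny - 1)] - psi[i, j0 - 1]
            current = ux[i, j0:j1 + 1].sum()
            if current > 0 and target > 0:
                ux[i, j0:j1 + 1] *= target / current
    scale = ux[0].max()
    shape_x = ux / scale
    shape_y = vy / scale
    zs = np.arange(nz, dtype=float)
    prof = plane_poiseuille_profile(
        zs, h, spec.force_density, spec.density, spec.kinematic_viscosity
    )
    vel = np.zeros((nx + 1, ny, nz, 3))
    vel[:nx, :, :, 0] = shape_x[:, :, None] * prof[None, None, :]
    vel[:nx, :, :, 1] = shape_y[:, :, None] * prof[None, None, :]
    vel[nx] = vel[0]
    solid = np.zeros((nx + 1, ny, nz), dtype=bool)
    solid[:, ys <= 0, :] = True
    solid[:, ys >= ly, :] = True
    solid[:, :, (zs <= 0) | (zs >= h)] = True
    solid2d = np.concatenate([~fluid, [~fluid[0]]], axis=0)
    solid |= solid2d[:, :, None]
    vel[solid] = 0.0
    return LatticeVelocityField(
        origin=np.zeros(3), velocities=vel, solid_mask=solid,
        meta={
            "geometry": "slit_obstacle_channel",
            "solver_residual": residual,
            "solver_sweeps": sweeps,
        },
    )


def make_field(spec: FlowFixtureSpec, **kwargs) -> LatticeVelocityField:
    """Dispatch to the field builder matching ``spec.geometry``."""
    builder = {
        "plane_slit": plane_poiseuille_field,
        "box_duct": duct_flow_field,
        "slit_obstacle_channel": slit_obstacle_field,
    }[spec.geometry]
    return builder(spec, **kwargs)


# --------------------------------------------------------------------------
# trajectory generation


def _fluid_point(field: LatticeVelocityField, pts: np.ndarray) -> np.ndarray:
    """True where all 8 grid-cell corners around each point are fluid."""
    lo = np.floor(pts - field.origin).astype(int)
    nx, ny, nz = field.shape
    lo = np.clip(lo, 0, [nx - 2, ny - 2, nz - 2])
    ok = np.ones(len(pts), dtype=bool)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ok &= ~field.solid_mask[lo[:, 0] + dx, lo[:, 1] + dy, lo[:, 2] + dz]
    return ok


def _fluid_corner(field: LatticeVelocityField, pts: np.ndarray) -> np.ndarray:
    """True where at least one grid-cell corner around each point is fluid."""
    lo = np.floor(pts - field.origin).astype(int)
    nx, ny, nz = field.shape
    lo = np.clip(lo, 0, [nx - 2, ny - 2, nz - 2])
    any_fluid = np.zeros(len(pts), dtype=bool)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                any_fluid |= ~field.solid_mask[
                    lo[:, 0] + dx, lo[:, 1] + dy, lo[:, 2] + dz
                ]
    return any_fluid


def _seed_cells(field: LatticeVelocityField, spec: FlowFixtureSpec,
                rng: np.random.Generator) -> np.ndarray:
    lx, ly, h = spec.dimensions
    m = spec.seed_margin
    lo = np.array([0.0, m, m])
    hi = np.array([lx, ly - m, h - m])
    hi = np.minimum(hi, field.upper_corner)  # stay interpolable
    if spec.geometry == "plane_slit":
        lo[1], hi[1] = 0.0, min(ly, field.upper_corner[1])  # no side walls
    if (hi <= lo).any():
        raise ValueError("no fluid space to seed cells in (margin too large?)")
    out = np.empty((spec.n_cells, 3))
    filled = 0
    for _ in range(1000):
        need = spec.n_cells - filled
        if need == 0:
            break
        cand = lo + rng.random((max(need * 2, 16), 3)) * (hi - lo)
        good = cand[_fluid_point(field, cand)][:need]
        out[filled:filled + len(good)] = good
        filled += len(good)
    if filled < spec.n_cells:
        raise ValueError("could not seed cells in fluid space")
    return out


def generate_trajectories(
    field: LatticeVelocityField, spec: FlowFixtureSpec
) -> TrajectoryDataset:
    """Advect seeded cells through the field and record snapshot trajectories.

    Integration is RK4 with ``spec.rk4_substeps`` sub-steps per snapshot of
    duration ``spec.snapshot_stride`` (in the field's time unit), through the
    velocity field scaled by ``lag_factor``. The channel is periodic in x.
    Recorded velocities are finite differences of (unwrapped) consecutive
    positions, optionally perturbed by Gaussian noise; passages through the
    periodic boundary are split into separate trajectories.
    """
    if spec.n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    if spec.n_snapshots < 2:
        raise ValueError("n_snapshots must be at least 2")
    rng = np.random.default_rng(spec.seed)
    period = float(field.upper_corner[0] - field.origin[0])
    x = _seed_cells(field, spec, rng)

    halted = np.zeros(spec.n_cells, dtype=bool)
    narrow = []
    if spec.stiff_threshold is not None and spec.geometry == "slit_obstacle_channel":
        narrow = [
            (y0, y1) for (y0, y1), w in zip(spec.slit_intervals(), spec.slits)
            if w < spec.stiff_threshold
        ]

    def rhs(pos: np.ndarray) -> np.ndarray:
        q = pos.copy()
        q[:, 0] = field.origin[0] + np.mod(q[:, 0] - field.origin[0], period)
        return spec.lag_factor * interpolate_velocity(field, q)

    # n_snapshots records need n_snapshots + 1 positions (forward differences)
    traj = np.empty((spec.n_snapshots + 1, spec.n_cells, 3))
    traj[0] = x
    dt = spec.snapshot_stride / spec.rk4_substeps
    for n in range(1, spec.n_snapshots + 1):
        cur = traj[n - 1].copy()
        for _ in range(spec.rk4_substeps):
            k1 = rhs(cur)
            k2 = rhs(cur + 0.5 * dt * k1)
            k3 = rhs(cur + 0.5 * dt * k2)
            k4 = rhs(cur + dt * k3)
            nxt = cur + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            nxt[halted] = cur[halted]  # stuck cells stay put
            # no-penetration guard: the interpolated boundary is fuzzy between
            # nodes, so a cell creeping along an obstacle face could otherwise
            # slip into a fully solid grid cell and freeze there
            wrapped_nxt = nxt.copy()
            wrapped_nxt[:, 0] = field.origin[0] + np.mod(
                wrapped_nxt[:, 0] - field.origin[0], period
            )
            inside = ~_fluid_corner(field, wrapped_nxt)
            nxt[inside] = cur[inside]
            if narrow:
                x_entry = spec.obstacle_x[0]
                wrapped = np.mod(cur[:, 0] - field.origin[0], period) + field.origin[0]
                entering = (wrapped <= x_entry) & (
                    np.mod(nxt[:, 0] - field.origin[0], period) + field.origin[0] > x_entry
                )
                in_narrow = np.zeros(spec.n_cells, dtype=bool)
                for y0, y1 in narrow:
                    in_narrow |= (cur[:, 1] >= y0) & (cur[:, 1] <= y1)
                newly = entering & in_narrow & ~halted
                # halt at the slit entry, keeping the in-plane coordinates
                nxt[newly, 0] = cur[newly, 0] + (x_entry - wrapped[newly]).clip(min=0.0)
                nxt[newly, 1:] = cur[newly, 1:]
                halted |= newly
            cur = nxt
        traj[n] = cur

    vel = np.diff(traj, axis=0)  # displacement per snapshot, unwrapped
    if spec.noise_sd > 0:
        vel = vel + rng.normal(0.0, spec.noise_sd, size=vel.shape)
    pos = traj[:-1].copy()
    pos[:, :, 0] = field.origin[0] + np.mod(pos[:, :, 0] - field.origin[0], period)

    n_rec = spec.n_cells * spec.n_snapshots
    cell_ids = np.empty(n_rec, dtype=object)
    steps = np.empty(n_rec, dtype=np.int64)
    for c in range(spec.n_cells):
        sl = slice(c * spec.n_snapshots, (c + 1) * spec.n_snapshots)
        cell_ids[sl] = f"c{c:04d}"
        steps[sl] = np.arange(spec.n_snapshots)
    positions = pos.transpose(1, 0, 2).reshape(n_rec, 3)
    velocities = vel.transpose(1, 0, 2).reshape(n_rec, 3)
    bbox = np.vstack([field.origin, field.upper_corner])
    ds = TrajectoryDataset(
        cell_ids=cell_ids, steps=steps, positions=positions, velocities=velocities,
        bounding_box=bbox, channel_id=spec.label or spec.geometry,
        snapshot_interval=spec.snapshot_stride,
    )
    return split_periodic_passages(ds, axis=0, period=period)
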