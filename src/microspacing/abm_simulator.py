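"""Hybrid particle / reaction–diffusion model of microglial spacing.

Off-lattice cells move by (i) chemotaxis up the extracellular ATP gradient,
(ii) pairwise linear contact repulsion ``f(r) = k (sigma - r)`` for
``r < sigma``, and (iii) a persistent random walk at constant speed ``v``
with heading re-randomised at Poisson rate ``2/tau`` (see
:mod:`microspacing.trackstats` for why the tumble rate is ``2/tau``).
The ATP field obeys

    da/dt = p_atp - h a - b * sum_i delta(r_i) + d_a Laplacian(a),

solved on a regular grid by explicit (forward-Euler, 5-point Laplacian)
finite differences; each cell's uptake ``b`` is removed from the grid node
nearest the cell, and the field is clamped at zero.

Scenarios: a homogeneous periodic tissue (``run``) and a wound
(``wound_scenario``) in which one domain edge is held at a high ATP
concentration ``a_w`` and cells accumulate against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .pointstats import PointPattern, hsi

__all__ = [
    "ModelParams",
    "NumericsConfig",
    "CellState",
    "ATPField",
    "SimResult",
    "repulsion_force",
    "gradient_at",
    "atp_step",
    "cell_step",
    "run",
    "wound_scenario",
    "PRESETS",
    "apply_preset",
]


@dataclass(frozen=True)
class ModelParams:
    """Biophysical parameters of the cell/ATP model.

    Defaults are the measured/estimated values for retinal microglia:
    chemotactic coefficient ``c`` (µm² µM⁻¹ min⁻¹), persistence ``tau``
    (min), speed ``v`` (µm/min), ATP production ``p_atp`` (µM/min), decay
    ``h`` (/min), per-cell uptake ``b`` (µM/min per microglia, removed from
    the containing grid cell), diffusion ``d_a`` (µm²/min), repulsive radius
    ``sigma`` (µm), repulsive strength ``k`` (/min) and wound ATP level
    ``a_w`` (µM).
    """

    c: float = 18.0
    tau: float = 7.7
    v: float = 0.88
    p_atp: float = 1.7e-3
    h: float = 0.2
    b: float = 9.5e-4
    d_a: float = 180.0
    sigma: float = 45.0
    k: float = 0.1
    a_w: float = 25.0

    def __post_init__(self) -> None:
        for name in ("c", "tau", "v", "p_atp", "h", "b", "d_a", "k", "a_w"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class NumericsConfig:
    """Numerical settings: domain (µm), grid spacing, time step, boundary.

    ``dt=None`` selects ``min(0.9 dx²/(4 d_a), 0.01/k, tau/50)`` — the
    explicit-diffusion stability bound with a safety factor, a repulsion
    resolution bound, and a tumbling resolution bound.
    """

    domain: tuple[float, float] = (400.0, 400.0)
    dx: float = 5.0
    dt: float | None = None
    boundary: str = "periodic"  # periodic | no-flux | wound-strip
    t_end: float = 720.0
    seed: int = 0
    n_cells: int = 65
    hsi_interval: float = 60.0
    snapshot_interval: float | None = None
    save_fields: bool = False
    wound_width: float = 100.0  # µm band used for the wound-proximal fraction

    def __post_init__(self) -> None:
        if self.boundary not in ("periodic", "no-flux", "wound-strip"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.domain[0] <= 0 or self.domain[1] <= 0 or self.dx <= 0:
            raise ValueError("domain lengths and dx must be positive")

    def resolve_dt(self, params: ModelParams) -> float:
        if self.dt is not None:
            return self.dt
        bounds = [0.9 * self.dx**2 / (4.0 * params.d_a) if params.d_a > 0 else np.inf]
        if params.k > 0:
            bounds.append(0.01 / params.k)
        if params.tau > 0:
            bounds.append(params.tau / 50.0)
        return float(min(bounds))


@dataclass
class CellState:
    """Positions (µm), unit headings, and each cell's next tumble time (min)."""

    positions: np.ndarray
    headings: np.ndarray
    next_tumble_times: np.ndarray

    def copy(self) -> "CellState":
        return CellState(
            self.positions.copy(), self.headings.copy(), self.next_tumble_times.copy()
        )


@dataclass
class ATPField:
    """Gridded ATP concentration in µM; ``a[ix, iy]`` sits at (ix·dx, iy·dx)."""

    a: np.ndarray
    dx: float


@dataclass
class SimResult:
    snapshots: list  # (t, CellState, ATPField | None)
    hsi_series: np.ndarray  # (n, 2): time, HSI
    final_pattern: PointPattern
    final_field: ATPField | None = None
    wound_fraction: np.ndarray | None = None  # (n, 2): time, fraction
    params: ModelParams | None = None
    config: NumericsConfig | None = None


# ---------------------------------------------------------------------------
# elementary operations


def repulsion_force(r: float | np.ndarray, params: ModelParams) -> float | np.ndarray:
    """Magnitude of the pairwise repulsion, ``k (sigma - r)`` inside ``sigma``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be nonnegative")
    out = np.where(r < params.sigma, params.k * (params.sigma - r), 0.0)
    return float(out) if out.ndim == 0 else out


def _laplacian(a: np.ndarray, dx: float, boundary: str) -> np.ndarray:
    if boundary == "periodic":
        lap = (
            np.roll(a, 1, axis=0)
            + np.roll(a, -1, axis=0)
            + np.roll(a, 1, axis=1)
            + np.roll(a, -1, axis=1)
            - 4.0 * a
        )
    else:  # no-flux (and the wound strip, whose Dirichlet row is re-imposed after)
        ap = np.pad(a, 1, mode="edge")
        lap = ap[:-2, 1:-1] + ap[2:, 1:-1] + ap[1:-1, :-2] + ap[1:-1, 2:] - 4.0 * a
    return lap / dx**2


def _node_gradient(a: np.ndarray, dx: float, boundary: str) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient at every node."""
    if boundary == "periodic":
        gx = (np.roll(a, -1, axis=0) - np.roll(a, 1, axis=0)) / (2.0 * dx)
        gy = (np.roll(a, -1, axis=1) - np.roll(a, 1, axis=1)) / (2.0 * dx)
    else:
        gx = np.gradient(a, dx, axis=0)
        gy = np.gradient(a, dx, axis=1)
    return gx, gy


def _bilinear(grid: np.ndarray, xi: np.ndarray, yi: np.ndarray, periodic: bool) -> np.ndarray:
    """Sample ``grid`` at fractional node coordinates (xi, yi)."""
    nx, ny = grid.shape
    if periodic:
        x0 = np.floor(xi).astype(int)
        y0 = np.floor(yi).astype(int)
        fx = xi - x0
        fy = yi - y0
        x0 %= nx
        y0 %= ny
        x1 = (x0 + 1) % nx
        y1 = (y0 + 1) % ny
    else:
        xi = np.clip(xi, 0, nx - 1)
        yi = np.clip(yi, 0, ny - 1)
        x0 = np.clip(np.floor(xi).astype(int), 0, nx - 2)
        y0 = np.clip(np.floor(yi).astype(int), 0, ny - 2)
        fx = xi - x0
        fy = yi - y0
        x1 = x0 + 1
        y1 = y0 + 1
    return (
        grid[x0, y0] * (1 - fx) * (1 - fy)
        + grid[x1, y0] * fx * (1 - fy)
        + grid[x0, y1] * (1 - fx) * fy
        + grid[x1, y1] * fx * fy
    )


def gradient_at(
    field: ATPField, pos: np.ndarray, boundary: str = "periodic"
) -> np.ndarray:
    """ATP gradient (µM/µm) at arbitrary positions, bilinearly interpolated.

    ``pos`` is ``(n, 2)`` or ``(2,)``; returns the matching shape.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    nx, ny = field.a.shape
    periodic = boundary == "periodic"
    if not periodic:
        Lx, Ly = nx * field.dx, ny * field.dx
        if np.any(pos[:, 0] < 0) or np.any(pos[:, 0] > Lx) or np.any(
            pos[:, 1] < 0
        ) or np.any(pos[:, 1] > Ly):
            raise ValueError("position outside domain")
    gx, gy = _node_gradient(field.a, field.dx, boundary)
    xi = pos[:, 0] / field.dx
    yi = pos[:, 1] / field.dx
    out = np.column_stack(
        [_bilinear(gx, xi, yi, periodic), _bilinear(gy, xi, yi, periodic)]
    )
    return out[0] if out.shape[0] == 1 and pos.shape[0] == 1 else out


def atp_step(
    field: ATPField,
    cells: CellState | None,
    params: ModelParams,
    dt: float,
    boundary: str = "periodic",
) -> ATPField:
    """One explicit Euler step of the ATP reaction–diffusion equation.

    Production, first-order decay, 5-point-Laplacian diffusion, and a point
    sink of ``b`` µM/min at the grid node nearest each cell; the result is
    clamped at zero (uptake cannot drive the concentration negative).
    """
    if params.d_a > 0 and dt > field.dx**2 / (4.0 * params.d_a) + 1e-12:
        raise ValueError(
            "explicit diffusion unstable: require dt <= dx^2/(4 d_a) "
            f"= {field.dx**2 / (4 * params.d_a):.4g} min"
        )
    a = field.a
    new = a + dt * (params.p_atp - params.h * a + params.d_a * _laplacian(a, field.dx, boundary))
    if cells is not None and params.b > 0 and len(cells.positions):
        nx, ny = a.shape
        ix = np.rint(cells.positions[:, 0] / field.dx).astype(int)
        iy = np.rint(cells.positions[:, 1] / field.dx).astype(int)
        if boundary == "periodic":
            ix %= nx
            iy %= ny
        else:
            ix = np.clip(ix, 0, nx - 1)
            iy = np.clip(iy, 0, ny - 1)
        np.subtract.at(new, (ix, iy), params.b * dt)
    np.maximum(new, 0.0, out=new)
    return ATPField(a=new, dx=field.dx)


def _pairwise_repulsion(
    positions: np.ndarray, params: ModelParams, domain: tuple[float, float], periodic: bool
) -> np.ndarray:
    """Summed repulsive drift on each cell (exact O(n²); n is tens of cells)."""
    n = len(positions)
    if n < 2 or params.k == 0:
        return np.zeros_like(positions)
    diff = positions[:, None, :] - positions[None, :, :]  # r_i - r_j
    if periodic:
        for ax, L in enumerate(domain):
            diff[..., ax] -= L * np.rint(diff[..., ax] / L)
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    np.fill_diagonal(dist, np.inf)
    mag = np.where(dist < params.sigma, params.k * (params.sigma - dist), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = diff / dist[..., None]
    unit = np.nan_to_num(unit)
    return np.sum(mag[..., None] * unit, axis=1)


def cell_step(
    cells: CellState,
    field: ATPField,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
    t: float = 0.0,
    boundary: str = "periodic",
) -> CellState:
    """Forward-Euler update of all cell positions over one time step.

    Drift = chemotaxis ``c ∇a`` + pairwise repulsion + ``v``·heading.
    Headings are re-drawn uniformly on the circle whenever a cell's scheduled
    tumble time passes (Poisson rate ``2/tau``); the boundary wraps
    (periodic) or reflects (otherwise).
    """
    nx, ny = field.a.shape
    domain = (nx * field.dx, ny * field.dx)
    periodic = boundary == "periodic"

    drift = np.zeros_like(cells.positions)
    if params.c > 0:
        drift += params.c * np.atleast_2d(gradient_at(field, cells.positions, boundary))
    drift += _pairwise_repulsion(cells.positions, params, domain, periodic)
    drift += params.v * cells.headings

    new_pos = cells.positions + dt * drift
    if not np.all(np.isfinite(new_pos)):
        raise FloatingPointError(
            "non-finite cell position: reduce dt or check parameters"
        )

    if periodic:
        new_pos[:, 0] %= domain[0]
        new_pos[:, 1] %= domain[1]
    else:
        for ax, L in enumerate(domain):
            x = new_pos[:, ax]
            x = np.abs(x)  # reflect at 0
            over = x > L
            x[over] = 2 * L - x[over]
            new_pos[:, ax] = np.clip(x, 0.0, L)

    headings = cells.headings.copy()
    tumbles = cells.next_tumble_times.copy()
    t_next = t + dt
    due = tumbles <= t_next
    if np.any(due) and params.tau > 0:
        ang = rng.uniform(0.0, 2.0 * np.pi, size=int(due.sum()))
        headings[due] = np.column_stack([np.cos(ang), np.sin(ang)])
        tumbles[due] += rng.exponential(params.tau / 2.0, size=int(due.sum()))
    return CellState(new_pos, headings, tumbles)


# ---------------------------------------------------------------------------
# scenarios


def _init_cells(config: NumericsConfig, params: ModelParams, rng: np.random.Generator) -> CellState:
    Lx, Ly = config.domain
    pos = np.column_stack(
        [rng.uniform(0, Lx, config.n_cells), rng.uniform(0, Ly, config.n_cells)]
    )
    ang = rng.uniform(0, 2 * np.pi, config.n_cells)
    headings = np.column_stack([np.cos(ang), np.sin(ang)])
    if params.tau > 0:
        tumbles = rng.exponential(params.tau / 2.0, config.n_cells)
    else:
        tumbles = np.full(config.n_cells, np.inf)
    return CellState(pos, headings, tumbles)


def _hsi_of(positions: np.ndarray, config: NumericsConfig, seed: int) -> float:
    pattern = PointPattern(
        np.clip(positions, 0, None), (0.0, 0.0, config.domain[0], config.domain[1])
    )
    return hsi(pattern, n_sample=len(positions), seed=seed).hsi


def run(params: ModelParams, config: NumericsConfig) -> SimResult:
    """Integrate the full model from a CSR initial condition to ``t_end``.

    Alternates one ATP field step and one cell step per ``dt``; records the
    Hopkins–Skellam index every ``hsi_interval`` minutes and returns the
    final configuration as a :class:`PointPattern`.  Bit-reproducible for a
    given (params, config) including the seed.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.resolve_dt(params)
    Lx, Ly = config.domain
    nx, ny = int(round(Lx / config.dx)), int(round(Ly / config.dx))
    boundary = config.boundary

    a0 = params.p_atp / params.h if params.h > 0 else 0.0
    field = ATPField(a=np.full((nx, ny), a0), dx=config.dx)
    cells = _init_cells(config, params, rng)

    wound = boundary == "wound-strip"
    if wound:
        field.a[0, :] = params.a_w

    n_steps = int(round(config.t_end / dt))
    hsi_seed = (config.seed * 7919 + 17) % (2**31)
    hsi_records = [(0.0, _hsi_of(cells.positions, config, hsi_seed))]
    wound_records = (
        [(0.0, float(np.mean(cells.positions[:, 0] <= config.wound_width)))] if wound else None
    )
    snapshots = [(0.0, cells.copy(), ATPField(field.a.copy(), field.dx) if config.save_fields else None)]

    next_hsi = config.hsi_interval
    next_snap = config.snapshot_interval if config.snapshot_interval else np.inf

    t = 0.0
    bnd_field = "no-flux" if wound else boundary
    for _ in range(n_steps):
        field = atp_step(field, cells, params, dt, bnd_field)
        if wound:
            field.a[0, :] = params.a_w
        cells = cell_step(cells, field, params, dt, rng, t, "no-flux" if wound else boundary)
        t += dt
        if t + 1e-9 >= next_hsi:
            hsi_records.append((t, _hsi_of(cells.positions, config, hsi_seed)))
            if wound_records is not None:
                wound_records.append(
                    (t, float(np.mean(cells.positions[:, 0] <= config.wound_width)))
                )
            next_hsi += config.hsi_interval
        if t + 1e-9 >= next_snap:
            snapshots.append(
                (t, cells.copy(), ATPField(field.a.copy(), field.dx) if config.save_fields else None)
            )
            next_snap += config.snapshot_interval

    final_pattern = PointPattern(
        np.clip(cells.positions, [0, 0], [Lx, Ly]), (0.0, 0.0, Lx, Ly)
    )
    snapshots.append(
        (t, cells.copy(), ATPField(field.a.copy(), field.dx) if config.save_fields else None)
    )
    return SimResult(
        snapshots=snapshots,
        hsi_series=np.array(hsi_records),
        final_pattern=final_pattern,
        final_field=ATPField(field.a.copy(), field.dx),
        wound_fraction=np.array(wound_records) if wound_records is not None else None,
        params=params,
        config=config,
    )


def wound_scenario(params: ModelParams, config: NumericsConfig) -> SimResult:
    """Wound variant: one edge held at ``a_w`` µM, other edges no-flux.

    Cells reflect at the edges; the result additionally carries the fraction
    of cells within ``config.wound_width`` µm of the wounded edge over time.
    """
    if config.boundary != "wound-strip":
        config = replace(config, boundary="wound-strip")
    return run(params, config)


# scenario presets map experimental perturbations onto parameter changes only
PRESETS: dict[str, dict] = {
    "baseline": {},
    "no-repulsion": {"k": 0.0},
    "chemotaxis-only": {"k": 0.0},
    "wound": {"boundary": "wound-strip"},
    "uptake-off": {"b": 0.0},
}


def apply_preset(
    name: str, params: ModelParams, config: NumericsConfig
) -> tuple[ModelParams, NumericsConfig]:
    """Return (params, config) adjusted for a named scenario preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    changes = dict(PRESETS[name])
    if "boundary" in changes:
        config = replace(config, boundary=changes.pop("boundary"))
    if changes:
        params = replace(params, **changes)
    return params, config
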