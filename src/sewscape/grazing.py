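"""Stochastic spatial grazing dynamics (Noy-Meir model).

The mean-field model is the classic grazed-vegetation system

    dB/dt = r B (1 - B/K) - c B^2 / (B0^2 + B^2)

with logistic regrowth (rate ``r``, carrying capacity ``K``) and a saturating
(Holling type III) grazing loss with mean rate ``c`` and half-saturation
biomass ``B0``.  For suitable parameters the biomass response to grazing is
bistable and hysteretic: between the two fold (saddle-node) points a high-
and a low-biomass branch coexist, and which one the system occupies depends
on its history.  With the defaults (r=1 /yr, K=100 g/m2, B0=10 g/m2) the
bistable window is c in (17.87, 26.04) g m-2 yr-1.

The spatial extension places the same local dynamics on an L x L lattice
with periodic boundaries, diffusive seed dispersal (discrete 4-neighbour
Laplacian with coefficient ``D``) and a grazing rate that fluctuates
randomly in space and time: each cell and step draws c_ij = c + sigma*eta
(eta standard normal, clipped at 0).  Snapshots of such lattices along a
grazing gradient are the raw material for spatial early-warning-signal
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .grid import Grid, SnapshotSeries

__all__ = [
    "ModelParams",
    "Trajectory",
    "PulseResult",
    "NoFoldError",
    "drift",
    "equilibria",
    "fold_points",
    "integrate_meanfield",
    "hysteresis_sweep",
    "simulate_lattice",
    "gradient_snapshots",
    "pulse_recovery",
]


class NoFoldError(ValueError):
    """Raised when the parameters give a monotone (non-bistable) response."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the mean-field and lattice grazing model.

    Units: ``r`` 1/yr, ``K`` and ``B0`` g/m2, ``c`` and ``sigma``
    g m-2 yr-1, ``D`` 1/yr (unit lattice spacing), ``dt`` years.
    """

    r: float = 1.0
    K: float = 100.0
    B0: float = 10.0
    c: float = 10.0
    D: float = 0.1
    sigma: float = 1.0
    dt: float = 0.01
    L: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.r > 0 and self.K > 0 and self.B0 > 0):
            raise ValueError("r, K and B0 must be positive")
        if self.c < 0 or self.D < 0 or self.sigma < 0:
            raise ValueError("c, D and sigma must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        # explicit-scheme stability guard for the growth + diffusion stencil
        if self.dt * (self.r + 4.0 * self.D) >= 1.0:
            raise ValueError(
                f"unstable explicit step: dt*(r + 4*D) = "
                f"{self.dt * (self.r + 4 * self.D):.3g} >= 1"
            )
        if self.L < 2:
            raise ValueError("lattice side L must be >= 2")


@dataclass
class Trajectory:
    """Time-ordered biomass states: scalars (mean field) or Grids (lattice)."""

    times: np.ndarray
    states: list | np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def final(self):
        return self.states[-1]


@dataclass
class PulseResult:
    """Outcome of a pulse-perturbation experiment.

    ``trajectory`` holds the post-pulse recovery (time zero at pulse end);
    ``collapsed`` flags the distinct outcome where the pulse tipped the
    system onto the low-biomass branch instead of recovering.
    """

    trajectory: Trajectory
    equilibrium: float
    collapsed: bool


def drift(B, c: float, params: ModelParams):
    """Deterministic growth rate dB/dt at biomass ``B`` and grazing rate ``c``.

    Accepts scalars or arrays.  ``drift(0, c) = 0`` for every ``c``:
    extinction is always an equilibrium.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("biomass must be non-negative")
    out = params.r * B * (1.0 - B / params.K) - c * B**2 / (params.B0**2 + B**2)
    return float(out) if out.ndim == 0 else out


def _drift_derivative(B: float, c: float, p: ModelParams) -> float:
    """d(drift)/dB, used to classify equilibrium stability."""
    den = p.B0**2 + B**2
    return p.r * (1.0 - 2.0 * B / p.K) - c * (2.0 * B * p.B0**2) / den**2


def equilibria(c: float, params: ModelParams) -> list[tuple[float, bool]]:
    """All equilibria of the mean-field model at grazing rate ``c``.

    Returns ``(biomass, stable)`` pairs sorted by biomass; ``B = 0`` is
    always included.  Positive equilibria are the real roots in (0, K] of
    the cubic  r(1-B/K)(B^2+B0^2) - cB = 0.
    """
    if c < 0:
        raise ValueError("grazing rate must be non-negative")
    p = params
    # -(r/K) B^3 + r B^2 - (r B0^2/K + c) B + r B0^2 = 0
    coeffs = [-p.r / p.K, p.r, -(p.r * p.B0**2 / p.K + c), p.r * p.B0**2]
    roots = np.roots(coeffs)
    out: list[tuple[float, bool]] = [(0.0, _drift_derivative(0.0, c, p) < 0)]
    for root in roots:
        if abs(root.imag) > 1e-9 * p.K:
            continue
        b = float(root.real)
        if b <= 1e-12 * p.K or b > p.K * (1 + 1e-9):
            continue
        out.append((b, _drift_derivative(b, c, p) < 0.0))
    out.sort(key=lambda t: t[0])
    return out


def _c_of_B(B: np.ndarray, p: ModelParams) -> np.ndarray:
    """Grazing rate at which biomass B is an equilibrium (B > 0)."""
    return p.r * (1.0 - B / p.K) * (B**2 + p.B0**2) / B


def fold_points(params: ModelParams) -> tuple[float, float]:
    """The two saddle-node grazing rates (c_lower, c_upper).

    Computed exactly as the interior extrema of the equilibrium curve
    c(B) = r (1 - B/K)(B^2 + B0^2)/B on B in (0, K):  dc/dB = 0 reduces to
    the cubic  (2/K) B^3 - B^2 + B0^2 = 0.  Bistability holds exactly for
    c strictly between the two returned values.

    Raises
    ------
    NoFoldError
        If c(B) is monotone (no interior extrema): the stress-response
        curve has no tipping point.
    """
    p = params
    roots = np.roots([2.0 / p.K, -1.0, 0.0, p.B0**2])
    crit = sorted(
        float(b.real)
        for b in roots
        if abs(b.imag) < 1e-9 * p.K and 1e-12 * p.K < b.real < p.K
    )
    if len(crit) < 2:
        raise NoFoldError("monotone grazing response: no fold bifurcation")
    c_vals = _c_of_B(np.array(crit), p)
    c_lower, c_upper = float(c_vals.min()), float(c_vals.max())
    if not np.isfinite([c_lower, c_upper]).all() or np.isclose(c_lower, c_upper):
        raise NoFoldError("degenerate extrema: no fold bifurcation")
    return c_lower, c_upper


def integrate_meanfield(
    params: ModelParams,
    B_init: float,
    duration: float,
    forcing: Callable[[float], float] | None = None,
    n_points: int = 1001,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Deterministic mean-field trajectory over ``duration`` years.

    ``forcing`` optionally maps time to a grazing rate; otherwise
    ``params.c`` is used throughout.  Integration uses an adaptive
    Runge-Kutta scheme; non-negativity is preserved because drift(0) = 0.
    """
    if B_init < 0:
        raise ValueError("initial biomass must be non-negative")
    c_of_t = forcing if forcing is not None else (lambda t: params.c)

    def rhs(t, y):
        return [drift(max(y[0], 0.0), c_of_t(t), params)]

    t_eval = np.linspace(0.0, duration, n_points)
    sol = solve_ivp(
        rhs, (0.0, duration), [B_init], t_eval=t_eval, rtol=rtol, atol=atol,
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    states = np.clip(sol.y[0], 0.0, None)
    return Trajectory(times=sol.t, states=states)


def _relax(params: ModelParams, c: float, B_init: float,
           horizon: float = 200.0, tol_frac: float = 1e-8) -> float:
    """Integrate at constant c until (near) equilibrium; return final biomass."""
    p = replace(params, c=c)
    traj = integrate_meanfield(p, B_init, horizon, n_points=201)
    return float(traj.states[-1])


def hysteresis_sweep(
    params: ModelParams,
    c_values: Sequence[float],
    horizon: float = 200.0,
):
    """Quasi-static up-then-down sweep of the grazing rate.

    For each ``c`` (first in increasing, then in decreasing order) the
    mean-field model relaxes from the previously converged state, tracing
    the hysteresis loop: the up branch collapses just above the upper fold,
    the down branch recovers just below the lower fold.

    Returns a pandas DataFrame with columns ``c``, ``direction`` and
    ``biomass``.
    """
    import pandas as pd

    c_values = list(c_values)
    if any(b <= a for a, b in zip(c_values, c_values[1:])):
        raise ValueError("c_values must be strictly increasing")
    rows = []
    state = params.K  # begin on the (pristine) high branch
    for c in c_values:
        state = _relax(params, c, state, horizon)
        rows.append({"c": c, "direction": "up", "biomass": state})
    for c in reversed(c_values):
        state = _relax(params, c, state, horizon)
        rows.append({"c": c, "direction": "down", "biomass": state})
    return pd.DataFrame(rows)


def _laplacian(B: np.ndarray) -> np.ndarray:
    """Discrete 4-neighbour (rook) Laplacian with periodic boundaries."""
    return (
        np.roll(B, 1, axis=0) + np.roll(B, -1, axis=0)
        + np.roll(B, 1, axis=1) + np.roll(B, -1, axis=1)
        - 4.0 * B
    )


def simulate_lattice(
    params: ModelParams,
    B_init,
    duration: float,
    record_every: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Explicit stochastic integration on an L x L periodic lattice.

    Each step advances every cell by
    ``dt * (drift(B, c_ij) + D * laplacian(B))`` where
    ``c_ij = max(c + sigma*eta, 0)`` is redrawn independently per cell per
    step; biomass is floored at 0 afterwards.  Identical ``params``
    (including ``seed``) give bit-identical output.

    ``record_every`` controls how many steps pass between recorded frames
    (default: about 100 frames over the run; the final state is always
    recorded).  Pass an explicit ``rng`` to continue a stream instead of
    seeding from ``params.seed``.
    """
    p = params
    if np.isscalar(B_init):
        if B_init < 0:
            raise ValueError("initial biomass must be non-negative")
        B = np.full((p.L, p.L), float(B_init))
    else:
        B = np.asarray(B_init, dtype=float).copy()
        if B.shape != (p.L, p.L):
            raise ValueError(f"B_init shape {B.shape} != lattice ({p.L}, {p.L})")
        if np.any(B < 0):
            raise ValueError("initial biomass must be non-negative")
    if rng is None:
        rng = np.random.default_rng(p.seed)
    n_steps = max(1, int(round(duration / p.dt)))
    if record_every is None:
        record_every = max(1, n_steps // 100)

    times = [0.0]
    states = [Grid(B.copy(), cell_size=1.0, kind="continuous")]
    for step in range(1, n_steps + 1):
        if p.sigma > 0:
            c_ij = p.c + p.sigma * rng.standard_normal(B.shape)
            np.clip(c_ij, 0.0, None, out=c_ij)
        else:
            c_ij = p.c
        growth = p.r * B * (1.0 - B / p.K) - c_ij * B**2 / (p.B0**2 + B**2)
        B = B + p.dt * (growth + p.D * _laplacian(B))
        np.clip(B, 0.0, None, out=B)
        if step % record_every == 0 or step == n_steps:
            times.append(step * p.dt)
            states.append(Grid(B.copy(), cell_size=1.0, kind="continuous"))
    return Trajectory(times=np.array(times), states=states)


def _high_branch(c: float, params: ModelParams) -> tuple[float, bool]:
    """Largest stable equilibrium at c and whether it is the high branch."""
    stable = [b for b, s in equilibria(c, params) if s and b > 0]
    try:
        _, c_up = fold_points(params)
        beyond = c > c_up
    except NoFoldError:
        beyond = False
    if not stable:
        return 0.0, True
    return max(stable), beyond


def gradient_snapshots(
    params: ModelParams,
    c_values: Sequence[float],
    burn_in: float = 100.0,
) -> SnapshotSeries:
    """One equilibrated lattice snapshot per grazing level.

    For each ``c`` the lattice starts uniform on the high branch (its
    largest stable equilibrium; beyond the upper fold only the degraded
    branch exists and the snapshot is flagged by a warning) and runs for
    ``burn_in`` years; the final grid is emitted.  Per-level RNG streams
    are spawned from ``params.seed`` so the series is reproducible and
    insensitive to the order of levels.
    """
    if any(c < 0 for c in c_values):
        raise ValueError("grazing rates must be non-negative")
    grids = []
    children = np.random.SeedSequence(params.seed).spawn(len(c_values))
    for c, ss in zip(c_values, children):
        b0, beyond = _high_branch(c, params)
        if beyond:
            import warnings

            warnings.warn(
                f"c={c} is beyond the upper fold: snapshot will be on the "
                "collapsed branch", stacklevel=2,
            )
        p = replace(params, c=float(c))
        traj = simulate_lattice(
            p, b0, burn_in, record_every=10**9, rng=np.random.default_rng(ss)
        )
        grids.append(traj.final)
    return SnapshotSeries(gradient=[float(c) for c in c_values], grids=grids)


def pulse_recovery(
    params: ModelParams,
    c_base: float,
    delta_c: float = 1.0,
    pulse_duration: float = 1.0,
    max_recovery: float = 500.0,
    sample_dt: float = 0.05,
) -> PulseResult:
    """Mean-field pulse-perturbation experiment at grazing level ``c_base``.

    The model is equilibrated at ``c_base`` (high branch), grazing is
    raised to ``c_base + delta_c`` for ``pulse_duration`` years, then
    restored; the recovery is recorded (time zero at pulse end) until
    biomass is within ``1e-6 * K`` of the pre-pulse equilibrium.  If the
    pulse tips the system onto the low branch the result is flagged
    ``collapsed`` rather than raising.
    """
    p = params
    try:
        _, c_up = fold_points(p)
        if c_base >= c_up:
            raise ValueError("c_base must lie on the high branch (c_base < c_upper)")
    except NoFoldError:
        pass
    b_eq, _ = _high_branch(c_base, p)
    if b_eq <= 0:
        raise ValueError("no positive equilibrium at c_base")

    pulse = integrate_meanfield(
        replace(p, c=c_base + delta_c), b_eq, pulse_duration, n_points=101
    )
    b_pulsed = float(pulse.final)

    tol = 1e-6 * p.K
    n_pts = int(round(max_recovery / sample_dt)) + 1
    rec = integrate_meanfield(
        replace(p, c=c_base), b_pulsed, max_recovery, n_points=n_pts
    )
    recovered = np.abs(rec.states - b_eq) < tol
    if recovered.any():
        # keep at least a short flat tail so degenerate (delta_c = 0) pulses
        # still yield a fittable series
        end = min(len(rec.times), max(int(np.argmax(recovered)) + 1, 21))
    else:
        end = len(rec.times)
    traj = Trajectory(times=rec.times[:end], states=np.asarray(rec.states[:end]))
    # collapse = settling near a different (lower) attractor
    collapsed = abs(float(traj.final) - b_eq) > 0.1 * b_eq and not recovered.any()
    return PulseResult(trajectory=traj, equilibrium=b_eq, collapsed=collapsed)
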