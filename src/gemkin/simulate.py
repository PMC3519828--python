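"""Stochastic (Gillespie) and mean-field (ODE) simulation of a NetworkModel.

A :class:`Trajectory` is either *event*-kind — the piecewise-constant
copy-number path of an exact SSA run, recorded at every reaction event —
or *grid*-kind — states on a fixed time grid (ODE solutions, grid-recorded
SSA runs, replicate means).  AUC (the time integral of a species' copy
number, in molecules·hours) is exact for event trajectories and
trapezoidal for grid trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _ssa
from .network import NetworkModel

__all__ = [
    "Trajectory",
    "SimConfig",
    "ssa_simulate",
    "ssa_auc",
    "ode_simulate",
    "mean_trajectory",
    "auc",
    "replicate_seeds",
]


@dataclass
class Trajectory:
    """Time-ordered per-species copy numbers.

    ``times[0]`` is 0; for event kind the state ``states[i]`` holds on
    ``[times[i], times[i+1])`` and the final row restates the state at
    the end of the simulated horizon.
    """

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_species)
    species: list[str]
    kind: str  # "event" | "grid"
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.kind not in ("event", "grid"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.times[0] != 0:
            raise ValueError("trajectories must start at t = 0")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if self.states.shape != (self.times.size, len(self.species)):
            raise ValueError("states shape mismatch")
        self._index = {s: i for i, s in enumerate(self.species)}

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def counts(self, species: str) -> np.ndarray:
        if species not in self._index:
            raise KeyError(f"unknown species {species!r}")
        return self.states[:, self._index[species]]

    def at(self, t: float) -> dict[str, float]:
        """State at time ``t`` (previous-event state for event kind,
        linear interpolation for grid kind)."""
        if not (0 <= t <= self.t_end):
            raise ValueError("time outside trajectory span")
        if self.kind == "event":
            i = int(np.searchsorted(self.times, t, side="right")) - 1
            return {s: float(self.states[i, j]) for s, j in self._index.items()}
        return {
            s: float(np.interp(t, self.times, self.states[:, j]))
            for s, j in self._index.items()
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.species)
        df.insert(0, "time_h", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SimConfig:
    """Simulation settings: horizon (h), seed, replicate count, count scaling."""

    t_end: float = 24.0
    seed: int = 0
    replicates: int = 1
    scaling: float = 1.0

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0 < self.scaling <= 1):
            raise ValueError("scaling must be in (0, 1]")


def replicate_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds derived from a master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % np.uint32(2**31)


def _prepare(model: NetworkModel, state0: dict[str, float]):
    x0 = model.state_array(state0)
    if np.any(x0 < 0):
        raise ValueError("initial counts must be non-negative")
    if not np.allclose(x0, np.round(x0)):
        raise ValueError("SSA initial counts must be integers")
    k, order, ra, rb, net = model.stoichiometry()
    if not np.all(np.isfinite(k)):
        raise ValueError("non-finite rate constant")
    return x0, k, order, ra, rb, net


def ssa_simulate(
    model: NetworkModel,
    state0: dict[str, float],
    config: SimConfig | None = None,
    max_events: int = 200_000,
) -> Trajectory:
    """Exact SSA sample path, recorded at every reaction event.

    Samples the continuous-time Markov chain defined by the model's
    mass-action propensities with Gillespie's direct method.  Identical
    seeds give identical trajectories.  The event buffer grows (and the
    seeded run is repeated) if ``max_events`` is exceeded; for large
    systems prefer :func:`mean_trajectory` or :func:`ssa_auc`, which
    record on a grid instead.
    """
    config = config or SimConfig()
    x0, k, order, ra, rb, net = _prepare(model, state0)
    cap = max_events
    while True:
        times, rxns, n = _ssa.ssa_events(
            k, order, ra, rb, net, x0, config.t_end, int(config.seed), cap
        )
        if n < cap:
            break
        cap *= 4
    states = np.empty((n + 2, x0.size))
    states[0] = x0
    if n:
        np.cumsum(net[rxns[:n]], axis=0, out=states[1 : n + 1])
        states[1 : n + 1] += x0
    states[n + 1] = states[n]
    t = np.concatenate(([0.0], times[:n], [config.t_end]))
    return Trajectory(t, states, list(model.species_names), "event")


def ssa_auc(
    model: NetworkModel,
    state0: dict[str, float],
    t_end: float = 24.0,
    seed: int = 0,
) -> dict[str, float]:
    """Exact per-species AUC over [0, t_end] of a single SSA run.

    Accumulates level x holding-time on the fly without storing the
    path; the sample path is the one :func:`ssa_simulate` would produce
    with the same seed.
    """
    x0, k, order, ra, rb, net = _prepare(model, state0)
    grid = np.array([t_end])
    _, auc_arr = _ssa.ssa_grid(k, order, ra, rb, net, x0, t_end, grid, int(seed))
    return dict(zip(model.species_names, auc_arr.tolist()))


def _rhs_factory(model: NetworkModel):
    k, order, ra, rb, net = model.stoichiometry()
    netT = net.T.astype(float)

    def rhs(_t, x):
        a = np.where(order == 0, k, 0.0)
        o1 = order == 1
        a[o1] = k[o1] * x[ra[o1]]
        o2 = order == 2
        if np.any(o2):
            same = o2 & (ra == rb)
            mixed = o2 & (ra != rb)
            a[mixed] = k[mixed] * x[ra[mixed]] * x[rb[mixed]]
            a[same] = k[same] * x[ra[same]] ** 2 * 0.5
        return netT @ a

    return rhs


def ode_simulate(
    model: NetworkModel,
    state0: dict[str, float],
    grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> Trajectory:
    """Mean-field mass-action rate equations solved on a time grid.

    Deterministic counterpart of the SSA (propensities with products of
    concentrations; the 2A combinatorial factor becomes x^2/2).  Uses a
    stiff-capable integrator; failures are raised, and small negative
    excursions (within integrator tolerance) are clipped to zero.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must increase from 0")
    x0 = model.state_array(state0)
    if np.any(x0 < 0):
        raise ValueError("initial amounts must be non-negative")
    sol = solve_ivp(
        _rhs_factory(model),
        (0.0, float(grid[-1])),
        x0,
        method="LSODA",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = sol.y.T
    floor = -1e-3 * max(1.0, float(np.max(np.abs(y))))
    if np.any(y < floor):
        raise RuntimeError("ODE solution went significantly negative")
    return Trajectory(grid, np.clip(y, 0.0, None), list(model.species_names), "grid")


def mean_trajectory(
    model: NetworkModel,
    state0: dict[str, float],
    config: SimConfig,
    grid: np.ndarray | None = None,
) -> Trajectory:
    """Per-species mean of replicate SSA runs, resampled on a uniform grid."""
    if grid is None:
        grid = np.linspace(0.0, config.t_end, 241)
    grid = np.asarray(grid, dtype=float)
    x0, k, order, ra, rb, net = _prepare(model, state0)
    seeds = replicate_seeds(config.seed, config.replicates)
    acc = np.zeros((grid.size, x0.size))
    for s in seeds:
        states, _ = _ssa.ssa_grid(
            k, order, ra, rb, net, x0, config.t_end, grid, int(s)
        )
        acc += states
    acc /= config.replicates
    return Trajectory(grid, acc, list(model.species_names), "grid")


def auc(
    traj: Trajectory, species: str, window: tuple[float, float] = (0.0, 24.0)
) -> float:
    """Time integral of a species' copy number over ``window``.

    Event kind: exact sum of level x holding-time of the
    piecewise-constant path.  Grid kind: trapezoidal rule with linear
    interpolation at the window edges.  Units: molecules·hours.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty AUC window")
    if t0 < traj.times[0] or t1 > traj.t_end:
        raise ValueError("AUC window outside trajectory span")
    y = traj.counts(species)
    t = traj.times
    if traj.kind == "event":
        lo = np.maximum(t[:-1], t0)
        hi = np.minimum(t[1:], t1)
        dur = np.clip(hi - lo, 0.0, None)
        return float(np.dot(y[:-1], dur))
    inside = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inside], [t1]))
    yy = np.concatenate(([np.interp(t0, t, y)], y[inside], [np.interp(t1, t, y)]))
    return float(np.trapezoid(yy, tt))
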