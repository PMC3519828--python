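"""Synthetic observation tables and toy models with known solutions.

The generator emulates the structure of the measured data the
calibration consumes: sparse multi-species time series of per-cell
molecule counts produced by a mass-action model, optionally corrupted
with multiplicative lognormal noise (counts are positive and span four
orders of magnitude, so additive Gaussian noise would be a poor
emulation).  Toy linear chains with closed-form solutions serve as
independent oracles for the simulation and fitting machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import ObservationTable
from .network import NetworkModel, Reaction, Species
from .simulate import ode_simulate

__all__ = ["NoiseModel", "generate_observations", "make_toy_chain"]


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: none, or mean-one multiplicative lognormal.

    ``cv`` is the coefficient of variation of the multiplicative
    factor; ``kind="none"`` and ``cv=0`` are equivalent.
    """

    kind: str = "none"  # "none" | "lognormal_multiplicative"
    cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "lognormal_multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.kind == "none" and self.cv != 0:
            raise ValueError("kind 'none' requires cv = 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "none" or self.cv == 0:
            return values
        rng = np.random.default_rng(self.seed)
        sigma2 = np.log1p(self.cv**2)
        factors = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), values.shape)
        return values * factors


def generate_observations(
    model: NetworkModel,
    rates: dict[str, float],
    timepoints: np.ndarray,
    noise: NoiseModel | None = None,
    state0: dict[str, float] | None = None,
    species: list[str] | None = None,
) -> ObservationTable:
    """ODE-simulate ``model`` at ``rates`` and sample noisy observations.

    The mean-field solution is sampled at ``timepoints`` (which must
    include 0) for the requested species and the noise factors are
    applied per cell; deterministic given the noise seed.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if 0.0 not in timepoints:
        raise ValueError("timepoints must include 0")
    if any(v <= 0 for v in rates.values()):
        raise ValueError("generating rates must be positive")
    noise = noise or NoiseModel()
    m = model.with_rates(rates)
    traj = ode_simulate(m, state0 or {}, timepoints)
    species = species or [
        s.name for s in m.species if s.role == "metabolite"
    ]
    cols = [m.index[s] for s in species]
    clean = traj.states[:, cols]
    return ObservationTable(
        timepoints, list(species), noise.apply(clean), "molecules"
    )


def make_toy_chain(n_steps: int, rates) -> NetworkModel:
    """Linear first-order chain S0 -> S1 -> ... -> Sn.

    The mean-field solution is the matrix exponential of a bidiagonal
    generator (single exponential for n=1, the classic two-compartment
    cascade solution for n=2), making the chain a closed-form oracle
    for simulator and fitting tests.  Total copy number is conserved.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rates = np.asarray(rates, dtype=float)
    if rates.size != n_steps:
        raise ValueError("need one rate per step")
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    species = [Species(f"S{i}") for i in range(n_steps + 1)]
    reactions = [
        Reaction(f"step_{i}", ((f"S{i}", 1),), ((f"S{i+1}", 1),), float(rates[i]))
        for i in range(n_steps)
    ]
    moiety = [frozenset(s.name for s in species)]
    return NetworkModel(species, reactions, moiety)
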