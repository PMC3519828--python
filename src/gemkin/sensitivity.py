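"""In-silico sensitivity experiments: AUC surfaces over rate grids.

Drug exposure over the 24 h after administration is summarized by the
AUC of dFdC-TP (efficacy surrogate) and of dCTP (the competing natural
nucleotide, whose depletion raises efficacy).  Sweeps vary the
association rates of the three inhibitions and the dFdC influx rate on
log-spaced grids, running replicate SSA simulations at reduced count
scaling so intrinsic noise is represented, and record replicate-mean
AUCs.  Two summary statistics quantify the regimes seen in the sweeps:

* ``complementarity_score`` — Spearman rank correlation between the
  AUC(dFdC-TP) and AUC(dCTP) arrays across grid points; strongly
  negative values mark the complementary regime in which conditions
  that accumulate dFdC-TP simultaneously deplete dCTP (induced by
  sufficiently strong irreversible RR inhibition);
* ``efficacy_ratio`` — AUC(dFdC-TP)/AUC(dCTP) of one trajectory, the
  model's efficacy metric, which across conditions with varying enzyme
  amounts correlates positively with the dCK/RR abundance ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .network import NetworkModel, scale_model
from .simulate import Trajectory, auc as _auc, replicate_seeds, ssa_auc

__all__ = [
    "UNDEFINED",
    "SweepGrid",
    "AUCSurface",
    "EfficacyRecord",
    "sweep_auc",
    "complementarity_score",
    "efficacy_ratio",
    "influx_experiment",
    "efficacy_factorial",
    "default_association_axis",
    "control_association_axis",
]

#: Distinguished return value for statistics undefined on the input
#: (zero-variance arrays, zero denominator AUC).
UNDEFINED = float("nan")

DEFAULT_SPECIES = ("dFdC-TP", "dCTP")


def default_association_axis(n: int = 10, lo: float = 1e-9, hi: float = 1e-3):
    """Log-spaced association-rate axis spanning six decades (/molecule/h)."""
    return np.geomspace(lo, hi, n)


def control_association_axis(
    model: NetworkModel, reaction_id: str, n: int = 6, decades: float = 3.0
):
    """Log-spaced axis of ``n`` points centred on the model's control rate.

    The sweep experiments vary an association (or influx) rate around
    the calibrated control regime; anchoring the axis to the control
    value guarantees the swept range brackets both the
    inhibition-negligible and inhibition-saturated regimes of *this*
    model, whatever absolute scale the calibration produced.
    """
    k = model.rate(reaction_id)
    if k <= 0:
        raise ValueError(
            f"control rate of {reaction_id!r} is zero; use an absolute axis"
        )
    return np.geomspace(k * 10.0**-decades, k * 10.0**decades, n)


@dataclass
class SweepGrid:
    """1-3 swept parameter axes plus fixed overrides and run settings.

    ``axes`` maps reaction ids to value arrays (log-spaced; exactly 0 is
    allowed and means "inhibition disabled").  ``scaling`` is the count
    scaling applied before each SSA run; ``replicates`` seeded runs are
    averaged per grid point.
    """

    axes: dict[str, np.ndarray]
    fixed: dict[str, float] = field(default_factory=dict)
    scaling: float = 1e-3
    replicates: int = 20
    seed: int = 0
    t_end: float = 24.0
    #: re-derive the drug-free steady state at every grid point (each
    #: swept condition is its own metabolic regime; e.g. weak dCK
    #: binding must not inherit the control regime's loaded dCK:dCTP
    #: complex, which would release its dCTP into the simulation)
    equilibrate: bool = False
    #: species held out of the equilibration and restored afterwards
    dose_species: tuple[str, ...] = ("dFdC-out",)

    def __post_init__(self):
        if not (1 <= len(self.axes) <= 3):
            raise ValueError("1-3 sweep axes required")
        self.axes = {k: np.asarray(v, dtype=float) for k, v in self.axes.items()}
        for k, v in self.axes.items():
            if np.any(v < 0):
                raise ValueError(f"axis {k!r} has negative values")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(v.size for v in self.axes.values())

    def points(self):
        names = list(self.axes)
        for combo in itertools.product(*(self.axes[n] for n in names)):
            yield dict(zip(names, combo))


@dataclass
class AUCSurface:
    """Replicate-mean AUC per observed species over a sweep grid."""

    grid: SweepGrid
    values: dict[str, np.ndarray]  # species -> array of grid.shape
    sem: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        names = list(self.grid.axes)
        rows = []
        for idx, point in zip(
            itertools.product(*(range(n) for n in self.grid.shape)),
            self.grid.points(),
        ):
            for sp, arr in self.values.items():
                row = dict(point)
                row["species"] = sp
                row["auc"] = arr[idx]
                if sp in self.sem:
                    row["sem"] = self.sem[sp][idx]
                rows.append(row)
        return pd.DataFrame(rows, columns=names + ["species", "auc", "sem"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EfficacyRecord:
    """One condition of the enzyme-abundance factorial."""

    condition: str
    dck_amount: float
    rr_amount: float
    efficacy: float

    @property
    def ratio(self) -> float:
        return self.dck_amount / self.rr_amount


def sweep_auc(
    model: NetworkModel,
    state0: dict[str, float],
    grid: SweepGrid,
    species: tuple[str, ...] = DEFAULT_SPECIES,
) -> AUCSurface:
    """Replicate-mean SSA AUC of each species at every grid point.

    For each point the axis parameters (and ``grid.fixed`` overrides)
    replace the corresponding reaction rate constants; with
    ``grid.equilibrate`` the drug-free steady state of the modified
    model is re-derived (the dose species held aside) so every
    condition starts from its own endogenous equilibrium.  The model
    and state are rescaled by ``grid.scaling`` and ``grid.replicates``
    seeded 24 h SSA runs are averaged.  AUCs are reported on the
    *unscaled* count scale (divided by the scaling factor) so surfaces
    at different scalings are comparable.  Deterministic given the seed.
    """
    for pid in list(grid.axes) + list(grid.fixed):
        if pid not in model.reaction_index:
            raise KeyError(f"sweep parameter {pid!r} is not a model reaction")
    for sp in species:
        if sp not in model.index:
            raise KeyError(f"unknown species {sp!r}")
    shape = grid.shape
    values = {sp: np.full(shape, np.nan) for sp in species}
    sems = {sp: np.full(shape, np.nan) for sp in species}
    # common random numbers: the same replicate seeds at every grid
    # point, so comparisons across points share their noise
    seeds = replicate_seeds(grid.seed, grid.replicates)
    for flat, point in enumerate(grid.points()):
        overrides = dict(grid.fixed)
        overrides.update(point)
        m = model.with_rates(overrides)
        st0 = state0
        if grid.equilibrate:
            from .calibrate import pre_equilibrate

            dose = {sp: state0[sp] for sp in grid.dose_species
                    if state0.get(sp, 0.0)}
            base = dict(state0)
            for sp in dose:
                base[sp] = 0.0
            st0 = pre_equilibrate(m, base)
            st0.update(dose)
        ms, ss = scale_model(m, st0, grid.scaling)
        idx = np.unravel_index(flat, shape)
        per_rep = {sp: np.empty(grid.replicates) for sp in species}
        try:
            for r in range(grid.replicates):
                res = ssa_auc(ms, ss, grid.t_end, int(seeds[r]))
                for sp in species:
                    per_rep[sp][r] = res[sp] / grid.scaling
        except (ValueError, RuntimeError):
            continue  # recorded as missing (NaN), not fatal
        for sp in species:
            values[sp][idx] = per_rep[sp].mean()
            sems[sp][idx] = per_rep[sp].std(ddof=1) / np.sqrt(grid.replicates) \
                if grid.replicates > 1 else 0.0
    return AUCSurface(grid, values, sems)


def complementarity_score(surface: AUCSurface) -> float:
    """Spearman rank correlation of AUC(dFdC-TP) vs AUC(dCTP).

    Strongly negative means complementary: across the swept conditions,
    the two metabolites trade off against each other.  Returns
    :data:`UNDEFINED` (NaN) when either array is constant.
    """
    for sp in DEFAULT_SPECIES:
        if sp not in surface.values:
            raise KeyError(f"surface lacks {sp}")
    a = surface.values["dFdC-TP"].ravel()
    b = surface.values["dCTP"].ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return UNDEFINED
    rho = spearmanr(a, b).statistic
    return float(rho)


def efficacy_ratio(traj: Trajectory, window: tuple[float, float] = (0.0, 24.0)) -> float:
    """AUC(dFdC-TP) / AUC(dCTP) over the 24 h exposure window.

    Higher values mean more drug triphosphate exposure relative to the
    competing natural nucleotide, i.e. higher expected efficacy.
    Returns :data:`UNDEFINED` when the dCTP AUC is zero.
    """
    num = _auc(traj, "dFdC-TP", window)
    den = _auc(traj, "dCTP", window)
    if den == 0:
        return UNDEFINED
    return num / den


def influx_experiment(
    model: NetworkModel,
    state0: dict[str, float],
    influx_values: np.ndarray,
    dck_assoc_values: np.ndarray,
    rr_assoc_values: np.ndarray,
    scaling: float = 1e-3,
    replicates: int = 20,
    seed: int = 0,
) -> AUCSurface:
    """Three-axis sweep: dFdC influx x dCK association x RR association.

    Models variation in nucleoside-transporter expression jointly with
    the two key inhibition propensities.  The control influx is the
    model's current ``influx_dFdC`` rate constant.
    """
    grid = SweepGrid(
        axes={
            "influx_dFdC": np.asarray(influx_values, dtype=float),
            "bind_dCK": np.asarray(dck_assoc_values, dtype=float),
            "bind_RR": np.asarray(rr_assoc_values, dtype=float),
        },
        scaling=scaling,
        replicates=replicates,
        seed=seed,
    )
    return sweep_auc(model, state0, grid)


def efficacy_factorial(
    model: NetworkModel,
    state0: dict[str, float],
    dck_amounts: np.ndarray,
    rr_amounts: np.ndarray,
    scaling: float = 1e-3,
    replicates: int = 20,
    seed: int = 0,
    t_end: float = 24.0,
    equilibrate: bool = True,
) -> list[EfficacyRecord]:
    """Efficacy across conditions varying total dCK and RR amounts.

    Each condition sets the *total* enzyme copy numbers (rate constants
    are untouched, so enzyme abundance directly scales the catalytic
    and binding propensities), re-derives its drug-free equilibrium
    (which partitions each enzyme between free and complexed forms),
    and then administers the dose.  Efficacy is the replicate-pooled
    AUC ratio.  Mirrors the observation that efficacy rises with the
    dCK/RR abundance ratio.
    """
    from .calibrate import pre_equilibrate

    records = []
    seeds = replicate_seeds(seed, replicates)
    complexes = [s.name for s in model.species if s.role == "complex"]
    dose = {sp: state0[sp] for sp in ("dFdC-out",) if state0.get(sp, 0.0)}
    for nd in dck_amounts:
        for nr in rr_amounts:
            st = dict(state0)
            for sp in dose:
                st[sp] = 0.0
            for sp in complexes:
                st[sp] = 0.0
            st["dCK"] = float(nd)
            st["RR"] = float(nr)
            if equilibrate:
                st = pre_equilibrate(model, st)
            st.update(dose)
            ms, ss = scale_model(model, st, scaling)
            num = den = 0.0
            for r in range(replicates):
                res = ssa_auc(ms, ss, t_end, int(seeds[r]))
                num += res["dFdC-TP"]
                den += res["dCTP"]
            eff = UNDEFINED if den == 0 else num / den
            records.append(
                EfficacyRecord(
                    condition=f"dCK={nd:g},RR={nr:g}",
                    dck_amount=float(nd),
                    rr_amount=float(nr),
                    efficacy=eff,
                )
            )
    return records
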