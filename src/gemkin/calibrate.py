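"""Unit conversion, initial-condition estimation and rate calibration.

The measured HepG2 time series report intracellular metabolite
concentrations in pmol per mg of cellular protein at 0/4/12/24 h.  With
12x10^6 cells per mg of protein, one pmol/mg corresponds to

    1e-12 mol x N_A / (12x10^6 cells)  ~=  5.02x10^4 molecules/cell,

which converts the concentration table into per-cell molecule counts.
The initial extracellular gemcitabine pool is unknown and is estimated
as the sum of all eight intracellular metabolite counts at the 4 h
sample (negligible degradation and no loss from the cell within the
first hours), about 10^7 molecules.

The drug cascade's rate constants are fitted by Nelder-Mead least
squares against the count time series, using the deterministic
mean-field ODE (the cascade without inhibitors is linear, so solutions
come from a matrix exponential).  The endogenous CDP production rate is
calibrated separately so the drug-free steady-state dCTP pool matches a
target copy number (215,000 molecules per cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .network import (
    DRUG_METABOLITES,
    NetworkModel,
    Reaction,
    Species,
)
from .simulate import ode_simulate, _rhs_factory

__all__ = [
    "UnitConstants",
    "ObservationTable",
    "ParameterEstimate",
    "FitOptions",
    "pmol_per_mg_to_count",
    "count_to_pmol_per_mg",
    "estimate_initial_extracellular",
    "build_fit_cascade",
    "CASCADE_RATE_IDS",
    "fit_parameters",
    "calibrate_cdp_production",
    "pre_equilibrate",
]


@dataclass(frozen=True)
class UnitConstants:
    """Physical constants of the HepG2 concentration-to-count conversion.

    ``cell_volume_fl`` (17 fL) is the HepG2 cell volume of the
    concentration assay; ``dctp_volume_pl`` (0.943 pL) is the average
    cell volume used in the literature dCTP-concentration context.
    """

    avogadro: float = 6.02214e23  # /mol
    cells_per_mg_protein: float = 12e6  # cells/mg
    cell_volume_fl: float = 17.0
    dctp_volume_pl: float = 0.943

    @property
    def protein_per_cell(self) -> float:
        """mg of cellular protein per cell (~8.33e-8)."""
        return 1.0 / self.cells_per_mg_protein

    @property
    def count_per_pmol_mg(self) -> float:
        """Molecules per cell per (pmol/mg protein), ~5.02e4."""
        return 1e-12 * self.avogadro * self.protein_per_cell


def pmol_per_mg_to_count(conc, constants: UnitConstants | None = None):
    """Convert pmol per mg protein to molecules per cell."""
    constants = constants or UnitConstants()
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    out = conc * constants.count_per_pmol_mg
    return float(out) if out.ndim == 0 else out


def count_to_pmol_per_mg(count, constants: UnitConstants | None = None):
    """Convert molecules per cell back to pmol per mg protein."""
    constants = constants or UnitConstants()
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be >= 0")
    out = count / constants.count_per_pmol_mg
    return float(out) if out.ndim == 0 else out


@dataclass
class ObservationTable:
    """Sparse multi-species time series in pmol/mg or molecules per cell."""

    timepoints: np.ndarray
    species: list[str]
    values: np.ndarray  # shape (n_timepoints, n_species)
    unit: str  # "pmol_per_mg" | "molecules"

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in ("pmol_per_mg", "molecules"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if np.any(self.values < 0):
            raise ValueError("observed values must be >= 0")
        t = self.timepoints
        if t.size != np.unique(t).size or np.any(np.diff(t) < 0):
            raise ValueError("timepoints must be unique and sorted")
        if self.values.shape != (t.size, len(self.species)):
            raise ValueError("values shape mismatch")

    def value(self, species: str, t: float) -> float:
        j = self.species.index(species)
        i = np.flatnonzero(self.timepoints == t)
        if i.size != 1:
            raise KeyError(f"no observation at t = {t}")
        return float(self.values[i[0], j])

    def to_counts(self, constants: UnitConstants | None = None) -> "ObservationTable":
        if self.unit == "molecules":
            return self
        return ObservationTable(
            self.timepoints,
            list(self.species),
            pmol_per_mg_to_count(self.values, constants),
            "molecules",
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.species)
        df.insert(0, "time_h", self.timepoints)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, unit: str) -> "ObservationTable":
        df = pd.read_csv(path)
        if "time_h" not in df.columns:
            raise ValueError("observation CSV must have a 'time_h' column")
        species = [c for c in df.columns if c != "time_h"]
        return cls(df["time_h"].to_numpy(), species, df[species].to_numpy(), unit)


def estimate_initial_extracellular(
    table: ObservationTable, constants: UnitConstants | None = None
) -> float:
    """Initial extracellular gemcitabine pool (molecules per cell).

    Approximated as the sum of every observed metabolite at the 4 h
    timepoint: within the first hours degradation is negligible and the
    converted metabolites remain inside the cell, so everything seen
    intracellularly at 4 h entered as extracellular drug.
    """
    counts = table.to_counts(constants)
    if 4.0 not in counts.timepoints:
        raise KeyError("table lacks the 4 h timepoint")
    i = int(np.flatnonzero(counts.timepoints == 4.0)[0])
    return float(counts.values[i].sum())


# ---------------------------------------------------------------------------
# The fit cascade (drug network without inhibitors; all first order)
# ---------------------------------------------------------------------------

#: Rate constants estimated by the cascade fit, in model-reaction-id form.
CASCADE_RATE_IDS = (
    "influx_dFdC", "efflux_dFdC", "phos_dFdC", "dephos_dFdC_MP", "phos_dFdC_MP",
    "dephos_dFdC_DP", "phos_dFdC_DP", "dephos_dFdC_TP", "incorp_dFdC_TP",
    "deam_dFdC", "deam_dFdC_MP", "efflux_dFdU", "phos_dFdU",
    "dephos_dFdU_MP", "phos_dFdU_MP", "phos_dFdU_DP", "incorp_dFdU_TP",
)


def build_fit_cascade(rates: dict[str, float]) -> NetworkModel:
    """Drug metabolization cascade with enzymes folded into the rates.

    Without the inhibitory bindings the enzyme pools are constant, so
    the dCK-, dCMPD- and CDA-catalysed steps reduce to effective
    first-order reactions; the whole cascade is then linear, which is
    the form used for parameter estimation.
    """
    r = {rid: 0.0 for rid in CASCADE_RATE_IDS}
    r["influx_dFdU"] = 0.0
    unknown = set(rates) - set(r)
    if unknown:
        raise KeyError(f"unknown cascade rates: {sorted(unknown)}")
    r.update(rates)
    species = [
        Species("dFdC-out", "extracellular"),
        Species("dFdU-out", "extracellular"),
        *(Species(m) for m in DRUG_METABOLITES),
        Species("DNA-dFdC", role="sink"),
        Species("DNA-dFdU", role="sink"),
    ]

    def f(rid, a, b):
        return Reaction(rid, ((a, 1),), ((b, 1),), r[rid])

    reactions = [
        f("influx_dFdC", "dFdC-out", "dFdC"),
        f("efflux_dFdC", "dFdC", "dFdC-out"),
        f("influx_dFdU", "dFdU-out", "dFdU"),
        f("efflux_dFdU", "dFdU", "dFdU-out"),
        f("phos_dFdC", "dFdC", "dFdC-MP"),
        f("dephos_dFdC_MP", "dFdC-MP", "dFdC"),
        f("phos_dFdC_MP", "dFdC-MP", "dFdC-DP"),
        f("dephos_dFdC_DP", "dFdC-DP", "dFdC-MP"),
        f("phos_dFdC_DP", "dFdC-DP", "dFdC-TP"),
        f("dephos_dFdC_TP", "dFdC-TP", "dFdC-DP"),
        f("incorp_dFdC_TP", "dFdC-TP", "DNA-dFdC"),
        f("deam_dFdC", "dFdC", "dFdU"),
        f("deam_dFdC_MP", "dFdC-MP", "dFdU-MP"),
        f("phos_dFdU", "dFdU", "dFdU-MP"),
        f("dephos_dFdU_MP", "dFdU-MP", "dFdU"),
        f("phos_dFdU_MP", "dFdU-MP", "dFdU-DP"),
        f("phos_dFdU_DP", "dFdU-DP", "dFdU-TP"),
        f("incorp_dFdU_TP", "dFdU-TP", "DNA-dFdU"),
    ]
    return NetworkModel(species, reactions)


# ---------------------------------------------------------------------------
# Least-squares fitting
# ---------------------------------------------------------------------------

def _linear_system(model: NetworkModel):
    """(A, b) of dx/dt = A x + b for an order <= 1 model."""
    k, order, ra, rb, net = model.stoichiometry()
    S = model.n_species
    A = np.zeros((S, S))
    b = np.zeros(S)
    for j in range(k.size):
        if order[j] == 0:
            b += k[j] * net[j]
        else:
            A[:, ra[j]] += k[j] * net[j]
    return A, b


def _solve_at_times(model: NetworkModel, x0: np.ndarray, times: np.ndarray):
    """States at the given times; exact matrix exponential for linear
    models, stiff ODE integration otherwise."""
    if model.is_linear():
        S = x0.size
        A, b = _linear_system(model)
        aug = np.zeros((S + 1, S + 1))
        aug[:S, :S] = A
        aug[:S, S] = b
        x = np.concatenate([x0, [1.0]])
        out = np.empty((times.size, S))
        t_prev = 0.0
        M = None
        dt_prev = None
        for i, t in enumerate(times):
            dt = t - t_prev
            if dt > 0:
                if dt_prev is None or not np.isclose(dt, dt_prev):
                    M = expm(aug * dt)
                    dt_prev = dt
                x = M @ x
                t_prev = t
            out[i] = x[:S]
        return out
    grid = times if times[0] == 0 else np.concatenate([[0.0], times])
    traj = ode_simulate(model, model.state_dict(x0), grid)
    keep = np.isin(grid, times)
    return traj.states[keep]


@dataclass
class FitOptions:
    """Nelder-Mead settings: restarts are seeded log-space perturbations."""

    n_restarts: int = 10
    seed: int = 0
    perturb_sd: float = 0.7  # log10 units
    maxiter: int | None = None
    xatol: float = 1e-4
    fatol: float = 1e-10
    weighting: str = "per_cell"  # "per_cell" | "per_species"


@dataclass
class ParameterEstimate:
    """Fitted rate vector with objective value and convergence metadata."""

    rates: dict[str, float]
    objective: float
    converged: bool
    n_restarts_used: int
    residuals: pd.DataFrame | None = field(default=None, repr=False)


def _weighted_sse(pred, obs, w):
    return float(np.sum(w * (pred - obs) ** 2))


def fit_parameters(
    model: NetworkModel,
    observations: ObservationTable,
    init: dict[str, float],
    options: FitOptions | None = None,
    state0: dict[str, float] | None = None,
) -> ParameterEstimate:
    """Nelder-Mead least-squares fit of rate constants to a time series.

    The objective is sum over observed species s and timepoints t of
    ``w_st (x_s(t; rates) - obs_s(t))^2`` with relative weights:
    per-cell ``w_st = 1 / obs_s(t)^2`` by default (zero cells fall back
    to the species maximum), or per-species ``w_s = 1 / max_t
    obs_s(t)^2``.  Observed counts span four orders of magnitude, so
    unweighted least squares would see only the largest pools, and
    per-species weighting still lets the optimizer ignore a species'
    low-count late samples; the per-cell default targets relative error
    in every cell.  Rates are optimized in log10 space; seeded
    multi-start perturbations guard against local minima.  The fit
    targets the deterministic mean-field solution, never stochastic
    output, so the objective is smooth and deterministic.
    """
    options = options or FitOptions()
    obs = observations.to_counts()
    missing = [s for s in obs.species if s not in model.index]
    if missing:
        raise ValueError(f"observed species not in model: {missing}")
    fit_species = list(obs.species)
    param_ids = list(init)
    p0 = np.array([init[p] for p in param_ids], dtype=float)
    if np.any(p0 <= 0):
        raise ValueError("initial rates must be positive")
    cols = [model.index[s] for s in fit_species]
    obs_vals = obs.values
    col_max = obs_vals.max(axis=0)
    w_species = np.where(col_max > 0, 1.0 / np.maximum(col_max, 1e-300) ** 2, 0.0)
    if options.weighting == "per_cell":
        w = np.broadcast_to(w_species, obs_vals.shape).copy()
        nz = obs_vals > 0
        w[nz] = 1.0 / obs_vals[nz] ** 2
    elif options.weighting == "per_species":
        w = np.broadcast_to(w_species, obs_vals.shape)
    else:
        raise ValueError(f"unknown weighting {options.weighting!r}")
    times = obs.timepoints
    if state0 is None:
        state0 = {}
    x0 = model.state_array(state0)

    def objective(logp):
        if np.any(np.abs(logp) > 12):
            return 1e12
        rates = dict(zip(param_ids, 10.0**logp))
        try:
            sol = _solve_at_times(model.with_rates(rates), x0, times)
        except RuntimeError:
            return 1e12
        val = _weighted_sse(sol[:, cols], obs_vals, w)
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(options.seed)
    log0 = np.log10(p0)
    best = None
    maxiter = options.maxiter or 400 * len(param_ids)
    n_used = 0
    for i in range(options.n_restarts + 1):
        start = log0 if i == 0 else log0 + rng.normal(0, options.perturb_sd, log0.size)
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": options.xatol,
                "fatol": options.fatol,
                "adaptive": True,
            },
        )
        n_used = i + 1
        if best is None or res.fun < best.fun:
            best = res
        if best.fun == 0.0:
            break
    rates = dict(zip(param_ids, 10.0**best.x))
    sol = _solve_at_times(model.with_rates(rates), x0, times)
    rows = []
    for ti, t in enumerate(times):
        for s, c in zip(fit_species, cols):
            rows.append(
                {
                    "time_h": t,
                    "species": s,
                    "observed": obs_vals[ti, obs.species.index(s)],
                    "predicted": sol[ti, c],
                }
            )
    resid = pd.DataFrame(rows)
    resid["residual"] = resid["predicted"] - resid["observed"]
    return ParameterEstimate(
        rates=rates,
        objective=float(best.fun),
        converged=bool(best.success),
        n_restarts_used=n_used,
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# Endogenous-cascade calibration
# ---------------------------------------------------------------------------

def calibrate_cdp_production(
    model: NetworkModel,
    target_dctp: float,
    state0: dict[str, float] | None = None,
    incorporation_id: str = "incorp_dCTP",
    verify: bool = True,
) -> float:
    """CDP production rate whose drug-free steady state has the target dCTP.

    At steady state every molecule produced as CDP leaves the cascade
    through dCTP incorporation (the reversible dCK binding carries no
    net flux), so flux balance gives ``k_prod = c x target`` with ``c``
    the first-order dCTP incorporation rate.  With ``verify`` the
    drug-free ODE is integrated to steady state and required to land
    within 1% of the target.
    """
    if target_dctp < 0:
        raise ValueError("target must be >= 0")
    c = model.rate(incorporation_id)
    k_prod = c * target_dctp
    if target_dctp == 0 or not verify:
        return k_prod
    calibrated = model.with_rates({"prod_CDP": k_prod})
    if state0 is None:
        state0 = {}
    eq = pre_equilibrate(calibrated, state0)
    dctp = eq["dCTP"]
    if abs(dctp - target_dctp) > 0.01 * target_dctp:
        raise RuntimeError(
            f"steady-state dCTP {dctp:.1f} not within 1% of target {target_dctp:.1f}"
            " (cascade may have no bounded steady state)"
        )
    return k_prod


def pre_equilibrate(
    model: NetworkModel,
    state0: dict[str, float],
    horizon: float = 1e5,
    tol: float = 1e-6,
) -> dict[str, float]:
    """Drug-free steady state of the endogenous pools.

    Integrates the model from ``state0`` (which must contain no drug
    species) over doubling time windows until the relative state change
    rate falls below ``tol`` per hour, so dFdC can then be administered
    to a cell whose dCTP synthesis cascade is already at steady state.
    """
    drug = [s for s in ("dFdC-out", "dFdC") if s in model.index]
    for s in drug:
        if state0.get(s, 0.0) != 0:
            raise ValueError("pre-equilibration requires a drug-free state")
    rhs = _rhs_factory(model)
    sink = [i for i, sp in enumerate(model.species) if sp.role == "sink"]
    x = model.state_array(state0)
    t, window = 0.0, 1.0
    while t < horizon:
        w = min(window, horizon - t)
        traj = ode_simulate(model, model.state_dict(x), np.array([0.0, w]))
        x = traj.states[-1]
        t += w
        window *= 2
        dx = rhs(0.0, x)
        dx[sink] = 0.0  # sinks grow forever by construction
        rel = np.abs(dx) / np.maximum(np.abs(x), 1.0)
        if np.max(rel) < tol:
            out = model.state_dict(x)
            for i in sink:
                out[model.species_names[i]] = 0.0
            return out
    raise RuntimeError(f"no steady state within {horizon} h")
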