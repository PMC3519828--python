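"""Species/reaction data model and the gemcitabine metabolic network.

The network couples two nucleotide cascades that compete for DNA
incorporation:

* the drug cascade — extracellular gemcitabine (dFdC) enters the cell,
  is phosphorylated stepwise to dFdC-MP/-DP/-TP (the first step catalysed
  by deoxycytidine kinase, dCK), and dFdC-TP is incorporated into DNA;
  a deamination branch converts dFdC to dFdU (via cytidine deaminase,
  folded into a first-order rate) and dFdC-MP to dFdU-MP (via
  deoxycytidylate deaminase, dCMPD), feeding an analogous dFdU cascade;
* the endogenous cascade — CDP is produced at a constant rate, reduced
  to dCDP by ribonucleotide reductase (RR), phosphorylated to dCTP, and
  incorporated into DNA.

Three inhibitory bindings couple the cascades: dCTP binds and
sequesters dCK (reversible), dFdC-DP binds RR irreversibly, and
dFdC-TP binds dCMPD (reversible).  Free enzyme alone is catalytically
active, so each binding removes catalytic capacity.

All kinetics are elementary mass action with kinetic order 0, 1 or 2.
Time unit: hours.  Second-order rate constants are per molecule per
hour; copy numbers are molecules per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IRREVERSIBLE",
    "Species",
    "Reaction",
    "InhibitionSpec",
    "NetworkModel",
    "ModelConfig",
    "build_gemcitabine_network",
    "propensity",
    "scale_model",
    "write_reaction_list",
    "read_reaction_list",
    "METABOLITES",
    "DRUG_METABOLITES",
]

#: Distinguished dissociation-rate value marking a binding with no
#: unbinding reaction (used for the RR : dFdC-DP association).
IRREVERSIBLE = "irreversible"

#: The eight intracellular metabolites observed in the HepG2 assay.
DRUG_METABOLITES = (
    "dFdC", "dFdC-MP", "dFdC-DP", "dFdC-TP",
    "dFdU", "dFdU-MP", "dFdU-DP", "dFdU-TP",
)

#: All dynamically interesting metabolites (drug + endogenous pools).
METABOLITES = DRUG_METABOLITES + ("CDP", "dCDP", "dCTP")


@dataclass(frozen=True)
class Species:
    """A chemical species of the model.

    ``role`` distinguishes metabolites, enzymes, enzyme-ligand complexes
    and absorbing sinks (DNA incorporation).  A complex names its two
    constituents (enzyme, ligand).
    """

    name: str
    compartment: str = "intracellular"  # or "extracellular"
    role: str = "metabolite"  # metabolite | enzyme | complex | sink
    constituents: tuple[str, str] | None = None

    def __post_init__(self):
        if self.compartment not in ("intracellular", "extracellular"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.role not in ("metabolite", "enzyme", "complex", "sink"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "complex":
            if self.constituents is None or len(self.constituents) != 2:
                raise ValueError(
                    f"complex {self.name!r} must name exactly two constituents"
                )
        elif self.constituents is not None:
            raise ValueError("only complexes have constituents")


@dataclass(frozen=True)
class Reaction:
    """An elementary mass-action reaction.

    ``reactants`` and ``products`` are tuples of (species name, stoichiometric
    count).  Kinetic order (sum of reactant counts) must be 0, 1 or 2.
    Units of ``rate_constant``: /h for order 0 and 1, /molecule/h for order 2.
    """

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float

    def __post_init__(self):
        if self.rate_constant < 0 or not math.isfinite(self.rate_constant):
            raise ValueError(
                f"reaction {self.id!r}: rate must be finite and >= 0, "
                f"got {self.rate_constant}"
            )
        for name, count in self.reactants + self.products:
            if count < 1:
                raise ValueError(f"reaction {self.id!r}: stoichiometry < 1 for {name}")
        if self.order not in (0, 1, 2):
            raise ValueError(
                f"reaction {self.id!r}: kinetic order {self.order} unsupported"
            )

    @property
    def order(self) -> int:
        return sum(c for _, c in self.reactants)

    def net_change(self) -> dict[str, int]:
        delta: dict[str, int] = {}
        for name, c in self.products:
            delta[name] = delta.get(name, 0) + c
        for name, c in self.reactants:
            delta[name] = delta.get(name, 0) - c
        return {k: v for k, v in delta.items() if v != 0}


@dataclass(frozen=True)
class InhibitionSpec:
    """Reversible (or irreversible) enzyme sequestration by a ligand.

    ``k_assoc = 0`` disables the inhibition entirely (no reactions are
    generated).  ``k_dissoc`` may be the distinguished value
    :data:`IRREVERSIBLE`, in which case no unbinding reaction exists;
    the RR inhibition must be irreversible.
    """

    enzyme: str
    ligand: str
    k_assoc: float
    k_dissoc: float | str

    def __post_init__(self):
        if self.k_assoc < 0:
            raise ValueError("k_assoc must be >= 0")
        if self.k_dissoc != IRREVERSIBLE and self.k_dissoc < 0:
            raise ValueError("k_dissoc must be >= 0 or IRREVERSIBLE")

    @property
    def complex_name(self) -> str:
        return f"{self.enzyme}:{self.ligand}"


class NetworkModel:
    """A mass-action reaction network over a fixed species list.

    Provides index-based stoichiometry arrays for the simulation engines
    and structural audits of conserved moieties.
    """

    def __init__(
        self,
        species: list[Species],
        reactions: list[Reaction],
        conserved_moieties: list[frozenset[str]] | None = None,
    ):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        self.species = list(species)
        self.species_names = names
        self.index = {n: i for i, n in enumerate(names)}
        known = set(names)
        for r in reactions:
            for name, _ in r.reactants + r.products:
                if name not in known:
                    raise ValueError(
                        f"reaction {r.id!r} references unknown species {name!r}"
                    )
        ids = [r.id for r in reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("reaction ids must be unique")
        self.reactions = list(reactions)
        self.reaction_index = {r.id: i for i, r in enumerate(reactions)}
        self.conserved_moieties = [frozenset(m) for m in (conserved_moieties or [])]
        for moiety in self.conserved_moieties:
            self._audit_moiety(moiety)

    # -- structural checks -------------------------------------------------

    def _audit_moiety(self, moiety: frozenset[str]) -> None:
        for name in moiety:
            if name not in self.index:
                raise ValueError(f"moiety references unknown species {name!r}")
        for r in self.reactions:
            net = sum(d for n, d in r.net_change().items() if n in moiety)
            if net != 0:
                raise ValueError(
                    f"moiety {sorted(moiety)} not conserved by reaction {r.id!r}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def rate(self, reaction_id: str) -> float:
        return self.reactions[self.reaction_index[reaction_id]].rate_constant

    def with_rates(self, rates: dict[str, float]) -> "NetworkModel":
        """Return a copy with the given reaction rate constants replaced."""
        unknown = set(rates) - set(self.reaction_index)
        if unknown:
            raise KeyError(f"unknown reaction ids: {sorted(unknown)}")
        new = [
            replace(r, rate_constant=float(rates.get(r.id, r.rate_constant)))
            for r in self.reactions
        ]
        return NetworkModel(self.species, new, self.conserved_moieties)

    def stoichiometry(self):
        """Return (rates, orders, reactant index pairs, net-change matrix).

        Arrays for the simulation engines: ``k[j]`` rate constant,
        ``order[j]`` in {0,1,2}, ``ra[j]``/``rb[j]`` reactant species
        indices (-1 when absent; ``ra == rb`` encodes a 2A reaction),
        ``net[j, i]`` the copy-number change of species ``i``.
        """
        R, S = self.n_reactions, self.n_species
        k = np.zeros(R)
        order = np.zeros(R, dtype=np.int64)
        ra = np.full(R, -1, dtype=np.int64)
        rb = np.full(R, -1, dtype=np.int64)
        net = np.zeros((R, S), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            k[j] = r.rate_constant
            order[j] = r.order
            flat: list[int] = []
            for name, c in r.reactants:
                flat.extend([self.index[name]] * c)
            if len(flat) >= 1:
                ra[j] = flat[0]
            if len(flat) == 2:
                rb[j] = flat[1]
            for name, d in r.net_change().items():
                net[j, self.index[name]] = d
        return k, order, ra, rb, net

    def state_array(self, state: dict[str, float]) -> np.ndarray:
        """Dense state vector from a (possibly partial) species->count map."""
        x = np.zeros(self.n_species)
        for name, v in state.items():
            if name not in self.index:
                raise KeyError(f"unknown species {name!r}")
            x[self.index[name]] = v
        return x

    def state_dict(self, x: np.ndarray) -> dict[str, float]:
        return {n: float(x[i]) for n, i in self.index.items()}

    def is_linear(self) -> bool:
        """True when every reaction is of kinetic order 0 or 1."""
        return all(r.order <= 1 for r in self.reactions)


def propensity(reaction: Reaction, state: dict[str, float]) -> float:
    """Mass-action propensity of ``reaction`` in copy-number ``state``.

    Order 0: k.  Order 1 (A): k*nA.  Order 2 (A+B): k*nA*nB.
    Order 2 (2A): k*nA*(nA-1)/2 (number of distinct pairs).
    """
    for name, _ in reaction.reactants:
        if name not in state:
            raise KeyError(f"state lacks reactant {name!r}")
        if state[name] < 0:
            raise ValueError(f"negative count for {name!r}")
    k = reaction.rate_constant
    if reaction.order == 0:
        return k
    if reaction.order == 1:
        (a, _), = reaction.reactants
        return k * state[a]
    if len(reaction.reactants) == 1:  # 2A
        (a, _), = reaction.reactants
        n = state[a]
        return k * n * (n - 1) / 2.0
    (a, _), (b, _) = reaction.reactants
    return k * state[a] * state[b]


def scale_model(
    model: NetworkModel, state: dict[str, float], s: float
) -> tuple[NetworkModel, dict[str, float]]:
    """Rescale copy numbers by ``s`` with compensating rate rescaling.

    Zeroth-order constants are multiplied by ``s``, first-order left
    unchanged and second-order divided by ``s``, so the mean-field
    trajectory of the scaled system is ``s`` times the original's.
    Smaller ``s`` therefore amplifies intrinsic noise without changing
    the deterministic kinetics.  Counts are rounded to nearest integer.
    """
    if not (0 < s <= 1):
        raise ValueError("scaling factor must be in (0, 1]")
    if s == 1:
        return model, dict(state)
    new_reactions = []
    for r in model.reactions:
        if r.order == 0:
            kk = r.rate_constant * s
        elif r.order == 1:
            kk = r.rate_constant
        else:
            kk = r.rate_constant / s
        new_reactions.append(replace(r, rate_constant=kk))
    scaled_model = NetworkModel(model.species, new_reactions, model.conserved_moieties)
    scaled_state = {n: float(round(v * s)) for n, v in state.items()}
    return scaled_model, scaled_state


# ---------------------------------------------------------------------------
# The gemcitabine network
# ---------------------------------------------------------------------------

def _default_inhibitions() -> dict[str, InhibitionSpec]:
    return {
        "dCK": InhibitionSpec("dCK", "dCTP", k_assoc=1e-6, k_dissoc=1.0),
        "RR": InhibitionSpec("RR", "dFdC-DP", k_assoc=1e-7, k_dissoc=IRREVERSIBLE),
        "dCMPD": InhibitionSpec("dCMPD", "dFdC-TP", k_assoc=1e-6, k_dissoc=1.0),
    }


def _default_rates() -> dict[str, float]:
    # Cascade rates are placeholders to be replaced by calibration
    # (see gemkin.calibrate / gemkin.datasets.load_calibrated_rates).
    return {
        "influx_dFdC": 0.5,
        "efflux_dFdC": 0.01,
        "influx_dFdU": 0.5,
        "efflux_dFdU": 0.01,
        "phos_dFdC": 5.0,          # effective first-order, divided by n(dCK)
        "dephos_dFdC_MP": 0.0,     # 5'-nucleotidase back-step
        "phos_dFdC_MP": 1.0,
        "dephos_dFdC_DP": 0.0,
        "phos_dFdC_DP": 0.1,
        "dephos_dFdC_TP": 0.0,
        "incorp_dFdC_TP": 0.1,
        "deam_dFdC": 0.1,
        "deam_dFdC_MP": 0.01,      # effective first-order, divided by n(dCMPD)
        "phos_dFdU": 1.0,
        "dephos_dFdU_MP": 0.0,     # 5'-nucleotidase back-step
        "phos_dFdU_MP": 0.1,
        "phos_dFdU_DP": 0.1,
        "incorp_dFdU_TP": 0.1,
        "prod_CDP": 215000.0,      # zeroth order, calibrated against the dCTP pool
        "reduce_CDP": 1.0,         # effective first-order, divided by n(RR)
        "phos_dCDP": 1.0,
        "incorp_dCTP": 1.0,
    }


@dataclass
class ModelConfig:
    """Configuration for :func:`build_gemcitabine_network`.

    ``rates`` holds the cascade rate constants keyed by reaction id; the
    three catalysed steps (``phos_dFdC``/``phos_dFdU`` via dCK,
    ``deam_dFdC_MP`` via dCMPD, ``reduce_CDP`` via RR) are given as
    *effective first-order* constants at the nominal enzyme copy numbers
    in ``enzyme_amounts`` and converted internally to second-order
    constants k2 = k_eff / n_enzyme.  This keeps the calibrated cascade
    (fit without inhibitors, where enzyme levels are constant)
    consistent with the explicit-enzyme network at its nominal amounts.
    """

    rates: dict[str, float] = field(default_factory=_default_rates)
    inhibitions: dict[str, InhibitionSpec] = field(default_factory=_default_inhibitions)
    enzyme_amounts: dict[str, float] = field(
        default_factory=lambda: {"dCK": 1e5, "RR": 1e5, "dCMPD": 1e5}
    )

    def merged_rates(self) -> dict[str, float]:
        r = _default_rates()
        unknown = set(self.rates) - set(r)
        if unknown:
            raise KeyError(f"unknown rate keys: {sorted(unknown)}")
        r.update(self.rates)
        return r


_CATALYSED = {"phos_dFdC": "dCK", "phos_dFdU": "dCK",
              "deam_dFdC_MP": "dCMPD", "reduce_CDP": "RR"}


def build_gemcitabine_network(config: ModelConfig | None = None) -> NetworkModel:
    """Construct the full gemcitabine/dCTP reaction network.

    Reaction groups: membrane transport of dFdC and dFdU; the dFdC
    phosphorylation cascade (first step via free dCK); the dFdU cascade
    (first step via free dCK); the two deaminations (dFdC->dFdU
    first-order, dFdC-MP->dFdU-MP via free dCMPD); DNA incorporation of
    dFdC-TP, dFdU-TP and dCTP as absorbing sinks; the endogenous
    CDP -> dCDP -> dCTP cascade with zeroth-order CDP production and
    reduction via free RR; and the three inhibitory bindings.
    Optional back-dephosphorylation steps default to rate 0.
    """
    config = config or ModelConfig()
    rates = config.merged_rates()
    inhib = config.inhibitions
    for key in ("dCK", "RR", "dCMPD"):
        if key not in inhib:
            raise ValueError(f"missing InhibitionSpec for {key}")
    rr = inhib["RR"]
    if rr.k_dissoc != IRREVERSIBLE:
        raise ValueError("the RR inhibition must be IRREVERSIBLE")
    for v in rates.values():
        if v < 0:
            raise ValueError("rate constants must be >= 0")

    species = [
        Species("dFdC-out", "extracellular"),
        Species("dFdU-out", "extracellular"),
        *(Species(m) for m in METABOLITES),
        Species("dCK", role="enzyme"),
        Species("RR", role="enzyme"),
        Species("dCMPD", role="enzyme"),
        Species("DNA-dFdC", role="sink"),
        Species("DNA-dFdU", role="sink"),
        Species("DNA-dCTP", role="sink"),
    ]

    def first(rid, a, b):
        return Reaction(rid, ((a, 1),), ((b, 1),), rates[rid])

    def catalysed(rid, sub, prod):
        enz = _CATALYSED[rid]
        n_e = config.enzyme_amounts[enz]
        if n_e <= 0:
            raise ValueError(f"enzyme amount for {enz} must be > 0")
        k2 = rates[rid] / n_e
        return Reaction(rid, ((sub, 1), (enz, 1)), ((prod, 1), (enz, 1)), k2)

    reactions = [
        # transport
        first("influx_dFdC", "dFdC-out", "dFdC"),
        first("efflux_dFdC", "dFdC", "dFdC-out"),
        first("influx_dFdU", "dFdU-out", "dFdU"),
        first("efflux_dFdU", "dFdU", "dFdU-out"),
        # dFdC phosphorylation cascade (NMPK/NDPK folded into rates)
        catalysed("phos_dFdC", "dFdC", "dFdC-MP"),
        first("dephos_dFdC_MP", "dFdC-MP", "dFdC"),
        first("phos_dFdC_MP", "dFdC-MP", "dFdC-DP"),
        first("dephos_dFdC_DP", "dFdC-DP", "dFdC-MP"),
        first("phos_dFdC_DP", "dFdC-DP", "dFdC-TP"),
        first("dephos_dFdC_TP", "dFdC-TP", "dFdC-DP"),
        first("incorp_dFdC_TP", "dFdC-TP", "DNA-dFdC"),
        # deamination branch
        first("deam_dFdC", "dFdC", "dFdU"),
        catalysed("deam_dFdC_MP", "dFdC-MP", "dFdU-MP"),
        # dFdU cascade
        catalysed("phos_dFdU", "dFdU", "dFdU-MP"),
        first("dephos_dFdU_MP", "dFdU-MP", "dFdU"),
        first("phos_dFdU_MP", "dFdU-MP", "dFdU-DP"),
        first("phos_dFdU_DP", "dFdU-DP", "dFdU-TP"),
        first("incorp_dFdU_TP", "dFdU-TP", "DNA-dFdU"),
        # endogenous dCTP synthesis cascade
        Reaction("prod_CDP", (), (("CDP", 1),), rates["prod_CDP"]),
        catalysed("reduce_CDP", "CDP", "dCDP"),
        first("phos_dCDP", "dCDP", "dCTP"),
        first("incorp_dCTP", "dCTP", "DNA-dCTP"),
    ]

    # inhibitory bindings
    complexes: list[Species] = []
    for key, spec in inhib.items():
        if spec.enzyme != key:
            raise ValueError(f"InhibitionSpec under key {key!r} names {spec.enzyme!r}")
        cname = spec.complex_name
        complexes.append(
            Species(cname, role="complex", constituents=(spec.enzyme, spec.ligand))
        )
        if spec.k_assoc > 0:
            reactions.append(
                Reaction(
                    f"bind_{key}",
                    ((spec.enzyme, 1), (spec.ligand, 1)),
                    ((cname, 1),),
                    spec.k_assoc,
                )
            )
            if spec.k_dissoc != IRREVERSIBLE and spec.k_dissoc > 0:
                reactions.append(
                    Reaction(
                        f"unbind_{key}",
                        ((cname, 1),),
                        ((spec.enzyme, 1), (spec.ligand, 1)),
                        spec.k_dissoc,
                    )
                )
    species.extend(complexes)

    moieties = [
        frozenset({"dCK", inhib["dCK"].complex_name}),
        frozenset({"RR", inhib["RR"].complex_name}),
        frozenset({"dCMPD", inhib["dCMPD"].complex_name}),
    ]
    return NetworkModel(species, reactions, moieties)


def initial_state(
    config: ModelConfig | None = None,
    dfdc_out: float = 0.0,
    endogenous: dict[str, float] | None = None,
) -> dict[str, float]:
    """Initial copy-number map: enzymes at nominal amounts, drug outside.

    ``endogenous`` optionally supplies pre-equilibrated CDP/dCDP/dCTP
    (and complex) levels, e.g. from :func:`gemkin.calibrate.pre_equilibrate`.
    """
    config = config or ModelConfig()
    state = {name: 0.0 for name in config.enzyme_amounts}
    state.update(config.enzyme_amounts)
    state["dFdC-out"] = float(dfdc_out)
    if endogenous:
        state.update(endogenous)
    return state


# ---------------------------------------------------------------------------
# Plain-text reaction-list round trip
# ---------------------------------------------------------------------------

def _side_to_str(side: tuple[tuple[str, int], ...]) -> str:
    if not side:
        return "0"
    parts = []
    for name, c in side:
        parts.append(name if c == 1 else f"{c} {name}")
    return " + ".join(parts)


def _parse_side(text: str) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if text == "0" or not text:
        return ()
    out = []
    for term in text.split("+"):
        toks = term.split()
        if len(toks) == 1:
            out.append((toks[0], 1))
        elif len(toks) == 2:
            out.append((toks[1], int(toks[0])))
        else:
            raise ValueError(f"cannot parse reaction side term {term!r}")
    return tuple(out)


def write_reaction_list(model: NetworkModel, path) -> None:
    """Write the model as a tab-separated reaction list (one per line)."""
    with open(path, "w") as fh:
        fh.write("# id\treaction\trate_constant\n")
        for r in model.reactions:
            fh.write(
                f"{r.id}\t{_side_to_str(r.reactants)} -> "
                f"{_side_to_str(r.products)}\t{r.rate_constant:.10g}\n"
            )


def read_reaction_list(path) -> NetworkModel:
    """Read a tab-separated reaction list back into a NetworkModel.

    Species roles/compartments are not stored in the text format; every
    species is reconstructed as an intracellular metabolite, which is
    sufficient for simulation (kinetics depend only on stoichiometry).
    """
    reactions = []
    names: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, eqn, rate = line.split("\t")
            lhs, rhs = eqn.split("->")
            r = Reaction(rid, _parse_side(lhs), _parse_side(rhs), float(rate))
            reactions.append(r)
            for name, _ in r.reactants + r.products:
                if name not in seen:
                    seen.add(name)
                    names.append(name)
    return NetworkModel([Species(n) for n in names], reactions)
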