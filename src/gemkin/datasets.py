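"""Bundled HepG2 observation tables and the package's calibrated rates.

Two small tables ship with the package: the intracellular metabolite
concentrations measured in HepG2 cells at 0/4/12/24 h (pmol per mg of
cellular protein) and their published molecule-count equivalents for
the gemcitabine branch.  ``load_calibrated_rates`` returns the rate set
produced by this package's own calibration pipeline (regenerate with
``gemkin fit`` or :func:`gemkin.calibrate.fit_parameters`).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .calibrate import (
    ObservationTable,
    UnitConstants,
    estimate_initial_extracellular,
)

__all__ = [
    "load_hepg2_concentrations",
    "load_hepg2_counts",
    "hepg2_fit_observations",
    "load_calibrated_rates",
    "default_cascade_init",
]


def _data(name: str):
    return resources.files("gemkin").joinpath("data").joinpath(name)


def load_hepg2_concentrations() -> ObservationTable:
    """Measured metabolite concentrations (pmol/mg protein, 0/4/12/24 h)."""
    with resources.as_file(_data("hepg2_concentrations.csv")) as p:
        return ObservationTable.from_csv(p, unit="pmol_per_mg")


def load_hepg2_counts() -> ObservationTable:
    """Published per-cell molecule counts of the gemcitabine branch."""
    with resources.as_file(_data("hepg2_counts.csv")) as p:
        return ObservationTable.from_csv(p, unit="molecules")


def hepg2_fit_observations(
    constants: UnitConstants | None = None,
) -> ObservationTable:
    """Count-unit calibration target: all eight metabolites plus dFdC-out.

    Metabolite counts are converted from the concentration table; the
    extracellular pool is the 4 h metabolite sum at t = 0 and (drug
    essentially fully taken up) 0 afterwards.
    """
    conc = load_hepg2_concentrations()
    counts = conc.to_counts(constants)
    out0 = estimate_initial_extracellular(conc, constants)
    col = np.zeros((counts.timepoints.size, 1))
    col[counts.timepoints == 0.0] = out0
    return ObservationTable(
        counts.timepoints,
        ["dFdC-out"] + list(counts.species),
        np.hstack([col, counts.values]),
        "molecules",
    )


def default_cascade_init() -> dict[str, float]:
    """Heuristic initial guess for the cascade fit.

    Derived from flux balance on the count table: the extracellular
    pool empties within hours (influx ~0.3/h); the intracellular dFdC
    pool is small against the throughput, so its clearance is fast
    (~5/h); the MP/DP and TP/DP pool ratios suggest near-equilibrated
    phosphorylation steps with a slow net drain through DNA
    incorporation (~0.1/h); the dFdU branch carries ~2% of the flux.
    """
    return {
        "influx_dFdC": 0.3,
        "efflux_dFdC": 0.01,
        "phos_dFdC": 5.0,
        "dephos_dFdC_MP": 0.3,
        "phos_dFdC_MP": 3.0,
        "dephos_dFdC_DP": 0.4,
        "phos_dFdC_DP": 1.0,
        "dephos_dFdC_TP": 0.5,
        "incorp_dFdC_TP": 0.08,
        "deam_dFdC": 0.09,
        "deam_dFdC_MP": 0.005,
        "efflux_dFdU": 0.05,
        "phos_dFdU": 1.0,
        "dephos_dFdU_MP": 0.05,
        "phos_dFdU_MP": 0.3,
        "phos_dFdU_DP": 0.5,
        "incorp_dFdU_TP": 0.5,
    }


def load_calibrated_rates() -> dict[str, float]:
    """Cascade rates fitted by this package's calibration pipeline."""
    with resources.as_file(_data("calibrated_rates.yaml")) as p:
        with open(p) as fh:
            doc = yaml.safe_load(fh)
    return {k: float(v) for k, v in doc["rates"].items()}
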