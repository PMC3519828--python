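# Methods

## The model

`gemkin` implements a continuous-time discrete-state stochastic model of
intracellular gemcitabine (dFdC) metabolism in a single cell, as an explicit
mass-action reaction network (27 reactions over 22 species). Two cascades
compete for DNA incorporation:

* **Drug cascade.** Extracellular dFdC enters the cell (first-order influx,
  standing in for hENT1/hCNT1 transport) and is phosphorylated stepwise:
  dFdC → dFdC-MP (catalysed by free deoxycytidine kinase, dCK, explicit
  second order), then dFdC-MP → dFdC-DP → dFdC-TP (NMPK/NDPK folded into
  first-order constants). dFdC-TP is incorporated into DNA, modelled as an
  absorbing sink. A deamination branch converts dFdC → dFdU (cytidine
  deaminase folded into a first-order rate) and dFdC-MP → dFdU-MP (catalysed
  by free deoxycytidylate deaminase, dCMPD); the dFdU cascade mirrors the
  dFdC one, with its first phosphorylation also routed through free dCK.
* **Endogenous cascade.** CDP is produced at a constant (zeroth-order) rate,
  reduced to dCDP by free ribonucleotide reductase (RR, second order),
  phosphorylated to dCTP, and incorporated into DNA.

Three inhibitory bindings couple the cascades and are the object of the
sensitivity experiments:

1. **dCK inhibition** — dCTP binds dCK reversibly, throttling the
   rate-limiting first phosphorylation of both dFdC and dFdU;
2. **RR inhibition** — dFdC-DP binds RR irreversibly (no dissociation
   reaction exists, by construction), shutting down dCTP synthesis;
3. **dCMPD inhibition** — dFdC-TP binds dCMPD reversibly, throttling the
   monophosphate deamination branch.

Only free enzyme is catalytically active, so each enzyme's total
(free + complexed) copy number is a conserved moiety; the build audits this
structurally (every reaction's net stoichiometric change over each moiety
set is zero) and the test suite asserts it on every stochastic trajectory.

Assumptions inherited from the modelled system: deamination is intracellular
only; enzymes that take part in no inhibition are absorbed into rate
constants; transport is mass-action (no saturation); all kinetics are
elementary with order ≤ 2. Back-dephosphorylation steps
(dFdC-MP → dFdC, dFdC-DP ↔ dFdC-MP, dFdC-TP ↔ dFdC-DP, dFdU-MP → dFdU;
5′-nucleotidases and reverse kinase steps) are included as optional
reactions defaulting to zero; the calibration estimates them. The
dFdC-MP → dFdC step matters: without any route back to free intracellular
dFdC, the measured persistence of dFdC at 12–24 h (5.0e4 and 5.0e3
molecules/cell while the extracellular pool is exhausted within hours) is
unreachable by any parameterization.

Units: time in hours; amounts in molecules per cell; second-order constants
in /molecule/h.

## Unit conversion and initial conditions

Measured concentrations (pmol per mg of cellular protein, sampled at
0/4/12/24 h) are converted to per-cell counts with
1 mg protein = 12×10⁶ cells, i.e. 8.33×10⁻⁸ mg/cell and

    count = conc × 10⁻¹² mol × N_A / (12×10⁶)  ≈  conc × 5.02×10⁴.

The initial extracellular dFdC pool is unknown and is estimated as the sum
of all eight intracellular metabolites at 4 h (≈9.70×10⁶ molecules),
assuming negligible degradation and no export of phosphorylated metabolites
over the first hours.

The endogenous cascade is calibrated so the drug-free steady-state dCTP pool
is 215,000 molecules/cell. Because at steady state every CDP produced leaves
through dCTP incorporation (the reversible dCK binding carries no net flux),
flux balance gives `prod_CDP = incorp_dCTP × 215,000` in closed form; the
package verifies this by integrating the drug-free network to steady state
(tolerance: relative state change < 10⁻⁶/h). Note the known inconsistency in
the source constants: 38.4 µM × 0.943 pL × N_A ≈ 2.2×10⁷ molecules, about
100× the stated per-cell average; the calibration deliberately targets the
stated 215,000 and does not attempt to reconcile the two.

## Calibration

Rates are estimated by Nelder-Mead least squares in log₁₀ parameter space
against the count-converted time series, with relative per-cell weights
`w = 1/obs²` (zero cells fall back to the species maximum). Counts span
5×10³–10⁷, so unweighted least squares would see only the largest pools,
and per-species weighting (1/max²) still lets the optimizer park a species'
low-count late samples at ~100% error. The objective targets the
deterministic mean-field ODE, never stochastic output, so it is smooth and
deterministic; seeded multi-start perturbations (log₁₀ s.d. 0.7, default
10 restarts) guard against local minima.

Calibration is two-stage:

1. **Cascade fit.** The drug cascade without inhibitors is linear (constant
   enzyme pools fold into first-order constants), so the objective solves
   the system exactly via a matrix exponential; Nelder-Mead fits the 17
   cascade rates.
2. **Full-network refinement.** The cascade rates are refit jointly with
   the dCK association/dissociation rates, the RR and dCMPD association
   rates, and the dCTP turnover rate (CDP production stays tied to the
   215,000 target) on the full inhibited network. This stage exists for a
   structural reason: the measured dFdC/dFdC-MP ratio falls ~17× between
   4 h and 24 h, which no linear chain can produce once the extracellular
   pool is empty. In the full network, dCTP depletion (RR inhibited by
   dFdC-DP) progressively releases the dCK:dCTP complex, accelerating the
   first phosphorylation late — the model's own central mechanism supplies
   the required time-varying rate. The refinement also grounds the
   *control* inhibition propensities in data instead of fixing them
   arbitrarily.

The refined rate set ships with the package (`gemkin.datasets.
load_calibrated_rates`) and is reproducible with `gemkin fit`.

Nominal enzyme amounts are 10⁵ copies each for dCK, RR and dCMPD (a
mid-range abundance for metabolic enzymes; only products k_cat×E and
k_assoc×E are identifiable from this data, so the absolute level is a
convention that fixes the scale of the association-rate axes). Catalytic
second-order constants are derived as k_eff/E_total.

## Stochastic simulation

Exact Gillespie direct method (small network, exactness is cheap; no
tau-leaping). Two recording modes share one random stream, so they follow
identical sample paths given the same seed: event recording (times +
reaction indices, reconstructed to full paths) and grid recording with
exact on-the-fly AUC accumulation (Σ level × holding time), used by the
sweeps where storing ~10⁸ events is impossible. Cores are numba-compiled
with a pure-NumPy fallback that draws the identical MT19937 sequence.
Replicate seeds derive from `numpy.random.SeedSequence(seed)`.

The mean-field ODE integrator is LSODA with rtol 10⁻⁸ (10⁻⁶ inside fitting
objectives) and atol 10⁻⁶; small negative excursions are clipped at zero
and significant ones raise. For order-≤1 models the fit uses the exact
matrix-exponential propagator instead.

Count scaling by s ∈ (0,1] multiplies copy numbers by s (rounded),
zeroth-order constants by s and divides second-order constants by s, so the
mean-field trajectory scales exactly by s while intrinsic noise grows as
1/√s. Sensitivity experiments run at s = 10⁻³.

## Sensitivity experiments

AUC over 0–24 h of dFdC-TP (exposure/efficacy surrogate) and dCTP is
recorded over log-spaced grids of the inhibition association rates and
the influx rate. Axes span six decades *centred on the calibrated
control value* of the swept rate (exactly 0 is allowed and disables a
binding): the sweeps model metabolic variation around the reference
condition, and anchoring to the control guarantees the range brackets
both the inhibition-negligible and the inhibition-saturated regime
whatever absolute scale the calibration produced. An absolute axis
helper (10⁻⁹–10⁻³ /molecule/h) is also provided. The dissociation rates
of the reversible inhibitions stay at their calibrated control values. Each grid point
averages ≥20 seeded SSA replicates; replicate seeds are shared across grid
points (common random numbers), which reduces the variance of cross-point
comparisons and makes surfaces over irrelevant parameters exactly flat.
AUCs are reported on the unscaled count scale (divided by s).

Every grid point re-derives its own drug-free steady state before the
dose is administered (each swept condition is its own metabolic regime);
inheriting the control equilibrium instead would let the control's loaded
dCK:dCTP complex release its dCTP into weak-binding conditions and
distort the dCTP exposure there. The enzyme-abundance factorial likewise
re-equilibrates each condition with its own total enzyme amounts.

Two summary statistics: the **complementarity score** (Spearman rank
correlation between the AUC(dFdC-TP) and AUC(dCTP) arrays over a grid;
strongly negative = the anti-coupled regime induced by strong RR
inhibition) and the **efficacy ratio** AUC(dFdC-TP)/AUC(dCTP), oriented so
larger is more efficacious, which across enzyme-abundance conditions rises
with the dCK/RR ratio. Both return NaN (UNDEFINED) on degenerate input
(constant arrays, zero denominator). Monotonicity claims are always
asserted on replicate means with a 2-standard-error slack, never on single
runs.

In the enzyme-abundance factorial the initial free-enzyme copy numbers are
replaced per condition while rate constants stay fixed; the endogenous
complex pools are left at the control equilibrium (the re-equilibration
transient is short against the 24 h horizon).

## Synthetic data

`generate_observations` emulates the calibration's data shape: mean-field
counts of the eight metabolites sampled on the sparse 0/4/12/24 h design
(or a dense 25-point design for recovery tests) with mean-one
multiplicative lognormal noise (counts are positive and span four decades;
the default cv is 0.1). It does **not** emulate measurement workflow
effects (extraction efficiency, LC-MS calibration, detection limits), so
passing recovery tests demonstrate statistical correctness of the fitting
machinery, not robustness to real assay artefacts. Toy linear chains
(single exponential; two-step cascade with the classic closed-form
solution) serve as independent oracles.

## Problem sizes and numerical choices

Test-suite experiment sizes: 20 SSA replicates per grid point at scaling
10⁻³ for sweeps; 6-point association axes; a 5×5 enzyme factorial; 200
replicates for the exponential/cascade statistical oracles at 3 standard
errors; 2 replicates for the scaling-1 SSA/ODE comparison (counts there
make sampling error ≪ 5%, and species with mean-field counts below 2×10³
are excluded from the 5% bound since sampling noise alone exceeds it); 20
noisy refits for the noise-recovery check. Nelder-Mead uses xatol 10⁻⁴–10⁻⁶
in log₁₀ units and adaptive simplex parameters. Ties in the sweep
monotonicity checks are accepted within 2 standard errors of the replicate
means.

## Known limitations

* The fit is a phenomenological compromise: with four timepoints and eight
  observed species, the 22 refined rates are not individually identifiable;
  only the fitted trajectory and the products k×E are constrained. The
  sparse-design test asserts fit quality, deliberately not per-rate
  recovery.
* The calibrated trajectory does not reproduce every measured cell tightly:
  the dFdC-MP series and the 4 h dFdC-TP point carry residuals of roughly
  a quarter to a third of the observed value at the optimum, across
  multistart Nelder-Mead and a differential-evolution search. Two features
  of the data sit outside this reaction structure: the dFdC-MP pool rises
  between 4 and 12 h and then halves while all of its source pools fall
  monotonically, and the dFdC-TP/dFdC-DP ratio drifts from 2.05 to 1.06
  although the early throughput requires a fast, constant DP↔TP exchange
  that pins this ratio once equilibrated. Matching them would need
  regulation (e.g. of NMPK/NDPK activity) that elementary mass action with
  constant rate constants cannot express.
* The anti-coupled (complementary) dFdC-TP/dCTP regime appears for RR
  association rates in the decade around and above the calibrated control
  value, and dissolves at the top of the swept range: there RR inhibition
  saturates for every dCK condition (RR survival decays with the dFdC-DP
  exposure, and some conversion always leaks through), so dCTP is uniformly
  depleted and a rank correlation across conditions reads ~0 rather than
  strongly negative.
* DNA incorporation is an absorbing sink; downstream pharmacodynamics
  (S-phase arrest, apoptosis, toxicity) and cell-to-cell heterogeneity are
  out of scope.
* Transport is linear; transporter saturation and extracellular deamination
  are not modelled.
* The dCTP-pool constants carry the ~100× source inconsistency noted above.
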