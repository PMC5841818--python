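# Methods

`fuelswitch` models whole-body fuel selection — the balance between glucose
and fatty-acid (FA) catabolism as ATP demand rises during exercise — with a
thermodynamically constrained model of central catabolism in three
compartments (extracellular space, cytosol, mitochondrion). It combines a
per-time-point constraint-based flux solve with a 98-state kinetic ODE model
driven by an imposed ATP-hydrolysis rate, and layers fitting, sensitivity
and capacity analyses on top. The package is exercised entirely on
synthetic data with known ground truth; this note records the model, its
assumptions, the numerical choices, and what the synthetic conditions do and
do not establish about real physiology.

## The network

The canonical network (packaged as `data/network.json`, regenerated by
`scripts/build_network.py` + `scripts/polish_concentrations.py`) has exactly
**98 species and 87 reactions**: six boundary exchanges (glucose, FA and O2
in; lactate, CO2 and H2O out), substrate and gas transport, the ten
glycolytic steps plus lactate dehydrogenase and lactate export, the
glycerol-3-phosphate shuttle, the mitochondrial pyruvate carrier and PDH,
the eight TCA steps, palmitate activation (acyl-CoA synthetase producing AMP
and PPi) and the carnitine shuttle (CPT1, the translocase, CPT2), a
seven-round beta-oxidation spiral (C16 → C4 in two-carbon steps, four
enzymatic steps per round with explicit FAD/FADH2 and a shared ETF:Q
oxidoreductase), acyl-carnitine pool handling for the six measured pools
(C16, C14, C8, C4, acetyl, free carnitine), oxidative phosphorylation
(Complex 1, lumped Complex 3+4, ATP synthase, ANT, the phosphate carrier)
and the bioenergetic reactions (the driven ATPase, creatine kinase,
adenylate kinase, a matrix nucleoside-diphosphate kinase closing the
GTP-linked succinyl-CoA synthetase, and inorganic pyrophosphatase).

Conventions worth knowing:

* **Carbon bookkeeping** counts catabolic skeleton carbons only; carrier
  moieties (CoA, NAD, FAD, Q, adenine nucleotides, carnitine, creatine)
  carry zero. Every non-boundary reaction is then exactly carbon-balanced,
  which the loader enforces.
* **The protonmotive force** is a pseudo-species (`dpsi_m`) whose
  "concentration" enters mass-action ratios like any species; its log is the
  electrochemical potential in units of RT per charge (ln-concentration
  ≈ F·ΔΨ/RT, so a value near 600 corresponds to ≈165 mV). Complex 1 pumps 4
  charges per NADH, Complex 3+4 pumps 12 per O2, ATP synthesis costs 3, and
  ANT and the phosphate carrier cost 1 each — an integer-stoichiometry P/O
  of 2.0 for NADH.
* **Standard transformed free energies** are fixed at 25 °C and pH 7
  (pH is never a state variable), compiled from standard textbook/database
  values; transport steps and transesterifications are assigned ΔG′⁰ = 0,
  water is held at unit activity, and the boundary exchanges carry a nominal
  −30 kJ/mol so they are one-way in the physiological concentration range.

## Thermodynamics and the resting state

The transformed reaction free energy is ΔG′ = ΔG′⁰ + RT ln Q with Q the
product/substrate mass-action ratio (1 M reference). A concentration vector
is feasible for a flux pattern J when ΔG′_k·J_k < 0 for every
flux-carrying reaction. Two routes produce such vectors:

* a **Monte Carlo sampler** (`thermo.sample_feasible_concentrations`):
  log-uniform draws between the per-species literature bounds, with a
  coordinate repair mode that resamples only the species of violated
  reactions, and a final all-or-nothing re-check (strictness margin
  10⁻⁹ kJ/mol);
* the **packaged resting vector**: a deterministic linear-programming polish
  (dissipation margins are linear in log-concentration) frozen into the
  network file. Margins are targeted per reaction class: near-equilibrium
  steps rest ≈0.4 kJ/mol from equilibrium — which makes their algebraically
  assigned activities large, giving bidirectional buffering — while the
  committed steps (the kinases of upper glycolysis, the dehydrogenase
  complexes, citrate synthase, the thiolases, the respiratory pumps, ATP
  hydrolysis) keep multi-kJ displacements so that transient surpluses
  throttle them rather than run them backwards (e.g. reverse electron
  transport through Complex 1).

Reactions with no resting flux (creatine kinase, the acyl-carnitine
transferases and translocases) have their side-pool species solved
analytically to ΔG′ = 0 at t = 0, so the packaged state is an exact steady
state of the kinetic model at the resting demand (verified: <1% drift over
50 simulated minutes).

## Constraint-based solve

At each protocol time point, `cba.solve_timepoint` solves S·J = 0 with the
six exchange columns pinned to the measured boundary values, maximizing
mitochondrial ATP production (flux through ATP synthase) with HiGHS, then
breaking ties by minimizing total flux magnitude (the parsimonious
solution, which also strips any sign-consistent internal cycle). A
null-space cycle scan backstops the loop law, escalating to an ll-FBA MILP
(binary direction indicators, big-M) when a cycle is active; the canonical
network's direction-bounded flux space contains no internal cycles — its
null space is exactly the three physiological catabolic modes (glucose
oxidation, palmitate oxidation, glycolysis-to-lactate).

Because the network stores no fuel, exchange fluxes must close elementally
(JO2 = JCO2 + 7·J_FA in a storage-free network); noisy inputs never do, so
exchange columns are pinned within a small band (±2% or ±2σ when variances
are supplied) instead of strict equality. Lactate export is left free and
non-negative by default and absorbs the carbon imbalance, which is also how
the solver decides the aerobic/anaerobic split.

The **inner-membrane proton leak** appears in the solve as a virtual flux
on the pmf pseudo-species coupled to the pumps
(L = f·(4·J_C1 + 12·J_C3+4), resting fraction f = 0.15, the scale of
state-4 respiration), so the measured resting O2 uptake funds both
phosphorylating and leak respiration, and the extracted ATPase demand curve
is correspondingly lower. The ATPase fluxes of a solved series are fitted
with a degree-3 least-squares polynomial (clamped ≥ 0) to drive the
kinetics.

## Kinetic model

State: the 98 concentrations (molar). Dynamics: dC/dt = P⁻¹·S·J(C) with P
the diagonal matrix of effective compartment water volumes (0.755 L water
per kg muscle × volume fractions 0.2/0.75/0.05). Every reaction follows
the generalized thermodynamic rate law

    J_k = X_k · Ct_k · (1 − e^{ΔG′_k/RT}) / (1 + e^{(ΔG′_k−ΔG′⁰_k)/RT}),
    Ct_k = Π C_i^μ_i + Π C_i^ν_i ,

whose sign always opposes ΔG′ — mass action plus the second law are the
only kinetic assumptions (no saturation constants, no allosteric
regulation, no calcium activation). The ATP-demand reaction is not given a
rate law: it runs at the protocol's demanded rate, attenuated smoothly
(×[ATP]/([ATP]+10⁻⁶ M)) so an unmeetable demand produces a detectable,
integrable collapse rather than a solver abort. A collapse is flagged only
when cytosolic ATP stays below 25% of its initial value (terminally, or
for over two minutes): brief dips with full recovery occur as bounded
relaxation oscillations of the acetyl buffers at sustained surplus and are
not failures.

Numerical choices:

* integration in **log-concentration space** with BDF and a
  stoichiometry-derived Jacobian sparsity pattern — positivity is
  structural (the analogue of a non-negativity solver option) and the
  tolerances act on relative concentration errors. Default tolerances are
  1e-10/1e-12 (`SolverOptions()`); fitting loops and scans use 1e-6/1e-9
  (`SolverOptions.fast()`), under which a 50-minute protocol integrates in
  well under a second;
* the pmf pseudo-species gets a small capacitance (10⁻⁴ × its compartment
  water volume) so the potential equilibrates in seconds, as a membrane
  potential should, and a **non-ohmic leak** g·dpsi³ whose conductance is
  calibrated to the resting leak fraction. The leak is the model's
  pressure-relief: without it any capacity surplus backs the respiratory
  chain up (ΔΨ and NADH rise, oxaloacetate is crushed through the
  near-equilibrium MDH, and acetyl-CoA sequesters the CoA and carnitine
  pools);
* boundary species (plasma glucose, FA, O2, CO2 and the waters) are
  clamped; plasma lactate is a free state whose export acts as clearance,
  so it accumulates when glycolytic output exceeds disposal — that is the
  plasma-lactate observable. "Total" acyl-carnitine pools are
  volume-fraction-weighted sums over compartments.

### Activity mobilization

The resting activities X_rest are solved algebraically from the rate law at
the resting fluxes and concentrations; reactions with no resting flux get
the median activity (the fast equilibrium buffers — creatine kinase,
carnitine acetyltransferase and its translocase — get 20× the median,
reflecting their large excess capacity in muscle). Catalytic capacity is
then **mobilized with the work rate** (`ActivitySchedule`):

    X_k(d) = X_rest_k · min(s(d), h·f_k),  s(d) = clip(1 + γ(d/d₀ − 1), 1, h)

with headroom h = 10, tracking margin γ = 1.02 and per-reaction capacity
factors f_k. This is the time-domain counterpart of the monoexponential
rest-to-exercise activity transition the normalized-exercise protocols use
(X(%VO2max) = X_ex + (X_rest − X_ex)·e^{−(%VO2max−%VO2rest)·Tc}, with the
multiplicative-Tc convention): muscle recruits catalytic capacity on the
timescale of the work-rate change, and a resting muscle does not hold its
exercise capacity in the active state. Under this rate law the alternative
— constant activities at full exercise capacity — is dynamically unstable,
because the model deliberately excludes the allosteric throttles (hexokinase
product inhibition, PFK regulation, the malonyl-CoA brake on CPT1) that
let real muscle idle with excess enzyme.

The two knobs separate cleanly and deliberately:

* the **86 base activities** X_rest (every reaction except the driven
  ATPase) are the adjustable parameters — sensitivity analysis and
  ensemble perturbations act here and rescale the whole schedule;
* **capacity factors** f_k carry genotype transforms and hypothesis fits —
  resting metabolism is shared between phenotypes (resting oxygen uptake of
  high- and low-capacity runner lines is alike), and a capacity deficit
  only binds at workloads that exceed the reduced ceiling. The effective
  exercise-activity ratio between phenotypes approaches the reciprocal
  factor ratio.

## Synthetic study conditions

The generator emulates a graded treadmill experiment (speed and therefore
demand stepping every 2 minutes): the high-capacity-like phenotype sustains
50 minutes with peak O2 uptake 4.5 mmol·min⁻¹·kg⁻¹ (5× the resting
0.9 mmol·min⁻¹·kg⁻¹) and a respiratory quotient held in the 0.80–0.87 band;
the low-capacity-like phenotype exhausts at 14 minutes at 2.7 mmol·min⁻¹·kg⁻¹
peak with its RQ driven toward 1 and a larger glycolytic lactate fraction.
O2 and CO2 follow saturating ramps; carbohydrate and FA uptakes are derived
from the prescribed RQ trajectory through indirect-calorimetry stoichiometry
(glucose 6 O2 → 6 CO2; palmitate 23 O2 → 16 CO2; lactate export is
O2-neutral), so the four series close elementally when noise is zero.
Noise is independent Gaussian, truncated at zero: 3% relative SD on gas
fluxes, 10% on lactate, 15% on carnitine pools. Biopsies are taken at 0 and
10 minutes for both phenotypes plus 45 minutes for the high-capacity one.

The canonical ground-truth transform takes the low-capacity phenotype as the
high-capacity one with **all mitochondrial capacities halved and the FA
transport steps (CD36/FAT, CPT1, the translocase, CPT2) reduced a further
5-fold** (so the transport steps' exercise-activity ratio is 10). Every
generator output is a pure function of its specification and seed.

What the synthetic conditions do *not* establish: the generator has no
inter-animal variability structure, no glycogen or triglyceride stores, no
amino-acid catabolism, and its absolute flux magnitudes are
order-of-magnitude physiology rather than calibrated measurements — so
passing recovery tests demonstrates that the pipeline identifies the
generating mechanism under its own model class, not that the specific
numbers transfer to rats.

## Fitting and analyses

The misfit is the mean standardized squared residual pooled over every data
point (gas series, lactate, RQ, biopsies). The RQ series is derived from
the gas fluxes, so including it (the default) double-weights gas exchange;
a flag drops it. Three constrained hypothesis modes (single mitochondrial
factor; single FAO-block factor; mitochondrial factor plus FA-transport
factor with optional forward-selected per-enzyme extras, keep-if-2%-better)
are optimized by coarse log-grid scans plus Nelder–Mead; the free 86-
parameter mode uses seeded simulated annealing in log space (single-
coordinate proposals σ = 0.2, geometric cooling per 25-proposal epoch)
with a Nelder–Mead polish of the most mobile coordinates. Ensembles
perturb the base activities log-normally (default σ = 0.05) and retain
candidates within 1.5× the base error; ratio distributions take all
pairwise combinations of two ensembles' exercise activities.

Sensitivities are central finite differences (±1%) of the log
protocol-averaged RQ with respect to each base activity, ranked by
magnitude (one-sided with a flag if a perturbed run fails). The enzyme
importance score multiplies the between-phenotype median activity ratio by
the median |sensitivity| (a power form is available behind a flag), with
bootstrap SDs over ensemble members.

The **FAO-capacity experiment** multiplies glycolytic capacities (including
glucose transport) by 10⁻⁶, removes creatine kinase, pre-mobilizes the
surviving machinery (mobilization floor 1.5, slope γ = 2 — the leak
dissipates the surplus, and fully rested machinery could not even cover the
resting deficit left by the knockout), and ramps demand linearly
(default slope = resting demand/4 per minute) until cytosolic ATP
collapses below 25% of its initial value. Capacity is the demand level one
minute before collapse; fluxes are reported at a sustained sub-capacity
point (85% of maximum) where the ANT flux tracks the realized demand to
within 5% — in the last pre-collapse minute the draining ATP pool
transiently covers part of the hydrolysis. Under the canonical transform
the low-capacity ceiling sits roughly 70% below the high-capacity one,
dominated by the frozen FA-transport ceiling; milder, free-fitted
reductions give proportionally smaller gaps.

## Problem sizes used

Default budgets keep the full pipeline desk-scale: boundary series of 8–26
time points, 50-minute kinetic protocols at the fast tolerances,
hypothesis fits of 20–80 error evaluations, ensembles of ~10²,
sensitivity over reaction subsets or the full 86 at a 20-minute horizon,
and capacity ramps of ≤60 minutes. All are configurable upward; results
quoted in the README come from the defaults.

## Known limitations

* No glycogen, triglyceride or amino-acid pools: fuel must arrive through
  the sarcolemmal transporters, which caps anaerobic compensation below
  what glycogenolysis provides in vivo and makes the low-capacity
  phenotype's collapse earlier and sharper than real exhaustion.
* No allosteric regulation by design: supply/demand matching rests
  entirely on thermodynamic back-pressure, the membrane leak, and the
  mobilization schedule.
* The mitochondrial-density hypothesis acts only above resting workloads
  (capacity-ceiling semantics), so its one-dimensional fit optimum is not
  directly comparable to formulations that scale resting activity too.
* ΔG′⁰ values are fixed-condition transformed energies; no ionic-strength
  or pH corrections, and the lumped pmf pseudo-species has no ΔpH/ΔΨ split.
* The fitted "activities" are rate-law prefactors with the concentration
  term's units folded in; only ratios and relative changes are
  interpretable, not absolute enzyme amounts.
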