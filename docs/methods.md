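# Methods

Modeling and statistical choices behind `apkpath`, in enough detail to
re-derive every number the package reports.

## Network generation

A design is produced by breadth-first expansion from the source species
under a fixed rule priority:

1. **feeder oxidation** — a non-sugar alcohol source is first oxidized to
   its registered carbonyl entry point (one step, flagged `untested`);
2. **PK cleavage** — any species on the phosphoketolase substrate
   whitelist `{F6P, Xu5P, D-erythrulose, L-erythrulose, DHA,
   glycolaldehyde}` is cleaved to AcP plus the registered C(n−2)
   product. The whitelist is curated, not structure-derived: DHAP and
   erythrulose-4-phosphate are excluded because phosphate anchoring at
   the cleavage end blocks the enzyme;
3. **isomerization / dephosphorylation** — aldose products are converted
   back into cleavable ketoses by the route each has an enzyme for:
   E4P is dephosphorylated first (EcHAD) and then isomerized
   (Ps-LRhI), because no isomerase accepts E4P; G3P is isomerized first
   (EcTIM) and then dephosphorylated (CpHAD), because no enzyme
   isomerizes free glyceraldehyde;
4. **formose condensation** — formaldehyde is condensed by formolase
   (FLS, 3 HCHO → DHA, the default) or glycolaldehyde synthase
   (GALS, 2 HCHO → glycolaldehyde), or deliberately stranded
   (`recycle_mode="none"`).

Each species is expanded at most once, so generation terminates and is
deterministic. Every emitted reaction is checked for backbone carbon
balance against the registry.

## Exact flux analysis

The overall reaction of a design is the solution of the linear system
"net source = −1, net internal species = 0" over the reaction fluxes,
solved symbolically (sympy `linsolve`) and returned as
`fractions.Fraction` values. Internal species are those both produced
and consumed, excluding the source and the terminal products
(AcP/acetate/AcCoA); a species produced but never consumed (stranded
HCHO) appears in the overall reaction instead of making the system
infeasible. The solve fails loudly: free flux directions raise
`AmbiguousFluxError` (reporting the directions), negative or empty
solutions raise `InfeasibleFluxError`. Duplicate-stoichiometry reactions
are collapsed before solving, since only their joint flux is determined.

Carbon yield is carbon-only: `2 × (AcP + acetate + AcCoA) /
n_carbons(source)`. Percent reporting rounds half up (2/3 → 67).
The bundled glycolysis reference (10 glycolytic steps + pyruvate
dehydrogenase) is solved by the same machinery, giving 11 reactions,
2 acetyl-CoA per glucose and a 67% yield with 2 CO₂ lost.

The test suite validates the solver against an independent brute-force
oracle that enumerates all flux vectors on a rational lattice and keeps
those satisfying the constraints; on every bundled network the lattice
solution set is a singleton equal to the solver's answer.

## Cascade kinetics

Concentrations are in mM, time in hours, kcat in s⁻¹, enzyme loadings
in mg·mL⁻¹ with molar masses in kDa (so E[mM] = loading / molar mass).

Rate laws:

- **Shared-active-site competition** (default): substrates of one enzyme
  compete for the same site,
  `v_i = kcat_i·E·(S_i/Km_i) / (1 + Σ_j S_j/Km_j)`.
  This matters for BbPK, which sees up to three substrates at once. An
  `independent` mode (plain MM per substrate) is available; as all Km →
  ∞ at fixed kcat/Km the two coincide.
- **Reversible isomerases** (Ps-LRhI, EcTIM): reversible MM with the
  reverse Vmax fixed by the Haldane relation
  `Vr = Vf·Kmp/(Kms·Keq)`, so the simulated equilibrium honors Keq.
- **Formose condensation**: a single saturating step in HCHO consuming
  3 HCHO (FLS) or 2 HCHO (GALS) per turnover; the multi-step aldol
  mechanism is not resolved.

Integration uses scipy `solve_ivp` LSODA at rtol 1e-8, atol 1e-12.
Concentrations below −1e-9 mM raise `NegativeConcentrationError` rather
than being clipped silently; smaller undershoot is clipped to zero.
Carbon-pool abundances divide pooled backbone carbon by total carbon at
t = 0; `final_yield` is the final acetyl-pool fraction.

### Placeholder parameters

The shipped `default_parameters()` are **not measurements**. They encode
only the documented qualitative structure: F6P and Xu5P cleavage fast
(kcat 5 and 3 s⁻¹, consumed within 2 h at the default loadings),
short-chain cleavage 10–100× slower (DHA 0.1, glycolaldehyde 0.08 s⁻¹)
producing the slow terminal phase, DHA bound more tightly than
glycolaldehyde (Km 15 vs 40 mM), and isomerase Keq values favoring the
ketose. `mutant_parameters()` applies exact catalytic-efficiency folds
to BbPK via kcat scaling: E520I 2.3× (DHA), Q321A 5× (DHA), H142N 8.5×
(glycolaldehyde) and 3.6× (D-erythrulose). Consequently simulated
absolute yields at fixed times (e.g. 0.838 for F6P at 10 h) are
illustrative; only conservation, ordering and asymptotic-yield claims
are asserted by tests.

## Parameter estimation

- **MM initial-rate fits** (lmfit): `v = Vmax·S/(Km+S)` with relative
  weights `1/max(|v|, 10⁻³·v_scale)` matching multiplicative assay
  scatter; 95% Wald intervals. Fits are flagged `unreliable` — never
  silently returned — when the grid has < 5 distinct concentrations, the
  rates carry no signal, the optimizer fails, Km exceeds 10× the largest
  assayed concentration, or an estimate is non-positive. kcat =
  Vmax/(E[mM]·60).
- **Efficiency fold changes** are kcat/Km ratios: loading-scale
  invariant, propagating input unreliability.
- **Cascade calibration**: least squares of simulated vs observed
  concentrations (scaled per species by dynamic range) over selected
  (enzyme, substrate, kcat|Km) parameters, optimized in log10 space with
  Levenberg–Marquardt and seeded multi-start (default 20 starts, ±1
  decade, seed 1729). After the best start converges, each freed
  parameter is perturbed ±1.5×; parameters whose cost profile is flat
  are reported `nonidentifiable`.
- **NNK library sizing**: the smallest N with `1 − (31/32)^N ≥ coverage`
  per-codon (1/20 in the approximate per-residue mode), rounded up to
  whole 96-well plates, times the number of sites. 34 sites at 95% →
  raw 95 → 96/plate → 3264 total.

## Synthetic data

All generators are deterministic under their seed and record the
generating truth in metadata. The default error model is multiplicative
Gaussian with CV 5% (scatter proportional to signal); negative draws are
clipped at zero and the clip count recorded. With `NO_NOISE` the
generators reproduce the analytic MM curve / ODE solution bitwise.
Protein families mutate each position of a recorded ancestor
independently with the given rate to a uniformly chosen *different*
residue, so the column consensus estimates the ancestor.

## Consensus selection

Hit filtering keeps records whose best-hit class matches the target and
whose identity and alignment length are **strictly** above 40% and 600.
The consensus is the column-wise majority with gaps excluded from the
tally (all-gap columns keep a gap); tied columns resolve to the
alphabetically first residue. The representative is the member with the
most consensus-matching columns (or highest non-gap identity fraction
under `metric="identity"`); ties resolve to the earliest row and set
`tie=True`. Both steps are validated against exhaustive brute-force
scoring in the test suite.
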