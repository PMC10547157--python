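# apkpath

Design, stoichiometry and kinetics of the **artificial phosphoketolase
(APK) pathway**: an in vitro enzyme cascade that converts C1–C6 carbon
sources into acetyl-phosphate (AcP) with up to 100% carbon yield.

## The science in one page

Glycolysis converts glucose to 2 acetyl-CoA in 11 reactions but discards
one third of the carbon as CO₂ at the pyruvate dehydrogenase step — a
67% carbon ceiling. The APK pathway instead cleaves sugars iteratively
with **phosphoketolase (PK)**, a ThDP-dependent enzyme that splits the
C2–C3 bond of a ketose into acetyl-phosphate and a two-carbon-shorter
aldose. Repeating cleavage, with isomerization and dephosphorylation
steps to re-create a cleavable ketose from each aldose product, strips a
sugar down two carbons at a time:

- **F6P (C6)** → AcP + E4P → (dephosphorylate, isomerize) → D-erythrulose
  → AcP + glycolaldehyde → AcP. Net: **1 F6P → 3 AcP**, 100% carbon yield,
  using only three core reaction types (cleavage, isomerization,
  dephosphorylation).
- **Xu5P (C5)** → AcP + G3P → (isomerize, dephosphorylate) → DHA →
  AcP + formaldehyde. The odd carbon leaves as HCHO; a **formolase (FLS)**
  condenses 3 HCHO back into DHA, closing the loop. Net:
  **1 Xu5P → 5/2 AcP** — still 100% carbon yield, and an exact rational
  stoichiometry.

Because formaldehyde can be condensed into the cycle, even C1 feedstocks
(methanol via formaldehyde) reach 100% theoretical carbon yield to AcP,
which phosphate acetyltransferase converts to acetyl-CoA.

The package implements this system end to end:

| Module | What it does |
|---|---|
| `species` | Curated species registry and enzyme capability table (PK substrate whitelist, isomerase/phosphatase pairs, formose variants) |
| `network` | Rule-based generator producing the cascade for any registered source, with routing policy and validation |
| `stoichiometry` | Exact rational flux solve (sympy) → overall reaction and carbon yield; bundled glycolysis reference |
| `kinetics` | Michaelis–Menten ODE cascade simulation (scipy LSODA) with shared-active-site substrate competition, carbon-pool bookkeeping |
| `fitting` | MM initial-rate fits (lmfit), efficiency fold changes, cascade calibration against time courses, NNK saturation-library sizing |
| `synthetic` | Seeded generators for assays, time courses and toy protein families, with declared noise structure |
| `consensus` | Homology hit filtering (identity > 40%, length > 600, strict) and consensus-closest representative selection |

## Worked example

Generate the xylulose-5-phosphate design and solve its exact yield:

```bash
$ apkpath yield --source Xu5P
overall: 1 Xu5P -> 5/2 AcP
AcP per Xu5P: 5/2
carbon yield: 1 (100%)
```

Simulate the F6P cascade with the bundled kinetics and watch the carbon
move between pools (fractions of total carbon; columns are hours):

```python
>>> import apkpath as ap
>>> design = ap.generate("F6P", "fls")
>>> ds = ap.simulate(design, ap.default_parameters(), {"F6P": 10.0})
>>> ap.carbon_abundance(ds, ap.default_pools(design)).round(3)
     0.0    2.0    4.0    6.0    8.0    10.0
F6P   1.0  0.000  0.000  0.000  0.000  0.000
Ac    0.0  0.493  0.618  0.712  0.784  0.838
C4    0.0  0.381  0.209  0.113  0.059  0.030
C2    0.0  0.126  0.173  0.176  0.157  0.132
>>> round(ap.final_yield(ds), 3)
0.838
```

The qualitative shape is the cascade's signature: the hexose is consumed
within 2 h (fast cleavage), carbon piles up transiently in the C4 and C2
intermediates, and the acetyl pool climbs toward the stoichiometric
limit on a slow short-chain tail (it reaches 1.000 ± 10⁻³ by ~200 h in
simulation).

Size a saturation-mutagenesis screen (NNK codons, 95% per-codon
coverage, 96-well plate rounding, 34 sites):

```python
>>> ap.nnk_screen_size(sites=34, coverage=0.95)
NNKScreenSize(clones_per_library=96, total_clones=3264, raw_clones=95)
```

## Reproduction

`scripts/acceptance.py` recomputes the headline numbers from scratch:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

| Target | Value | Meaning |
|---|---|---|
| t1 | 67 | glycolysis reference carbon yield (%) |
| t2 | 100 | APK theoretical carbon yield with HCHO recycling (%), identical over DHA, D-erythrulose, Xu5P, F6P |
| t3 | 2 | acetyl-CoA per glucose via glycolysis |
| t4 | 3 | distinct core reaction types in the F6P design |
| t5 | 11 | glycolysis reference reaction count |
| t6 | 96 | clones per single-site NNK library (95% per-codon coverage, plate-rounded) |
| t7 | 3264 | total clones across the 34-site screen |

All of these are exact (rational flux solves and integer arithmetic), so
the `--seed` argument does not change them; the script verifies that.

## Honest limitations

- **The default kinetic constants are placeholders**, not measured
  values. They respect the qualitative ordering of the real system (fast
  F6P/Xu5P cleavage, much slower short-chain cleavage, DHA bound tighter
  than glycolaldehyde) and the engineered-mutant efficiency ratios
  (2.3×, 5×, 8.5×, 3.6×) are encoded exactly, but absolute simulated
  concentrations and times are illustrative. Measured wet-lab yields are
  therefore *not* asserted numerically anywhere; the test suite instead
  checks conservation laws, convergence to exact stoichiometry, and
  generate-then-fit recovery. See `docs/methods.md`.
- The five alcohol feeder entries (methanol, ethylene glycol,
  ethanolamine, glycerol, erythritol) are modeled as single oxidation
  steps and carry an `"untested"` flag: they are design proposals, not
  characterized reactions.
- Yield accounting is carbon-only; ATP/NAD(P)H/CoA/Pi cofactor balances
  are out of scope.
- Tie-breaks that the underlying procedures leave open are resolved
  deterministically and flagged: tied consensus columns go to the
  alphabetically first residue, tied representatives to the earliest
  input row (with `tie=True` on the result).
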