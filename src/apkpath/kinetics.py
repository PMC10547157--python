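"""Deterministic ODE simulation of the in vitro APK enzyme cascades.

The cascade model assigns every reaction of a generated design a
Michaelis-Menten rate law and integrates d y / d t = S v(y) with a
stiff-capable adaptive integrator.  Rate-law conventions:

* Irreversible steps (phosphoketolase cleavage, dephosphorylation,
  formose condensation, feeder oxidation) use
  ``v = kcat * E * (S / Km) / (1 + sum_j S_j / Km_j)``, where the sum
  runs over every substrate of the same enzyme present in the design.
  This shared-active-site competitive form reflects a single
  phosphoketolase pocket fielding competing ketoses; an independent-site
  variant (denominator per substrate) is selectable.
* Reversible isomerizations use the net reversible Michaelis-Menten form
  ``v = (Vf S/Ks - Vr P/Kp) / (1 + S/Ks + P/Kp)`` with the reverse
  maximal rate constrained by the Haldane relation
  ``Keq = Vf Kp / (Vr Ks)``.
* The formolase step is one saturating turnover consuming three
  formaldehyde molecules (its stoichiometric coefficient); no
  termolecular elementary kinetics are attempted.

Units: concentrations mM, time hours, kcat s^-1, Km mM, loadings
mg mL^-1, molar masses kDa.  Specific-activity parameterization
(umol min^-1 mg^-1 at saturation) is accepted as an alternative per
enzyme.  The phosphate buffer is treated as a constant excess and AcP is
reported merged with acetate as an "Ac" pool, since the assay hydrolyzes
AcP to acetate before quantification.

The shipped default parameter set is a plausible placeholder, not
measured ground truth: the underlying study's fitted constants are not
printed in its main text.  The defaults do respect the printed ordering
constraints — cleavage of F6P/Xu5P is fast (minutes), the short-chain
ketoses are slow (hours), and phosphoketolase binds dihydroxyacetone
more tightly than glycolaldehyde.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import (
    PathwayDesign,
    RTYPE_ISO,
    TERMINAL_IDS,
)
from .species import SpeciesRegistry, default_registry

#: integrator defaults
RTOL = 1e-8
ATOL = 1e-12  # mM; keeps integrator undershoot well inside the negativity guard
NEGATIVITY_TOL = 1e-9  # mM

DEFAULT_GRID_STEP = 2.0  # hours between samples
DEFAULT_HORIZON = 10.0  # hours

AC_POOL_IDS = frozenset({"AcP", "acetate", "AcCoA"})


class MissingParameterError(KeyError):
    """A (enzyme, substrate) pair required by the design has no constants."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the last valid state."""

    def __init__(self, message: str, last_time: float, last_state: np.ndarray):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


class NegativeConcentrationError(RuntimeError):
    """A trajectory went negative beyond tolerance (never silently clipped)."""


# ---------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeLoad:
    """Loading (mg/mL) and molar mass (kDa) of one enzyme."""

    loading: float
    molar_mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.loading < 0:
            raise ValueError("loading must be >= 0")
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0")

    @property
    def concentration_mm(self) -> float:
        """Molar enzyme concentration in mM (needs molar_mass)."""
        if self.molar_mass is None:
            raise ValueError("molar_mass required for molar concentration")
        return self.loading / self.molar_mass


@dataclass(frozen=True)
class RateConstants:
    """Catalytic constants for one (enzyme, substrate) pair.

    Exactly one of ``kcat`` (s^-1, with the enzyme's molar mass known) or
    ``specific_activity`` (umol min^-1 mg^-1 at saturation) must be set.
    Reversible pairs additionally carry ``keq`` (product/substrate at
    equilibrium) and ``km_product`` (mM).
    """

    km: float
    kcat: Optional[float] = None
    specific_activity: Optional[float] = None
    keq: Optional[float] = None
    km_product: Optional[float] = None

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ValueError("Km must be > 0")
        if (self.kcat is None) == (self.specific_activity is None):
            raise ValueError("exactly one of kcat / specific_activity must be set")
        if self.kcat is not None and self.kcat <= 0:
            raise ValueError("kcat must be > 0")
        if self.specific_activity is not None and self.specific_activity <= 0:
            raise ValueError("specific_activity must be > 0")


@dataclass(frozen=True)
class KineticParameterSet:
    """Per-enzyme loadings plus per (enzyme, substrate) catalytic constants."""

    enzymes: Mapping[str, EnzymeLoad]
    constants: Mapping[tuple[str, str], RateConstants]
    rate_law: str = "competitive"  # or "independent"
    label: str = "unnamed"

    def __post_init__(self) -> None:
        if self.rate_law not in ("competitive", "independent"):
            raise ValueError(f"unknown rate_law {self.rate_law!r}")
        object.__setattr__(self, "enzymes", dict(self.enzymes))
        object.__setattr__(self, "constants", dict(self.constants))

    def get(self, enzyme: str, substrate: str) -> RateConstants:
        try:
            return self.constants[(enzyme, substrate)]
        except KeyError:
            raise MissingParameterError(
                f"no kinetic constants for enzyme {enzyme!r} on {substrate!r}"
            ) from None

    def load(self, enzyme: str) -> EnzymeLoad:
        try:
            return self.enzymes[enzyme]
        except KeyError:
            raise MissingParameterError(f"no loading for enzyme {enzyme!r}") from None

    def vmax(self, enzyme: str, substrate: str) -> float:
        """Saturating rate in mM/h for the pair."""
        rc = self.get(enzyme, substrate)
        ld = self.load(enzyme)
        if rc.kcat is not None:
            return rc.kcat * ld.concentration_mm * 3600.0
        # umol min^-1 mg^-1 * mg mL^-1 = mM min^-1
        return rc.specific_activity * ld.loading * 60.0

    # -- functional updates (used by the fitting stage) ----------------

    def with_constants(
        self, enzyme: str, substrate: str, **changes: float
    ) -> "KineticParameterSet":
        rc = dataclasses.replace(self.get(enzyme, substrate), **changes)
        constants = dict(self.constants)
        constants[(enzyme, substrate)] = rc
        return dataclasses.replace(self, constants=constants)

    def with_loading(self, enzyme: str, loading: float) -> "KineticParameterSet":
        enzymes = dict(self.enzymes)
        enzymes[enzyme] = dataclasses.replace(self.load(enzyme), loading=loading)
        return dataclasses.replace(self, enzymes=enzymes)

    def scaled_loadings(self, factor: float) -> "KineticParameterSet":
        enzymes = {
            e: dataclasses.replace(ld, loading=ld.loading * factor)
            for e, ld in self.enzymes.items()
        }
        return dataclasses.replace(self, enzymes=enzymes)


#: Catalytic-efficiency fold changes of the characterized single-point
#: phosphoketolase mutants relative to wild type.
MUTANT_EFFICIENCY_FOLDS: Mapping[str, Mapping[str, float]] = {
    "E520I": {"DHA": 2.3},
    "Q321A": {"DHA": 5.0},
    "H142N": {"GALD": 8.5, "D-EUS": 3.6},
}


def default_parameters(rate_law: str = "competitive") -> KineticParameterSet:
    """Placeholder wild-type parameter set for the bundled cascades.

    Loadings follow the printed in vitro recipe (PK 2, EcHAD 0.5,
    Ps-LRhI 1, CpHAD 1, TIM 0.1, FLS 2 mg/mL at 10 mM substrate).  The
    catalytic constants are plausible placeholders consistent with the
    qualitative orderings reported for the real enzymes, not fitted
    values.
    """
    enzymes = {
        "BbPK": EnzymeLoad(2.0, 92.0),
        "EcHAD": EnzymeLoad(0.5, 25.0),
        "Ps-LRhI": EnzymeLoad(1.0, 47.0),
        "CpHAD": EnzymeLoad(1.0, 30.0),
        "EcTIM": EnzymeLoad(0.1, 27.0),
        "FLS": EnzymeLoad(2.0, 60.0),
        "GALS": EnzymeLoad(2.0, 60.0),
        # feeder oxidations (all flagged untested in the designs)
        "MDH": EnzymeLoad(1.0, 40.0),
        "EGDH": EnzymeLoad(1.0, 40.0),
        "EOX": EnzymeLoad(1.0, 40.0),
        "GDH": EnzymeLoad(1.0, 40.0),
        "ERDH": EnzymeLoad(1.0, 40.0),
    }
    rc = RateConstants
    constants = {
        # fast cleavage of the phosphorylated ketoses
        ("BbPK", "F6P"): rc(km=5.0, kcat=10.0),
        ("BbPK", "Xu5P"): rc(km=3.0, kcat=12.0),
        # slow short-chain ketoses; DHA bound more tightly than GALD
        ("BbPK", "DHA"): rc(km=15.0, kcat=0.10),
        ("BbPK", "GALD"): rc(km=40.0, kcat=0.08),
        ("BbPK", "D-EUS"): rc(km=25.0, kcat=0.15),
        ("BbPK", "L-EUS"): rc(km=30.0, kcat=0.10),
        ("EcHAD", "E4P"): rc(km=2.0, kcat=5.0),
        ("CpHAD", "DHAP"): rc(km=1.0, kcat=5.0),
        ("Ps-LRhI", "D-ETS"): rc(km=10.0, kcat=5.0, keq=4.0, km_product=10.0),
        ("EcTIM", "G3P"): rc(km=0.5, kcat=100.0, keq=22.0, km_product=1.0),
        ("FLS", "HCHO"): rc(km=5.0, kcat=0.5),
        ("GALS", "HCHO"): rc(km=10.0, kcat=0.5),
        ("MDH", "methanol"): rc(km=10.0, kcat=1.0),
        ("EGDH", "ethylene_glycol"): rc(km=10.0, kcat=1.0),
        ("EOX", "ethanolamine"): rc(km=10.0, kcat=1.0),
        ("GDH", "glycerol"): rc(km=10.0, kcat=1.0),
        ("ERDH", "erythritol"): rc(km=10.0, kcat=1.0),
    }
    return KineticParameterSet(enzymes, constants, rate_law, label="wild-type default")


def mutant_parameters(
    mutant: str, base: Optional[KineticParameterSet] = None
) -> KineticParameterSet:
    """Parameter set for a characterized phosphoketolase point mutant.

    The mutant's kcat on the affected substrate(s) is scaled so that its
    catalytic efficiency kcat/Km exceeds wild type by exactly the
    reported fold change (Km held fixed).
    """
    if mutant not in MUTANT_EFFICIENCY_FOLDS:
        raise KeyError(
            f"unknown mutant {mutant!r}; known: {sorted(MUTANT_EFFICIENCY_FOLDS)}"
        )
    params = base or default_parameters()
    for substrate, fold in MUTANT_EFFICIENCY_FOLDS[mutant].items():
        rc = params.get("BbPK", substrate)
        params = params.with_constants("BbPK", substrate, kcat=rc.kcat * fold)
    return dataclasses.replace(params, label=f"BbPK-{mutant}")


# ---------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------

def make_rate_function(
    design: PathwayDesign, params: KineticParameterSet
) -> Callable[[np.ndarray], np.ndarray]:
    """Compile the design's per-reaction rate vector v(y) in mM/h.

    The returned function takes concentrations ordered as
    ``design.species`` and returns one rate per reaction in design order.
    Raises ``MissingParameterError`` up front for any pair the parameter
    set lacks.
    """
    idx = {sid: i for i, sid in enumerate(design.species)}
    compiled = []  # (kind, payload)
    # enzyme -> [(substrate_index, km)] for competitive denominators
    competitors: dict[str, list[tuple[int, float]]] = {}

    for r in design.reactions:
        consumed = r.consumed
        if len(consumed) != 1:
            raise ValueError(f"reaction {r.id} must consume exactly one species")
        sub = consumed[0]
        if r.rtype == RTYPE_ISO and r.reversible:
            prod = r.produced[0]
            rc = params.get(r.enzyme, sub)
            if rc.keq is None or rc.km_product is None:
                raise MissingParameterError(
                    f"reversible pair ({r.enzyme}, {sub}) needs keq and km_product"
                )
            vf = params.vmax(r.enzyme, sub)
            vr = vf * rc.km_product / (rc.km * rc.keq)  # Haldane
            compiled.append(
                ("rev", (idx[sub], idx[prod], vf, vr, rc.km, rc.km_product))
            )
        else:
            rc = params.get(r.enzyme, sub)
            vmax = params.vmax(r.enzyme, sub)
            compiled.append(("irr", (idx[sub], vmax, rc.km, r.enzyme)))
            competitors.setdefault(r.enzyme, []).append((idx[sub], rc.km))

    shared = params.rate_law == "competitive"

    def rate_vector(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        yc = np.maximum(y, 0.0)  # rate laws see nonnegative concentrations
        denoms = {}
        if shared:
            for enz, subs in competitors.items():
                denoms[enz] = 1.0 + sum(yc[i] / km for i, km in subs)
        v = np.empty(len(compiled))
        for k, (kind, payload) in enumerate(compiled):
            if kind == "irr":
                i, vmax, km, enz = payload
                denom = denoms[enz] if shared else 1.0 + yc[i] / km
                v[k] = vmax * (yc[i] / km) / denom
            else:
                i, j, vf, vr, ks, kp = payload
                denom = 1.0 + yc[i] / ks + yc[j] / kp
                v[k] = (vf * yc[i] / ks - vr * yc[j] / kp) / denom
        return v

    return rate_vector


def rate_vector(
    design: PathwayDesign,
    params: KineticParameterSet,
    concentrations: Mapping[str, float],
) -> dict[str, float]:
    """One-shot per-reaction rates (mM/h) at the given concentrations."""
    y = np.array([concentrations.get(sid, 0.0) for sid in design.species])
    v = make_rate_function(design, params)(y)
    return {r.id: float(val) for r, val in zip(design.reactions, v)}


# ---------------------------------------------------------------------
# Time courses
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class TimecourseDataset:
    """Sampled concentrations over time: species x time matrix in mM."""

    time: np.ndarray  # hours, strictly increasing
    species: tuple[str, ...]
    conc: np.ndarray  # shape (n_species, n_time)
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        conc = np.asarray(self.conc, dtype=float)
        if np.any(np.diff(time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if conc.shape != (len(self.species), len(time)):
            raise ValueError("conc must be species x time")
        if np.any(conc < 0):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __getitem__(self, species_id: str) -> np.ndarray:
        return self.conc[self.species.index(species_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.conc.T, columns=list(self.species))
        df.insert(0, "time_h", self.time)
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, metadata: Optional[Mapping[str, object]] = None
    ) -> "TimecourseDataset":
        species = tuple(c for c in df.columns if c != "time_h")
        return cls(
            time=df["time_h"].to_numpy(),
            species=species,
            conc=df[list(species)].to_numpy().T,
            metadata=metadata or {},
        )


def simulate(
    design: PathwayDesign,
    params: KineticParameterSet,
    y0: Mapping[str, float],
    horizon: float = DEFAULT_HORIZON,
    grid: Optional[Sequence[float]] = None,
    registry: Optional[SpeciesRegistry] = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "LSODA",
) -> TimecourseDataset:
    """Integrate the cascade and sample it on a time grid.

    The default grid matches the in vitro sampling scheme: every 2 h from
    0 to the 10 h horizon.  Unknown species in ``y0`` raise; design
    species missing from ``y0`` start at 0 mM.
    """
    registry = registry or default_registry()
    unknown = set(y0) - set(design.species)
    if unknown:
        raise ValueError(f"initial condition for species outside design: {sorted(unknown)}")
    if any(c < 0 for c in y0.values()):
        raise ValueError("initial concentrations must be nonnegative")
    if grid is None:
        grid = np.arange(0.0, horizon + 1e-9, DEFAULT_GRID_STEP)
    grid = np.asarray(grid, dtype=float)

    y_init = np.array([float(y0.get(sid, 0.0)) for sid in design.species])
    rates = make_rate_function(design, params)
    smat = np.zeros((len(design.species), len(design.reactions)))
    sidx = {sid: i for i, sid in enumerate(design.species)}
    for j, r in enumerate(design.reactions):
        for sid, coeff in r.stoich.items():
            smat[sidx[sid], j] = coeff

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return smat @ rates(y)

    sol = solve_ivp(
        rhs,
        (float(grid[0]), float(grid[-1])),
        y_init,
        t_eval=grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last_t = sol.t[-1] if len(sol.t) else float(grid[0])
        last_y = sol.y[:, -1] if sol.y.size else y_init
        raise IntegrationError(
            f"integration failed at t={last_t:.3g} h: {sol.message}", last_t, last_y
        )
    conc = sol.y
    if conc.min() < -NEGATIVITY_TOL:
        i, j = np.unravel_index(np.argmin(conc), conc.shape)
        raise NegativeConcentrationError(
            f"{design.species[i]} reached {conc[i, j]:.3e} mM at "
            f"t={sol.t[j]:.3g} h (tolerance {NEGATIVITY_TOL} mM)"
        )
    conc = np.clip(conc, 0.0, None)
    total_c0 = sum(
        registry.n_carbons(sid) * y_init[i] for sid, i in sidx.items()
    )
    return TimecourseDataset(
        time=sol.t,
        species=design.species,
        conc=conc,
        metadata={
            "source": design.source,
            "recycle_mode": design.recycle_mode,
            "parameter_set": params.label,
            "initial_mM": dict(y0),
            "total_carbon_mM_t0": total_c0,
        },
    )


# ---------------------------------------------------------------------
# Carbon-abundance pools
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PoolGrouping:
    """Disjoint pools of species ids covering a design's carbon species."""

    pools: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pools", {k: frozenset(v) for k, v in self.pools.items()}
        )
        seen: set[str] = set()
        for label, members in self.pools.items():
            overlap = seen & members
            if overlap:
                raise ValueError(f"pool {label!r} overlaps others on {sorted(overlap)}")
            seen |= members

    def validate_covers(self, species: Sequence[str]) -> None:
        missing = set(species) - set().union(*self.pools.values())
        if missing:
            raise ValueError(f"species not covered by any pool: {sorted(missing)}")


def default_pools(
    design: PathwayDesign, registry: Optional[SpeciesRegistry] = None
) -> PoolGrouping:
    """Pool grouping in the style of the in vitro metabolite analysis.

    The source keeps its own pool, the acetyl products merge into "Ac",
    and every other intermediate is grouped by carbon count ("C1" ...
    "C6").
    """
    registry = registry or default_registry()
    pools: dict[str, set[str]] = {design.source: {design.source}, "Ac": set()}
    for sid in design.species:
        if sid == design.source:
            continue
        if sid in AC_POOL_IDS:
            pools["Ac"].add(sid)
        else:
            pools.setdefault(f"C{registry.n_carbons(sid)}", set()).add(sid)
    return PoolGrouping({k: frozenset(v) for k, v in pools.items() if v})


def carbon_abundance(
    dataset: TimecourseDataset,
    pools: PoolGrouping,
    registry: Optional[SpeciesRegistry] = None,
) -> pd.DataFrame:
    """Per-pool carbon fractions over time.

    The fraction of a pool at time t is the carbon held by its members
    divided by the total carbon present at time 0, so a conservative
    simulation has columns summing to 1 throughout.
    """
    registry = registry or default_registry()
    for label, members in pools.pools.items():
        unknown = members - set(dataset.species)
        if unknown:
            raise ValueError(f"pool {label!r} references unknown species {sorted(unknown)}")
    weights = np.array([registry.n_carbons(s) for s in dataset.species], dtype=float)
    total_c0 = float(weights @ dataset.conc[:, 0])
    if total_c0 <= 0:
        raise ValueError("no carbon at time 0")
    rows = {}
    for label, members in pools.pools.items():
        mask = np.array([s in members for s in dataset.species])
        rows[label] = (weights[mask] @ dataset.conc[mask, :]) / total_c0
    return pd.DataFrame(rows, index=dataset.time).T


def final_yield(
    dataset: TimecourseDataset,
    pools: Optional[PoolGrouping] = None,
    registry: Optional[SpeciesRegistry] = None,
) -> float:
    """Carbon fraction of the merged Ac pool at the final sample."""
    registry = registry or default_registry()
    if pools is None:
        members = AC_POOL_IDS & set(dataset.species)
        pools = PoolGrouping({"Ac": members})
    if "Ac" not in pools.pools:
        raise ValueError("pool grouping lacks an 'Ac' pool")
    frame = carbon_abundance(dataset, PoolGrouping({"Ac": pools.pools["Ac"]}), registry)
    return float(frame.loc["Ac"].iloc[-1])
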