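"""Exact rational flux analysis and carbon-yield accounting.

Given a generated design, the overall reaction is obtained by solving for
a nonnegative rational flux vector with net consumption 1 of the source
and zero net production of every internal species.  All arithmetic is
exact (``fractions.Fraction`` via sympy), so recycle-loop stoichiometries
such as 5/2 AcP per Xu5P come out as rationals rather than floats.

Carbon yield follows the carbon-abundance convention: the ratio of carbon
moles in the acetyl product to the carbon moles of source consumed,
i.e. ``2 * AcP_per_source / n_carbons(source)``.  Cofactors (ATP,
NAD(P)H, CoA, inorganic phosphate) are not tracked: the metric is
carbon-only.

A bundled glucose -> acetyl-CoA route (10 glycolytic steps plus pyruvate
dehydrogenase, 11 reactions) provides the canonical comparison point:
2 acetyl-CoA per glucose and a 67% carbon yield, the two carbons lost as
CO2 at the decarboxylation step.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import sympy

from .network import PathwayDesign, TERMINAL_IDS
from .species import SpeciesRegistry, default_registry

#: species counted as acetyl product in yield accounting (2 carbons each)
ACETYL_IDS = ("AcP", "acetate", "AcCoA")


class InfeasibleFluxError(RuntimeError):
    """No nonnegative flux vector satisfies the steady-state constraints."""


class AmbiguousFluxError(RuntimeError):
    """The network admits free flux directions; the solve is underdetermined."""

    def __init__(self, free_directions: Sequence[Mapping[str, Fraction]]):
        self.free_directions = list(free_directions)
        super().__init__(
            f"flux solve underdetermined; {len(self.free_directions)} free "
            f"direction(s): {self.free_directions}"
        )


@dataclass(frozen=True)
class StoichModel:
    """Species-by-reaction integer matrix form of a reaction list."""

    species_order: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    matrix: tuple[tuple[int, ...], ...]  # rows follow species_order
    internal_set: frozenset[str]
    source: str


@dataclass(frozen=True)
class YieldReport:
    """Overall reaction and carbon yield of a design, exactly."""

    source: str
    acp_per_source: Fraction
    carbon_yield: Fraction
    overall_reaction: Mapping[str, Fraction]
    fluxes: Mapping[str, Fraction]

    @property
    def carbon_yield_percent(self) -> int:
        return percent(self.carbon_yield)


def percent(value: Fraction) -> int:
    """Whole-percent representation, rounding half up (2/3 -> 67)."""
    return int(value * 100 + Fraction(1, 2))


# ---------------------------------------------------------------------
# Core solver (generic over a stoichiometry list — also used for the
# glycolysis reference, whose species are not in the APK registry)
# ---------------------------------------------------------------------

def build_model(
    reactions: Sequence[tuple[str, Mapping[str, int]]],
    source: str,
    terminals: frozenset[str] = TERMINAL_IDS,
) -> StoichModel:
    """Matrix form with the internal set inferred from turnover.

    Internal species are those both produced and consumed, excluding the
    source (whose net is pinned to -1) and declared terminals.  A species
    produced but never consumed (stranded HCHO with recycling off) is a
    terminal product and shows up in the overall reaction rather than
    making the system infeasible.

    Reactions with identical stoichiometry are collapsed onto the first
    occurrence (their fluxes are only jointly determined), so duplicating
    a reaction cannot make the solve ambiguous.
    """
    uniq: list[tuple[str, Mapping[str, int]]] = []
    seen_stoich: list[dict[str, int]] = []
    for rid, stoich in reactions:
        normalized = {k: v for k, v in stoich.items() if v != 0}
        if normalized in seen_stoich:
            continue
        seen_stoich.append(normalized)
        uniq.append((rid, stoich))
    reactions = uniq
    species: list[str] = []
    seen: set[str] = set()
    for _, stoich in reactions:
        for sid in stoich:
            if sid not in seen:
                seen.add(sid)
                species.append(sid)
    produced = {s for _, st in reactions for s, c in st.items() if c > 0}
    consumed = {s for _, st in reactions for s, c in st.items() if c < 0}
    internal = (produced & consumed) - {source} - terminals
    matrix = tuple(
        tuple(st.get(sid, 0) for _, st in reactions) for sid in species
    )
    return StoichModel(
        species_order=tuple(species),
        reaction_ids=tuple(rid for rid, _ in reactions),
        matrix=matrix,
        internal_set=frozenset(internal),
        source=source,
    )


def solve_fluxes(model: StoichModel) -> dict[str, Fraction]:
    """Exact flux vector: source net -1, internal species net 0, fluxes >= 0.

    Raises ``AmbiguousFluxError`` when the constraints leave free flux
    directions and ``InfeasibleFluxError`` when no nonnegative solution
    exists.
    """
    n = len(model.reaction_ids)
    rows = []
    rhs = []
    row_of = {sid: i for i, sid in enumerate(model.species_order)}
    for sid in model.species_order:
        if sid in model.internal_set:
            rows.append(list(model.matrix[row_of[sid]]))
            rhs.append(0)
    if model.source not in row_of:
        raise InfeasibleFluxError(f"source {model.source!r} not in network")
    rows.append(list(model.matrix[row_of[model.source]]))
    rhs.append(-1)

    A = sympy.Matrix(rows)
    b = sympy.Matrix(rhs)
    v = sympy.symbols(f"v0:{n}", real=True)
    solset = sympy.linsolve((A, b), v)
    if not solset:
        raise InfeasibleFluxError(
            f"no flux vector satisfies steady state for {model.source!r}"
        )
    (sol,) = solset
    free = sorted(set().union(*(expr.free_symbols for expr in sol)), key=str)
    if free:
        # Report the free directions in reaction space.
        directions = []
        for f in free:
            direction = {}
            for rid, expr in zip(model.reaction_ids, sol):
                coeff = expr.coeff(f)
                if coeff != 0:
                    direction[rid] = Fraction(int(sympy.nsimplify(coeff).p),
                                              int(sympy.nsimplify(coeff).q))
            directions.append(direction)
        raise AmbiguousFluxError(directions)
    fluxes = {}
    for rid, expr in zip(model.reaction_ids, sol):
        val = sympy.Rational(expr)
        if val < 0:
            raise InfeasibleFluxError(
                f"flux through {rid} is negative ({val}); no nonnegative solution"
            )
        fluxes[rid] = Fraction(int(val.p), int(val.q))
    return fluxes


def net_production(
    model: StoichModel, fluxes: Mapping[str, Fraction]
) -> dict[str, Fraction]:
    """Net stoichiometry over non-internal species at the solved fluxes."""
    out: dict[str, Fraction] = {}
    for i, sid in enumerate(model.species_order):
        net = sum(
            Fraction(model.matrix[i][j]) * fluxes[rid]
            for j, rid in enumerate(model.reaction_ids)
        )
        if sid not in model.internal_set and net != 0:
            out[sid] = net
    return out


# ---------------------------------------------------------------------
# Design-level interface
# ---------------------------------------------------------------------

def overall_reaction(
    design: PathwayDesign, registry: Optional[SpeciesRegistry] = None
) -> YieldReport:
    """Overall reaction and carbon yield of a design by exact flux solve."""
    registry = registry or default_registry()
    model = build_model(
        [(r.id, r.stoich) for r in design.reactions], design.source
    )
    fluxes = solve_fluxes(model)
    overall = net_production(model, fluxes)
    acp = sum((overall.get(sid, Fraction(0)) for sid in ACETYL_IDS), Fraction(0))
    n_source = registry.n_carbons(design.source)
    cy = Fraction(2) * acp / n_source
    if not (0 <= cy <= 1):
        raise InfeasibleFluxError(
            f"carbon yield {cy} outside [0, 1] for {design.source}"
        )
    return YieldReport(
        source=design.source,
        acp_per_source=acp,
        carbon_yield=cy,
        overall_reaction=overall,
        fluxes=fluxes,
    )


def theoretical_yield(
    source: str,
    recycle_mode: str = "fls",
    registry: Optional[SpeciesRegistry] = None,
) -> Fraction:
    """Carbon yield of the generated design for a source, as an exact fraction.

    1 for every routable C2-C6 source (and for HCHO) with recycling on;
    (n-1)/n for an odd-carbon free ketose with recycling off, the lost
    carbon being the stranded formaldehyde.
    """
    from .network import generate

    registry = registry or default_registry()
    design = generate(source, recycle_mode, registry)
    return overall_reaction(design, registry).carbon_yield


# ---------------------------------------------------------------------
# Glycolysis reference (glucose -> 2 acetyl-CoA in 11 reactions)
# ---------------------------------------------------------------------

#: backbone carbon counts for the glycolytic species
GLYCOLYSIS_CARBONS: Mapping[str, int] = {
    "glucose": 6, "G6P": 6, "F6P": 6, "FBP": 6,
    "DHAP": 3, "GAP": 3, "BPG": 3, "PG3": 3, "PG2": 3, "PEP": 3,
    "pyruvate": 3, "AcCoA": 2, "CO2": 1,
}

#: the 10 glycolytic steps plus pyruvate dehydrogenase
GLYCOLYSIS_REACTIONS: Sequence[tuple[str, Mapping[str, int]]] = (
    ("HK", {"glucose": -1, "G6P": 1}),
    ("PGI", {"G6P": -1, "F6P": 1}),
    ("PFK", {"F6P": -1, "FBP": 1}),
    ("FBA", {"FBP": -1, "DHAP": 1, "GAP": 1}),
    ("TPI", {"DHAP": -1, "GAP": 1}),
    ("GAPDH", {"GAP": -1, "BPG": 1}),
    ("PGK", {"BPG": -1, "PG3": 1}),
    ("PGM", {"PG3": -1, "PG2": 1}),
    ("ENO", {"PG2": -1, "PEP": 1}),
    ("PYK", {"PEP": -1, "pyruvate": 1}),
    ("PDH", {"pyruvate": -1, "AcCoA": 1, "CO2": 1}),
)


@dataclass(frozen=True)
class GlycolysisReference:
    """Flux-solved summary of the canonical glucose -> acetyl-CoA route."""

    n_reactions: int
    acetyl_coa_per_glucose: Fraction
    carbon_yield: Fraction

    @property
    def carbon_yield_percent(self) -> int:
        return percent(self.carbon_yield)


def glycolysis_reference() -> GlycolysisReference:
    """Recompute the glycolysis comparison point by exact flux solve."""
    model = build_model(
        GLYCOLYSIS_REACTIONS, "glucose", terminals=frozenset({"AcCoA", "CO2"})
    )
    for rid, stoich in GLYCOLYSIS_REACTIONS:  # carbon balance of the bundle
        bal = sum(c * GLYCOLYSIS_CARBONS[s] for s, c in stoich.items())
        if bal != 0:
            raise ValueError(f"glycolysis step {rid} breaks carbon balance")
    fluxes = solve_fluxes(model)
    overall = net_production(model, fluxes)
    accoa = overall.get("AcCoA", Fraction(0))
    cy = accoa * GLYCOLYSIS_CARBONS["AcCoA"] / Fraction(GLYCOLYSIS_CARBONS["glucose"])
    return GlycolysisReference(
        n_reactions=len(GLYCOLYSIS_REACTIONS),
        acetyl_coa_per_glucose=accoa,
        carbon_yield=cy,
    )
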