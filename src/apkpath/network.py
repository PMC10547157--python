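"""Rule-based generation of the APK reaction network for a carbon source.

Starting from a registered species, the generator expands breadth-first,
applying one rule per species in a fixed priority order:

1. phosphoketolase cleavage, whenever the species is a PK substrate;
2. aldose -> ketose isomerization, when an isomerase pair exists
   (this is how G3P is routed: isomerize at the phosphate level to DHAP,
   because no enzyme isomerizes free glyceraldehyde);
3. dephosphorylation, when a phosphatase pair exists (the E4P route:
   dephosphorylate first, then isomerize D-erythrose to D-erythrulose);
4. formose-type condensation of formaldehyde, per the chosen recycle
   variant (formolase: 3 HCHO -> DHA; glycolaldehyde synthase:
   2 HCHO -> GALD), or leave HCHO stranded when recycling is off.

Feeder alcohols (methanol, ethylene glycol, ethanolamine, glycerol,
erythritol) enter through a one-step oxidation before the rules above.
The priority order encodes the design principle of keeping the number of
phosphorylated intermediates low; a per-species override table can force
a different rule.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx

from .species import (
    CapabilityError,
    SpeciesRegistry,
    default_registry,
)

# Core reaction types (the pathway proper).
RTYPE_PK = "pk_cleavage"
RTYPE_ISO = "isomerization"
RTYPE_DEPHOS = "dephosphorylation"
RTYPE_FORMOSE = "formose_condensation"
# Auxiliary types.
RTYPE_FEEDER = "feeder_oxidation"
RTYPE_TERMINAL = "terminal_transfer"

CORE_RTYPES = frozenset({RTYPE_PK, RTYPE_ISO, RTYPE_DEPHOS, RTYPE_FORMOSE})
RTYPES = CORE_RTYPES | {RTYPE_FEEDER, RTYPE_TERMINAL}

RECYCLE_MODES = ("fls", "gals", "none")

PK_ENZYME = "BbPK"
FORMOSE_ENZYMES = {"fls": "FLS", "gals": "GALS"}

#: One-step feeder oxidations (S-figure entries); every one is flagged
#: untested because the in vitro assays fed the oxidation product directly.
FEEDER_ENTRIES: Mapping[str, tuple[str, str]] = {
    "methanol": ("HCHO", "MDH"),
    "ethylene_glycol": ("GALD", "EGDH"),
    "ethanolamine": ("GALD", "EOX"),
    "glycerol": ("DHA", "GDH"),
    "erythritol": ("D-EUS", "ERDH"),
}

#: Species at which expansion stops.
TERMINAL_IDS = frozenset({"AcP", "acetate", "AcCoA"})


class GenerationError(RuntimeError):
    """The generator hit a species with no applicable rule."""


@dataclass(frozen=True)
class Reaction:
    """A typed, enzyme-labelled stoichiometry map.

    ``stoich`` maps species id to a signed integer coefficient (negative
    consumed, positive produced).  Phosphate and water are implicit, so
    carbon — not mass — is the conserved quantity.
    """

    id: str
    rtype: str
    enzyme: str
    stoich: Mapping[str, int]
    reversible: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rtype not in RTYPES:
            raise ValueError(f"{self.id}: unknown reaction type {self.rtype!r}")
        object.__setattr__(self, "stoich", dict(self.stoich))

    @property
    def consumed(self) -> tuple[str, ...]:
        return tuple(s for s, c in self.stoich.items() if c < 0)

    @property
    def produced(self) -> tuple[str, ...]:
        return tuple(s for s, c in self.stoich.items() if c > 0)

    def carbon_balance(self, registry: SpeciesRegistry) -> int:
        return sum(c * registry.n_carbons(s) for s, c in self.stoich.items())


@dataclass(frozen=True)
class PathwayDesign:
    """A generated network: ordered reactions plus the species they touch.

    ``species`` is kept in discovery order (source first) so that golden
    serializations are stable across runs.
    """

    source: str
    recycle_mode: str
    reactions: tuple[Reaction, ...]
    species: tuple[str, ...]

    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    def core_rtypes(self) -> frozenset[str]:
        return frozenset(r.rtype for r in self.reactions) & CORE_RTYPES

    # -- validation ----------------------------------------------------

    def validate(self, registry: Optional[SpeciesRegistry] = None) -> None:
        """Check carbon balance, connectivity and intermediate turnover."""
        registry = registry or default_registry()
        for r in self.reactions:
            bal = r.carbon_balance(registry)
            if bal != 0:
                raise ValueError(f"reaction {r.id} breaks carbon balance ({bal:+d})")
        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        for r in self.reactions:
            for s in r.consumed:
                for p in r.produced:
                    g.add_edge(s, p)
        reachable = nx.descendants(g, self.source) | {self.source}
        unreachable = set(self.species) - reachable
        if unreachable:
            raise ValueError(f"species unreachable from source: {sorted(unreachable)}")
        if "AcP" not in reachable:
            raise ValueError("design does not reach AcP")
        if self.recycle_mode != "none":
            produced = {s for r in self.reactions for s in r.produced}
            consumed = {s for r in self.reactions for s in r.consumed}
            # HCHO may be deliberately stranded by a routing override even
            # when a recycle variant is selected
            dangling = produced - consumed - TERMINAL_IDS - {"HCHO"}
            if dangling:
                raise ValueError(
                    f"non-terminal intermediates never consumed: {sorted(dangling)}"
                )

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "recycle_mode": self.recycle_mode,
                "species": list(self.species),
                "reactions": [
                    {
                        "id": r.id,
                        "rtype": r.rtype,
                        "enzyme": r.enzyme,
                        "stoich": dict(r.stoich),
                        "reversible": r.reversible,
                        "flags": list(r.flags),
                    }
                    for r in self.reactions
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PathwayDesign":
        doc = json.loads(text)
        return cls(
            source=doc["source"],
            recycle_mode=doc["recycle_mode"],
            reactions=tuple(
                Reaction(
                    id=e["id"],
                    rtype=e["rtype"],
                    enzyme=e["enzyme"],
                    stoich={k: int(v) for k, v in e["stoich"].items()},
                    reversible=e["reversible"],
                    flags=tuple(e.get("flags", ())),
                )
                for e in doc["reactions"]
            ),
            species=tuple(doc["species"]),
        )


# ---------------------------------------------------------------------
# Rule application
# ---------------------------------------------------------------------

def feeder_entry(
    alcohol: str, registry: Optional[SpeciesRegistry] = None
) -> Reaction:
    """One-step oxidation of a feeder alcohol into the pathway.

    Methanol -> HCHO (MDH), ethylene glycol -> GALD (EGDH), ethanolamine
    -> GALD (EOX), glycerol -> DHA (GDH), erythritol -> D-EUS (ERDH).
    The formaldehyde intermediate of methanol assimilation is explicit:
    MDH stops at HCHO and condensation continues from there.
    """
    registry = registry or default_registry()
    registry.get(alcohol)  # raises RegistryError for unknown ids
    if alcohol not in FEEDER_ENTRIES:
        raise CapabilityError(f"{alcohol} is not a feeder alcohol")
    product, enzyme = FEEDER_ENTRIES[alcohol]
    return Reaction(
        id=f"{enzyme}:{alcohol}",
        rtype=RTYPE_FEEDER,
        enzyme=enzyme,
        stoich={alcohol: -1, product: 1},
        flags=("untested",),
    )


def _rule_for(
    sid: str,
    recycle_mode: str,
    registry: SpeciesRegistry,
    overrides: Mapping[str, str],
) -> Optional[str]:
    caps = registry.capabilities
    if sid in overrides:
        return overrides[sid]
    if sid in TERMINAL_IDS:
        return None
    if sid in FEEDER_ENTRIES:
        return "feeder"
    if registry.is_pk_substrate(sid):
        return "pk"
    if sid in caps.isomerase_pairs:
        return "isomerize"
    if sid in caps.phosphatase_pairs:
        return "dephosphorylate"
    if sid == "HCHO":
        return "formose" if recycle_mode != "none" else "strand"
    return "dead_end"


def _apply_rule(
    rule: str, sid: str, recycle_mode: str, registry: SpeciesRegistry
) -> Optional[Reaction]:
    caps = registry.capabilities
    if rule == "feeder":
        return feeder_entry(sid, registry)
    if rule == "pk":
        acp, remainder = registry.pk_cleavage_products(sid)
        stoich = {sid: -1, acp.id: 1}
        if remainder is not None:
            stoich[remainder.id] = stoich.get(remainder.id, 0) + 1
        return Reaction(
            id=f"{PK_ENZYME}:{sid}", rtype=RTYPE_PK, enzyme=PK_ENZYME, stoich=stoich
        )
    if rule == "isomerize":
        ketose, enzyme = caps.isomerase_pairs[sid]
        return Reaction(
            id=f"{enzyme}:{sid}",
            rtype=RTYPE_ISO,
            enzyme=enzyme,
            stoich={sid: -1, ketose: 1},
            reversible=True,
        )
    if rule == "dephosphorylate":
        free, enzyme = caps.phosphatase_pairs[sid]
        return Reaction(
            id=f"{enzyme}:{sid}",
            rtype=RTYPE_DEPHOS,
            enzyme=enzyme,
            stoich={sid: -1, free: 1},
        )
    if rule == "formose":
        n, product = caps.formose_variants[recycle_mode]
        enzyme = FORMOSE_ENZYMES[recycle_mode]
        return Reaction(
            id=f"{enzyme}:HCHO",
            rtype=RTYPE_FORMOSE,
            enzyme=enzyme,
            stoich={"HCHO": -n, product: 1},
        )
    if rule == "strand":
        return None  # HCHO left as a terminal with recycling off
    raise GenerationError(f"no applicable rule for species {sid!r}")


def generate(
    source: str,
    recycle_mode: str = "fls",
    registry: Optional[SpeciesRegistry] = None,
    overrides: Optional[Mapping[str, str]] = None,
) -> PathwayDesign:
    """Generate the APK design for a carbon source.

    Expansion is breadth-first from the source; each species is processed
    once, so termination follows from the finite species universe.  With
    recycling on, the only terminal product is AcP; with recycling off an
    odd-carbon source additionally strands one formaldehyde.

    Parameters
    ----------
    source : registered species id (a sugar, sugar phosphate, HCHO, or a
        feeder alcohol).
    recycle_mode : ``"fls"`` (default, formolase), ``"gals"``
        (glycolaldehyde synthase) or ``"none"``.
    overrides : optional per-species routing table mapping species id to
        one of ``pk | isomerize | dephosphorylate | formose | strand``.
    """
    registry = registry or default_registry()
    if recycle_mode not in RECYCLE_MODES:
        raise ValueError(f"recycle_mode must be one of {RECYCLE_MODES}")
    registry.get(source)
    overrides = dict(overrides or {})

    seen: set[str] = {source}
    order: list[str] = [source]
    reactions: list[Reaction] = []
    queue: deque[str] = deque([source])
    while queue:
        sid = queue.popleft()
        rule = _rule_for(sid, recycle_mode, registry, overrides)
        if rule is None:
            continue
        if rule == "dead_end":
            raise GenerationError(
                f"species {sid!r} has no applicable rule "
                f"(recycle_mode={recycle_mode!r})"
            )
        reaction = _apply_rule(rule, sid, recycle_mode, registry)
        if reaction is None:
            continue
        reactions.append(reaction)
        for pid in reaction.produced:
            if pid not in seen:
                seen.add(pid)
                order.append(pid)
                queue.append(pid)

    design = PathwayDesign(
        source=source,
        recycle_mode=recycle_mode,
        reactions=tuple(reactions),
        species=tuple(order),
    )
    design.validate(registry)
    return design


def count_reaction_types(design: PathwayDesign) -> int:
    """Number of distinct core reaction types in a design.

    Core types are phosphoketolase cleavage, isomerization,
    dephosphorylation and formose condensation; feeder oxidations and
    terminal transfers are auxiliary and not counted.
    """
    return len(design.core_rtypes())
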