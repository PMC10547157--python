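"""Canonical chemical model of the compounds the APK pathway touches.

The artificial phosphoketolase (APK) pathway converts ketoses to
acetyl-phosphate (AcP) by repeated C2 cleavage.  This module holds the
species universe — sugars, sugar phosphates, the C1/C2 end points and the
feeder alcohols — together with the enzyme capability tables the network
generator consults: which species phosphoketolase accepts, which
aldose/ketose pairs an isomerase interconverts, which phosphates a
phosphatase removes, and how the formose-type condensations recondense
formaldehyde.

The substrate set of phosphoketolase is an explicit whitelist, not a
structural predicate: acceptance is empirical (phosphate anchoring blocks
DHAP and Eu4P even though they are ketoses), so no rule could derive it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

REGISTRY_SCHEMA_VERSION = 1

#: carbon_weight_role values
ROLE_INTERMEDIATE = "intermediate"
ROLE_SOURCE = "source"
ROLE_TERMINAL = "terminal"

SUGAR_CLASSES = ("aldose", "ketose", "nonsugar")


class RegistryError(KeyError):
    """Lookup of a species id that is not registered."""


class CapabilityError(ValueError):
    """An operation was asked of a species outside the capability tables."""


@dataclass(frozen=True)
class Species:
    """A carbon compound in the APK species universe.

    ``phospho_position`` is one-based on the carbon backbone (e.g. 6 for
    fructose-6-phosphate) and ``None`` for unphosphorylated species.
    ``n_carbons`` counts backbone carbons; for acetyl-CoA only the acetyl
    unit is counted, since the CoA moiety is catalytic, not substrate
    carbon.
    """

    id: str
    name: str
    n_carbons: int
    sugar_class: str
    phospho_position: Optional[int] = None
    carbon_weight_role: str = ROLE_INTERMEDIATE

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"{self.id}: n_carbons must be >= 1")
        if self.sugar_class not in SUGAR_CLASSES:
            raise ValueError(f"{self.id}: bad sugar_class {self.sugar_class!r}")
        if self.phospho_position is not None and not (
            1 <= self.phospho_position <= self.n_carbons
        ):
            raise ValueError(
                f"{self.id}: phospho_position {self.phospho_position} "
                f"outside carbon backbone 1..{self.n_carbons}"
            )

    @property
    def is_phosphorylated(self) -> bool:
        return self.phospho_position is not None


@dataclass(frozen=True)
class EnzymeCapabilityTable:
    """What the pathway's enzymes can do, as explicit lookup tables.

    ``pk_cleavage`` maps each phosphoketolase substrate to its C(n-2)
    aldose remainder (``None`` for glycolaldehyde, which leaves none).
    ``isomerase_pairs`` maps aldose id -> (ketose id, enzyme label);
    ``phosphatase_pairs`` maps phospho id -> (free id, enzyme label);
    ``formose_variants`` maps a recycle label -> (formaldehyde
    stoichiometry, product id).
    """

    pk_cleavage: Mapping[str, Optional[str]]
    isomerase_pairs: Mapping[str, tuple[str, str]]
    phosphatase_pairs: Mapping[str, tuple[str, str]]
    formose_variants: Mapping[str, tuple[int, str]]

    @property
    def pk_substrates(self) -> frozenset[str]:
        return frozenset(self.pk_cleavage)


def _default_species() -> tuple[Species, ...]:
    S = Species
    return (
        # C1
        S("HCHO", "formaldehyde", 1, "aldose"),
        # C2
        S("GALD", "glycolaldehyde", 2, "aldose"),
        # C3
        S("GCD", "D-glyceraldehyde", 3, "aldose"),
        S("DHA", "dihydroxyacetone", 3, "ketose"),
        S("G3P", "D-glyceraldehyde-3-phosphate", 3, "aldose", 3),
        S("DHAP", "dihydroxyacetone phosphate", 3, "ketose", 3),
        # C4
        S("D-ETS", "D-erythrose", 4, "aldose"),
        S("D-EUS", "D-erythrulose", 4, "ketose"),
        S("L-EUS", "L-erythrulose", 4, "ketose"),
        S("E4P", "D-erythrose-4-phosphate", 4, "aldose", 4),
        S("Eu4P", "D-erythrulose-4-phosphate", 4, "ketose", 4),
        # C5 / C6
        S("Xu5P", "D-xylulose-5-phosphate", 5, "ketose", 5),
        S("F6P", "D-fructose-6-phosphate", 6, "ketose", 6),
        # products
        S("AcP", "acetyl-phosphate", 2, "nonsugar", 1, ROLE_TERMINAL),
        S("acetate", "acetic acid", 2, "nonsugar", None, ROLE_TERMINAL),
        S("AcCoA", "acetyl-CoA (acetyl carbons)", 2, "nonsugar", None, ROLE_TERMINAL),
        # feeder alcohols
        S("methanol", "methanol", 1, "nonsugar", None, ROLE_SOURCE),
        S("ethylene_glycol", "ethylene glycol", 2, "nonsugar", None, ROLE_SOURCE),
        S("ethanolamine", "ethanolamine", 2, "nonsugar", None, ROLE_SOURCE),
        S("glycerol", "glycerol", 3, "nonsugar", None, ROLE_SOURCE),
        S("erythritol", "erythritol", 4, "nonsugar", None, ROLE_SOURCE),
    )


def _default_capabilities() -> EnzymeCapabilityTable:
    return EnzymeCapabilityTable(
        # Phosphoketolase whitelist with C(n-2) remainders.  DHAP and Eu4P
        # are deliberately absent: phosphate anchoring keeps their carbonyl
        # away from the ThDP cofactor.
        pk_cleavage={
            "F6P": "E4P",
            "Xu5P": "G3P",
            "D-EUS": "GALD",
            "L-EUS": "GALD",
            "DHA": "HCHO",
            "GALD": None,
        },
        # No entry for free glyceraldehyde (GCD): no enzyme isomerizes it
        # to DHA, which is exactly why G3P is isomerized before
        # dephosphorylation.
        isomerase_pairs={
            "D-ETS": ("D-EUS", "Ps-LRhI"),
            "G3P": ("DHAP", "EcTIM"),
        },
        phosphatase_pairs={
            "E4P": ("D-ETS", "EcHAD"),
            "DHAP": ("DHA", "CpHAD"),
        },
        formose_variants={
            "fls": (3, "DHA"),   # formolase: 3 HCHO -> dihydroxyacetone
            "gals": (2, "GALD"),  # glycolaldehyde synthase: 2 HCHO -> GALD
        },
    )


class SpeciesRegistry:
    """Total, id-keyed lookup over the bundled species set plus capabilities."""

    def __init__(
        self,
        species: Iterable[Species],
        capabilities: EnzymeCapabilityTable,
    ) -> None:
        self._species: dict[str, Species] = {}
        for sp in species:
            if sp.id in self._species:
                raise ValueError(f"duplicate species id {sp.id!r}")
            self._species[sp.id] = sp
        self.capabilities = capabilities
        self._validate_closure()

    # -- basic lookup -------------------------------------------------

    def get(self, species_id: str) -> Species:
        try:
            return self._species[species_id]
        except KeyError:
            raise RegistryError(f"unknown species id {species_id!r}") from None

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._species

    def ids(self) -> tuple[str, ...]:
        return tuple(self._species)

    def species(self) -> tuple[Species, ...]:
        return tuple(self._species.values())

    def n_carbons(self, species_id: str) -> int:
        return self.get(species_id).n_carbons

    # -- capability predicates ----------------------------------------

    def is_pk_substrate(self, species: Species | str) -> bool:
        """True iff phosphoketolase cleaves this species to AcP."""
        sp = species if isinstance(species, Species) else self.get(species)
        if sp.id not in self._species:
            raise RegistryError(f"unknown species id {sp.id!r}")
        return sp.id in self.capabilities.pk_cleavage

    def pk_cleavage_products(
        self, species: Species | str
    ) -> tuple[Species, Optional[Species]]:
        """AcP plus the two-carbon-shorter aldose remainder (or ``None``).

        Phosphoketolase breaks the C2-C3 bond of a ketose: two carbons
        leave as acetyl-phosphate and the rest as the free aldose (HCHO
        for dihydroxyacetone, nothing for glycolaldehyde).
        """
        sp = species if isinstance(species, Species) else self.get(species)
        if not self.is_pk_substrate(sp):
            raise CapabilityError(
                f"{sp.id} is not a phosphoketolase substrate"
            )
        remainder_id = self.capabilities.pk_cleavage[sp.id]
        remainder = self.get(remainder_id) if remainder_id else None
        got = 2 + (remainder.n_carbons if remainder else 0)
        if got != sp.n_carbons:  # defensive: table must conserve carbon
            raise CapabilityError(
                f"cleavage of {sp.id} does not conserve carbon "
                f"({sp.n_carbons} in, {got} out)"
            )
        return self.get("AcP"), remainder

    # -- consistency ---------------------------------------------------

    def _validate_closure(self) -> None:
        """Every id referenced by a capability table must be registered."""
        caps = self.capabilities
        referenced: set[str] = set(caps.pk_cleavage)
        referenced |= {r for r in caps.pk_cleavage.values() if r}
        for table in (caps.isomerase_pairs, caps.phosphatase_pairs):
            referenced |= set(table)
            referenced |= {prod for prod, _ in table.values()}
        referenced |= {prod for _, prod in caps.formose_variants.values()}
        referenced.add("AcP")
        missing = sorted(referenced - set(self._species))
        if missing:
            raise ValueError(f"capability tables reference unregistered ids: {missing}")

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        caps = self.capabilities
        doc = {
            "schema_version": REGISTRY_SCHEMA_VERSION,
            "species": [
                {
                    "id": sp.id,
                    "name": sp.name,
                    "carbons": sp.n_carbons,
                    "class": sp.sugar_class,
                    "phosphate": sp.phospho_position,
                    "role": sp.carbon_weight_role,
                }
                for sp in self._species.values()
            ],
            "capabilities": {
                "pk_cleavage": dict(caps.pk_cleavage),
                "isomerase_pairs": {k: list(v) for k, v in caps.isomerase_pairs.items()},
                "phosphatase_pairs": {
                    k: list(v) for k, v in caps.phosphatase_pairs.items()
                },
                "formose_variants": {
                    k: list(v) for k, v in caps.formose_variants.items()
                },
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SpeciesRegistry":
        doc = json.loads(text)
        if doc.get("schema_version") != REGISTRY_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported registry schema version {doc.get('schema_version')!r}"
            )
        species = [
            Species(
                id=e["id"],
                name=e["name"],
                n_carbons=e["carbons"],
                sugar_class=e["class"],
                phospho_position=e["phosphate"],
                carbon_weight_role=e.get("role", ROLE_INTERMEDIATE),
            )
            for e in doc["species"]
        ]
        c = doc["capabilities"]
        caps = EnzymeCapabilityTable(
            pk_cleavage=dict(c["pk_cleavage"]),
            isomerase_pairs={k: tuple(v) for k, v in c["isomerase_pairs"].items()},
            phosphatase_pairs={k: tuple(v) for k, v in c["phosphatase_pairs"].items()},
            formose_variants={k: (int(v[0]), v[1]) for k, v in c["formose_variants"].items()},
        )
        return cls(species, caps)

    @classmethod
    def default(cls) -> "SpeciesRegistry":
        """The bundled registry covering every compound the APK pathway uses."""
        return cls(_default_species(), _default_capabilities())


_DEFAULT: Optional[SpeciesRegistry] = None


def default_registry() -> SpeciesRegistry:
    """Shared instance of the bundled registry (immutable by convention)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = SpeciesRegistry.default()
    return _DEFAULT
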