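"""Compound/pathway libraries and adduct rule sets.

A :class:`CompoundPathwayLibrary` is the reference against which m/z features
are annotated: a table of compounds (id, name, elemental formula,
monoisotopic mass) and a list of named compound sets (metabolic pathways).
An :class:`AdductRuleSet` holds the ion-mode-specific mass-arithmetic rules
(e.g. ``[M-H]-``) that map a neutral monoisotopic mass to observable m/z
values.

The bundled ``library_hsa_toy.json`` is a small synthetic stand-in for a
genome-scale human metabolic library: real elemental formulas, toy pathway
memberships. The bundled ``adducts.csv`` carries the common singly-charged
electrospray adducts with proton mass 1.00727646 Da and explicit electron
bookkeeping.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import chem

__all__ = [
    "Compound",
    "PathwaySet",
    "CompoundPathwayLibrary",
    "AdductRule",
    "AdductRuleSet",
    "LibraryError",
    "load_library",
    "load_adduct_rules",
    "bundled_library",
    "bundled_adduct_rules",
]


class LibraryError(ValueError):
    """Raised when a library or rule file violates its invariants."""


@dataclass(frozen=True)
class Compound:
    id: str
    name: str
    formula: str
    monoisotopic_mass: float

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise LibraryError(f"compound {self.id}: non-positive mass")
        chem.parse_formula(self.formula)  # raises FormulaError if invalid


@dataclass(frozen=True)
class PathwaySet:
    id: str
    name: str
    compound_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.compound_ids:
            raise LibraryError(f"pathway {self.id}: empty compound set")


@dataclass
class CompoundPathwayLibrary:
    name: str
    compounds: dict[str, Compound]
    pathways: list[PathwaySet]
    ion_modes_supported: frozenset[str] = frozenset({"positive", "negative"})

    def __post_init__(self) -> None:
        dangling = sorted(
            cid
            for pw in self.pathways
            for cid in pw.compound_ids
            if cid not in self.compounds
        )
        if dangling:
            raise LibraryError(f"pathway compound ids not in library: {dangling}")

    def pathway(self, pathway_id: str) -> PathwaySet:
        for pw in self.pathways:
            if pw.id == pathway_id:
                return pw
        raise KeyError(pathway_id)


@dataclass(frozen=True)
class AdductRule:
    label: str
    ion_mode: str
    mass_multiplier: int
    mass_shift: float
    charge: int

    def __post_init__(self) -> None:
        if self.ion_mode not in ("positive", "negative"):
            raise LibraryError(f"adduct {self.label}: bad ion mode {self.ion_mode!r}")
        if self.mass_multiplier < 1:
            raise LibraryError(f"adduct {self.label}: multiplier must be >= 1")
        if self.charge == 0:
            raise LibraryError(f"adduct {self.label}: zero charge")

    def mz(self, neutral_mass: float) -> float:
        return chem.adduct_mz(neutral_mass, self.mass_multiplier, self.mass_shift, self.charge)


@dataclass
class AdductRuleSet:
    rules: list[AdductRule]
    ppm_tolerance: float = 5.0

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise LibraryError("ppm tolerance must be positive")
        seen: set[tuple[str, str]] = set()
        for r in self.rules:
            key = (r.ion_mode, r.label)
            if key in seen:
                raise LibraryError(f"duplicate adduct label {r.label!r} in {r.ion_mode} mode")
            seen.add(key)

    def for_mode(self, ion_mode: str) -> list[AdductRule]:
        if ion_mode not in ("positive", "negative"):
            raise LibraryError(f"unknown ion mode {ion_mode!r}")
        return [r for r in self.rules if r.ion_mode == ion_mode]

    def rule(self, label: str, ion_mode: str | None = None) -> AdductRule:
        for r in self.rules:
            if r.label == label and (ion_mode is None or r.ion_mode == ion_mode):
                return r
        raise KeyError(label)


def load_library(path: str | Path) -> CompoundPathwayLibrary:
    """Load and validate a compound/pathway library from JSON.

    Compounds without a precomputed ``mass`` get their monoisotopic mass
    computed from the formula. Duplicate compound ids and pathway references
    to unknown compounds are hard errors.
    """
    with open(path) as fh:
        raw = json.load(fh)
    compounds: dict[str, Compound] = {}
    for entry in raw.get("compounds", []):
        cid = entry["id"]
        if cid in compounds:
            raise LibraryError(f"duplicate compound id {cid!r}")
        mass = entry.get("mass")
        if mass is None:
            mass = chem.monoisotopic_mass(entry["formula"])
        compounds[cid] = Compound(
            id=cid, name=entry.get("name", cid), formula=entry["formula"],
            monoisotopic_mass=float(mass),
        )
    pathways = [
        PathwaySet(id=p["id"], name=p["name"], compound_ids=frozenset(p["cpds"]))
        for p in raw.get("pathways", [])
    ]
    mode = raw.get("ion_mode", "both")
    modes = frozenset({"positive", "negative"}) if mode == "both" else frozenset({mode})
    return CompoundPathwayLibrary(
        name=raw.get("name", str(path)), compounds=compounds, pathways=pathways,
        ion_modes_supported=modes,
    )


def load_adduct_rules(path: str | Path, ppm_tolerance: float = 5.0) -> AdductRuleSet:
    """Load an adduct rule table (CSV: label, ion_mode, multiplier, shift_da, charge)."""
    rules = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rules.append(
                AdductRule(
                    label=row["label"],
                    ion_mode=row["ion_mode"],
                    mass_multiplier=int(row["multiplier"]),
                    mass_shift=float(row["shift_da"]),
                    charge=int(row["charge"]),
                )
            )
    return AdductRuleSet(rules=rules, ppm_tolerance=ppm_tolerance)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mzpathway") / "data" / name))


def bundled_library() -> CompoundPathwayLibrary:
    """The bundled synthetic toy compound/pathway library."""
    return load_library(_data_path("library_hsa_toy.json"))


def bundled_adduct_rules(ppm_tolerance: float = 5.0) -> AdductRuleSet:
    """The bundled default electrospray adduct rule table."""
    return load_adduct_rules(_data_path("adducts.csv"), ppm_tolerance=ppm_tolerance)
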