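"""Declarative model description for multispecific T-cell-engager systems.

A :class:`ModelDefinition` lists the cell populations, the surface receptors
they express, the binding arms of the drug, and the admissible drug-bridged
cell--cell pairings.  Everything downstream (the generated ODE system, the
simulator, calibration and the dose--response studies) is derived from this
single validated object.

Units are fixed globally: nM for solution concentrations, hours for time,
absolute counts for cells and receptors, mL for volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Optional, Union

import yaml

SCHEMA_VERSION = 1

LINEAGES = ("CD4-T", "CD8-T", "tumor", "PBMC")
ACTIVATION_STATES = ("naive", "effector-memory", "active", "not-applicable")


class ValidationError(ValueError):
    """Raised when a model definition fails validation.

    Carries the full list of failing fields so that a config author can fix
    every problem in one pass.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid model definition:\n" + "\n".join(f"  - {p}" for p in problems))


def derive_koff(kon: float, KD: float) -> float:
    """Dissociation rate (per hour) from kon (per nM per hour) and KD (nM).

    koff = KD * kon.
    """
    if kon < 0 or KD <= 0:
        raise ValueError(f"require kon >= 0 and KD > 0, got kon={kon}, KD={KD}")
    return KD * kon


@dataclass
class DrugArmSpec:
    """One binding arm of the drug. koff is always derived as KD * kon."""

    name: str
    kon: float  # per nM per hour
    KD: float  # nM

    @property
    def koff(self) -> float:  # per hour
        return derive_koff(self.kon, self.KD)


@dataclass
class ReceptorSpec:
    name: str
    expressed_on: dict[str, float]  # cell name -> copies per cell
    drug_arm: str


@dataclass
class CellTypeSpec:
    name: str
    lineage: str  # one of LINEAGES
    activation_state: str = "not-applicable"
    receptors: list[str] = field(default_factory=list)
    proliferation_rate: float = 0.0  # per hour
    degradation_rate: float = 0.0  # per hour
    can_kill: bool = False
    killable: bool = False
    initial_count: float = 0.0  # cells


@dataclass(frozen=True, order=True)
class SynapsePairing:
    """Unordered drug-bridged pairing, stored in canonical order.

    ``cell_a`` carries ``receptor_a`` and ``cell_b`` carries ``receptor_b``;
    the two receptors are bound by *different* drug arms (one arm cannot
    bridge two copies of its own target).  Canonical order is lexicographic
    by (cell name, receptor name).
    """

    cell_a: str
    receptor_a: str
    cell_b: str
    receptor_b: str

    @staticmethod
    def make(cell_a: str, receptor_a: str, cell_b: str, receptor_b: str) -> "SynapsePairing":
        if (cell_a, receptor_a) <= (cell_b, receptor_b):
            return SynapsePairing(cell_a, receptor_a, cell_b, receptor_b)
        return SynapsePairing(cell_b, receptor_b, cell_a, receptor_a)

    @property
    def key(self) -> str:
        return f"{self.cell_a}:{self.receptor_a}|{self.cell_b}:{self.receptor_b}"


@dataclass
class CytokineProducer:
    cell: str
    rate: float  # molecules per cell per hour
    in_synapse_only: bool = False


@dataclass
class CytokineSpec:
    name: str
    producers: list[CytokineProducer] = field(default_factory=list)


@dataclass
class SolubleAntigenSpec:
    """Shed soluble antigen that sequesters drug into an inert complex."""

    name: str
    shedding_sources: list[str]  # cell names (free pools shed)
    shedding_rate: float  # molecules per cell per hour
    kon: float  # per nM per hour
    KD: float  # nM

    @property
    def koff(self) -> float:
        return derive_koff(self.kon, self.KD)


@dataclass
class ActivationSpec:
    """T-cell activation kinetics.

    Effector-memory cells bridged in synapse through CD3 convert at the
    constant rate ``k_act_EM``.  Naive cells additionally require CD28
    co-stimulation: an AND gate of Michaelis--Menten terms in drug-bound CD3
    and drug-bound CD28 on the cell multiplies ``k_act_naive``.
    """

    k_act_EM: float = 0.0  # per hour
    k_act_naive: float = 0.0  # per hour
    Km_CD3_bound: float = 1.0  # bound receptors per cell
    Km_CD28_bound: float = 1.0  # bound receptors per cell
    cd3_receptor: str = "CD3"
    cd28_receptor: str = "CD28"


@dataclass
class ModelDefinition:
    name: str
    cells: list[CellTypeSpec]
    receptors: list[ReceptorSpec]
    arms: list[DrugArmSpec]
    #: explicit allow-list of pairings; None admits every enumerable pairing
    pairings: Optional[list[SynapsePairing]] = None
    cytokines: list[CytokineSpec] = field(default_factory=list)
    soluble_antigen: Optional[SolubleAntigenSpec] = None
    activation: ActivationSpec = field(default_factory=ActivationSpec)
    # killing rates per (killer lineage, victim lineage), per hour
    killing: dict[tuple[str, str], float] = field(default_factory=dict)
    resistance_rate: Optional[float] = None  # per hour; None disables escape
    collision_factor: float = 1.0  # dimensionless
    bridges_per_synapse: float = 1.0
    volume: float = 0.2  # mL
    reference_volume: float = 0.2  # mL
    schema_version: int = SCHEMA_VERSION

    # -- lookups ---------------------------------------------------------
    def cell(self, name: str) -> CellTypeSpec:
        return self._cells[name]

    def receptor(self, name: str) -> ReceptorSpec:
        return self._receptors[name]

    def arm(self, name: str) -> DrugArmSpec:
        return self._arms[name]

    def arm_of(self, receptor: str) -> DrugArmSpec:
        return self._arms[self._receptors[receptor].drug_arm]

    def receptors_on(self, cell: str) -> list[str]:
        return list(self._cells[cell].receptors)

    def expression(self, cell: str, receptor: str) -> float:
        return self._receptors[receptor].expressed_on.get(cell, 0.0)

    def __post_init__(self):
        self._reindex()

    def _reindex(self):
        self._cells = {c.name: c for c in self.cells}
        self._receptors = {r.name: r for r in self.receptors}
        self._arms = {a.name: a for a in self.arms}

    def validate(self) -> "ModelDefinition":
        problems: list[str] = []
        self._reindex()
        if len(self._cells) != len(self.cells):
            problems.append("duplicate cell names")
        if len(self._receptors) != len(self.receptors):
            problems.append("duplicate receptor names")
        if len(self._arms) != len(self.arms):
            problems.append("duplicate arm names")
        for a in self.arms:
            if a.kon < 0:
                problems.append(f"arm {a.name}: kon < 0")
            if a.KD <= 0:
                problems.append(f"arm {a.name}: KD <= 0")
        for r in self.receptors:
            if r.drug_arm not in self._arms:
                problems.append(f"receptor {r.name}: unknown drug arm {r.drug_arm!r}")
            for cell, copies in r.expressed_on.items():
                if cell not in self._cells:
                    problems.append(f"receptor {r.name}: expressed_on unknown cell {cell!r}")
                if copies < 0:
                    problems.append(f"receptor {r.name}: negative copies on {cell}")
        for c in self.cells:
            if c.lineage not in LINEAGES:
                problems.append(f"cell {c.name}: unknown lineage {c.lineage!r}")
            if c.activation_state not in ACTIVATION_STATES:
                problems.append(f"cell {c.name}: unknown activation state {c.activation_state!r}")
            if c.initial_count < 0:
                problems.append(f"cell {c.name}: negative initial count")
            if c.lineage in ("tumor", "PBMC") and c.can_kill:
                problems.append(f"cell {c.name}: {c.lineage} cells cannot kill")
            for rname in c.receptors:
                if rname not in self._receptors:
                    problems.append(f"cell {c.name}: unknown receptor {rname!r}")
                elif c.name not in self._receptors[rname].expressed_on:
                    problems.append(
                        f"cell {c.name}: receptor {rname} listed but no expression level given"
                    )
        for cy in self.cytokines:
            for p in cy.producers:
                if p.cell not in self._cells:
                    problems.append(f"cytokine {cy.name}: unknown producer cell {p.cell!r}")
        if self.soluble_antigen is not None:
            for src in self.soluble_antigen.shedding_sources:
                if src not in self._cells:
                    problems.append(f"soluble antigen: unknown shedding source {src!r}")
        if self.pairings is not None:
            for p in self.pairings:
                for cell, rec in ((p.cell_a, p.receptor_a), (p.cell_b, p.receptor_b)):
                    if cell not in self._cells:
                        problems.append(f"pairing {p.key}: unknown cell {cell!r}")
                    elif rec not in self._receptors:
                        problems.append(f"pairing {p.key}: unknown receptor {rec!r}")
                    elif rec not in self._cells[cell].receptors:
                        problems.append(f"pairing {p.key}: {cell} does not carry {rec}")
                if (p.receptor_a in self._receptors and p.receptor_b in self._receptors
                        and self._receptors[p.receptor_a].drug_arm
                        == self._receptors[p.receptor_b].drug_arm):
                    problems.append(f"pairing {p.key}: both receptors use the same arm")
        for (killer, victim), rate in self.killing.items():
            if killer not in LINEAGES or victim not in LINEAGES:
                problems.append(f"killing rate for unknown lineages ({killer}, {victim})")
            if rate < 0:
                problems.append(f"negative killing rate for ({killer}, {victim})")
        if self.bridges_per_synapse <= 0:
            problems.append("bridges_per_synapse must be > 0")
        if self.collision_factor < 0:
            problems.append("collision_factor must be >= 0")
        if self.volume <= 0 or self.reference_volume <= 0:
            problems.append("volumes must be > 0")
        if problems:
            raise ValidationError(problems)
        return self


def enumerate_pairings(definition: ModelDefinition) -> list[SynapsePairing]:
    """All admissible drug-bridged pairings between distinct cell pools.

    A pairing (cell_a:receptor_a -- cell_b:receptor_b) is admissible when the
    two receptors are bound by different drug arms.  Pairings within a single
    pool (homotypic) are excluded: the enumeration resolves pairs of distinct
    populations.  Output is sorted in the canonical order, independent of the
    order in which cells were declared.
    """
    out: set[SynapsePairing] = set()
    cells = definition.cells
    for ca, cb in combinations(sorted(cells, key=lambda c: c.name), 2):
        for ra in ca.receptors:
            for rb in cb.receptors:
                arm_a = definition.receptor(ra).drug_arm
                arm_b = definition.receptor(rb).drug_arm
                if arm_a != arm_b:
                    out.add(SynapsePairing.make(ca.name, ra, cb.name, rb))
    if definition.pairings is not None:
        allowed = {SynapsePairing.make(p.cell_a, p.receptor_a, p.cell_b, p.receptor_b)
                   for p in definition.pairings}
        out &= allowed
    return sorted(out)


# -- serialization ---------------------------------------------------------


def definition_to_dict(defn: ModelDefinition) -> dict:
    d = {
        "schema_version": defn.schema_version,
        "name": defn.name,
        "collision_factor": defn.collision_factor,
        "bridges_per_synapse": defn.bridges_per_synapse,
        "volume": defn.volume,
        "reference_volume": defn.reference_volume,
        "arms": [{"name": a.name, "kon": a.kon, "KD": a.KD} for a in defn.arms],
        "receptors": [asdict(r) for r in defn.receptors],
        "cells": [asdict(c) for c in defn.cells],
        "cytokines": [asdict(c) for c in defn.cytokines],
        "activation": asdict(defn.activation),
        "killing": [
            {"killer": k, "victim": v, "rate": rate} for (k, v), rate in sorted(defn.killing.items())
        ],
        "resistance_rate": defn.resistance_rate,
    }
    if defn.pairings is not None:
        d["pairings"] = [
            {"cell_a": p.cell_a, "receptor_a": p.receptor_a,
             "cell_b": p.cell_b, "receptor_b": p.receptor_b}
            for p in defn.pairings
        ]
    if defn.soluble_antigen is not None:
        sa = defn.soluble_antigen
        d["soluble_antigen"] = {
            "name": sa.name,
            "shedding_sources": sa.shedding_sources,
            "shedding_rate": sa.shedding_rate,
            "kon": sa.kon,
            "KD": sa.KD,
        }
    return d


def definition_from_dict(d: dict) -> ModelDefinition:
    version = d.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValidationError([f"unsupported schema_version {version}"])
    try:
        arms = [DrugArmSpec(**a) for a in d.get("arms", [])]
        receptors = [ReceptorSpec(**r) for r in d.get("receptors", [])]
        cells = [CellTypeSpec(**c) for c in d.get("cells", [])]
        cytokines = [
            CytokineSpec(name=c["name"], producers=[CytokineProducer(**p) for p in c.get("producers", [])])
            for c in d.get("cytokines", [])
        ]
        activation = ActivationSpec(**d.get("activation", {}))
        killing = {(k["killer"], k["victim"]): k["rate"] for k in d.get("killing", [])}
        sa = d.get("soluble_antigen")
        soluble = SolubleAntigenSpec(**sa) if sa else None
        pairings = None
        if "pairings" in d:
            pairings = [SynapsePairing.make(**p) for p in d["pairings"]]
    except (TypeError, KeyError) as exc:
        raise ValidationError([f"malformed definition document: {exc}"]) from exc
    defn = ModelDefinition(
        name=d.get("name", "model"),
        pairings=pairings,
        cells=cells,
        receptors=receptors,
        arms=arms,
        cytokines=cytokines,
        soluble_antigen=soluble,
        activation=activation,
        killing=killing,
        resistance_rate=d.get("resistance_rate"),
        collision_factor=d.get("collision_factor", 1.0),
        bridges_per_synapse=d.get("bridges_per_synapse", 1.0),
        volume=d.get("volume", 0.2),
        reference_volume=d.get("reference_volume", 0.2),
        schema_version=version,
    )
    return defn.validate()


def load_model_definition(path_or_dict: Union[str, Path, dict]) -> ModelDefinition:
    """Load and validate a model definition from YAML/JSON file or dict."""
    if isinstance(path_or_dict, dict):
        return definition_from_dict(path_or_dict)
    text = Path(path_or_dict).read_text()
    doc = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(doc, dict):
        raise ValidationError(["document root must be a mapping"])
    return definition_from_dict(doc)


def save_model_definition(defn: ModelDefinition, path: Union[str, Path]) -> None:
    path = Path(path)
    d = definition_to_dict(defn)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
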