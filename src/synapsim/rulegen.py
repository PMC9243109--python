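"""Rule-based expansion of a model definition into a complete ODE system.

The generator traverses the declarative :class:`~synapsim.schema.ModelDefinition`
and emits every species and rate term of the kinetic model: drug--receptor
binding on every cell context, synapse formation and dissociation for every
admissible pairing, T-cell activation, killing, escape into a
killing-resistant pool, cell lifecycle, cytokine secretion and soluble-antigen
shedding.  Alongside the state equations it emits synthesis/degradation
flux-accumulator equations per conserved lineage so that mass balance can be
audited on any trajectory.

Enumeration convention
----------------------
State species are::

    {free drug, soluble antigen, drug--antigen complex, cytokines}
  u {one free pool per cell type, plus one resistant pool per killable tumor type}
  u {one synapse species per admissible (cell pool pair, bridge receptor pair)}
  u {free / drug-bound receptor copies per (receptor, context)}

where a *context* is a free pool or a synapse membership.  Receptors
sequestered in bridges are not separate states: a synapse holds exactly
``b`` (bridges-per-synapse) copies of each of its two bridging receptors per
synapse, so the bridged amount is ``b x`` the synapse copy number and is
accounted implicitly in occupancy and mass-balance bookkeeping.  Pairings
join two *distinct* pools; flux accumulators are audit variables and are not
counted as model species.

Parameters are emitted per named rate constant, binding constant,
expression level and structural factor, including one collision factor per
interacting pool pair (all initialised from the definition's single
``collision_factor``), per-(cell, receptor) expression levels and per-pool
initial counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
from scipy import sparse

from .schema import ModelDefinition, SynapsePairing

#: molecules per mL per nM (Avogadro x 1e-9 mol/L x 1e-3 L/mL)
COUNTS_PER_NM_PER_ML = 6.02214076e11

#: regularisation for per-cell shares X/(N + EPS)
EPS_SHARE = 1e-12

FREE, BOUND = "free", "bound"


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class Species:
    name: str
    kind: str  # free-cell | synapse | receptor-state | drug | soluble-antigen |
    #            drug-antigen-complex | cytokine
    context: str = ""  # owning pool or synapse key ("" for well-mixed species)
    receptor_state: str = "not-applicable"


@dataclass
class Parameter:
    name: str
    value: float
    units: str = ""


@dataclass
class Coeff:
    """Stoichiometric coefficient ``const * params[pname]`` (pname optional)."""

    const: float
    pname: Optional[str] = None


@dataclass
class Gate:
    """Saturating factor (xn + beta*xd) / (Km*(xd+eps) + xn + beta*xd).

    ``xn`` is a pooled bound-receptor species, ``xd`` the synapse species it
    is normalised by (per-cell Michaelis--Menten in pooled coordinates);
    ``beta`` adds the implicit bridged (hence drug-bound) copies per synapse.
    """

    num: str
    den: str
    Km_param: str
    beta_param: Optional[str] = None


@dataclass
class RateTerm:
    rule: str
    k_const: float = 1.0
    param_pows: list[tuple[str, int]] = field(default_factory=list)
    lin: list[str] = field(default_factory=list)  # multiply by these species
    inv: list[str] = field(default_factory=list)  # divide by (x + eps)
    gates: list[Gate] = field(default_factory=list)
    stoich: dict[str, Coeff] = field(default_factory=dict)
    # (lineage name, "synth"|"deg", Coeff)
    flux: list[tuple[str, str, Coeff]] = field(default_factory=list)

    def add(self, species: str, const: float, pname: Optional[str] = None):
        cur = self.stoich.get(species)
        if cur is not None and cur.pname == pname:
            cur.const += const
        else:
            self.stoich[species] = Coeff(const, pname)


@dataclass
class Lineage:
    """Group of species whose weighted total changes only via registered fluxes."""

    name: str
    weights: dict[str, Coeff]


# ---------------------------------------------------------------------------
# extended cell view (adds the resistant shadow pools)


@dataclass
class _CellView:
    name: str
    lineage: str
    activation_state: str
    receptors: list[str]
    k_prolif: float
    k_deg: float
    can_kill: bool
    killable: bool
    initial: float
    resistant: bool = False
    parent: Optional[str] = None


def _extended_cells(defn: ModelDefinition) -> list[_CellView]:
    views = [
        _CellView(
            c.name, c.lineage, c.activation_state, list(c.receptors),
            c.proliferation_rate, c.degradation_rate, c.can_kill, c.killable,
            c.initial_count,
        )
        for c in defn.cells
    ]
    if defn.resistance_rate is not None:
        for c in defn.cells:
            if c.lineage == "tumor" and c.killable:
                views.append(
                    _CellView(
                        f"{c.name}_res", c.lineage, "not-applicable",
                        list(c.receptors), c.proliferation_rate,
                        c.degradation_rate, False, False, 0.0,
                        resistant=True, parent=c.name,
                    )
                )
    return views


# ---------------------------------------------------------------------------
# species naming helpers (the consistent naming standard the generator's
# pattern matching relies on)


def pool_name(cell: str) -> str:
    return f"cell.{cell}"


def syn_name(p: SynapsePairing) -> str:
    return f"syn.{p.key}"


def rec_name(receptor: str, state: str, context: str, member: Optional[str] = None) -> str:
    if member is None:
        return f"rec.{receptor}.{state}@{context}"
    return f"rec.{receptor}.{state}@{context}#{member}"


class GeneratedModel:
    """Enumerated species, parameters, rate terms and flux-audit structure."""

    def __init__(self, definition: ModelDefinition):
        self.definition = definition
        self.cells: list[_CellView] = []
        self.pairings: list[SynapsePairing] = []
        self.species: list[Species] = []
        self.parameters: list[Parameter] = []
        self.terms: list[RateTerm] = []
        self.lineages: list[Lineage] = []
        self._sidx: dict[str, int] = {}
        self._pidx: dict[str, int] = {}
        self._lidx: dict[str, int] = {}
        self._compiled: Optional[_Compiled] = None

    # -- lookups --------------------------------------------------------
    def species_index(self, name: str) -> int:
        return self._sidx[name]

    def param_index(self, name: str) -> int:
        return self._pidx[name]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    @property
    def n_states(self) -> int:
        """Integrated state dimension: species plus flux accumulators."""
        return self.n_species + 2 * len(self.lineages)

    def flux_index(self, lineage: str, kind: str) -> int:
        base = self.n_species + 2 * self._lidx[lineage]
        return base if kind == "synth" else base + 1

    def default_params(self) -> np.ndarray:
        return np.array([p.value for p in self.parameters])

    def params_with(self, overrides: dict[str, float]) -> np.ndarray:
        p = self.default_params()
        for k, v in overrides.items():
            p[self._pidx[k]] = v
        return p

    # -- counts ---------------------------------------------------------
    def count(self) -> dict[str, int]:
        return {"n_species": self.n_species, "n_parameters": self.n_parameters}

    # -- lineage totals -------------------------------------------------
    def lineage_weights(self, lineage: str, params: np.ndarray) -> np.ndarray:
        w = np.zeros(self.n_species)
        for sp, c in self.lineages[self._lidx[lineage]].weights.items():
            w[self._sidx[sp]] += c.const * (params[self._pidx[c.pname]] if c.pname else 1.0)
        return w

    def lineage_total(self, lineage: str, states: np.ndarray, params: np.ndarray) -> np.ndarray:
        """Weighted total of a lineage; ``states`` is (n_states,) or (n_states, nt)."""
        w = self.lineage_weights(lineage, params)
        return w @ np.asarray(states)[: self.n_species]

    # -- manifest / listing --------------------------------------------
    def to_manifest(self) -> dict:
        return {
            "definition": self.definition.name,
            "n_species": self.n_species,
            "n_parameters": self.n_parameters,
            "species": [
                {"name": s.name, "kind": s.kind, "context": s.context,
                 "receptor_state": s.receptor_state}
                for s in self.species
            ],
            "parameters": [
                {"name": p.name, "value": p.value, "units": p.units}
                for p in self.parameters
            ],
            "terms": [
                {"rule": t.rule,
                 "rate": _rate_string(t),
                 "stoich": {k: _coeff_string(c) for k, c in t.stoich.items()},
                 "flux": [[ln, kind, _coeff_string(c)] for ln, kind, c in t.flux]}
                for t in self.terms
            ],
            "lineages": [ln.name for ln in self.lineages],
        }

    def equation_listing(self) -> str:
        """Human-readable ODE listing for audit diffing."""
        per_species: dict[str, list[str]] = {s.name: [] for s in self.species}
        for ln in self.lineages:
            per_species[f"flux.synth.{ln.name}"] = []
            per_species[f"flux.deg.{ln.name}"] = []
        for t in self.terms:
            rate = _rate_string(t)
            for spname, c in t.stoich.items():
                per_species[spname].append(f"{_signed(c)} * {rate}  [{t.rule}]")
            for lname, kind, c in t.flux:
                per_species[f"flux.{kind}.{lname}"].append(
                    f"{_signed(c, always_plus=True)} * {rate}  [{t.rule}]"
                )
        lines = []
        for name, contribs in per_species.items():
            lines.append(f"d({name})/dt =")
            if not contribs:
                lines.append("    0")
            for c in contribs:
                lines.append(f"    {c}")
        return "\n".join(lines) + "\n"

    # -- compiled RHS ---------------------------------------------------
    def compiled(self) -> "_Compiled":
        if self._compiled is None:
            self._compiled = _Compiled(self)
        return self._compiled


def _coeff_string(c: Coeff) -> str:
    return f"{c.const:g}" if c.pname is None else f"{c.const:g}*{c.pname}"


def _signed(c: Coeff, always_plus: bool = False) -> str:
    s = _coeff_string(c)
    return f"+{s}" if (c.const >= 0 or always_plus) and not s.startswith("-") else s


def _rate_string(t: RateTerm) -> str:
    parts = [f"{t.k_const:g}"] if t.k_const != 1.0 or not (t.param_pows or t.lin) else []
    for name, pw in t.param_pows:
        parts.append(name if pw == 1 else f"{name}^{pw}")
    parts += list(t.lin)
    for s in t.inv:
        parts.append(f"1/({s}+eps)")
    for g in t.gates:
        beta = f" + {g.beta_param}*{g.den}" if g.beta_param else ""
        parts.append(f"[({g.num}{beta})/({g.Km_param}*{g.den}{beta} + {g.num})]")
    return " * ".join(parts) if parts else "1"


# ---------------------------------------------------------------------------
# generation


def generate_model(definition: ModelDefinition) -> GeneratedModel:
    """Expand a validated definition into the full ODE system."""
    definition.validate()
    if not definition.cells:
        raise GenerationError("definition has no cell types")
    if not definition.arms:
        raise GenerationError("definition has no drug arms")
    m = GeneratedModel(definition)
    b = _Builder(m)
    b.build()
    return m


class _Builder:
    def __init__(self, model: GeneratedModel):
        self.m = model
        self.d = model.definition

    # expression level, transparent to resistant shadow pools
    def expr_param(self, cell: _CellView, receptor: str) -> str:
        return f"R.{receptor}.{cell.name}"

    def build(self):
        d, m = self.d, self.m
        m.cells = _extended_cells(d)
        self.cv = {c.name: c for c in m.cells}
        m.pairings = self._enumerate_extended()
        self._emit_species()
        self._emit_parameters()
        self._emit_lineages()
        self._emit_terms()
        m._sidx = {s.name: i for i, s in enumerate(m.species)}
        m._pidx = {p.name: i for i, p in enumerate(m.parameters)}
        m._lidx = {ln.name: i for i, ln in enumerate(m.lineages)}
        self._check()

    def _enumerate_extended(self) -> list[SynapsePairing]:
        allowed = None
        if self.d.pairings is not None:
            allowed = {SynapsePairing.make(p.cell_a, p.receptor_a,
                                           p.cell_b, p.receptor_b)
                       for p in self.d.pairings}
        out: set[SynapsePairing] = set()
        for ca, cb in combinations(sorted(self.m.cells, key=lambda c: c.name), 2):
            for ra in ca.receptors:
                for rb in cb.receptors:
                    if self.d.receptor(ra).drug_arm == self.d.receptor(rb).drug_arm:
                        continue
                    if allowed is not None:
                        # resistant shadow pools inherit their parent's pairings
                        base_a = ca.parent or ca.name
                        base_b = cb.parent or cb.name
                        if SynapsePairing.make(base_a, ra, base_b, rb) not in allowed:
                            continue
                    out.add(SynapsePairing.make(ca.name, ra, cb.name, rb))
        return sorted(out)

    # -- species --------------------------------------------------------
    def _emit_species(self):
        d, m = self.d, self.m
        sp = m.species
        sp.append(Species("drug", "drug"))
        if d.soluble_antigen is not None:
            sa = d.soluble_antigen.name
            sp.append(Species(f"sol.{sa}", "soluble-antigen"))
            sp.append(Species(f"complex.drug:{sa}", "drug-antigen-complex"))
        for cy in d.cytokines:
            sp.append(Species(f"cyt.{cy.name}", "cytokine"))
        for c in m.cells:
            sp.append(Species(pool_name(c.name), "free-cell", context=pool_name(c.name)))
        for p in m.pairings:
            sp.append(Species(syn_name(p), "synapse", context=syn_name(p)))
        for c in m.cells:
            for r in c.receptors:
                for st in (FREE, BOUND):
                    sp.append(
                        Species(rec_name(r, st, pool_name(c.name)), "receptor-state",
                                context=pool_name(c.name), receptor_state=st)
                    )
        for p in m.pairings:
            for member in (p.cell_a, p.cell_b):
                for r in self.cv[member].receptors:
                    for st in (FREE, BOUND):
                        sp.append(
                            Species(rec_name(r, st, syn_name(p), member), "receptor-state",
                                    context=syn_name(p), receptor_state=st)
                        )

    # -- parameters -----------------------------------------------------
    def _emit_parameters(self):
        d, m = self.d, self.m
        P = m.parameters
        for a in d.arms:
            P.append(Parameter(f"kon.{a.name}", a.kon, "1/nM/h"))
            P.append(Parameter(f"KD.{a.name}", a.KD, "nM"))
            P.append(Parameter(f"koff.{a.name}", a.koff, "1/h"))
        P.append(Parameter("bridges_per_synapse", d.bridges_per_synapse, "bridges"))
        self.cell_pairs = sorted({tuple(sorted((p.cell_a, p.cell_b))) for p in m.pairings})
        for ca, cb in self.cell_pairs:
            P.append(Parameter(f"collision.{ca}|{cb}", d.collision_factor, ""))
        P.append(Parameter("dose", 0.0, "nM"))
        P.append(Parameter("volume", d.volume, "mL"))
        P.append(Parameter("ref_volume", d.reference_volume, "mL"))
        states = {c.activation_state for c in m.cells}
        if "effector-memory" in states:
            P.append(Parameter("k_act.EM", d.activation.k_act_EM, "1/h"))
        if "naive" in states:
            P.append(Parameter("k_act.naive", d.activation.k_act_naive, "1/h"))
            P.append(Parameter("Km.CD3_bound", d.activation.Km_CD3_bound, "receptors/cell"))
            P.append(Parameter("Km.CD28_bound", d.activation.Km_CD28_bound, "receptors/cell"))
        for (killer, victim), rate in sorted(d.killing.items()):
            P.append(Parameter(f"k_kill.{killer}.{victim}", rate, "1/h"))
        if d.resistance_rate is not None:
            P.append(Parameter("k_res", d.resistance_rate, "1/h"))
        for c in m.cells:
            P.append(Parameter(f"k_prolif.{c.name}", c.k_prolif, "1/h"))
            P.append(Parameter(f"k_deg.{c.name}", c.k_deg, "1/h"))
        for cy in d.cytokines:
            for pr in cy.producers:
                P.append(Parameter(f"k_cyt.{pr.cell}.{cy.name}", pr.rate, "molec/cell/h"))
        if d.soluble_antigen is not None:
            sa = d.soluble_antigen
            P.append(Parameter(f"k_shed.{sa.name}", sa.shedding_rate, "molec/cell/h"))
            P.append(Parameter(f"kon.{sa.name}", sa.kon, "1/nM/h"))
            P.append(Parameter(f"KD.{sa.name}", sa.KD, "nM"))
            P.append(Parameter(f"koff.{sa.name}", sa.koff, "1/h"))
        for c in m.cells:
            for r in c.receptors:
                base = c.parent if c.resistant else c.name
                P.append(Parameter(self.expr_param(c, r), d.expression(base, r), "copies/cell"))
        for c in m.cells:
            P.append(Parameter(f"N0.{c.name}", c.initial, "cells"))

    # -- lineages -------------------------------------------------------
    def _emit_lineages(self):
        d, m = self.d, self.m
        L = m.lineages
        by_lineage: dict[str, list[_CellView]] = {}
        for c in m.cells:
            by_lineage.setdefault(c.lineage, []).append(c)

        def member_cells(p: SynapsePairing) -> list[tuple[str, str]]:
            return [(p.cell_a, p.receptor_a), (p.cell_b, p.receptor_b)]

        for lineage, cells in by_lineage.items():
            names = {c.name for c in cells}
            w: dict[str, Coeff] = {pool_name(c.name): Coeff(1.0) for c in cells}
            for p in m.pairings:
                n = sum(1 for mem, _ in member_cells(p) if mem in names)
                if n:
                    w[syn_name(p)] = Coeff(float(n))
            L.append(Lineage(f"cells.{lineage}", w))

        rec_lineages = sorted(
            {(r, c.lineage) for c in m.cells for r in c.receptors}
        )
        for r, lineage in rec_lineages:
            names = {c.name for c in by_lineage[lineage] if r in c.receptors}
            w = {}
            for c in by_lineage[lineage]:
                if r in c.receptors:
                    for st in (FREE, BOUND):
                        w[rec_name(r, st, pool_name(c.name))] = Coeff(1.0)
            for p in m.pairings:
                for mem, bridge_r in member_cells(p):
                    if mem in names:
                        for st in (FREE, BOUND):
                            w[rec_name(r, st, syn_name(p), mem)] = Coeff(1.0)
                        if bridge_r == r:
                            key = syn_name(p)
                            prev = w.get(key)
                            const = (prev.const if prev else 0.0) + 1.0
                            w[key] = Coeff(const, "bridges_per_synapse")
            L.append(Lineage(f"rec.{r}.{lineage}", w))

        w = {"drug": Coeff(1.0)}
        for s in m.species:
            if s.kind == "receptor-state" and s.receptor_state == BOUND:
                w[s.name] = Coeff(1.0)
        for p in m.pairings:
            w[syn_name(p)] = Coeff(1.0, "bridges_per_synapse")
        if d.soluble_antigen is not None:
            w[f"complex.drug:{d.soluble_antigen.name}"] = Coeff(1.0)
        L.append(Lineage("drug", w))

        if d.soluble_antigen is not None:
            sa = d.soluble_antigen.name
            L.append(Lineage(f"sol.{sa}",
                             {f"sol.{sa}": Coeff(1.0), f"complex.drug:{sa}": Coeff(1.0)}))
        for cy in d.cytokines:
            L.append(Lineage(f"cyt.{cy.name}", {f"cyt.{cy.name}": Coeff(1.0)}))

    # -- terms ----------------------------------------------------------
    def _emit_terms(self):
        self._terms_binding()
        self._terms_soluble()
        self._terms_synapse()
        self._terms_activation()
        self._terms_killing_resistance()
        self._terms_lifecycle()
        self._terms_cytokines()

    def _contexts(self):
        """Yield (context label, member cell view, member tag or None)."""
        for c in self.m.cells:
            yield pool_name(c.name), c, None
        for p in self.m.pairings:
            for mem in (p.cell_a, p.cell_b):
                yield syn_name(p), self.cv[mem], mem

    def _terms_binding(self):
        """Monovalent drug binding/unbinding on every receptor context."""
        for ctx, cell, mem in self._contexts():
            for r in cell.receptors:
                arm = self.d.receptor(r).drug_arm
                free = rec_name(r, FREE, ctx, mem)
                bound = rec_name(r, BOUND, ctx, mem)
                on = RateTerm(
                    rule="drug-binding",
                    k_const=1.0 / COUNTS_PER_NM_PER_ML,
                    param_pows=[(f"kon.{arm}", 1), ("volume", -1)],
                    lin=["drug", free],
                )
                on.add(free, -1.0)
                on.add(bound, +1.0)
                on.add("drug", -1.0)
                self.m.terms.append(on)
                off = RateTerm(
                    rule="drug-unbinding",
                    param_pows=[(f"koff.{arm}", 1)],
                    lin=[bound],
                )
                off.add(bound, -1.0)
                off.add(free, +1.0)
                off.add("drug", +1.0)
                self.m.terms.append(off)

    def _terms_soluble(self):
        sa = self.d.soluble_antigen
        if sa is None:
            return
        sol = f"sol.{sa.name}"
        cx = f"complex.drug:{sa.name}"
        sources = set(sa.shedding_sources)
        for c in self.m.cells:
            base = c.parent if c.resistant else c.name
            if base in sources:
                t = RateTerm(rule="shedding",
                             param_pows=[(f"k_shed.{sa.name}", 1)],
                             lin=[pool_name(c.name)])
                t.add(sol, +1.0)
                t.flux.append((sol, "synth", Coeff(1.0)))
                self.m.terms.append(t)
        on = RateTerm(rule="antigen-sink",
                      k_const=1.0 / COUNTS_PER_NM_PER_ML,
                      param_pows=[(f"kon.{sa.name}", 1), ("volume", -1)],
                      lin=["drug", sol])
        on.add("drug", -1.0)
        on.add(sol, -1.0)
        on.add(cx, +1.0)
        self.m.terms.append(on)
        off = RateTerm(rule="antigen-sink", param_pows=[(f"koff.{sa.name}", 1)], lin=[cx])
        off.add(cx, -1.0)
        off.add("drug", +1.0)
        off.add(sol, +1.0)
        self.m.terms.append(off)

    # formation rate prefactor: (collision * Vref/V) / (counts-per-nM at Vref)
    # / bridges-per-synapse = collision / (b * AVO * V); one direction per
    # pre-bound side, with the bridging bond's kon.
    def _formation_params(self, p: SynapsePairing, bond_receptor: str):
        ca, cb = sorted((p.cell_a, p.cell_b))
        arm = self.d.receptor(bond_receptor).drug_arm
        return [
            (f"collision.{ca}|{cb}", 1),
            (f"kon.{arm}", 1),
            ("volume", -1),
            ("bridges_per_synapse", -1),
        ]

    def _member_states(self, p: SynapsePairing, mem: str):
        """(pool species, synapse species) pairs for every receptor state of a member."""
        out = []
        for r in self.cv[mem].receptors:
            for st in (FREE, BOUND):
                out.append((r, st,
                            rec_name(r, st, pool_name(mem)),
                            rec_name(r, st, syn_name(p), mem)))
        return out

    def _terms_synapse(self):
        b = "bridges_per_synapse"
        for p in self.m.pairings:
            syn = syn_name(p)
            sides = [(p.cell_a, p.receptor_a, p.cell_b, p.receptor_b),
                     (p.cell_b, p.receptor_b, p.cell_a, p.receptor_a)]
            for pre_cell, pre_rec, new_cell, new_rec in sides:
                # formation: drug pre-bound on pre_cell:pre_rec bridges the
                # free new_rec on new_cell; rate is kon of the newly formed bond
                lin = [rec_name(pre_rec, BOUND, pool_name(pre_cell)),
                       rec_name(new_rec, FREE, pool_name(new_cell))]
                pows = self._formation_params(p, new_rec)
                ev = RateTerm(rule="synapse-formation",
                              k_const=1.0 / COUNTS_PER_NM_PER_ML,
                              param_pows=list(pows), lin=list(lin))
                ev.add(pool_name(p.cell_a), -1.0)
                ev.add(pool_name(p.cell_b), -1.0)
                ev.add(syn, +1.0)
                # b bridges sequester b pre-bound and b newly-bound receptors
                ev.add(rec_name(pre_rec, BOUND, syn, pre_cell), -1.0, b)
                ev.add(rec_name(new_rec, FREE, syn, new_cell), -1.0, b)
                self.m.terms.append(ev)
                # proportional transfer of each member's receptor states
                for mem in (p.cell_a, p.cell_b):
                    for _r, _st, at_pool, at_syn in self._member_states(p, mem):
                        tr = RateTerm(rule="synapse-formation",
                                      k_const=1.0 / COUNTS_PER_NM_PER_ML,
                                      param_pows=list(pows),
                                      lin=lin + [at_pool],
                                      inv=[pool_name(mem)])
                        tr.add(at_pool, -1.0)
                        tr.add(at_syn, +1.0)
                        self.m.terms.append(tr)
                # dissociation: the bond through new_rec breaks at its koff;
                # bridging drug stays monovalently bound on the other member
                arm = self.d.receptor(new_rec).drug_arm
                ev = RateTerm(rule="synapse-dissociation",
                              param_pows=[(f"koff.{arm}", 1)], lin=[syn])
                ev.add(syn, -1.0)
                ev.add(pool_name(p.cell_a), +1.0)
                ev.add(pool_name(p.cell_b), +1.0)
                ev.add(rec_name(pre_rec, BOUND, pool_name(pre_cell)), +1.0, b)
                ev.add(rec_name(new_rec, FREE, pool_name(new_cell)), +1.0, b)
                self.m.terms.append(ev)
                for mem in (p.cell_a, p.cell_b):
                    for _r, _st, at_pool, at_syn in self._member_states(p, mem):
                        tr = RateTerm(rule="synapse-dissociation",
                                      param_pows=[(f"koff.{arm}", 1)], lin=[at_syn])
                        tr.add(at_syn, -1.0)
                        tr.add(at_pool, +1.0)
                        self.m.terms.append(tr)

    # -- activation -----------------------------------------------------
    def _active_counterpart(self, cell: _CellView) -> Optional[str]:
        for c in self.m.cells:
            if c.lineage == cell.lineage and c.activation_state == "active":
                return c.name
        return None

    def _terms_activation(self):
        act = self.d.activation
        have = {sp.name for sp in self.m.species}
        for p in self.m.pairings:
            for mem, bridge_r, other in ((p.cell_a, p.receptor_a, p.cell_b),
                                         (p.cell_b, p.receptor_b, p.cell_a)):
                cell = self.cv[mem]
                if cell.activation_state not in ("naive", "effector-memory"):
                    continue
                if bridge_r != act.cd3_receptor:
                    continue  # must be bridged in synapse through the CD3 arm
                target = self._active_counterpart(cell)
                if target is None or target == other:
                    continue  # suppressed: product synapse would be homotypic
                p2 = SynapsePairing.make(target, bridge_r, other,
                                         p.receptor_b if mem == p.cell_a else p.receptor_a)
                if syn_name(p2) not in have:
                    continue
                naive = cell.activation_state == "naive"
                rate_p = "k_act.naive" if naive else "k_act.EM"
                gates = []
                if naive:
                    gates = [
                        Gate(rec_name(act.cd3_receptor, BOUND, syn_name(p), mem),
                             syn_name(p), "Km.CD3_bound", "bridges_per_synapse"),
                        Gate(rec_name(act.cd28_receptor, BOUND, syn_name(p), mem),
                             syn_name(p), "Km.CD28_bound", None),
                    ]
                rule = "activation-naive" if naive else "activation-EM"
                ev = RateTerm(rule=rule, param_pows=[(rate_p, 1)],
                              lin=[syn_name(p)], gates=list(gates))
                ev.add(syn_name(p), -1.0)
                ev.add(syn_name(p2), +1.0)
                self.m.terms.append(ev)
                for src in (mem, other):
                    dst = target if src == mem else other
                    for r in self.cv[src].receptors:
                        for st in (FREE, BOUND):
                            tr = RateTerm(rule=rule, param_pows=[(rate_p, 1)],
                                          lin=[rec_name(r, st, syn_name(p), src)],
                                          gates=list(gates))
                            tr.add(rec_name(r, st, syn_name(p), src), -1.0)
                            tr.add(rec_name(r, st, syn_name(p2), dst), +1.0)
                            self.m.terms.append(tr)

    # -- killing & resistance -------------------------------------------
    def _terms_killing_resistance(self):
        b = "bridges_per_synapse"
        for p in self.m.pairings:
            pairs = [(p.cell_a, p.receptor_a, p.cell_b, p.receptor_b),
                     (p.cell_b, p.receptor_b, p.cell_a, p.receptor_a)]
            for k_mem, k_rec, v_mem, v_rec in pairs:
                killer, victim = self.cv[k_mem], self.cv[v_mem]
                if not (killer.can_kill and victim.killable):
                    continue
                if victim.lineage not in ("tumor", "PBMC"):
                    continue  # T--T synapses never produce killing
                rate_key = (killer.lineage, victim.lineage)
                if rate_key in self.d.killing:
                    kk = f"k_kill.{killer.lineage}.{victim.lineage}"
                    syn = syn_name(p)
                    ev = RateTerm(rule="killing", param_pows=[(kk, 1)], lin=[syn])
                    ev.add(syn, -1.0)
                    ev.add(pool_name(k_mem), +1.0)
                    # killer's bridged receptors return free (bridge drug is
                    # cleared with the victim); victim cell, its implicit
                    # bridged receptors and the bridge drug are degraded
                    ev.add(rec_name(k_rec, FREE, pool_name(k_mem)), +1.0, b)
                    ev.flux.append((f"cells.{victim.lineage}", "deg", Coeff(1.0)))
                    ev.flux.append((f"rec.{v_rec}.{victim.lineage}", "deg", Coeff(1.0, b)))
                    ev.flux.append(("drug", "deg", Coeff(1.0, b)))
                    self.m.terms.append(ev)
                    for _r, _st, at_pool, at_syn in self._member_states(p, k_mem):
                        tr = RateTerm(rule="killing", param_pows=[(kk, 1)], lin=[at_syn])
                        tr.add(at_syn, -1.0)
                        tr.add(at_pool, +1.0)
                        self.m.terms.append(tr)
                    for r, st, _ap, at_syn in self._member_states(p, v_mem):
                        tr = RateTerm(rule="killing", param_pows=[(kk, 1)], lin=[at_syn])
                        tr.add(at_syn, -1.0)
                        tr.flux.append((f"rec.{r}.{victim.lineage}", "deg", Coeff(1.0)))
                        if st == BOUND:
                            tr.flux.append(("drug", "deg", Coeff(1.0)))
                        self.m.terms.append(tr)
                # resistance: the tumor member escapes to its resistant pool
                if (self.d.resistance_rate is not None and killer.can_kill
                        and victim.lineage == "tumor" and victim.killable):
                    res = f"{v_mem}_res"
                    if res not in self.cv:
                        continue
                    syn = syn_name(p)
                    ev = RateTerm(rule="resistance", param_pows=[("k_res", 1)], lin=[syn])
                    ev.add(syn, -1.0)
                    ev.add(pool_name(k_mem), +1.0)
                    ev.add(pool_name(res), +1.0)
                    ev.add(rec_name(k_rec, BOUND, pool_name(k_mem)), +1.0, b)
                    ev.add(rec_name(v_rec, FREE, pool_name(res)), +1.0, b)
                    self.m.terms.append(ev)
                    for _r, _st, at_pool, at_syn in self._member_states(p, k_mem):
                        tr = RateTerm(rule="resistance", param_pows=[("k_res", 1)], lin=[at_syn])
                        tr.add(at_syn, -1.0)
                        tr.add(at_pool, +1.0)
                        self.m.terms.append(tr)
                    for r, st, _ap, at_syn in self._member_states(p, v_mem):
                        tr = RateTerm(rule="resistance", param_pows=[("k_res", 1)], lin=[at_syn])
                        tr.add(at_syn, -1.0)
                        tr.add(rec_name(r, st, pool_name(res)), +1.0)
                        self.m.terms.append(tr)

    # -- lifecycle -------------------------------------------------------
    def _terms_lifecycle(self):
        for c in self.m.cells:
            pool = pool_name(c.name)
            t = RateTerm(rule="proliferation", param_pows=[(f"k_prolif.{c.name}", 1)],
                         lin=[pool])
            t.add(pool, +1.0)
            t.flux.append((f"cells.{c.lineage}", "synth", Coeff(1.0)))
            for r in c.receptors:
                t.add(rec_name(r, FREE, pool), +1.0, self.expr_param(c, r))
                t.flux.append((f"rec.{r}.{c.lineage}", "synth", Coeff(1.0, self.expr_param(c, r))))
            self.m.terms.append(t)
            t = RateTerm(rule="degradation", param_pows=[(f"k_deg.{c.name}", 1)], lin=[pool])
            t.add(pool, -1.0)
            t.flux.append((f"cells.{c.lineage}", "deg", Coeff(1.0)))
            self.m.terms.append(t)
            for r in c.receptors:
                for st in (FREE, BOUND):
                    sp = rec_name(r, st, pool)
                    tr = RateTerm(rule="degradation", param_pows=[(f"k_deg.{c.name}", 1)],
                                  lin=[sp])
                    tr.add(sp, -1.0)
                    tr.flux.append((f"rec.{r}.{c.lineage}", "deg", Coeff(1.0)))
                    if st == BOUND:
                        tr.flux.append(("drug", "deg", Coeff(1.0)))
                    self.m.terms.append(tr)

    # -- cytokines -------------------------------------------------------
    def _terms_cytokines(self):
        for cy in self.d.cytokines:
            cyt = f"cyt.{cy.name}"
            for pr in cy.producers:
                kp = f"k_cyt.{pr.cell}.{cy.name}"
                if not pr.in_synapse_only:
                    t = RateTerm(rule="cytokine-secretion", param_pows=[(kp, 1)],
                                 lin=[pool_name(pr.cell)])
                    t.add(cyt, +1.0)
                    t.flux.append((cyt, "synth", Coeff(1.0)))
                    self.m.terms.append(t)
                for p in self.m.pairings:
                    n = (p.cell_a == pr.cell) + (p.cell_b == pr.cell)
                    if n:
                        t = RateTerm(rule="cytokine-secretion", k_const=float(n),
                                     param_pows=[(kp, 1)], lin=[syn_name(p)])
                        t.add(cyt, +1.0)
                        t.flux.append((cyt, "synth", Coeff(float(n))))
                        self.m.terms.append(t)

    # -- sanity ----------------------------------------------------------
    def _check(self):
        names = {s.name for s in self.m.species}
        if len(names) != len(self.m.species):
            raise GenerationError("duplicate species names generated")
        pnames = {p.name for p in self.m.parameters}
        if len(pnames) != len(self.m.parameters):
            raise GenerationError("duplicate parameter names generated")
        lnames = {ln.name for ln in self.m.lineages}
        for t in self.m.terms:
            for s in list(t.stoich) + t.lin + t.inv:
                if s not in names:
                    raise GenerationError(f"term {t.rule} references unknown species {s}")
            for name, _pw in t.param_pows:
                if name not in pnames:
                    raise GenerationError(f"term {t.rule} references unknown parameter {name}")
            for lname, kind, _c in t.flux:
                if lname not in lnames or kind not in ("synth", "deg"):
                    raise GenerationError(f"term {t.rule} has bad flux target {lname}/{kind}")


# ---------------------------------------------------------------------------
# compiled vectorized RHS


class _Compiled:
    """Array-compiled form of the generated model for fast integration."""

    MAX_LIN = 3

    def __init__(self, model: GeneratedModel):
        self.model = model
        nt = len(model.terms)
        ns = model.n_states
        sidx = model._sidx
        pidx = model._pidx
        self.k_const = np.array([t.k_const for t in model.terms])
        tp_t, tp_p, tp_w = [], [], []
        lin = -np.ones((nt, self.MAX_LIN), dtype=np.int64)
        inv = -np.ones(nt, dtype=np.int64)
        g_num = -np.ones((nt, 2), dtype=np.int64)
        g_den = -np.ones((nt, 2), dtype=np.int64)
        g_km = -np.ones((nt, 2), dtype=np.int64)
        g_beta = -np.ones((nt, 2), dtype=np.int64)
        rows, cols, consts, cpidx = [], [], [], []
        for i, t in enumerate(model.terms):
            for name, pw in t.param_pows:
                tp_t.append(i)
                tp_p.append(pidx[name])
                tp_w.append(pw)
            if len(t.lin) > self.MAX_LIN or len(t.inv) > 1 or len(t.gates) > 2:
                raise GenerationError("term exceeds compiled factor capacity")
            for j, s in enumerate(t.lin):
                lin[i, j] = sidx[s]
            if t.inv:
                inv[i] = sidx[t.inv[0]]
            for j, g in enumerate(t.gates):
                g_num[i, j] = sidx[g.num]
                g_den[i, j] = sidx[g.den]
                g_km[i, j] = pidx[g.Km_param]
                g_beta[i, j] = pidx[g.beta_param] if g.beta_param else -1
            for sname, c in t.stoich.items():
                rows.append(sidx[sname])
                cols.append(i)
                consts.append(c.const)
                cpidx.append(pidx[c.pname] if c.pname else -1)
            for lname, kind, c in t.flux:
                rows.append(model.flux_index(lname, kind))
                cols.append(i)
                consts.append(c.const if kind == "synth" else c.const)
                cpidx.append(pidx[c.pname] if c.pname else -1)
        self.tp = (np.array(tp_t, dtype=np.int64), np.array(tp_p, dtype=np.int64),
                   np.array(tp_w, dtype=np.int64))
        self.lin, self.inv = lin, inv
        self.g_num, self.g_den, self.g_km, self.g_beta = g_num, g_den, g_km, g_beta
        self.s_rows = np.array(rows, dtype=np.int64)
        self.s_cols = np.array(cols, dtype=np.int64)
        self.s_const = np.array(consts)
        self.s_pidx = np.array(cpidx, dtype=np.int64)
        self.n_species = model.n_species
        self.n_states = ns
        self.n_terms = nt
        self._sparsity: Optional[sparse.csr_matrix] = None

    def bind(self, params: np.ndarray):
        """Resolve parameter values into a fast RHS callable."""
        params = np.asarray(params, dtype=float)
        k = self.k_const.copy()
        tt, pp, ww = self.tp
        if len(tt):
            np.multiply.at(k, tt, params[pp].astype(float) ** ww)
        data = np.where(self.s_pidx >= 0, self.s_const * params[np.maximum(self.s_pidx, 0)],
                        self.s_const)
        S = sparse.csr_matrix((data, (self.s_rows, self.s_cols)),
                              shape=(self.n_states, self.n_terms))
        km = np.where(self.g_km >= 0, params[np.maximum(self.g_km, 0)], 0.0)
        beta = np.where(self.g_beta >= 0, params[np.maximum(self.g_beta, 0)], 0.0)
        lin, inv = self.lin, self.inv
        g_num, g_den = self.g_num, self.g_den
        nsp = self.n_species

        def rhs(t, x):
            xc = np.maximum(x[:nsp], 0.0)
            r = k.copy()
            for j in range(lin.shape[1]):
                col = lin[:, j]
                mask = col >= 0
                if mask.any():
                    r[mask] *= xc[col[mask]]
            mask = inv >= 0
            if mask.any():
                r[mask] /= xc[inv[mask]] + EPS_SHARE
            for j in range(g_num.shape[1]):
                mask = g_num[:, j] >= 0
                if mask.any():
                    xn = xc[g_num[mask, j]] + beta[mask, j] * xc[g_den[mask, j]]
                    r[mask] *= xn / (km[mask, j] * (xc[g_den[mask, j]] + EPS_SHARE) + xn + EPS_SHARE)
            return S @ r

        return rhs

    def jac_sparsity(self) -> sparse.csr_matrix:
        if self._sparsity is None:
            rows, cols = [], []
            for i in range(self.n_terms):
                deps = set()
                for j in range(self.lin.shape[1]):
                    if self.lin[i, j] >= 0:
                        deps.add(int(self.lin[i, j]))
                if self.inv[i] >= 0:
                    deps.add(int(self.inv[i]))
                for j in range(2):
                    if self.g_num[i, j] >= 0:
                        deps.add(int(self.g_num[i, j]))
                        deps.add(int(self.g_den[i, j]))
                for d in deps:
                    rows.append(i)
                    cols.append(d)
            F = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                                  shape=(self.n_terms, self.n_states))
            Sp = sparse.csr_matrix(
                (np.ones(len(self.s_rows)), (self.s_rows, self.s_cols)),
                shape=(self.n_states, self.n_terms))
            self._sparsity = ((Sp @ F) != 0).astype(np.int8)
        return self._sparsity


# ---------------------------------------------------------------------------
# public helpers


def rhs_evaluate(model: GeneratedModel, state: np.ndarray, params: np.ndarray,
                 t: float = 0.0) -> np.ndarray:
    """Time derivatives of the full state (species then flux accumulators)."""
    state = np.asarray(state, dtype=float)
    params = np.asarray(params, dtype=float)
    if state.shape != (model.n_states,):
        raise ValueError(f"state must have shape ({model.n_states},), got {state.shape}")
    if params.shape != (model.n_parameters,):
        raise ValueError(f"params must have shape ({model.n_parameters},), got {params.shape}")
    return model.compiled().bind(params)(t, state)


def count_model(model: GeneratedModel) -> dict[str, int]:
    """Species and parameter counts (flux accumulators excluded)."""
    return model.count()


def initial_state(model: GeneratedModel, params: np.ndarray,
                  counts: Optional[dict[str, float]] = None,
                  dose_nM: Optional[float] = None,
                  volume_mL: Optional[float] = None) -> np.ndarray:
    """Initial condition: free pools at their initial counts, all receptors
    free at expression level, dose converted from nM to molecules, no
    synapses, no soluble antigen, no cytokines."""
    p = np.asarray(params, dtype=float)
    x = np.zeros(model.n_states)
    counts = counts or {}
    vol = volume_mL if volume_mL is not None else p[model.param_index("volume")]
    dose = dose_nM if dose_nM is not None else p[model.param_index("dose")]
    x[model.species_index("drug")] = dose * COUNTS_PER_NM_PER_ML * vol
    for c in model.cells:
        n = counts.get(c.name, p[model.param_index(f"N0.{c.name}")])
        x[model.species_index(pool_name(c.name))] = n
        for r in c.receptors:
            expr = p[model.param_index(f"R.{r}.{c.name}")]
            x[model.species_index(rec_name(r, FREE, pool_name(c.name)))] = n * expr
    return x
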