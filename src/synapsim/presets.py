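"""Reference model definitions and experiment setups.

The full in vitro model describes a CD3xCD28xCD38 trispecific T-cell engager
acting on a sample of multiple-myeloma patient peripheral blood: naive,
effector-memory and active T cells of CD4 and CD8 lineage, MM cells, and a
lumped CD38+ PBMC population (B cells, NK cells, monocytes).  T cells express
CD3 and CD28; MM cells express CD38 and CD28; PBMCs express CD38 only (CD38
on T cells is deliberately omitted - its expression is far below CD28 and
would only inflate model size).

Rate constants, expression levels and blood composition shipped here are
order-of-magnitude, literature-plausible stand-ins used as generating truth
for the synthetic datasets; binding affinities sit in the nM range typical of
engineered TCE arms, lifecycle rates give realistic doubling/death times, and
the CD38 levels of the two tumor lines are 1.29e5 (high, RPMI-8226-like) and
2.5e3 (low, KMS-11-like) copies per cell.
"""

from __future__ import annotations

from .schema import (
    ActivationSpec,
    CellTypeSpec,
    CytokineProducer,
    CytokineSpec,
    DrugArmSpec,
    ModelDefinition,
    ReceptorSpec,
    SolubleAntigenSpec,
)

CD38_HIGH = 1.29e5  # copies/cell, CD38-high tumor line
CD38_LOW = 2.5e3  # copies/cell, CD38-low tumor line

#: receptor copies per cell (stand-ins; T-cell CD3/CD28 from typical
#: cytometry quantification ranges, PBMC CD38 an order-of-magnitude value)
EXPRESSION = {
    "CD3_T": 6.0e4,
    "CD28_T": 3.0e4,
    "CD28_MM": 1.0e4,
    "CD38_PBMC": 1.0e4,
}

#: default composition of the dose-prediction context, cells per mL of
#: MM-patient peripheral blood (elevated circulating tumor burden)
BLOOD_PER_ML = {
    "CD4_naive": 4.0e5,
    "CD4_EM": 3.5e5,
    "CD4_active": 5.0e4,
    "CD8_naive": 2.0e5,
    "CD8_EM": 1.8e5,
    "CD8_active": 2.0e4,
    "MM": 5.0e4,
    "PBMC": 6.0e5,
}

DEFAULT_VOLUME_ML = 0.2

#: lifecycle rates, per hour
_LIFECYCLE = {
    # (proliferation, degradation)
    "naive": (0.001, 0.002),
    "effector-memory": (0.002, 0.002),
    "active": (0.03, 0.01),
    "tumor": (0.02, 0.005),
    "PBMC": (0.0, 0.01),
}


def _t_cells(lineage: str, counts: dict[str, float],
             states: tuple[str, ...] = ("naive", "effector-memory", "active")
             ) -> list[CellTypeSpec]:
    tag = lineage.split("-")[0]
    out = []
    for state, suffix in (("naive", "naive"), ("effector-memory", "EM"), ("active", "active")):
        if state not in states:
            continue
        kp, kd = _LIFECYCLE[state]
        out.append(
            CellTypeSpec(
                name=f"{tag}_{suffix}",
                lineage=lineage,
                activation_state=state,
                receptors=["CD3", "CD28"],
                proliferation_rate=kp,
                degradation_rate=kd,
                can_kill=(state == "active"),
                killable=False,
                initial_count=counts.get(f"{tag}_{suffix}", 0.0),
            )
        )
    return out


def trispecific_definition(
    cd38_per_cell: float = CD38_HIGH,
    volume_mL: float = DEFAULT_VOLUME_ML,
    counts: dict[str, float] | None = None,
    include_cytokines: bool = True,
    include_soluble_antigen: bool = True,
    t_subsets: tuple[str, ...] = ("CD4-T", "CD8-T"),
    t_states: tuple[str, ...] = ("naive", "effector-memory", "active"),
    include_tumor: bool = True,
    include_pbmc: bool = True,
) -> ModelDefinition:
    """The full 8-cell trispecific in vitro model (or a reduced variant).

    ``counts`` gives initial cells per pool (absolute counts in ``volume_mL``);
    by default the MM-patient blood composition is scaled to the volume.
    """
    if counts is None:
        counts = {k: v * volume_mL for k, v in BLOOD_PER_ML.items()}
    cells: list[CellTypeSpec] = []
    for lin in t_subsets:
        cells += _t_cells(lin, counts, t_states)
    if include_tumor:
        kp, kd = _LIFECYCLE["tumor"]
        cells.append(
            CellTypeSpec(
                name="MM", lineage="tumor", receptors=["CD38", "CD28"],
                proliferation_rate=kp, degradation_rate=kd,
                killable=True, initial_count=counts.get("MM", 0.0),
            )
        )
    if include_pbmc:
        kp, kd = _LIFECYCLE["PBMC"]
        cells.append(
            CellTypeSpec(
                name="PBMC", lineage="PBMC", receptors=["CD38"],
                proliferation_rate=kp, degradation_rate=kd,
                killable=True, initial_count=counts.get("PBMC", 0.0),
            )
        )
    t_names = [c.name for c in cells if c.lineage.endswith("-T")]
    receptors = [
        ReceptorSpec("CD3", {n: EXPRESSION["CD3_T"] for n in t_names}, "CD3"),
        ReceptorSpec(
            "CD28",
            {**{n: EXPRESSION["CD28_T"] for n in t_names},
             **({"MM": EXPRESSION["CD28_MM"]} if include_tumor else {})},
            "CD28",
        ),
        ReceptorSpec(
            "CD38",
            {**({"MM": cd38_per_cell} if include_tumor else {}),
             **({"PBMC": EXPRESSION["CD38_PBMC"]} if include_pbmc else {})},
            "CD38",
        ),
    ]
    receptors = [r for r in receptors if r.expressed_on]
    arms = [
        DrugArmSpec("CD3", kon=0.2, KD=1.0),
        DrugArmSpec("CD28", kon=0.1, KD=5.0),
        DrugArmSpec("CD38", kon=0.5, KD=0.3),
    ]
    used_arms = {r.drug_arm for r in receptors}
    arms = [a for a in arms if a.name in used_arms]

    cytokines: list[CytokineSpec] = []
    if include_cytokines:
        active = [c.name for c in cells if c.activation_state == "active"]
        for name, rate in (("TNFa", 2.0e3), ("IFNg", 4.0e3), ("IL6", 1.0e3)):
            cytokines.append(
                CytokineSpec(name, [CytokineProducer(c, rate) for c in active])
            )
        if include_pbmc:
            # PBMCs secrete IL-6 and IL-10 only while engaged in synapse
            for cy in cytokines:
                if cy.name == "IL6":
                    cy.producers.append(CytokineProducer("PBMC", 8.0e2, in_synapse_only=True))
            cytokines.append(
                CytokineSpec("IL10", [CytokineProducer("PBMC", 5.0e2, in_synapse_only=True)])
            )

    soluble = None
    if include_soluble_antigen and include_tumor:
        soluble = SolubleAntigenSpec(
            name="sCD38", shedding_sources=["MM"], shedding_rate=50.0,
            kon=0.1, KD=10.0,
        )

    killing = {}
    killers = {c.lineage for c in cells if c.can_kill}
    # CD8 killers are more efficient than CD4 (enforced as calibration bound)
    rates = {("CD8-T", "tumor"): 0.4, ("CD4-T", "tumor"): 0.1,
             ("CD8-T", "PBMC"): 0.15, ("CD4-T", "PBMC"): 0.04}
    for (kl, vl), rate in rates.items():
        if kl in killers and ((vl == "tumor" and include_tumor) or (vl == "PBMC" and include_pbmc)):
            killing[(kl, vl)] = rate

    has_naive = any(c.activation_state == "naive" for c in cells)
    has_em = any(c.activation_state == "effector-memory" for c in cells)
    activation = ActivationSpec(
        k_act_EM=0.2 if has_em else 0.0,
        k_act_naive=0.3 if has_naive else 0.0,
        Km_CD3_bound=500.0,
        Km_CD28_bound=200.0,
    )

    defn = ModelDefinition(
        name="trispecific-invitro",
        cells=cells,
        receptors=receptors,
        arms=arms,
        cytokines=cytokines,
        soluble_antigen=soluble,
        activation=activation,
        killing=killing,
        resistance_rate=0.05 if include_tumor else None,
        collision_factor=2.0e-3,
        bridges_per_synapse=5.0,
        volume=volume_mL,
        reference_volume=DEFAULT_VOLUME_ML,
    )
    return defn.validate()


def minimal_definition() -> ModelDefinition:
    """Two-cell binding/synapse model used as the structural oracle case:
    one T pool carrying CD3, one tumor pool carrying CD38, two arms, one
    pairing; no cytokines, soluble antigen, activation, killing or escape."""
    cells = [
        CellTypeSpec("T", "CD8-T", "not-applicable", ["CD3"],
                     proliferation_rate=0.01, degradation_rate=0.005,
                     initial_count=1.0e5),
        CellTypeSpec("MM", "tumor", "not-applicable", ["CD38"],
                     proliferation_rate=0.02, degradation_rate=0.005,
                     killable=False, initial_count=1.0e4),
    ]
    receptors = [
        ReceptorSpec("CD3", {"T": 6.0e4}, "CD3"),
        ReceptorSpec("CD38", {"MM": 1.29e5}, "CD38"),
    ]
    arms = [DrugArmSpec("CD3", kon=0.2, KD=1.0), DrugArmSpec("CD38", kon=0.5, KD=0.3)]
    return ModelDefinition(
        name="minimal-two-cell",
        cells=cells, receptors=receptors, arms=arms,
        collision_factor=2.0e-3, bridges_per_synapse=5.0,
        volume=0.2, reference_volume=0.2,
    ).validate()


# -- calibration-stage model variants ---------------------------------------


def activation_stage_definition(t_subsets=("CD4-T", "CD8-T"),
                                total_pbmc: float = 2.0e5) -> ModelDefinition:
    """PBMC-incubation model used to train T-cell activation: T subsets plus
    CD38+ PBMCs, no tumor cells (so no meaningful killing takes place)."""
    frac_t = 0.6  # T cells among PBMCs
    t_per_lineage = {"CD4-T": 2 / 3, "CD8-T": 1 / 3}
    t_state_split = {"naive": 0.5, "EM": 0.45, "active": 0.05}
    counts = {"PBMC": total_pbmc * (1 - frac_t)}
    for lin in t_subsets:
        tag = lin.split("-")[0]
        lin_total = total_pbmc * frac_t * t_per_lineage[lin] * (
            len(t_subsets) / sum(t_per_lineage[l] for l in t_subsets) / len(t_subsets)
        )
        lin_total = total_pbmc * frac_t * t_per_lineage[lin] / sum(
            t_per_lineage[l] for l in t_subsets
        )
        for state, frac in t_state_split.items():
            counts[f"{tag}_{state}"] = lin_total * frac
    return trispecific_definition(
        counts=counts, include_tumor=False, include_soluble_antigen=False,
        t_subsets=tuple(t_subsets),
    )


def cytotoxicity_stage_definition(cd38_per_cell: float = CD38_HIGH,
                                  n_effector: float = 5.0e4,
                                  n_tumor: float = 1.0e4) -> ModelDefinition:
    """Pre-activated CD8 T cells incubated with a tumor line: the species and
    parameters involved are deliberately minimal so killing and resistance
    are well informed by the cytotoxicity data."""
    counts = {"CD8_active": n_effector, "MM": n_tumor}
    return trispecific_definition(
        cd38_per_cell=cd38_per_cell, counts=counts, include_pbmc=False,
        include_cytokines=False, t_subsets=("CD8-T",), t_states=("active",),
    )


def proliferation_definition(total_t: float = 1.0e5) -> ModelDefinition:
    """Sorted-T-cell 6-day proliferation qualification setup."""
    split = {"CD4_naive": 0.33, "CD4_EM": 0.30, "CD4_active": 0.04,
             "CD8_naive": 0.17, "CD8_EM": 0.14, "CD8_active": 0.02}
    counts = {k: total_t * v for k, v in split.items()}
    return trispecific_definition(
        counts=counts, include_tumor=False, include_pbmc=False,
        include_soluble_antigen=False,
    )


def qualification_definition(cd38_per_cell: float = CD38_HIGH,
                             n_pbmc: float = 2.0e5,
                             n_tumor: float = 2.0e4) -> ModelDefinition:
    """24-h cytotoxicity qualification: PBMC pool with tumor at 10:1 E:T."""
    frac_t = 0.6
    split = {"CD4_naive": 0.22, "CD4_EM": 0.20, "CD4_active": 0.025,
             "CD8_naive": 0.11, "CD8_EM": 0.10, "CD8_active": 0.012}
    total = sum(split.values())
    counts = {k: n_pbmc * frac_t * v / total for k, v in split.items()}
    counts["PBMC"] = n_pbmc * (1 - frac_t)
    counts["MM"] = n_tumor
    return trispecific_definition(cd38_per_cell=cd38_per_cell, counts=counts)


def reduced_blood_definition(volume_mL: float = DEFAULT_VOLUME_ML) -> ModelDefinition:
    """CD8-only blood-composition model: same structure class as the full
    dose-prediction model at roughly a fifth of the species count; used where
    a population of simulations is required at desk runtime."""
    counts = {k: v * volume_mL for k, v in BLOOD_PER_ML.items() if not k.startswith("CD4")}
    return trispecific_definition(
        counts=counts, t_subsets=("CD8-T",), volume_mL=volume_mL,
        include_cytokines=False,
    )
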