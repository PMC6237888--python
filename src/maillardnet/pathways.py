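"""Reconstruction of the general Maillard reaction scheme.

Maillard products formed from different amino acids often differ only in
the amino-acid side chain R. Stripping R maps each system's formulas into a
shared *core composition* space (the 1:1 ribose-glycine Amadori product
C7H13NO6, for instance, has core C7H12NO6). Cores observed with sufficient
signal in most model systems, and reachable from a pathway root through
dehydration, redox (+-H2) or carbonyl-cleavage steps, constitute the
general scheme: (a) Amadori product (ARP) formation/degradation, (b)
diketosamine degradation after addition of a second sugar, and (c, d) C2-
and C3-cleavage branches of the diketosamine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chemcore import (
    AA_BACKBONE,
    CompositionDelta,
    CompositionError,
    ElementalComposition,
    side_chain,
    try_apply_delta,
)

__all__ = [
    "AminoAcidSpec",
    "TransformationEdge",
    "SchemeNode",
    "AMINO_ACIDS",
    "SUGARS",
    "SCHEME_DELTAS",
    "core_of",
    "pathway_roots",
    "build_transformation_network",
    "dehydration_series",
    "redox_partners",
    "detect_general_scheme",
    "scheme_intensity_share",
]

DEHYDRATION = CompositionDelta(h=-2, o=-1)
OXIDATION = CompositionDelta(h=-2)
REDUCTION = CompositionDelta(h=2)
C2_BYPRODUCT = CompositionDelta(c=-2, h=-4, o=-2)   # loss of C2H4O2
C3_BYPRODUCT = CompositionDelta(c=-3, h=-6, o=-3)   # loss of C3H6O3
C3_BYPRODUCT_ALT = CompositionDelta(c=-3, h=-4, o=-2)  # C3H4O2 alternative

#: Named deltas of the reaction scheme (dehydration backbone plus redox and
#: cleavage steps, and pentose addition towards the diketosamine).
SCHEME_DELTAS: dict[str, CompositionDelta] = {
    "dehydration": DEHYDRATION,
    "oxidation": OXIDATION,
    "reduction": REDUCTION,
    "pentose_addition": CompositionDelta(c=5, h=8, o=4),
    "C2_cleavage": C2_BYPRODUCT,
    "C3_cleavage": C3_BYPRODUCT,
    "decarboxylation": CompositionDelta(c=-1, o=-2),
}


@dataclass(frozen=True)
class AminoAcidSpec:
    """An alpha-amino acid: full composition and side chain R."""

    name: str
    composition: ElementalComposition

    @property
    def side_chain(self) -> ElementalComposition:
        return side_chain(self.composition)

    @classmethod
    def from_formula(cls, name: str, formula: str) -> "AminoAcidSpec":
        return cls(name=name, composition=ElementalComposition.parse(formula))


AMINO_ACIDS: dict[str, AminoAcidSpec] = {
    name: AminoAcidSpec.from_formula(name, formula)
    for name, formula in {
        "glycine": "C2H5NO2",
        "alanine": "C3H7NO2",
        "serine": "C3H7NO3",
        "cysteine": "C3H7NO2S",
        "isoleucine": "C6H13NO2",
        "leucine": "C6H13NO2",
        "lysine": "C6H14N2O2",
    }.items()
}

SUGARS: dict[str, ElementalComposition] = {
    name: ElementalComposition.parse(formula)
    for name, formula in {
        "ribose": "C5H10O5",
        "arabinose": "C5H10O5",
        "xylose": "C5H10O5",
        "glucose": "C6H12O6",
        "fructose": "C6H12O6",
        "galactose": "C6H12O6",
    }.items()
}


@dataclass(frozen=True)
class TransformationEdge:
    source: ElementalComposition
    target: ElementalComposition
    delta_name: str


@dataclass
class SchemeNode:
    """One core composition of the general scheme."""

    core: ElementalComposition
    pathway: str              # ARP_DEGRADATION | DIKETOSAMINE | C2_CLEAVAGE | C3_CLEAVAGE
    step: int                 # dehydrations from the pathway root
    redox: int                # hydrogens relative to the backbone: 0, +2, -2
    present_in: dict[str, bool] = field(default_factory=dict)
    intensity_share: dict[str, float] = field(default_factory=dict)

    @property
    def n_systems(self) -> int:
        return sum(self.present_in.values())


def core_of(
    formula: ElementalComposition, amino_acid: AminoAcidSpec
) -> ElementalComposition:
    """Strip the amino-acid side chain R to get the core composition.

    Raises :class:`CompositionError` when the formula cannot carry this
    residue (subtraction would go negative).
    """
    r = amino_acid.side_chain
    try:
        return formula - r
    except CompositionError as exc:
        raise CompositionError(
            f"{formula.hill()} cannot carry the {amino_acid.name} side "
            f"chain {r.hill()}"
        ) from exc


def pathway_roots(
    sugar: ElementalComposition,
    amino_acid: AminoAcidSpec,
    c3_delta: CompositionDelta = C3_BYPRODUCT,
) -> dict[str, ElementalComposition]:
    """Root formulas of the four scheme branches for one model system.

    ARP = sugar + amino acid - H2O (1:1 condensation); the diketosamine
    adds a second sugar molecule; the cleavage roots lose a C2H4O2 or C3
    by-product from the diketosamine.
    """
    water = ElementalComposition(h=2, o=1)
    arp = sugar + amino_acid.composition - water
    diketosamine = arp + sugar - water
    return {
        "ARP": arp,
        "diketosamine": diketosamine,
        "C2_root": try_apply_delta(diketosamine, C2_BYPRODUCT),
        "C3_root": try_apply_delta(diketosamine, c3_delta),
    }


def build_transformation_network(
    formulas: Iterable[ElementalComposition],
    deltas: Mapping[str, CompositionDelta] = SCHEME_DELTAS,
) -> list[TransformationEdge]:
    """All ordered formula pairs related by one named delta; no self-edges."""
    formula_set = set(formulas)
    edges = []
    for source in sorted(formula_set):
        for name, delta in deltas.items():
            target = try_apply_delta(source, delta)
            if target is not None and target != source and target in formula_set:
                edges.append(TransformationEdge(source, target, name))
    return edges


def dehydration_series(
    formulas: Iterable[ElementalComposition],
    root: ElementalComposition,
    max_steps: int = 3,
) -> list[ElementalComposition]:
    """Maximal uninterrupted chain root, root-H2O, ... (no gap skipping)."""
    formula_set = set(formulas)
    if root not in formula_set:
        return []
    chain = [root]
    current = root
    for _ in range(max_steps):
        nxt = try_apply_delta(current, DEHYDRATION)
        if nxt is None or nxt not in formula_set:
            break
        chain.append(nxt)
        current = nxt
    return chain


def redox_partners(
    formulas: Iterable[ElementalComposition],
    formula: ElementalComposition,
) -> dict[str, ElementalComposition | None]:
    """Presence-checked oxidized (-H2) and reduced (+H2) neighbours."""
    formula_set = set(formulas)
    ox = try_apply_delta(formula, OXIDATION)
    red = try_apply_delta(formula, REDUCTION)
    return {
        "oxidized": ox if ox in formula_set else None,
        "reduced": red if red in formula_set else None,
    }


#: Default dehydration depths per branch: three ARP dehydration products,
#: six for the diketosamine; the cleavage branches inherit the diketosamine
#: depth.
DEFAULT_MAX_STEPS = {
    "ARP_DEGRADATION": 3,
    "DIKETOSAMINE": 6,
    "C2_CLEAVAGE": 6,
    "C3_CLEAVAGE": 6,
}

_BRANCH_ROOT_KEY = {
    "ARP_DEGRADATION": "ARP",
    "DIKETOSAMINE": "diketosamine",
    "C2_CLEAVAGE": "C2_root",
    "C3_CLEAVAGE": "C3_root",
}


def _system_cores(
    classified: pd.DataFrame,
    amino_acid: AminoAcidSpec,
    min_snr: float,
) -> dict[ElementalComposition, float]:
    """Map MRP formulas (S/N >= min_snr) of one system to core intensities."""
    mrps = classified[classified["product_class"] == "MRP"]
    mrps = mrps[mrps["snr"] >= min_snr]
    cores: dict[ElementalComposition, float] = {}
    for _, row in mrps.iterrows():
        formula = ElementalComposition.parse(row["formula"])
        try:
            core = core_of(formula, amino_acid)
        except CompositionError:
            continue
        cores[core] = cores.get(core, 0.0) + float(row["intensity"])
    return cores


def detect_general_scheme(
    classified_tables: Mapping[str, pd.DataFrame],
    amino_acids: Mapping[str, AminoAcidSpec],
    sugar: ElementalComposition,
    min_systems: int = 3,
    min_snr: float = 8.0,
    max_steps: Mapping[str, int] = DEFAULT_MAX_STEPS,
    c3_delta: CompositionDelta = C3_BYPRODUCT,
) -> tuple[list[SchemeNode], list[ElementalComposition]]:
    """Detect the general scheme across model systems.

    ``classified_tables`` maps a system name to its classified consensus
    table; ``amino_acids`` maps the same names to their amino-acid specs.
    A core is accepted when it is observed (as an MRP with S/N >= min_snr)
    in at least ``min_systems`` systems AND lies on a dehydration/redox
    series rooted at one of the four pathway roots. Returns the accepted
    nodes plus the cores that met the presence threshold but are not
    reachable from any root (reported separately, never silently dropped).
    """
    systems = sorted(classified_tables)
    if len(systems) < min_systems:
        raise ValueError(
            f"need at least {min_systems} systems, got {len(systems)}"
        )
    per_system = {
        name: _system_cores(classified_tables[name], amino_acids[name], min_snr)
        for name in systems
    }
    totals = {
        name: classified_tables[name].loc[
            classified_tables[name]["product_class"] == "MRP", "intensity"
        ].sum()
        for name in systems
    }
    presence: dict[ElementalComposition, set[str]] = {}
    for name, cores in per_system.items():
        for core in cores:
            presence.setdefault(core, set()).add(name)
    candidates = {
        core for core, names in presence.items() if len(names) >= min_systems
    }

    # branch roots in core space (amino-acid independent: R is stripped);
    # the bare backbone acts as a pseudo-amino-acid with an empty side chain
    backbone_aa = AminoAcidSpec("backbone", AA_BACKBONE)
    root_cores = pathway_roots(sugar, backbone_aa, c3_delta=c3_delta)

    nodes: dict[tuple, SchemeNode] = {}
    explained: set[ElementalComposition] = set()

    def add_node(core: ElementalComposition, pathway: str, step: int,
                 redox: int) -> None:
        key = (core, pathway, step, redox)
        if key in nodes:
            return
        node = SchemeNode(core=core, pathway=pathway, step=step, redox=redox)
        for name in systems:
            node.present_in[name] = core in per_system[name]
            total = totals[name]
            node.intensity_share[name] = (
                float(per_system[name].get(core, 0.0) / total)
                if total > 0 else 0.0
            )
        nodes[key] = node
        explained.add(core)

    for pathway, root_key in _BRANCH_ROOT_KEY.items():
        root = root_cores[root_key]
        if root is None:
            continue
        chain = dehydration_series(
            candidates, root, max_steps=max_steps[pathway]
        )
        for step, backbone_core in enumerate(chain):
            add_node(backbone_core, pathway, step, redox=0)
            partners = redox_partners(candidates, backbone_core)
            if partners["oxidized"] is not None:
                add_node(partners["oxidized"], pathway, step, redox=-2)
            if partners["reduced"] is not None:
                add_node(partners["reduced"], pathway, step, redox=+2)

    unexplained = sorted(candidates - explained)
    ordered = sorted(
        nodes.values(), key=lambda n: (n.pathway, n.step, n.redox)
    )
    return ordered, unexplained


def scheme_intensity_share(
    nodes: Sequence[SchemeNode],
    classified: pd.DataFrame,
    amino_acid: AminoAcidSpec,
    min_snr: float = 0.0,
) -> float:
    """Fraction of a system's total MRP intensity explained by the scheme."""
    mrps = classified[classified["product_class"] == "MRP"]
    total = mrps["intensity"].sum()
    if total == 0 or not len(nodes):
        return 0.0
    scheme_cores = {n.core for n in nodes}
    explained = 0.0
    for _, row in mrps.iterrows():
        if row["snr"] < min_snr:
            continue
        formula = ElementalComposition.parse(row["formula"])
        try:
            core = core_of(formula, amino_acid)
        except CompositionError:
            continue
        if core in scheme_cores:
            explained += float(row["intensity"])
    return float(explained / total)
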