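"""Ground-truth Maillard reaction networks and simulated ESI(-) peak lists.

The generator plants the four-branch reaction scheme (Amadori product
formation and degradation, diketosamine degradation, C2- and C3-cleavage)
with redox side products, expands it stochastically with generic Maillard
transformation chemistry, and adds independent sugar-only and
amino-acid-only degradation branches so blank spectra can be simulated.
Peak lists then emulate a direct-infusion FT-ICR measurement: [M-H]- ions
in m/z 100-600, Gaussian ppm mass error, about four decades of dynamic
range, optional 13C1/34S1 isotopologue peaks, formula-free noise peaks,
replicate intensity scatter and dropouts.

Every simulated spectrum is backed by a truth table, so recovery, product
classification and scheme detection can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assignment import (
    ElementBounds,
    Peak,
    PeakList,
    enumerate_candidates,
    chemical_filter,
)
from .chemcore import (
    CompositionDelta,
    ElementalComposition,
    PROTON_MASS,
    isotope_fine_structure,
    monoisotopic_mass,
    try_apply_delta,
)
from .classification import ProductClass
from .pathways import (
    AMINO_ACIDS,
    AminoAcidSpec,
    C3_BYPRODUCT,
    DEFAULT_MAX_STEPS,
    OXIDATION,
    REDUCTION,
    SUGARS,
    pathway_roots,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "generate_reaction_network",
    "simulate_peaklist",
    "simulate_blanks",
    "write_truth_table",
    "read_truth_table",
    "truth_to_table",
]

WATER = CompositionDelta(h=-2, o=-1)

# generic expansion chemistry applied on top of the planted scheme
EXPANSION_DELTAS: dict[str, CompositionDelta] = {
    "dehydration": WATER,
    "oxidation": OXIDATION,
    "reduction": REDUCTION,
    "oxygenation": CompositionDelta(o=1),
    "decarboxylation": CompositionDelta(c=-1, o=-2),
    "retro_aldol": CompositionDelta(c=-1, h=-2, o=-1),
    "C2_cleavage": CompositionDelta(c=-2, h=-4, o=-2),
    "C3_cleavage": C3_BYPRODUCT,
}

SUGAR_DEG_DELTAS: dict[str, CompositionDelta] = {
    "dehydration": WATER,
    "retro_aldol": CompositionDelta(c=-1, h=-2, o=-1),
    "C2_cleavage": CompositionDelta(c=-2, h=-4, o=-2),
    "oxidation": OXIDATION,
}

AA_DEG_DELTAS: dict[str, CompositionDelta] = {
    "decarboxylation": CompositionDelta(c=-1, o=-2),
    "dehydration": WATER,
    "oxidation": OXIDATION,
    "deamination": CompositionDelta(h=-3, n=-1),
}


@dataclass
class SimulationConfig:
    """Stated world of the simulated study.

    Defaults mirror the experimental design being emulated: ribose with
    four amino acids, heated 2/4/6/10 h, measured in triplicate, [M-H]-
    ions in m/z 100-600 spanning roughly four orders of magnitude in
    intensity at sub-0.2-ppm mass accuracy.
    """

    sugar: str = "ribose"
    amino_acids: tuple[str, ...] = (
        "glycine", "isoleucine", "lysine", "cysteine"
    )
    time_points_h: tuple[float, ...] = (2.0, 4.0, 6.0, 10.0)
    replicates: int = 3
    # network growth
    generations: int = 2
    delta_probability: float = 0.18     # per delta, per formula, per generation
    delta_probabilities: dict[str, float] | None = None  # per-delta override
    redox_probability: float = 0.8      # chance a backbone node has each +-H2 partner
    max_formulas_per_system: int = 160
    cleavage_depth: int = 4             # dehydrations planted after C2/C3 cleavage
    plant_scheme: bool = True           # plant the four-branch scheme
    degradation_branches: bool = True   # sugar-only / AA-only blank branches
    # intensity model: base / noise_floor spans 4 decades
    base_intensity: float = 1.0e8
    depth_decay: float = 0.45           # geometric attenuation per pathway step
    time_growth: float = 1.8            # deeper products gain weight over time
    intensity_sigma: float = 0.35       # per-formula static log-normal scatter (ln)
    replicate_sigma: float = 0.15       # per-replicate log-normal scatter (ln)
    noise_floor: float = 1.0e4          # S/N reference level
    min_truth_snr: float = 8.0          # planted products stay detectable
    # measurement model
    mass_error_ppm_sd: float = 0.1
    isotopologues: bool = True
    noise_peaks: int = 40
    mz_range: tuple[float, float] = (100.0, 600.0)
    dropout_probability: float = 0.0
    resolution_floor_mda: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.delta_probability <= 1
                and 0 <= self.redox_probability <= 1
                and 0 <= self.dropout_probability <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mass_error_ppm_sd < 0:
            raise ValueError("mass-error sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def sugar_composition(self) -> ElementalComposition:
        return SUGARS[self.sugar]

    def amino_acid_spec(self, name: str) -> AminoAcidSpec:
        return AMINO_ACIDS[name]


@dataclass
class TruthRecord:
    """One planted formula with its provenance and emission bookkeeping."""

    formula: ElementalComposition
    product_class: ProductClass
    pathway: str | None          # scheme branch label, or None
    step: int                    # pathway depth (0 for precursors/roots)
    redox: int                   # 0 / +2 / -2 hydrogens vs backbone
    intensity: float             # per-formula base intensity
    appears_at_index: int        # first time-point index at which it exists
    emitted_mz: dict[tuple[int, int], float] = field(default_factory=dict)
    # key: (time index, replicate) -> measured m/z actually emitted


def _mz_of(formula: ElementalComposition) -> float:
    return monoisotopic_mass(formula) - PROTON_MASS


def _in_range(formula: ElementalComposition, cfg: SimulationConfig) -> bool:
    lo, hi = cfg.mz_range
    return lo <= _mz_of(formula) <= hi


def _intensity(cfg: SimulationConfig, step: int, rng: np.random.Generator) -> float:
    value = (
        cfg.base_intensity
        * cfg.depth_decay**step
        * rng.lognormal(0.0, cfg.intensity_sigma)
    )
    # a planted product is by definition detectable: censor the intensity
    # model at the instrument's detection window instead of planting
    # formulas no measurement could recover
    return float(max(value, cfg.min_truth_snr * cfg.noise_floor))


def generate_reaction_network(
    config: SimulationConfig, amino_acid: str
) -> list[TruthRecord]:
    """Plant the ground-truth reaction network of one model system.

    Deterministic given (config.seed, amino acid): precursors, the
    four-branch scheme with stochastic redox partners, a stochastic
    expansion of generic Maillard chemistry, and sugar-only / amino-acid-
    only degradation branches for the blanks. All formulas are chemically
    plausible and yield [M-H]- ions inside the configured m/z window
    (precursors are exempt from the window so the blanks always carry their
    precursor).
    """
    aa = config.amino_acid_spec(amino_acid)
    sugar = config.sugar_composition
    aa_index = config.amino_acids.index(amino_acid) if amino_acid in config.amino_acids else 99
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed % (2**31), 101, aa_index])
    )
    records: list[TruthRecord] = []
    known: set[ElementalComposition] = set()
    n_times = len(config.time_points_h)

    def appears(step: int) -> int:
        return min(step, n_times - 1)

    def add(formula: ElementalComposition, cls: ProductClass,
            pathway: str | None, step: int, redox: int = 0,
            base: float | None = None) -> bool:
        if formula in known:
            return False
        if cls is not ProductClass.PRECURSOR:
            if not chemical_filter(formula) or not _in_range(formula, config):
                return False
        known.add(formula)
        records.append(
            TruthRecord(
                formula=formula,
                product_class=cls,
                pathway=pathway,
                step=step,
                redox=redox,
                intensity=base if base is not None
                else _intensity(config, step, rng),
                appears_at_index=appears(step),
            )
        )
        return True

    # precursors
    add(sugar, ProductClass.PRECURSOR, None, 0, base=config.base_intensity)
    add(aa.composition, ProductClass.PRECURSOR, None, 0,
        base=config.base_intensity)

    # the ARP (1:1 condensation) always forms; further branches optional
    roots = pathway_roots(sugar, aa)
    if not config.plant_scheme:
        add(roots["ARP"], ProductClass.MRP, "ARP_DEGRADATION", 0, redox=0)

    # planted scheme: backbone chains plus stochastic redox partners
    branch_depths = dict(DEFAULT_MAX_STEPS)
    branch_depths["C2_CLEAVAGE"] = config.cleavage_depth
    branch_depths["C3_CLEAVAGE"] = config.cleavage_depth
    branch_roots = {
        "ARP_DEGRADATION": roots["ARP"],
        "DIKETOSAMINE": roots["diketosamine"],
        "C2_CLEAVAGE": roots["C2_root"],
        "C3_CLEAVAGE": roots["C3_root"],
    }
    # cleavage/diketosamine roots start deeper than the ARP: step offsets
    # reflect how many reaction events separate them from the precursors
    branch_offset = {
        "ARP_DEGRADATION": 0,
        "DIKETOSAMINE": 1,
        "C2_CLEAVAGE": 2,
        "C3_CLEAVAGE": 2,
    }
    for pathway in (
        ("ARP_DEGRADATION", "DIKETOSAMINE", "C2_CLEAVAGE", "C3_CLEAVAGE")
        if config.plant_scheme else ()
    ):
        current = branch_roots[pathway]
        if current is None:
            continue
        offset = branch_offset[pathway]
        for step in range(branch_depths[pathway] + 1):
            ok = add(current, ProductClass.MRP, pathway, step + offset,
                     redox=0)
            if step == 0 and not ok and current not in known:
                break  # root itself invalid; skip branch
            for redox, delta in ((-2, OXIDATION), (+2, REDUCTION)):
                if rng.random() < config.redox_probability:
                    partner = try_apply_delta(current, delta)
                    if partner is not None:
                        add(partner, ProductClass.MRP, pathway,
                            step + offset, redox=redox)
            nxt = try_apply_delta(current, WATER)
            if nxt is None:
                break
            current = nxt

    # sugar-only degradation branch (BFS, depth 2)
    frontier = [(sugar, 0)] if config.degradation_branches else []
    for _ in range(2):
        nxt_frontier = []
        for formula, depth in frontier:
            for name in sorted(SUGAR_DEG_DELTAS):
                product = try_apply_delta(formula, SUGAR_DEG_DELTAS[name])
                if product is not None and product.n == 0:
                    if add(product, ProductClass.SUGAR_DEG, None, depth + 1):
                        nxt_frontier.append((product, depth + 1))
        frontier = nxt_frontier

    # amino-acid-only degradation branch (BFS, depth 2)
    frontier = [(aa.composition, 0)] if config.degradation_branches else []
    for _ in range(2):
        nxt_frontier = []
        for formula, depth in frontier:
            for name in sorted(AA_DEG_DELTAS):
                product = try_apply_delta(formula, AA_DEG_DELTAS[name])
                if product is not None:
                    if add(product, ProductClass.AA_DEG, None, depth + 1):
                        nxt_frontier.append((product, depth + 1))
        frontier = nxt_frontier

    # stochastic expansion of generic Maillard chemistry around the scheme
    mrp_pool = [
        (r.formula, r.step) for r in records
        if r.product_class is ProductClass.MRP
    ]
    for _ in range(config.generations):
        new_pool = []
        for formula, step in mrp_pool:
            for name in sorted(EXPANSION_DELTAS):
                if len(records) >= config.max_formulas_per_system:
                    break
                if config.delta_probabilities is not None:
                    p = config.delta_probabilities.get(name, 0.0)
                else:
                    p = config.delta_probability
                if p < 1.0 and rng.random() >= p:
                    continue
                product = try_apply_delta(formula, EXPANSION_DELTAS[name])
                if product is None or product.n == 0:
                    continue  # MRPs keep their nitrogen; CHO stays blank-only
                if add(product, ProductClass.MRP, None, step + 1):
                    new_pool.append((product, step + 1))
        mrp_pool = new_pool
        if not new_pool:
            break
    return records


def _replicate_rng(
    config: SimulationConfig, sample_key: int, time_index: int, replicate: int
) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [config.seed % (2**31), 211, sample_key, time_index, replicate]
        )
    )


def _time_weight(cfg: SimulationConfig, step: int, time_index: int) -> float:
    n = max(len(cfg.time_points_h) - 1, 1)
    return cfg.time_growth ** (step * time_index / n)


def simulate_peaklist(
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    replicate: int,
    time_index: int | None = None,
    sample_id: str = "sample",
    system: str = "mixture",
    is_blank: bool = False,
    sugar: str | None = None,
    amino_acid: str | None = None,
    sample_key: int = 0,
) -> PeakList:
    """Simulate one replicate measurement of a truth network.

    Emits one [M-H]- peak per visible truth record with Gaussian ppm mass
    error and log-normal replicate scatter, optional 13C1/34S1 isotopologue
    peaks at their theoretical relative abundance, formula-free noise
    peaks, and per-replicate dropouts; the result is sorted and merged at
    the instrument resolution floor. Measured m/z values are recorded back
    into each record's ``emitted_mz`` under ``(time_index, replicate)``.
    """
    if not truth:
        raise ValueError("truth network is empty")
    if time_index is None:
        time_index = len(config.time_points_h) - 1
    rng = _replicate_rng(config, sample_key, time_index, replicate)
    raw: list[tuple[float, float]] = []
    for record in truth:
        if record.appears_at_index > time_index:
            continue
        if (config.dropout_probability > 0
                and rng.random() < config.dropout_probability):
            continue
        theo_mz = _mz_of(record.formula)
        eps = rng.normal(0.0, config.mass_error_ppm_sd)
        mz = theo_mz * (1.0 + eps * 1e-6)
        intensity = (
            record.intensity
            * _time_weight(config, record.step, time_index)
            * float(rng.lognormal(0.0, config.replicate_sigma))
        )
        record.emitted_mz[(time_index, replicate)] = mz
        raw.append((mz, intensity))
        if config.isotopologues:
            pattern = {
                p.label: p for p in isotope_fine_structure(record.formula)
            }
            for label in ("13C1", "34S1"):
                iso = pattern.get(label)
                if iso is not None:
                    raw.append((mz + iso.mass_shift, intensity * iso.abundance))

    # formula-free noise peaks: redrawn if any CHNOS mass lies within the
    # hard ppm cut, so false positives are unambiguously accountable
    bounds = ElementBounds()
    lo, hi = config.mz_range
    for _ in range(config.noise_peaks):
        for _ in range(100):
            mz = float(rng.uniform(lo, hi))
            neutral = mz + PROTON_MASS
            if not enumerate_candidates(
                neutral, bounds, ppm_tol=bounds.hard_ppm_cut
            ):
                break
        else:
            continue
        intensity = float(
            config.noise_floor * 10 ** rng.uniform(0.0, 2.0)
        )
        raw.append((mz, intensity))

    raw.sort(key=lambda t: t[0])
    floor = config.resolution_floor_mda * 1e-3
    merged: list[list[float]] = []
    for mz, intensity in raw:
        if merged and mz - merged[-1][0] < floor:
            # unresolved neighbours coalesce; the stronger centroid wins
            if intensity > merged[-1][1]:
                merged[-1][0] = mz
            merged[-1][1] += intensity
        else:
            merged.append([mz, intensity])
    peaks = [
        Peak(mz=mz, intensity=intensity, snr=intensity / config.noise_floor)
        for mz, intensity in merged
    ]
    t = config.time_points_h[time_index]
    return PeakList(
        sample_id=sample_id,
        system=system,
        time_h=t,
        replicate=replicate,
        peaks=peaks,
        is_blank=is_blank,
        sugar=sugar,
        amino_acid=amino_acid,
        resolution_floor_mda=config.resolution_floor_mda,
    )


def sugar_blank_truth(
    truth: Sequence[TruthRecord], config: SimulationConfig
) -> list[TruthRecord]:
    """Records a heated sugar-only blank contains."""
    sugar = config.sugar_composition
    return [
        r for r in truth
        if r.product_class is ProductClass.SUGAR_DEG
        or (r.product_class is ProductClass.PRECURSOR and r.formula == sugar)
    ]


def aa_blank_truth(
    truth: Sequence[TruthRecord], config: SimulationConfig
) -> list[TruthRecord]:
    """Records a heated amino-acid-only blank contains."""
    sugar = config.sugar_composition
    return [
        r for r in truth
        if r.product_class is ProductClass.AA_DEG
        or (r.product_class is ProductClass.PRECURSOR and r.formula != sugar)
    ]


def simulate_blanks(
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    replicate: int,
    time_index: int | None = None,
    amino_acid: str = "",
    sample_key: int = 0,
) -> tuple[PeakList, PeakList]:
    """Simulate the sugar-only and amino-acid-only blank measurements."""
    sugar_blank = simulate_peaklist(
        sugar_blank_truth(truth, config), config, replicate,
        time_index=time_index,
        sample_id=f"blank-{config.sugar}-t{time_index}-r{replicate}",
        system=f"{config.sugar}-blank",
        is_blank=True, sugar=config.sugar,
        sample_key=1000 + sample_key,
    )
    aa_blank = simulate_peaklist(
        aa_blank_truth(truth, config), config, replicate,
        time_index=time_index,
        sample_id=f"blank-{amino_acid}-t{time_index}-r{replicate}",
        system=f"{amino_acid}-blank",
        is_blank=True, amino_acid=amino_acid,
        sample_key=2000 + sample_key,
    )
    return sugar_blank, aa_blank


def truth_to_table(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    rows = [
        {
            "formula": r.formula.hill(),
            "product_class": r.product_class.value,
            "pathway": r.pathway or "",
            "step": r.step,
            "redox": r.redox,
            "intensity": r.intensity,
            "appears_at_index": r.appears_at_index,
        }
        for r in truth
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "formula", "product_class", "pathway", "step", "redox",
            "intensity", "appears_at_index",
        ],
    )


def write_truth_table(truth: Sequence[TruthRecord], path) -> None:
    """Write the truth network as CSV (formula strings in Hill notation)."""
    truth_to_table(truth).to_csv(path, index=False)


def read_truth_table(path) -> list[TruthRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            TruthRecord(
                formula=ElementalComposition.parse(row["formula"]),
                product_class=ProductClass(row["product_class"]),
                pathway=row["pathway"] or None,
                step=int(row["step"]),
                redox=int(row["redox"]),
                intensity=float(row["intensity"]),
                appears_at_index=int(row["appears_at_index"]),
            )
        )
    return out
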