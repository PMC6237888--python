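"""Molecular-formula assignment for direct-infusion ESI(-) peak lists.

Measured [M-H]- peaks are converted to neutral masses, candidate CHNOS
compositions are enumerated exhaustively within element bounds and a ppm
window, and candidates are then accepted by mass-difference network
propagation: starting from seed formulas (the precursors and their Amadori
product), a candidate is accepted when it is one chemical transformation
away from an already-accepted formula. Peaks that the network cannot reach
fall back to a unique unambiguous brute-force candidate. Finally only
formulas reproduced in every replicate are reported (replicate consensus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chemcore import (
    CompositionDelta,
    ElementalComposition,
    PROTON_MASS,
    dbe,
    isotope_fine_structure,
    monoisotopic_mass,
    try_apply_delta,
)

__all__ = [
    "Peak",
    "PeakList",
    "ElementBounds",
    "FormulaAssignment",
    "DEFAULT_TRANSFORMATIONS",
    "neutral_mass_from_mz",
    "enumerate_candidates",
    "chemical_filter",
    "network_annotate",
    "validate_isotopes",
    "replicate_consensus",
    "assignments_to_table",
]


@dataclass(frozen=True)
class Peak:
    """One ion observation: centroid m/z (Da), intensity, signal-to-noise."""

    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.intensity <= 0 or self.snr <= 0:
            raise ValueError("intensity and snr must be positive")


@dataclass
class PeakList:
    """A peak list in its sample context (system, time point, replicate)."""

    sample_id: str
    system: str
    time_h: float
    replicate: int
    peaks: list[Peak]
    is_blank: bool = False
    sugar: str | None = None
    amino_acid: str | None = None
    resolution_floor_mda: float = 1.0

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")
        if self.is_blank and bool(self.sugar) == bool(self.amino_acid):
            raise ValueError("a blank carries exactly one precursor label")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        floor = self.resolution_floor_mda * 1e-3
        for a, b in zip(self.peaks, self.peaks[1:]):
            if b.mz - a.mz < floor:
                raise ValueError(
                    f"peaks at {a.mz:.6f}/{b.mz:.6f} closer than the "
                    f"{self.resolution_floor_mda} mDa resolution floor"
                )


@dataclass(frozen=True)
class ElementBounds:
    """Element count ranges and ppm windows for candidate enumeration.

    ``ppm_tolerance`` is the strict window applied to assignments without
    network support; ``hard_ppm_cut`` is the outer envelope no accepted
    assignment may exceed.
    """

    c: tuple[int, int] = (1, 40)
    h: tuple[int, int] = (1, 80)
    n: tuple[int, int] = (0, 6)
    o: tuple[int, int] = (0, 25)
    s: tuple[int, int] = (0, 4)
    ppm_tolerance: float = 0.2
    hard_ppm_cut: float = 0.5

    def __post_init__(self) -> None:
        for el in ("c", "h", "n", "o", "s"):
            lo, hi = getattr(self, el)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid bounds for {el}: {(lo, hi)}")
        if self.ppm_tolerance <= 0 or self.hard_ppm_cut < self.ppm_tolerance:
            raise ValueError("need 0 < ppm_tolerance <= hard_ppm_cut")


@dataclass
class FormulaAssignment:
    """A peak bound to a neutral composition (or left unassigned)."""

    peak: Peak
    composition: ElementalComposition | None
    neutral_mass: float
    error_ppm: float = float("nan")
    dbe: float = float("nan")
    network_support: int = 0
    isotope_validated: bool = False
    accepted: bool = False


def neutral_mass_from_mz(mz: float, charge: int = 1) -> float:
    """Neutral monoisotopic mass of a singly charged [M-H]- ion."""
    if charge != 1:
        raise ValueError("only singly charged [M-H]- ions are supported")
    return mz + PROTON_MASS


# Default transformation library: the reaction types at work in the
# sugar/amino-acid cascade. Dehydration/hydration, redox (+-H2, +-O),
# pentose addition (ribose - H2O), decarboxylation, C2/C3 cleavage,
# retro-aldol formaldehyde loss. Amino-acid condensation (+AA - H2O) is
# appended per system by `condensation_delta`.
DEFAULT_TRANSFORMATIONS: tuple[CompositionDelta, ...] = (
    CompositionDelta(h=-2, o=-1),            # -H2O dehydration
    CompositionDelta(h=2, o=1),              # +H2O hydration
    CompositionDelta(h=-2),                  # -H2 oxidation
    CompositionDelta(h=2),                   # +H2 reduction
    CompositionDelta(o=-1),                  # -O
    CompositionDelta(o=1),                   # +O oxygenation
    CompositionDelta(c=5, h=8, o=4),         # +C5H8O4 pentose addition
    CompositionDelta(c=-1, o=-2),            # -CO2 decarboxylation
    CompositionDelta(c=-2, h=-4, o=-2),      # -C2H4O2 C2 cleavage
    CompositionDelta(c=-3, h=-6, o=-3),      # -C3H6O3 C3 cleavage
    CompositionDelta(c=-1, h=-2, o=-1),      # -CH2O retro-aldol
)


def condensation_delta(amino_acid: ElementalComposition) -> CompositionDelta:
    """The +AA-H2O amino-acid condensation delta for one model system."""
    return CompositionDelta(
        c=amino_acid.c,
        h=amino_acid.h - 2,
        n=amino_acid.n,
        o=amino_acid.o - 1,
        s=amino_acid.s,
    )


_GRID_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _chnos_grid(bounds: ElementBounds) -> tuple[np.ndarray, np.ndarray]:
    """All (c, n, o, s) count combinations and their partial masses."""
    key = (bounds.c, bounds.n, bounds.o, bounds.s)
    if key not in _GRID_CACHE:
        from .chemcore import MONOISOTOPIC_MASS as M

        c = np.arange(bounds.c[0], bounds.c[1] + 1)
        n = np.arange(bounds.n[0], bounds.n[1] + 1)
        o = np.arange(bounds.o[0], bounds.o[1] + 1)
        s = np.arange(bounds.s[0], bounds.s[1] + 1)
        cc, nn, oo, ss = np.meshgrid(c, n, o, s, indexing="ij")
        counts = np.stack(
            [cc.ravel(), nn.ravel(), oo.ravel(), ss.ravel()], axis=1
        )
        masses = (
            counts[:, 0] * M["c"]
            + counts[:, 1] * M["n"]
            + counts[:, 2] * M["o"]
            + counts[:, 3] * M["s"]
        )
        _GRID_CACHE[key] = (counts, masses)
    return _GRID_CACHE[key]


def enumerate_candidates(
    neutral_mass: float,
    bounds: ElementBounds,
    ppm_tol: float | None = None,
) -> list[tuple[ElementalComposition, float]]:
    """Exhaustive CHNOS compositions within ``ppm_tol`` of a neutral mass.

    Returns ``(composition, error_ppm)`` pairs sorted by |error_ppm| (ties
    by composition for determinism). ``error_ppm`` is signed:
    (theoretical - observed) / observed * 1e6. Defaults to the bounds'
    strict ppm tolerance.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    if ppm_tol is None:
        ppm_tol = bounds.ppm_tolerance
    from .chemcore import MONOISOTOPIC_MASS as M

    counts, partial = _chnos_grid(bounds)
    window = neutral_mass * ppm_tol * 1e-6
    h_float = (neutral_mass - partial) / M["h"]
    out: list[tuple[ElementalComposition, float]] = []
    # each grid point admits at most a couple of integer H counts
    for h in (np.floor(h_float), np.ceil(h_float)):
        h = h.astype(int)
        mass = partial + h * M["h"]
        ok = (
            (np.abs(mass - neutral_mass) <= window)
            & (h >= bounds.h[0])
            & (h <= bounds.h[1])
        )
        for idx in np.nonzero(ok)[0]:
            comp = ElementalComposition(
                c=int(counts[idx, 0]),
                h=int(h[idx]),
                n=int(counts[idx, 1]),
                o=int(counts[idx, 2]),
                s=int(counts[idx, 3]),
            )
            err = (monoisotopic_mass(comp) - neutral_mass) / neutral_mass * 1e6
            out.append((comp, err))
    out = sorted(set(out), key=lambda ce: (abs(ce[1]), ce[0]))
    # floor/ceil can coincide; dedupe on composition
    seen: set[ElementalComposition] = set()
    deduped = []
    for comp, err in out:
        if comp not in seen:
            seen.add(comp)
            deduped.append((comp, err))
    return deduped


def chemical_filter(comp: ElementalComposition) -> bool:
    """Heuristic plausibility filter for neutral even-electron molecules.

    Requires DBE >= 0 and integral, H/C in [0, 3] and O/C <= 2.
    """
    if comp.c < 1:
        return False
    d = dbe(comp)
    if d < 0 or (comp.h + comp.n) % 2 != 0:
        return False
    return comp.h / comp.c <= 3.0 and comp.o / comp.c <= 2.0


def _neighbors(
    comp: ElementalComposition,
    accepted: set[ElementalComposition],
    transformations: Sequence[CompositionDelta],
) -> set[ElementalComposition]:
    """Accepted formulas one transformation away from ``comp`` (either
    direction)."""
    found: set[ElementalComposition] = set()
    for delta in transformations:
        for d in (delta, -delta):
            other = try_apply_delta(comp, d)
            if other is not None and other != comp and other in accepted:
                found.add(other)
    return found


# mass shifts of the 13C1 and 34S1 substitutions used for de-isotoping
_ISO_SHIFTS = (1.0033548353, 1.9957958356)


def _isotopologue_indices(
    peaks: Sequence[Peak],
    window_da: float = 0.0008,
    max_ratio: float = 0.6,
) -> set[int]:
    """Indices of peaks that look like isotopologues of a stronger peak.

    A peak is flagged when it sits within ``window_da`` of a stronger
    peak's m/z plus a 13C1 or 34S1 shift at a plausible intensity ratio.
    The window must stay well below 1.3 mDa: the chemical delta
    +C3 -H2 -O2 (1.99452 Da) lies that close to the 34S shift (1.99580 Da),
    and ultrahigh resolution is exactly what separates the two.
    """
    mzs = np.array([p.mz for p in peaks])
    out: set[int] = set()
    for j, p in enumerate(peaks):
        for shift in _ISO_SHIFTS:
            target = p.mz - shift
            lo = np.searchsorted(mzs, target - window_da)
            hi = np.searchsorted(mzs, target + window_da)
            for i in range(lo, hi):
                if p.intensity <= max_ratio * peaks[i].intensity:
                    out.add(j)
                    break
    return out


def network_annotate(
    peaklist: PeakList,
    seed_formulas: Iterable[ElementalComposition],
    transformations: Sequence[CompositionDelta] = DEFAULT_TRANSFORMATIONS,
    bounds: ElementBounds = ElementBounds(),
    snr_floor: float = 4.0,
    deisotope: bool = True,
) -> list[FormulaAssignment]:
    """Assign formulas to a peak list by network propagation from seeds.

    Breadth-first to a fixed point: in each pass, peaks are visited in
    ascending m/z and a candidate is accepted when it passes the chemical
    filter, lies within the hard ppm cut, and either equals a seed or is one
    transformation away from an accepted formula. Per-peak ties are broken
    by highest network support, then smallest |ppm| error. Unreached peaks
    fall back to a unique brute-force candidate within the strict ppm
    tolerance; otherwise they stay unassigned.

    Peaks below the S/N floor are ignored, as are peaks recognized as
    isotopologues of a stronger peak (``deisotope``); only monoisotopic
    ions receive formulas.
    """
    seeds = set(seed_formulas)
    if not seeds:
        raise ValueError("at least one seed formula is required")
    if not transformations:
        raise ValueError("transformation set must be nonempty")

    all_sorted = sorted(peaklist.peaks, key=lambda p: p.mz)
    iso_like = _isotopologue_indices(all_sorted) if deisotope else set()
    usable = [
        p for i, p in enumerate(all_sorted)
        if p.snr >= snr_floor and i not in iso_like
    ]
    neutral = [neutral_mass_from_mz(p.mz) for p in usable]
    candidates = [
        [
            (comp, err)
            for comp, err in enumerate_candidates(
                m, bounds, ppm_tol=bounds.hard_ppm_cut
            )
            if chemical_filter(comp)
        ]
        for m in neutral
    ]

    accepted: set[ElementalComposition] = set(seeds)
    chosen: dict[int, tuple[ElementalComposition, float]] = {}

    changed = True
    while changed:
        changed = False
        for i, peak in enumerate(usable):
            if i in chosen:
                continue
            best: tuple[int, float, ElementalComposition] | None = None
            for comp, err in candidates[i]:
                support = len(_neighbors(comp, accepted, transformations))
                if support == 0 and comp not in seeds:
                    continue
                key = (support, -abs(err), comp)
                if best is None or (key[0], key[1]) > (best[0], best[1]):
                    best = (support, -abs(err), comp)
                    best_err = err
            if best is not None:
                chosen[i] = (best[2], best_err)
                accepted.add(best[2])
                changed = True

    # fallback: a unique unambiguous brute-force candidate, strict tolerance
    for i, peak in enumerate(usable):
        if i in chosen:
            continue
        strict = [
            (c, e) for c, e in candidates[i]
            if abs(e) <= bounds.ppm_tolerance
        ]
        if len(strict) == 1:
            chosen[i] = strict[0]
            accepted.add(strict[0][0])

    out: list[FormulaAssignment] = []
    for i, peak in enumerate(usable):
        if i in chosen:
            comp, err = chosen[i]
            out.append(
                FormulaAssignment(
                    peak=peak,
                    composition=comp,
                    neutral_mass=neutral[i],
                    error_ppm=err,
                    dbe=dbe(comp),
                    network_support=len(
                        _neighbors(comp, accepted - {comp}, transformations)
                    ),
                    accepted=True,
                )
            )
        else:
            out.append(
                FormulaAssignment(
                    peak=peak, composition=None, neutral_mass=neutral[i]
                )
            )
    return out


def validate_isotopes(
    assignment: FormulaAssignment,
    peaklist: PeakList,
    ppm_tol: float = 1.0,
    rel_int_tol: float = 0.3,
) -> bool:
    """Confirm a formula by its isotopic fine structure.

    Requires the predicted 13C1 isotopologue peak — and the 34S1 peak for
    sulphur-bearing formulas — to be present within ``ppm_tol`` of its
    theoretical m/z, with an observed/parent intensity ratio matching the
    predicted relative abundance within ``rel_int_tol`` (relative).
    """
    if not assignment.accepted or assignment.composition is None:
        return False
    comp = assignment.composition
    pattern = {p.label: p for p in isotope_fine_structure(comp)}
    required = ["13C1"]
    if comp.s >= 1:
        required.append("34S1")
    mzs = np.array([p.mz for p in peaklist.peaks])
    intens = np.array([p.intensity for p in peaklist.peaks])
    parent_int = assignment.peak.intensity
    for label in required:
        iso = pattern.get(label)
        if iso is None:
            return False
        target_mz = assignment.peak.mz + iso.mass_shift
        window = target_mz * ppm_tol * 1e-6
        hits = np.nonzero(np.abs(mzs - target_mz) <= window)[0]
        if hits.size == 0:
            return False
        observed = intens[hits[np.argmin(np.abs(mzs[hits] - target_mz))]]
        ratio = observed / parent_int
        if abs(ratio - iso.abundance) > rel_int_tol * iso.abundance:
            return False
    return True


def assignments_to_table(
    peaklist: PeakList, assignments: Sequence[FormulaAssignment]
) -> pd.DataFrame:
    """Flatten assignments into the formula-table schema used throughout."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "sample_id": peaklist.sample_id,
                "system": peaklist.system,
                "time_h": peaklist.time_h,
                "replicate": peaklist.replicate,
                "mz": a.peak.mz,
                "intensity": a.peak.intensity,
                "snr": a.peak.snr,
                "formula": a.composition.hill() if a.composition else "",
                "neutral_mass": a.neutral_mass,
                "error_ppm": a.error_ppm,
                "dbe": a.dbe,
                "network_support": a.network_support,
                "isotope_validated": a.isotope_validated,
                "accepted": a.accepted,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "system", "time_h", "replicate", "mz", "intensity",
            "snr", "formula", "neutral_mass", "error_ppm", "dbe",
            "network_support", "isotope_validated", "accepted",
        ],
    )


def replicate_consensus(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Keep only formulas assigned in every replicate of a condition.

    ``tables`` are per-replicate formula tables of one (system, time point)
    condition. Consensus intensity and S/N are replicate means; consensus
    error is the mean |ppm| error. A single replicate passes through as-is.
    """
    if not tables:
        raise ValueError("need at least one replicate table")
    frames = [t[t["accepted"] & (t["formula"] != "")] for t in tables]
    n_rep = len(frames)
    merged = pd.concat(frames, ignore_index=True)
    if merged.empty:
        return pd.DataFrame(
            columns=[
                "system", "time_h", "formula", "intensity", "snr",
                "error_ppm", "dbe", "n_replicates", "isotope_validated",
            ]
        )
    merged["abs_ppm"] = merged["error_ppm"].abs()
    grouped = merged.groupby("formula", sort=True)
    out = grouped.agg(
        system=("system", "first"),
        time_h=("time_h", "first"),
        intensity=("intensity", "mean"),
        snr=("snr", "mean"),
        error_ppm=("abs_ppm", "mean"),
        dbe=("dbe", "first"),
        n_found=("replicate", "nunique"),
        isotope_validated=("isotope_validated", "all"),
    ).reset_index()
    out = out[out["n_found"] == n_rep].drop(columns="n_found")
    out["n_replicates"] = n_rep
    return out[
        [
            "system", "time_h", "formula", "intensity", "snr", "error_ppm",
            "dbe", "n_replicates", "isotope_validated",
        ]
    ].reset_index(drop=True)
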