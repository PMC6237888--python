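"""Exact elemental-composition algebra for CHNOS molecules.

Everything downstream — formula assignment, product classification,
van Krevelen descriptors and reaction-scheme reconstruction — operates on
the small value types defined here: :class:`ElementalComposition` (atom
counts), :class:`CompositionDelta` (a signed change in atom counts, the
currency of reaction transformations such as dehydration) and
:class:`IsotopologuePeak` (one resolved isotope-substitution peak).

Atomic masses and isotopic abundances are pinned to the CIAAW/IUPAC 2021
tables so that results are bit-reproducible; compositions are restricted to
C, H, N, O and S, the only elements present in sugar + amino-acid model
systems.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterator

ELEMENTS = ("c", "h", "n", "o", "s")

# Monoisotopic (lightest-isotope) masses, Da. CIAAW/IUPAC 2021.
MONOISOTOPIC_MASS = {
    "c": 12.0,
    "h": 1.00782503224,
    "n": 14.00307400446,
    "o": 15.99491461960,
    "s": 31.9720711744,
}

# Heavy-isotope substitutions: per element, (label, mass shift vs lightest
# isotope in Da, abundance ratio heavy/lightest). CIAAW representative
# isotopic compositions.
_ISOTOPES = {
    "c": (("13C", 13.00335483534 - 12.0, 0.0107 / 0.9893),),
    "h": (("2H", 2.01410177811 - 1.00782503224, 0.000115 / 0.999885),),
    "n": (("15N", 15.00010889894 - 14.00307400446, 0.00364 / 0.99636),),
    "o": (
        ("17O", 16.99913175664 - 15.99491461960, 0.00038 / 0.99757),
        ("18O", 17.99915961284 - 15.99491461960, 0.00205 / 0.99757),
    ),
    "s": (
        ("33S", 32.9714589099 - 31.9720711744, 0.0075 / 0.9499),
        ("34S", 33.96786701 - 31.9720711744, 0.0425 / 0.9499),
        ("36S", 35.96708070 - 31.9720711744, 0.0001 / 0.9499),
    ),
}

#: Mass of a proton (with the electron mass folded in, classical [M-H]-
#: convention), Da.
PROTON_MASS = 1.007276467

_HILL_SYMBOL = {"c": "C", "h": "H", "n": "N", "o": "O", "s": "S"}
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class CompositionError(ValueError):
    """Raised when composition arithmetic would produce a negative count."""


@dataclass(frozen=True, order=True)
class ElementalComposition:
    """Non-negative CHNOS atom counts of a neutral molecule."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            v = getattr(self, el)
            if not isinstance(v, int) or v < 0:
                raise CompositionError(
                    f"atom count {el}={v!r} must be a non-negative integer"
                )

    def counts(self) -> tuple[int, int, int, int, int]:
        return (self.c, self.h, self.n, self.o, self.s)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            *(a + b for a, b in zip(self.counts(), other.counts()))
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        diff = [a - b for a, b in zip(self.counts(), other.counts())]
        if any(v < 0 for v in diff):
            raise CompositionError(f"{self} - {other} has negative counts")
        return ElementalComposition(*diff)

    def is_empty(self) -> bool:
        return all(v == 0 for v in self.counts())

    def hill(self) -> str:
        """Render in Hill notation (C first, H second, then alphabetical)."""
        parts = []
        for el in ("c", "h", "n", "o", "s"):
            v = getattr(self, el)
            if v == 0:
                continue
            parts.append(_HILL_SYMBOL[el] + (str(v) if v != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    @classmethod
    def parse(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-notation formula string such as ``"C7H13NO6"``.

        Omitted subscripts mean 1. Only C, H, N, O, S are accepted.
        """
        if not formula:
            return cls()
        counts = dict.fromkeys(ELEMENTS, 0)
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            el = sym.lower()
            if el not in counts:
                raise ValueError(f"element {sym!r} outside CHNOS in {formula!r}")
            counts[el] += int(num) if num else 1
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(**counts)


@dataclass(frozen=True)
class CompositionDelta:
    """Signed per-element change; the arrow of a chemical transformation."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0

    def counts(self) -> tuple[int, int, int, int, int]:
        return (self.c, self.h, self.n, self.o, self.s)

    def __neg__(self) -> "CompositionDelta":
        return CompositionDelta(*(-v for v in self.counts()))

    def __add__(self, other: "CompositionDelta") -> "CompositionDelta":
        return CompositionDelta(
            *(a + b for a, b in zip(self.counts(), other.counts()))
        )

    def is_zero(self) -> bool:
        return all(v == 0 for v in self.counts())

    @classmethod
    def between(
        cls, source: ElementalComposition, target: ElementalComposition
    ) -> "CompositionDelta":
        return cls(*(b - a for a, b in zip(source.counts(), target.counts())))

    @classmethod
    def from_formula(cls, formula: str, sign: int = 1) -> "CompositionDelta":
        comp = ElementalComposition.parse(formula)
        return cls(*(sign * v for v in comp.counts()))

    def mass(self) -> float:
        return sum(
            v * MONOISOTOPIC_MASS[el] for el, v in zip(ELEMENTS, self.counts())
        )


@dataclass(frozen=True)
class IsotopologuePeak:
    """One resolved isotope-substitution peak of a fine-structure pattern.

    ``abundance`` is relative to the monoisotopic (all-light-isotope) peak.
    """

    mass_shift: float
    abundance: float
    label: str


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Exact neutral monoisotopic mass in Da (12C = 12 exactly)."""
    return sum(
        v * MONOISOTOPIC_MASS[el] for el, v in zip(ELEMENTS, comp.counts())
    )


def dbe(comp: ElementalComposition) -> float:
    """Double-bond equivalents: 1 + C - H/2 + N/2 (O and S contribute zero)."""
    return 1.0 + comp.c - comp.h / 2.0 + comp.n / 2.0


def apply_delta(
    comp: ElementalComposition, delta: CompositionDelta
) -> ElementalComposition:
    """Apply a transformation delta; raises :class:`CompositionError` when a
    resulting atom count would be negative (the transformation does not apply,
    e.g. dehydrating an oxygen-free molecule)."""
    out = [a + d for a, d in zip(comp.counts(), delta.counts())]
    if any(v < 0 for v in out):
        raise CompositionError(f"{comp} + delta{delta.counts()} is negative")
    return ElementalComposition(*out)


def try_apply_delta(
    comp: ElementalComposition, delta: CompositionDelta
) -> ElementalComposition | None:
    """Like :func:`apply_delta` but returns None for inapplicable deltas."""
    out = [a + d for a, d in zip(comp.counts(), delta.counts())]
    if any(v < 0 for v in out):
        return None
    return ElementalComposition(*out)


def _element_patterns(
    el: str, count: int, threshold: float
) -> list[tuple[float, float, str]]:
    """Isotope-substitution states of ``count`` atoms of one element.

    Yields (mass shift, abundance relative to all-light state, label) for
    every combination of heavy-isotope counts whose relative abundance
    clears ``threshold``; exact multinomial statistics.
    """
    isotopes = _ISOTOPES[el]
    states: list[tuple[float, float, str]] = []

    # nested enumeration of heavy-isotope counts with exact multinomial weights
    def enumerate_counts(idx: int, left: int) -> Iterator[tuple[tuple[int, ...], float]]:
        if idx == len(isotopes):
            yield (), 1.0
            return
        _, _, ratio = isotopes[idx]
        for k in range(left + 1):
            w = ratio**k
            # upper bound on the final multinomial weight of this branch;
            # monotone decreasing in k for the trace abundances handled here
            if k > 0 and math.comb(count, k) * w < threshold:
                break
            for rest, rw in enumerate_counts(idx + 1, left - k):
                yield (k,) + rest, w * rw

    for ks, ratio_w in enumerate_counts(0, count):
        if all(k == 0 for k in ks):
            states.append((0.0, 1.0, ""))
            continue
        # multinomial coefficient count! / (prod k_i! * (count - sum k)!)
        # divided by count!/(count!) baseline -> C(count; k1, k2, ...)
        total_heavy = sum(ks)
        coeff = math.factorial(count) // (
            math.prod(math.factorial(k) for k in ks)
            * math.factorial(count - total_heavy)
        )
        ab = coeff * ratio_w
        if ab < threshold:
            continue
        shift = sum(k * isotopes[i][1] for i, k in enumerate(ks))
        label = " ".join(
            f"{isotopes[i][0]}{k}" for i, k in enumerate(ks) if k > 0
        )
        states.append((shift, ab, label))
    return states


def isotope_fine_structure(
    comp: ElementalComposition, min_rel_abundance: float = 1e-4
) -> list[IsotopologuePeak]:
    """Predict the resolved isotopic fine structure of a composition.

    Distinct substitutions (13C1 vs 15N1 vs 34S1 ...) are kept as separate
    peaks, exactly as an FT-ICR instrument resolves them. Abundances are
    relative to the monoisotopic peak; peaks below ``min_rel_abundance`` are
    dropped, as is the monoisotopic peak itself. Peaks are sorted by mass
    shift.
    """
    if not 0.0 < min_rel_abundance < 1.0:
        raise ValueError("min_rel_abundance must be in (0, 1)")
    if comp.is_empty():
        return []
    # cross-element convolution of per-element substitution states
    combined: list[tuple[float, float, str]] = [(0.0, 1.0, "")]
    for el in ELEMENTS:
        count = getattr(comp, el)
        if count == 0:
            continue
        states = _element_patterns(el, count, min_rel_abundance)
        nxt = []
        for shift0, ab0, lab0 in combined:
            for shift1, ab1, lab1 in states:
                ab = ab0 * ab1
                if ab < min_rel_abundance:
                    continue
                lab = " ".join(p for p in (lab0, lab1) if p)
                nxt.append((shift0 + shift1, ab, lab))
        combined = nxt
    peaks = [
        IsotopologuePeak(mass_shift=shift, abundance=ab, label=lab)
        for shift, ab, lab in combined
        if lab  # drop the monoisotopic (no-substitution) state
    ]
    peaks.sort(key=lambda p: p.mass_shift)
    return peaks


#: The common alpha-amino-acid backbone: an amino acid is backbone + side
#: chain R, so glycine (C2H5NO2) carries R = H.
AA_BACKBONE = ElementalComposition(c=2, h=4, n=1, o=2)


def side_chain(amino_acid: ElementalComposition) -> ElementalComposition:
    """Side chain R of an alpha-amino acid (composition minus C2H4NO2).

    Raises :class:`CompositionError` for inputs that do not contain the
    backbone, signalling a non-alpha-amino-acid composition.
    """
    try:
        return amino_acid - AA_BACKBONE
    except CompositionError as exc:
        raise CompositionError(
            f"{amino_acid.hill()} does not contain the alpha-amino-acid "
            f"backbone {AA_BACKBONE.hill()}"
        ) from exc
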