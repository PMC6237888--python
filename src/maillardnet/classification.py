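"""Blank-based product classification.

A formula observed in a heated sugar + amino-acid mixture is attributed to
one of four origins by comparing against time-matched heated blanks: a
Maillard reaction product (MRP) needs both precursors, a sugar or
amino-acid degradation product also forms in the respective blank, and the
precursors themselves are labelled as such. Formulas present in both blanks
cannot be attributed and are kept as AMBIGUOUS rather than forced into a
priority order.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

class ProductClass(str, Enum):
    MRP = "MRP"
    SUGAR_DEG = "SUGAR_DEG"
    AA_DEG = "AA_DEG"
    PRECURSOR = "PRECURSOR"
    AMBIGUOUS = "AMBIGUOUS"


class MissingBlankError(ValueError):
    """A required blank consensus table was not supplied."""


def classify_formulas(
    mixture_formulas: Iterable[str],
    sugar_blank_formulas: Iterable[str] | None,
    aa_blank_formulas: Iterable[str] | None,
    precursors: Iterable[str],
) -> dict[str, ProductClass]:
    """Map each mixture formula (Hill string) to its product class.

    All inputs must come from the same time point. Raises
    :class:`MissingBlankError` when a blank table is missing (None);
    empty blanks are legitimate.
    """
    if sugar_blank_formulas is None:
        raise MissingBlankError("sugar blank table is missing")
    if aa_blank_formulas is None:
        raise MissingBlankError("amino-acid blank table is missing")
    sugar_set = set(sugar_blank_formulas)
    aa_set = set(aa_blank_formulas)
    precursor_set = set(precursors)
    out: dict[str, ProductClass] = {}
    for formula in mixture_formulas:
        if formula in precursor_set:
            out[formula] = ProductClass.PRECURSOR
        elif formula in sugar_set and formula in aa_set:
            out[formula] = ProductClass.AMBIGUOUS
        elif formula in sugar_set:
            out[formula] = ProductClass.SUGAR_DEG
        elif formula in aa_set:
            out[formula] = ProductClass.AA_DEG
        else:
            out[formula] = ProductClass.MRP
    return out


def classify_table(
    mixture: pd.DataFrame,
    sugar_blank: pd.DataFrame | None,
    aa_blank: pd.DataFrame | None,
    precursors: Iterable[str],
) -> pd.DataFrame:
    """Add a ``product_class`` column to a consensus formula table."""
    classes = classify_formulas(
        mixture["formula"],
        None if sugar_blank is None else sugar_blank["formula"],
        None if aa_blank is None else aa_blank["formula"],
        precursors,
    )
    out = mixture.copy()
    out["product_class"] = out["formula"].map(
        lambda f: classes[f].value
    )
    return out


def class_counts_over_time(
    classified_tables: Mapping[float, pd.DataFrame] | Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Distinct-formula counts per product class and time point.

    Accepts either a mapping time -> classified table or a sequence of
    classified tables carrying a ``time_h`` column. Returns a long-format
    table (system, time_h, product_class, n_formulas) including zero rows
    for absent classes.
    """
    if isinstance(classified_tables, Mapping):
        items = sorted(classified_tables.items())
        frames = []
        for t, table in items:
            f = table.copy()
            f["time_h"] = t
            frames.append(f)
    else:
        frames = [t for t in classified_tables]
    rows = []
    all_classes = [c.value for c in ProductClass]
    for f in frames:
        if f.empty:
            continue
        for (system, t), grp in f.groupby(["system", "time_h"], sort=True):
            counts = grp.groupby("product_class")["formula"].nunique()
            for cls in all_classes:
                rows.append(
                    {
                        "system": system,
                        "time_h": t,
                        "product_class": cls,
                        "n_formulas": int(counts.get(cls, 0)),
                    }
                )
    return pd.DataFrame(
        rows, columns=["system", "time_h", "product_class", "n_formulas"]
    )
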