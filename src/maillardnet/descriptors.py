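"""Compositional descriptors of assigned formulas.

Van Krevelen coordinates (H/C vs O/C), degree of unsaturation per carbon
(DBE/C), CHO/CHNO/CHOS/CHNOS compositional spaces, intensity-weighted mean
ratios over reaction time with their regression trends, carbon-number
intensity histograms, and odd-nitrogen screening (an odd nitrogen count in
a product of an even-N amino acid flags side-chain fragmentation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chemcore import ElementalComposition, dbe


@dataclass(frozen=True)
class TrendPoint:
    """Intensity-weighted mean H/C and O/C of one sample at one time."""

    time_h: float
    h_c: float
    o_c: float


def composition_space(comp: ElementalComposition) -> str:
    """CHO / CHNO / CHOS / CHNOS label by heteroatom presence."""
    if comp.c < 1:
        raise ValueError("composition space needs at least one carbon")
    label = "CH"
    if comp.n > 0:
        label += "N"
    label += "O"
    if comp.s > 0:
        label += "S"
    return label


def van_krevelen(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-formula van Krevelen coordinates and relative intensities.

    Adds ``h_c``, ``o_c``, ``dbe_c``, ``rel_intensity`` (normalized within
    the table so shares sum to one) and ``space`` columns. Carbon-free
    formulas are excluded with a warning.
    """
    out = classified.copy()
    comps = out["formula"].map(ElementalComposition.parse)
    carbonless = comps.map(lambda c: c.c < 1)
    if carbonless.any():
        warnings.warn(
            f"excluding {int(carbonless.sum())} carbon-free formula(s) "
            "from van Krevelen descriptors"
        )
        out = out[~carbonless.values].copy()
        comps = comps[~carbonless.values]
    out["h_c"] = [c.h / c.c for c in comps]
    out["o_c"] = [c.o / c.c for c in comps]
    out["dbe_c"] = [dbe(c) / c.c for c in comps]
    out["space"] = [composition_space(c) for c in comps]
    total = out["intensity"].sum()
    out["rel_intensity"] = out["intensity"] / total
    return out


def weighted_mean_ratios(vk: pd.DataFrame) -> TrendPoint:
    """Intensity-weighted mean H/C and O/C of a van Krevelen table."""
    if vk.empty:
        raise ValueError("cannot average an empty point set")
    w = vk["intensity"].to_numpy()
    return TrendPoint(
        time_h=float(vk["time_h"].iloc[0]),
        h_c=float(np.average(vk["h_c"], weights=w)),
        o_c=float(np.average(vk["o_c"], weights=w)),
    )


def trend_regression(points: Sequence[TrendPoint]) -> dict[str, float]:
    """OLS trends of the weighted-mean composition trajectory.

    Fits the trajectory in van Krevelen space (H/C on O/C) — the plane in
    which reaction trajectories are usually drawn — and additionally each
    ratio against time. Raises on fewer than two points or a degenerate
    (constant) predictor for the van Krevelen fit.
    """
    if len(points) < 2:
        raise ValueError("need at least two time points for a regression")
    t = np.array([p.time_h for p in points])
    hc = np.array([p.h_c for p in points])
    oc = np.array([p.o_c for p in points])
    if np.ptp(t) == 0:
        raise ValueError("all time points identical")
    out: dict[str, float] = {}
    out["hc_vs_time_slope"], out["hc_vs_time_intercept"] = np.polyfit(t, hc, 1)
    out["oc_vs_time_slope"], out["oc_vs_time_intercept"] = np.polyfit(t, oc, 1)
    if np.ptp(oc) == 0:
        raise ValueError("degenerate van Krevelen predictor (constant O/C)")
    out["hc_vs_oc_slope"], out["hc_vs_oc_intercept"] = np.polyfit(oc, hc, 1)
    return {k: float(v) for k, v in out.items()}


def carbon_histogram(classified: pd.DataFrame) -> dict[int, float]:
    """Relative intensity share per carbon number.

    Shares sum to one over the supplied table (typically the MRPs of one
    system); invariant under rescaling of all intensities.
    """
    if classified.empty:
        return {}
    comps = classified["formula"].map(ElementalComposition.parse)
    carbons = pd.Series([c.c for c in comps], index=classified.index)
    sums = classified.groupby(carbons)["intensity"].sum()
    total = sums.sum()
    return {int(c): float(v / total) for c, v in sums.items()}


def nitrogen_parity_summary(classified: pd.DataFrame) -> dict[str, float]:
    """Counts and intensity shares of odd- vs even-nitrogen formulas."""
    if classified.empty:
        return {
            "n_odd": 0, "n_even": 0,
            "odd_intensity_share": 0.0, "even_intensity_share": 0.0,
        }
    comps = classified["formula"].map(ElementalComposition.parse)
    odd = pd.Series([c.n % 2 == 1 for c in comps], index=classified.index)
    total = classified["intensity"].sum()
    odd_int = classified.loc[odd, "intensity"].sum()
    return {
        "n_odd": int(odd.sum()),
        "n_even": int((~odd).sum()),
        "odd_intensity_share": float(odd_int / total),
        "even_intensity_share": float((total - odd_int) / total),
    }
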