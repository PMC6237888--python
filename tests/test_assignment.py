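"""Formula assignment: enumeration, network propagation, isotope checks,
replicate consensus."""

import random

import numpy as np
import pandas as pd
import pytest

from maillardnet.assignment import (
    DEFAULT_TRANSFORMATIONS,
    ElementBounds,
    Peak,
    PeakList,
    assignments_to_table,
    chemical_filter,
    condensation_delta,
    enumerate_candidates,
    network_annotate,
    neutral_mass_from_mz,
    replicate_consensus,
    validate_isotopes,
)
from maillardnet.chemcore import (
    ElementalComposition,
    isotope_fine_structure,
    monoisotopic_mass,
)

# Independent atomic-mass table (typed from the NIST/CODATA listing) used
# only by the brute-force oracle below, keeping it decoupled from the
# package's own constants.
ORACLE_MASS = {
    "c": 12.0,
    "h": 1.00782503207,
    "n": 14.0030740048,
    "o": 15.9949146196,
    "s": 31.97207100,
}
ORACLE_PROTON = 1.007276467


def oracle_mass(c, h, n, o, s):
    return (c * ORACLE_MASS["c"] + h * ORACLE_MASS["h"]
            + n * ORACLE_MASS["n"] + o * ORACLE_MASS["o"]
            + s * ORACLE_MASS["s"])


def brute_force_enumeration(neutral_mass, bounds: ElementBounds, ppm_tol):
    """Plain nested-loop enumeration, the oracle for enumerate_candidates."""
    window = neutral_mass * ppm_tol * 1e-6
    out = set()
    for c in range(bounds.c[0], bounds.c[1] + 1):
        for n in range(bounds.n[0], bounds.n[1] + 1):
            for o in range(bounds.o[0], bounds.o[1] + 1):
                for s in range(bounds.s[0], bounds.s[1] + 1):
                    rest = neutral_mass - oracle_mass(c, 0, n, o, s)
                    for h in range(bounds.h[0], bounds.h[1] + 1):
                        m = oracle_mass(c, h, n, o, s)
                        if abs(m - neutral_mass) <= window:
                            out.add(ElementalComposition(c, h, n, o, s))
                        if m > neutral_mass + window:
                            break
    return out


def test_neutral_mass_from_mz():
    assert neutral_mass_from_mz(0.0 + 1e-12) == pytest.approx(1.007276467)
    assert neutral_mass_from_mz(149.045547) == pytest.approx(150.052823, abs=1e-5)
    assert neutral_mass_from_mz(206.067011) == pytest.approx(207.074287, abs=1e-5)
    with pytest.raises(ValueError):
        neutral_mass_from_mz(200.0, charge=2)


class TestEnumerateCandidates:
    small = ElementBounds(c=(1, 15), h=(1, 30), n=(0, 3), o=(0, 10), s=(0, 2))

    @pytest.mark.parametrize("target", ["C7H13NO6", "C5H10O5", "C8H15NO6S"])
    def test_matches_brute_force(self, target):
        mass = monoisotopic_mass(ElementalComposition.parse(target))
        for tol in (0.2, 5.0):
            got = {c for c, _ in enumerate_candidates(mass, self.small, tol)}
            assert got == brute_force_enumeration(mass, self.small, tol)
            assert ElementalComposition.parse(target) in got

    def test_random_masses_match_brute_force(self):
        rng = random.Random(1)
        for _ in range(15):
            mass = rng.uniform(100.0, 450.0)
            got = {c for c, _ in enumerate_candidates(mass, self.small, 3.0)}
            assert got == brute_force_enumeration(mass, self.small, 3.0)

    def test_zero_tolerance_limit(self):
        mass = monoisotopic_mass(ElementalComposition.parse("C7H13NO6"))
        got = [c for c, e in enumerate_candidates(mass, self.small, 1e-7)]
        assert got == [ElementalComposition.parse("C7H13NO6")]

    def test_below_lightest_candidate(self):
        assert enumerate_candidates(10.0, ElementBounds(), 0.2) == []

    def test_sorted_by_abs_error(self):
        mass = monoisotopic_mass(ElementalComposition.parse("C12H21NO10"))
        cands = enumerate_candidates(mass, ElementBounds(), 5.0)
        errs = [abs(e) for _, e in cands]
        assert errs == sorted(errs)


@pytest.mark.parametrize(
    "formula,ok",
    [
        ("C7H13NO6", True),
        ("C2H5NO2", True),
        ("C5H14O", False),   # DBE = -1.5
        ("C2H8O", False),    # H/C = 4
        ("CH2O5", False),    # O/C > 2
        ("C3H8NO2", False),  # half-integral DBE (odd H+N)
    ],
)
def test_chemical_filter(formula, ok):
    assert chemical_filter(ElementalComposition.parse(formula)) is ok


def _exact_peaklist(formulas, intensities=None, **kwargs):
    peaks = []
    for i, f in enumerate(formulas):
        comp = ElementalComposition.parse(f)
        mz = monoisotopic_mass(comp) - 1.007276467
        inten = intensities[i] if intensities else 1e6
        peaks.append(Peak(mz=mz, intensity=inten, snr=inten / 1e4))
    defaults = dict(sample_id="t", system="ribose-glycine", time_h=10.0,
                    replicate=1)
    defaults.update(kwargs)
    return PeakList(peaks=peaks, **defaults)


RIBOSE = ElementalComposition.parse("C5H10O5")
GLYCINE = ElementalComposition.parse("C2H5NO2")
GLY_ARP = ElementalComposition.parse("C7H13NO6")
GLY_DELTAS = DEFAULT_TRANSFORMATIONS + (condensation_delta(GLYCINE),)


class TestNetworkAnnotate:
    def test_seeded_chain_all_assigned(self):
        pl = _exact_peaklist(["C5H10O5", "C2H5NO2", "C7H13NO6", "C7H11NO5"])
        out = network_annotate(pl, {RIBOSE, GLYCINE, GLY_ARP}, GLY_DELTAS)
        assigned = {a.composition.hill(): a for a in out if a.accepted}
        assert set(assigned) == {"C5H10O5", "C2H5NO2", "C7H13NO6", "C7H11NO5"}
        assert all(a.network_support >= 1 for a in assigned.values())
        assert all(abs(a.error_ppm) < 1e-6 for a in assigned.values())

    def test_empty_peaklist(self):
        pl = PeakList(sample_id="e", system="s", time_h=0.0, replicate=1,
                      peaks=[])
        assert network_annotate(pl, {RIBOSE}, GLY_DELTAS) == []

    def test_reachable_candidate_beats_closer_unreachable(self):
        """When two candidates share the ppm window, network support decides."""
        target = ElementalComposition.parse("C7H11NO5")  # ARP - H2O
        m_t = monoisotopic_mass(target)
        # find a chemically plausible decoy nearby and centre the peak so
        # the decoy is strictly closer in mass
        decoy = None
        for comp, err in enumerate_candidates(m_t, ElementBounds(), 40.0):
            if comp != target and chemical_filter(comp):
                decoy = comp
                break
        assert decoy is not None
        m_d = monoisotopic_mass(decoy)
        peak_mass = m_t + 0.6 * (m_d - m_t)  # decoy closer than target
        wide = ElementBounds(
            ppm_tolerance=abs(m_d - m_t) / m_t * 1e6 * 2,
            hard_ppm_cut=abs(m_d - m_t) / m_t * 1e6 * 2,
        )
        pl = PeakList(
            sample_id="t", system="s", time_h=0.0, replicate=1,
            peaks=[
                Peak(mz=monoisotopic_mass(GLY_ARP) - 1.007276467,
                     intensity=1e7, snr=1e3),
                Peak(mz=peak_mass - 1.007276467, intensity=1e6, snr=100.0),
            ],
        )
        out = network_annotate(pl, {GLY_ARP}, GLY_DELTAS, bounds=wide)
        got = {a.composition for a in out if a.accepted}
        assert target in got
        assert decoy not in got

    def test_fallback_unique_candidate(self):
        """A peak unreachable from seeds still gets its unambiguous formula."""
        pl = _exact_peaklist(["C5H10O5", "C12H22O11"])  # sucrose: not 1 delta away
        out = network_annotate(pl, {RIBOSE}, GLY_DELTAS)
        assigned = {a.composition.hill() for a in out if a.accepted}
        assert "C12H22O11" in assigned

    def test_order_invariance(self):
        formulas = ["C5H10O5", "C2H5NO2", "C7H13NO6", "C7H11NO5", "C7H9NO4"]
        pl1 = _exact_peaklist(formulas)
        pl2 = _exact_peaklist(list(reversed(formulas)))
        out1 = network_annotate(pl1, {RIBOSE, GLYCINE}, GLY_DELTAS)
        out2 = network_annotate(pl2, {RIBOSE, GLYCINE}, GLY_DELTAS)
        as1 = {(a.peak.mz, a.composition) for a in out1}
        as2 = {(a.peak.mz, a.composition) for a in out2}
        assert as1 == as2

    def test_snr_floor_ignores_weak_peaks(self):
        pl = _exact_peaklist(["C5H10O5", "C7H13NO6"], intensities=[1e6, 2e4])
        out = network_annotate(pl, {RIBOSE, GLYCINE, GLY_ARP}, GLY_DELTAS,
                               snr_floor=4.0)
        assert len(out) == 1  # the snr=2 peak is not even reported

    def test_accepted_within_hard_cut(self, noisy_run):
        cfg, out_dir = noisy_run
        tables = sorted((out_dir / "assign").glob("*.csv"))[:10]
        for path in tables:
            t = pd.read_csv(path)
            acc = t[t["accepted"] == True]  # noqa: E712
            assert (acc["error_ppm"].abs() <= 0.5 + 1e-9).all()


class TestValidateIsotopes:
    def _spectrum_with_isotopologues(self, formula, drop=()):
        comp = ElementalComposition.parse(formula)
        mono_mz = monoisotopic_mass(comp) - 1.007276467
        peaks = [Peak(mz=mono_mz, intensity=1e7, snr=1e3)]
        for p in isotope_fine_structure(comp):
            if p.label in ("13C1", "34S1") and p.label not in drop:
                peaks.append(
                    Peak(mz=mono_mz + p.mass_shift,
                         intensity=1e7 * p.abundance,
                         snr=1e3 * p.abundance)
                )
        pl = PeakList(sample_id="t", system="s", time_h=0.0, replicate=1,
                      peaks=peaks)
        out = network_annotate(pl, {comp}, GLY_DELTAS)
        (assignment,) = [a for a in out if a.composition == comp]
        return assignment, pl

    def test_complete_pattern_validates(self):
        a, pl = self._spectrum_with_isotopologues("C7H13NO6")
        assert validate_isotopes(a, pl) is True

    def test_missing_13c_fails(self):
        a, pl = self._spectrum_with_isotopologues("C7H13NO6", drop=("13C1",))
        assert validate_isotopes(a, pl) is False

    def test_sulfur_needs_both_peaks(self):
        a, pl = self._spectrum_with_isotopologues("C8H15NO6S", drop=("13C1",))
        assert validate_isotopes(a, pl) is False
        a, pl = self._spectrum_with_isotopologues("C8H15NO6S")
        assert validate_isotopes(a, pl) is True

    def test_wrong_intensity_ratio_fails(self):
        a, pl = self._spectrum_with_isotopologues("C7H13NO6")
        bad = [
            Peak(mz=p.mz, intensity=p.intensity * 3.0, snr=p.snr)
            if i == len(pl.peaks) - 1 else p
            for i, p in enumerate(pl.peaks)
        ]
        pl2 = PeakList(sample_id="t", system="s", time_h=0.0, replicate=1,
                       peaks=bad)
        assert validate_isotopes(a, pl2) is False


class TestReplicateConsensus:
    def _table(self, formulas, replicate):
        pl = _exact_peaklist(formulas, replicate=replicate)
        out = network_annotate(pl, {RIBOSE, GLYCINE, GLY_ARP}, GLY_DELTAS)
        return assignments_to_table(pl, out)

    def test_three_of_three_kept_two_of_three_dropped(self):
        tables = [
            self._table(["C5H10O5", "C7H13NO6"], 1),
            self._table(["C5H10O5", "C7H13NO6"], 2),
            self._table(["C5H10O5"], 3),
        ]
        out = replicate_consensus(tables)
        assert set(out["formula"]) == {"C5H10O5"}
        assert (out["n_replicates"] == 3).all()

    def test_single_replicate_pass_through(self):
        out = replicate_consensus([self._table(["C5H10O5", "C7H13NO6"], 1)])
        assert set(out["formula"]) == {"C5H10O5", "C7H13NO6"}

    def test_consensus_statistics(self):
        t1 = self._table(["C5H10O5"], 1)
        t2 = self._table(["C5H10O5"], 2)
        t1.loc[0, "intensity"] = 100.0
        t2.loc[0, "intensity"] = 300.0
        out = replicate_consensus([t1, t2])
        assert out.loc[0, "intensity"] == pytest.approx(200.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            replicate_consensus([])
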