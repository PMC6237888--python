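"""Core compositions, pathway roots and general-scheme detection."""

import pandas as pd
import pytest

from maillardnet.chemcore import CompositionError, ElementalComposition
from maillardnet.pathways import (
    AMINO_ACIDS,
    SUGARS,
    build_transformation_network,
    core_of,
    dehydration_series,
    detect_general_scheme,
    pathway_roots,
    redox_partners,
    scheme_intensity_share,
)

from conftest import classified_table, planted_scheme_cores

EC = ElementalComposition.parse
RIBOSE = SUGARS["ribose"]


class TestCoreOf:
    def test_glycine_arp_core(self):
        core = core_of(EC("C7H13NO6"), AMINO_ACIDS["glycine"])
        assert core == EC("C7H12NO6")

    def test_isoleucine_same_core(self):
        core = core_of(EC("C11H21NO6"), AMINO_ACIDS["isoleucine"])
        assert core == EC("C7H12NO6")

    def test_round_trip(self):
        for aa_name in ("glycine", "isoleucine", "lysine", "cysteine"):
            aa = AMINO_ACIDS[aa_name]
            formula = pathway_roots(RIBOSE, aa)["ARP"]
            assert core_of(formula, aa) + aa.side_chain == formula

    def test_residue_not_contained_raises(self):
        with pytest.raises(CompositionError):
            core_of(EC("C5H10O5"), AMINO_ACIDS["lysine"])


class TestPathwayRoots:
    """Carbon counts of the 1:1 and 2:1 condensation products."""

    @pytest.mark.parametrize(
        "aa,arp_c,dk_c",
        [("glycine", 7, 12), ("isoleucine", 11, 16), ("lysine", 11, 16),
         ("cysteine", 8, 13)],
    )
    def test_carbon_counts(self, aa, arp_c, dk_c):
        roots = pathway_roots(RIBOSE, AMINO_ACIDS[aa])
        assert roots["ARP"].c == arp_c == RIBOSE.c + AMINO_ACIDS[aa].composition.c
        assert roots["diketosamine"].c == dk_c == 2 * RIBOSE.c + AMINO_ACIDS[aa].composition.c

    def test_glycine_formulas(self):
        roots = pathway_roots(RIBOSE, AMINO_ACIDS["glycine"])
        assert roots["ARP"] == EC("C7H13NO6")
        assert roots["diketosamine"] == EC("C12H21NO10")
        assert roots["C2_root"] == EC("C10H17NO8")
        assert roots["C3_root"] == EC("C9H15NO7")


class TestTransformationNetwork:
    def test_dehydration_edge(self):
        edges = build_transformation_network({EC("C7H13NO6"), EC("C7H11NO5")})
        named = {(e.source.hill(), e.target.hill(), e.delta_name)
                 for e in edges}
        assert ("C7H13NO6", "C7H11NO5", "dehydration") in named

    def test_reduction_edge(self):
        edges = build_transformation_network({EC("C7H11NO5"), EC("C7H13NO5")})
        named = {(e.source.hill(), e.target.hill(), e.delta_name)
                 for e in edges}
        assert ("C7H11NO5", "C7H13NO5", "reduction") in named
        assert ("C7H13NO5", "C7H11NO5", "oxidation") in named

    def test_disjoint_masses_no_edges(self):
        assert build_transformation_network({EC("C7H13NO6"), EC("C19H30O2")}) == []


class TestDehydrationSeries:
    CHAIN = [EC("C7H13NO6"), EC("C7H11NO5"), EC("C7H9NO4"), EC("C7H7NO3")]

    def test_full_chain(self):
        assert dehydration_series(self.CHAIN, self.CHAIN[0], 3) == self.CHAIN

    def test_missing_root_empty(self):
        assert dehydration_series(self.CHAIN[1:], self.CHAIN[0], 3) == []

    def test_chain_stops_at_gap(self):
        gapped = [self.CHAIN[0], self.CHAIN[1], self.CHAIN[3]]  # no C7H9NO4
        assert dehydration_series(gapped, self.CHAIN[0], 3) == self.CHAIN[:2]

    def test_isolated_root_is_singleton(self):
        assert dehydration_series([self.CHAIN[0]], self.CHAIN[0], 3) == [self.CHAIN[0]]


def test_redox_partners():
    pool = [EC("C7H11NO5"), EC("C7H13NO5"), EC("C7H9NO5")]
    out = redox_partners(pool, EC("C7H11NO5"))
    assert out["reduced"] == EC("C7H13NO5")
    assert out["oxidized"] == EC("C7H9NO5")
    out = redox_partners(pool[:1], EC("C7H11NO5"))
    assert out["reduced"] is None and out["oxidized"] is None


class TestGeneralScheme:
    def _detect(self, noiseless_run, **kwargs):
        cfg, out = noiseless_run
        sim = cfg.simulation_config()
        tables = {
            f"ribose-{aa}": classified_table(out, f"ribose-{aa}")
            for aa in sim.amino_acids
        }
        specs = {f"ribose-{aa}": AMINO_ACIDS[aa] for aa in sim.amino_acids}
        nodes, unexplained = detect_general_scheme(
            tables, specs, RIBOSE, **kwargs
        )
        return tables, specs, nodes, unexplained

    def test_all_planted_cores_recovered_with_labels(self, noiseless_run):
        cfg, _ = noiseless_run
        expected = planted_scheme_cores(cfg)
        _, _, nodes, _ = self._detect(noiseless_run)
        found = {(n.core, n.pathway) for n in nodes}
        missing = set(expected) - found
        assert not missing
        # pathway labels are unambiguous: no planted core under a wrong label
        by_core = {}
        for core, pathway in found:
            by_core.setdefault(core, set()).add(pathway)
        for (core, pathway) in expected:
            assert by_core[core] == {pathway}

    def test_presence_threshold(self, noiseless_run):
        _, _, nodes, _ = self._detect(noiseless_run)
        assert nodes, "scheme detection found nothing"
        assert all(n.n_systems >= 3 for n in nodes)
        strict, _, nodes4, _ = (*self._detect(noiseless_run, min_systems=4),)
        assert all(n.n_systems == 4 for n in nodes4)
        assert len(nodes4) <= len(nodes)

    def test_residue_round_trip(self, noiseless_run):
        """core + R reconstructs an observed formula in every flagged system."""
        tables, specs, nodes, _ = self._detect(noiseless_run)
        violations = 0
        for node in nodes:
            for system, present in node.present_in.items():
                if not present:
                    continue
                formula = node.core + specs[system].side_chain
                if formula.hill() not in set(tables[system]["formula"]):
                    violations += 1
        assert violations == 0

    def test_system_order_invariance(self, noiseless_run):
        cfg, out = noiseless_run
        sim = cfg.simulation_config()
        names = [f"ribose-{aa}" for aa in sim.amino_acids]
        tables = {n: classified_table(out, n) for n in names}
        specs = {n: AMINO_ACIDS[n.split("-")[1]] for n in names}
        nodes_fwd, _ = detect_general_scheme(tables, specs, RIBOSE)
        rev = list(reversed(names))
        nodes_rev, _ = detect_general_scheme(
            {n: tables[n] for n in rev}, {n: specs[n] for n in rev}, RIBOSE
        )
        key = lambda n: (n.core, n.pathway, n.step, n.redox)
        assert sorted(map(key, nodes_fwd)) == sorted(map(key, nodes_rev))

    def test_nodes_reachable_from_roots(self, noiseless_run):
        """Independent graph check: every scheme node is reachable from a
        pathway root core through declared deltas (networkx route)."""
        import networkx as nx

        from maillardnet.chemcore import AA_BACKBONE
        from maillardnet.pathways import (
            AminoAcidSpec,
            build_transformation_network,
        )

        _, _, nodes, _ = self._detect(noiseless_run)
        cores = {n.core for n in nodes}
        root_cores = set(
            pathway_roots(RIBOSE, AminoAcidSpec("bb", AA_BACKBONE)).values()
        )
        g = nx.DiGraph()
        g.add_nodes_from(cores | root_cores)
        for e in build_transformation_network(cores | root_cores):
            g.add_edge(e.source, e.target)
        reachable = set()
        for root in root_cores:
            reachable |= nx.descendants(g, root) | {root}
        assert cores <= reachable

    def test_too_few_systems_raises(self, noiseless_run):
        cfg, out = noiseless_run
        tables = {"ribose-glycine": classified_table(out, "ribose-glycine")}
        with pytest.raises(ValueError):
            detect_general_scheme(
                tables, {"ribose-glycine": AMINO_ACIDS["glycine"]}, RIBOSE
            )


class TestSchemeIntensityShare:
    def _mrp_table(self):
        return pd.DataFrame([
            {"system": "s", "formula": "C7H13NO6", "intensity": 60.0,
             "snr": 100.0, "product_class": "MRP"},
            {"system": "s", "formula": "C7H11NO5", "intensity": 40.0,
             "snr": 100.0, "product_class": "MRP"},
        ])

    def test_full_and_empty_scheme(self, noiseless_run):
        from maillardnet.pathways import SchemeNode
        table = self._mrp_table()
        gly = AMINO_ACIDS["glycine"]
        all_nodes = [
            SchemeNode(core=EC("C7H12NO6"), pathway="ARP_DEGRADATION",
                       step=0, redox=0),
            SchemeNode(core=EC("C7H10NO5"), pathway="ARP_DEGRADATION",
                       step=1, redox=0),
        ]
        assert scheme_intensity_share(all_nodes, table, gly) == pytest.approx(1.0)
        assert scheme_intensity_share([], table, gly) == 0.0
        assert scheme_intensity_share(all_nodes[:1], table, gly) == pytest.approx(0.6)
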