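"""Stage drivers tying simulation, assignment, classification, descriptors
and scheme detection into one reproducible pipeline.

Each stage reads and writes plain CSV/YAML/JSON, echoes the effective
configuration into its output directory, and logs per-stage counts. The
functions here are what both the command-line interface and the test suite
drive.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .assignment import (
    DEFAULT_TRANSFORMATIONS,
    assignments_to_table,
    condensation_delta,
    network_annotate,
    replicate_consensus,
    validate_isotopes,
)
from .chemcore import ElementalComposition
from .classification import class_counts_over_time, classify_table
from .config import PipelineConfig
from .descriptors import (
    carbon_histogram,
    nitrogen_parity_summary,
    trend_regression,
    van_krevelen,
    weighted_mean_ratios,
)
from .io import load_peaklist, read_manifest, write_manifest, write_peaklist_csv
from .pathways import AMINO_ACIDS, SUGARS, detect_general_scheme, \
    build_transformation_network, scheme_intensity_share
from .synthetic import (
    SimulationConfig,
    generate_reaction_network,
    simulate_blanks,
    simulate_peaklist,
    write_truth_table,
)

log = logging.getLogger("maillardnet")


def _mixture_system(cfg: SimulationConfig, amino_acid: str) -> str:
    return f"{cfg.sugar}-{amino_acid}"


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Simulate the full study: peak lists, manifest and truth tables."""
    out = Path(out_dir)
    (out / "peaklists").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    config.echo(out)
    sim = config.simulation_config()
    manifest: dict[str, dict] = {}
    n_peaks = 0
    for ai, amino_acid in enumerate(sim.amino_acids):
        truth = generate_reaction_network(sim, amino_acid)
        write_truth_table(truth, out / "truth" / f"{amino_acid}.csv")
        system = _mixture_system(sim, amino_acid)
        for ti in range(len(sim.time_points_h)):
            for rep in range(1, sim.replicates + 1):
                sid = f"{system}-t{ti}-r{rep}"
                pl = simulate_peaklist(
                    truth, sim, rep, time_index=ti, sample_id=sid,
                    system=system, sugar=sim.sugar, amino_acid=amino_acid,
                    sample_key=ai,
                )
                write_peaklist_csv(pl, out / "peaklists" / f"{sid}.csv")
                n_peaks += len(pl.peaks)
                manifest[sid] = {
                    "file": f"peaklists/{sid}.csv", "system": system,
                    "sugar": sim.sugar, "amino_acid": amino_acid,
                    "time_h": sim.time_points_h[ti], "replicate": rep,
                    "is_blank": False,
                }
                sugar_blank, aa_blank = simulate_blanks(
                    truth, sim, rep, time_index=ti, amino_acid=amino_acid,
                    sample_key=ai,
                )
                # the sugar blank is shared across systems; write it once
                for blank in (sugar_blank, aa_blank):
                    if blank.sample_id in manifest:
                        continue
                    write_peaklist_csv(
                        blank, out / "peaklists" / f"{blank.sample_id}.csv"
                    )
                    n_peaks += len(blank.peaks)
                    manifest[blank.sample_id] = {
                        "file": f"peaklists/{blank.sample_id}.csv",
                        "system": blank.system,
                        "sugar": blank.sugar,
                        "amino_acid": blank.amino_acid,
                        "time_h": sim.time_points_h[ti], "replicate": rep,
                        "is_blank": True,
                    }
    write_manifest(manifest, out / "manifest.yaml")
    log.info(
        "simulate: %d samples, %d peaks written", len(manifest), n_peaks
    )
    return out


def _seeds_and_deltas(cfg: SimulationConfig, entry: Mapping) -> tuple[set, tuple]:
    """Seed formulas and transformation set appropriate for one sample."""
    sugar = SUGARS[entry["sugar"]] if entry.get("sugar") else None
    aa = (
        AMINO_ACIDS[entry["amino_acid"]].composition
        if entry.get("amino_acid") else None
    )
    deltas = list(DEFAULT_TRANSFORMATIONS)
    seeds = set()
    if sugar is not None:
        seeds.add(sugar)
    if aa is not None:
        seeds.add(aa)
    if sugar is not None and aa is not None:
        water = ElementalComposition(h=2, o=1)
        seeds.add(sugar + aa - water)  # the ARP
        deltas.append(condensation_delta(aa))
    return seeds, tuple(deltas)


def run_assign(
    config: PipelineConfig, sample_dir: str | Path, out_dir: str | Path
) -> Path:
    """Assign formulas to every sample in a simulated/measured directory."""
    sample_dir = Path(sample_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out)
    sim = config.simulation_config()
    bounds = config.element_bounds()
    manifest = read_manifest(sample_dir / "manifest.yaml")
    n_assigned = 0
    for sid, entry in manifest.items():
        pl = load_peaklist(sid, entry, sample_dir)
        seeds, deltas = _seeds_and_deltas(sim, entry)
        assignments = network_annotate(
            pl, seeds, deltas, bounds,
            snr_floor=config.assignment.snr_floor,
        )
        for a in assignments:
            if a.accepted:
                a.isotope_validated = validate_isotopes(
                    a, pl,
                    ppm_tol=config.assignment.isotope_ppm_tol,
                    rel_int_tol=config.assignment.isotope_rel_int_tol,
                )
        table = assignments_to_table(pl, assignments)
        table.to_csv(out / f"{sid}.csv", index=False, float_format="%.10g")
        n_assigned += int(table["accepted"].sum())
    log.info(
        "assign: %d samples, %d accepted assignments",
        len(manifest), n_assigned,
    )
    return out


def _consensus_by_condition(
    manifest: Mapping[str, dict], assign_dir: Path
) -> dict[tuple[str, float], pd.DataFrame]:
    """Replicate-consensus table per (system, time) condition."""
    groups: dict[tuple[str, float], list[pd.DataFrame]] = {}
    for sid, entry in sorted(manifest.items()):
        path = assign_dir / f"{sid}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing formula table {path}")
        table = pd.read_csv(path)
        table["formula"] = table["formula"].fillna("").astype(str)
        key = (entry["system"], entry["time_h"])
        groups.setdefault(key, []).append(table)
    return {key: replicate_consensus(tabs) for key, tabs in groups.items()}


def run_classify(
    config: PipelineConfig,
    sample_dir: str | Path,
    assign_dir: str | Path,
    out_dir: str | Path,
) -> Path:
    """Consensus + blank-based classification per system and time point."""
    sample_dir, assign_dir, out = Path(sample_dir), Path(assign_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out)
    sim = config.simulation_config()
    manifest = read_manifest(sample_dir / "manifest.yaml")
    consensus = _consensus_by_condition(manifest, assign_dir)
    counts_frames = []
    for amino_acid in sim.amino_acids:
        system = _mixture_system(sim, amino_acid)
        aa_comp = AMINO_ACIDS[amino_acid].composition
        precursors = [sim.sugar_composition.hill(), aa_comp.hill()]
        for time_h in sim.time_points_h:
            mixture = consensus.get((system, time_h))
            if mixture is None:
                continue
            sugar_blank = consensus.get((f"{sim.sugar}-blank", time_h))
            aa_blank = consensus.get((f"{amino_acid}-blank", time_h))
            classified = classify_table(
                mixture, sugar_blank, aa_blank, precursors
            )
            classified.to_csv(
                out / f"{system}-t{time_h:g}.csv", index=False,
                float_format="%.10g",
            )
            counts_frames.append(classified)
    counts = class_counts_over_time(counts_frames)
    counts.to_csv(out / "class_counts.csv", index=False)
    log.info(
        "classify: %d conditions; class counts:\n%s",
        len(counts_frames),
        counts.groupby("product_class")["n_formulas"].sum().to_string(),
    )
    return out


def _classified_paths(classified_dir: Path) -> list[Path]:
    return sorted(
        p for p in classified_dir.glob("*.csv")
        if p.name != "class_counts.csv"
    )


def run_describe(
    config: PipelineConfig, classified_dir: str | Path, out_dir: str | Path
) -> Path:
    """Descriptor tables: van Krevelen points, trends, carbon histograms,
    nitrogen parity."""
    classified_dir, out = Path(classified_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out)
    trend_rows, carbon_rows, parity_rows = [], [], []
    regressions: dict[str, dict[str, float]] = {}
    by_system: dict[str, list] = {}
    for path in _classified_paths(classified_dir):
        table = pd.read_csv(path, keep_default_na=False)
        if table.empty:
            continue
        mrps = table[table["product_class"] == "MRP"]
        if mrps.empty:
            continue
        vk = van_krevelen(mrps)
        vk.to_csv(out / f"vk-{path.stem}.csv", index=False,
                  float_format="%.10g")
        system = str(table["system"].iloc[0])
        point = weighted_mean_ratios(vk)
        trend_rows.append(
            {"system": system, "time_h": point.time_h,
             "h_c": point.h_c, "o_c": point.o_c}
        )
        by_system.setdefault(system, []).append(point)
        for c, share in sorted(carbon_histogram(mrps).items()):
            carbon_rows.append(
                {"system": system, "time_h": point.time_h,
                 "carbon": c, "intensity_share": share}
            )
        parity = nitrogen_parity_summary(mrps)
        parity_rows.append({"system": system, "time_h": point.time_h, **parity})
    for system, points in sorted(by_system.items()):
        if len(points) >= 2:
            points = sorted(points, key=lambda p: p.time_h)
            try:
                regressions[system] = trend_regression(points)
            except ValueError:
                pass  # degenerate trajectory; nothing to report
    pd.DataFrame(trend_rows).to_csv(
        out / "trends.csv", index=False, float_format="%.10g"
    )
    pd.DataFrame(carbon_rows).to_csv(
        out / "carbon_histogram.csv", index=False, float_format="%.10g"
    )
    pd.DataFrame(parity_rows).to_csv(
        out / "nitrogen_parity.csv", index=False, float_format="%.10g"
    )
    (out / "trend_regressions.json").write_text(
        json.dumps(regressions, indent=2, sort_keys=True) + "\n"
    )
    log.info("describe: %d samples described", len(trend_rows))
    return out


def run_pathways(
    config: PipelineConfig, classified_dir: str | Path, out_dir: str | Path
) -> Path:
    """Detect the general scheme on the final-time classified tables."""
    classified_dir, out = Path(classified_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out)
    sim = config.simulation_config()
    t_final = sim.time_points_h[-1]
    tables, specs = {}, {}
    for amino_acid in sim.amino_acids:
        system = _mixture_system(sim, amino_acid)
        path = classified_dir / f"{system}-t{t_final:g}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing classified table {path}")
        tables[system] = pd.read_csv(path, keep_default_na=False)
        specs[system] = AMINO_ACIDS[amino_acid]
    nodes, unexplained = detect_general_scheme(
        tables, specs, sim.sugar_composition,
        min_systems=config.scheme.min_systems,
        min_snr=config.scheme.min_snr,
    )
    shares = {
        system: scheme_intensity_share(nodes, tables[system], specs[system])
        for system in sorted(tables)
    }
    report = {
        "nodes": [
            {
                "core": n.core.hill(),
                "pathway": n.pathway,
                "step": n.step,
                "redox": n.redox,
                "present_in": n.present_in,
                "intensity_share": n.intensity_share,
            }
            for n in nodes
        ],
        "unexplained_cores": [c.hill() for c in unexplained],
        "explained_intensity_share": shares,
    }
    (out / "scheme.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    edges = build_transformation_network({n.core for n in nodes})
    pd.DataFrame(
        [
            {"source": e.source.hill(), "target": e.target.hill(),
             "delta": e.delta_name}
            for e in edges
        ],
        columns=["source", "target", "delta"],
    ).to_csv(out / "scheme_edges.csv", index=False)
    log.info(
        "pathways: %d scheme nodes, %d unexplained cores, shares %s",
        len(nodes), len(unexplained), shares,
    )
    return out


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Simulate, assign, classify, describe and detect pathways in one go."""
    out = Path(out_dir)
    run_simulate(config, out / "simulate")
    run_assign(config, out / "simulate", out / "assign")
    run_classify(config, out / "simulate", out / "assign", out / "classified")
    run_describe(config, out / "classified", out / "descriptors")
    run_pathways(config, out / "classified", out / "pathways")
    return out
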