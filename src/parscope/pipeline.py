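"""End-to-end pipeline configuration and the truth-scored demo run.

``run_demo`` simulates a sex-chromosome pair, runs every analysis stage
(alignment, boundary calling, gametolog classification, family clustering,
segmentation, scaffold QC, gap counting) and scores each stage against the
generator's ground truth, returning one machine-readable report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .gametolog import (
    IdentityBand,
    cluster_gene_family,
    family_copy_numbers,
    pair_gametologs,
    segment_regions,
)
from .homology import AlignerParams
from .parcall import PabCall, Thresholds, call_pab, par_report
from .scaffoldqc import (
    MarkerMap,
    QcThresholds,
    ScaffoldLayout,
    detect_inversions,
    marker_concordance,
)
from .seqio import GenomicInterval, count_gap_runs
from .simulate import SimulationConfig, simulate_sex_chromosome_pair


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one round-trippable container.

    The default boundary-calling schedule matches the simulation scale
    (100 kb coarse windows refined to 10 kb then 1 kb — one-tenth of the
    1 Mb chromosome-scale window).
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(
        default_factory=lambda: Thresholds(window=100_000, refine_schedule=(10_000, 1_000))
    )
    band: IdentityBand = field(default_factory=IdentityBand)
    qc: QcThresholds = field(default_factory=QcThresholds)
    aligner: AlignerParams = field(default_factory=AlignerParams)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        from .simulate import AmpliconFamily, XdegSegment

        sim_raw = dict(raw.get("simulation", {}))
        if "xdeg_segments" in sim_raw:
            sim_raw["xdeg_segments"] = [
                XdegSegment(s["length"], tuple(s["divergence"]), s["n_genes"])
                for s in sim_raw["xdeg_segments"]
            ]
        if "ampliconic_families" in sim_raw:
            sim_raw["ampliconic_families"] = [
                AmpliconFamily(
                    f["copy_count"],
                    f["unit_length"],
                    tuple(f["within_family_divergence"]),
                    f.get("name", ""),
                )
                for f in sim_raw["ampliconic_families"]
            ]
        if "n_gap_runs" in sim_raw:
            sim_raw["n_gap_runs"] = [tuple(g) for g in sim_raw["n_gap_runs"]]
        if "corruption_ops" in sim_raw:
            sim_raw["corruption_ops"] = [
                tuple(tuple(x) if isinstance(x, list) else x for x in op)
                for op in sim_raw["corruption_ops"]
            ]
        thr_raw = dict(raw.get("thresholds", {}))
        if "refine_schedule" in thr_raw:
            thr_raw["refine_schedule"] = tuple(thr_raw["refine_schedule"])
        return cls(
            simulation=SimulationConfig(**sim_raw),
            thresholds=Thresholds(**thr_raw),
            band=IdentityBand(**raw.get("band", {})),
            qc=QcThresholds(**raw.get("qc", {})),
            aligner=AlignerParams(**raw.get("aligner", {})),
        )


def run_demo(config: PipelineConfig | None = None, seed: int | None = None) -> dict:
    """Simulate, analyse, and score every stage against ground truth.

    Returns a JSON-serialisable report. Deterministic given config and seed.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config.simulation.seed = seed

    sim = simulate_sex_chromosome_pair(config.simulation)
    truth = sim.truth

    # --- boundary ---
    call = call_pab(sim.x, sim.y, config.thresholds, config.aligner)
    boundary_error = abs(call.boundary - truth.pab_position)

    # --- gametolog classification ---
    pairs = pair_gametologs(sim.x_genes, sim.y_genes, config.band)
    pred_gam = {(p.x_gene, p.y_gene) for p in pairs if p.classification == "gametolog"}
    true_gam = {(x, y) for x, y, _ in truth.gametolog_pairs}
    tp = len(pred_gam & true_gam)
    precision = tp / len(pred_gam) if pred_gam else 1.0
    recall = tp / len(true_gam) if true_gam else 1.0
    pred_par_grade = {
        (p.x_gene, p.y_gene) for p in pairs if p.classification == "PAR-grade"
    }
    true_par = {(x, y) for x, y, _ in truth.par_pairs}
    par_grade_ok = pred_par_grade == true_par

    # --- family clustering on unpaired Y genes ---
    paired_y = {p.y_gene for p in pairs}
    unpaired = [g for g in sim.y_genes if g.id not in paired_y]
    assignments = cluster_gene_family(unpaired, config.band.family_cluster_min)
    copies = family_copy_numbers(assignments)
    family_ok = True
    recovered_counts = {}
    for fam, true_n in truth.family_copy_numbers.items():
        members = [g for g, f in truth.family_assignments.items() if f == fam]
        clusters = {assignments.get(m) for m in members}
        if len(clusters) != 1 or None in clusters:
            family_ok = False
            recovered_counts[fam] = None
        else:
            n = copies[clusters.pop()]
            recovered_counts[fam] = n
            if n != true_n:
                family_ok = False

    # --- segmentation ---
    labels = {p.y_gene: p.classification for p in pairs}
    for gid, fam in assignments.items():
        if copies[fam] > 1:
            labels[gid] = "multi-copy"
    par_iv = GenomicInterval("Y", 0, max(call.boundary, 1))
    regions = segment_regions(sim.y_genes, labels, par_iv)
    region_names = [r.name for r in regions]
    true_region_names = [r.name for r in truth.region_map]
    segmentation_ok = region_names == true_region_names

    # --- scaffold QC on the corrupted assembly ---
    qc_result: dict = {}
    if truth.layout is not None:
        layout = ScaffoldLayout(
            [(r.id, len(r), "+") for r in sim.corrupted_contigs]
        )
        maps = []
        for i, t in enumerate(sim.marker_tables, 1):
            frame = t.copy()
            frame["assembly_position"] = [
                truth.layout.project(p) for p in frame["true_position"]
            ]
            frame = frame.dropna(subset=["assembly_position"])
            maps.append(MarkerMap.from_frame(f"RH{i}", frame))
        proposed = detect_inversions(layout, maps)
        truly_inverted = sorted(
            c.contig_id for c in truth.layout.contigs if c.orientation == "-"
        )
        base = {m.map_name: marker_concordance(layout, m) for m in maps}
        qc_result = {
            "proposed_flips": sorted(proposed),
            "true_inversions": truly_inverted,
            "inversion_detection_correct": sorted(proposed) == truly_inverted,
            "baseline_discordance": {k: v[0] for k, v in base.items()},
        }
        if sorted(proposed) == truly_inverted and proposed:
            from .scaffoldqc import _discordance, _flip_positions

            post = {}
            for m in maps:
                pos = m.positions
                for cid in proposed:
                    ci = [c[0] for c in layout.contigs].index(cid)
                    pos = _flip_positions(layout, ci, pos)
                post[m.map_name] = _discordance(pos)
            qc_result["post_flip_discordance"] = post

    # --- gap counting in the called Y PAR ---
    runs = count_gap_runs(sim.y)
    runs_in_par = [r for r in runs if r.interval.end <= call.boundary]
    true_in_par = [g for g in truth.gap_runs if g[0] + g[1] <= truth.pab_position_y]

    report = par_report(call, [g for g in sim.x_genes])

    return {
        "seed": config.simulation.seed,
        "boundary": {
            "called": call.boundary,
            "true": truth.pab_position,
            "error_bp": boundary_error,
            "resolution": call.resolution,
            "found": call.boundary_found,
        },
        "par_genes": {
            "count": len(report.par_genes),
            "nearest_gene": report.nearest_gene,
            "distance_to_boundary_bp": report.distance,
        },
        "gametologs": {
            "predicted": len(pred_gam),
            "true": len(true_gam),
            "precision": precision,
            "recall": recall,
            "par_grade_exact": par_grade_ok,
        },
        "families": {
            "recovered_copy_numbers": recovered_counts,
            "true_copy_numbers": truth.family_copy_numbers,
            "exact": family_ok,
        },
        "segmentation": {
            "region_names": region_names,
            "true_region_names": true_region_names,
            "exact": segmentation_ok,
        },
        "scaffold_qc": qc_result,
        "gaps": {
            "y_par_gap_count": len(runs_in_par),
            "true_y_par_gap_count": len(true_in_par),
            "exact": len(runs_in_par) == len(true_in_par),
        },
    }
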