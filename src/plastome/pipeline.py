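"""End-to-end pipeline over synthetic or user-supplied inputs.

Stages run in dependency order (simulate -> structure/repeats/diversity ->
editing/expression); a run manifest records parameters and input checksums
so that identical manifests reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diversity import call_hotspots, sliding_window_pi, track_to_frame
from .editing import EditingFilterConfig, call_editing_sites, sites_to_frame
from .expression import expression_table
from .genome import gene_census, write_plastome
from .partition import detect_quadripartite, ir_reduced_seq, region_report
from .repeats import find_long_repeats, find_ssrs, ssr_census
from .simulate import SimulationConfig, simulate_counts, simulate_pileups, simulate_plastome_set
from .structure import detect_inversions_between, presence_absence_matrix, ssc_boundary_report

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "structure", "repeats", "diversity", "compare", "editing", "expression")


@dataclass
class PipelineConfig:
    out_dir: str = "plastome_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    min_ir_len: int = 1000
    ssr_min_copies: dict[int, int] = field(
        default_factory=lambda: {1: 7, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}
    )
    repeat_min_len: int = 30
    repeat_max_hamming: int = 3
    window: int = 500
    step: int = 500
    pi_threshold: float = 0.02
    min_coverage: int = 10
    min_replicates: int = 2
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages on a synthetic study set; returns a summary
    dict and writes per-stage TSV reports plus a manifest under
    ``cfg.out_dir``."""
    unknown = set(cfg.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": list(cfg.stages), "seed": cfg.seed}
    sim = simulate_plastome_set(cfg.simulation, seed=cfg.seed)
    plastomes = sim.plastomes
    if "simulate" in cfg.stages:
        for p in plastomes:
            write_plastome(p, out / f"{p.id}.fasta", out / f"{p.id}.gff3")
    partitions = {}
    if "structure" in cfg.stages:
        rows = []
        for p in plastomes:
            part = detect_quadripartite(p, min_ir_len=cfg.min_ir_len)
            partitions[p.id] = part
            rep = region_report(p, part)
            rep.insert(0, "genome", p.id)
            rows.append(rep)
            census = gene_census(p)
            summary.setdefault("gene_census", {})[p.id] = census
        pd.concat(rows).to_csv(out / "region_report.tsv", sep="\t", index=False)
        summary["partitions"] = {
            pid: {
                "lsc": part.lsc_length,
                "ssc": part.ssc_length,
                "ir": part.ir_length,
            }
            for pid, part in partitions.items()
        }
        boundary = ssc_boundary_report(plastomes[0], partitions[plastomes[0].id])
        boundary.to_csv(out / "ssc_boundaries.tsv", sep="\t", index=False)
    if "repeats" in cfg.stages:
        census_all = {}
        for p in plastomes:
            part = partitions.get(p.id) or detect_quadripartite(p, min_ir_len=cfg.min_ir_len)
            reduced = ir_reduced_seq(p, part)
            ssrs = find_ssrs(reduced, cfg.ssr_min_copies)
            census_all[p.id] = ssr_census(ssrs)
            reps = find_long_repeats(reduced, cfg.repeat_min_len, cfg.repeat_max_hamming)
            pd.DataFrame(
                [dataclasses.asdict(r) for r in reps]
            ).to_csv(out / f"{p.id}.repeats.tsv", sep="\t", index=False)
            pd.DataFrame([dataclasses.asdict(r) for r in ssrs]).to_csv(
                out / f"{p.id}.ssrs.tsv", sep="\t", index=False
            )
        summary["ssr_census"] = census_all
    if "diversity" in cfg.stages:
        track = sliding_window_pi(sim.alignment, window=cfg.window, step=cfg.step)
        track_to_frame(track).to_csv(out / "pi_windows.tsv", sep="\t", index=False)
        hot = call_hotspots(track, threshold=cfg.pi_threshold)
        track_to_frame(hot).to_csv(out / "pi_hotspots.tsv", sep="\t", index=False)
        summary["n_hotspots"] = len(hot)
    if "compare" in cfg.stages:
        diffs = detect_inversions_between(plastomes[0], plastomes[-1])
        pd.DataFrame([dataclasses.asdict(d) for d in diffs]).to_csv(
            out / "structural_differences.tsv", sep="\t", index=False
        )
        pam = presence_absence_matrix(plastomes)
        pam.to_csv(out / "ndh_presence.tsv", sep="\t")
        summary["inversions"] = [d.kind for d in diffs]
    if "editing" in cfg.stages:
        pileups, truth_sites = simulate_pileups(cfg.simulation, plastomes[0], seed=cfg.seed)
        sites = call_editing_sites(
            pileups,
            plastomes[0],
            EditingFilterConfig(
                min_coverage=cfg.min_coverage, min_replicates=cfg.min_replicates
            ),
        )
        sites_to_frame(sites).to_csv(out / "editing_sites.tsv", sep="\t", index=False)
        summary["n_editing_sites"] = len(sites)
    if "expression" in cfg.stages:
        counts, groups, _ = simulate_counts(cfg.simulation, plastomes[0], seed=cfg.seed)
        result = expression_table(counts, groups)
        result["normalized"].to_csv(out / "normalized_counts.tsv", sep="\t")
        result["heatmap"].to_csv(out / "log2_heatmap.tsv", sep="\t")
        (out / "expression_dendrogram.nwk").write_text(result["newick"] + "\n")
        summary["expression_leaf_order"] = result["leaf_order"]
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "parameters": {
            "min_ir_len": cfg.min_ir_len,
            "ssr_min_copies": cfg.ssr_min_copies,
            "repeat_min_len": cfg.repeat_min_len,
            "repeat_max_hamming": cfg.repeat_max_hamming,
            "window": cfg.window,
            "step": cfg.step,
            "pi_threshold": cfg.pi_threshold,
            "min_coverage": cfg.min_coverage,
            "min_replicates": cfg.min_replicates,
        },
        "input_checksums": {
            p.id: hashlib.sha256(p.seq.encode()).hexdigest() for p in plastomes
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return summary
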