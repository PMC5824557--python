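"""End-to-end pipeline: genotypes -> QC -> family/sex maps -> consensus ->
synteny blocks -> stats -> feature placement. Every intermediate is written
to the output directory and a run log records parameters and per-stage
locus counts."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as sio
from .config import PipelineConfig
from .consensus import ConsensusMapModel
from .linkmap import LinkageMapModel
from .markerqc import filter_markers
from .synteny import assign_anchors, block_stats, cluster_placements, find_blocks, place_features, union_coverage_pct

logger = logging.getLogger("sibmap")


def _read_family(path: str, cfg: PipelineConfig, family_id: str):
    fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    return sio.read_genotypes(
        path, fmt,
        mother=cfg.paths.get("mother", "mother"),
        father=cfg.paths.get("father", "father"),
        family_id=family_id,
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on the inputs named in ``config.paths`` and return a
    dict of the in-memory artifacts. Any stage error halts the run with the
    stage name attached."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    counts: dict = {}
    stage = "read_genotypes"
    try:
        fam_a = _read_family(config.paths["family_a"], config, "famA")
        fam_b = _read_family(config.paths["family_b"], config, "famB")
        counts["input_loci"] = {"famA": len(fam_a), "famB": len(fam_b)}

        stage = "marker_qc"
        maps = {}
        for fam in (fam_a, fam_b):
            kept, log = filter_markers(
                fam, config.call_rate, config.max_indiv_missing,
                config.maf, config.alpha,
            )
            log.to_csv(out / f"{fam.family_id}_qc_removals.tsv", sep="\t", index=False)
            counts.setdefault("qc_kept_loci", {})[fam.family_id] = len(kept)

            stage = f"map_{fam.family_id}"
            scopes = ["both"] + (["female", "male"] if config.sex_maps else [])
            for scope in scopes:
                res = LinkageMapModel(
                    kept, scope=scope, min_lod=config.min_lod, max_rf=config.max_rf,
                    ripple_window=config.ripple_window,
                    mapping_function=config.mapping_function,
                    gap_cM=config.gap_cM, xo_z=config.xo_z,
                ).fit()
                maps[(fam.family_id, scope)] = res
                sio.write_map(res.map, out / f"{fam.family_id}_{scope}_map.tsv")
                counts.setdefault("mapped_loci", {})[f"{fam.family_id}/{scope}"] = res.map.total_loci

        stage = "consensus"
        cons = ConsensusMapModel(
            maps[("famA", "both")].map, maps[("famB", "both")].map,
            max_rounds=config.rounds, epsilon=config.epsilon,
        ).fit()
        sio.write_map(cons.map, out / "consensus_map.tsv")
        cons.resolution_log.to_csv(out / "conflict_resolution_log.tsv", sep="\t", index=False)
        counts["consensus_loci"] = cons.map.total_loci
        artifacts["consensus"] = cons
        artifacts["maps"] = maps

        stage = "synteny"
        blocks = []
        hits_paths = config.paths.get("hits", {})
        anchors_all = []
        for genome_id, hp in sorted(hits_paths.items()):
            hits = sio.read_hits(hp)
            anchors = assign_anchors(hits, cons.map, genome_id,
                                     config.min_evalue, config.min_bitscore_margin)
            anchors_all.append(anchors)
            b, excl = find_blocks(cons.map, anchors, config.tolerance_frac, config.min_block)
            blocks.extend(b)
            excl.to_csv(out / f"{genome_id}_tolerance_exclusions.tsv", sep="\t", index=False)
        artifacts["blocks"] = blocks
        if blocks:
            sio.write_blocks(blocks, out / "blocks.tsv")
            sio.write_blocks_bed(blocks, out / "blocks.bed")

        stage = "block_stats"
        stats = block_stats(blocks, cons.map)
        extra = {"union_coverage_pct": union_coverage_pct(blocks, cons.map),
                 "map": cons.map.summary_stats()}
        sio.write_stats_json(stats, out / "stats.json", extra)
        sio.stats_to_frame(stats).to_csv(out / "stats.tsv", sep="\t", index=False)
        artifacts["stats"] = stats

        stage = "place_features"
        fh_path = config.paths.get("feature_hits")
        if fh_path:
            import pandas as pd
            fhits = sio.read_hits(fh_path)
            placements, unplaced = place_features(
                fhits, blocks, cons.map, pd.concat(anchors_all) if anchors_all else None,
                config.min_evalue, config.min_bitscore_margin,
            )
            placements.to_csv(out / "placements.tsv", sep="\t", index=False)
            unplaced.to_csv(out / "unplaced_features.tsv", sep="\t", index=False)
            clusters = cluster_placements(placements, config.cluster_gap_cM)
            clusters.to_csv(out / "placement_clusters.tsv", sep="\t", index=False)
            artifacts["placements"] = placements
            artifacts["clusters"] = clusters
            counts["placed_features"] = int(placements["primary"].sum()) if len(placements) else 0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from . import __version__
    run_log = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in config.__dict__.items() if k != "paths"},
        "stage_counts": counts,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str) + "\n")
    artifacts["run_log"] = run_log
    return artifacts
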