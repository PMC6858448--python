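"""End-to-end pipeline orchestration.

Stages (simulate? -> extract -> cluster -> graph -> mini -> protospacer ->
assemble) communicate through plain TSV/FASTA/FASTQ artifacts in the output
directory, so any stage can be re-run from its predecessors' files.  A JSON
manifest with content hashes of every artifact is written at the end.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import arrays as arrays_mod
from . import assembly as assembly_mod
from . import cluster as cluster_mod
from . import extract as extract_mod
from . import io
from . import miniarrays as mini_mod
from . import protospacers as proto_mod
from . import simulate as sim_mod

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError("pipeline config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _motifs_from_config(cfg: dict):
    """Build {repeat_type: (repeat motif, primers)} from config/simulation."""
    patterns = cfg.get("motifs")
    if patterns is None and "simulate" in cfg:
        community = cfg["simulate"].get("community", {})
        patterns = community.get(
            "repeat_consensus_by_type", dict(sim_mod.DEFAULT_REPEATS)
        )
    if not patterns:
        raise PipelineError("no repeat motifs configured")
    reads_cfg = cfg.get("simulate", {}).get("reads", {})
    primers = (
        extract_mod.DegenerateMotif(
            "primer_fwd", reads_cfg.get("primer_fwd", sim_mod.DEFAULT_PRIMER_FWD)
        ),
        extract_mod.DegenerateMotif(
            "primer_rev", reads_cfg.get("primer_rev", sim_mod.DEFAULT_PRIMER_REV)
        ),
    )
    return {
        label: (extract_mod.DegenerateMotif(label, pat), primers)
        for label, pat in patterns.items()
    }


def run_pipeline(config, outdir, seed: int | None = None) -> dict:
    """Run all configured stages; returns the artifact manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))

    samples: dict[str, Path] = {
        str(k): Path(v) for k, v in (config.get("samples") or {}).items()
    }
    for sid, path in samples.items():
        if not path.exists():
            raise PipelineError(f"sample {sid}: FASTQ not found: {path}")

    artifacts: list[Path] = []
    truth = None

    # --- simulate -----------------------------------------------------------
    if "simulate" in config:
        sim_cfg = config["simulate"] or {}
        community = sim_mod.CommunityConfig(
            **{**sim_cfg.get("community", {}), "seed": seed}
        )
        params = sim_mod.ReadSimParams(
            **{**sim_cfg.get("reads", {}), "seed": seed + 1}
        )
        truth, fasta = sim_mod.generate_community(community)
        reads, truth_table = sim_mod.generate_amplicon_reads(truth, params)
        io.write_fasta(fasta, outdir / "community.fasta")
        io.write_fastq(reads, outdir / "sim.fastq")
        io.write_tsv(truth_table, outdir / "truth_units.tsv")
        io.write_tsv(
            pd.DataFrame(sorted(truth.adjacency), columns=["first", "second"]),
            outdir / "truth_adjacency.tsv",
        )
        artifacts += [
            outdir / "community.fasta",
            outdir / "sim.fastq",
            outdir / "truth_units.tsv",
            outdir / "truth_adjacency.tsv",
        ]
        samples.setdefault("sim", outdir / "sim.fastq")
        logger.info("simulate: %d reads, %d arrays", len(reads), len(truth.arrays))

    if not samples:
        raise PipelineError("no samples configured and no simulation requested")

    # --- extract ------------------------------------------------------------
    motifs = _motifs_from_config(config)
    eparams = extract_mod.ExtractionParams(**(config.get("extract") or {}))
    sp_tables, pair_tables = [], []
    for sid in sorted(samples):
        sp, pairs, summary = extract_mod.extract_sample(
            io.read_fastq(samples[sid]), motifs, eparams, sample_id=sid
        )
        sp_tables.append(sp)
        pair_tables.append(pairs)
        logger.info(
            "extract[%s]: reads=%d spacers=%d filtered=%d pairs=%d",
            sid, summary.reads_scanned, summary.spacers_kept,
            summary.spacers_filtered, summary.pairs_kept,
        )
    spacer_table = pd.concat(sp_tables, ignore_index=True)
    pair_table = pd.concat(pair_tables, ignore_index=True)
    io.write_tsv(spacer_table, outdir / "spacers.tsv")
    io.write_tsv(pair_table, outdir / "pairs.tsv")
    artifacts += [outdir / "spacers.tsv", outdir / "pairs.tsv"]

    # --- cluster ------------------------------------------------------------
    ccfg = config.get("cluster") or {}
    clusters, assignment = cluster_mod.cluster_spacers(
        spacer_table, threshold=float(ccfg.get("threshold", 0.85))
    )
    sample_ids = sorted(samples)
    cl_rows = [
        [c.cluster_id, c.centroid]
        + [c.abundance_by_sample.get(s, 0) for s in sample_ids]
        for c in clusters
    ]
    cluster_table = pd.DataFrame(
        cl_rows, columns=["cluster_id", "centroid"] + sample_ids
    )
    io.write_tsv(cluster_table, outdir / "clusters.tsv")
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    io.write_fasta(
        [SeqRecord(Seq(c.centroid), id=c.cluster_id, description="") for c in clusters],
        outdir / "centroids.fasta",
    )
    div_rows = []
    for s in sample_ids:
        counts = [c.abundance_by_sample.get(s, 0) for c in clusters]
        counts = [n for n in counts if n > 0]
        if counts:
            d = cluster_mod.diversity_summary(counts)
            div_rows.append((s, d.goods_C, d.shannon_H, d.chao1, d.n_clusters, d.n_rare))
    io.write_tsv(
        pd.DataFrame(
            div_rows,
            columns=["sample_id", "goods_C", "shannon_H", "chao1", "n_clusters", "n_rare"],
        ),
        outdir / "diversity.tsv",
    )
    artifacts += [outdir / "clusters.tsv", outdir / "centroids.fasta", outdir / "diversity.tsv"]
    logger.info("cluster: %d observations -> %d clusters", len(spacer_table), len(clusters))

    # --- graph + mini, per sample ------------------------------------------
    gcfg = config.get("graph") or {}
    mcfg = config.get("mini") or {}
    cluster_of = assignment
    abundance_df = cluster_table.set_index("cluster_id")[sample_ids]
    mini_reports = []
    for sid in sample_ids:
        sp = spacer_table[spacer_table["sample_id"] == sid]
        pr = pair_table[pair_table["sample_id"] == sid].copy()
        if len(pr):
            pr["first"] = pr["first"].map(cluster_of)
            pr["second"] = pr["second"].map(cluster_of)
        nodes = sorted({cluster_of[s] for s in sp["sequence"]})
        g = arrays_mod.build_pair_graph(pr, nodes=nodes)
        filtered, report = arrays_mod.filter_chimeric_edges(
            g,
            fraction=float(gcfg.get("fraction", 0.05)),
            rule=str(gcfg.get("rule", "either")),
        )
        io.write_tsv(report, outdir / f"edges_{sid}.tsv")
        paths = arrays_mod.reconstruct_paths(filtered)
        io.write_tsv(
            pd.DataFrame(
                [(i, p.component_id, len(p), p.min_weight, ",".join(p.nodes))
                 for i, p in enumerate(paths)],
                columns=["path_id", "component_id", "n_spacers", "min_weight", "clusters"],
            ),
            outdir / f"paths_{sid}.tsv",
        )
        ecc = arrays_mod.node_eccentricity(filtered)
        io.write_tsv(
            pd.DataFrame(sorted(ecc.items()), columns=["cluster_id", "eccentricity"]),
            outdir / f"eccentricity_{sid}.tsv",
        )
        artifacts += [outdir / f"edges_{sid}.tsv", outdir / f"paths_{sid}.tsv",
                      outdir / f"eccentricity_{sid}.tsv"]

        if len(sp):
            pp = mini_mod.estimate_pair_probability(sp, sample_id=sid)
            pair_weights = {
                (u, v): d["weight"] for u, v, d in filtered.edges(data=True)
            }
            cands = mini_mod.mini_array_candidates(
                paths, ecc, abundance_df[sid].to_dict(),
                pair_weights={(u, v): w for (u, v), w in pair_weights.items()},
                sample_id=sid,
            )
            calls = mini_mod.call_mini_arrays(
                cands, pp,
                alpha=float(mcfg.get("alpha", 0.01)),
                thresholds={int(k): int(v) for k, v in mcfg.get("thresholds", mini_mod.PAPER_THRESHOLDS).items()},
            )
            mini_reports.append(
                pd.DataFrame(
                    [
                        (sid, ",".join(c.candidate.cluster_ids), len(c.candidate.cluster_ids),
                         c.candidate.n, pp.p, c.p_value, c.threshold_used,
                         c.passes_pvalue, c.passes_threshold, c.decision)
                        for c in calls
                    ],
                    columns=["sample_id", "clusters", "k", "N", "p", "p_value",
                             "threshold", "passes_pvalue", "passes_threshold", "decision"],
                )
            )
    if mini_reports:
        io.write_tsv(pd.concat(mini_reports, ignore_index=True), outdir / "mini_calls.tsv")
        artifacts.append(outdir / "mini_calls.tsv")

    # --- protospacer --------------------------------------------------------
    pcfg = config.get("protospacer") or {}
    genomes: dict[str, str] = {}
    if "genomes" in pcfg:
        for rec in io.read_fasta(pcfg["genomes"]):
            genomes[rec.id] = str(rec.seq)
    elif truth is not None:
        genomes = dict(truth.viral_genomes)
    if genomes:
        mparams = proto_mod.MatchParams(
            word_size=int(pcfg.get("word_size", 8)),
            min_identity=float(pcfg.get("min_identity", 0.85)),
        )
        hit_rows = []
        for gid, gseq in sorted(genomes.items()):
            index = proto_mod.GenomeIndex(gseq, gid, mparams)
            for c in clusters:
                for h in index.search(c.centroid, c.cluster_id):
                    hit_rows.append(
                        (h.cluster_id, h.genome_id, h.start, h.end, h.strand,
                         h.identity, h.flank_5, h.flank_3)
                    )
        hits_df = pd.DataFrame(
            hit_rows,
            columns=["cluster_id", "genome_id", "start", "end", "strand",
                     "identity", "flank_5", "flank_3"],
        )
        io.write_tsv(hits_df, outdir / "protospacers.tsv")
        cov_rows = [
            (gid, proto_mod.genome_protospacer_coverage(
                list(hits_df[hits_df["genome_id"] == gid][["start", "end"]].itertuples(index=False)),
                len(genomes[gid]),
            ))
            for gid in sorted(genomes)
        ]
        io.write_tsv(
            pd.DataFrame(cov_rows, columns=["genome_id", "covered_fraction"]),
            outdir / "protospacer_coverage.tsv",
        )
        artifacts += [outdir / "protospacers.tsv", outdir / "protospacer_coverage.tsv"]

    # --- assemble -----------------------------------------------------------
    acfg = config.get("assemble") or {}
    if len(clusters) >= 2:
        centroid_seqs = {c.cluster_id: c.centroid for c in clusters}
        match_graph = assembly_mod.all_vs_all_matches(
            centroid_seqs,
            min_identity=float(acfg.get("min_identity", 0.7)),
            word_size=int(acfg.get("word_size", 8)),
        )
        contigs = assembly_mod.tile_contigs(match_graph, centroid_seqs)
        io.write_fasta(
            [SeqRecord(Seq(c.consensus), id=c.contig_id, description="") for c in contigs],
            outdir / "contigs.fasta",
        )
        io.write_tsv(
            pd.DataFrame(
                [(c.contig_id, sid, off, ori) for c in contigs for sid, off, ori in c.members],
                columns=["contig_id", "spacer_id", "offset", "strand"],
            ),
            outdir / "contig_layout.tsv",
        )
        artifacts += [outdir / "contigs.fasta", outdir / "contig_layout.tsv"]

    manifest = {
        "seed": seed,
        "artifacts": [
            {"path": p.name, "sha256": _sha256(p)} for p in artifacts
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
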