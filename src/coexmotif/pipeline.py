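"""End-to-end orchestration: stage functions, manifest and resume logic.

Each stage reads and writes plain-text files in a working directory, so
every stage is also runnable standalone through the CLI.  ``run_all``
executes the nine stages in dependency order, skips a stage when its outputs
are all newer than its inputs, and writes a deterministic ``manifest.json``
(package version, seeds, per-stage row counts; no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__, enrich, inference, motiflib, netanalysis, scan, synthetic
from .errors import DegenerateInputError
from .expression import (
    complete_sample_subset,
    filter_min_observations,
    read_annotations,
    read_expression,
    write_annotation_tsv,
    write_expression,
)
from .meme import read_meme, write_meme
from .synthetic import SimulationConfig

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "infer_network",
    "extract_promoters",
    "scan",
    "dedup_motifs",
    "gene_motif_maps",
    "network_analysis",
    "enrichment",
    "sweep",
)


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        n_genes=150, n_tfs=4, module_size=12, n_samples=48, library_redundancy=3,
        consensus_strength=0.95, motif_width_range=(10, 14),
    ))
    min_obs: int = 20
    min_overlap: int = 20
    n_bins: int | None = None
    taus: tuple[float, ...] = (3.0, 4.0, 5.0)
    base_tau: float = 4.0
    scan_q_keep: float = 0.3
    map_q_grid: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3)
    base_map_q: float = 0.15
    enrich_q_flag: float = 0.05
    mcl_inflation: float = 2.0
    dedup_score_threshold: float = 0.7
    dedup_min_overlap: int = 5
    dedup_include_threshold: float = 0.3
    n_random_lists: int = 1000
    random_list_size: int = 50
    n_shuffles: int = 99
    sweep_shuffles: int = 0
    top_k: int = 40

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim_raw:
            sim = SimulationConfig(**sim_raw)
            if isinstance(sim.motif_width_range, list):
                sim.motif_width_range = tuple(sim.motif_width_range)
            if isinstance(sim.background_freqs, list):
                sim.background_freqs = tuple(sim.background_freqs)
            cfg.simulation = sim
        cfg.taus = tuple(cfg.taus)
        cfg.map_q_grid = tuple(cfg.map_q_grid)
        return cfg

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["simulation"] = dataclasses.asdict(self.simulation)
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _paths(outdir: Path) -> dict[str, Path]:
    return {
        "expression": outdir / "expression.tsv",
        "genome": outdir / "genome.fasta",
        "gff": outdir / "genes.gff3",
        "motifs": outdir / "motifs.meme",
        "go": outdir / "go_terms.tsv",
        "categories": outdir / "categories.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "clr_complete": outdir / "clr_complete.tsv",
        "clr_subset": outdir / "clr_subset.tsv",
        "promoters": outdir / "promoters.tsv",
        "hits": outdir / "hits.tsv",
        "motif_clusters": outdir / "motif_clusters.tsv",
        "central_motifs": outdir / "central_motifs.meme",
        "similarity_gml": outdir / "motif_similarity.gml",
        "coverage": outdir / "coverage.tsv",
        "centrality": outdir / "centrality.tsv",
        "gene_clusters": outdir / "gene_clusters.tsv",
        "cluster_graph": outdir / "cluster_graph.gml",
        "enrichment": outdir / "neighborhood_enrichment.tsv",
        "enrichment_summary": outdir / "enrichment_summary.tsv",
        "nulls": outdir / "null_distributions.tsv",
        "sweep": outdir / "sweep.tsv",
        "manifest": outdir / "manifest.json",
    }


def simulate_to_dir(sim: SimulationConfig, outdir) -> dict:
    """Write the full synthetic data set into ``outdir``; returns row counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = _paths(outdir)
    sim.validate()
    motifs, clusters = synthetic.generate_motif_library(
        sim.n_tfs, sim.library_redundancy, sim.motif_width_range,
        sim.background, sim.seed, sim.consensus_strength,
    )
    gt = synthetic.generate_regulatory_structure(sim, sorted(clusters))
    # plant the base variant of each assigned group
    gt.planted_motifs = {tf: f"{base}v0" for tf, base in gt.planted_motifs.items()}
    genome, features, _ = synthetic.generate_promoters(gt, sim, motifs)
    expr = synthetic.generate_expression(gt, sim)
    write_expression(expr, p["expression"])
    synthetic.write_genome_fasta(genome, p["genome"])
    synthetic.write_gff3(features, p["gff"])
    write_meme(motifs, p["motifs"], sim.background)
    write_annotation_tsv({g: {t} for g, t in gt.gene_labels.items()}, p["go"])
    write_annotation_tsv({g: set(c) for g, c in gt.gene_categories.items()}, p["categories"])
    gt.to_json(p["ground_truth"])
    return {"genes": expr.n_genes, "samples": expr.n_samples,
            "motifs": len(motifs), "planted_instances": len(gt.motif_instances)}


def write_clr_edges(clrnet: inference.CLRNetwork, path, min_score: float) -> int:
    """Persist CLR scores above ``min_score`` as a sorted edge TSV."""
    n = 0
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tclr\n")
        ii, jj = np.nonzero(np.triu(clrnet.clr > min_score, k=1))
        order = sorted(
            range(ii.size),
            key=lambda k: (clrnet.gene_ids[ii[k]], clrnet.gene_ids[jj[k]]),
        )
        for k in order:
            i, j = ii[k], jj[k]
            fh.write(f"{clrnet.gene_ids[i]}\t{clrnet.gene_ids[j]}\t{clrnet.clr[i, j]:.6f}\n")
            n += 1
    return n


def graph_from_clr_edges(path, tau: float) -> nx.Graph:
    g = nx.Graph(threshold=float(tau))
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        if row.clr > tau:
            g.add_edge(row.gene_a, row.gene_b, weight=float(row.clr))
    return g


def coverage_curves(hits: list, q_grid) -> pd.DataFrame:
    """Mapping counts, unique motifs and unique genes against the q threshold."""
    rows = []
    for q in q_grid:
        gm = scan.gene_motif_map(hits, q)
        rows.append({
            "q_threshold": q, "n_mappings": gm.n_mappings,
            "n_unique_motifs": gm.n_unique_motifs, "n_unique_genes": gm.n_unique_genes,
        })
    return pd.DataFrame(rows)


def _outputs_current(inputs: list[Path], outputs: list[Path]) -> bool:
    if not outputs or not all(p.exists() for p in outputs):
        return False
    newest_input = max((p.stat().st_mtime for p in inputs if p.exists()), default=0.0)
    oldest_output = min(p.stat().st_mtime for p in outputs)
    return oldest_output >= newest_input


def run_all(cfg: PipelineConfig, force: bool = False, simulate: bool = True) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = _paths(outdir)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "simulation_seed": cfg.simulation.seed,
        "stages": {},
    }

    def record(stage: str, outputs: list[Path], skipped: bool, counts: dict) -> None:
        manifest["stages"][stage] = {
            "outputs": [str(o.name) for o in outputs],
            "skipped": skipped,
            "row_counts": counts,
        }

    # 1. simulate -----------------------------------------------------------
    sim_outputs = [p["expression"], p["genome"], p["gff"], p["motifs"],
                   p["go"], p["categories"], p["ground_truth"]]
    if simulate:
        # simulation has no file inputs; rerun unless everything already exists
        if force or not all(o.exists() for o in sim_outputs):
            counts = simulate_to_dir(cfg.simulation, outdir)
            record("simulate", sim_outputs, False, counts)
        else:
            record("simulate", sim_outputs, True, {})
    else:
        record("simulate", sim_outputs, True, {})

    # 2. infer networks (complete + subset) ---------------------------------
    net_outputs = [p["clr_complete"], p["clr_subset"]]
    if force or not _outputs_current([p["expression"]], [p["clr_complete"]]):
        expr = read_expression(p["expression"])
        expr = filter_min_observations(expr, min(cfg.min_obs, expr.n_samples))
        counts = {}
        mim = inference.mi_matrix(expr, cfg.n_bins, cfg.min_overlap)
        clr_complete = inference.clr_scores(mim)
        counts["complete_edges"] = write_clr_edges(
            clr_complete, p["clr_complete"], min(cfg.taus)
        )
        try:
            subset = complete_sample_subset(expr)
            subset.require_minimum_size()
            mim_s = inference.mi_matrix(subset, cfg.n_bins, min(cfg.min_overlap, subset.n_samples))
            clr_subset = inference.clr_scores(mim_s)
            counts["subset_edges"] = write_clr_edges(clr_subset, p["clr_subset"], min(cfg.taus))
            counts["subset_samples"] = subset.n_samples
        except DegenerateInputError as exc:
            logger.warning("subset network unavailable: %s", exc)
            with open(p["clr_subset"], "wt", encoding="utf-8") as fh:
                fh.write("gene_a\tgene_b\tclr\n")
            counts["subset_edges"] = 0
        record("infer_network", net_outputs, False, counts)
    else:
        record("infer_network", net_outputs, True, {})

    # 3. extract promoters --------------------------------------------------
    if force or not _outputs_current([p["genome"], p["gff"]], [p["promoters"]]):
        genome = scan.read_fasta(p["genome"])
        features = scan.read_gff3(p["gff"])
        promoters = scan.extract_promoters(genome, features, cfg.simulation.promoter_length)
        with open(p["promoters"], "wt", encoding="utf-8") as fh:
            fh.write("gene\tcontig\tstart\tend\tstrand\tsequence\n")
            for gene in sorted(promoters):
                pr = promoters[gene]
                fh.write(f"{pr.gene}\t{pr.contig}\t{pr.start}\t{pr.end}\t{pr.strand}\t{pr.seq}\n")
        record("extract_promoters", [p["promoters"]], False, {"promoters": len(promoters)})
    else:
        record("extract_promoters", [p["promoters"]], True, {})

    # 4. scan ----------------------------------------------------------------
    if force or not _outputs_current([p["promoters"], p["motifs"]], [p["hits"]]):
        promoters = _read_promoters_tsv(p["promoters"])
        motifs = read_meme(p["motifs"])
        hits = scan.scan(promoters, motifs, q_threshold=cfg.scan_q_keep)
        scan.write_hits_tsv(hits, p["hits"])
        record("scan", [p["hits"]], False, {"hits": len(hits)})
    else:
        record("scan", [p["hits"]], True, {})

    # 5. dedup motifs --------------------------------------------------------
    dedup_outputs = [p["motif_clusters"], p["central_motifs"], p["similarity_gml"]]
    if force or not _outputs_current([p["motifs"]], dedup_outputs):
        motifs = read_meme(p["motifs"])
        library, simnet = motiflib.dedup_library(
            motifs, cfg.dedup_include_threshold, cfg.dedup_score_threshold,
            cfg.dedup_min_overlap, cfg.mcl_inflation,
        )
        with open(p["motif_clusters"], "wt", encoding="utf-8") as fh:
            fh.write("motif\tcluster\tis_central\n")
            for mid in sorted(library.clusters):
                cid = library.clusters[mid]
                fh.write(f"{mid}\t{cid}\t{int(library.representatives[cid] == mid)}\n")
        central = [m for m in motifs if m.id in set(library.central_ids)]
        write_meme(central, p["central_motifs"], cfg.simulation.background)
        netanalysis.export_gml(simnet, p["similarity_gml"])
        record("dedup_motifs", dedup_outputs, False,
               {"motifs": len(motifs), "clusters": len(library.representatives)})
    else:
        record("dedup_motifs", dedup_outputs, True, {})

    # 6. gene/motif coverage maps -------------------------------------------
    if force or not _outputs_current([p["hits"], p["motif_clusters"]], [p["coverage"]]):
        hits = scan.read_hits_tsv(p["hits"])
        central_ids = set(_central_ids_from_tsv(p["motif_clusters"]))
        central_hits = [h for h in hits if h.motif_id in central_ids]
        frames = []
        for label, subset_hits in (("all", hits), ("central", central_hits)):
            df = coverage_curves(subset_hits, cfg.map_q_grid)
            df.insert(0, "motif_set", label)
            frames.append(df)
        pd.concat(frames).to_csv(p["coverage"], sep="\t", index=False)
        record("gene_motif_maps", [p["coverage"]], False, {"rows": 2 * len(cfg.map_q_grid)})
    else:
        record("gene_motif_maps", [p["coverage"]], True, {})

    # 7. network analysis: centrality + clustering + cluster graph ----------
    na_outputs = [p["centrality"], p["gene_clusters"], p["cluster_graph"]]
    if force or not _outputs_current([p["clr_complete"]], na_outputs):
        net = graph_from_clr_edges(p["clr_complete"], cfg.base_tau)
        counts = {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()}
        if net.number_of_nodes() >= 3:
            deg = netanalysis.degree_centrality(net)
            betw = netanalysis.betweenness_centrality(net)
            ranked = sorted(deg, key=lambda g: (-deg[g], g))
            with open(p["centrality"], "wt", encoding="utf-8") as fh:
                fh.write("gene\tdegree\tbetweenness\trank_by_degree\n")
                for r, gene in enumerate(ranked, start=1):
                    fh.write(f"{gene}\t{deg[gene]:.6f}\t{betw[gene]:.6f}\t{r}\n")
            clustering = netanalysis.mcl_cluster(net, cfg.mcl_inflation)
            with open(p["gene_clusters"], "wt", encoding="utf-8") as fh:
                fh.write("gene\tcluster\n")
                for gene in sorted(clustering.partition):
                    fh.write(f"{gene}\t{clustering.partition[gene]}\n")
            cg = netanalysis.cluster_graph(net, clustering)
            netanalysis.export_gml(cg, p["cluster_graph"])
            counts["clusters"] = len(clustering.clusters())
        else:
            for out in na_outputs:
                out.write_text("")
        record("network_analysis", na_outputs, False, counts)
    else:
        record("network_analysis", na_outputs, True, {})

    # 8. neighborhood enrichment + nulls ------------------------------------
    enr_outputs = [p["enrichment"], p["enrichment_summary"], p["nulls"]]
    if force or not _outputs_current([p["clr_complete"], p["hits"], p["categories"]], enr_outputs):
        net = graph_from_clr_edges(p["clr_complete"], cfg.base_tau)
        hits = scan.read_hits_tsv(p["hits"])
        gm = scan.gene_motif_map(hits, cfg.base_map_q)
        annotations = read_annotations(category_path=p["categories"])
        rows, summary_rows, null_rows = [], [], []
        for group in ("regulatory", "dna_binding"):
            seeds = sorted(annotations.genes_in_category(group))
            report = enrich.neighborhood_motif_enrichment(
                net, seeds, gm.gene_to_motifs, cfg.enrich_q_flag
            )
            for s in report.seeds:
                best = min(s.results, key=lambda r: r.q, default=None)
                rows.append({
                    "group": group, "seed": s.seed, "n_neighbors": s.n_neighbors,
                    "enriched": int(s.enriched),
                    "best_motif": best.feature_id if best else "",
                    "best_q": f"{best.q:.6g}" if best else "",
                })
            observed = report.fraction_enriched
            summary = {"group": group, "n_seeds": len(seeds),
                       "n_enriched": report.n_enriched, "fraction": observed}
            if net.number_of_nodes() >= cfg.random_list_size and seeds:
                rl = enrich.random_genelist_null(
                    net, gm.gene_to_motifs, observed, cfg.n_random_lists,
                    cfg.random_list_size, cfg.seed, cfg.enrich_q_flag,
                )
                sh = enrich.shuffled_network_null(
                    net, seeds, gm.gene_to_motifs, observed, cfg.n_shuffles,
                    cfg.seed, cfg.enrich_q_flag,
                )
                summary["p_random_lists"] = rl.p_empirical
                summary["p_shuffled"] = sh.p_empirical
                null_rows.extend(
                    {"group": group, "null": "random_lists", "index": i, "fraction": v}
                    for i, v in enumerate(rl.samples)
                )
                null_rows.extend(
                    {"group": group, "null": "shuffled", "index": i, "fraction": v}
                    for i, v in enumerate(sh.samples)
                )
            summary_rows.append(summary)
        pd.DataFrame(rows).to_csv(p["enrichment"], sep="\t", index=False)
        pd.DataFrame(summary_rows).to_csv(p["enrichment_summary"], sep="\t", index=False)
        pd.DataFrame(null_rows).to_csv(p["nulls"], sep="\t", index=False)
        record("enrichment", enr_outputs, False, {"seeds": len(rows)})
    else:
        record("enrichment", enr_outputs, True, {})

    # 9. parameter sweep -----------------------------------------------------
    sweep_inputs = [p["clr_complete"], p["clr_subset"], p["hits"], p["categories"]]
    if force or not _outputs_current(sweep_inputs, [p["sweep"]]):
        hits = scan.read_hits_tsv(p["hits"])
        annotations = read_annotations(category_path=p["categories"])
        expr_genes = set(read_expression(p["expression"]).gene_ids)
        variants = {}
        for name in ("complete", "subset"):
            path = p[f"clr_{name}"]
            df = pd.read_csv(path, sep="\t")
            if len(df):
                variants[name] = _clrnet_from_edges(df)
        table = enrich.parameter_sweep(
            variants, hits, annotations.categories, cfg.taus, cfg.map_q_grid,
            cfg.enrich_q_flag, cfg.sweep_shuffles, cfg.seed, expr_genes,
        )
        table.to_csv(p["sweep"], sep="\t", index=False)
        record("sweep", [p["sweep"]], False, {"rows": len(table)})
    else:
        record("sweep", [p["sweep"]], True, {})

    with open(p["manifest"], "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _read_promoters_tsv(path) -> scan.PromoterSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: scan.PromoterSet = {}
    for row in df.itertuples(index=False):
        out[row.gene] = scan.Promoter(
            row.gene, row.sequence, row.contig, int(row.start), int(row.end), row.strand
        )
    return out


def _central_ids_from_tsv(path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return list(df.loc[df["is_central"] == 1, "motif"])


def _clrnet_from_edges(df: pd.DataFrame) -> inference.CLRNetwork:
    genes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    index = {g: i for i, g in enumerate(genes)}
    clr = np.zeros((len(genes), len(genes)))
    for row in df.itertuples(index=False):
        i, j = index[row.gene_a], index[row.gene_b]
        clr[i, j] = clr[j, i] = float(row.clr)
    return inference.CLRNetwork(genes, clr, [])
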