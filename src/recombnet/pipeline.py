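"""End-to-end orchestration: scan -> prioritize -> RWR -> complexes -> GO.

Each stage reads the previous stage's file outputs and writes its own, so
the stages are independently runnable (the CLI exposes one subcommand per
stage). ``run_pipeline`` chains them and records a JSON manifest with the
config hash, input checksums, and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import complex_detect, go_semantics, io_formats, motif_scan, network_walk, prioritize

log = logging.getLogger("recombnet")

DEFAULT_PARAMS = {
    "p_threshold": 1e-4,
    "bin_length": 5_000_000,
    "pearson_threshold": 0.7,
    "seed_fraction": 0.10,
    "p0_mode": "scores",
    "gamma": 0.7,
    "tol": 1e-10,
    "max_iter": 10_000,
    "top_k": 200,
    "density_threshold": 0.7,
    "attach_ratio": 0.5,
    "redundancy_na": 0.25,
    "na_threshold": 0.25,
    "method": "or",
    "motif_dialect": "jaspar_pfm",
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_PARAMS)
    cfg.update(user.get("params", {}))
    cfg["inputs"] = user.get("inputs", {})
    cfg["outdir"] = user.get("outdir", "recombnet_out")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True, default_flow_style=True).encode()
    ).hexdigest()[:16]


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def stage_scan(genome_path, motifs_path, hotspots_path, coldspots_path, out_tsv,
               p_threshold=1e-4, motif_dialect="jaspar_pfm"):
    """Scan hotspot and coldspot intervals with every motif; write FIMO TSV."""
    genome, _ = io_formats.read_fasta(genome_path)
    lengths = io_formats.chrom_lengths(genome)
    hot, _ = io_formats.read_intervals(hotspots_path, lengths, label="hotspot")
    cold, _ = io_formats.read_intervals(coldspots_path, lengths, label="coldspot")
    motifs, _ = io_formats.read_motifs(motifs_path, dialect=motif_dialect)
    hits = []
    for m in motifs:
        for spots in (hot, cold):
            hits.extend(motif_scan.scan_intervals(m, genome, spots, p_threshold))
    io_formats.write_fimo_hits(hits, out_tsv)
    log.info("scan: %d motifs, %d hits", len(motifs), len(hits))
    return {"n_motifs": len(motifs), "n_hits": len(hits)}


def stage_prioritize(hits_path, genome_path, hotspots_path, coldspots_path,
                     motifs_path, outdir, clusters_path=None, method="or",
                     seed_fraction=0.10, bin_length=5_000_000,
                     pearson_threshold=0.7, motif_dialect="jaspar_pfm",
                     p0_mode="scores"):
    """Build OR / HB / KM rankings from motif hits and select seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, _ = io_formats.read_fasta(genome_path)
    lengths = io_formats.chrom_lengths(genome)
    hot, _ = io_formats.read_intervals(hotspots_path, lengths, label="hotspot")
    cold, _ = io_formats.read_intervals(coldspots_path, lengths, label="coldspot")
    motifs, _ = io_formats.read_motifs(motifs_path, dialect=motif_dialect)
    motif_ids = [m.motif_id for m in motifs]
    hits, _ = io_formats.read_fimo_hits(hits_path)

    table = motif_scan.tabulate_hits(hits, hot, cold)
    records = prioritize.odds_ratios_from_table(table, motif_ids)
    or_ranking = prioritize.rank_by_or(records)
    or_scores = {r.motif_id: r.odds_ratio for r in records}
    prioritize.write_ranking(or_ranking, or_scores, "or", outdir / "ranking_or.tsv")

    rankings = {"or": (or_ranking, or_scores)}
    if clusters_path is not None:
        clusters, _ = io_formats.read_clusters(clusters_path)
        relevance = prioritize.relevance_from_clusters(clusters, motif_ids)
        hb_ranking = prioritize.rank_by_relevance(
            {g: relevance.get(g, 0.0) for g in motif_ids}
        )
        prioritize.write_ranking(hb_ranking, relevance, "hb", outdir / "ranking_hb.tsv")
        rankings["hb"] = (hb_ranking, relevance)
        km_ranking, km_cost = prioritize.km_aggregate(or_ranking, hb_ranking)
        km_scores = {g: 1.0 / km_ranking.position(g) for g in km_ranking}
        prioritize.write_ranking(km_ranking, km_scores, "km", outdir / "ranking_km.tsv")
        rankings["km"] = (km_ranking, km_scores)
        log.info("prioritize: KM aggregation cost %d", km_cost)

    if method not in rankings:
        raise ValueError(f"method {method!r} unavailable (no clusters file?)")
    ranking, scores = rankings[method]
    seeds = prioritize.select_seeds(ranking, scores, seed_fraction, mode=p0_mode)
    with open(outdir / "seeds.tsv", "w") as fh:
        fh.write("gene_id\tscore\n")
        for g in sorted(seeds.scores, key=lambda x: -seeds.scores[x]):
            fh.write(f"{g}\t{seeds.scores[g]:g}\n")
    log.info("prioritize: %d TFs scored, %d seeds (%s)", len(motif_ids), len(seeds), method)
    return {"n_tfs": len(motif_ids), "n_seeds": len(seeds), "method": method}


def read_seeds(path) -> prioritize.SeedSet:
    scores = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            gene, score = line.split("\t")
            scores[gene] = float(score)
    return prioritize.SeedSet(scores)


def stage_rwr(network_path, seeds_path, out_tsv, gamma=0.7, tol=1e-10,
              max_iter=10_000):
    """Random walk with restart from the seed file over a PPI edge list."""
    net, _ = io_formats.read_network(network_path)
    seeds = read_seeds(seeds_path)
    tm = network_walk.normalize_adjacency(net)
    rv = network_walk.rwr(tm, seeds, gamma=gamma, tol=tol, max_iter=max_iter)
    network_walk.write_relevance(rv, seeds, out_tsv)
    log.info("rwr: %d nodes, %d iterations, converged=%s",
             len(rv.nodes), rv.iterations, rv.converged)
    return {"n_nodes": len(rv.nodes), "iterations": rv.iterations,
            "converged": rv.converged}


def read_relevance(path):
    scores, seeds = {}, set()
    with open(path) as fh:
        fh.readline()
        for line in fh:
            gene, p, is_seed, _rank = line.rstrip("\n").split("\t")
            scores[gene] = float(p)
            if is_seed == "1":
                seeds.add(gene)
    return scores, seeds


def stage_complexes(network_path, relevance_path, out_path, top_k=200,
                    density_threshold=0.7, attach_ratio=0.5, redundancy_na=0.25):
    """Induce the top-k subnetwork and mine core-attachment complexes."""
    net, _ = io_formats.read_network(network_path)
    scores, _ = read_relevance(relevance_path)
    k = min(top_k, net.number_of_nodes())
    top = sorted(net.nodes(), key=lambda v: (-scores.get(v, 0.0), v))[:k]
    sub = net.subgraph(top).copy()
    complexes = complex_detect.detect_complexes(
        sub, density_threshold, attach_ratio, redundancy_na
    )
    complex_detect.write_complexes(complexes, out_path)
    log.info("complexes: %d detected in top-%d subnetwork", len(complexes), k)
    return {"n_complexes": len(complexes), "top_k": k}


def stage_conserved(complexes_a_path, complexes_b_path, orthologs_path, out_path,
                    na_threshold=0.25):
    """Match complexes across species by NA over orthologs."""
    ca = complex_detect.read_complexes(complexes_a_path)
    cb = complex_detect.read_complexes(complexes_b_path)
    orthologs, _ = io_formats.read_orthologs(orthologs_path)
    pairs = complex_detect.match_conserved(ca, cb, orthologs, na_threshold)
    complex_detect.write_conserved_pairs(pairs, out_path)
    log.info("conserved: %d pairs", len(pairs))
    return {"n_pairs": len(pairs)}


def stage_go_gap(obo_path, gaf_path, seeds_path, motifs_path, out_path,
                 motif_dialect="jaspar_pfm"):
    """Rank GO terms by gap score of seeds vs the full TF universe."""
    dag, ann, _ = io_formats.read_ontology(obo_path, gaf_path)
    seeds = read_seeds(seeds_path)
    motifs, _ = io_formats.read_motifs(motifs_path, dialect=motif_dialect)
    universe = {m.motif_id for m in motifs} | seeds.genes
    results = go_semantics.rank_terms_by_gap(
        dag.terms(), seeds.genes, universe, ann, dag
    )
    go_semantics.write_gap_table(results, dag, out_path)
    log.info("go-gap: %d terms ranked", len(results))
    return {"n_terms": len(results)}


# ---------------------------------------------------------------------------
# full run


def run_pipeline(cfg: dict) -> dict:
    """Execute all stages in order; abort on the first hard error.

    Expects ``cfg['inputs']`` with keys genome, motifs, hotspots, coldspots,
    ppi_a (and optionally clusters, ppi_b, orthologs, obo, gaf) and writes
    everything under ``cfg['outdir']``.
    """
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = cfg["inputs"]
    manifest = {
        "config_hash": config_hash({k: v for k, v in cfg.items() if k != "inputs"}),
        "inputs": {k: {"path": str(v), "sha256": _checksum(v)}
                   for k, v in inputs.items() if v and Path(v).exists()},
        "stages": {},
        "failed_stage": None,
    }

    def run_stage(name, fn, *args, **kwargs):
        try:
            manifest["stages"][name] = fn(*args, **kwargs)
        except Exception as exc:
            manifest["failed_stage"] = name
            manifest["stages"][name] = {"error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise

    run_stage("scan", stage_scan, inputs["genome"], inputs["motifs"],
              inputs["hotspots"], inputs["coldspots"], outdir / "hits.tsv",
              cfg["p_threshold"], cfg["motif_dialect"])
    run_stage("prioritize", stage_prioritize, outdir / "hits.tsv", inputs["genome"],
              inputs["hotspots"], inputs["coldspots"], inputs["motifs"], outdir,
              clusters_path=inputs.get("clusters"), method=cfg["method"],
              seed_fraction=cfg["seed_fraction"], bin_length=cfg["bin_length"],
              pearson_threshold=cfg["pearson_threshold"],
              motif_dialect=cfg["motif_dialect"], p0_mode=cfg["p0_mode"])
    run_stage("rwr", stage_rwr, inputs["ppi_a"], outdir / "seeds.tsv",
              outdir / "rwr_a.tsv", cfg["gamma"], cfg["tol"], cfg["max_iter"])
    run_stage("complexes", stage_complexes, inputs["ppi_a"], outdir / "rwr_a.tsv",
              outdir / "complexes_a.txt", cfg["top_k"], cfg["density_threshold"],
              cfg["attach_ratio"], cfg["redundancy_na"])

    if inputs.get("ppi_b") and inputs.get("orthologs"):
        orthologs, _ = io_formats.read_orthologs(inputs["orthologs"])
        omap = {}
        for a, b in orthologs:
            omap.setdefault(a, b)
        seeds_a = read_seeds(outdir / "seeds.tsv")
        seeds_b = {omap[g]: s for g, s in seeds_a.scores.items() if g in omap}
        if seeds_b:
            with open(outdir / "seeds_b.tsv", "w") as fh:
                fh.write("gene_id\tscore\n")
                for g, s in sorted(seeds_b.items(), key=lambda kv: -kv[1]):
                    fh.write(f"{g}\t{s:g}\n")
            run_stage("rwr_b", stage_rwr, inputs["ppi_b"], outdir / "seeds_b.tsv",
                      outdir / "rwr_b.tsv", cfg["gamma"], cfg["tol"], cfg["max_iter"])
            run_stage("complexes_b", stage_complexes, inputs["ppi_b"],
                      outdir / "rwr_b.tsv", outdir / "complexes_b.txt", cfg["top_k"],
                      cfg["density_threshold"], cfg["attach_ratio"],
                      cfg["redundancy_na"])
            run_stage("conserved", stage_conserved, outdir / "complexes_a.txt",
                      outdir / "complexes_b.txt", inputs["orthologs"],
                      outdir / "conserved_pairs.tsv", cfg["na_threshold"])

    if inputs.get("obo") and inputs.get("gaf"):
        run_stage("go_gap", stage_go_gap, inputs["obo"], inputs["gaf"],
                  outdir / "seeds.tsv", inputs["motifs"], outdir / "go_gap.tsv",
                  cfg["motif_dialect"])

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
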