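"""Seeded generators for synthetic pipeline inputs with planted ground truth.

The generators emulate the full input stack: a random genome with hotspot
and coldspot intervals, TF motifs whose occurrences are planted into
hotspots at an elevated rate for a subset of "hot" TFs, two species' PPI
networks with planted dense complexes linked to those hot TFs, a 1:1
ortholog map partially conserving complex membership, and a small GO DAG
whose marker term annotates the planted regulators. Every planted signal
is recorded in a truth table so recovery can be verified independently.

All randomness flows from one integer seed; each generator draws from its
own labelled substream, so adding a generator never perturbs another's
output and identical configs produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from . import io_formats
from .complex_detect import ProteinComplex, graph_density
from .go_semantics import AnnotationMap, GoDag
from .motif_scan import BASES, GenomeIntervalSet, GenomicInterval, MotifMatrix

GO_ROOT = "GO:1000000"


@dataclass
class SyntheticConfig:
    """Strong-signal study conditions (defaults) for the synthetic bundle."""

    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 500_000}
    )
    n_hotspots: int = 200
    n_coldspots: int = 200
    interval_length_range: tuple = (300, 700)
    # TF roster: hot TFs bind hotspots preferentially
    n_tfs: int = 30
    n_hot_tfs: int = 3
    motif_width: int = 8
    hot_rate_hotspot: float = 0.8
    hot_rate_coldspot: float = 0.1
    background_rate: float = 0.1
    motif_count_total: int = 18  # PFM counts assigned to the consensus base
    # PPI networks (per species)
    complex_sizes: tuple = (6, 6, 6)
    intra_complex_p: float = 1.0
    background_p: float = 0.01
    tf_complex_edges: int = 2
    n_background_nodes: int = 252
    conservation_rate: float = 0.8
    # conserved HB clusters (hot TFs recur across clusters)
    n_clusters: int = 12
    cluster_hot_p: float = 0.9
    cluster_bg_size: int = 3
    # GO DAG
    go_depth: int = 3
    go_branching: int = 3
    annotations_per_gene: int = 2
    # HB profiling resolution on the synthetic genome
    bin_length: int = 50_000

    def __post_init__(self):
        for p in (self.hot_rate_hotspot, self.hot_rate_coldspot, self.background_rate,
                  self.intra_complex_p, self.background_p,
                  self.conservation_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.complex_sizes, default=3) < 3:
            raise ValueError("complex sizes must be >= 3")
        if self.go_depth < 2:
            raise ValueError("go_depth must be >= 2")

    def rng(self, label: str) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), zlib.crc32(label.encode())])


@dataclass
class TFSpec:
    tf_id: str
    consensus: str
    rate_hotspot: float
    rate_coldspot: float
    is_hot: bool


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: dict
    hotspots: GenomeIntervalSet
    coldspots: GenomeIntervalSet
    roster: list
    motifs: list
    planted_hits: list
    ppi_a: nx.Graph
    ppi_b: nx.Graph
    true_complexes_a: list
    true_complexes_b: list
    orthologs: set
    clusters: list
    go_dag: GoDag
    annotations: AnnotationMap
    marker_term: str = ""

    @property
    def hot_tf_ids(self):
        return [tf.tf_id for tf in self.roster if tf.is_hot]


# ---------------------------------------------------------------------------
# genome + interval placement


def _place_intervals(cfg: SyntheticConfig, rng) -> tuple:
    lo, hi = cfg.interval_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_hotspots)
    cold_lengths = rng.permutation(
        np.resize(lengths, cfg.n_coldspots) if cfg.n_hotspots else
        rng.integers(lo, hi + 1, size=cfg.n_coldspots)
    )
    chroms = list(cfg.chrom_lengths)
    weights = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    occupied = {c: [] for c in chroms}

    def place(length: int, label: str) -> GenomicInterval:
        for _ in range(10_000):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            limit = cfg.chrom_lengths[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + int(length)
            if all(end <= s or start >= e for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                return GenomicInterval(chrom, start, end, label)
        raise RuntimeError("could not place intervals without overlap; genome too small")

    hot = [place(int(l), "hotspot") for l in lengths]
    cold = [place(int(l), "coldspot") for l in cold_lengths]
    return GenomeIntervalSet("hotspot", hot), GenomeIntervalSet("coldspot", cold)


def gen_genome_and_spots(cfg: SyntheticConfig):
    """Uniform-ACGT genome plus non-overlapping, length-matched spot sets."""
    rng = cfg.rng("genome")
    genome_codes = {
        chrom: rng.integers(0, 4, size=length).astype(np.uint8)
        for chrom, length in cfg.chrom_lengths.items()
    }
    hot, cold = _place_intervals(cfg, cfg.rng("spots"))
    return genome_codes, hot, cold


def _codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# TF roster + motif planting


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def make_roster(cfg: SyntheticConfig) -> list:
    """Distinct consensus motifs (pairwise distinct, including revcomps)."""
    rng = cfg.rng("roster")
    taken = set()
    roster = []
    for i in range(cfg.n_tfs):
        while True:
            consensus = "".join(BASES[b] for b in rng.integers(0, 4, cfg.motif_width))
            if consensus not in taken and _revcomp(consensus) not in taken:
                taken.add(consensus)
                break
        is_hot = i < cfg.n_hot_tfs
        roster.append(
            TFSpec(
                tf_id=f"TF{i + 1:02d}",
                consensus=consensus,
                rate_hotspot=cfg.hot_rate_hotspot if is_hot else cfg.background_rate,
                rate_coldspot=cfg.hot_rate_coldspot if is_hot else cfg.background_rate,
                is_hot=is_hot,
            )
        )
    return roster


def roster_motifs(cfg: SyntheticConfig, roster) -> list:
    """Near-one-hot count matrices for the roster consensi."""
    motifs = []
    for tf in roster:
        counts = np.zeros((4, cfg.motif_width))
        for j, base in enumerate(tf.consensus):
            counts["ACGT".index(base), j] = cfg.motif_count_total
        motifs.append(MotifMatrix(tf.tf_id, counts))
    return motifs


def plant_motifs(cfg: SyntheticConfig, genome_codes: dict, hot: GenomeIntervalSet,
                 cold: GenomeIntervalSet, roster) -> list:
    """Write consensus occurrences into intervals; returns the truth table.

    For each TF and each interval an occurrence is planted with the TF's
    per-label rate at a uniformly chosen position; planted occurrences
    never overlap one another (an interval too crowded to host another
    occurrence is recorded as skipped).
    """
    rng = cfg.rng("plant")
    base_lut = {b: i for i, b in enumerate(BASES)}
    truth = []
    occupied = {}  # (label, interval idx) -> list of (start, end) within genome
    for tf in roster:
        for spots, rate in ((hot, tf.rate_hotspot), (cold, tf.rate_coldspot)):
            for idx, iv in enumerate(spots):
                if rng.random() >= rate:
                    continue
                w = len(tf.consensus)
                if iv.length < w:
                    truth.append(
                        {"tf": tf.tf_id, "label": spots.label, "interval": idx,
                         "status": "interval_too_short"}
                    )
                    continue
                slots = occupied.setdefault((spots.label, idx), [])
                placed = None
                for _ in range(50):
                    start = iv.start + int(rng.integers(0, iv.length - w + 1))
                    if all(start + w <= s or start >= e for s, e in slots):
                        placed = start
                        break
                if placed is None:
                    truth.append(
                        {"tf": tf.tf_id, "label": spots.label, "interval": idx,
                         "status": "no_free_slot"}
                    )
                    continue
                slots.append((placed, placed + w))
                codes = genome_codes[iv.chrom]
                for j, base in enumerate(tf.consensus):
                    codes[placed + j] = base_lut[base]
                truth.append(
                    {"tf": tf.tf_id, "label": spots.label, "interval": idx,
                     "chrom": iv.chrom, "start": placed, "end": placed + w,
                     "status": "planted"}
                )
    return truth


# ---------------------------------------------------------------------------
# PPI networks with planted complexes


def gen_ppi_with_complexes(cfg: SyntheticConfig, roster):
    """Two species networks, planted complexes, and a 1:1 ortholog map.

    Each species network is the union of planted near-cliques (one per
    entry of ``complex_sizes``), Erdos-Renyi background edges, and edges
    wiring each hot TF to its corresponding complex. TFs are fully
    orthologous across species; complex members are conserved at
    ``conservation_rate``.
    """
    rng = cfg.rng("ppi")
    species = {}
    complexes = {}
    members = {}
    for tag in ("A", "B"):
        g = nx.Graph()
        tf_nodes = [tf.tf_id if tag == "A" else f"{tf.tf_id}_{tag}" for tf in roster]
        g.add_nodes_from(tf_nodes)
        comp_lists = []
        for k, size in enumerate(cfg.complex_sizes, 1):
            nodes = [f"{tag}_cx{k}_{i + 1}" for i in range(size)]
            comp_lists.append(nodes)
            g.add_nodes_from(nodes)
            for i in range(size):
                for j in range(i + 1, size):
                    if rng.random() < cfg.intra_complex_p:
                        g.add_edge(nodes[i], nodes[j], weight=1.0)
        for i in range(cfg.n_background_nodes):
            g.add_node(f"{tag}_bg{i + 1:03d}")
        # each hot TF touches its own machinery through a fixed pair of
        # member interactions: enough to route restart mass into the
        # complex without making the regulator a de facto member
        hot_nodes = [n for n, tf in zip(tf_nodes, roster) if tf.is_hot]
        for k, tf_node in enumerate(hot_nodes):
            if k < len(comp_lists):
                for member in comp_lists[k][: cfg.tf_complex_edges]:
                    g.add_edge(tf_node, member, weight=1.0)
        nodes_sorted = sorted(g.nodes())
        n = len(nodes_sorted)
        draws = rng.random(n * (n - 1) // 2)
        pos = 0
        for i in range(n):
            for j in range(i + 1, n):
                if draws[pos] < cfg.background_p and not g.has_edge(
                    nodes_sorted[i], nodes_sorted[j]
                ):
                    g.add_edge(nodes_sorted[i], nodes_sorted[j], weight=1.0)
                pos += 1
        species[tag] = g
        members[tag] = comp_lists
        complexes[tag] = [
            ProteinComplex(frozenset(c), graph_density(g.subgraph(c)))
            for c in comp_lists
        ]

    orthologs = set()
    for tf in roster:
        orthologs.add((tf.tf_id, f"{tf.tf_id}_B"))
    # exactly round(rate * size) members of each complex are conserved
    for ca, cb in zip(members["A"], members["B"]):
        n_cons = int(round(cfg.conservation_rate * len(ca)))
        picks = rng.choice(len(ca), size=n_cons, replace=False)
        for i in sorted(picks):
            orthologs.add((ca[i], cb[i]))
    return species["A"], species["B"], complexes["A"], complexes["B"], orthologs


# ---------------------------------------------------------------------------
# conserved clusters


def gen_clusters(cfg: SyntheticConfig, roster) -> list:
    """Conserved-cluster lists over the TF roster.

    Hot TFs recur across most clusters (high cluster frequency, hence
    relevance near 1); each cluster is padded with a few random cold TFs.
    """
    rng = cfg.rng("clusters")
    cold = [tf.tf_id for tf in roster if not tf.is_hot]
    clusters = []
    for _ in range(cfg.n_clusters):
        members = {tf.tf_id for tf in roster if tf.is_hot and rng.random() < cfg.cluster_hot_p}
        if cold:
            picks = rng.choice(len(cold), size=min(cfg.cluster_bg_size, len(cold)),
                               replace=False)
            members |= {cold[i] for i in picks}
        if len(members) >= 2:
            clusters.append(frozenset(members))
    return clusters


# ---------------------------------------------------------------------------
# GO DAG + annotations


def gen_go(cfg: SyntheticConfig, designated, other_genes):
    """Balanced is_a DAG plus annotations separating designated genes.

    The marker term (first leaf of the first branch) annotates exactly the
    ``designated`` genes; all ``other_genes`` are annotated to leaves of
    the last branch, so the marker term's gap score against the designated
    subset is positive by construction.
    """
    rng = cfg.rng("go")
    dag = GoDag()
    dag.add_term(GO_ROOT, "biological_process", "root process")
    levels = [[GO_ROOT]]
    counter = 1
    for _depth in range(cfg.go_depth):
        level = []
        for parent in levels[-1]:
            for _ in range(cfg.go_branching):
                term = f"GO:{1000000 + counter:07d}"
                counter += 1
                dag.add_term(term, "biological_process", f"synthetic term {counter}")
                dag.add_edge(term, parent, "is_a")
                level.append(term)
        levels.append(level)
    leaves = levels[-1]
    marker = leaves[0]
    distant = [t for t in leaves if t != marker][-max(1, len(leaves) // 2):]

    annotations: dict = {}
    for gene in designated:
        annotations.setdefault(gene, set()).add(marker)
    for gene in other_genes:
        if gene in annotations:
            continue
        picks = rng.choice(len(distant), size=min(cfg.annotations_per_gene, len(distant)),
                           replace=False)
        annotations[gene] = {distant[i] for i in picks}
    return dag, AnnotationMap(annotations), marker


# ---------------------------------------------------------------------------
# full bundle


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate every input class in memory, with consistent ground truth."""
    genome_codes, hot, cold = gen_genome_and_spots(cfg)
    roster = make_roster(cfg)
    truth = plant_motifs(cfg, genome_codes, hot, cold, roster)
    genome = {c: _codes_to_str(codes) for c, codes in genome_codes.items()}
    ppi_a, ppi_b, cx_a, cx_b, orthologs = gen_ppi_with_complexes(cfg, roster)
    hot_tfs = [tf.tf_id for tf in roster if tf.is_hot]
    designated = set(hot_tfs) | {m for c in cx_a for m in c.members}
    others = sorted(set(ppi_a.nodes()) - designated)
    dag, ann, marker = gen_go(cfg, sorted(designated), others)
    bundle = SyntheticBundle(
        config=cfg,
        genome=genome,
        hotspots=hot,
        coldspots=cold,
        roster=roster,
        motifs=roster_motifs(cfg, roster),
        planted_hits=truth,
        ppi_a=ppi_a,
        ppi_b=ppi_b,
        true_complexes_a=cx_a,
        true_complexes_b=cx_b,
        orthologs=orthologs,
        clusters=gen_clusters(cfg, roster),
        go_dag=dag,
        annotations=ann,
        marker_term=marker,
    )
    return bundle


def _write_obo(dag: GoDag, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(dag.terms()):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.name.get(term, term)}\n")
            fh.write(f"namespace: {dag.namespace.get(term, '')}\n")
            for _, parent, rel in sorted(dag.graph.out_edges(term, keys=True)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def _write_gaf(ann: AnnotationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in sorted(ann.annotations):
            for term in sorted(ann.annotations[gene]):
                cols = ["SYN", gene, gene, "", term, "SYN:0001", "IEA", "", "P",
                        "", "", "protein", "taxon:0", "20140911", "SYN", "", ""]
                fh.write("\t".join(cols) + "\n")


def write_bundle(cfg: SyntheticConfig, outdir) -> dict:
    """Write the full bundle to ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(cfg)
    paths = {
        "genome": outdir / "genome.fa",
        "hotspots": outdir / "hotspots.bed",
        "coldspots": outdir / "coldspots.bed",
        "motifs": outdir / "motifs.pfm",
        "ppi_a": outdir / "ppi_speciesA.tsv",
        "ppi_b": outdir / "ppi_speciesB.tsv",
        "orthologs": outdir / "orthologs.tsv",
        "clusters": outdir / "clusters.txt",
        "obo": outdir / "ontology.obo",
        "gaf": outdir / "annotations.gaf",
        "truth": outdir / "truth.json",
    }
    io_formats.write_fasta(bundle.genome, paths["genome"])
    io_formats.write_intervals(bundle.hotspots, paths["hotspots"])
    io_formats.write_intervals(bundle.coldspots, paths["coldspots"])
    io_formats.write_jaspar_pfm(bundle.motifs, paths["motifs"])
    io_formats.write_network(bundle.ppi_a, paths["ppi_a"])
    io_formats.write_network(bundle.ppi_b, paths["ppi_b"])
    io_formats.write_orthologs(bundle.orthologs, paths["orthologs"])
    io_formats.write_clusters(bundle.clusters, paths["clusters"])
    _write_obo(bundle.go_dag, paths["obo"])
    _write_gaf(bundle.annotations, paths["gaf"])
    truth = {
        "hot_tfs": bundle.hot_tf_ids,
        "roster": [asdict(tf) for tf in bundle.roster],
        "planted_hits": bundle.planted_hits,
        "complexes_a": [c.sorted_members() for c in bundle.true_complexes_a],
        "complexes_b": [c.sorted_members() for c in bundle.true_complexes_b],
        "marker_term": bundle.marker_term,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    manifest = {
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "paths": {k: str(v) for k, v in paths.items()},
        "checksums": {
            k: hashlib.sha256(Path(v).read_bytes()).hexdigest() for k, v in paths.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
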