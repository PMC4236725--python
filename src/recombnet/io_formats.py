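"""Readers and writers for the external formats the pipeline touches.

Every reader returns ``(result, ParseReport)``; malformed records are
skipped and counted rather than aborting the run, except where a file is
structurally unusable (wrong motif shape, cyclic ontology, non-numeric
edge weight), which raises ``ValueError``.

Coordinate convention: everything is stored 0-based half-open. BED is
consumed as-is; FIMO TSV (1-based inclusive) is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet

from .motif_scan import GenomeIntervalSet, GenomicInterval, MotifHit, MotifMatrix


@dataclass
class ParseReport:
    n_records: int = 0
    n_skipped: int = 0
    warnings: list = field(default_factory=list)

    def skip(self, message: str) -> None:
        self.n_skipped += 1
        self.warnings.append(message)


# ---------------------------------------------------------------------------
# intervals (BED)


def read_intervals(path, genome_index: dict, label: str = "other"):
    """Read a BED3+ file into a GenomeIntervalSet, 0-based half-open.

    Lines with unknown chromosomes, non-integer or inverted coordinates, or
    coordinates beyond the chromosome length are skipped with a warning.
    """
    report = ParseReport()
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                report.skip(f"line {lineno}: fewer than 3 BED fields")
                continue
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                report.skip(f"line {lineno}: non-integer coordinates")
                continue
            if chrom not in genome_index:
                report.skip(f"line {lineno}: unknown chromosome {chrom!r}")
                continue
            if not (0 <= start < end <= genome_index[chrom]):
                report.skip(f"line {lineno}: invalid interval {chrom}:{start}-{end}")
                continue
            ivs.append(GenomicInterval(chrom, start, end, label))
            report.n_records += 1
    return GenomeIntervalSet(label, ivs), report


def write_intervals(interval_set: GenomeIntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in interval_set:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{interval_set.label}\n")


# ---------------------------------------------------------------------------
# genome (FASTA)


def read_fasta(path):
    """Read FASTA into {name: sequence}; returns (dict, ParseReport)."""
    from Bio import SeqIO

    report = ParseReport()
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
        report.n_records += 1
    return genome, report


def write_fasta(genome: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def chrom_lengths(genome: dict) -> dict:
    return {name: len(seq) for name, seq in genome.items()}


# ---------------------------------------------------------------------------
# motifs


def _parse_jaspar_pfm(lines):
    motifs = []
    current_id, rows = None, []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current_id is not None:
                motifs.append((current_id, rows))
            current_id = line[1:].split()[0]
            rows = []
        else:
            # tolerate "A [ 1 2 3 ]" and bare "1 2 3" styles
            parts = line.replace("[", " ").replace("]", " ").split()
            if parts and parts[0].upper() in "ACGT" and len(parts[0]) == 1:
                parts = parts[1:]
            rows.append([float(x) for x in parts])
    if current_id is not None:
        motifs.append((current_id, rows))
    return motifs


def _parse_meme_minimal(lines):
    motifs = []
    it = iter(lines)
    for line in it:
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            rows = []
            for line2 in it:
                s = line2.strip()
                if s.startswith("letter-probability"):
                    continue
                if not s:
                    if rows:
                        break
                    continue
                if s.startswith(("MOTIF", "URL")):
                    break
                try:
                    rows.append([float(x) for x in s.split()])
                except ValueError:
                    break
            # MEME stores one row per position, columns A C G T
            motifs.append((motif_id, list(map(list, zip(*rows)))))
    return motifs


def read_motifs(path, dialect: str = "jaspar_pfm"):
    """Read motifs from a JASPAR PFM or MEME minimal file.

    Raises ValueError for matrices without exactly 4 nucleotide rows or with
    negative entries (hard errors: the file is unusable, not merely noisy).
    """
    report = ParseReport()
    with open(path) as fh:
        lines = fh.readlines()
    if dialect == "jaspar_pfm":
        raw = _parse_jaspar_pfm(lines)
    elif dialect == "meme_minimal":
        raw = _parse_meme_minimal(lines)
    else:
        raise ValueError(f"unknown motif dialect {dialect!r}")
    motifs = []
    for motif_id, rows in raw:
        if len(rows) != 4 or any(len(r) != len(rows[0]) for r in rows):
            raise ValueError(f"malformed motif {motif_id!r}: expected 4 equal-length rows")
        motifs.append(MotifMatrix(motif_id, np.array(rows)))
        report.n_records += 1
    return motifs, report


def write_jaspar_pfm(motifs, path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id}\n")
            for b, row in zip("ACGT", m.counts):
                fh.write(f"{b} [ " + " ".join(f"{x:g}" for x in row) + " ]\n")


# ---------------------------------------------------------------------------
# FIMO-style hits

_FIMO_COLUMNS = ("motif_id", "sequence_name", "start", "stop", "strand", "score", "p-value")


def read_fimo_hits(path):
    """Read a FIMO TSV (modern header dialect) into MotifHit records.

    FIMO coordinates are 1-based inclusive; they are converted to 0-based
    half-open. Rows with unparseable numbers are skipped with a warning.
    """
    report = ParseReport()
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            return [], report
        header = header_line.rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for required in ("motif_id", "sequence_name", "start", "stop", "p-value"):
            if required not in col:
                raise ValueError(f"FIMO file missing required column {required!r}")
        hits = []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                start = int(fields[col["start"]])
                stop = int(fields[col["stop"]])
                p = float(fields[col["p-value"]])
                score = float(fields[col["score"]]) if "score" in col else 0.0
            except (ValueError, IndexError):
                report.skip(f"line {lineno}: unparseable numeric field")
                continue
            strand = fields[col["strand"]] if "strand" in col else "+"
            hits.append(
                MotifHit(
                    motif_id=fields[col["motif_id"]],
                    chrom=fields[col["sequence_name"]],
                    start=start - 1,
                    end=stop,
                    strand=strand,
                    score=score,
                    p_value=p,
                )
            )
            report.n_records += 1
    return hits, report


def write_fimo_hits(hits, path) -> None:
    """Write hits in FIMO TSV layout (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write(
            "motif_id\tmotif_alt_id\tsequence_name\tstart\tstop\tstrand\tscore\tp-value\tq-value\tmatched_sequence\n"
        )
        for h in hits:
            fh.write(
                f"{h.motif_id}\t\t{h.chrom}\t{h.start + 1}\t{h.end}\t{h.strand}"
                f"\t{h.score:.4f}\t{h.p_value:.6g}\t\t\n"
            )


# ---------------------------------------------------------------------------
# PPI network


def read_network(path):
    """Read a 2- or 3-column TSV edge list into an undirected simple graph.

    Duplicate edges keep the maximum weight; self-loops are dropped with a
    warning (their endpoints remain as nodes); a non-numeric weight is a
    hard error.
    """
    report = ParseReport()
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                report.skip(f"line {lineno}: fewer than 2 columns")
                continue
            u, v = fields[0], fields[1]
            if len(fields) >= 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ValueError(f"line {lineno}: non-numeric weight {fields[2]!r}")
            else:
                w = 1.0
            if w <= 0:
                report.skip(f"line {lineno}: non-positive weight")
                continue
            if u == v:
                g.add_node(u)
                report.skip(f"line {lineno}: self-loop on {u!r} dropped")
                continue
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
            report.n_records += 1
    return g, report


def write_network(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):g}\n")


# ---------------------------------------------------------------------------
# ontology (OBO) + annotations (GAF)


def read_ontology(obo_path, gaf_path):
    """Load a GO DAG (OBO 1.2) and a GAF 2.x annotation file.

    Returns ``(GoDag, AnnotationMap, ParseReport)``. Obsolete terms are
    excluded by the OBO parser; annotations with a NOT qualifier or to
    unknown terms are skipped with warnings; a cyclic ontology is a hard
    error.
    """
    from .go_semantics import AnnotationMap, GoDag

    report = ParseReport()
    graph = obonet.read_obo(str(obo_path))
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("ontology graph contains a cycle")
    dag = GoDag.from_obonet(graph)

    annotations: dict = {}
    with open(gaf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                report.skip(f"line {lineno}: fewer than 5 GAF columns")
                continue
            gene, qualifier, term = fields[1], fields[3], fields[4]
            if "NOT" in qualifier.split("|"):
                report.skip(f"line {lineno}: NOT qualifier")
                continue
            if term not in dag:
                report.skip(f"line {lineno}: unknown term {term!r}")
                continue
            annotations.setdefault(gene, set()).add(term)
            report.n_records += 1
    return dag, AnnotationMap(annotations), report


# ---------------------------------------------------------------------------
# clusters + orthologs


def read_clusters(path):
    """One whitespace-separated gene list per line; clusters of size < 2 dropped."""
    report = ParseReport()
    clusters = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            genes = line.split()
            if not genes:
                continue
            n_lines += 1
            if len(set(genes)) < 2:
                report.skip(f"line {lineno}: cluster of size < 2 dropped")
                continue
            clusters.append(frozenset(genes))
            report.n_records += 1
    if n_lines == 0:
        report.warnings.append("empty cluster file")
    return clusters, report


def write_clusters(clusters, path) -> None:
    with open(path, "w") as fh:
        for cluster in clusters:
            fh.write(" ".join(sorted(cluster)) + "\n")


def read_orthologs(path):
    """Two-column TSV of (species A id, species B id) pairs, deduplicated."""
    report = ParseReport()
    pairs = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                report.skip(f"line {lineno}: fewer than 2 columns")
                continue
            pair = (fields[0], fields[1])
            if pair in pairs:
                report.skip(f"line {lineno}: duplicate pair {pair}")
                continue
            pairs.add(pair)
            report.n_records += 1
    return pairs, report


def write_orthologs(pairs, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")
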