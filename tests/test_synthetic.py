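import json
from collections import Counter

import networkx as nx
import pytest

from conftest import tiny_config
from recombnet import motif_scan
from recombnet.complex_detect import na_score
from recombnet.go_semantics import geneset_similarity, gap_score
from recombnet.synthetic import (
    SyntheticConfig,
    gen_genome_and_spots,
    gen_go,
    generate_bundle,
    make_roster,
    write_bundle,
)


class TestGenomeAndSpots:
    def test_deterministic_bundle_bytes(self, tmp_path):
        cfg = tiny_config(seed=3)
        m1 = write_bundle(cfg, tmp_path / "run1")
        m2 = write_bundle(tiny_config(seed=3), tmp_path / "run2")
        assert m1["checksums"] == m2["checksums"]

    def test_different_seed_different_genome(self, tmp_path):
        m1 = write_bundle(tiny_config(seed=3), tmp_path / "a")
        m2 = write_bundle(tiny_config(seed=4), tmp_path / "b")
        assert m1["checksums"]["genome"] != m2["checksums"]["genome"]

    def test_no_hotspots_gives_empty_set(self):
        cfg = tiny_config(n_hotspots=0)
        _, hot, cold = gen_genome_and_spots(cfg)
        assert hot.n == 0 and cold.n == cfg.n_coldspots

    def test_length_multisets_match(self):
        _, hot, cold = gen_genome_and_spots(tiny_config())
        assert Counter(iv.length for iv in hot) == Counter(iv.length for iv in cold)

    def test_intervals_do_not_overlap(self):
        _, hot, cold = gen_genome_and_spots(tiny_config())
        by_chrom = {}
        for iv in list(hot) + list(cold):
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_impossible_placement_raises(self):
        cfg = tiny_config(chrom_lengths={"chr1": 1_000}, n_hotspots=50, n_coldspots=50)
        with pytest.raises(RuntimeError):
            gen_genome_and_spots(cfg)


class TestPlanting:
    def test_rate_one_plants_everywhere(self):
        cfg = tiny_config(hot_rate_hotspot=1.0, background_rate=0.0, n_hot_tfs=1, n_tfs=2)
        bundle = generate_bundle(cfg)
        hot_tf = bundle.hot_tf_ids[0]
        planted = [t for t in bundle.planted_hits
                   if t["tf"] == hot_tf and t["label"] == "hotspot"]
        assert len(planted) == cfg.n_hotspots
        assert all(t["status"] == "planted" for t in planted)

    def test_rate_zero_plants_nothing(self):
        cfg = tiny_config(hot_rate_hotspot=0.0, hot_rate_coldspot=0.0, background_rate=0.0)
        bundle = generate_bundle(cfg)
        assert all(t["status"] != "planted" for t in bundle.planted_hits) and not bundle.planted_hits

    def test_truth_table_consistent_with_genome(self, tiny_bundle):
        consensus = {tf.tf_id: tf.consensus for tf in tiny_bundle.roster}
        planted = [t for t in tiny_bundle.planted_hits if t["status"] == "planted"]
        assert planted
        for t in planted:
            seq = tiny_bundle.genome[t["chrom"]][t["start"]: t["end"]]
            assert seq == consensus[t["tf"]]

    def test_scanner_recovers_at_least_planted_count(self, tiny_bundle):
        tf = tiny_bundle.roster[0]
        planted = sum(
            1 for t in tiny_bundle.planted_hits
            if t["tf"] == tf.tf_id and t["status"] == "planted" and t["label"] == "hotspot"
        )
        m = motif_scan.one_hot_matrix(tf.tf_id, tf.consensus)
        hits = motif_scan.scan_intervals(
            m, tiny_bundle.genome, tiny_bundle.hotspots,
            p_threshold=4 ** -len(tf.consensus) * 1.5,
        )
        assert len(hits) >= planted

    def test_planted_occurrences_never_overlap(self, tiny_bundle):
        spans = {}
        for t in tiny_bundle.planted_hits:
            if t["status"] != "planted":
                continue
            spans.setdefault(t["chrom"], []).append((t["start"], t["end"]))
        for chrom_spans in spans.values():
            chrom_spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(chrom_spans, chrom_spans[1:]))


class TestRoster:
    def test_consensi_distinct_including_revcomp(self):
        roster = make_roster(tiny_config(n_tfs=20))
        rc = lambda s: s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seen = set()
        for tf in roster:
            assert tf.consensus not in seen and rc(tf.consensus) not in seen
            seen.add(tf.consensus)


class TestPPI:
    def test_degenerate_cliques(self):
        cfg = tiny_config(background_p=0.0, intra_complex_p=1.0, tf_complex_edges=0)
        bundle = generate_bundle(cfg)
        for c in bundle.true_complexes_a:
            sub = bundle.ppi_a.subgraph(c.members)
            n = len(c.members)
            assert sub.number_of_edges() == n * (n - 1) // 2

    def test_full_conservation_gives_na_one(self):
        cfg = tiny_config(conservation_rate=1.0)
        bundle = generate_bundle(cfg)
        for ca, cb in zip(bundle.true_complexes_a, bundle.true_complexes_b):
            assert na_score(ca, cb, bundle.orthologs) == pytest.approx(1.0)

    def test_partial_conservation_arithmetic(self):
        # 0.6 of a size-5 complex -> exactly 3 ortholog pairs -> NA = 9/25
        cfg = tiny_config(conservation_rate=0.6, complex_sizes=(5,))
        bundle = generate_bundle(cfg)
        ca, cb = bundle.true_complexes_a[0], bundle.true_complexes_b[0]
        assert na_score(ca, cb, bundle.orthologs) == pytest.approx(9 / 25)

    def test_tf_orthologs_complete(self, tiny_bundle):
        tf_pairs = {(tf.tf_id, f"{tf.tf_id}_B") for tf in tiny_bundle.roster}
        assert tf_pairs <= tiny_bundle.orthologs


class TestGO:
    def test_balanced_dag_term_count(self):
        cfg = tiny_config(go_depth=2, go_branching=2)
        dag, _, _ = gen_go(cfg, ["g1"], ["g2"])
        assert len(dag) == 7  # 1 + 2 + 4

    def test_marker_similarity_one_for_designated(self, tiny_bundle):
        marker = tiny_bundle.marker_term
        designated = [tf.tf_id for tf in tiny_bundle.roster if tf.is_hot]
        s = geneset_similarity(marker, designated, tiny_bundle.annotations,
                               tiny_bundle.go_dag)
        assert s == pytest.approx(1.0)

    def test_marker_gap_positive_for_hot_tfs(self, tiny_bundle):
        hg = set(tiny_bundle.hot_tf_ids)
        g = {tf.tf_id for tf in tiny_bundle.roster}
        r = gap_score(tiny_bundle.marker_term, hg, g, tiny_bundle.annotations,
                      tiny_bundle.go_dag)
        assert r.defined and r.gap > 0

    def test_written_bundle_is_self_consistent(self, tmp_path):
        from recombnet import io_formats

        cfg = tiny_config(seed=5)
        manifest = write_bundle(cfg, tmp_path / "bundle")
        paths = manifest["paths"]
        genome, _ = io_formats.read_fasta(paths["genome"])
        lengths = io_formats.chrom_lengths(genome)
        assert lengths == cfg.chrom_lengths
        hot, rep = io_formats.read_intervals(paths["hotspots"], lengths, "hotspot")
        assert hot.n == cfg.n_hotspots and rep.n_skipped == 0
        motifs, _ = io_formats.read_motifs(paths["motifs"], "jaspar_pfm")
        assert len(motifs) == cfg.n_tfs
        net, _ = io_formats.read_network(paths["ppi_a"])
        truth = json.loads((tmp_path / "bundle" / "truth.json").read_text())
        for members in truth["complexes_a"]:
            assert set(members) <= set(net.nodes())
        dag, ann, _ = io_formats.read_ontology(paths["obo"], paths["gaf"])
        for tf_id in truth["hot_tfs"]:
            assert truth["marker_term"] in ann.terms_for(tf_id)
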