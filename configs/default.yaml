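# Full default parameter block for `recombnet run --config <file>`.
# CLI flags override config values; inputs must point at existing files.

params:
  # motif scanning
  p_threshold: 1.0e-4        # per-window p-value cutoff for a motif hit
  motif_dialect: jaspar_pfm  # or meme_minimal
  # HB profiling
  bin_length: 5000000        # genome bin size (bases) for hotspot-binding profiles
  pearson_threshold: 0.7     # HB-network edge rule: correlation strictly greater
  # seed selection
  seed_fraction: 0.10        # top fraction of the ranking used as RWR seeds
  p0_mode: scores            # restart vector from prioritization scores | uniform
  method: or                 # ranking that feeds the walk: or | hb | km
  # random walk with restart
  gamma: 0.7                 # restart probability
  tol: 1.0e-10               # L1 convergence threshold
  max_iter: 10000
  top_k: 200                 # induced subnetwork size for complex mining
  # complex detection and matching
  density_threshold: 0.7
  attach_ratio: 0.5
  redundancy_na: 0.25
  na_threshold: 0.25         # conserved-pair matching threshold

inputs:
  genome: bundle/genome.fa
  motifs: bundle/motifs.pfm
  hotspots: bundle/hotspots.bed
  coldspots: bundle/coldspots.bed
  clusters: bundle/clusters.txt
  ppi_a: bundle/ppi_speciesA.tsv
  ppi_b: bundle/ppi_speciesB.tsv
  orthologs: bundle/orthologs.tsv
  obo: bundle/ontology.obo
  gaf: bundle/annotations.gaf

outdir: recombnet_out
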