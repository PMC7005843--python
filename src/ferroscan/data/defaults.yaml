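# Default configuration. Values here are the tool's published defaults;
# override via the `config` argument of the high-level entry points.
homology:
  evalue_cutoff: 1.0e-10      # acceptance threshold for homology-fallback hits
  matrix: BLOSUM62
  gap_open: 11                # affine gap opening penalty (positive convention)
  gap_extend: 1
  # Karlin-Altschul gapped scaling constants for BLOSUM62 11/1
  lambda: 0.267
  K: 0.041
calibrate:
  min_identity: 35.0          # percent amino-acid identity floor for homolog gathering
  min_coverage: 0.7           # fraction of query length that must align
  dereplication_identity: 70.0  # percent identity at which sequences collapse
neighborhoods:
  max_gap: 3                  # max intervening gene-index gap within one neighborhood
annotate:
  heme_motif: CxxCH           # canonical c-type heme-binding motif (x = any residue)
summarize:
  scale_ddof: 1               # sample (n-1) standard deviation for row z-scaling
  scale_input: normalized     # z-score ORF-normalized values (alternative: counts)
  bootstrap_default: 100
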