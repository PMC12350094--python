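# Default pipeline configuration (flat key-value; all keys optional).
# Values shown are the built-in defaults.

# --- hit curation ---
evalue_max: 0.01          # keep CM hits with E-value strictly below this
pair_max_gap: 2000        # max sense-strand gap (nt) between D1-D4 run and D5/D6 hit
pair_max_gap_alt: 3000    # looser gap for fragmented metagenomic contigs
pair_overlap_tolerance: 100  # allowed envelope overlap (nt) when pairing
dedup_flank: 500          # flanking context compared when collapsing duplicates
exclusion_list: []        # genome ids to drop outright (manual curation)

# --- boundary calling ---
five_prime_motif: GWYRG   # conserved 5' splice-site motif (IUPAC)
search_upstream: 150      # motif search window upstream of the D1-D4 hit start
search_into_hit: 30       # ... and into the hit
motif_slack: 5            # refined 5' must carry the motif within this many nt

# --- intron-encoded proteins ---
min_orf_aa: 150           # minimum stop-free ORF length
iep_evalue_cutoff: 0.001  # domain hits at or above this i-E-value are ignored

# --- interaction windows ---
exon5_window: 20          # nt of 5' exon searched for IBS1/IBS2
exon3_window: 10          # nt of 3' exon searched for delta'
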