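# lariat

Discovery and annotation of **group II introns in phage genomes** from
covariance-model hit tables.

Group II introns are self-splicing ribozymes and retroelements. They carry
almost no primary sequence conservation but a strongly conserved six-domain
secondary structure (D1–D6), which makes RNA structure-aware homology search
with covariance models (profile SCFGs, e.g. Infernal + the Rfam models for
the intron's 5′ D1–D4 region and its conserved 3′ D5/D6 core) the method of
choice for finding them. What the search tools emit, however, is only a table
of partial-model hits. `lariat` turns those tables into curated intron calls:

- **Hit curation** — E-value filtering (`E < 0.01`), pairing of D1–D4 hits
  with their downstream D5/D6 partner (gap ≤ 2 kb on the sense strand),
  completeness labelling (complete / 5′-only / 3′-only), and deduplication of
  identical intron loci with identical flanking context.
- **Splice boundaries** — the 5′ site at the conserved `GWYRG` motif near the
  D1–D4 hit start; the 3′ site from the D5/D6 hit end; both refined exactly
  by semi-global alignment of an intronless homolog against the intron-plus
  locus (the intron is the large insertion the homolog skips).
- **Structure annotation** — detection of the long-range pseudoknot and
  tertiary pairings (EBS1:IBS1, EBS2:IBS2, α:α′, β:β′, γ:γ′, δ:δ′, ε:ε′,
  λ:λ′, κ:κ′, ζ:ζ′) as antiparallel duplexes (Watson–Crick + bounded G:T
  wobble) between labelled partner regions; the AGC/CGC catalytic triad at
  the start of D5; the bulged branch-point adenosine in D6; and subtype
  classification from the λ–ε′ region (IIA: 11-nt loop with AGC; IIB: 4-nt
  bulge matching AARC; IIC: 7–12-nt loop with AGG).
- **Intron-encoded proteins** — three-frame translation within the intron,
  maximal stop-free ORFs, and classification from protein-domain hits
  (i-E-value < 10⁻³): reverse transcriptase (RVT, e.g. PF00078, usually with
  the maturase "X" domain), homing endonuclease (HEG), other, or none;
  ORF-less introns co-resident with an RVT intron are flagged
  *trans*-mobilizable.
- **Representative selection** — pairwise percent identity (denominator =
  shorter unaligned sequence), single-linkage clustering with an exact-K
  threshold search, capped per-family sampling, and one-per-cluster picks
  for building phylogenetic marker sets (e.g. TerL).
- **Synthetic data** — a generator that plants consensus-conformant introns
  (GWYRG start, D1–D6 skeleton, EBS/IBS complements, subtype motifs,
  catalytic triad, bulged A, optional D4 ORF) into mock genomes and emits
  matching mock `cmsearch --tblout` / `hmmscan --domtblout` tables,
  dot-bracket structures with region labels, intronless homologs, and a
  machine-readable truth table.

The package consumes standard formats (FASTA, Infernal tblout, HMMER
domtblout, Vienna dot-bracket + region TSV) and writes GFF3, TSV inventories
and JSON censuses. It does **not** run the search tools themselves.

## Worked example

Generate a synthetic bundle and run the full pipeline on it:

```bash
$ lariat synthesize --seed 11 --n-genomes 8 --out-dir demo
wrote 8 genomes, 8 introns
manifest: demo/manifest.json

$ lariat run --genomes demo/genomes.fasta --tblout demo/hits.tbl \
    --domtblout demo/domains.domtbl --structures demo/structures.db \
    --homologs demo/homologs.fasta --out-dir demo_out
{"census": {"complete": 8, "five_only": 0, "three_only": 0},
 "stages": {"hits_in": 32, "hits_significant": 16, "calls_paired": 8,
            "calls_after_dedup": 8}}
```

32 mock hit rows enter; 16 survive the E-value filter (the other 16 are
planted noise rows straddling the threshold); they pair into 8 complete
calls, none of which are duplicates. The inventory
(`demo_out/inventory.tsv`) then reads:

```
genome_id  intron_index  start  end    strand  completeness  subtype  iep_class  trans_mobilizable  n_interactions_detected
SYN0002    1             13022  15305  +       complete      IIB      RVT        False              10
SYN0002    2             16533  17114  +       complete      IIB      none       True               10
SYN0003    1             15653  17986  -       complete      IIB      HEG        False              10
SYN0004    1             31183  33107  -       complete      IIA      HEG        False              10
SYN0005    1             7183   10097  -       complete      IIB      RVT        False              10
```

Each row is one intron call with exact 1-based boundaries. All ten consensus
pairings were detected for every call. Note `SYN0002` intron 2: a ~580-nt
ORF-less intron flagged `trans_mobilizable=True` because it shares its
genome with an RVT-encoding intron — the biology behind ORF-less intron
persistence. `demo_out/introns.gff3` carries the same calls with child
features for the hits, the IEP ORF and each detected interaction.

The library surface mirrors the CLI: `lariat.curation.pair_hits`,
`lariat.boundaries.refine_boundaries`, `lariat.structure.annotate_interactions`,
`lariat.iep.classify_iep`, `lariat.representatives.threshold_for_k`, and
`lariat.synthetic.generate_bundle` are the main entry points.

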