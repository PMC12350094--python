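# Methods

This note documents the models, procedures and numerical choices behind
`lariat`, and what the synthetic test bed does and does not demonstrate.

## The calling model

A complete group II intron appears in a covariance-model search as one or
two hits: a hit to one of the 5′-end (D1–D4) models and a hit to the
conserved 3′ (D5/D6) model a few hundred nucleotides to ~1 kb downstream
(ORF-less vs ORF-containing introns respectively). The caller therefore:

1. **Filters** hits at `E < 0.01` (strict inequality). The threshold is the
   conventional significance cutoff for this kind of search and is exposed
   as `PipelineConfig.evalue_max`.
2. **Pairs** hits per (genome, strand) in 5′→3′ sense order. Consecutive
   D1–D4 hits within `pair_max_gap` (default 2000 nt) merge into one run —
   the seven 5′-end models are alternatives for the same region, and a
   single intron can legitimately produce two D1–D4 hits. A run is closed
   by the nearest downstream D5/D6 hit whose gap (sense 5′ start of the
   D5/D6 hit minus sense 3′ end of the run) is at most `pair_max_gap`;
   gaps measure envelope distance, not midpoints, because the D5/D6 hit
   begins where the D1–D4 envelope ends. Because hit envelopes from
   independent models may abut or slightly overlap, a negative gap down to
   `pair_overlap_tolerance` (100 nt) still pairs. Assignment is greedy
   nearest-downstream — hits are processed in sense order, so once a D5/D6
   hit is too far from the open run, nothing downstream can be closer and
   the run is flushed as a 5′-only call. Every hit lands in exactly one
   call; the test suite checks this against a brute-force oracle.
   A looser gap (`pair_max_gap_alt`, 3000 nt) is provided for fragmented
   metagenomic contigs but is not the default.
3. **Deduplicates**: calls with byte-identical intron-region sequence *and*
   byte-identical flanking context (500 nt each side, sense strand) are
   collapsed to one representative (lexicographically smallest genome id,
   for determinism). Identical introns in *different* context are all kept:
   an identical element at a different locus is independent evidence, not a
   database duplicate. An explicit exclusion list supports manual removals
   (misannotated prophages, integrative elements); each drop is logged with
   a reason.

## Boundary resolution

The 5′ splice site of group II introns falls on a conserved `GWYRG` motif.
The caller scans the window from 150 nt upstream of the D1–D4 hit start to
30 nt into the hit (both configurable; the upstream reach is a design
choice — the motif is only described as being "in the upstream vicinity" of
the 5′ hit) and takes the match closest to the hit start, ties upstream.
The 3′ splice site is taken as the end of the D5/D6 hit; whether the true
terminus extends a nucleotide or two beyond D6 is not resolvable from the
hit alone, which is precisely why homolog refinement exists.

When an intronless homolog of the host gene is available, both boundaries
are pinned at once: the homolog is aligned semi-globally (its own ends must
align; locus overhangs are free) against the intron-plus locus, and the
largest unaligned locus insertion overlapping the coarse call is the
intron. A refined 5′ boundary must carry the `GWYRG` motif within ±5 nt or
the coarse boundaries are kept and the call flagged. Refined boundaries
take precedence over motif-only ones.

**Alignment scoring.** General pairwise alignment (`align_pair`,
`percent_identity`) uses match +2, mismatch −1, gap open −5, extension −1
(a gap of length L costs −5 − (L−1)); the suite verifies optimality against
exhaustive enumeration on short strings. The homolog-vs-locus alignment is
the one place this scoring cannot work: an intron insertion is routinely
2–3 kb while the informative exon match is only a few hundred nt, so a
linear −1/nt insertion cost would make force-aligning exon into intron
sequence outscore skipping the intron. The refinement aligner therefore
keeps match/mismatch/open but uses a near-free insertion extension (−0.05/nt).
With both junctions locally unambiguous, the optimal alignment then places
the intron as a single insertion block with exact endpoints.

Percent identity uses the *shorter unaligned sequence length* as
denominator, so a perfect substring scores 100. The identity matrix aligns
shorter-against-longer semi-globally for the same reason.

## Interaction detection

Profile SCFGs cannot model pseudoknots, so the consensus long-range
pairings are independent evidence for a call. Detection is deliberately a
*complementarity test given labelled regions*, not ab-initio structure
prediction: partner intervals come from a curated or synthetic
`StructureRecord` (the real-data workflow for these regions is prediction
tools plus manual curation, which automation should check, not replace).
For each rule the best antiparallel duplex between the two segments is
found under Watson–Crick pairing plus at most one G:T wobble (wobble policy
is a package decision, exposed per rule). EBS segments are restricted to
unpaired positions of the labelled interval; IBS1 is searched in the last
10 nt of the 5′ exon, IBS2 in the 10 nt upstream of the detected IBS1, and
δ′ in the first 3 nt of the 3′ exon. Minimum duplex lengths default to
EBS1:IBS1 ≥ 5, EBS2:IBS2 ≥ 4 (the one biologically anchored floor — a
functional EBS2:IBS2 can be as short as 4 bp), α/β ≥ 4, λ/κ/ζ ≥ 2,
γ/δ/ε ≥ 1. All are configuration, not biology claims.

Subtype classification reads the λ–ε′ region: IIA is an 11-nt loop
containing AGC, IIB a 4-nt bulge matching the IUPAC pattern AARC, IIC a
7–12-nt loop containing AGG (checked only when IIA fails; a length-11 loop
carrying both motifs counts as IIA, since the 11-nt loop is IIA's defining
signature). Loop-vs-bulge is inferred from the dot-bracket flanks of the
labelled interval. Motif containment (not positional anchoring) is used for
IIA/IIC; the AARC pattern is matched strictly as A-A-[AG]-C. The catalytic
checks are fixed: AGC or CGC within the first 5 nt of D5, and a first
unpaired adenosine with paired neighbours inside D6.

## Intron-encoded proteins

Only the three sense-strand frames are translated (the IEP lies in D4 on
the intron's own strand). ORFs are maximal stop-free stretches of ≥150 aa
(`min_orf_aa`; below typical RVT/HEG sizes, above random expectation for
multi-kb introns) with no start-codon requirement — identification rests on
domain evidence, not gene calling. Domain hits with i-E-value ≥ 10⁻³ are
discarded; an RVT-domain accession (default {PF00078, PF07727}) wins over
everything, a nuclease-like accession without RVT gives HEG, any other
passing domain gives "other", nothing gives "none". The nuclease accession
set is deliberately user-extensible: phage intron HEGs are not closely
related to the classic HEG families, so whatever the user's domain search
reports must be mappable in. The architecture string orders passing domains
by alignment start (RT, X, En, or the raw domain name).

Trans-mobilizability is a per-genome closure: every non-RVT intron in a
genome that also contains at least one RVT-encoding intron is flagged.

## Representative selection

Single-linkage clustering is connected components of the graph with edges
where identity ≥ threshold (≥, not >, is the edge semantics; exposed in
config). The cluster count is a non-decreasing step function of the
threshold that changes only at observed identity values, so the exact-K
search binary-searches the finite candidate set (distinct off-diagonal
values, midpoints, and one value above the maximum) and returns the largest
threshold achieving K, for determinism; unreachable K raises an error
reporting the bracketing achievable counts. Capped sampling and
one-per-cluster picks use a seeded generator with sorted iteration order,
so results are reproducible to the byte.

## The synthetic generator

The generator stands in for the real inputs (a curated ~29k-genome phage
collection and a 15.7M-contig metagenomic set searched with the Rfam
group II models) at desk scale. Defaults encode the study conditions: a
subtype mix dominated by IIB (80%) with IIA (15%) and IIC (5%) minorities;
IEP classes ~35% RVT / 20% HEG / 45% ORF-less; ORF-less introns ~600 nt and
ORF-containing ~2–3 kb; mock hit envelopes covering the planted D1–D4 and
D5–D6 intervals with ±10 nt jitter (so boundary refinement is actually
exercised); E-values log-uniform in [10⁻¹², 10⁻³] for planted rows and
straddling the 0.01 threshold for noise rows; genomes ~30 kb of i.i.d.
uniform background around codon-encoded host genes.

Planted introns are consensus-conformant by construction: GWYRG start, six
labelled domains in order, EBS1/EBS2 in unpaired D1 loop positions with
their reverse complements written into the 5′ exon tail, δ′ at the 3′ exon
start, the subtype region realized as the matching loop/bulge, AGC/CGC at
D5, a bulged A in D6, and γ′ as the final intron nucleotide. ORFs are
random proteins codon-encoded into the D4 loop, bounded by in-frame stops
on both sides so recovery coordinates are exact; EBS/δ choices are
pre-screened so the overwritten exon codons can never contain a stop, and
the two junction-adjacent bases are constrained to differ across the
junction so that the intron insertion has a unique optimal placement in the
homolog alignment. Spurious GWYRG occurrences in the upstream background
are allowed and exercise nearest-match selection. Intronless homologs are
the stitched exons, optionally mutated at a configurable substitution rate
(sparing 6 nt at the junction). Same seed ⇒ byte-identical outputs; a
manifest records config, seed and content hashes.

**What passing does and does not show.** The generator's backgrounds are
i.i.d. uniform, its exons are clean single-copy genes, its structures are
idealized hairpins, and its mock hit tables have no systematic biases —
perfect recovery here validates the *logic* (coordinate handling, strand
arithmetic, pairing, refinement, classification rules), not performance on
real genomes with repeats, nested elements, degraded introns or model
mis-specification. Real-data calls still need the independent evidence
lines the pipeline surfaces (interactions detected, triad/bulged-A flags,
homolog consistency).

## Problem sizes and determinism

Test and acceptance workloads are sized for interactive turnaround: the
end-to-end acceptance bundle is 50 genomes (~30 planted introns, a few
seconds total), oracle equivalence checks run on instances small enough for
exhaustive enumeration (alignments ≤ 6 nt, duplexes ≤ 12 nt, pairing ≤ 8
hits, clustering ≤ 12 sequences), and the marker-clustering demonstration
uses 30 synthetic families of 2 members. The pipeline itself is fully
deterministic given inputs and configuration — randomness exists only in
the generator and in the two sampling operations, all seeded; no timestamps
are written to outputs.

## Known limitations

- Interaction detection requires labelled partner regions; there is no
  ab-initio pseudoknot prediction.
- The 3′ boundary without a homolog is exactly the D5/D6 hit end.
- Clan competition among overlapping 5′-end model hits is handled by run
  merging (lowest E-value first) rather than formal model competition.
- Six-frame ORF search, phylogenetic tree inference, and searching public
  databases for homologs are out of scope; the package prepares the inputs
  such analyses consume.
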