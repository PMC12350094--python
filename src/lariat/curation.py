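"""Filtering, pairing and deduplication of covariance-model hits.

This is the core calling step: significant hits to the 5' (D1-D4) and 3'
(D5/D6) parts of the group II intron consensus are grouped per genome and
strand and joined into putative intron calls. A complete intron shows a
D1-D4 hit with a D5/D6 hit a few hundred nucleotides to ~1 kb downstream;
hits without a partner become partial (five_only / three_only) calls.
Identical intron loci with identical flanking context are collapsed to a
single representative, mirroring manual duplicate-genome removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from lariat._dna import revcomp
from lariat.io import CMHit, ModelType, SeqRecord

log = logging.getLogger(__name__)

COMPLETE = "complete"
FIVE_ONLY = "five_only"
THREE_ONLY = "three_only"


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds for hit filtering, pairing, and deduplication.

    evalue_max
        Hits with E-value >= this are discarded (strict ``<`` comparison).
    pair_max_gap
        Maximum sense-strand gap (nt) between the 3' end of a D1-D4 hit
        run and the 5' end of its downstream D5/D6 partner; also the
        merge distance for consecutive D1-D4 hits.
    pair_max_gap_alt
        Looser gap used for fragmented metagenomic contigs.
    pair_overlap_tolerance
        Hit envelopes from independent models may abut or slightly
        overlap; a negative gap down to this many nt still pairs.
    dedup_flank
        Flanking context (nt each side) compared when collapsing calls
        with identical intron-region sequence.
    exclusion_list
        Genome ids removed outright (manual curation decisions).
    """

    evalue_max: float = 0.01
    pair_max_gap: int = 2000
    pair_max_gap_alt: int = 3000
    pair_overlap_tolerance: int = 100
    dedup_flank: int = 500
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if min(self.evalue_max, self.pair_max_gap, self.pair_max_gap_alt,
               self.dedup_flank) <= 0:
            raise ValueError("all thresholds must be > 0")
        if self.pair_max_gap > self.pair_max_gap_alt:
            raise ValueError("pair_max_gap must be <= pair_max_gap_alt")


@dataclass
class IntronCall:
    """A putative group II intron assembled from one or more CM hits."""

    genome_id: str
    strand: str
    d1d4_hits: list[CMHit] = field(default_factory=list)
    d5d6_hit: Optional[CMHit] = None
    completeness: str = FIVE_ONLY
    five_prime: Optional[int] = None   # 0-based sense position of first intron base
    three_prime: Optional[int] = None  # 0-based sense position one past last base
    subtype: str = "unclassified"
    iep_class: str = "none"
    iep: Optional[object] = None
    trans_mobilizable: bool = False
    interactions: list = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        members = list(self.d1d4_hits) + ([self.d5d6_hit] if self.d5d6_hit else [])
        for h in members:
            if h.target_id != self.genome_id or h.strand != self.strand:
                raise ValueError(
                    f"call {self.genome_id}: member hits must share genome and strand"
                )
        want = (
            COMPLETE if (self.d1d4_hits and self.d5d6_hit)
            else FIVE_ONLY if self.d1d4_hits
            else THREE_ONLY
        )
        if self.completeness != want:
            raise ValueError(
                f"call {self.genome_id}: completeness {self.completeness!r} "
                f"inconsistent with member hits"
            )

    @property
    def hits(self) -> list[CMHit]:
        return list(self.d1d4_hits) + ([self.d5d6_hit] if self.d5d6_hit else [])

    def envelope(self) -> tuple[int, int]:
        """Coarse forward-strand interval (0-based half-open) of all member hits."""
        return (min(h.start for h in self.hits), max(h.end for h in self.hits))

    def resolved_interval(self) -> tuple[int, int]:
        """Forward-strand interval of the resolved boundaries.

        Falls back to the hit envelope where a boundary is unresolved.
        ``five_prime``/``three_prime`` are sense-axis coordinates (minus
        strand = negated forward coordinates, cf. CMHit.sense_start).
        """
        env = self.envelope()
        five = self.five_prime
        three = self.three_prime
        if self.strand == "+":
            lo = five if five is not None else env[0]
            hi = three if three is not None else env[1]
        else:
            lo = -three if three is not None else env[0]
            hi = -five if five is not None else env[1]
        return (min(lo, hi), max(lo, hi)) if lo != hi else env

    def sense_region(self, genome: SeqRecord, lo: int, hi: int) -> str:
        """Sense-strand sequence of the forward interval [lo, hi)."""
        s = genome.seq[max(lo, 0): max(hi, 0)]
        return s if self.strand == "+" else revcomp(s)


def filter_hits(hits: Sequence[CMHit], evalue_max: float) -> list[CMHit]:
    """Keep exactly the hits with E-value strictly below the threshold."""
    return [h for h in hits if h.evalue < evalue_max]


def _sense_gap(upstream: CMHit, downstream: CMHit) -> int:
    """Sense-strand gap from the 3' end of one hit to the 5' start of the next."""
    return downstream.sense_start - upstream.sense_end


def pair_hits(hits: Sequence[CMHit], cfg: PipelineConfig) -> list[IntronCall]:
    """Group filtered hits into intron calls.

    Hits are grouped by (genome, strand) and walked in 5'->3' sense
    order. Consecutive D1-D4 hits within ``pair_max_gap`` merge into one
    run (the seven 5'-end models are alternatives for the same region);
    a run is closed by the nearest downstream D5/D6 hit whose gap is at
    most ``pair_max_gap`` (one complete call). Unpaired runs and D5/D6
    hits become five_only / three_only calls. Every hit lands in exactly
    one call.
    """
    groups: dict[tuple[str, str], list[CMHit]] = {}
    for h in hits:
        if h.model_type is ModelType.UNKNOWN:
            raise ValueError(
                f"hit to model {h.model_name!r} has UNKNOWN type; filter it first"
            )
        groups.setdefault((h.target_id, h.strand), []).append(h)

    calls: list[IntronCall] = []
    for (gid, strand), group in sorted(groups.items()):
        group.sort(key=lambda h: (h.sense_start, h.sense_end, h.evalue))
        run: list[CMHit] = []

        def flush_run() -> None:
            if run:
                calls.append(
                    IntronCall(gid, strand, d1d4_hits=_order_run(run),
                               completeness=FIVE_ONLY)
                )
                run.clear()

        for h in group:
            if h.model_type is ModelType.D1D4:
                if run and _sense_gap(run[-1], h) > cfg.pair_max_gap:
                    flush_run()
                run.append(h)
            else:  # D5D6
                gap = _sense_gap(run[-1], h) if run else None
                if run and -cfg.pair_overlap_tolerance <= gap <= cfg.pair_max_gap:
                    calls.append(
                        IntronCall(gid, strand, d1d4_hits=_order_run(run),
                                   d5d6_hit=h, completeness=COMPLETE)
                    )
                    run.clear()
                else:
                    if run and gap is not None and gap > cfg.pair_max_gap:
                        # nothing further downstream can be closer
                        flush_run()
                    calls.append(
                        IntronCall(gid, strand, d5d6_hit=h, completeness=THREE_ONLY)
                    )
        flush_run()
    return calls


def _order_run(run: list[CMHit]) -> list[CMHit]:
    """Genomic (sense) order; exact-overlap ties put the lowest E-value first."""
    return sorted(run, key=lambda h: (h.sense_start, h.evalue, h.sense_end))


def dedup_calls(
    calls: Sequence[IntronCall],
    genomes: Mapping[str, SeqRecord],
    cfg: PipelineConfig,
) -> list[IntronCall]:
    """Collapse duplicated intron loci and apply the exclusion list.

    Calls are grouped by the exact sense-strand sequence of their hit
    envelope; within a group, a call whose flanking context
    (``dedup_flank`` nt each side, sense strand) matches an earlier kept
    call is dropped. Identical introns in *different* context are all
    kept — an identical intron in a non-identical host locus is
    independent biological evidence, not a database duplicate. The
    lexicographically smallest genome id in each context class is kept
    as representative. Idempotent.
    """
    survivors: list[IntronCall] = []
    by_seq: dict[str, list[tuple[str, IntronCall]]] = {}
    for call in calls:
        if call.genome_id in cfg.exclusion_list:
            log.info("dropping call in %s: genome on exclusion list", call.genome_id)
            continue
        genome = genomes.get(call.genome_id)
        if genome is None:
            raise KeyError(f"no genome sequence for call on {call.genome_id}")
        lo, hi = call.envelope()
        if not (0 <= lo < hi <= len(genome)):
            raise ValueError(
                f"call envelope [{lo},{hi}) outside genome {call.genome_id}"
            )
        by_seq.setdefault(call.sense_region(genome, lo, hi), []).append(
            (call.genome_id, call)
        )

    drop: set[int] = set()
    for intron_seq, members in by_seq.items():
        if len(members) == 1:
            continue
        members.sort(key=lambda t: (t[0],) + t[1].envelope())
        kept_contexts: list[tuple[str, str]] = []
        for gid, call in members:
            genome = genomes[gid]
            lo, hi = call.envelope()
            ctx = (
                call.sense_region(genome, lo - cfg.dedup_flank, lo),
                call.sense_region(genome, hi, hi + cfg.dedup_flank),
            )
            if call.strand == "-":
                ctx = (ctx[1], ctx[0])  # sense order: upstream, downstream
            if ctx in kept_contexts:
                log.info(
                    "dropping call in %s: intron region and %d-nt flanks "
                    "identical to an earlier representative", gid, cfg.dedup_flank,
                )
                drop.add(id(call))
            else:
                kept_contexts.append(ctx)
    for call in calls:
        if call.genome_id in cfg.exclusion_list or id(call) in drop:
            continue
        survivors.append(call)
    return survivors


def completeness_census(calls: Iterable[IntronCall]) -> dict[str, int]:
    """Count calls by completeness; the three counts partition the list."""
    census = {COMPLETE: 0, FIVE_ONLY: 0, THREE_ONLY: 0}
    for call in calls:
        census[call.completeness] += 1
    return census


def proportion_with_introns(n_positive: int, n_total: int) -> float:
    """Percentage of intron-containing genomes, half-even rounded to 2 dp."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_positive <= n_total):
        raise ValueError("need 0 <= n_positive <= n_total")
    pct = Decimal(100 * n_positive) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))
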