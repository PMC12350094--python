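"""Splice-boundary resolution and intronless-homolog validation.

The 5' splice site of a group II intron falls on a conserved GWYRG motif
just upstream of (or slightly inside) the D1-D4 model hit; the 3' splice
site is closely determined by the end of the conserved D5/D6 hit. When an
intronless homolog of the host gene is available, a semi-global alignment
of the homolog against the intron-plus locus pins both boundaries at once:
the intron is the large insertion the homolog skips.

All positions in this module are 0-based on the *sense* strand of the
call; the pipeline handles the strand transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from Bio import Align

from lariat._dna import iupac_regex

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundaryConfig:
    """Parameters of 5' motif search and homolog refinement.

    five_prime_motif
        IUPAC pattern of the conserved 5' splice-site motif
        (W={A,T}, Y={C,T}, R={A,G}).
    search_upstream / search_into_hit
        The motif is scanned in the window starting ``search_upstream``
        nt before the D1-D4 hit start and ending ``search_into_hit`` nt
        into the hit.
    motif_slack
        A homolog-refined 5' boundary must carry the motif starting
        within this many nt, otherwise the coarse boundary is kept.
    """

    five_prime_motif: str = "GWYRG"
    search_upstream: int = 150
    search_into_hit: int = 30
    motif_slack: int = 5

    def __post_init__(self) -> None:
        if len(self.five_prime_motif) < 3:
            raise ValueError("motif must be at least 3 nt")
        if self.search_upstream <= 0 or self.search_into_hit <= 0:
            raise ValueError("search windows must be > 0")


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment with gapped strings and summary statistics."""

    aligned_a: str
    aligned_b: str
    matches: int
    score: float
    a_span: tuple[int, int]  # 0-based half-open on a
    b_span: tuple[int, int]  # 0-based half-open on b

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")


@dataclass(frozen=True)
class RefinedBoundaries:
    five_prime: int
    three_prime: int  # exclusive
    refined: bool
    flag: Optional[str] = None


# Fixed scoring; identical for nucleotide and protein sequences. A gap of
# length L costs open + (L-1) * extend.
MATCH = 2
MISMATCH = -1
GAP_OPEN = -5
GAP_EXTEND = -1


def _aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    al.mode = "global"
    if mode == "semi_global":
        # terminal overhangs of b are free; a must align end to end
        al.end_insertion_score = 0.0
    elif mode != "global":
        raise ValueError(f"unknown alignment mode {mode!r}")
    return al


def find_five_prime(
    sense_genome: str, d1d4_sense_start: int, cfg: BoundaryConfig
) -> Optional[int]:
    """Locate the 5' splice-site motif near the D1-D4 hit start.

    Scans ``[d1d4_sense_start - search_upstream, d1d4_sense_start +
    search_into_hit)`` on the sense strand and returns the motif match
    start closest to the hit start (ties broken upstream-most), or None.
    The window is clipped at contig edges.
    """
    lo = d1d4_sense_start - cfg.search_upstream
    hi = d1d4_sense_start + cfg.search_into_hit
    if lo < 0 or hi > len(sense_genome):
        log.debug("5' search window clipped to contig bounds")
        lo, hi = max(lo, 0), min(hi, len(sense_genome))
    window = sense_genome[lo:hi]
    pat = iupac_regex(cfg.five_prime_motif)
    best: Optional[int] = None
    pos = 0
    while True:
        m = pat.search(window, pos)
        if m is None:
            break
        cand = lo + m.start()
        if best is None or _motif_rank(cand, d1d4_sense_start) < _motif_rank(
            best, d1d4_sense_start
        ):
            best = cand
        pos = m.start() + 1
    return best


def _motif_rank(pos: int, anchor: int) -> tuple[int, int]:
    # closest to the hit start; ties go to the upstream-most candidate
    return (abs(pos - anchor), pos)


def find_three_prime(call) -> int:
    """Sense-strand 3' end of the D5/D6 hit (exclusive) = end of intron."""
    if call.d5d6_hit is None:
        raise ValueError(f"call on {call.genome_id} has no D5/D6 hit")
    return call.d5d6_hit.sense_end


def stitch_exons(
    sense_genome: str, five_prime: int, three_prime: int, flank: int
) -> tuple[str, int]:
    """Concatenate ``flank`` nt of 5' exon and 3' exon around an intron.

    Returns the stitched sequence and the junction offset within it.
    Flanks are clipped (with a log message) at contig edges.
    """
    lo = five_prime - flank
    hi = three_prime + flank
    if lo < 0 or hi > len(sense_genome):
        log.debug("exon flank clipped to contig bounds")
        lo, hi = max(lo, 0), min(hi, len(sense_genome))
    left = sense_genome[lo:five_prime]
    right = sense_genome[three_prime:hi]
    return left + right, len(left)


def align_pair(a: str, b: str, mode: str = "global") -> AlignmentResult:
    """Optimal pairwise alignment under the module's fixed scoring.

    ``semi_global`` leaves terminal gaps in ``b`` free, i.e. ``a``
    aligns end-to-end somewhere inside ``b``.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _aligner(mode).align(a, b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a):
        a_span = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
        b_span = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    else:  # no aligned columns at all (pathological)
        a_span = (0, 0)
        b_span = (0, 0)
    return AlignmentResult(aligned_a, aligned_b, matches, float(aln.score), a_span, b_span)


def _align_homolog(homolog: str, locus: str) -> AlignmentResult:
    """Semi-global homolog-vs-locus alignment tolerant of multi-kb insertions.

    Intron insertions are routinely several kb while the informative
    exon match is only a few hundred nt, so the insertion extension
    penalty must be nearly length-free or force-aligning exon into
    intron sequence would outscore skipping the intron. Match, mismatch
    and gap-open scores are shared with :func:`align_pair`.
    """
    al = Align.PairwiseAligner()
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = -0.05
    al.mode = "global"
    al.end_insertion_score = 0.0
    aln = al.align(homolog, locus)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    blocks_a, blocks_b = aln.aligned
    a_span = (int(blocks_a[0][0]), int(blocks_a[-1][1])) if len(blocks_a) else (0, 0)
    b_span = (int(blocks_b[0][0]), int(blocks_b[-1][1])) if len(blocks_b) else (0, 0)
    return AlignmentResult(aligned_a, aligned_b, matches, float(aln.score), a_span, b_span)


def percent_identity(a: str, b: str, mode: str = "global") -> float:
    """Percent identity with the shorter unaligned length as denominator."""
    if not a or not b:
        raise ValueError("cannot compare empty sequences")
    res = align_pair(a, b, mode=mode)
    return 100.0 * res.matches / min(len(a), len(b))


def refine_boundaries(
    intron_plus_locus: str,
    intronless_homolog: str,
    coarse: tuple[int, int],
    cfg: Optional[BoundaryConfig] = None,
) -> RefinedBoundaries:
    """Pin intron boundaries by aligning an intronless homolog to the locus.

    The homolog is aligned semi-globally against the intron-plus locus;
    the largest unaligned insertion in the locus overlapping the coarse
    call defines the refined boundaries. A refined 5' boundary must carry
    the splice-site motif within ``motif_slack`` nt, otherwise the coarse
    boundaries are kept and the result is flagged.
    """
    if cfg is None:
        cfg = BoundaryConfig()
    lo, hi = coarse
    aln = _align_homolog(intronless_homolog, intron_plus_locus)
    insertions = _internal_insertions(aln)
    overlapping = [
        (s, e) for s, e in insertions if s < hi and e > lo
    ]
    if not overlapping:
        return RefinedBoundaries(lo, hi, refined=False, flag="homolog-inconsistent")
    s, e = max(overlapping, key=lambda iv: iv[1] - iv[0])
    # the refined 5' must still look like a splice site
    pat = iupac_regex(cfg.five_prime_motif)
    wlo = max(s - cfg.motif_slack, 0)
    whi = min(s + cfg.motif_slack + len(cfg.five_prime_motif), len(intron_plus_locus))
    if pat.search(intron_plus_locus[wlo:whi]) is None:
        return RefinedBoundaries(lo, hi, refined=False, flag="motif-missing-at-refined-5p")
    return RefinedBoundaries(s, e, refined=True)


def _internal_insertions(aln: AlignmentResult) -> list[tuple[int, int]]:
    """Intervals of b aligned against internal gaps in a (0-based half-open)."""
    out: list[tuple[int, int]] = []
    b_pos = 0
    run_start: Optional[int] = None
    seen_a = False
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca == "-" and cb != "-":
            if run_start is None:
                run_start = b_pos
        else:
            if run_start is not None:
                if seen_a:  # skip the left-terminal overhang of b
                    out.append((run_start, b_pos))
                run_start = None
            if ca != "-":
                seen_a = True
        if cb != "-":
            b_pos += 1
    # a run still open here is the right-terminal overhang of b: not internal
    return out
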