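"""Pseudoknot/tertiary interaction detection and subtype classification.

Profile SCFGs cannot model pseudoknots, so the long-range pairings of the
group II intron consensus — EBS1:IBS1 and EBS2:IBS2 between intron D1 and
the 5' exon, delta:delta' against the 3' exon, and the intron-internal
alpha, beta, gamma, epsilon, lambda, kappa and zeta pairings — are
independent evidence for an intron call. Detection is a complementarity
test between labeled partner regions: the partner intervals come from a
curated or synthetic :class:`~lariat.io.StructureRecord`, and this module
finds the best antiparallel duplex between them (Watson-Crick pairs plus
a bounded number of G:T wobbles).

The lambda-epsilon' region distinguishes the three intron subtypes:
IIA has an 11-nt loop with consensus AGC, IIB a 4-nt bulge matching AARC,
and IIC a 7-12-nt loop with consensus AGG. Two catalytic signatures are
checked as well: the AGC/CGC triad at the start of D5 and the bulged
adenosine (branch point) in D6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from lariat._dna import is_wc, is_wobble
from lariat.io import StructureRecord, paired_positions

__all__ = [
    "InteractionRule", "InteractionAnnotation", "SubtypeRules", "CatalyticChecks",
    "paired_positions", "best_duplex", "annotate_interactions",
    "check_catalytic_triad", "find_bulged_a", "classify_subtype",
    "default_interaction_rules",
]

log = logging.getLogger(__name__)

INTRON_REGION_PAIR = "intron_region_pair"
VS_FIVE_EXON = "intron_vs_5'exon"
VS_THREE_EXON = "intron_vs_3'exon"


@dataclass(frozen=True)
class InteractionRule:
    """Detection thresholds for one long-range pairing."""

    name: str
    min_bp: int
    partner_scope: str = INTRON_REGION_PAIR
    max_wobble: int = 1

    def __post_init__(self) -> None:
        if self.min_bp < 1 or self.max_wobble < 0:
            raise ValueError("min_bp >= 1 and max_wobble >= 0 required")


def default_interaction_rules() -> list[InteractionRule]:
    """The ten consensus interactions with default minimum duplex lengths.

    Only the EBS2:IBS2 minimum (4 bp) is anchored in known biology of
    functional introns; the others are conservative defaults and are
    config-overridable.
    """
    return [
        InteractionRule("EBS1:IBS1", min_bp=5, partner_scope=VS_FIVE_EXON),
        InteractionRule("EBS2:IBS2", min_bp=4, partner_scope=VS_FIVE_EXON),
        InteractionRule("alpha", min_bp=4),
        InteractionRule("beta", min_bp=4),
        InteractionRule("gamma", min_bp=1),
        InteractionRule("delta", min_bp=1, partner_scope=VS_THREE_EXON),
        InteractionRule("epsilon", min_bp=1),
        InteractionRule("lambda", min_bp=2),
        InteractionRule("kappa", min_bp=2),
        InteractionRule("zeta", min_bp=2),
    ]


@dataclass(frozen=True)
class InteractionAnnotation:
    """One detected (or tested-and-absent) long-range pairing.

    Intervals are 1-based inclusive; side A on the intron, side B on the
    partner segment's own coordinate system (intron, 5' exon or 3' exon).
    """

    rule_name: str
    detected: bool
    n_bp: int = 0
    n_wobble: int = 0
    side_a_interval: Optional[tuple[int, int]] = None
    side_b_interval: Optional[tuple[int, int]] = None
    reason: Optional[str] = None


@dataclass(frozen=True)
class SubtypeRules:
    """Shape/motif signatures of the lambda-epsilon' region per subtype."""

    iia_loop_len: int = 11
    iia_motif: str = "AGC"
    iib_bulge_len: int = 4
    iib_pattern: str = "AARC"
    iic_loop_len_min: int = 7
    iic_loop_len_max: int = 12
    iic_motif: str = "AGG"


@dataclass(frozen=True)
class CatalyticChecks:
    """Fixed catalytic sequence signatures."""

    triad_patterns: tuple[str, ...] = ("AGC", "CGC")
    triad_window: int = 5
    d6_branch_base: str = "A"


@dataclass(frozen=True)
class Duplex:
    n_bp: int
    n_wobble: int
    a_start: int  # 0-based within seg_a
    b_start: int  # 0-based within seg_b (original orientation)


def best_duplex(seg_a: str, seg_b: str, max_wobble: int = 1) -> Duplex:
    """Longest contiguous antiparallel duplex between two segments.

    Considers every register of ``seg_a`` (5'->3') against ``seg_b`` read
    3'->5'. A duplex may contain at most ``max_wobble`` G:T pairs; ties
    are broken by length, then fewest wobbles, then leftmost in
    ``seg_a``. Returns a zero-length duplex when no pair exists.
    """
    if not seg_a or not seg_b:
        return Duplex(0, 0, 0, 0)
    rb = seg_b[::-1]
    na, nb = len(seg_a), len(rb)
    best = Duplex(0, 0, 0, 0)
    best_key = (0, 0, 0)
    for off in range(-(nb - 1), na):
        i0 = max(0, off)
        i1 = min(na, off + nb)
        # classify each diagonal position: 2 = WC, 1 = wobble, 0 = none
        kinds = []
        for i in range(i0, i1):
            x, y = seg_a[i], rb[i - off]
            kinds.append(2 if is_wc(x, y) else 1 if is_wobble(x, y) else 0)
        # best window with no zeros and <= max_wobble wobbles (two pointers)
        left = 0
        wob = 0
        for right in range(len(kinds)):
            if kinds[right] == 0:
                left = right + 1
                wob = 0
                continue
            if kinds[right] == 1:
                wob += 1
            while wob > max_wobble:
                if kinds[left] == 1:
                    wob -= 1
                left += 1
            length = right - left + 1
            a_start = i0 + left
            key = (length, -wob, -a_start)
            if key > best_key:
                rb_start = a_start - off
                b_start = nb - (rb_start + length)
                best = Duplex(length, wob, a_start, b_start)
                best_key = key
    return best


def _unpaired_subseq(
    structure: StructureRecord, interval: tuple[int, int]
) -> tuple[str, int]:
    """Subsequence of an interval restricted to unpaired positions.

    Returns the (concatenated) unpaired bases and the 1-based position of
    the first one; labeled loop regions are contiguous in practice.
    """
    lo, hi = interval
    positions = [
        i for i in range(lo, hi + 1) if structure.dotbracket[i - 1] == "."
    ]
    if not positions:
        return "", lo
    return "".join(structure.seq[i - 1] for i in positions), positions[0]


def annotate_interactions(
    intron_seq: str,
    exon5: str,
    exon3: str,
    structure: StructureRecord,
    rules: Optional[Sequence[InteractionRule]] = None,
) -> list[InteractionAnnotation]:
    """Test every interaction rule against labeled partner regions.

    EBS segments are the labeled EBS1/EBS2 intervals restricted to
    positions unpaired in the dot-bracket; IBS1 is searched in the last
    10 nt of the 5' exon and IBS2 in the 10 nt upstream of the detected
    IBS1; delta' is searched in the first 3 nt of the 3' exon. A rule
    whose region label is missing is reported undetected with reason
    ``region-unlabeled``.
    """
    if rules is None:
        rules = default_interaction_rules()
    out: list[InteractionAnnotation] = []
    ibs1_window: Optional[tuple[int, int]] = None  # 1-based on exon5

    for rule in sorted(rules, key=lambda r: r.name != "EBS1:IBS1"):
        if rule.partner_scope == VS_FIVE_EXON:
            ebs_name = "EBS1" if rule.name == "EBS1:IBS1" else "EBS2"
            ival = structure.region(ebs_name)
            if ival is None:
                out.append(_undetected(rule, "region-unlabeled"))
                continue
            seg_a, a_off = _unpaired_subseq(structure, ival)
            if rule.name == "EBS1:IBS1":
                b_lo = max(len(exon5) - 10, 0)
                seg_b = exon5[b_lo:]
            else:
                if ibs1_window is not None:
                    b_hi = ibs1_window[0] - 1  # 0-based end (exclusive)
                else:
                    b_hi = max(len(exon5) - 6, 0)
                b_lo = max(b_hi - 10, 0)
                seg_b = exon5[b_lo:b_hi]
            b_base = b_lo
        elif rule.partner_scope == VS_THREE_EXON:
            ival = structure.region(rule.name)
            if ival is None:
                out.append(_undetected(rule, "region-unlabeled"))
                continue
            seg_a, a_off = _unpaired_subseq(structure, ival)
            if not seg_a:  # delta may sit in a paired context; use raw label
                seg_a, a_off = structure.region_seq(rule.name), ival[0]
            seg_b = exon3[:3]
            b_base = 0
        else:
            ival = structure.region(rule.name)
            ival_p = structure.region(rule.name + "'")
            if ival is None or ival_p is None:
                out.append(_undetected(rule, "region-unlabeled"))
                continue
            seg_a = structure.seq[ival[0] - 1 : ival[1]]
            a_off = ival[0]
            seg_b = structure.seq[ival_p[0] - 1 : ival_p[1]]
            b_base = ival_p[0] - 1

        if not seg_a or not seg_b:
            out.append(_undetected(rule, "empty-segment"))
            continue
        dup = best_duplex(seg_a, seg_b, max_wobble=rule.max_wobble)
        detected = dup.n_bp >= rule.min_bp and dup.n_wobble <= rule.max_wobble
        side_a = (a_off + dup.a_start, a_off + dup.a_start + dup.n_bp - 1)
        side_b = (b_base + dup.b_start + 1, b_base + dup.b_start + dup.n_bp)
        ann = InteractionAnnotation(
            rule_name=rule.name,
            detected=detected,
            n_bp=dup.n_bp,
            n_wobble=dup.n_wobble,
            side_a_interval=side_a if dup.n_bp else None,
            side_b_interval=side_b if dup.n_bp else None,
        )
        out.append(ann)
        if rule.name == "EBS1:IBS1" and detected:
            ibs1_window = ann.side_b_interval
    order = {r.name: i for i, r in enumerate(rules)}
    out.sort(key=lambda a: order[a.rule_name])
    return out


def _undetected(rule: InteractionRule, reason: str) -> InteractionAnnotation:
    return InteractionAnnotation(rule_name=rule.name, detected=False, reason=reason)


def check_catalytic_triad(
    d5_seq: Optional[str], checks: Optional[CatalyticChecks] = None
) -> tuple[bool, Optional[str]]:
    """Is the AGC/CGC catalytic triad present near the start of D5?

    Returns ``(pass, motif_found)``; with no D5 sequence the result is
    ``(False, None)`` (status unknown).
    """
    if checks is None:
        checks = CatalyticChecks()
    if not d5_seq:
        return False, None
    head = d5_seq[: checks.triad_window]
    for motif in checks.triad_patterns:
        if motif in head:
            return True, motif
    return False, None


def find_bulged_a(d6_seq: str, d6_dotbracket: str) -> Optional[int]:
    """1-based position of the first bulged adenosine within D6.

    A bulged adenosine is an unpaired A whose immediate neighbours are
    both paired. Returns None when no such position exists.
    """
    if len(d6_seq) != len(d6_dotbracket):
        raise ValueError("D6 sequence and structure lengths differ")
    for i in range(1, len(d6_seq) - 1):
        if (
            d6_seq[i] == "A"
            and d6_dotbracket[i] == "."
            and d6_dotbracket[i - 1] != "."
            and d6_dotbracket[i + 1] != "."
        ):
            return i + 1
    return None


def classify_subtype(
    region_seq: str,
    region_kind: str,
    rules: Optional[SubtypeRules] = None,
) -> str:
    """Assign IIA/IIB/IIC from the lambda-epsilon' region.

    IIA: loop of exactly 11 nt containing AGC. IIB: bulge of exactly
    4 nt matching AARC. IIC: loop of 7-12 nt containing AGG, checked
    only when IIA fails (length 11 with both motifs is IIA). Anything
    else is unclassified.
    """
    if rules is None:
        rules = SubtypeRules()
    if not region_seq:
        return "unclassified"
    if region_kind == "loop":
        if len(region_seq) == rules.iia_loop_len and rules.iia_motif in region_seq:
            if rules.iic_motif in region_seq:
                log.debug("length-11 loop carries both AGC and AGG; IIA takes precedence")
            return "IIA"
        if (
            rules.iic_loop_len_min <= len(region_seq) <= rules.iic_loop_len_max
            and rules.iic_motif in region_seq
        ):
            return "IIC"
    elif region_kind == "bulge":
        if len(region_seq) == rules.iib_bulge_len:
            from lariat._dna import iupac_match

            if iupac_match(rules.iib_pattern, region_seq):
                return "IIB"
    return "unclassified"


def region_kind(structure: StructureRecord, interval: tuple[int, int]) -> str:
    """Infer loop vs bulge for an unpaired interval from its flanks.

    A hairpin loop sits between an opening and a closing bracket; a
    bulge is flanked by brackets of the same orientation. Intervals at
    the molecule edge or with paired interiors are ``unknown``.
    """
    lo, hi = interval
    db = structure.dotbracket
    if lo < 2 or hi > len(db) - 1:
        return "unknown"
    if any(c != "." for c in db[lo - 1 : hi]):
        return "unknown"
    left, right = db[lo - 2], db[hi]
    if left in "([<" and right in ")]>":
        return "loop"
    if (left in "([<" and right in "([<") or (left in ")]>" and right in ")]>"):
        return "bulge"
    return "unknown"
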