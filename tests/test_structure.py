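"""Duplex search vs exhaustive enumeration, interaction calls, subtypes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lariat import synthetic
from lariat._dna import is_wc, is_wobble, revcomp
from lariat.io import StructureRecord
from lariat.structure import (
    InteractionRule,
    annotate_interactions,
    best_duplex,
    check_catalytic_triad,
    classify_subtype,
    default_interaction_rules,
    find_bulged_a,
    region_kind,
)


# --- best_duplex -----------------------------------------------------------


def test_duplex_exact_reverse_complement():
    d = best_duplex("GTTGAA", revcomp("GTTGAA"))
    assert (d.n_bp, d.n_wobble) == (6, 0)


def test_duplex_with_one_wobble():
    d = best_duplex("GGAG", "CTTC", max_wobble=1)
    assert (d.n_bp, d.n_wobble) == (4, 1)


def test_duplex_none_for_noncomplementary():
    assert best_duplex("AAAA", "AAAA").n_bp == 0


def _oracle_duplex(seg_a, seg_b, max_wobble):
    """Enumerate all equal-length substring pairs and registers."""
    best = (0, 0, 0)  # (n_bp, -n_wob, -a_start) maximized
    rb_full = seg_b[::-1]
    for length in range(1, min(len(seg_a), len(seg_b)) + 1):
        for i in range(len(seg_a) - length + 1):
            for j in range(len(rb_full) - length + 1):
                wob = 0
                ok = True
                for k in range(length):
                    x, y = seg_a[i + k], rb_full[j + k]
                    if is_wc(x, y):
                        continue
                    if is_wobble(x, y):
                        wob += 1
                    else:
                        ok = False
                        break
                if ok and wob <= max_wobble:
                    best = max(best, (length, -wob, -i))
    return best


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=12),
    st.text(alphabet="ACGT", min_size=1, max_size=12),
    st.integers(0, 2),
)
def test_duplex_matches_exhaustive_enumeration(a, b, max_wobble):
    d = best_duplex(a, b, max_wobble=max_wobble)
    assert (d.n_bp, -d.n_wobble, -d.a_start) == _oracle_duplex(a, b, max_wobble)
    # the reported intervals really form a duplex
    if d.n_bp:
        sub_a = a[d.a_start : d.a_start + d.n_bp]
        sub_b = b[d.b_start : d.b_start + d.n_bp]
        pairs = list(zip(sub_a, sub_b[::-1]))
        assert all(is_wc(x, y) or is_wobble(x, y) for x, y in pairs)
        assert sum(1 for x, y in pairs if is_wobble(x, y)) == d.n_wobble


# --- annotate_interactions -------------------------------------------------


def _planted_case(seed=5, subtype="IIB"):
    cfg = synthetic.SyntheticConfig(seed=seed)
    rng = np.random.default_rng(seed)
    seq, struct, tf = synthetic.generate_intron(cfg, subtype, "none", rng)
    struct = StructureRecord(
        seq_id="t", seq=seq, dotbracket=struct.dotbracket,
        region_labels=struct.region_labels,
    )
    exon5 = "TTTTTT" + revcomp(tf["ebs2"]) + revcomp(tf["ebs1"])
    exon3 = revcomp(tf["delta"]) + "TTTTTTT"
    return seq, exon5, exon3, struct


def test_all_consensus_interactions_detected_on_planted_intron():
    seq, exon5, exon3, struct = _planted_case()
    anns = annotate_interactions(seq, exon5, exon3, struct)
    assert all(a.detected for a in anns), [
        (a.rule_name, a.n_bp, a.reason) for a in anns if not a.detected
    ]
    ebs1 = next(a for a in anns if a.rule_name == "EBS1:IBS1")
    assert ebs1.n_bp >= 5


def test_short_ebs2_candidate_not_detected():
    # only 3 complementary bp available, below the 4 bp floor
    struct = StructureRecord(
        seq_id="x",
        seq="GGGGG" + "ACG" + "TTTTT",
        dotbracket="(((((" + "..." + ")))))",
        region_labels={"EBS2": [(6, 8)]},
    )
    rule = InteractionRule("EBS2:IBS2", min_bp=4, partner_scope="intron_vs_5'exon")
    (ann,) = annotate_interactions(
        struct.seq, "AAAAAAA" + revcomp("ACG") + "AAAAAA", "AAA", struct, [rule]
    )
    assert not ann.detected
    assert ann.n_bp == 3


def test_missing_region_label_reported():
    seq, exon5, exon3, struct = _planted_case()
    struct.region_labels.pop("kappa")
    anns = annotate_interactions(seq, exon5, exon3, struct)
    kappa = next(a for a in anns if a.rule_name == "kappa")
    assert not kappa.detected
    assert kappa.reason == "region-unlabeled"


def test_detection_never_below_min_bp():
    seq, exon5, exon3, struct = _planted_case(seed=9)
    rules = default_interaction_rules()
    for ann, rule in zip(annotate_interactions(seq, exon5, exon3, struct), rules):
        assert ann.rule_name == rule.name
        if ann.detected:
            assert ann.n_bp >= rule.min_bp and ann.n_wobble <= rule.max_wobble


# --- catalytic checks ------------------------------------------------------


@pytest.mark.parametrize(
    "d5,expected",
    [("AGCGG", (True, "AGC")), ("CGCAA", (True, "CGC")), ("AAATT", (False, None)),
     ("TTAGC", (True, "AGC")), ("TTTAGC", (False, None))],
)
def test_catalytic_triad_in_first_five_nt(d5, expected):
    assert check_catalytic_triad(d5 + "GGGCCC") == expected


def test_catalytic_triad_unknown_without_d5():
    assert check_catalytic_triad(None) == (False, None)


def test_bulged_a_found_and_first_match_wins():
    # classic one-bulge stem: GGGG A CCCC with the A between paired neighbours
    assert find_bulged_a("GGGGACCCC", "((((.))))") == 5
    assert find_bulged_a("GGGGCCCC", "(((())))") is None  # no unpaired A
    # two interior unpaired As, both flanked by pairs: the first is reported
    assert find_bulged_a("GGAGGACCCC", "((.((.))))") == 3
    # an unpaired A at the molecule edge does not count as bulged
    assert find_bulged_a("AGGCC", ".(())") is None
    with pytest.raises(ValueError):
        find_bulged_a("AAAA", "(((")


# --- subtype classification ------------------------------------------------


@pytest.mark.parametrize(
    "seq,kind,expected",
    [
        ("CTAGCAATGGC", "loop", "IIA"),      # 11-nt loop containing AGC
        ("AAAC", "bulge", "IIB"),   # R = A
        ("AAGC", "bulge", "IIB"),   # R = G
        ("AGAC", "bulge", "unclassified"),  # purine in the wrong slot of AARC
        ("CCAGGCCCT", "loop", "IIC"),        # 9-nt loop containing AGG
        ("CCCCC", "loop", "unclassified"),
        ("CTAGCAGGGGC", "loop", "IIA"),      # both motifs at length 11 -> IIA
        ("AAAC", "loop", "unclassified"),    # AARC only counts as a bulge
        ("CTAGGAATGGC", "loop", "IIC"),      # length 11, AGG without AGC
        ("", "loop", "unclassified"),
    ],
)
def test_classify_subtype(seq, kind, expected):
    assert classify_subtype(seq, kind) == expected


def test_region_kind_inference():
    loop = StructureRecord(
        seq_id="a", seq="GGGAAAACCC", dotbracket="(((....)))"
    )
    assert region_kind(loop, (4, 7)) == "loop"
    bulge = StructureRecord(
        seq_id="b", seq="GGAAAAGGTTTTCCCC", dotbracket="((....((....))))"
    )
    assert region_kind(bulge, (3, 6)) == "bulge"


# --- strand-mirroring consistency ------------------------------------------


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=10),
    st.text(alphabet="ACGT", min_size=1, max_size=10),
)
def test_wc_duplex_invariant_under_strand_mirror(a, b):
    """Reading a Watson-Crick duplex from the opposite strand swaps and
    reverse-complements the partners but preserves its length. (Wobble
    pairs are deliberately excluded: G:T complements to C:A, which does
    not pair — which is why annotation always happens in sense space.)"""
    d = best_duplex(a, b, max_wobble=0)
    m = best_duplex(revcomp(b), revcomp(a), max_wobble=0)
    assert (d.n_bp, d.n_wobble) == (m.n_bp, m.n_wobble)
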