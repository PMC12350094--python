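"""Splice-site motif search, alignment (vs brute force), homolog refinement."""

from __future__ import annotations

import math

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from lariat.boundaries import (
    BoundaryConfig,
    align_pair,
    find_five_prime,
    find_three_prime,
    percent_identity,
    refine_boundaries,
    stitch_exons,
)
from lariat.curation import IntronCall
from lariat.io import ModelType
from tests.conftest import make_hit

BCFG = BoundaryConfig()


# --- 5' motif --------------------------------------------------------------


def test_five_prime_motif_found_upstream_of_hit():
    genome = "A" * 200 + "GTCGG" + "T" * 300
    pos = find_five_prime(genome, 230, BCFG)
    assert pos == 200
    assert genome[pos : pos + 5] == "GTCGG"


def test_five_prime_none_when_no_motif():
    assert find_five_prime("AC" * 300, 300, BCFG) is None


def test_five_prime_prefers_match_nearest_to_hit_start():
    # matches at distances 40 and 5 upstream of the hit start
    genome = "C" * 100 + "GTCGG" + "C" * 30 + "GACAG" + "C" * 200
    hit_start = 140
    assert find_five_prime(genome, hit_start, BCFG) == 135
    # adjacent motifs: nearest wins on either side of the anchor
    genome3 = "C" * 100 + "GTCGG" + "GACAG" + "C" * 200
    # starts at 100 and 105; anchor 105 is distance 5 and 0 -> picks 105
    assert find_five_prime(genome3, 105, BCFG) == 105
    # anchor between them at 102/103: distances (2,3) then (3,2)
    assert find_five_prime(genome3, 102, BCFG) == 100
    assert find_five_prime(genome3, 103, BCFG) == 105


def test_five_prime_window_clipped_at_contig_edge():
    genome = "GTCGG" + "A" * 100
    assert find_five_prime(genome, 10, BCFG) == 0


# --- 3' end ----------------------------------------------------------------


def test_three_prime_is_d5d6_hit_end_on_each_strand():
    plus = IntronCall(
        "g1", "+",
        d5d6_hit=make_hit(model_type=ModelType.D5D6, start1=1400, end1=1650),
        completeness="three_only",
    )
    assert find_three_prime(plus) == 1650
    minus = IntronCall(
        "g1", "-",
        d5d6_hit=make_hit(model_type=ModelType.D5D6, start1=100, end1=900, strand="-"),
        completeness="three_only",
    )
    # sense-axis end of a minus-strand hit is the negated forward start
    assert find_three_prime(minus) == -99


def test_three_prime_requires_d5d6_hit():
    call = IntronCall("g1", "+", d1d4_hits=[make_hit()], completeness="five_only")
    with pytest.raises(ValueError):
        find_three_prime(call)


# --- exon stitching --------------------------------------------------------


def test_stitch_exons_by_construction():
    e1, intron, e2 = "AAACCC", "GTCGGTTTT", "GGGTTT"
    genome = e1 + intron + e2
    stitched, junction = stitch_exons(genome, len(e1), len(e1) + len(intron), flank=4)
    assert stitched == e1[-4:] + e2[:4]
    assert junction == 4


def test_stitch_exons_clipped_at_contig_start():
    genome = "GTCGGTTTT" + "GGGTTT"  # intron begins at position 0
    stitched, junction = stitch_exons(genome, 0, 9, flank=4)
    assert junction == 0
    assert stitched == "GGGT"


def test_stitched_exons_translate_to_host_protein(small_bundle):
    truth = next(t for t in small_bundle.truths if t.strand == "+")
    genome = small_bundle.genome_map()[truth.genome_id]
    flank = small_bundle.config.flank_gene_length
    stitched, junction = stitch_exons(genome.seq, truth.start, truth.end, flank=flank)
    assert junction == flank
    protein = str(Seq(stitched).translate())
    assert protein == truth.host_protein
    assert "*" not in protein


# --- pairwise alignment ----------------------------------------------------


def _brute_force_best_score(a: str, b: str) -> float:
    """Enumerate every global alignment; affine gaps: -5 to open, -1 to extend."""
    best = -math.inf

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (2 if a[i] == b[j] else -1), "M")
        if i < len(a):
            rec(i + 1, j, score + (-1 if last == "D" else -5), "D")
        if j < len(b):
            rec(i, j + 1, score + (-1 if last == "I" else -5), "I")

    rec(0, 0, 0.0, None)
    return best


def test_align_identical_strings_no_gaps():
    res = align_pair("ACGTACGT", "ACGTACGT")
    assert res.matches == 8
    assert "-" not in res.aligned_a + res.aligned_b


def test_align_terminal_gap():
    res = align_pair("ACGT", "ACG")
    assert res.aligned_a == "ACGT"
    assert res.aligned_b == "ACG-"
    assert res.score == 3 * 2 - 5


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=6),
    st.text(alphabet="ACGT", min_size=1, max_size=6),
)
def test_align_score_matches_bruteforce_enumeration(a, b):
    assert align_pair(a, b).score == pytest.approx(_brute_force_best_score(a, b))


def test_semi_global_probe_localizes_inside_target():
    probe = "ACGTACGTAC"
    target = "T" * 45 + probe + "G" * 45
    res = align_pair(probe, target, mode="semi_global")
    assert res.b_span == (45, 55)
    assert res.matches == 10


def test_align_empty_input_rejected():
    with pytest.raises(ValueError):
        align_pair("", "ACGT")


# --- percent identity ------------------------------------------------------


def test_percent_identity_shorter_denominator():
    assert percent_identity("A" * 50, "A" * 50) == 100.0
    assert percent_identity("AAAA", "GGGG") == 0.0
    # 10-mer with 5 identities to a 20-mer: denominator is the 10-mer
    a = "ACGTA" + "GGGGG"
    b = "ACGTA" + "CCCCC" + "T" * 10
    assert percent_identity(a, b, mode="semi_global") == 50.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=12),
    st.text(alphabet="ACGT", min_size=1, max_size=12),
)
def test_percent_identity_symmetric_and_bounded(a, b):
    x = percent_identity(a, b)
    assert x == pytest.approx(percent_identity(b, a))
    assert 0.0 <= x <= 100.0


# --- homolog refinement ----------------------------------------------------


def _locus(rng, intron_len=400):
    e1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    e2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    intron = "GTCGG" + "".join("ACGT"[i] for i in rng.integers(0, 4, intron_len - 6)) + "C"
    # keep the insertion position unambiguous at both junctions
    e2 = "A" + e2[1:]          # != intron[0] == 'G'
    e1 = e1[:-1] + "G"         # != intron[-1] == 'C'
    return e1 + intron + e2, e1 + e2, (300, 300 + intron_len)


def test_refine_recovers_planted_interval_exactly(rng):
    locus, homolog, truth = _locus(rng)
    coarse = (truth[0] + 17, truth[1] - 23)
    res = refine_boundaries(locus, homolog, coarse)
    assert res.refined
    assert (res.five_prime, res.three_prime) == truth


def test_refine_tolerates_exon_substitutions(rng):
    locus, homolog, truth = _locus(rng)
    # two substitutions well inside the exons
    h = list(homolog)
    for pos in (50, 550):
        h[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[h[pos]]
    res = refine_boundaries(locus, "".join(h), (truth[0] + 5, truth[1] - 5))
    assert res.refined
    assert (res.five_prime, res.three_prime) == truth


def test_refine_flags_unrelated_homolog(rng):
    locus, _, truth = _locus(rng)
    unrelated = "AC" * 300
    res = refine_boundaries(locus, unrelated, (truth[0], truth[1]))
    assert not res.refined
    assert res.flag is not None
    assert (res.five_prime, res.three_prime) == truth  # coarse kept
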