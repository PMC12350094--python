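"""Hit filtering, pairing against a brute-force oracle, dedup, census."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from lariat import curation
from lariat.curation import (
    COMPLETE,
    FIVE_ONLY,
    THREE_ONLY,
    PipelineConfig,
    completeness_census,
    dedup_calls,
    filter_hits,
    pair_hits,
    proportion_with_introns,
)
from lariat.io import ModelType, SeqRecord
from tests.conftest import make_hit

CFG = PipelineConfig()


# --- filtering -------------------------------------------------------------


def test_filter_uses_strict_threshold():
    hits = [make_hit(evalue=e) for e in (0.009, 0.011, 0.01)]
    kept = filter_hits(hits, 0.01)
    assert [h.evalue for h in kept] == [0.009]


def test_filter_identity_and_empty_cases():
    hits = [make_hit(evalue=1e-9), make_hit(evalue=1e-4)]
    assert filter_hits(hits, 0.01) == hits
    assert filter_hits([], 0.01) == []


# --- pairing ---------------------------------------------------------------


def test_pairing_joins_d1d4_with_downstream_d5d6():
    hits = [
        make_hit(start1=100, end1=900),
        make_hit(model_type=ModelType.D5D6, start1=1400, end1=1650),
    ]
    (call,) = pair_hits(hits, CFG)
    assert call.completeness == COMPLETE
    assert call.envelope() == (99, 1650)


def test_pairing_rejects_distant_partner():
    hits = [
        make_hit(start1=100, end1=900),
        make_hit(model_type=ModelType.D5D6, start1=9000, end1=9250),
    ]
    calls = pair_hits(hits, CFG)
    assert sorted(c.completeness for c in calls) == [FIVE_ONLY, THREE_ONLY]


def test_pairing_merges_consecutive_d1d4_hits_into_one_call():
    hits = [
        make_hit(start1=100, end1=500),
        make_hit(start1=520, end1=900, model_name="group-II-D1D4-3"),
        make_hit(model_type=ModelType.D5D6, start1=1200, end1=1400),
    ]
    (call,) = pair_hits(hits, CFG)
    assert call.completeness == COMPLETE
    assert len(call.d1d4_hits) == 2
    assert [h.model_name for h in call.d1d4_hits] == [
        "group-II-D1D4-1",
        "group-II-D1D4-3",
    ]


def test_pairing_minus_strand_mirrors_plus_strand():
    L = 10_000
    plus = [
        make_hit(start1=100, end1=900),
        make_hit(model_type=ModelType.D5D6, start1=1400, end1=1650),
    ]
    minus = [
        make_hit(start1=L - 899, end1=L - 99, strand="-"),
        make_hit(model_type=ModelType.D5D6, start1=L - 1649, end1=L - 1399, strand="-"),
    ]
    (pc,) = pair_hits(plus, CFG)
    (mc,) = pair_hits(minus, CFG)
    assert (pc.completeness, mc.completeness) == (COMPLETE, COMPLETE)
    assert mc.strand == "-"
    # same structure, mirrored coordinates
    assert mc.envelope() == (L - pc.envelope()[1], L - pc.envelope()[0])


def test_pairing_rejects_unknown_model_type():
    bad = make_hit(model_name="tRNA")
    object.__setattr__(bad, "model_type", ModelType.UNKNOWN)
    with pytest.raises(ValueError, match="UNKNOWN"):
        pair_hits([bad], CFG)


# Brute-force oracle: segment the sense-sorted hit list; each D5/D6 hit is
# paired with the immediately preceding unconsumed chain of D1-D4 hits
# (chained by gaps <= pair_max_gap) when its own gap fits the window.
def _oracle_pair(hits, cfg):
    from collections import defaultdict

    groups = defaultdict(list)
    for h in hits:
        groups[(h.target_id, h.strand)].append(h)
    result = []
    for key in sorted(groups):
        hs = sorted(groups[key], key=lambda h: (h.sense_start, h.sense_end, h.evalue))
        consumed = [False] * len(hs)
        for i, h in enumerate(hs):
            if h.model_type is not ModelType.D5D6:
                continue
            # chain of d1d4 hits immediately before i (list-contiguous)
            chain: list[int] = []
            j = i - 1
            while j >= 0 and not consumed[j] and hs[j].model_type is ModelType.D1D4:
                if chain and hs[chain[0]].sense_start - hs[j].sense_end > cfg.pair_max_gap:
                    break
                chain.insert(0, j)
                j -= 1
            if chain:
                gap = h.sense_start - hs[chain[-1]].sense_end
                if -cfg.pair_overlap_tolerance <= gap <= cfg.pair_max_gap:
                    for c in chain:
                        consumed[c] = True
                    consumed[i] = True
                    result.append(("complete", len(chain)))
                    continue
            consumed[i] = True
            result.append(("three_only", 0))
        # leftover d1d4 runs
        run = 0
        prev = None
        for j, h in enumerate(hs):
            if consumed[j]:
                if run:
                    result.append(("five_only", run))
                run, prev = 0, None
                continue
            if h.model_type is ModelType.D1D4:
                if prev is not None and h.sense_start - prev.sense_end > cfg.pair_max_gap:
                    result.append(("five_only", run))
                    run = 0
                run += 1
                prev = h
        if run:
            result.append(("five_only", run))
    return sorted(result)


@st.composite
def _hit_sets(draw):
    n = draw(st.integers(1, 8))
    hits = []
    pos = 0
    for _ in range(n):
        pos += draw(st.integers(1, 3500))
        length = draw(st.integers(100, 800))
        kind = draw(st.sampled_from([ModelType.D1D4, ModelType.D5D6]))
        hits.append(
            make_hit(
                model_type=kind,
                start1=pos,
                end1=pos + length,
                evalue=draw(st.floats(1e-12, 1e-3)),
            )
        )
        pos += length
    return hits


@settings(max_examples=200, deadline=None, derandomize=True)
@given(_hit_sets())
def test_pairing_matches_bruteforce_oracle_and_partitions_hits(hits):
    calls = pair_hits(hits, CFG)
    # partition: every hit in exactly one call
    members = [id(h) for c in calls for h in c.hits]
    assert sorted(members) == sorted(id(h) for h in hits)
    # all realized pair gaps within the window
    for c in calls:
        if c.completeness == COMPLETE:
            gap = c.d5d6_hit.sense_start - c.d1d4_hits[-1].sense_end
            assert -CFG.pair_overlap_tolerance <= gap <= CFG.pair_max_gap
    got = sorted((c.completeness, len(c.d1d4_hits)) for c in calls)
    assert got == _oracle_pair(hits, CFG)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(_hit_sets(), st.integers(200, 2000))
def test_tightening_pair_gap_never_creates_complete_calls(hits, smaller_gap):
    loose = pair_hits(hits, CFG)
    tight = pair_hits(hits, PipelineConfig(pair_max_gap=smaller_gap))
    n = lambda calls: sum(1 for c in calls if c.completeness == COMPLETE)
    assert n(tight) <= n(loose)


# --- dedup -----------------------------------------------------------------


def _dedup_fixture(intron, flank_a, flank_b):
    cfg = PipelineConfig(dedup_flank=50)
    genomes = {}
    calls = []
    for gid, (left, right) in (("gA", flank_a), ("gB", flank_b)):
        seq = left + intron + right
        genomes[gid] = SeqRecord(id=gid, seq=seq)
        h = make_hit(target=gid, start1=len(left) + 1, end1=len(left) + len(intron))
        calls.append(
            curation.IntronCall(gid, "+", d1d4_hits=[h], completeness=FIVE_ONLY)
        )
    return calls, genomes, cfg


def test_dedup_collapses_identical_intron_and_context():
    intron = "GTCGG" + "ACGT" * 50
    flanks = ("A" * 60 + "C" * 10, "G" * 60)
    calls, genomes, cfg = _dedup_fixture(intron, flanks, flanks)
    kept = dedup_calls(calls, genomes, cfg)
    assert [c.genome_id for c in kept] == ["gA"]  # smallest id is representative


def test_dedup_keeps_identical_introns_in_different_context():
    intron = "GTCGG" + "ACGT" * 50
    calls, genomes, cfg = _dedup_fixture(
        intron, ("A" * 70, "G" * 60), ("T" * 70, "C" * 60)
    )
    kept = dedup_calls(calls, genomes, cfg)
    assert len(kept) == 2


def test_dedup_is_identity_on_unique_calls_and_idempotent():
    calls, genomes, cfg = _dedup_fixture(
        "GTCGG" + "AAGT" * 50, ("A" * 70, "G" * 60), ("T" * 70, "C" * 60)
    )
    once = dedup_calls(calls, genomes, cfg)
    assert once == list(calls)
    assert dedup_calls(once, genomes, cfg) == once


def test_dedup_applies_exclusion_list():
    calls, genomes, cfg = _dedup_fixture(
        "GTCGG" + "ACGT" * 50, ("A" * 70, "G" * 60), ("T" * 70, "C" * 60)
    )
    cfg2 = PipelineConfig(dedup_flank=50, exclusion_list=frozenset({"gB"}))
    kept = dedup_calls(calls, genomes, cfg2)
    assert [c.genome_id for c in kept] == ["gA"]


# --- census and proportions ------------------------------------------------


def test_census_partitions_calls():
    calls, genomes, cfg = _dedup_fixture(
        "GTCGG" + "ACGT" * 50, ("A" * 70, "G" * 60), ("T" * 70, "C" * 60)
    )
    census = completeness_census(calls)
    assert census == {COMPLETE: 0, FIVE_ONLY: 2, THREE_ONLY: 0}
    assert sum(census.values()) == len(calls)
    assert completeness_census([]) == {COMPLETE: 0, FIVE_ONLY: 0, THREE_ONLY: 0}


@pytest.mark.parametrize(
    "pos,total,expected",
    [(20, 29015, 0.07), (9229, 15722824, 0.06), (0, 10, 0.0)],
)
def test_proportion_with_introns(pos, total, expected):
    assert proportion_with_introns(pos, total) == expected


def test_proportion_rejects_bad_inputs():
    with pytest.raises(ValueError):
        proportion_with_introns(1, 0)
    with pytest.raises(ValueError):
        proportion_with_introns(5, 4)
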