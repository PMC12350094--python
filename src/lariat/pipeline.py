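"""End-to-end orchestration: filter -> pair -> dedup -> boundaries ->
interactions -> subtype -> IEP -> trans-flag -> report.

Inputs are the formats a practitioner already has on disk (genome FASTA,
cmsearch tblout, hmmscan domtblout, dot-bracket structures, homolog
FASTA); each may also be passed pre-parsed. Auxiliary records (structures,
homologs, domain-table queries) are matched to calls through locus ids of
the form ``<genome>|<start>-<end>|<strand>`` (1-based inclusive), matched
by genome, strand and interval overlap, so coordinates only need to be
approximate.

The pipeline is deterministic: identical inputs and configuration give
byte-identical outputs (no timestamps are written).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from lariat import boundaries as bnd
from lariat import curation, iep as iep_mod, structure as struct_mod
from lariat._dna import revcomp
from lariat.io import (
    CMHit,
    ModelType,
    SeqRecord,
    StructureRecord,
    read_cm_tblout,
    read_domtblout,
    read_fasta,
    read_structures,
    write_gff3,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    """All knobs of a pipeline run in one place."""

    curation: curation.PipelineConfig = field(default_factory=curation.PipelineConfig)
    boundary: bnd.BoundaryConfig = field(default_factory=bnd.BoundaryConfig)
    min_orf_aa: int = iep_mod.DEFAULT_MIN_ORF_AA
    iep_evalue_cutoff: float = iep_mod.DEFAULT_EVALUE_CUTOFF
    exon5_window: int = 20
    exon3_window: int = 10


@dataclass
class PipelineResult:
    calls: list[curation.IntronCall]
    census: dict[str, int]
    inventory: pd.DataFrame
    stage_counts: dict[str, int]


def parse_locus_id(locus_id: str) -> Optional[tuple[str, int, int, str]]:
    """Parse ``genome|start-end|strand`` into (genome, start0, end0, strand)."""
    parts = locus_id.split("|")
    if len(parts) < 3 or parts[2] not in ("+", "-"):
        return None
    try:
        a, _, b = parts[1].partition("-")
        return parts[0], int(a) - 1, int(b), parts[2]
    except ValueError:
        return None


def _overlaps(lo1: int, hi1: int, lo2: int, hi2: int) -> bool:
    return lo1 < hi2 and lo2 < hi1


def _match_by_locus(
    call: curation.IntronCall, items: Sequence[tuple[str, object]]
) -> Optional[object]:
    env_lo, env_hi = call.envelope()
    for locus_id, obj in items:
        parsed = parse_locus_id(locus_id)
        if parsed is None:
            continue
        gid, lo, hi, strand = parsed
        if gid == call.genome_id and strand == call.strand and _overlaps(
            lo, hi, env_lo, env_hi
        ):
            return obj
    return None


def _coerce_genomes(genomes) -> dict[str, SeqRecord]:
    if isinstance(genomes, (str, Path)):
        genomes = read_fasta(genomes)
    if isinstance(genomes, Mapping):
        return dict(genomes)
    return {g.id: g for g in genomes}


def _coerce_hits(tblout) -> list[CMHit]:
    if isinstance(tblout, (str, Path)):
        return read_cm_tblout(tblout)
    return list(tblout)


class _SenseFrame:
    """Coordinate frame on the sense strand of one genome/strand pair.

    Sense positions run 0..L from the 5' end of the sense strand;
    ``axis`` converts them to the strand-independent sense axis used by
    :class:`~lariat.curation.IntronCall` (negated forward coordinates on
    the minus strand).
    """

    def __init__(self, genome: SeqRecord, strand: str) -> None:
        self.L = len(genome)
        self.strand = strand
        self.seq = genome.seq if strand == "+" else revcomp(genome.seq)

    def from_forward(self, pos0: int) -> int:
        return pos0 if self.strand == "+" else self.L - pos0

    def axis(self, sense_pos: int) -> int:
        return sense_pos if self.strand == "+" else sense_pos - self.L


def _resolve_boundaries(
    call: curation.IntronCall,
    genome: SeqRecord,
    homolog: Optional[SeqRecord],
    cfg: RunConfig,
) -> _SenseFrame:
    frame = _SenseFrame(genome, call.strand)
    env_lo, env_hi = call.envelope()
    s_lo = min(frame.from_forward(env_lo), frame.from_forward(env_hi))
    s_hi = max(frame.from_forward(env_lo), frame.from_forward(env_hi))

    five: Optional[int] = None
    three: Optional[int] = None
    if call.d1d4_hits:
        d1 = call.d1d4_hits[0]
        d1_sense_start = frame.from_forward(d1.start if call.strand == "+" else d1.end)
        five = bnd.find_five_prime(frame.seq, d1_sense_start, cfg.boundary)
        if five is None:
            call.flags.append("5'-unresolved")
    if call.d5d6_hit is not None:
        h = call.d5d6_hit
        three = frame.from_forward(h.end if call.strand == "+" else h.start)
        if h.truncated not in ("no", "-"):
            call.flags.append("3'-truncated")

    if homolog is not None:
        margin = len(homolog.seq)
        w_lo = max(s_lo - margin, 0)
        w_hi = min(s_hi + margin, frame.L)
        locus = frame.seq[w_lo:w_hi]
        coarse = (
            max((five if five is not None else s_lo) - w_lo, 0),
            min((three if three is not None else s_hi) - w_lo, len(locus)),
        )
        refined = bnd.refine_boundaries(locus, homolog.seq, coarse, cfg.boundary)
        if refined.refined:
            five = w_lo + refined.five_prime
            three = w_lo + refined.three_prime
            call.flags[:] = [f for f in call.flags if f != "5'-unresolved"]
        elif refined.flag:
            call.flags.append(refined.flag)
    elif call.completeness == curation.COMPLETE:
        call.flags.append("no-homolog")

    if five is not None:
        call.five_prime = frame.axis(five)
    if three is not None:
        call.three_prime = frame.axis(three)
    if five is None and call.completeness != curation.THREE_ONLY:
        pass  # already flagged
    if three is None and call.d5d6_hit is None:
        call.flags.append("3'-unresolved")
    return frame


def _annotate_call(
    call: curation.IntronCall,
    frame: _SenseFrame,
    structure: Optional[StructureRecord],
    cfg: RunConfig,
) -> None:
    if structure is None:
        call.flags.append("no-structure")
        return
    lo, hi = call.resolved_interval()
    s_lo = min(frame.from_forward(lo), frame.from_forward(hi))
    s_hi = max(frame.from_forward(lo), frame.from_forward(hi))
    intron_seq = frame.seq[s_lo:s_hi]
    exon5 = frame.seq[max(s_lo - cfg.exon5_window, 0) : s_lo]
    exon3 = frame.seq[s_hi : s_hi + cfg.exon3_window]
    call.interactions = struct_mod.annotate_interactions(
        intron_seq, exon5, exon3, structure
    )

    region = structure.region("lambda_eps_region")
    if region is not None:
        kind = struct_mod.region_kind(structure, region)
        call.subtype = struct_mod.classify_subtype(
            structure.region_seq("lambda_eps_region"), kind
        )
    else:
        call.flags.append("subtype-region-unlabeled")

    ok, _motif = struct_mod.check_catalytic_triad(structure.region_seq("D5"))
    if not ok:
        call.flags.append("triad-missing")
    d6 = structure.region("D6")
    if d6 is not None:
        d6_seq = structure.region_seq("D6")
        d6_db = structure.dotbracket[d6[0] - 1 : d6[1]]
        if struct_mod.find_bulged_a(d6_seq, d6_db) is None:
            call.flags.append("bulged-A-missing")


def _classify_call_iep(
    call: curation.IntronCall,
    frame: _SenseFrame,
    domain_hits: Sequence,
    cfg: RunConfig,
) -> None:
    lo, hi = call.resolved_interval()
    s_lo = min(frame.from_forward(lo), frame.from_forward(hi))
    s_hi = max(frame.from_forward(lo), frame.from_forward(hi))
    intron_seq = frame.seq[s_lo:s_hi]
    if len(intron_seq) < 3:
        call.iep = iep_mod.IepCall(orf=None, iep_class="none")
        call.iep_class = "none"
        return
    translations = iep_mod.three_frame_translate(intron_seq)
    orfs = iep_mod.find_orfs(
        translations, min_orf_aa=cfg.min_orf_aa, intron_id=call.genome_id
    )
    best = orfs[0] if orfs else None
    call.iep = iep_mod.classify_iep(
        best, domain_hits, evalue_cutoff=cfg.iep_evalue_cutoff
    )
    call.iep_class = call.iep.iep_class


def run_pipeline(
    genomes,
    tblout,
    domtblout=None,
    structures=None,
    homologs=None,
    cfg: Optional[RunConfig] = None,
    out_dir: Optional[PathLike] = None,
) -> PipelineResult:
    """Run every stage and optionally write GFF3/TSV/JSON reports.

    ``genomes``/``tblout``/``domtblout``/``structures``/``homologs`` may
    be paths or pre-parsed objects (``structures`` as a path means a
    dot-bracket file; its sidecar region TSV is expected next to it with
    the suffix ``.tsv`` replacing the file's suffix).
    """
    if cfg is None:
        cfg = RunConfig()
    genome_map = _coerce_genomes(genomes)
    hits = _coerce_hits(tblout)
    stage_counts = {"hits_in": len(hits)}

    known = [h for h in hits if h.model_type is not ModelType.UNKNOWN]
    if len(known) < len(hits):
        log.info("dropped %d hits to unknown models", len(hits) - len(known))
    kept = curation.filter_hits(known, cfg.curation.evalue_max)
    stage_counts["hits_significant"] = len(kept)
    log.info("E-value filter: %d of %d hits kept", len(kept), len(known))

    calls = curation.pair_hits(kept, cfg.curation)
    stage_counts["calls_paired"] = len(calls)
    calls = curation.dedup_calls(calls, genome_map, cfg.curation)
    stage_counts["calls_after_dedup"] = len(calls)

    if isinstance(structures, (str, Path)):
        structures = read_structures(
            structures, Path(structures).with_suffix(".tsv")
        )
    struct_items = [(s.seq_id, s) for s in (structures or [])]
    if isinstance(homologs, (str, Path)):
        homologs = read_fasta(homologs)
    homolog_items = [(h.id, h) for h in (homologs or [])]
    if isinstance(domtblout, (str, Path)):
        domtblout = read_domtblout(domtblout)
    dom_items: list[tuple[str, object]] = []
    by_query: dict[str, list] = {}
    for d in domtblout or []:
        by_query.setdefault(d.query_orf_id.split("|orf")[0], []).append(d)
    dom_items = [(k, v) for k, v in by_query.items()]

    for call in calls:
        genome = genome_map[call.genome_id]
        homolog = _match_by_locus(call, homolog_items)
        frame = _resolve_boundaries(call, genome, homolog, cfg)
        structure = _match_by_locus(call, struct_items)
        _annotate_call(call, frame, structure, cfg)
        d_hits = _match_by_locus(call, dom_items) or []
        _classify_call_iep(call, frame, d_hits, cfg)

    iep_mod.flag_trans_mobilizable(calls)
    census = curation.completeness_census(calls)
    inventory = build_inventory(calls)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gff3(calls, out_dir / "introns.gff3", genomes=genome_map)
        inventory.to_csv(out_dir / "inventory.tsv", sep="\t", index=False)
        (out_dir / "census.json").write_text(
            json.dumps({"census": census, "stage_counts": stage_counts},
                       indent=2, sort_keys=True) + "\n"
        )
    return PipelineResult(calls=calls, census=census, inventory=inventory,
                          stage_counts=stage_counts)


def build_inventory(calls: Sequence[curation.IntronCall]) -> pd.DataFrame:
    """One row per surviving call, in genome/coordinate order."""
    rows = []
    per_genome: dict[str, int] = {}
    for call in sorted(calls, key=lambda c: (c.genome_id,) + c.resolved_interval()):
        idx = per_genome.get(call.genome_id, 0) + 1
        per_genome[call.genome_id] = idx
        lo, hi = call.resolved_interval()
        rows.append(
            {
                "genome_id": call.genome_id,
                "intron_index": idx,
                "start": lo + 1,
                "end": hi,
                "strand": call.strand,
                "completeness": call.completeness,
                "subtype": call.subtype,
                "iep_class": call.iep_class,
                "trans_mobilizable": call.trans_mobilizable,
                "n_interactions_detected": sum(
                    1 for a in call.interactions if a.detected
                ),
                "flags": "|".join(call.flags) if call.flags else ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "intron_index", "start", "end", "strand",
            "completeness", "subtype", "iep_class", "trans_mobilizable",
            "n_interactions_detected", "flags",
        ],
    )
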