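"""Readers and writers for the external formats the pipeline touches.

Supported formats: FASTA (read/write), Infernal ``cmsearch --tblout``
(read), HMMER ``hmmscan --domtblout`` (read), dot-bracket structure files
with a sidecar region-label table (read/write), GFF3 (write/read-back),
and TSV reports.

Coordinate convention: everything in memory is 0-based half-open on the
forward strand plus a strand flag; all I/O converts to and from the
1-based inclusive convention used by tblout and GFF3. This keeps every
off-by-one conversion in this one module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger(__name__)

_DNA_OK = set("ACGTN")
# ambiguity codes silently collapsed to N on read (rare in phage assemblies)
_DNA_AMBIG = set("RYSWKMBDHV")

#: Region names understood by structure records.
REGION_NAMES = frozenset(
    ["D1", "D2", "D3", "D4", "D5", "D6", "EBS1", "EBS2", "lambda_eps_region"]
    + [
        name + prime
        for name in ("alpha", "beta", "gamma", "delta", "epsilon", "lambda", "kappa", "zeta")
        for prime in ("", "'")
    ]
)


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


class ModelType(str, Enum):
    """Which part of the group II intron consensus a covariance model covers."""

    D1D4 = "D1D4"
    D5D6 = "D5D6"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class SeqRecord:
    """A DNA sequence with a unique id, uppercased, over {A,C,G,T,N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        bad = set(self.seq) - _DNA_OK
        if bad:
            raise FormatError(
                f"sequence record {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CMHit:
    """One covariance-model hit on a genome.

    ``start``/``end`` are 0-based half-open forward-strand coordinates
    (start < end regardless of strand). 1-based inclusive views are
    available as :attr:`start1` / :attr:`end1`.
    """

    target_id: str
    model_name: str
    model_type: ModelType
    start: int
    end: int
    strand: str
    evalue: float
    bit_score: float
    truncated: str = "no"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"hit on {self.target_id}: bad interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"hit on {self.target_id}: bad strand {self.strand!r}")
        if self.evalue < 0:
            raise FormatError(f"hit on {self.target_id}: negative E-value")

    @property
    def start1(self) -> int:
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.end

    # Sense-axis coordinates: monotone along the 5'->3' direction of the
    # hit's strand, independent of genome length (minus strand is mapped
    # to negated forward coordinates).
    @property
    def sense_start(self) -> int:
        return self.start if self.strand == "+" else -self.end

    @property
    def sense_end(self) -> int:
        return self.end if self.strand == "+" else -self.start


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain hit inside an intron-encoded ORF.

    Coordinates are 1-based inclusive amino-acid positions on the query
    ORF translation, as reported by the domain table.
    """

    query_orf_id: str
    domain_accession: str
    domain_name: str
    ali_from: int
    ali_to: int
    i_evalue: float

    def __post_init__(self) -> None:
        if self.ali_from > self.ali_to:
            raise FormatError(f"domain hit {self.domain_name}: ali_from > ali_to")
        if self.i_evalue < 0:
            raise FormatError(f"domain hit {self.domain_name}: negative i-E-value")


@dataclass
class StructureRecord:
    """A per-intron secondary structure with labeled regions.

    ``dotbracket`` uses up to three independent bracket classes
    ``()``, ``[]`` and ``<>`` (pseudoknots are representable); ``.`` is
    unpaired. ``region_labels`` maps region names to lists of 1-based
    inclusive intervals on the intron sequence.
    """

    seq_id: str
    seq: str
    dotbracket: str
    region_labels: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.dotbracket):
            raise FormatError(
                f"structure {self.seq_id}: sequence and dot-bracket lengths differ"
            )
        paired_positions(self.dotbracket)  # raises on unbalanced brackets
        for name, ivals in self.region_labels.items():
            for lo, hi in ivals:
                if not (1 <= lo <= hi <= len(self.seq)):
                    raise FormatError(
                        f"structure {self.seq_id}: region {name} interval "
                        f"({lo},{hi}) outside sequence bounds"
                    )
        domains = [
            self.region_labels[d][0]
            for d in ("D1", "D2", "D3", "D4", "D5", "D6")
            if d in self.region_labels
        ]
        if len(domains) == 6:
            for (lo1, hi1), (lo2, hi2) in zip(domains, domains[1:]):
                if hi1 >= lo2:
                    raise FormatError(
                        f"structure {self.seq_id}: D1-D6 intervals must be "
                        "non-overlapping and ascending"
                    )

    def region(self, name: str) -> Optional[tuple[int, int]]:
        """First labeled interval for a region, or None."""
        ivals = self.region_labels.get(name)
        return ivals[0] if ivals else None

    def region_seq(self, name: str) -> Optional[str]:
        ival = self.region(name)
        if ival is None:
            return None
        return self.seq[ival[0] - 1 : ival[1]]


_BRACKETS = {"(": ")", "[": "]", "<": ">"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


def paired_positions(dotbracket: str) -> set[tuple[int, int]]:
    """Base-paired position pairs (1-based) of a dot-bracket string.

    Each bracket class is matched independently by stack discipline, so
    pseudoknots written with distinct classes are handled. Raises
    :class:`FormatError` (with the offending position) on unbalanced input.
    """
    stacks: dict[str, list[int]] = {k: [] for k in _BRACKETS}
    pairs: set[tuple[int, int]] = set()
    for i, c in enumerate(dotbracket, start=1):
        if c == ".":
            continue
        if c in _BRACKETS:
            stacks[c].append(i)
        elif c in _CLOSERS:
            opener = _CLOSERS[c]
            if not stacks[opener]:
                raise FormatError(f"unbalanced {c!r} at position {i}")
            pairs.add((stacks[opener].pop(), i))
        else:
            raise FormatError(f"illegal structure character {c!r} at position {i}")
    for opener, stack in stacks.items():
        if stack:
            raise FormatError(f"unclosed {opener!r} at position {stack[-1]}")
    return pairs


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into validated records.

    Sequences are uppercased, U is mapped to T, and IUPAC ambiguity codes
    are collapsed to N (with a warning). Duplicate ids and empty files are
    errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        ambig = set(seq) & _DNA_AMBIG
        if ambig:
            log.warning(
                "%s: record %s has ambiguity codes %s; collapsed to N",
                path, rec.id, sorted(ambig),
            )
            seq = "".join("N" if c in _DNA_AMBIG else c for c in seq)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, seq=seq, description=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Infernal cmsearch --tblout

# Fixed column schema of cmsearch --tblout (Infernal 1.1.x): 17 fixed
# whitespace-delimited fields, then a free-text target description.
_TBLOUT_NFIXED = 17


def default_model_map() -> dict[str, ModelType]:
    """Model-name -> consensus-part mapping for the stock Rfam models.

    RF00029 is the conserved 3' D5/D6 model; the seven clan models named
    ``group-II-D1D4-1`` .. ``group-II-D1D4-7`` cover the variable 5' end.
    """
    mapping = {"RF00029": ModelType.D5D6, "Intron_gpII": ModelType.D5D6}
    for i in range(1, 8):
        mapping[f"group-II-D1D4-{i}"] = ModelType.D1D4
    return mapping


def _classify_model(name: str, model_map: Mapping[str, ModelType]) -> ModelType:
    if name in model_map:
        return model_map[name]
    if name.startswith("group-II-D1D4"):
        return ModelType.D1D4
    return ModelType.UNKNOWN


def read_cm_tblout(
    path: str | Path,
    model_map: Optional[Mapping[str, ModelType]] = None,
    strict: bool = False,
) -> list[CMHit]:
    """Parse a ``cmsearch --tblout`` table into CM hits.

    Minus-strand rows (seq from > seq to) are normalized so start < end.
    Unknown model names map to :attr:`ModelType.UNKNOWN` and are kept with
    a warning, unless ``strict`` is set, in which case they are an error.
    """
    if model_map is None:
        model_map = default_model_map()
    hits: list[CMHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(None, _TBLOUT_NFIXED)
            if len(parts) < _TBLOUT_NFIXED:
                raise FormatError(
                    f"{path}:{lineno}: expected {_TBLOUT_NFIXED} columns, "
                    f"got {len(parts)}"
                )
            try:
                target = parts[0]
                model_name = parts[2]
                seq_from = int(parts[7])
                seq_to = int(parts[8])
                strand = parts[9]
                trunc = parts[10]
                score = float(parts[14])
                evalue = float(parts[15])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if seq_from > seq_to:
                if strand != "-":
                    raise FormatError(
                        f"{path}:{lineno}: seq from > seq to on + strand"
                    )
                seq_from, seq_to = seq_to, seq_from
            mtype = _classify_model(model_name, model_map)
            if mtype is ModelType.UNKNOWN:
                if strict:
                    raise FormatError(
                        f"{path}:{lineno}: unknown model name {model_name!r}"
                    )
                log.warning("%s:%d: unknown model %r", path, lineno, model_name)
            hits.append(
                CMHit(
                    target_id=target,
                    model_name=model_name,
                    model_type=mtype,
                    start=seq_from - 1,
                    end=seq_to,
                    strand=strand,
                    evalue=evalue,
                    bit_score=score,
                    truncated=trunc,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# HMMER hmmscan --domtblout

# 22 fixed fields, then a free-text description.
_DOMTBL_NFIXED = 22


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a ``hmmscan --domtblout`` per-domain table.

    Domain accessions are normalized by stripping the Pfam version suffix
    (``PF00078.33`` -> ``PF00078``).
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(None, _DOMTBL_NFIXED)
            if len(parts) < _DOMTBL_NFIXED:
                raise FormatError(
                    f"{path}:{lineno}: expected {_DOMTBL_NFIXED} columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    DomainHit(
                        query_orf_id=parts[3],
                        domain_accession=parts[1].split(".")[0],
                        domain_name=parts[0],
                        ali_from=int(parts[17]),
                        ali_to=int(parts[18]),
                        i_evalue=float(parts[12]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# Dot-bracket structures + sidecar region labels


def write_structures(
    records: Iterable[StructureRecord],
    db_path: str | Path,
    regions_path: str | Path,
) -> None:
    """Write structures as Vienna-style dot-bracket plus a region TSV."""
    with open(db_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n{rec.seq}\n{rec.dotbracket}\n")
    with open(regions_path, "w") as fh:
        fh.write("seq_id\tregion\tstart\tend\n")
        for rec in records:
            for name in sorted(rec.region_labels):
                for lo, hi in rec.region_labels[name]:
                    fh.write(f"{rec.seq_id}\t{name}\t{lo}\t{hi}\n")


def read_structures(
    db_path: str | Path, regions_path: str | Path
) -> list[StructureRecord]:
    raw: list[tuple[str, str, str]] = []
    with open(db_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"{db_path}: expected '>' header, got {lines[i]!r}")
        if i + 2 >= len(lines):
            raise FormatError(f"{db_path}: truncated record at {lines[i]!r}")
        raw.append((lines[i][1:].split()[0], lines[i + 1].upper(), lines[i + 2]))
        i += 3
    labels: dict[str, dict[str, list[tuple[int, int]]]] = {}
    with open(regions_path) as fh:
        header = fh.readline()
        if not header.startswith("seq_id"):
            raise FormatError(f"{regions_path}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(f"{regions_path}:{lineno}: expected 4 columns")
            sid, region, lo, hi = fields
            if region not in REGION_NAMES:
                raise FormatError(f"{regions_path}:{lineno}: unknown region {region!r}")
            labels.setdefault(sid, {}).setdefault(region, []).append((int(lo), int(hi)))
    return [
        StructureRecord(seq_id=sid, seq=seq, dotbracket=db, region_labels=labels.get(sid, {}))
        for sid, seq, db in raw
    ]


# ---------------------------------------------------------------------------
# GFF3


def _gff_escape(value: str) -> str:
    return (
        value.replace("%", "%25").replace(";", "%3B").replace("=", "%3D")
        .replace("&", "%26").replace(",", "%2C")
    )


def write_gff3(
    calls: Sequence,
    path: str | Path,
    genomes: Optional[Mapping[str, SeqRecord]] = None,
) -> None:
    """Write intron calls as GFF3.

    One ``group_II_intron`` parent feature per call (1-based inclusive,
    strand preserved) with child features for the D1-D4 and D5/D6 hits,
    the IEP ORF when present, and detected interactions. Attributes carry
    completeness, subtype and IEP class.
    """
    lines = ["##gff-version 3"]
    for idx, call in enumerate(calls, start=1):
        start0, end0 = call.resolved_interval()
        if genomes is not None and call.genome_id in genomes:
            glen = len(genomes[call.genome_id])
            if not (0 <= start0 < end0 <= glen):
                raise FormatError(
                    f"call {call.genome_id}[{start0},{end0}) outside sequence bounds"
                )
        cid = f"intron{idx:04d}"
        attrs = [
            f"ID={cid}",
            f"completeness={call.completeness}",
            f"subtype={call.subtype}",
            f"iep_class={call.iep_class}",
            f"trans_mobilizable={'true' if call.trans_mobilizable else 'false'}",
        ]
        if call.flags:
            attrs.append("flags=" + _gff_escape("|".join(call.flags)))
        lines.append(
            "\t".join(
                [
                    call.genome_id, "lariat", "group_II_intron",
                    str(start0 + 1), str(end0), ".", call.strand, ".",
                    ";".join(attrs),
                ]
            )
        )
        for j, hit in enumerate(call.d1d4_hits, start=1):
            lines.append(
                "\t".join(
                    [
                        call.genome_id, "lariat", "match_part",
                        str(hit.start1), str(hit.end1), f"{hit.bit_score:.1f}",
                        call.strand, ".",
                        f"ID={cid}.d1d4.{j};Parent={cid};"
                        f"model={_gff_escape(hit.model_name)};evalue={hit.evalue:g}",
                    ]
                )
            )
        if call.d5d6_hit is not None:
            hit = call.d5d6_hit
            lines.append(
                "\t".join(
                    [
                        call.genome_id, "lariat", "match_part",
                        str(hit.start1), str(hit.end1), f"{hit.bit_score:.1f}",
                        call.strand, ".",
                        f"ID={cid}.d5d6;Parent={cid};"
                        f"model={_gff_escape(hit.model_name)};evalue={hit.evalue:g}",
                    ]
                )
            )
        if getattr(call, "iep", None) is not None and call.iep.orf is not None:
            nt_lo, nt_hi = call.iep.orf.nt_interval
            arch = _gff_escape(",".join(call.iep.architecture))
            lines.append(
                "\t".join(
                    [
                        call.genome_id, "lariat", "CDS",
                        str(start0 + nt_lo + 1) if call.strand == "+" else str(end0 - nt_hi + 1),
                        str(start0 + nt_hi) if call.strand == "+" else str(end0 - nt_lo),
                        ".", call.strand, "0",
                        f"ID={cid}.orf;Parent={cid};iep_class={call.iep_class};"
                        f"architecture={arch}",
                    ]
                )
            )
        for k, ann in enumerate(
            [a for a in call.interactions if a.detected], start=1
        ):
            lines.append(
                "\t".join(
                    [
                        call.genome_id, "lariat", "base_pairing_interaction",
                        str(start0 + 1), str(end0), ".", call.strand, ".",
                        f"ID={cid}.int.{k};Parent={cid};"
                        f"rule={_gff_escape(ann.rule_name)};n_bp={ann.n_bp};"
                        f"n_wobble={ann.n_wobble}",
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[dict]:
    """Minimal GFF3 reader used for round-trip verification.

    Returns one dict per feature line with typed coordinates and parsed
    attributes.
    """
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: bad GFF3 line: {line!r}")
            attrs = {}
            for kv in cols[8].split(";"):
                if kv:
                    k, _, v = kv.partition("=")
                    attrs[k] = v
            feats.append(
                {
                    "seqid": cols[0], "source": cols[1], "type": cols[2],
                    "start": int(cols[3]), "end": int(cols[4]),
                    "score": cols[5], "strand": cols[6], "phase": cols[7],
                    "attributes": attrs,
                }
            )
    return feats
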