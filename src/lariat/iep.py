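"""Intron-encoded protein discovery and classification.

Group II introns often carry an ORF (typically in the D4 loop) encoding a
multifunctional reverse transcriptase (RVT) with a maturase "X" domain;
some phage introns instead encode homing endonucleases (HEGs). ORFs are
found by translating the intron in the three sense-strand frames and
taking maximal stop-free stretches; classification rests entirely on
protein-domain hits (a Pfam domain table), not on start codons or
sequence heuristics. ORF-less introns can still be mobile in trans when a
co-resident intron in the same genome supplies an RVT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from lariat.io import DomainHit

#: Pfam accessions recognized as reverse-transcriptase domains.
RVT_ACCESSIONS = frozenset({"PF00078", "PF07727"})
#: Pfam accessions recognized as the group II maturase "X" domain.
X_ACCESSIONS = frozenset({"PF01348", "PF08388"})
#: Nuclease / homing-endonuclease-like accessions. Phage intron HEGs are
#: not closely related to the classic HEG families, so this set is meant
#: to be extended by the user with whatever their domain search reports.
NUCLEASE_ACCESSIONS = frozenset({"PF03852", "PF01844", "PF00961", "PF01541"})

DEFAULT_MIN_ORF_AA = 150
DEFAULT_EVALUE_CUTOFF = 1e-3


@dataclass(frozen=True)
class OrfRecord:
    """A stop-free translated stretch within the intron bounds.

    ``aa_start``/``aa_end`` are 1-based inclusive on the frame
    translation; ``nt_interval`` is 0-based half-open on the intron
    sense sequence.
    """

    intron_id: str
    frame: int
    aa_start: int
    aa_end: int
    nt_interval: tuple[int, int]
    protein: str

    def __post_init__(self) -> None:
        if "*" in self.protein:
            raise ValueError("ORF protein must be stop-free")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")


@dataclass(frozen=True)
class IepCall:
    """Classification of an intron's encoded protein."""

    orf: Optional[OrfRecord]
    iep_class: str  # RVT | HEG | other | none
    architecture: tuple[str, ...] = ()
    evidence: tuple[DomainHit, ...] = ()


def three_frame_translate(intron_seq: str) -> list[str]:
    """Standard-code translations of the three sense frames.

    Stops are ``*``; a trailing partial codon is dropped.
    """
    if len(intron_seq) < 3:
        raise ValueError("sequence shorter than one codon")
    out = []
    for frame in range(3):
        sub = intron_seq[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate(table=1)) if sub else "")
    return out


def find_orfs(
    translations: Sequence[str],
    min_orf_aa: int = DEFAULT_MIN_ORF_AA,
    require_start: bool = False,
    intron_id: str = "",
) -> list[OrfRecord]:
    """Maximal stop-free stretches of length >= ``min_orf_aa``.

    With ``require_start`` each stretch is trimmed to its first
    methionine. Results are sorted by protein length, longest first.
    """
    orfs: list[OrfRecord] = []
    for frame, aa in enumerate(translations):
        start = 0
        for chunk in aa.split("*"):
            if chunk:
                s = start
                pep = chunk
                if require_start:
                    m = pep.find("M")
                    if m < 0:
                        start += len(chunk) + 1
                        continue
                    s += m
                    pep = pep[m:]
                if len(pep) >= min_orf_aa:
                    nt_lo = frame + 3 * s
                    orfs.append(
                        OrfRecord(
                            intron_id=intron_id,
                            frame=frame,
                            aa_start=s + 1,
                            aa_end=s + len(pep),
                            nt_interval=(nt_lo, nt_lo + 3 * len(pep)),
                            protein=pep,
                        )
                    )
            start += len(chunk) + 1
    orfs.sort(key=lambda o: (-len(o.protein), o.frame, o.aa_start))
    return orfs


def classify_iep(
    orf: Optional[OrfRecord],
    domain_hits: Sequence[DomainHit],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    rvt_accessions: frozenset[str] = RVT_ACCESSIONS,
    nuclease_accessions: frozenset[str] = NUCLEASE_ACCESSIONS,
    x_accessions: frozenset[str] = X_ACCESSIONS,
) -> IepCall:
    """Classify an ORF from its domain hits.

    Hits with independent E-value >= cutoff are discarded. RVT wins when
    any reverse-transcriptase accession passes; HEG requires a nuclease
    accession and no RVT; anything else that passes is ``other``;
    nothing passing (or no ORF) is ``none``. The architecture lists
    passing domains in alignment order.
    """
    passing = sorted(
        (h for h in domain_hits if h.i_evalue < evalue_cutoff),
        key=lambda h: (h.ali_from, h.ali_to),
    )
    if orf is None or not passing:
        return IepCall(orf=orf, iep_class="none")

    def label(h: DomainHit) -> str:
        if h.domain_accession in rvt_accessions:
            return "RT"
        if h.domain_accession in x_accessions:
            return "X"
        if h.domain_accession in nuclease_accessions:
            return "En"
        return h.domain_name

    labels = tuple(label(h) for h in passing)
    if any(lab == "RT" for lab in labels):
        cls = "RVT"
    elif any(lab == "En" for lab in labels):
        cls = "HEG"
    else:
        cls = "other"
    return IepCall(orf=orf, iep_class=cls, architecture=labels, evidence=tuple(passing))


def flag_trans_mobilizable(calls: Iterable) -> None:
    """Mark non-RVT introns mobilizable in trans by a co-resident RVT.

    For each genome, every call with ``iep_class`` in {none, HEG, other}
    is flagged true iff at least one *other* intron in the same genome
    encodes an RVT. Mutates the calls in place.
    """
    by_genome: dict[str, list] = {}
    for call in calls:
        by_genome.setdefault(call.genome_id, []).append(call)
    for group in by_genome.values():
        n_rvt = sum(1 for c in group if c.iep_class == "RVT")
        for c in group:
            c.trans_mobilizable = c.iep_class != "RVT" and n_rvt >= 1


def rvt_domain_sequences(calls: Iterable) -> dict[str, str]:
    """RVT-domain peptide per RVT-encoding call, keyed by genome id + index.

    This is the sequence set a downstream RVT phylogeny would consume;
    tree inference itself is out of scope here.
    """
    out: dict[str, str] = {}
    counter: dict[str, int] = {}
    for call in calls:
        if call.iep_class != "RVT" or call.iep is None or call.iep.orf is None:
            continue
        idx = counter.get(call.genome_id, 0) + 1
        counter[call.genome_id] = idx
        rt_hits = [h for h in call.iep.evidence if h.domain_accession in RVT_ACCESSIONS]
        pep = call.iep.orf.protein
        if rt_hits:
            h = rt_hits[0]
            pep = pep[h.ali_from - 1 : h.ali_to]
        out[f"{call.genome_id}_rvt{idx}"] = pep
    return out
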