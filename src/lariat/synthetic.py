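"""Synthetic genomes with planted group II introns and mock search output.

The generator emulates the real study inputs — phage genome sets searched
with RNA covariance models and protein domain profiles — at desk scale:
it plants consensus-conformant group II introns (GWYRG 5' site, D1-D6
skeleton, EBS/IBS complements, subtype-diagnostic lambda-epsilon' region,
AGC/CGC catalytic triad, bulged adenosine, optional D4 ORF) into random
host genes inside random genome backgrounds, then emits the matching mock
``cmsearch --tblout`` and ``hmmscan --domtblout`` tables with configurable
envelope jitter and noise rows, per-intron dot-bracket structures with
region labels, intronless homologs of the host genes, and a
machine-readable truth table that serves as the oracle for every other
module.

Planted introns are mutually consistent with the annotators by design:
every one passes the catalytic-triad and bulged-A checks, carries a
detectable EBS1:IBS1 duplex, and classifies as its planted subtype.
ORF-less introns are ~600 nt; ORF-containing introns are ~2-3 kb, as is
typical for the element.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from lariat._dna import STOP_CODONS, complement, revcomp
from lariat.io import SeqRecord, StructureRecord, write_fasta, write_structures

_BASES = "ACGT"
_AA_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(CodonTable.unambiguous_dna_by_id[1].forward_table.items()):
    _AA_CODONS.setdefault(aa, []).append(codon)
_AAS = sorted(_AA_CODONS)

_D1D4_MODELS = [f"group-II-D1D4-{i}" for i in range(1, 8)]
_D5D6_MODEL = "RF00029"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic bundle.

    The defaults reflect the composition of the real discovery set:
    subtype mix dominated by IIB with IIA and IIC minorities, roughly a
    third of introns encoding an RVT, a fifth a HEG, and the rest
    ORF-less; noise hit E-values straddle the 0.01 significance
    threshold so that filtering is exercised.
    """

    n_genomes: int = 50
    genome_length_mean: int = 30_000
    genome_length_sd: int = 3_000
    introns_per_genome: tuple[tuple[int, float], ...] = (
        (0, 0.45), (1, 0.45), (2, 0.10),
    )
    subtype_mix: tuple[tuple[str, float], ...] = (
        ("IIA", 0.15), ("IIB", 0.80), ("IIC", 0.05),
    )
    p_iep_rvt: float = 0.35
    p_iep_heg: float = 0.20
    p_orfless: float = 0.45
    p_partial_call: float = 0.10
    ebs1_len: int = 6
    ebs2_len: int = 4
    flank_gene_length: int = 300  # nt of coding exon on each side of the intron
    noise_hits_per_genome: int = 2
    noise_evalue_range: tuple[float, float] = (0.005, 10.0)
    hit_jitter: int = 10
    homolog_sub_rate: float = 0.0
    rvt_orf_aa: int = 450
    heg_orf_aa: int = 260
    rvt_len_range: tuple[int, int] = (2200, 3000)
    heg_len_range: tuple[int, int] = (1800, 2600)
    orfless_len_range: tuple[int, int] = (550, 680)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.p_iep_rvt, self.p_iep_heg, self.p_orfless]
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise ValueError("IEP class probabilities must be in [0,1] and sum to 1")
        if abs(sum(p for _, p in self.introns_per_genome) - 1) > 1e-9:
            raise ValueError("introns_per_genome probabilities must sum to 1")
        if abs(sum(p for _, p in self.subtype_mix) - 1) > 1e-9:
            raise ValueError("subtype mix must sum to 1")
        if self.ebs1_len < 4 or self.ebs2_len < 3:
            raise ValueError("EBS lengths too short to be detectable")
        if self.flank_gene_length % 3 or self.flank_gene_length < 30:
            raise ValueError("flank_gene_length must be a multiple of 3, >= 30")


@dataclass
class PlantedTruth:
    """Ground truth for one planted intron (the acceptance oracle)."""

    genome_id: str
    intron_id: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str
    subtype: str
    iep_class: str
    ebs1: str
    ebs2: str
    delta: str
    domain_intervals: dict[str, tuple[int, int]]  # 0-based half-open, intron sense
    orf_nt_interval: Optional[tuple[int, int]]  # 0-based half-open, intron sense
    orf_protein: Optional[str]
    host_frame: int
    host_protein: str
    homolog_id: str
    suppressed_row: Optional[str] = None  # None | 'd1d4' | 'd5d6'

    @property
    def start1(self) -> int:
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.end


@dataclass
class Bundle:
    """An in-memory synthetic dataset plus its rendered file contents."""

    config: SyntheticConfig
    genomes: list[SeqRecord]
    homologs: list[SeqRecord]
    structures: list[StructureRecord]
    truths: list[PlantedTruth]
    tblout: str
    domtblout: str

    def genome_map(self) -> dict[str, SeqRecord]:
        return {g.id: g for g in self.genomes}

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        return {
            "config": cfg,
            "seed": self.config.seed,
            "n_genomes": len(self.genomes),
            "n_introns": len(self.truths),
            "sha256": {
                "tblout": hashlib.sha256(self.tblout.encode()).hexdigest(),
                "domtblout": hashlib.sha256(self.domtblout.encode()).hexdigest(),
                "genomes": hashlib.sha256(
                    "".join(g.seq for g in self.genomes).encode()
                ).hexdigest(),
            },
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genomes": outdir / "genomes.fasta",
            "homologs": outdir / "homologs.fasta",
            "structures": outdir / "structures.db",
            "regions": outdir / "structures.tsv",  # sidecar next to the dot-bracket file
            "tblout": outdir / "hits.tbl",
            "domtblout": outdir / "domains.domtbl",
            "truth": outdir / "truth.tsv",
            "manifest": outdir / "manifest.json",
        }
        write_fasta(self.genomes, paths["genomes"])
        if self.homologs:
            write_fasta(self.homologs, paths["homologs"])
        write_structures(self.structures, paths["structures"], paths["regions"])
        paths["tblout"].write_text(self.tblout)
        paths["domtblout"].write_text(self.domtblout)
        paths["truth"].write_text(write_truth(self.truths))
        paths["manifest"].write_text(json.dumps(self.manifest(), indent=2, sort_keys=True))
        return paths


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _realize(pattern: str, rng: np.random.Generator) -> str:
    from lariat._dna import IUPAC

    out = []
    for c in pattern:
        choices = IUPAC[c].strip("[]")
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _rand_protein(rng: np.random.Generator, n: int, start_m: bool = True) -> str:
    core = "".join(_AAS[i] for i in rng.integers(0, len(_AAS), size=n - 1))
    return ("M" + core) if start_m else _AAS[int(rng.integers(len(_AAS)))] + core


def _encode(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _AA_CODONS[aa][int(rng.integers(len(_AA_CODONS[aa])))] for aa in protein
    )


class _Builder:
    """Accumulates sequence + dot-bracket + labeled intervals."""

    def __init__(self) -> None:
        self.seq: list[str] = []
        self.db: list[str] = []
        self.pos = 0
        self.labels: dict[str, list[tuple[int, int]]] = {}

    def add(self, seq: str, db: str, labels: Sequence[str] = ()) -> tuple[int, int]:
        assert len(seq) == len(db)
        start = self.pos
        self.seq.append(seq)
        self.db.append(db)
        self.pos += len(seq)
        for lab in labels:
            self.labels.setdefault(lab, []).append((start, self.pos))
        return start, self.pos

    def mark(self, label: str, start: int, end: Optional[int] = None) -> None:
        self.labels.setdefault(label, []).append((start, end if end is not None else self.pos))

    def build(self) -> tuple[str, str]:
        return "".join(self.seq), "".join(self.db)


def _ibs_tail(ebs1: str, ebs2: str) -> str:
    """The codon-aligned 3' tail of the 5' exon carrying IBS2 then IBS1.

    Padded to a codon boundary with C (no stop codon contains a C, so
    the padding can never create one).
    """
    core = revcomp(ebs2) + revcomp(ebs1)
    pad = (-len(core)) % 3
    return "C" * pad + core


def _ibs_tail_stop_free(ebs1: str, ebs2: str) -> bool:
    t = _ibs_tail(ebs1, ebs2)
    return all(t[i : i + 3] not in STOP_CODONS for i in range(0, len(t), 3))


def generate_intron(
    cfg: SyntheticConfig, subtype: str, iep_class: str, rng: np.random.Generator
) -> tuple[str, StructureRecord, dict]:
    """One consensus-conformant intron with structure and truth fragment.

    The sequence starts with a GWYRG realization, carries six labeled
    domains in ascending order, EBS1/EBS2 in unpaired D1 loop positions,
    a lambda-epsilon' region realizing the requested subtype, an AGC or
    CGC triad at the start of D5, a bulged interior adenosine in D6 and
    a terminal gamma' nucleotide. RVT introns embed a stop-free ORF in
    the D4 loop (truth domains RT + X), HEG introns a shorter ORF (truth
    nuclease domain); ORF-less introns come out around 600 nt.
    """
    if subtype not in ("IIA", "IIB", "IIC"):
        raise ValueError(f"unknown subtype {subtype!r}")
    if iep_class not in ("RVT", "HEG", "none"):
        raise ValueError(f"unknown IEP class {iep_class!r}")

    while True:
        ebs1 = _rand_dna(rng, cfg.ebs1_len)
        ebs2 = _rand_dna(rng, cfg.ebs2_len)
        if _ibs_tail_stop_free(ebs1, ebs2):
            break
    while True:
        delta = _rand_dna(rng, 3)
        rc = revcomp(delta)
        if rc not in STOP_CODONS and rc[0] != "G":
            break
    while True:
        gamma = _BASES[int(rng.integers(4))]
        if gamma != ebs1[0]:
            break

    if iep_class == "RVT":
        total_target = int(rng.integers(*cfg.rvt_len_range))
        orf_protein = _rand_protein(rng, cfg.rvt_orf_aa)
    elif iep_class == "HEG":
        total_target = int(rng.integers(*cfg.heg_len_range))
        orf_protein = _rand_protein(rng, cfg.heg_orf_aa)
    else:
        total_target = int(rng.integers(*cfg.orfless_len_range))
        orf_protein = None

    b = _Builder()

    # --- D1: outer stem opens with the GWYRG 5' splice site
    d1_start = b.pos
    stem1 = _realize("GWYRG", rng) + _rand_dna(rng, 1)
    b.add(stem1, "(" * 6)
    loop_items: list[tuple[Optional[str], str]] = [
        ("EBS2", ebs2), (None, _rand_dna(rng, 3)),
        ("EBS1", ebs1), (None, _rand_dna(rng, 3)),
        ("alpha", _rand_dna(rng, 4)), (None, _rand_dna(rng, 2)),
        ("beta", _rand_dna(rng, 4)), (None, _rand_dna(rng, 2)),
        ("epsilon", _rand_dna(rng, 3)), (None, _rand_dna(rng, 2)),
        ("lambda", _rand_dna(rng, 3)), (None, _rand_dna(rng, 2)),
        ("kappa", _rand_dna(rng, 3)), (None, _rand_dna(rng, 2)),
        ("zeta", _rand_dna(rng, 3)), (None, _rand_dna(rng, 2)),
        ("delta", delta),
    ]
    seqs = {}
    for lab, s in loop_items:
        b.add(s, "." * len(s), labels=(lab,) if lab else ())
        if lab:
            seqs[lab] = s
    b.add(revcomp(stem1), ")" * 6)
    b.mark("D1", d1_start)

    b.add(_rand_dna(rng, 5), ".....")  # spacer

    # --- D2: hairpin whose loop/bulge is the subtype-diagnostic region
    d2_start = b.pos
    if subtype == "IIB":
        bulge = "AA" + "AG"[int(rng.integers(2))] + "C"  # AARC
        outer = _rand_dna(rng, 4)
        inner = _rand_dna(rng, 4)
        b.add(outer, "((((")
        b.mark("lambda_eps_region", *b.add(bulge, "...."))
        b.add(inner, "((((")
        b.add(_rand_dna(rng, 5), ".....")
        b.add(revcomp(inner), "))))")
        b.add(revcomp(outer), "))))")
    else:
        if subtype == "IIA":
            loop_len, motif = 11, "AGC"
        else:
            loop_len = int(rng.integers(7, 13))
            motif = "AGG"
        while True:
            k = int(rng.integers(0, loop_len - 2))
            loop = _rand_dna(rng, k) + motif + _rand_dna(rng, loop_len - 3 - k)
            if subtype == "IIC" and loop_len == 11 and "AGC" in loop:
                continue  # would collide with the IIA signature
            if subtype == "IIA" or "AGC" not in loop or loop_len != 11:
                break
        stem2 = _rand_dna(rng, 5)
        b.add(stem2, "(((((")
        b.mark("lambda_eps_region", *b.add(loop, "." * loop_len))
        b.add(revcomp(stem2), ")))))")
    b.mark("D2", d2_start)

    b.add(revcomp(seqs["alpha"]), "....", labels=("alpha'",))
    b.add(_rand_dna(rng, 2), "..")
    b.add(gamma, ".", labels=("gamma",))
    b.add(_rand_dna(rng, 2), "..")

    # --- D3: loop carries the primed partners of beta, epsilon, kappa
    d3_start = b.pos
    stem3 = _rand_dna(rng, 4)
    b.add(stem3, "((((")
    b.add(revcomp(seqs["beta"]), "....", labels=("beta'",))
    b.add(_rand_dna(rng, 2), "..")
    b.add(revcomp(seqs["epsilon"]), "...", labels=("epsilon'",))
    b.add(_rand_dna(rng, 2), "..")
    b.add(revcomp(seqs["kappa"]), "...", labels=("kappa'",))
    b.add(revcomp(stem3), "))))")
    b.mark("D3", d3_start)

    b.add(_rand_dna(rng, 4), "....")

    # Fixed-length tail after the D4 loop (closing stem, spacers, D5, D6,
    # terminal gamma'): lets the D4 loop padding hit the length target.
    d4_stem = _rand_dna(rng, 4)
    tail_len = 4 + 4 + 14 + 3 + 9 + 1  # ")"*4, spacer, D5, spacer, D6, gamma'
    post_d4_items = 3 + 2 + 3  # lambda' + spacer + zeta'

    d4_start = b.pos
    b.add(d4_stem, "((((")
    if orf_protein is not None:
        pre = _rand_dna(rng, int(rng.integers(6, 13)))
        b.add(pre, "." * len(pre))
        b.add("TAA", "...")  # in-frame stop bounding the ORF on the 5' side
        orf_nt = _encode(orf_protein, rng)
        orf_span = b.add(orf_nt, "." * len(orf_nt))
        b.add("TAA", "...")  # the ORF's own stop
    else:
        b.add(_rand_dna(rng, 10), "." * 10)
        orf_span = None
    b.add(revcomp(seqs["lambda"]), "...", labels=("lambda'",))
    b.add(_rand_dna(rng, 2), "..")
    b.add(revcomp(seqs["zeta"]), "...", labels=("zeta'",))
    pad = max(4, total_target - b.pos - tail_len)
    b.add(_rand_dna(rng, pad), "." * pad)
    b.add(revcomp(d4_stem), "))))")
    b.mark("D4", d4_start)

    b.add(_rand_dna(rng, 4), "....")

    # --- D5: catalytic triad at the stem start
    d5_start = b.pos
    triad = ("AGC", "CGC")[int(rng.integers(2))]
    stem5 = triad + _rand_dna(rng, 2)
    b.add(stem5, "(((((")
    b.add(_rand_dna(rng, 4), "....")
    b.add(revcomp(stem5), ")))))")
    b.mark("D5", d5_start)

    b.add(_rand_dna(rng, 3), "...")

    # --- D6: bulged adenosine between paired neighbours
    d6_start = b.pos
    stem6 = _rand_dna(rng, 4)
    b.add(stem6, "((((")
    b.add("A", ".")
    b.add(revcomp(stem6), "))))")
    b.mark("D6", d6_start)

    b.add(complement(gamma), ".", labels=("gamma'",))

    seq, db = b.build()
    labels1 = {
        name: [(lo + 1, hi) for lo, hi in ivals] for name, ivals in b.labels.items()
    }
    structure = StructureRecord(
        seq_id="pending", seq=seq, dotbracket=db, region_labels=labels1
    )
    truth_fragment = {
        "subtype": subtype,
        "iep_class": iep_class,
        "ebs1": ebs1,
        "ebs2": ebs2,
        "delta": delta,
        "domain_intervals": {
            d: b.labels[d][0] for d in ("D1", "D2", "D3", "D4", "D5", "D6")
        },
        "orf_nt_interval": orf_span,
        "orf_protein": orf_protein,
    }
    return seq, structure, truth_fragment


def _make_exons(
    cfg: SyntheticConfig, tf: dict, rng: np.random.Generator
) -> tuple[str, str, str]:
    """5' and 3' exons carrying IBS1/IBS2 and delta', plus the host protein.

    The host gene is E1+E2 read in frame 0; the IBS and delta' bases are
    written into the exon ends (the generator's EBS/delta choices are
    pre-screened so this never creates an in-frame stop).
    """
    n_aa = cfg.flank_gene_length // 3
    e1 = _encode(_rand_protein(rng, n_aa), rng)
    e2 = _encode(_rand_protein(rng, n_aa, start_m=False), rng)
    tail = _ibs_tail(tf["ebs1"], tf["ebs2"])  # ...IBS2 then IBS1 at the 3' end
    e1 = e1[: -len(tail)] + tail
    e2 = revcomp(tf["delta"]) + e2[3:]
    from Bio.Seq import Seq

    host_protein = str(Seq(e1 + e2).translate(table=1))
    if "*" in host_protein:
        raise AssertionError("exon construction produced an in-frame stop")
    return e1, e2, host_protein


def _mutate_exons(
    e1: str, e2: str, rate: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Substitute exon bases at the given rate, sparing the 6 nt at the junction."""
    if rate <= 0:
        return e1, e2
    def mutate(seq: str, protect: range) -> str:
        chars = list(seq)
        for i in range(len(chars)):
            if i in protect:
                continue
            if rng.random() < rate:
                chars[i] = _BASES[int((_BASES.index(chars[i]) + 1 + rng.integers(3)) % 4)]
        return "".join(chars)

    return (
        mutate(e1, range(len(e1) - 6, len(e1))),
        mutate(e2, range(0, 6)),
    )


def plant_in_genome(
    genome_id: str,
    intron_index: int,
    intron: tuple[str, StructureRecord, dict],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    offset: int,
    strand: str,
) -> tuple[str, SeqRecord, PlantedTruth, StructureRecord]:
    """Embed one intron in a host-gene cassette at a genome offset.

    Returns the forward-strand cassette sequence to splice into the
    genome at ``offset``, the intronless homolog record, the truth
    record, and the structure record with its final id.
    """
    iseq, structure, tf = intron
    e1, e2, host_protein = _make_exons(cfg, tf, rng)
    cassette_sense = e1 + iseq + e2
    cassette = cassette_sense if strand == "+" else revcomp(cassette_sense)
    if strand == "+":
        start = offset + len(e1)
    else:
        start = offset + len(e2)
    end = start + len(iseq)
    iid = f"{genome_id}|{start + 1}-{end}|{strand}"
    h1, h2 = _mutate_exons(e1, e2, cfg.homolog_sub_rate, rng)
    homolog = SeqRecord(id=f"{iid}|homolog", seq=h1 + h2)
    structure = StructureRecord(
        seq_id=iid,
        seq=structure.seq,
        dotbracket=structure.dotbracket,
        region_labels=structure.region_labels,
    )
    truth = PlantedTruth(
        genome_id=genome_id,
        intron_id=iid,
        start=start,
        end=end,
        strand=strand,
        subtype=tf["subtype"],
        iep_class=tf["iep_class"],
        ebs1=tf["ebs1"],
        ebs2=tf["ebs2"],
        delta=tf["delta"],
        domain_intervals=tf["domain_intervals"],
        orf_nt_interval=tf["orf_nt_interval"],
        orf_protein=tf["orf_protein"],
        host_frame=0,
        host_protein=host_protein,
        homolog_id=homolog.id,
    )
    return cassette, homolog, truth, structure


def generate_bundle(
    cfg: SyntheticConfig,
    partial_plan: Optional[Sequence[Optional[str]]] = None,
) -> Bundle:
    """Generate a full synthetic dataset under one seed.

    ``partial_plan`` optionally fixes, per planted intron in generation
    order, which mock hit row to suppress (None, 'd1d4' or 'd5d6');
    without it suppression is random at ``p_partial_call`` per intron.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = [c for c, _ in cfg.introns_per_genome]
    count_p = [p for _, p in cfg.introns_per_genome]
    subtypes = [s for s, _ in cfg.subtype_mix]
    subtype_p = [p for _, p in cfg.subtype_mix]
    iep_classes = ["RVT", "HEG", "none"]
    iep_p = [cfg.p_iep_rvt, cfg.p_iep_heg, cfg.p_orfless]

    genomes: list[SeqRecord] = []
    homologs: list[SeqRecord] = []
    structures: list[StructureRecord] = []
    truths: list[PlantedTruth] = []

    for g in range(cfg.n_genomes):
        gid = f"SYN{g + 1:04d}"
        n_introns = int(rng.choice(counts, p=count_p))
        introns = [
            generate_intron(
                cfg,
                str(rng.choice(subtypes, p=subtype_p)),
                str(rng.choice(iep_classes, p=iep_p)),
                rng,
            )
            for _ in range(n_introns)
        ]
        cassette_len = sum(
            len(i[0]) + 2 * cfg.flank_gene_length for i in introns
        )
        glen = max(
            int(rng.normal(cfg.genome_length_mean, cfg.genome_length_sd)),
            cassette_len + 1000 * (n_introns + 1),
        )
        bg_total = glen - cassette_len
        # split background into n_introns + 1 chunks, each >= 400 nt
        chunks = []
        remaining = bg_total
        for i in range(n_introns):
            hi = remaining - 400 * (n_introns - i)
            chunks.append(int(rng.integers(400, max(hi, 401))))
            remaining -= chunks[-1]
        chunks.append(remaining)
        parts = [_rand_dna(rng, chunks[0])]
        pos = chunks[0]
        for i, intron in enumerate(introns):
            strand = "+-"[int(rng.integers(2))]
            cassette, homolog, truth, structure = plant_in_genome(
                gid, i, intron, cfg, rng, pos, strand
            )
            parts.append(cassette)
            pos += len(cassette)
            homologs.append(homolog)
            truths.append(truth)
            structures.append(structure)
            parts.append(_rand_dna(rng, chunks[i + 1]))
            pos += chunks[i + 1]
        genomes.append(SeqRecord(id=gid, seq="".join(parts)))

    tblout = emit_mock_tblout(truths, {g.id: len(g) for g in genomes}, cfg, rng,
                              partial_plan=partial_plan)
    domtblout = emit_mock_domtblout(truths)
    return Bundle(
        config=cfg,
        genomes=genomes,
        homologs=homologs,
        structures=structures,
        truths=truths,
        tblout=tblout,
        domtblout=domtblout,
    )


def _intron_to_forward(truth: PlantedTruth, lo: int, hi: int) -> tuple[int, int]:
    """Map an intron-sense interval to forward-strand genome coordinates."""
    if truth.strand == "+":
        return truth.start + lo, truth.start + hi
    return truth.end - hi, truth.end - lo


def _tbl_row(
    target: str, model: str, accession: str, fwd_lo: int, fwd_hi: int,
    strand: str, evalue: float, score: float,
) -> str:
    frm, to = (fwd_lo + 1, fwd_hi) if strand == "+" else (fwd_hi, fwd_lo + 1)
    return (
        f"{target} - {model} {accession} cm 1 100 {frm} {to} {strand} no 1 "
        f"0.45 0.0 {score:.1f} {evalue:.3g} ! -"
    )


def emit_mock_tblout(
    truths: Sequence[PlantedTruth],
    genome_lengths: dict[str, int],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    partial_plan: Optional[Sequence[Optional[str]]] = None,
) -> str:
    """Render a cmsearch-style hit table for the planted truths.

    Each intron yields a D1-D4 row over its D1..D4 interval and a D5/D6
    row over D5..D6, with endpoints jittered by up to ``hit_jitter`` nt
    and E-values log-uniform in [1e-12, 1e-3]; one of the two rows may
    be suppressed to exercise partial calls. Noise rows with E-values
    straddling the significance threshold are added per genome.
    """
    lines = [
        "#target name         accession query name           accession mdl mdl from   mdl to seq from   seq to strand trunc pass   gc  bias  score   E-value inc description of target",
        "#------------------- --------- -------------------- --------- --- -------- -------- -------- -------- ------ ----- ---- ---- ----- ------ --------- --- ---------------------",
    ]
    if partial_plan is not None and len(partial_plan) != len(truths):
        raise ValueError("partial_plan length must match number of truths")

    def jit() -> int:
        return int(rng.integers(-cfg.hit_jitter, cfg.hit_jitter + 1))

    def sig_evalue() -> float:
        return float(10 ** rng.uniform(-12, -3))

    for i, truth in enumerate(truths):
        glen = genome_lengths[truth.genome_id]
        if partial_plan is not None:
            suppress = partial_plan[i]
        elif rng.random() < cfg.p_partial_call:
            suppress = "d1d4" if rng.random() < 0.5 else "d5d6"
        else:
            suppress = None
        truth.suppressed_row = suppress

        d1 = truth.domain_intervals["D1"]
        d4 = truth.domain_intervals["D4"]
        d5 = truth.domain_intervals["D5"]
        d6 = truth.domain_intervals["D6"]
        if suppress != "d1d4":
            lo, hi = _intron_to_forward(truth, d1[0], d4[1])
            lo = min(max(lo + jit(), 0), glen - 2)
            hi = max(min(hi + jit(), glen), lo + 2)
            model = _D1D4_MODELS[int(rng.integers(len(_D1D4_MODELS)))]
            lines.append(
                _tbl_row(truth.genome_id, model, "-", lo, hi, truth.strand,
                         sig_evalue(), float(rng.uniform(40, 120)))
            )
        if suppress != "d5d6":
            lo, hi = _intron_to_forward(truth, d5[0], d6[1])
            lo = min(max(lo + jit(), 0), glen - 2)
            hi = max(min(hi + jit(), glen), lo + 2)
            lines.append(
                _tbl_row(truth.genome_id, _D5D6_MODEL, "RF00029", lo, hi,
                         truth.strand, sig_evalue(), float(rng.uniform(25, 80)))
            )

    e_lo, e_hi = cfg.noise_evalue_range
    for gid in sorted(genome_lengths):
        glen = genome_lengths[gid]
        for _ in range(cfg.noise_hits_per_genome):
            length = int(rng.integers(150, 400))
            lo = int(rng.integers(0, max(glen - length, 1)))
            strand = "+-"[int(rng.integers(2))]
            model = ([_D5D6_MODEL] + _D1D4_MODELS)[int(rng.integers(8))]
            acc = "RF00029" if model == _D5D6_MODEL else "-"
            ev = float(np.exp(rng.uniform(np.log(e_lo), np.log(e_hi))))
            lines.append(
                _tbl_row(gid, model, acc, lo, lo + length, strand, ev,
                         float(rng.uniform(5, 20)))
            )
    lines.append("#")
    return "\n".join(lines) + "\n"


_DOMAIN_SPECS = {
    "RVT": [
        ("RVT_1", "PF00078.33", 1e-30, (20, 270)),
        ("Intron_maturas2", "PF01348.25", 1e-10, (290, 390)),
    ],
    "HEG": [("Vsr", "PF03852.18", 1e-08, (100, 195))],
    "none": [],
}


def emit_mock_domtblout(truths: Sequence[PlantedTruth]) -> str:
    """Render an hmmscan-style per-domain table for the planted ORFs."""
    lines = [
        "#                                                                                  --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name             accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
        "#------------------- ----------  ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------",
    ]
    for truth in truths:
        specs = _DOMAIN_SPECS[truth.iep_class]
        if not specs or truth.orf_protein is None:
            continue
        qlen = len(truth.orf_protein)
        qname = f"{truth.intron_id}|orf"
        n = len(specs)
        for k, (name, acc, iev, (lo, hi)) in enumerate(specs, start=1):
            hi = min(hi, qlen)
            lines.append(
                f"{name} {acc} {hi - lo + 10} {qname} - {qlen} {iev:.1g} 150.0 0.1 "
                f"{k} {n} {iev:.1g} {iev:.1g} 148.0 0.1 5 {hi - lo + 5} {lo} {hi} "
                f"{max(lo - 3, 1)} {min(hi + 3, qlen)} 0.98 -"
            )
    lines.append("#")
    return "\n".join(lines) + "\n"


_TRUTH_COLUMNS = [
    "genome_id", "intron_id", "start", "end", "strand", "subtype", "iep_class",
    "five_prime", "three_prime", "orf_aa_len", "homolog_id", "suppressed_row",
]


def write_truth(truths: Sequence[PlantedTruth]) -> str:
    """Truth table as TSV (1-based inclusive genome coordinates)."""
    lines = ["\t".join(_TRUTH_COLUMNS)]
    for t in truths:
        five, three = (t.start1, t.end1) if t.strand == "+" else (t.end1, t.start1)
        lines.append(
            "\t".join(
                str(x)
                for x in [
                    t.genome_id, t.intron_id, t.start1, t.end1, t.strand,
                    t.subtype, t.iep_class, five, three,
                    len(t.orf_protein) if t.orf_protein else 0,
                    t.homolog_id, t.suppressed_row or "none",
                ]
            )
        )
    return "\n".join(lines) + "\n"
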