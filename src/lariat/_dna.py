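"""Small DNA helpers shared across modules.

All matching is done in the DNA alphabet with T standing for U; wobble
pairing rules treat G:T as the DNA image of the RNA G:U pair.
"""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC nucleotide ambiguity codes -> regex character classes
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC degenerate motif (e.g. GWYRG) into a regex."""
    try:
        expanded = "".join(IUPAC[c] for c in pattern.upper())
    except KeyError as exc:  # pragma: no cover - config error path
        raise ValueError(f"not an IUPAC nucleotide code: {exc.args[0]!r}") from exc
    return re.compile(expanded)


def iupac_match(pattern: str, seq: str) -> bool:
    """True if seq matches the degenerate pattern exactly (full length)."""
    return len(seq) == len(pattern) and iupac_regex(pattern).fullmatch(seq) is not None


def is_wc(a: str, b: str) -> bool:
    """Watson-Crick pair between two bases of an antiparallel duplex."""
    return (a, b) in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


def is_wobble(a: str, b: str) -> bool:
    """G:T wobble pair (DNA alphabet image of the RNA G:U pair)."""
    return (a, b) in (("G", "T"), ("T", "G"))
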