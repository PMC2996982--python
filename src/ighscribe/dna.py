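"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import re

from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNRYKMSWacgtn", "TGCANYRMKSWtgcan")

#: IUPAC degenerate-base expansions used for motif matching (e.g. the VH
#: promoter octamer ATG(C/T)AAA(G/T) is written ``ATGYAAAK``)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
    "S": "CG", "W": "AT", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string (standard code, '*' for stops).

    Trailing bases that do not fill a codon are ignored.
    """
    usable = len(seq) - len(seq) % 3
    if usable == 0:
        return ""
    return str(Seq(seq[:usable]).translate())


def degenerate_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC degenerate DNA motif into a regex."""
    parts = []
    for base in pattern.upper():
        expansion = IUPAC.get(base)
        if expansion is None:
            raise ValueError(f"not an IUPAC nucleotide code: {base!r}")
        parts.append(expansion if len(expansion) == 1 else f"[{expansion}]")
    return re.compile("".join(parts))
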