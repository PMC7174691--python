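"""Nucleotide-string helpers.

Internally, duplex work is done on the RNA alphabet (ACGU); everything that
touches disk (FASTA, GTF-derived sequences) uses DNA (ACGT). The two
``to_rna``/``to_dna`` converters are the only sanctioned crossing points.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
RNA_ALPHABET = "ACGU"

_DNA_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_RNA_COMP = str.maketrans("ACGUacgu", "UGCAugca")


def validate_nt(seq: str, alphabet: str = "ACGTU") -> None:
    """Raise ``ValueError`` naming the first offending position."""
    allowed = set(alphabet.upper()) | set(alphabet.lower())
    for i, base in enumerate(seq):
        if base not in allowed:
            raise ValueError(
                f"invalid nucleotide {base!r} at position {i} "
                f"(allowed alphabet: {alphabet})"
            )


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n``."""
    if n < 0:
        raise ValueError("length must be non-negative")
    idx = rng.integers(0, 4, size=n)
    return "".join(DNA_ALPHABET[i] for i in idx)
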