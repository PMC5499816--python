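"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC nucleotide ambiguity classes.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (IUPAC codes allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_acgt(seq: str, what: str = "sequence") -> None:
    """Raise ValueError unless *seq* consists only of A/C/G/T."""
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")


def encode(seq: str) -> np.ndarray:
    """Map an A/C/G/T string to an int array (A=0 ... T=3)."""
    check_acgt(seq)
    return np.array([BASE_INDEX[b] for b in seq], dtype=np.intp)


def gc_background(gc_fraction: float) -> np.ndarray:
    """Mononucleotide frequencies (A,C,G,T order) for a given GC fraction."""
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return np.array([at, gc, gc, at])


def empirical_background(sequences) -> np.ndarray:
    """Empirical A/C/G/T frequencies of a collection of sequences."""
    counts = np.zeros(4)
    for seq in sequences:
        for b in seq:
            if b in BASE_INDEX:
                counts[BASE_INDEX[b]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no A/C/G/T characters in input sequences")
    return counts / total
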