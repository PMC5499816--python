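"""Multimerised CATAC enhancer constructs: assembly, element discovery and scoring.

The CATAC element is a 29-bp promoter motif whose best-conserved part is a
10-bp "core" at motif residues 8-17 (consensus ``TRCGCATACG``) followed, after
one spacer residue, by an E-box-like hexamer at residues 19-24 (consensus
``CRCGTG``; the canonical bHLH E-box is ``CACGTG``).  Reporter enhancers are
built from four tandem native elements ("4xCATAC") whose order and orientation
match their genomic arrangement.  This module reconstructs those enhancers
from annealed oligonucleotide sets, locates the elements on either strand,
tallies per-construct consensus matches, and applies the six-residue
transversion mutation used to disable an element.

Residue numbering throughout is 1-based within the 29-bp motif, so "residue 8"
is ``element_seq[7]``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .dna import IUPAC, check_acgt, revcomp

MOTIF_WIDTH = 29

CORE_CONSENSUS = "TRCGCATACG"
CORE_OFFSET = 8  # 1-based motif residue where the core starts
EBOX_CONSENSUS = "CRCGTG"
EBOX_OFFSET = 19
CANONICAL_EBOX = "CACGTG"

#: Motif residues carrying the disabling A<->T / C<->G transversions.
TRANSVERSION_POSITIONS = (8, 10, 14, 16, 21, 23)

_TRANSVERSION = str.maketrans("ATCG", "TAGC")


@dataclass(frozen=True)
class ConsensusPattern:
    """An IUPAC consensus anchored at a 1-based residue of the 29-bp motif."""

    name: str
    iupac: str
    offset: int

    def __post_init__(self):
        bad = set(self.iupac) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)}")
        if not 1 <= self.offset and self.offset + len(self.iupac) - 1 <= MOTIF_WIDTH:
            raise ValueError("pattern does not fit inside the 29-bp motif")

    @property
    def slice(self) -> slice:
        """0-based slice of the pattern's region within a 29-base element."""
        return slice(self.offset - 1, self.offset - 1 + len(self.iupac))


CORE = ConsensusPattern("core", CORE_CONSENSUS, CORE_OFFSET)
EBOX = ConsensusPattern("ebox", EBOX_CONSENSUS, EBOX_OFFSET)
CANONICAL = ConsensusPattern("canonical_ebox", CANONICAL_EBOX, EBOX_OFFSET)


@dataclass(frozen=True)
class ConstructElement:
    """One 29-base CATAC element, stored in motif orientation."""

    element_seq: str
    source: str = ""
    orientation_in_enhancer: str = "+"
    start_in_enhancer: int | None = None
    core_mismatches: int | None = None

    def __post_init__(self):
        if len(self.element_seq) != MOTIF_WIDTH:
            raise ValueError("element must be exactly 29 bases")
        check_acgt(self.element_seq, "element")
        if self.orientation_in_enhancer not in "+-":
            raise ValueError("orientation must be '+' or '-'")

    @property
    def core(self) -> str:
        return self.element_seq[CORE.slice]

    @property
    def ebox(self) -> str:
        return self.element_seq[EBOX.slice]


@dataclass
class ConstructScore:
    """Consensus-match tallies over the four elements of a 4xCATAC construct."""

    core_matches: int
    ebox_matches: int
    canonical_mismatches: int
    catac_ebox_mismatches: int
    n_elements: int = 4

    @property
    def core_total(self) -> int:
        return self.n_elements * len(CORE_CONSENSUS)

    @property
    def ebox_total(self) -> int:
        return self.n_elements * len(EBOX_CONSENSUS)

    @property
    def core_score(self) -> float:
        return self.core_matches / self.core_total

    @property
    def ebox_score(self) -> float:
        return self.ebox_matches / self.ebox_total


def iupac_mismatches(pattern: ConsensusPattern | str, subseq: str) -> int:
    """Number of positions of *subseq* outside the pattern's IUPAC classes."""
    pat = pattern.iupac if isinstance(pattern, ConsensusPattern) else pattern
    if len(pat) != len(subseq):
        raise ValueError("pattern and subsequence lengths differ")
    return sum(b not in IUPAC[p] for p, b in zip(pat, subseq))


def _overlap_merge(asm: str, oligo: str, min_overlap: int, max_error_rate: float):
    """Best suffix(asm)/prefix(candidate) overlap over both orientations.

    Exact overlaps are preferred; if none reaches *min_overlap*, an
    overlap-alignment DP tolerating mismatches and indels (printed oligo sets
    occasionally disagree with their partner strand by a residue) is used.
    Returns the merged top strand.
    """
    best = None  # (exact, overlap_len, merged)
    for cand in (oligo, revcomp(oligo)):
        limit = min(len(asm), len(cand))
        for k in range(limit, min_overlap - 1, -1):
            if asm[-k:] == cand[:k]:
                if best is None or k > best[1]:
                    best = (True, k, asm + cand[k:])
                break
    if best is not None:
        return best[2]
    # approximate overlap: align a prefix of cand against a suffix of asm
    for cand in (oligo, revcomp(oligo)):
        n, m = len(asm), len(cand)
        dist = np.zeros((n + 1, m + 1), dtype=int)
        dist[0, :] = np.arange(m + 1)  # the cand prefix must be fully aligned
        dist[:, 0] = 0  # the aligned region may start anywhere in asm
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                sub = dist[i - 1, j - 1] + (asm[i - 1] != cand[j - 1])
                dist[i, j] = min(sub, dist[i - 1, j] + 1, dist[i, j - 1] + 1)
        # best end of the aligned cand prefix at row n: reward long overlaps,
        # penalise edits so a clean shorter overlap beats a ragged longer one
        for j in range(min_overlap, m + 1):
            if dist[n, j] <= max(1, int(max_error_rate * j)):
                score = j - 3 * dist[n, j]
                if best is None or score > best[1]:
                    best = (False, score, asm + cand[j:])
    if best is None:
        raise ValueError(
            f"no complementary overlap of >= {min_overlap} bp between consecutive oligos"
        )
    return best[2]


def assemble_enhancer(
    oligos: list[str], min_overlap: int = 10, max_error_rate: float = 0.1
) -> str:
    """Reconstruct the top strand of an annealed-duplex enhancer.

    Consecutive oligos alternate strands in a typical duplex design; each next
    oligo is merged via its maximal complementary overlap with the growing
    assembly, trying both orientations and keeping the longer overlap.
    """
    if len(oligos) < 2:
        raise ValueError("need at least two oligos")
    cleaned = []
    for o in oligos:
        o = o.upper().replace(" ", "")
        check_acgt(o, "oligo")
        cleaned.append(o)
    asm = cleaned[0]
    for o in cleaned[1:]:
        asm = _overlap_merge(asm, o, min_overlap, max_error_rate)
    return asm


def find_elements(
    enhancer_seq: str,
    core: ConsensusPattern = CORE,
    max_core_mismatch: int = 2,
    resolve_overlaps: bool = True,
) -> list[ConstructElement]:
    """Locate 29-base CATAC elements on either strand of an enhancer.

    A window qualifies when its core region carries at most
    *max_core_mismatch* IUPAC mismatches.  Overlapping windows are resolved
    greedily by ascending mismatch count (ties: leftmost, '+' strand first),
    mirroring PWM-scan hit resolution.  Elements are returned in motif
    orientation, left to right along the forward strand.
    """
    seq = enhancer_seq.upper()
    check_acgt(seq, "enhancer")
    w = MOTIF_WIDTH
    candidates = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for i in range(len(s) - w + 1):
            window = s[i : i + w]
            mm = iupac_mismatches(core, window[core.slice])
            if mm <= max_core_mismatch:
                start = i if strand == "+" else len(seq) - (i + w)
                candidates.append((mm, start, strand, window))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    if resolve_overlaps:
        kept = []
        for c in candidates:
            if all(c[1] + w <= k[1] or c[1] >= k[1] + w for k in kept):
                kept.append(c)
        candidates = kept
    candidates.sort(key=lambda c: c[1])
    return [
        ConstructElement(
            element_seq=window,
            orientation_in_enhancer=strand,
            start_in_enhancer=start,
            core_mismatches=mm,
        )
        for mm, start, strand, window in candidates
    ]


def score_construct(elements: list[ConstructElement]) -> ConstructScore:
    """Tally core and E-box consensus matches over the four elements."""
    if len(elements) != 4:
        raise ValueError(f"a 4xCATAC construct has 4 elements, got {len(elements)}")
    core_mm = sum(iupac_mismatches(CORE, e.core) for e in elements)
    ebox_mm = sum(iupac_mismatches(EBOX, e.ebox) for e in elements)
    canon_mm = sum(iupac_mismatches(CANONICAL, e.ebox) for e in elements)
    return ConstructScore(
        core_matches=4 * len(CORE_CONSENSUS) - core_mm,
        ebox_matches=4 * len(EBOX_CONSENSUS) - ebox_mm,
        canonical_mismatches=canon_mm,
        catac_ebox_mismatches=ebox_mm,
    )


def apply_transversions(
    element: ConstructElement,
    positions: tuple[int, ...] = TRANSVERSION_POSITIONS,
) -> ConstructElement:
    """Swap A<->T / C<->G at the given 1-based motif residues."""
    seq = list(element.element_seq)
    for pos in positions:
        if not 1 <= pos <= MOTIF_WIDTH:
            raise ValueError(f"residue {pos} outside 1..{MOTIF_WIDTH}")
        seq[pos - 1] = seq[pos - 1].translate(_TRANSVERSION)
    return ConstructElement(
        element_seq="".join(seq),
        source=element.source,
        orientation_in_enhancer=element.orientation_in_enhancer,
        start_in_enhancer=element.start_in_enhancer,
    )


def load_printed_oligos() -> dict[str, list[str]]:
    """The published 4xCATAC oligo sets, keyed by construct name.

    Constructs: ``slob_wt``, ``slob_mt``, ``pdp1_wt``, ``pdp1_mt`` and
    ``pdp1_pse`` (Pdp1 elements carrying Slob-like E-boxes).  Each value is
    the ordered list of four synthetic oligos as published.
    """
    from Bio import SeqIO

    ref = importlib.resources.files("catackit") / "data" / "catac_oligos.fasta"
    sets: dict[str, list[str]] = {}
    with ref.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            name, idx = rec.id.split("|")
            sets.setdefault(name, []).append((int(idx), str(rec.seq)))
    return {k: [s for _, s in sorted(v)] for k, v in sets.items()}


def score_printed_constructs() -> dict[str, ConstructScore]:
    """Assemble and score every packaged wild-type/variant construct.

    Mutant constructs whose elements carry four core transversions fall below
    the element-discovery mismatch cap and are skipped (no 4-element set).
    """
    out = {}
    for name, oligos in load_printed_oligos().items():
        enhancer = assemble_enhancer(oligos)
        elements = find_elements(enhancer)
        if len(elements) == 4:
            out[name] = score_construct(elements)
    return out
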