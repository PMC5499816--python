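"""Probabilistic 29-bp motif model: PWM construction, EM refinement, scanning.

The motif is represented as a position probability matrix with an explicit
mononucleotide background.  Sequence windows are scored by the log-odds bit
score ``sum_i log2(p_i[b_i] / q[b_i])`` and genome/promoter scans report every
window exceeding a strict bit-score threshold (default 5 bits) on either
strand.  A ZOOPS-style (zero-or-one occurrence per sequence) expectation-
maximisation step refines a seed matrix against unaligned sequences, standing
in for single-motif hidden-Markov-model training.  Promoter-set enrichment of
motif hits is assessed with the one-sided hypergeometric tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .dna import BASES, check_acgt, encode, revcomp

UNIFORM = np.full(4, 0.25)

#: Bit-score threshold used for site calling throughout ("bit score > 5").
DEFAULT_THRESHOLD_BITS = 5.0


@dataclass
class MotifMatrix:
    """Position probability matrix over A/C/G/T with a background model.

    ``probs`` has shape (width, 4); rows sum to one.  ``background`` is the
    genome-wide nucleotide frequency vector used in log-odds scoring.
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    pseudocount: float = 0.0
    converged: bool = True

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("probs must have shape (width, 4) with width >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        if np.any(self.probs < 0) or np.any(self.background <= 0):
            raise ValueError("negative probabilities or non-positive background")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """Per-position log2 odds; -inf where a probability is exactly 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)

    def information_content(self) -> np.ndarray:
        """Per-position relative entropy (bits) versus the background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(
                self.probs > 0,
                self.probs * (np.log2(self.probs) - np.log2(self.background)),
                0.0,
            )
        return terms.sum(axis=1)


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence, on forward-strand 0-based coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    score_bits: float

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not math.isfinite(self.score_bits):
            raise ValueError("hit score must be finite")


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter interval (nominally 2.5 kb centred on the TSS)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    clipped: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    set_size: int
    set_hits: int
    background_size: int
    background_hits: int
    fold: float
    p_value: float


def build_matrix(
    aligned_sites: list[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> MotifMatrix:
    """Estimate a probability matrix from aligned, equal-length sites.

    Laplace-style smoothing distributes *pseudocount* total weight according
    to the background: ``p[i][b] = (count + pc * q[b]) / (n + pc)``.
    """
    if len(aligned_sites) < 2:
        raise ValueError("need at least two aligned sites")
    width = len(aligned_sites[0])
    if any(len(s) != width for s in aligned_sites):
        raise ValueError("aligned sites must all have the same length")
    q = UNIFORM.copy() if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((width, 4))
    for site in aligned_sites:
        counts[np.arange(width), encode(site.upper())] += 1
    probs = (counts + pseudocount * q) / (len(aligned_sites) + pseudocount)
    return MotifMatrix(probs=probs, background=q, pseudocount=pseudocount)


def bit_score(matrix: MotifMatrix, subseq: str) -> float:
    """Log-odds score (bits) of one window of length ``matrix.width``."""
    if len(subseq) != matrix.width:
        raise ValueError(f"subsequence must have length {matrix.width}")
    idx = encode(subseq.upper())
    return float(matrix.log_odds()[np.arange(matrix.width), idx].sum())


def _window_scores(lo: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Bit scores of all windows of an encoded sequence (vectorised)."""
    w = lo.shape[0]
    n = idx.size - w + 1
    if n <= 0:
        return np.empty(0)
    per_pos = lo[np.arange(w)[:, None], idx[np.arange(w)[:, None] + np.arange(n)]]
    return per_pos.sum(axis=0)


def scan(
    matrix: MotifMatrix,
    sequences: dict[str, str] | list[tuple[str, str]],
    threshold_bits: float = DEFAULT_THRESHOLD_BITS,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All windows scoring strictly above *threshold_bits* on either strand.

    Coordinates are reported on the forward strand, 0-based half-open.
    Overlapping hits on the same strand are resolved greedily by descending
    score (ties: leftmost).  Sequences shorter than the motif are skipped.
    """
    items = sequences.items() if isinstance(sequences, dict) else sequences
    if not items:
        raise ValueError("no sequences to scan")
    lo = matrix.log_odds()
    w = matrix.width
    hits: list[MotifHit] = []
    for seq_id, seq in items:
        seq = seq.upper()
        if len(seq) < w:
            import warnings

            warnings.warn(f"sequence {seq_id!r} shorter than motif; skipped")
            continue
        candidates = []
        strands = "+-" if both_strands else "+"
        for strand in strands:
            s = seq if strand == "+" else revcomp(seq)
            scores = _window_scores(lo, encode(s))
            for i in np.nonzero(scores > threshold_bits)[0]:
                start = int(i) if strand == "+" else len(seq) - (int(i) + w)
                candidates.append((float(scores[i]), start, strand))
        kept: dict[str, list[tuple[float, int, str]]] = {"+": [], "-": []}
        for c in sorted(candidates, key=lambda c: (-c[0], c[1])):
            same = kept[c[2]]
            if all(c[1] + w <= k[1] or c[1] >= k[1] + w for k in same):
                same.append(c)
        for strand in strands:
            for score, start, st in kept[strand]:
                hits.append(MotifHit(seq_id, start, start + w, st, score))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def refine_matrix(
    seed: MotifMatrix,
    sequences: list[str],
    max_iter: int = 100,
    tol: float = 1e-6,
    gamma: float = 0.5,
) -> MotifMatrix:
    """ZOOPS expectation-maximisation refinement of a seed matrix.

    Each sequence is modelled as containing either exactly one motif
    occurrence (prior probability *gamma*, placed uniformly) or none, with all
    remaining bases drawn from the background.  The per-iteration data
    log-likelihood is non-decreasing; iteration stops when its improvement
    falls below *tol* or after *max_iter* rounds (``converged=False`` then
    flags the returned matrix).
    """
    w = seed.width
    encoded = [encode(s.upper()) for s in sequences if len(s) >= w]
    if not encoded:
        raise ValueError("no sequence is at least as long as the motif")
    q = seed.background
    probs = np.clip(seed.probs, 1e-9, None)
    probs = probs / probs.sum(axis=1, keepdims=True)
    pc = seed.pseudocount if seed.pseudocount > 0 else 0.5
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        post, ll, gamma_new = _zoops_estep(probs, q, gamma, encoded)
        counts = np.zeros((w, 4))
        for idx, resp in zip(encoded, post):
            for j, r in enumerate(resp):
                counts[np.arange(w), idx[j : j + w]] += r
        total = counts.sum(axis=1, keepdims=True)
        probs = (counts + pc * q) / (total + pc)
        gamma = min(max(gamma_new, 1e-6), 1 - 1e-6)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
    return MotifMatrix(
        probs=probs, background=q, pseudocount=pc, converged=converged
    )


def _zoops_estep(probs, q, gamma, encoded):
    """Posterior placement responsibilities, log-likelihood, updated gamma."""
    w = probs.shape[0]
    log_p = np.log(probs)
    log_q = np.log(q)
    posts = []
    ll = 0.0
    occ_total = 0.0
    for idx in encoded:
        n = idx.size - w + 1
        bg_ll = log_q[idx].sum()
        # log-likelihood of placement at j, background elsewhere
        ratios = np.array(
            [log_p[np.arange(w), idx[j : j + w]].sum() - log_q[idx[j : j + w]].sum() for j in range(n)]
        )
        place = np.log(gamma / n) + bg_ll + ratios
        none = math.log(1 - gamma) + bg_ll
        all_log = np.concatenate([place, [none]])
        m = all_log.max()
        lse = m + math.log(np.exp(all_log - m).sum())
        resp = np.exp(place - lse)
        posts.append(resp)
        ll += lse
        occ_total += resp.sum()
    return posts, ll, occ_total / len(encoded)


def zoops_posteriors(
    matrix: MotifMatrix, sequences: list[str], gamma: float = 0.5
) -> list[np.ndarray]:
    """Posterior probability of a motif occurrence at each placement.

    Under the ZOOPS model used by :func:`refine_matrix`; entry ``j`` of the
    array for a sequence is P(occurrence starts at j | sequence); the
    remainder to 1 is the posterior of no occurrence.
    """
    encoded = [encode(s.upper()) for s in sequences]
    probs = np.clip(matrix.probs, 1e-12, None)
    probs = probs / probs.sum(axis=1, keepdims=True)
    post, _, _ = _zoops_estep(probs, matrix.background, gamma, encoded)
    return post


def zoops_log_likelihood(
    matrix: MotifMatrix, sequences: list[str], gamma: float = 0.5
) -> float:
    """Data log-likelihood of sequences under the ZOOPS model."""
    encoded = [encode(s.upper()) for s in sequences]
    probs = np.clip(matrix.probs, 1e-12, None)
    probs = probs / probs.sum(axis=1, keepdims=True)
    _, ll, _ = _zoops_estep(probs, matrix.background, gamma, encoded)
    return ll


def assign_hits_to_genes(
    hits: list[MotifHit], windows: list[PromoterWindow]
) -> dict[str, int]:
    """Count hits overlapping each gene's promoter window by >= 1 bp.

    Hits are matched on ``seq_id == chrom``; a hit overlapping two windows
    counts for both genes.
    """
    counts = {win.gene_id: 0 for win in windows}
    for hit in hits:
        for win in windows:
            if hit.seq_id == win.chrom and hit.start < win.end and hit.end > win.start:
                counts[win.gene_id] += 1
    return counts


def promoter_enrichment(
    hits: list[MotifHit] | dict[str, int],
    windows: list[PromoterWindow],
    gene_set: set[str],
) -> EnrichmentResult:
    """Hypergeometric enrichment of motif-bearing promoters in a gene set.

    The background universe is all genes with a promoter window; a gene
    "has the motif" when >= 1 hit overlaps its window.  ``p_value`` is the
    one-sided tail P(X >= set_hits).
    """
    if not gene_set:
        raise ValueError("empty gene set")
    per_gene = hits if isinstance(hits, dict) else assign_hits_to_genes(hits, windows)
    universe = [w.gene_id for w in windows]
    missing = set(gene_set) - set(universe)
    if missing:
        raise ValueError(f"gene set members without promoter windows: {sorted(missing)}")
    background_size = len(universe)
    background_hits = sum(per_gene.get(g, 0) > 0 for g in universe)
    set_size = len(gene_set)
    set_hits = sum(per_gene.get(g, 0) > 0 for g in gene_set)
    p = float(hypergeom.sf(set_hits - 1, background_size, background_hits, set_size))
    if background_hits == 0:
        fold = math.inf if set_hits > 0 else math.nan
    else:
        fold = (set_hits / set_size) / (background_hits / background_size)
    return EnrichmentResult(
        set_size=set_size,
        set_hits=set_hits,
        background_size=background_size,
        background_hits=background_hits,
        fold=fold,
        p_value=min(p, 1.0),
    )
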