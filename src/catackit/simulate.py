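"""Synthetic inputs for every pipeline stage, with stored ground truth.

Three generators emulate the data the analyses consume:

* per-fly luciferase traces: an exponentially settling baseline (fresh
  luciferin produces an initial excess of active luciferase), a circadian
  (~24 h) cosine, a phase-locked 12-h second harmonic, and Gaussian counting
  noise, sampled roughly hourly on a jittered grid;
* background promoter sequence with 29-bp motif instances planted at known
  coordinates and strands, drawn from a probability matrix;
* comparative-Ct qRT-PCR tables for a flat reference gene and a rhythmic
  target sampled at circadian timepoints with replicate noise.

Every generator is fully determined by the integer seed in its spec.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .dna import BASES, gc_background, revcomp
from .motif import MotifMatrix, bit_score


def _check_finite(spec) -> None:
    for key, value in asdict(spec).items():
        if isinstance(value, (int, float)) and not math.isfinite(value):
            raise ValueError(f"{key} must be finite")


@dataclass(frozen=True)
class TraceSimSpec:
    """Parameters of the bioluminescence-trace generator.

    The trend settles from ``baseline`` at t=0 onto a persistent plateau of
    ``plateau_fraction * baseline`` with e-folding time ``settle_tau`` (the
    initial excess reflects previously synthesised luciferase);
    ``jitter_fraction`` perturbs each sampling interval uniformly by up to
    that fraction; the 12-h component is the second harmonic locked to
    ``phase_24``.  An LD head of ``ld_head_h`` hours precedes release into
    constant darkness (DD).
    """

    n_flies: int = 20
    duration_h: float = 168.0
    sampling_interval_h: float = 1.0
    jitter_fraction: float = 0.2
    period_24: float = 24.0
    amp_24: float = 50.0
    phase_24: float = 4.0
    amp_12: float = 10.0
    baseline: float = 200.0
    settle_tau: float = 12.0
    plateau_fraction: float = 0.5
    noise_sd: float = 10.0
    ld_head_h: float = 12.0
    seed: int = 0

    def __post_init__(self):
        _check_finite(self)
        if self.duration_h <= 48:
            raise ValueError("duration_h must exceed 48 h")
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling_interval_h must be positive")
        if min(self.amp_24, self.amp_12, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        if self.n_flies < 1:
            raise ValueError("need at least one fly")


@dataclass(frozen=True)
class PromoterSimSpec:
    """Parameters of the planted-motif promoter generator."""

    n_seqs: int = 100
    seq_length_bp: int = 2500
    gc_fraction: float = 0.43
    motif: MotifMatrix | None = None
    inserts_per_seq: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must lie strictly between 0 and 1")
        if self.motif is not None and self.seq_length_bp < self.motif.width * self.inserts_per_seq:
            raise ValueError("sequence too short for the requested inserts")


@dataclass(frozen=True)
class CtSimSpec:
    """Parameters of the qRT-PCR Ct-table generator.

    The target's Ct dips (expression peaks) at ``peak_ct_hour``:
    ``ct(t) = target_mean_ct - rhythm_amplitude_ct * cos(2*pi*(t-peak)/24)``.
    """

    timepoints: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0)
    n_replicates: int = 4
    reference_mean_ct: float = 20.0
    target_mean_ct: float = 24.0
    rhythm_amplitude_ct: float = 1.0
    peak_ct_hour: float = 6.0
    replicate_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        _check_finite(self)
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per timepoint")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")


def simulate_traces(spec: TraceSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-fly luminescence traces plus their ground truth.

    Returns ``(traces, truth)``: a tidy frame with columns ``fly_id``,
    ``time_h``, ``counts``, ``regime`` and a per-fly record of the generating
    parameters.  Counts are floored at zero.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    truth_rows = []
    for fly in range(spec.n_flies):
        n_max = int(spec.duration_h / (spec.sampling_interval_h * (1 - spec.jitter_fraction))) + 2
        steps = spec.sampling_interval_h * (
            1 + spec.jitter_fraction * rng.uniform(-1, 1, size=n_max)
        )
        times = np.concatenate([[0.0], np.cumsum(steps)])
        times = times[times <= spec.duration_h]
        f = spec.plateau_fraction
        trend = spec.baseline * (f + (1 - f) * np.exp(-times / spec.settle_tau))
        phase = 2 * np.pi * (times - spec.phase_24) / spec.period_24
        signal = trend + spec.amp_24 * np.cos(phase) + spec.amp_12 * np.cos(2 * phase)
        noise = rng.normal(0.0, spec.noise_sd, size=times.size) if spec.noise_sd > 0 else 0.0
        counts = np.maximum(signal + noise, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": f"fly{fly:03d}",
                    "time_h": times,
                    "counts": counts,
                    "regime": np.where(times < spec.ld_head_h, "LD", "DD"),
                }
            )
        )
        truth_rows.append({"fly_id": f"fly{fly:03d}", **asdict(spec)})
    traces = pd.concat(frames, ignore_index=True)
    return traces, pd.DataFrame(truth_rows)


def simulate_promoters(
    spec: PromoterSimSpec, max_tries: int = 1000
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate background sequences with planted motif instances.

    Returns ``(sequences, truth_bed)`` where the truth frame holds BED6-style
    records (0-based half-open, strand, planted-site bit score).
    """
    rng = np.random.default_rng(spec.seed)
    bg = gc_background(spec.gc_fraction)
    sequences: dict[str, str] = {}
    rows = []
    motif = spec.motif
    for i in range(spec.n_seqs):
        seq_id = f"prom{i:04d}"
        seq = rng.choice(list(BASES), size=spec.seq_length_bp, p=bg)
        if motif is not None and spec.inserts_per_seq > 0:
            w = motif.width
            starts: list[int] = []
            for _ in range(spec.inserts_per_seq):
                for _try in range(max_tries):
                    s = int(rng.integers(0, spec.seq_length_bp - w + 1))
                    if all(s + w <= t or s >= t + w for t in starts):
                        starts.append(s)
                        break
                else:
                    raise ValueError("could not place inserts without overlap")
            for j, s in enumerate(starts):
                site = "".join(
                    BASES[rng.choice(4, p=motif.probs[k])] for k in range(w)
                )
                strand = "+" if rng.random() < 0.5 else "-"
                seq[s : s + w] = list(site if strand == "+" else revcomp(site))
                rows.append(
                    {
                        "chrom": seq_id,
                        "start": s,
                        "end": s + w,
                        "name": f"{seq_id}_site{j}",
                        "score": bit_score(motif, site),
                        "strand": strand,
                    }
                )
        sequences[seq_id] = "".join(seq)
    truth = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return sequences, truth


def simulate_ct_table(
    spec: CtSimSpec, target_gene: str = "target", reference_gene: str = "reference"
) -> pd.DataFrame:
    """Generate a long-format Ct table for a rhythmic target and flat reference."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for gene, mean_ct, amp in (
        (reference_gene, spec.reference_mean_ct, 0.0),
        (target_gene, spec.target_mean_ct, spec.rhythm_amplitude_ct),
    ):
        for t in spec.timepoints:
            centre = mean_ct - amp * math.cos(2 * math.pi * (t - spec.peak_ct_hour) / 24.0)
            noise = (
                rng.normal(0.0, spec.replicate_sd, size=spec.n_replicates)
                if spec.replicate_sd > 0
                else np.zeros(spec.n_replicates)
            )
            for rep in range(spec.n_replicates):
                rows.append(
                    {
                        "gene": gene,
                        "timepoint": t,
                        "replicate": rep,
                        "ct": centre + noise[rep],
                    }
                )
    return pd.DataFrame(rows)
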