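"""Readers and writers for the pipeline's standard text formats.

FASTA goes through Biopython; BED6 and the tidy trace/Ct tables are plain
CSV/TSV handled with pandas; motif matrices are serialised as MEME minimal
motif text so they can be exchanged with standard motif tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import MotifHit, MotifMatrix

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def hits_to_bed(hits: list[MotifHit]) -> pd.DataFrame:
    """BED6 frame from motif hits; score = bits x 100, rounded (BED integers)."""
    return pd.DataFrame(
        [
            {
                "chrom": h.seq_id,
                "start": h.start,
                "end": h.end,
                "name": f"{h.seq_id}:{h.start}-{h.end}({h.strand})",
                "score": int(round(h.score_bits * 100)),
                "strand": h.strand,
            }
            for h in hits
        ],
        columns=BED6_COLUMNS,
    )


def write_bed(bed: pd.DataFrame, path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)


def write_traces(traces: pd.DataFrame, path) -> None:
    traces.to_csv(path, index=False)


def read_traces(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"fly_id", "time_h", "counts"}
    if not required <= set(df.columns):
        raise ValueError(f"trace table must have columns {sorted(required)}")
    return df


def write_ct_table(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"gene", "timepoint", "replicate", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    return df


def motif_to_meme(matrix: MotifMatrix, name: str = "CATAC") -> str:
    """Serialise a matrix as MEME minimal motif format text."""
    bg = matrix.background
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        f"A {bg[0]:.6f} C {bg[1]:.6f} G {bg[2]:.6f} T {bg[3]:.6f}",
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {matrix.width} nsites= 20 E= 0",
    ]
    for row in matrix.probs:
        lines.append("  " + "  ".join(f"{p:.6f}" for p in row))
    lines.append("")
    return "\n".join(lines)


def write_meme(matrix: MotifMatrix, path, name: str = "CATAC") -> None:
    Path(path).write_text(motif_to_meme(matrix, name=name))


def read_meme(path_or_text) -> MotifMatrix:
    """Parse a MEME minimal motif file back into a MotifMatrix."""
    text = (
        path_or_text
        if "\n" in str(path_or_text)
        else Path(path_or_text).read_text()
    )
    lines = text.splitlines()
    background = np.full(4, 0.25)
    rows = []
    in_matrix = False
    for i, line in enumerate(lines):
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
        if line.startswith("letter-probability matrix"):
            in_matrix = True
            continue
        if in_matrix:
            parts = line.split()
            if len(parts) == 4:
                rows.append([float(p) for p in parts])
            elif rows:
                break
    if not rows:
        raise ValueError("no letter-probability matrix found")
    probs = np.array(rows)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return MotifMatrix(probs=probs, background=background / background.sum())
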