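"""FASTA / BED / TSV adapters (Biopython + pandas)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(path: str, name: str, sequence: str) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], path, "fasta")


def read_fasta(path: str) -> tuple[str, str]:
    """Read the first record of a FASTA file as (name, sequence)."""
    rec = next(SeqIO.parse(path, "fasta"))
    return rec.id, str(rec.seq).upper()


def write_bed(path: str, name: str, intervals: list[tuple[int, int]]) -> None:
    """Write 0-based half-open intervals as 3-column BED."""
    pd.DataFrame(
        {"chrom": name, "start": [s for s, _ in intervals], "end": [e for _, e in intervals]}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], comment="#")
    return [(int(s), int(e)) for s, e in zip(df["start"], df["end"])]


def target_mask(intervals: list[tuple[int, int]], length: int) -> np.ndarray:
    """Boolean membership mask over [0, length) for a set of intervals."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(s, 0):min(e, length)] = True
    return mask
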