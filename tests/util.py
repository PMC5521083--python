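"""Hand-construction helpers and brute-force oracles for the test suite.

The oracles deliberately avoid the library's vectorized machinery: SAM text is
parsed with plain string handling and tallies are nested python loops, so they
can serve as independent recounts.
"""

from __future__ import annotations

import numpy as np

from bgnoise import ReadSet
from bgnoise.seqs import encode

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def make_readset(reads, sample="t", rname="panel") -> ReadSet:
    """Build a ReadSet from dicts with keys:
    pair, mate, pos, seq (str), qual (int or list), rev/proper/clip optional.
    """
    n = len(reads)
    seq_parts, qual_parts = [], []
    for r in reads:
        seq_parts.append(encode(r["seq"]))
        q = r.get("qual", 37)
        qual_parts.append(np.full(len(r["seq"]), q, np.uint8) if np.isscalar(q)
                          else np.asarray(q, np.uint8))
    offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum([len(s) for s in seq_parts], out=offsets[1:])
    return ReadSet(
        pair_id=np.array([r["pair"] for r in reads], dtype=np.int64),
        mate=np.array([r["mate"] for r in reads], dtype=np.uint8),
        pos=np.array([r["pos"] for r in reads], dtype=np.int64),
        is_reverse=np.array([r.get("rev", False) for r in reads], dtype=bool),
        seq=np.concatenate(seq_parts) if seq_parts else np.empty(0, np.uint8),
        qual=np.concatenate(qual_parts) if qual_parts else np.empty(0, np.uint8),
        offsets=offsets,
        is_proper=np.array([r.get("proper", True) for r in reads], dtype=bool),
        is_unmapped=np.array([r.get("unmapped", False) for r in reads], dtype=bool),
        has_clip=np.array([r.get("clip", False) for r in reads], dtype=bool),
        rname=rname,
        sample=sample,
    )


def parse_sam_text(path):
    """Minimal independent SAM text parser (M-only CIGARs)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            out.append({
                "qname": f[0],
                "flag": flag,
                "rev": bool(flag & 0x10),
                "read1": bool(flag & 0x40),
                "pos": int(f[3]) - 1,
                "cigar": f[5],
                "seq": f[9],
                "qual": [ord(c) - 33 for c in f[10]],
            })
    return out


def naive_pileup(sam_path, refseq, targets, qmin):
    """Brute-force recount: {(pos, base): count} and covered position set."""
    in_target = set()
    for s, e in targets:
        in_target.update(range(s, e))
    counts: dict[tuple[int, str], int] = {}
    covered = set()
    for r in parse_sam_text(sam_path):
        if "S" in r["cigar"] or "H" in r["cigar"] or "I" in r["cigar"] or "D" in r["cigar"]:
            continue
        for i, base in enumerate(r["seq"]):
            p = r["pos"] + i
            if p not in in_target:
                continue
            covered.add(p)
            if r["qual"][i] >= qmin:
                counts[(p, base)] = counts.get((p, base), 0) + 1
    return counts, covered


def naive_windows(sam_path, refseq, qmin, flank=50):
    """Brute-force fragment-mode break-point windows as strings ('.' = missing)."""
    L = len(refseq)
    wins = []
    for r in parse_sam_text(sam_path):
        rl = len(r["seq"])
        if not r["rev"]:
            a = r["pos"]
            if a - flank < 0 or a + flank + 1 > L:
                continue
            w = list(refseq[a - flank:a + flank])
            for i in range(min(rl, flank)):
                w[flank + i] = r["seq"][i] if r["qual"][i] >= qmin else "."
        else:
            a = r["pos"] + rl - 1
            if a - flank < 0 or a + flank + 1 > L:
                continue
            plus = list(refseq[a - flank + 1:a + flank + 1])
            for i in range(rl):
                p = r["pos"] + i
                j = p - (a - flank + 1)
                if 0 <= j < 2 * flank:
                    plus[j] = r["seq"][i] if r["qual"][i] >= qmin else "."
            w = [COMP.get(b, ".") for b in reversed(plus)]
        wins.append("".join(w))
    return wins


def naive_mono_counts(windows, flank=50):
    """{(slot, base): count} from window strings."""
    counts: dict[tuple[int, str], int] = {}
    for w in windows:
        for k, b in enumerate(w):
            if b in "ACGT":
                counts[(k, b)] = counts.get((k, b), 0) + 1
    return counts


def naive_di_counts(windows, flank=50):
    """{(distance, dinuc): count} from window strings."""
    counts: dict[tuple[int, str], int] = {}
    labels = list(range(-flank, 0)) + list(range(1, flank + 1))
    for w in windows:
        for k in range(len(w) - 1):
            d1, d2 = w[k], w[k + 1]
            if d1 not in "ACGT" or d2 not in "ACGT":
                continue
            la, lb = labels[k], labels[k + 1]
            dist = la if la >= 1 else (lb if lb <= -1 else 0)
            counts[(dist, d1 + d2)] = counts.get((dist, d1 + d2), 0) + 1
    return counts
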