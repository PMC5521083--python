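"""Fragment break-point analysis.

Acoustic shearing leaves two footprints at the cleavage site: a dinucleotide
cleavage preference (cuts 5' of A; CG > CA > TA ~ GA) visible in the sequence
composition around read 5' ends, and A>K (A>G / A>T) substitutions confined
to the first sequenced base.  This module extracts +/-50-base windows around
each read's 5' end, tallies mono- and dinucleotide composition by position,
and resolves substitution rates by distance from the read 5' end with
fold-change normalization against the 1-50 bp mean.

Window slots are labeled -50..-1, +1..+50 (no zero): +1 is the first read
base and -1 the reference base immediately 5' of it; "distance zero" for
dinucleotides is the bond straddling the break point.  In ``fragment`` mode,
windows from reverse-strand reads are reverse-complemented so +1 is always
the first sequenced base; ``plus_strand`` mode reports windows in reference
plus-strand orientation instead.  Read bases (quality-gated) fill the
positions the read covers; reference bases fill the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import seqs
from .background import BackgroundAlleleTable
from .reads import ReadSet
from .simulate import ReferenceBundle
from .profile import STRAND_CLASSES, _CODE

FLANK = 50


@dataclass
class EndWindows:
    """Oriented break-point windows; -1 codes mark no observation."""

    windows: np.ndarray   # (n, 2*FLANK) int8
    mode: str
    n_skipped_edge: int
    n_skipped_clipped: int = 0

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def labels(self) -> np.ndarray:
        f = self.windows.shape[1] // 2
        return np.r_[np.arange(-f, 0), np.arange(1, f + 1)]


def end_windows(records: ReadSet, ref: ReferenceBundle, mode: str = "fragment",
                qmin: int = 30, flank: int = FLANK) -> EndWindows:
    """Extract +/-``flank``-base windows around every read 5' end."""
    if mode not in ("fragment", "plus_strand"):
        raise ValueError("mode must be 'fragment' or 'plus_strand'")
    n_clip = int(np.count_nonzero(records.has_clip))
    if n_clip:  # clipped 5' ends do not mark true break points
        records = records.take(~records.has_clip)
    L = len(ref)
    lens = records.lengths
    anchor = np.where(records.is_reverse, records.end - 1, records.pos)
    ok = (anchor - flank >= 0) & (anchor + flank + 1 <= L)
    n_skip = int((~ok).sum())
    idx = np.flatnonzero(ok)

    wins = np.empty((len(idx), 2 * flank), dtype=np.int8)
    offs = records.offsets
    fwd_gather = np.arange(-flank, flank)       # positions a-flank .. a+flank-1
    rev_gather = np.arange(-flank + 1, flank + 1)  # positions a-flank+1 .. a+flank
    for row, r in enumerate(idx):
        a = int(anchor[r])
        rl = int(lens[r])
        rev = bool(records.is_reverse[r])
        if rev and mode == "fragment":
            vec = ref.codes[a + rev_gather].astype(np.int8)
            # read covers positions a-rl+1 .. a -> tail slots of the gather
            rseq = records.seq[offs[r]:offs[r] + rl].astype(np.int8)
            rq = records.qual[offs[r]:offs[r] + rl]
            span = min(rl, flank)
            sl = slice(flank - span, flank)
            vec[sl] = np.where(rq[rl - span:] >= qmin, rseq[rl - span:], -1)
            wins[row] = seqs.revcomp(vec)
        else:
            vec = ref.codes[a + fwd_gather].astype(np.int8)
            if rev:  # plus_strand mode: read covers a-rl+1 .. a
                rseq = records.seq[offs[r]:offs[r] + rl].astype(np.int8)
                rq = records.qual[offs[r]:offs[r] + rl]
                span = min(rl, flank + 1)
                sl = slice(flank - span + 1, flank + 1)
                vec[sl] = np.where(rq[rl - span:] >= qmin, rseq[rl - span:], -1)
            else:     # forward: read covers a .. a+rl-1 -> slots flank..
                rseq = records.seq[offs[r]:offs[r] + rl].astype(np.int8)
                rq = records.qual[offs[r]:offs[r] + rl]
                span = min(rl, flank)
                sl = slice(flank, flank + span)
                vec[sl] = np.where(rq[:span] >= qmin, rseq[:span], -1)
            wins[row] = vec
    return EndWindows(windows=wins, mode=mode, n_skipped_edge=n_skip,
                      n_skipped_clipped=n_clip)


def mono_frequencies(windows: EndWindows) -> pd.DataFrame:
    """Per-position base proportions over counted (observed) bases."""
    w = windows.windows
    n_pos = w.shape[1]
    counts = np.zeros((n_pos, 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (w == b).sum(axis=0)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freq = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
    return pd.DataFrame(freq, index=pd.Index(windows.labels, name="position"),
                        columns=list(seqs.BASES))


def di_frequencies(windows: EndWindows) -> pd.DataFrame:
    """Distance-indexed dinucleotide proportions.

    Distance 0 is the bond straddling the break point (slots -1, +1);
    positive distances sit inside the fragment, negative outside.
    """
    w = windows.windows
    n_pos = w.shape[1]
    flank = n_pos // 2
    first = w[:, :-1]
    second = w[:, 1:]
    valid = (first >= 0) & (second >= 0)
    key = first.astype(np.int64) * 4 + second.astype(np.int64)
    # bond k sits between slots k and k+1; distance counts nucleotides
    # between the bond and the break point, 0 straddling it
    labels = windows.labels
    dist = np.where(labels[:-1] >= 1, labels[:-1],
                    np.where(labels[1:] <= -1, labels[1:], 0))
    counts = np.zeros((n_pos - 1, 16), dtype=np.int64)
    for d in range(16):
        counts[:, d] = ((key == d) & valid).sum(axis=0)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freq = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
    return pd.DataFrame(freq, index=pd.Index(dist, name="distance"),
                        columns=seqs.DINUCS)


def fold_changes(rates: pd.DataFrame) -> pd.DataFrame:
    """Normalize each class's positional rates by its mean over all positions."""
    return rates.div(rates.mean(axis=1), axis=0)


@dataclass
class PositionalRates:
    rates: pd.DataFrame        # class x position (1..max_pos) rate
    fold_change: pd.DataFrame  # rates / per-class mean over 1..max_pos
    numerators: pd.DataFrame
    denominators: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Quartiles of the 1..N fold-change distribution, with FC(1), FC(2)."""
        fc = self.fold_change
        return pd.DataFrame({
            "q1": fc.quantile(0.25, axis=1),
            "median": fc.quantile(0.5, axis=1),
            "q3": fc.quantile(0.75, axis=1),
            "fc_1": fc[1],
            "fc_2": fc[2],
        })


def positional_rates(records: ReadSet, table: BackgroundAlleleTable,
                     ref: ReferenceBundle, qmin: int = 30,
                     max_pos: int = 50) -> PositionalRates:
    """Read-position-resolved class rates from R1 reads.

    Classes are taken in read orientation (reverse-strand reads complemented)
    so break-point phenomena align at position 1; only R1 is used because its
    initial cycles carry higher base quality than R2's.
    """
    r1 = records.take(records.mate == 1)
    pos = r1.base_positions()
    ridx = r1.base_read_index()
    lens = r1.lengths
    off_in_read = np.arange(len(pos), dtype=np.int64) - r1.offsets[:-1][ridx]
    dist5 = np.where(r1.is_reverse[ridx], lens[ridx] - off_in_read, off_in_read + 1)

    keep = (dist5 >= 1) & (dist5 <= max_pos) & (r1.qual >= qmin)
    pos, dist5 = pos[keep], dist5[keep]
    base = r1.seq[keep]
    rev = r1.is_reverse[ridx[keep]]
    refc = ref.codes[pos]

    comp = seqs.COMP
    o_ref = np.where(rev, comp[refc.astype(np.intp)], refc)
    o_base = np.where(rev, comp[base.astype(np.intp)], base)
    bg_mask = table.background_mask()

    num = np.zeros((12, max_pos + 1), dtype=np.int64)
    den = np.zeros((12, max_pos + 1), dtype=np.int64)
    for k, cls in enumerate(STRAND_CLASSES):
        x, y = _CODE[cls[0]], _CODE[cls[2]]
        # plus-projected alt of the read-oriented class at these bases
        alt_plus = np.where(rev, comp[y], y)
        elig = (o_ref == x) & bg_mask[pos, alt_plus]
        den[k] += np.bincount(dist5[elig], minlength=max_pos + 1)
        hit = elig & (o_base == y)
        num[k] += np.bincount(dist5[hit], minlength=max_pos + 1)

    cols = np.arange(1, max_pos + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(den[:, 1:] > 0, num[:, 1:] / np.maximum(den[:, 1:], 1), np.nan)
    rates = pd.DataFrame(rate, index=pd.Index(STRAND_CLASSES, name="class"), columns=cols)
    fc = fold_changes(rates)
    return PositionalRates(
        rates=rates,
        fold_change=fc,
        numerators=pd.DataFrame(num[:, 1:], index=rates.index, columns=cols),
        denominators=pd.DataFrame(den[:, 1:], index=rates.index, columns=cols),
    )
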