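"""Read filtering and quality-aware per-site allele counting.

The pileup is the substrate for every downstream rate: per target position it
counts bases with Phred quality >= ``qmin`` (default 30, chosen at the trough
of the biphasic quality distribution), after removal of PCR duplicates,
non-proper pairs and clipped reads.  Mate-overlap bases are counted twice
here; the overlap module analyzes them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io, seqs
from .reads import ReadSet
from .simulate import ReferenceBundle


@dataclass
class FilterThresholds:
    """Filtering and classification thresholds.

    Defaults follow deep-panel practice: Q>=30 bases, >500x paired depth,
    <5% germline gate, and a 250x / 2.5% tumor-biopsy (FNA) gate.
    """

    qmin: int = 30
    min_depth_pair: int = 500
    germline_af: float = 0.05
    fna_min_depth: int = 250
    fna_max_af: float = 0.025
    exclude_clipped: bool = True
    dedup: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.germline_af <= 1 and 0 <= self.fna_max_af <= 1):
            raise ValueError("allele-frequency thresholds must be in [0, 1]")
        if self.min_depth_pair < 0 or self.fna_min_depth < 0 or self.qmin < 0:
            raise ValueError("depth and quality thresholds must be >= 0")


@dataclass
class FilterResult:
    reads: ReadSet
    removed: dict[str, int]


def filter_reads(records: ReadSet, thresholds: FilterThresholds) -> FilterResult:
    """Remove unusable reads and PCR duplicates.

    Duplicates are defined at the fragment level by the (start, end,
    orientation) key; the pair with the highest summed base quality survives,
    ties broken by coordinate order.  Removal counts are reported per reason
    (in reads).
    """
    rs = records
    removed: dict[str, int] = {}

    keep = ~rs.is_unmapped
    removed["unmapped"] = int((~keep).sum())
    rs = rs.take(keep)

    keep = rs.is_proper
    removed["improper"] = int((~keep).sum())
    rs = rs.take(keep)

    if thresholds.exclude_clipped:
        keep = ~rs.has_clip
        removed["clipped"] = int((~keep).sum())
        rs = rs.take(keep)

    pt = rs.pair_table()
    paired = np.zeros(len(rs), dtype=bool)
    paired[pt["r1"]] = True
    paired[pt["r2"]] = True
    removed["broken_pair"] = int((~paired).sum())

    if not thresholds.dedup:
        rs = rs.take(paired)
        removed["duplicate"] = 0
        return FilterResult(rs, removed)

    r1, r2 = pt["r1"], pt["r2"]
    ends = rs.end
    frag_start = np.minimum(rs.pos[r1], rs.pos[r2])
    frag_end = np.maximum(ends[r1], ends[r2])
    orient = rs.is_reverse[r1]
    # summed base quality per pair
    qsum = np.zeros(len(rs), dtype=np.int64)
    np.add.at(qsum, rs.base_read_index(), rs.qual.astype(np.int64))
    pair_q = qsum[r1] + qsum[r2]

    df = pd.DataFrame({
        "fs": frag_start, "fe": frag_end, "orient": orient,
        "q": pair_q, "first_read": np.minimum(r1, r2),
        "i": np.arange(len(r1)),
    })
    # best quality first; among ties, first in the (coordinate-sorted) input
    df = df.sort_values(["fs", "fe", "orient", "q", "first_read"],
                        ascending=[True, True, True, False, True], kind="mergesort")
    best = df.drop_duplicates(["fs", "fe", "orient"], keep="first")["i"].to_numpy()
    removed["duplicate"] = 2 * (len(r1) - len(best))

    keep_idx = np.sort(np.concatenate([r1[best], r2[best]]))
    return FilterResult(rs.take(keep_idx), removed)


@dataclass
class SiteAlleleCounts:
    """Quality-filtered allele counts over covered target positions.

    ``counts[i, b]`` is the number of bases of code ``b`` with quality >=
    ``qmin`` at ``positions[i]``; ``highq_depth`` is their row sum.  The
    source ReadSet is retained so downstream modules can revisit per-read
    detail (mate, strand, distance from the read 5' end).
    """

    positions: np.ndarray        # int64, sorted covered target positions
    ref_codes: np.ndarray        # uint8
    counts: np.ndarray           # (n, 4) int64
    thresholds: FilterThresholds
    rname: str = ""
    source: ReadSet | None = field(default=None, repr=False)

    @property
    def highq_depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(seqs.BASES))
        df.insert(0, "ref", np.array(list(seqs.BASES))[self.ref_codes.astype(np.intp)])
        df.insert(0, "pos", self.positions)
        df["depth"] = self.highq_depth
        return df

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_pileup(records: ReadSet, ref: ReferenceBundle,
                 targets: list[tuple[int, int]] | None = None,
                 thresholds: FilterThresholds | None = None) -> SiteAlleleCounts:
    """Count quality-filtered alleles per covered target position.

    Bases below ``qmin`` are excluded from counts and depth; a position enters
    the table if covered by at least one aligned base of any quality.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    if targets is None:
        targets = ref.targets
    if records.rname and ref.name and records.rname != ref.name:
        raise ValueError(
            f"contig mismatch: reads on {records.rname!r}, reference is {ref.name!r}"
        )
    L = len(ref)
    tmask = io.target_mask(targets, L)

    pos = records.base_positions()
    if len(pos) and (pos.min() < 0 or pos.max() >= L):
        raise ValueError("read bases fall outside the reference")
    in_t = tmask[pos]
    cov = np.bincount(pos[in_t], minlength=L)
    hq = in_t & (records.qual >= thresholds.qmin)
    key = pos[hq] * 4 + records.seq[hq]
    counts = np.bincount(key, minlength=4 * L).reshape(L, 4)

    covered = np.flatnonzero(cov > 0)
    return SiteAlleleCounts(
        positions=covered.astype(np.int64),
        ref_codes=ref.codes[covered],
        counts=counts[covered].astype(np.int64),
        thresholds=thresholds,
        rname=ref.name,
        source=records,
    )


def quality_histogram(records: ReadSet, ref: ReferenceBundle,
                      positions: np.ndarray | None = None,
                      max_q: int = 60) -> dict:
    """Quality-score distributions for total and non-reference bases.

    Returns histograms (index = Phred score) for all bases and for bases that
    disagree with the reference, a per-called-base breakdown of the
    non-reference histogram, and the mean quality by distance from the read
    5' end.  ``positions`` optionally restricts the tally to a set of
    reference positions (e.g. background-eligible sites).
    """
    pos = records.base_positions()
    qual = records.qual.astype(np.int64)
    base = records.seq
    refc = ref.codes[pos]

    sel = np.ones(len(pos), dtype=bool)
    if positions is not None:
        inset = np.zeros(len(ref), dtype=bool)
        inset[np.asarray(positions)] = True
        sel = inset[pos]

    nonref = sel & (base != refc)
    out = {
        "total": np.bincount(qual[sel], minlength=max_q + 1),
        "nonref": np.bincount(qual[nonref], minlength=max_q + 1),
        "nonref_by_base": {
            b: np.bincount(qual[nonref & (base == i)], minlength=max_q + 1)
            for i, b in enumerate(seqs.BASES)
        },
    }

    # distance of each base from its read's 5' end (1-based)
    lens = records.lengths
    ridx = records.base_read_index()
    off_in_read = np.arange(len(pos), dtype=np.int64) - records.offsets[:-1][ridx]
    dist5 = np.where(records.is_reverse[ridx], lens[ridx] - off_in_read, off_in_read + 1)
    max_d = int(lens.max()) if len(lens) else 0
    sums = np.bincount(dist5[sel], weights=qual[sel], minlength=max_d + 1)
    ns = np.bincount(dist5[sel], minlength=max_d + 1)
    with np.errstate(invalid="ignore"):
        mean_q = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    out["mean_q_by_position"] = pd.Series(mean_q[1:], index=np.arange(1, max_d + 1),
                                          name="mean_q")
    return out
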