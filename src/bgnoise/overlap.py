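"""Mate-overlap consistency of high-quality errors.

An error present in the library molecule (oxidation, capture damage, template
damage) is read out identically by reads 1 and 2 where they overlap, whereas
a sequencing-run miscall almost never recurs in the mate.  The fraction of
overlap errors inconsistent between mates therefore estimates the share of
post-filter errors attributable to the sequencing run itself.

A site is scored only when both mate bases pass the quality gate; a
high-quality alt facing a low-quality partner base is excluded rather than
counted inconsistent, to avoid conflating quality censoring with discordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .background import BackgroundAlleleTable
from .reads import ReadSet
from .simulate import ReferenceBundle


@dataclass
class OverlapStats:
    n_pairs: int
    n_overlap_bases: int
    n_error_sites: int
    n_consistent: int
    n_inconsistent: int

    @property
    def fraction_inconsistent(self) -> float:
        if self.n_error_sites == 0:
            return float("nan")
        return self.n_inconsistent / self.n_error_sites

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_pairs": self.n_pairs,
            "n_overlap_bases": self.n_overlap_bases,
            "n_error_sites": self.n_error_sites,
            "n_consistent": self.n_consistent,
            "n_inconsistent": self.n_inconsistent,
            "fraction_inconsistent": self.fraction_inconsistent,
        }])


def find_overlaps(records: ReadSet) -> pd.DataFrame:
    """Per complete pair, the reference interval covered by both mates.

    ``start >= end`` marks disjoint mates (empty overlap).
    """
    pt = records.pair_table()
    ends = records.end
    start = np.maximum(records.pos[pt["r1"]], records.pos[pt["r2"]])
    end = np.minimum(ends[pt["r1"]], ends[pt["r2"]])
    return pd.DataFrame({"pair_id": pt["pair_id"], "r1": pt["r1"], "r2": pt["r2"],
                         "start": start, "end": end,
                         "length": np.maximum(end - start, 0)})


def consistency_fractions(records: ReadSet, table: BackgroundAlleleTable,
                          ref: ReferenceBundle, qmin: int = 30) -> OverlapStats:
    """Classify overlap error sites as mate-consistent or -inconsistent.

    Scored sites are overlap positions where at least one mate shows a
    background-category non-reference allele and both mate bases have quality
    >= ``qmin``; consistent means both mates show the same alternative base.
    """
    ov = find_overlaps(records)
    n_overlap = int(ov["length"].sum())
    bg_mask = table.background_mask()
    codes = ref.codes

    # candidate sites: any mismatch vs reference inside an overlap
    pos = records.base_positions()
    mism = records.seq != codes[pos]
    ridx = records.base_read_index()

    ov_start = np.full(len(records), -1, dtype=np.int64)
    ov_end = np.full(len(records), -1, dtype=np.int64)
    partner = np.full(len(records), -1, dtype=np.int64)
    for col_a, col_b in (("r1", "r2"), ("r2", "r1")):
        ov_start[ov[col_a]] = ov["start"]
        ov_end[ov[col_a]] = ov["end"]
        partner[ov[col_a]] = ov[col_b]

    in_ov = mism & (partner[ridx] >= 0) & (pos >= ov_start[ridx]) & (pos < ov_end[ridx])
    cand_read = ridx[in_ov]
    cand_pos = pos[in_ov]
    # one scored site per (pair, position) even if both mates mismatch
    pair_of = records.pair_id[cand_read]
    _, first = np.unique(np.stack([pair_of, cand_pos]), axis=1, return_index=True)

    n_cons = n_incons = 0
    offs = records.offsets
    for k in first:
        r = int(cand_read[k])
        p = int(cand_pos[k])
        m = int(partner[r])
        b1 = int(records.seq[offs[r] + (p - records.pos[r])])
        q1 = int(records.qual[offs[r] + (p - records.pos[r])])
        b2 = int(records.seq[offs[m] + (p - records.pos[m])])
        q2 = int(records.qual[offs[m] + (p - records.pos[m])])
        if q1 < qmin or q2 < qmin:
            continue
        rc = int(codes[p])
        bg1 = b1 != rc and bg_mask[p, b1]
        bg2 = b2 != rc and bg_mask[p, b2]
        if not (bg1 or bg2):
            continue
        if b1 == b2:
            n_cons += 1
        else:
            n_incons += 1
    return OverlapStats(
        n_pairs=len(ov),
        n_overlap_bases=n_overlap,
        n_error_sites=n_cons + n_incons,
        n_consistent=n_cons,
        n_inconsistent=n_incons,
    )
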