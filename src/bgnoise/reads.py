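"""Columnar container for aligned paired-end reads plus SAM import/export.

All downstream estimators are vectorized over a :class:`ReadSet`, which keeps
per-read metadata in flat numpy arrays and the base/quality payload in two
concatenated arrays indexed by ``offsets``.  Alignments are restricted to
ungapped (all-``M``) records, optionally with terminal clipping flagged via
``has_clip``; indels and chimeric alignments are out of scope and rejected on
import.

Coordinates are 0-based half-open internally; SAM output is 1-based per the
standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from . import seqs


class UnsupportedRecordError(ValueError):
    """Raised for alignments the container cannot represent (indels, etc.)."""


@dataclass
class ReadSet:
    pair_id: np.ndarray        # int64, shared by the two mates of a pair
    mate: np.ndarray           # uint8: 1 = read1, 2 = read2
    pos: np.ndarray            # int64, 0-based leftmost reference position
    is_reverse: np.ndarray     # bool
    seq: np.ndarray            # uint8 codes, concatenated (plus-strand SEQ)
    qual: np.ndarray           # uint8 Phred scores, concatenated
    offsets: np.ndarray        # int64, len n+1 into seq/qual
    is_proper: np.ndarray | None = None
    is_unmapped: np.ndarray | None = None
    has_clip: np.ndarray | None = None
    mapq: np.ndarray | None = None
    molecule_id: np.ndarray | None = None  # int64, -1 if unknown
    copy: np.ndarray | None = None         # int32 PCR-copy index, -1 if unknown
    rname: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        n = len(self.pos)
        if self.is_proper is None:
            self.is_proper = np.ones(n, dtype=bool)
        if self.is_unmapped is None:
            self.is_unmapped = np.zeros(n, dtype=bool)
        if self.has_clip is None:
            self.has_clip = np.zeros(n, dtype=bool)
        if self.mapq is None:
            self.mapq = np.full(n, 60, dtype=np.uint8)
        if self.molecule_id is None:
            self.molecule_id = np.full(n, -1, dtype=np.int64)
        if self.copy is None:
            self.copy = np.full(n, -1, dtype=np.int32)

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.offsets)

    @property
    def end(self) -> np.ndarray:
        """0-based exclusive reference end (ungapped alignments)."""
        return self.pos + self.lengths

    def read_seq(self, i: int) -> np.ndarray:
        return self.seq[self.offsets[i]:self.offsets[i + 1]]

    def read_qual(self, i: int) -> np.ndarray:
        return self.qual[self.offsets[i]:self.offsets[i + 1]]

    def base_positions(self) -> np.ndarray:
        """Reference position of every base in the concatenated payload."""
        lens = self.lengths
        total = int(self.offsets[-1])
        starts = np.repeat(self.pos - self.offsets[:-1], lens)
        return starts + np.arange(total, dtype=np.int64)

    def base_read_index(self) -> np.ndarray:
        """Read index of every base in the concatenated payload."""
        return np.repeat(np.arange(len(self), dtype=np.int64), self.lengths)

    def take(self, idx: np.ndarray) -> "ReadSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        lens = self.lengths[idx]
        new_off = np.zeros(len(idx) + 1, dtype=np.int64)
        np.cumsum(lens, out=new_off[1:])
        flat = (
            np.repeat(self.offsets[:-1][idx] - new_off[:-1], lens)
            + np.arange(int(new_off[-1]), dtype=np.int64)
        )
        return replace(
            self,
            pair_id=self.pair_id[idx],
            mate=self.mate[idx],
            pos=self.pos[idx],
            is_reverse=self.is_reverse[idx],
            seq=self.seq[flat],
            qual=self.qual[flat],
            offsets=new_off,
            is_proper=self.is_proper[idx],
            is_unmapped=self.is_unmapped[idx],
            has_clip=self.has_clip[idx],
            mapq=self.mapq[idx],
            molecule_id=self.molecule_id[idx],
            copy=self.copy[idx],
        )

    def sort_by_coordinate(self) -> "ReadSet":
        order = np.lexsort((self.mate, self.pair_id, self.pos))
        return self.take(order)

    # ---- pairing -------------------------------------------------------

    def pair_table(self) -> dict[str, np.ndarray]:
        """Indices of mate1/mate2 per complete pair (singletons dropped).

        Returns arrays ``r1``, ``r2`` (read indices) and ``pair_id``.
        """
        order = np.lexsort((self.mate, self.pair_id))
        pid = self.pair_id[order]
        mate = self.mate[order]
        # complete pairs: runs of length 2 with mates 1 and 2
        starts = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1]])
        counts = np.diff(np.r_[starts, len(pid)])
        good = starts[(counts == 2)]
        good = good[(mate[good] == 1) & (mate[good + 1] == 2)]
        return {
            "r1": order[good],
            "r2": order[good + 1],
            "pair_id": pid[good],
        }

    # ---- SAM I/O -------------------------------------------------------

    def qnames(self) -> list[str]:
        prefix = self.sample or "rp"
        mol = self.molecule_id
        cp = self.copy
        return [
            f"{prefix}-m{mol[i]}.{cp[i]}" if mol[i] >= 0 else f"{prefix}-p{self.pair_id[i]}"
            for i in range(len(self))
        ]

    def to_sam(self, path: str, ref_name: str, ref_length: int) -> None:
        """Write a coordinate-sorted SAM file (text) via pysam."""
        rs = self.sort_by_coordinate()
        names = rs.qnames()
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": ref_name, "LN": int(ref_length)}],
        }
        pt = rs.pair_table()
        mate_of = np.full(len(rs), -1, dtype=np.int64)
        mate_of[pt["r1"]] = pt["r2"]
        mate_of[pt["r2"]] = pt["r1"]
        ends = rs.end
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            for i in range(len(rs)):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = names[i]
                a.reference_id = 0
                a.reference_start = int(rs.pos[i])
                a.mapping_quality = int(rs.mapq[i])
                ln = int(rs.lengths[i])
                a.cigarstring = f"{ln}M"
                a.query_sequence = seqs.decode(rs.read_seq(i))
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in rs.read_qual(i))
                )
                flag = 0x1
                if rs.is_proper[i]:
                    flag |= 0x2
                if rs.is_reverse[i]:
                    flag |= 0x10
                j = mate_of[i]
                if j >= 0:
                    if rs.is_reverse[j]:
                        flag |= 0x20
                    a.next_reference_id = 0
                    a.next_reference_start = int(rs.pos[j])
                    frag_start = int(min(rs.pos[i], rs.pos[j]))
                    frag_end = int(max(ends[i], ends[j]))
                    tlen = frag_end - frag_start
                    a.template_length = tlen if rs.pos[i] <= rs.pos[j] else -tlen
                flag |= 0x40 if rs.mate[i] == 1 else 0x80
                a.flag = flag
                fh.write(a)

    @classmethod
    def from_sam(cls, path: str, sample: str = "") -> "ReadSet":
        """Load a single-contig SAM/BAM into a ReadSet.

        Terminal soft/hard clips are trimmed and flagged in ``has_clip``;
        any other non-``M`` CIGAR operation raises
        :class:`UnsupportedRecordError`.
        """
        pair_ids: dict[str, int] = {}
        pid_l, mate_l, pos_l, rev_l = [], [], [], []
        prop_l, unmap_l, clip_l, mapq_l, mol_l, cp_l = [], [], [], [], [], []
        seq_parts, qual_parts = [], []
        rname = ""
        with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                if not rec.is_paired:
                    raise UnsupportedRecordError(
                        f"unpaired record without mate information: {rec.query_name}"
                    )
                clip = False
                if not rec.is_unmapped:
                    if rname == "":
                        rname = rec.reference_name or ""
                    elif rec.reference_name != rname:
                        raise UnsupportedRecordError(
                            f"multiple contigs in input: {rname} vs {rec.reference_name}"
                        )
                    for op, _n in rec.cigartuples or []:
                        if op in (4, 5):
                            clip = True
                        elif op != 0:
                            raise UnsupportedRecordError(
                                f"unsupported CIGAR op {op} in {rec.query_name}"
                            )
                qname = rec.query_name or ""
                pid = pair_ids.setdefault(qname, len(pair_ids))
                mol, cp = -1, -1
                tail = qname.rsplit("-m", 1)
                if len(tail) == 2 and "." in tail[1]:
                    m, _, c = tail[1].partition(".")
                    if m.isdigit() and c.isdigit():
                        mol, cp = int(m), int(c)
                # aligned portion only (clips trimmed)
                qseq = rec.query_alignment_sequence or ""
                qq = rec.query_alignment_qualities
                pid_l.append(pid)
                mate_l.append(1 if rec.is_read1 else 2)
                pos_l.append(rec.reference_start if not rec.is_unmapped else -1)
                rev_l.append(rec.is_reverse)
                prop_l.append(rec.is_proper_pair)
                unmap_l.append(rec.is_unmapped)
                clip_l.append(clip)
                mapq_l.append(rec.mapping_quality)
                mol_l.append(mol)
                cp_l.append(cp)
                seq_parts.append(seqs.encode(qseq))
                qual_parts.append(
                    np.asarray(qq, dtype=np.uint8) if qq is not None
                    else np.zeros(len(qseq), dtype=np.uint8)
                )
        offsets = np.zeros(len(pid_l) + 1, dtype=np.int64)
        np.cumsum([len(s) for s in seq_parts], out=offsets[1:])
        return cls(
            pair_id=np.asarray(pid_l, dtype=np.int64),
            mate=np.asarray(mate_l, dtype=np.uint8),
            pos=np.asarray(pos_l, dtype=np.int64),
            is_reverse=np.asarray(rev_l, dtype=bool),
            seq=np.concatenate(seq_parts) if seq_parts else np.empty(0, np.uint8),
            qual=np.concatenate(qual_parts) if qual_parts else np.empty(0, np.uint8),
            offsets=offsets,
            is_proper=np.asarray(prop_l, dtype=bool),
            is_unmapped=np.asarray(unmap_l, dtype=bool),
            has_clip=np.asarray(clip_l, dtype=bool),
            mapq=np.asarray(mapq_l, dtype=np.uint8),
            molecule_id=np.asarray(mol_l, dtype=np.int64),
            copy=np.asarray(cp_l, dtype=np.int32),
            rname=rname,
            sample=sample,
        )


def concat(readsets: list[ReadSet]) -> ReadSet:
    """Concatenate ReadSets, re-keying pair ids to stay unique."""
    if not readsets:
        raise ValueError("nothing to concatenate")
    shift = 0
    pids = []
    for rs in readsets:
        pids.append(rs.pair_id + shift)
        shift += int(rs.pair_id.max(initial=-1)) + 1
    first = readsets[0]
    return replace(
        first,
        pair_id=np.concatenate(pids),
        mate=np.concatenate([r.mate for r in readsets]),
        pos=np.concatenate([r.pos for r in readsets]),
        is_reverse=np.concatenate([r.is_reverse for r in readsets]),
        seq=np.concatenate([r.seq for r in readsets]),
        qual=np.concatenate([r.qual for r in readsets]),
        offsets=np.concatenate(
            [first.offsets]
            + [r.offsets[1:] + off for r, off in zip(
                readsets[1:],
                np.cumsum([int(r.offsets[-1]) for r in readsets])[:-1],
            )]
        ),
        is_proper=np.concatenate([r.is_proper for r in readsets]),
        is_unmapped=np.concatenate([r.is_unmapped for r in readsets]),
        has_clip=np.concatenate([r.has_clip for r in readsets]),
        mapq=np.concatenate([r.mapq for r in readsets]),
        molecule_id=np.concatenate([r.molecule_id for r in readsets]),
        copy=np.concatenate([r.copy for r in readsets]),
    )
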