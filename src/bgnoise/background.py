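"""Background-allele classification for a matched plasma / PBL (/ FNA) set.

Every (site, alternative allele) combination at co-covered target positions is
assigned exactly one category:

* ``depth_excluded`` — paired depth below the gate in either sample, or (when
  a tumor biopsy is available) FNA depth below its own gate; excludes the
  whole position.
* ``germline`` — allele frequency at or above the germline gate in either
  paired sample; excludes that allele only.
* ``somatic_excluded`` — allele above the FNA frequency gate (a true tumor
  variant must not be counted as noise); excludes that allele only.
* ``background`` — everything else, including zero-count alleles, which
  define the error-free capacity of the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import seqs
from .pileup import FilterThresholds, SiteAlleleCounts

CATEGORIES = ("background", "germline", "somatic_excluded", "depth_excluded")


@dataclass
class BackgroundAlleleTable:
    """Per (position, alt) classification plus per-sample counts."""

    table: pd.DataFrame   # pos, ref, alt, category, {sample}_{count,depth,freq}
    samples: tuple[str, ...]
    ref_length: int

    def __len__(self) -> int:
        return len(self.table)

    def background(self) -> pd.DataFrame:
        return self.table[self.table["category"] == "background"]

    def background_mask(self) -> np.ndarray:
        """(ref_length, 4) boolean: is (pos, alt code) a background allele."""
        mask = np.zeros((self.ref_length, 4), dtype=bool)
        bg = self.background()
        code = {b: i for i, b in enumerate(seqs.BASES)}
        mask[bg["pos"].to_numpy(), [code[a] for a in bg["alt"]]] = True
        return mask

    def eligible_positions(self) -> np.ndarray:
        """Positions with at least one background-category allele."""
        bg = self.background()
        return np.unique(bg["pos"].to_numpy())

    def write_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _aligned_counts(pile: SiteAlleleCounts, positions: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Counts and depth of ``pile`` at ``positions`` (zero where uncovered)."""
    counts = np.zeros((len(positions), 4), dtype=np.int64)
    idx = np.searchsorted(pile.positions, positions)
    idx_ok = (idx < len(pile.positions))
    hit = np.zeros(len(positions), dtype=bool)
    hit[idx_ok] = pile.positions[idx[idx_ok]] == positions[idx_ok]
    counts[hit] = pile.counts[idx[hit]]
    return counts, counts.sum(axis=1)


def call_background(plasma: SiteAlleleCounts, pbl: SiteAlleleCounts,
                    fna: SiteAlleleCounts | None = None,
                    thresholds: FilterThresholds | None = None,
                    ref_length: int | None = None) -> BackgroundAlleleTable:
    """Classify all site/alt-allele pairs of a matched sample set."""
    if thresholds is None:
        thresholds = plasma.thresholds
    positions = np.intersect1d(plasma.positions, pbl.positions)
    if len(positions) == 0:
        raise ValueError("coordinate mismatch: plasma and PBL pileups share no site")
    ri = np.searchsorted(plasma.positions, positions)
    rj = np.searchsorted(pbl.positions, positions)
    refc = plasma.ref_codes[ri]
    if not np.array_equal(refc, pbl.ref_codes[rj]):
        raise ValueError("coordinate mismatch: reference bases disagree between pileups")

    pc, pdep = _aligned_counts(plasma, positions)
    bc, bdep = _aligned_counts(pbl, positions)
    samples = ["plasma", "pbl"]
    if fna is not None:
        fc, fdep = _aligned_counts(fna, positions)
        samples.append("fna")

    with np.errstate(invalid="ignore", divide="ignore"):
        pfreq = np.where(pdep[:, None] > 0, pc / np.maximum(pdep[:, None], 1), 0.0)
        bfreq = np.where(bdep[:, None] > 0, bc / np.maximum(bdep[:, None], 1), 0.0)
        if fna is not None:
            ffreq = np.where(fdep[:, None] > 0, fc / np.maximum(fdep[:, None], 1), 0.0)

    # position-level depth gate
    depth_bad = (pdep < thresholds.min_depth_pair) | (bdep < thresholds.min_depth_pair)
    if fna is not None:
        depth_bad |= fdep < thresholds.fna_min_depth

    n = len(positions)
    # three alternative alleles per site
    alt_codes = np.empty((n, 3), dtype=np.uint8)
    for b in range(4):
        rows = refc == b
        alt_codes[rows] = [c for c in range(4) if c != b]

    rows_pos = np.repeat(positions, 3)
    rows_ref = np.repeat(refc, 3)
    rows_alt = alt_codes.reshape(-1)
    flat = np.arange(n).repeat(3), rows_alt  # (site index, alt code) indexers

    cat = np.full(3 * n, "background", dtype=object)
    germ = (pfreq[flat] >= thresholds.germline_af) | (bfreq[flat] >= thresholds.germline_af)
    cat[germ] = "germline"
    if fna is not None:
        som = (~germ) & (ffreq[flat] > thresholds.fna_max_af)
        cat[som] = "somatic_excluded"
    cat[np.repeat(depth_bad, 3)] = "depth_excluded"

    bases = np.array(list(seqs.BASES))
    data = {
        "pos": rows_pos,
        "ref": bases[rows_ref.astype(np.intp)],
        "alt": bases[rows_alt.astype(np.intp)],
        "category": cat,
        "plasma_count": pc[flat], "plasma_depth": np.repeat(pdep, 3),
        "plasma_freq": pfreq[flat],
        "pbl_count": bc[flat], "pbl_depth": np.repeat(bdep, 3),
        "pbl_freq": bfreq[flat],
    }
    if fna is not None:
        data.update({"fna_count": fc[flat], "fna_depth": np.repeat(fdep, 3),
                     "fna_freq": ffreq[flat]})
    table = pd.DataFrame(data)
    L = ref_length if ref_length is not None else int(positions.max()) + 1
    return BackgroundAlleleTable(table=table, samples=tuple(samples), ref_length=L)


def snp_table(table: BackgroundAlleleTable) -> pd.DataFrame:
    """Paired allele frequencies of germline-category alleles (QC input)."""
    g = table.table[table.table["category"] == "germline"]
    return g[["pos", "ref", "alt", "plasma_freq", "pbl_freq"]].reset_index(drop=True)
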