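"""Substitution-class and context error rates, plus process attribution.

Rates are computed over background-eligible (position, allele) pairs only:
for a class X>Y the numerator is the quality-filtered count of Y bases at
positions with reference X where (position, Y) is background-category, and
the denominator is the quality-filtered depth summed over those positions.
The 12 strand-resolved classes collapse pairwise into 6 classes written in
the pyrimidine-centered convention (C:G>A:T etc.).

Attribution estimators:

* shear (fragmentation step): per collapsed class,
  shear_fraction = (r_PBL - r_plasma) / r_PBL and
  shear_increase = (r_PBL - r_plasma) / r_plasma, exploiting the fact that
  naturally fragmented plasma DNA never sees the shearing step.
* hybrid selection (strand-specific capture): per reciprocal strand pair,
  asymmetry = (f_excess - f_baseline) / f_excess, with the excess side fixed
  by the captured strand.

Cohort aggregation of per-sample statistics is mean +/- SD of the per-sample
values; pooled-count versions are also available where they differ.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import seqs
from .background import BackgroundAlleleTable
from .pileup import SiteAlleleCounts
from .simulate import ReferenceBundle

STRAND_CLASSES = [f"{x}>{y}" for x in seqs.BASES for y in seqs.BASES if x != y]

COLLAPSED_PAIRS: dict[str, tuple[str, str]] = {
    "C:G>A:T": ("C>A", "G>T"),
    "C:G>G:C": ("C>G", "G>C"),
    "C:G>T:A": ("C>T", "G>A"),
    "T:A>A:T": ("T>A", "A>T"),
    "T:A>C:G": ("T>C", "A>G"),
    "T:A>G:C": ("T>G", "A>C"),
}
COLLAPSED_CLASSES = list(COLLAPSED_PAIRS)

_CODE = {b: i for i, b in enumerate(seqs.BASES)}


def _rate_frame(index: list[str], num: np.ndarray, den: np.ndarray) -> pd.DataFrame:
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return pd.DataFrame({"numerator": num.astype(np.int64),
                         "denominator": den.astype(np.int64),
                         "rate": rate}, index=pd.Index(index, name="class"))


def class_rates(pile: SiteAlleleCounts, table: BackgroundAlleleTable) -> pd.DataFrame:
    """Strand-resolved (12-class) error rates for one sample."""
    bg = table.background()
    pos = bg["pos"].to_numpy()
    idx = np.searchsorted(pile.positions, pos)
    ok = (idx < len(pile)) & (pile.positions[np.minimum(idx, len(pile) - 1)] == pos)
    bg = bg[ok]
    idx = idx[ok]
    ref_c = np.array([_CODE[b] for b in bg["ref"]], dtype=np.intp)
    alt_c = np.array([_CODE[b] for b in bg["alt"]], dtype=np.intp)
    num16 = np.zeros(16, dtype=np.int64)
    den16 = np.zeros(16, dtype=np.int64)
    key = ref_c * 4 + alt_c
    np.add.at(num16, key, pile.counts[idx, alt_c])
    np.add.at(den16, key, pile.highq_depth[idx])
    order = [_CODE[c[0]] * 4 + _CODE[c[2]] for c in STRAND_CLASSES]
    return _rate_frame(STRAND_CLASSES, num16[order], den16[order])


def collapse_classes(t: pd.DataFrame) -> pd.DataFrame:
    """Pool reciprocal strand classes into the 6 collapsed classes."""
    num, den = [], []
    for cls, (a, b) in COLLAPSED_PAIRS.items():
        num.append(t.loc[a, "numerator"] + t.loc[b, "numerator"])
        den.append(t.loc[a, "denominator"] + t.loc[b, "denominator"])
    return _rate_frame(COLLAPSED_CLASSES, np.array(num), np.array(den))


def overall_background_rate(pile: SiteAlleleCounts, table: BackgroundAlleleTable) -> float:
    """Total background alt bases over total quality-filtered bases at
    background-eligible positions."""
    t = class_rates(pile, table)
    elig = table.eligible_positions()
    idx = np.searchsorted(pile.positions, elig)
    ok = (idx < len(pile)) & (pile.positions[np.minimum(idx, len(pile) - 1)] == elig)
    total = int(pile.highq_depth[idx[ok]].sum())
    if total == 0:
        raise ValueError("no quality-filtered bases at eligible positions")
    return float(t["numerator"].sum() / total)


def error_free_fraction(pile: SiteAlleleCounts, table: BackgroundAlleleTable) -> float:
    """Fraction of background-eligible positions with zero background alt bases."""
    bg = table.background()
    if len(bg) == 0:
        raise ValueError("no background-eligible positions")
    pos = bg["pos"].to_numpy()
    idx = np.searchsorted(pile.positions, pos)
    ok = (idx < len(pile)) & (pile.positions[np.minimum(idx, len(pile) - 1)] == pos)
    bg, idx = bg[ok], idx[ok]
    if len(bg) == 0:
        raise ValueError("no background-eligible positions covered by the pileup")
    alt_c = np.array([_CODE[b] for b in bg["alt"]], dtype=np.intp)
    counts = pile.counts[idx, alt_c]
    per_pos = pd.Series(counts).groupby(bg["pos"].to_numpy()).sum()
    return float((per_pos == 0).mean())


def context_rates(pile: SiteAlleleCounts, table: BackgroundAlleleTable,
                  ref: ReferenceBundle) -> pd.DataFrame:
    """Collapsed-class rates stratified by the 16 flanking contexts.

    Context is read from the strand carrying the pyrimidine of the collapsed
    class (N_C_N / N_T_N); positions at the reference edges are excluded.
    Marginalizing contexts recovers the class rates over the same positions.
    """
    L = len(ref)
    bg = table.background()
    pos = bg["pos"].to_numpy()
    edge_ok = (pos > 0) & (pos < L - 1)
    bg, pos = bg[edge_ok], pos[edge_ok]
    idx = np.searchsorted(pile.positions, pos)
    ok = (idx < len(pile)) & (pile.positions[np.minimum(idx, len(pile) - 1)] == pos)
    bg, pos, idx = bg[ok], pos[ok], idx[ok]

    ref_c = np.array([_CODE[b] for b in bg["ref"]], dtype=np.intp)
    alt_c = np.array([_CODE[b] for b in bg["alt"]], dtype=np.intp)
    cls_of = np.full(16, -1, dtype=np.intp)
    for k, (name, (a, b)) in enumerate(COLLAPSED_PAIRS.items()):
        for member in (a, b):
            cls_of[_CODE[member[0]] * 4 + _CODE[member[2]]] = k
    cls = cls_of[ref_c * 4 + alt_c]

    is_pyr = (ref_c == _CODE["C"]) | (ref_c == _CODE["T"])
    left = ref.codes[pos - 1].astype(np.intp)
    right = ref.codes[pos + 1].astype(np.intp)
    comp = seqs.COMP.astype(np.intp)
    n5 = np.where(is_pyr, left, comp[right])
    n3 = np.where(is_pyr, right, comp[left])
    ctx = n5 * 4 + n3

    num = np.zeros((6, 16), dtype=np.int64)
    den = np.zeros((6, 16), dtype=np.int64)
    np.add.at(num, (cls, ctx), pile.counts[idx, alt_c])
    np.add.at(den, (cls, ctx), pile.highq_depth[idx])

    rows = []
    for k, name in enumerate(COLLAPSED_CLASSES):
        pyr = name[0]  # C or T, the pyrimidine source base
        for c in range(16):
            label = seqs.BASES[c // 4] + pyr + seqs.BASES[c % 4]
            rows.append((name, label, num[k, c], den[k, c]))
    df = pd.DataFrame(rows, columns=["class", "context", "numerator", "denominator"])
    with np.errstate(invalid="ignore", divide="ignore"):
        df["rate"] = np.where(df["denominator"] > 0,
                              df["numerator"] / df["denominator"].clip(lower=1), np.nan)
    return df.set_index(["class", "context"])


def reciprocal_ratio(t: pd.DataFrame, pair: tuple[str, str] = ("C>A", "G>T")) -> float:
    """Ratio of the two member rates of a reciprocal pair (excess / baseline)."""
    f_excess = t.loc[pair[0], "rate"]
    f_baseline = t.loc[pair[1], "rate"]
    if not np.isfinite(f_baseline) or f_baseline == 0:
        return float("nan")
    return float(f_excess / f_baseline)


def attribute_shear(t_pbl: pd.DataFrame, t_plasma: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each collapsed class attributable to the fragmentation step."""
    if set(t_pbl.index) != set(t_plasma.index):
        raise ValueError("class tables do not match")
    r_pbl = t_pbl["rate"]
    r_plasma = t_plasma["rate"].reindex(r_pbl.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (r_pbl - r_plasma) / r_pbl
        incr = (r_pbl - r_plasma) / r_plasma
    return pd.DataFrame({"r_pbl": r_pbl, "r_plasma": r_plasma,
                         "shear_fraction": frac, "shear_increase": incr})


def attribute_hybsel(t: pd.DataFrame, captured_strand: str = "-") -> pd.DataFrame:
    """Strand-asymmetry attribution of capture-step damage.

    For minus-strand baits the reference-projected excess classes are C>A
    (vs G>T) and C>T (vs G>A); for plus-strand baits the roles swap.
    """
    if captured_strand == "-":
        pairs = [("C>A", "G>T"), ("C>T", "G>A")]
    elif captured_strand == "+":
        pairs = [("G>T", "C>A"), ("G>A", "C>T")]
    else:
        raise ValueError("captured_strand must be '+' or '-'")
    rows = []
    for excess, baseline in pairs:
        fe = t.loc[excess, "rate"]
        fb = t.loc[baseline, "rate"]
        asym = (fe - fb) / fe if np.isfinite(fe) and fe > 0 else float("nan")
        ratio = fe / fb if np.isfinite(fb) and fb > 0 else float("nan")
        rows.append((f"{excess}|{baseline}", fe, fb, asym, ratio))
    return pd.DataFrame(rows, columns=["pair", "f_excess", "f_baseline",
                                       "asymmetry", "reciprocal_ratio"]
                        ).set_index("pair")


def cohort_mean_sd(values: list[float] | np.ndarray) -> tuple[float, float]:
    """Mean +/- SD over per-sample statistics (NaN-aware)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return float("nan"), float("nan")
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
    return float(np.mean(v)), sd
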