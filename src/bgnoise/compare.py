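"""Paired group comparison of class rates and SNP-concordance QC."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def paired_class_test(group_a: list[pd.DataFrame], group_b: list[pd.DataFrame],
                      method: str = "wilcoxon", alpha: float = 0.05,
                      min_pairs: int = 6) -> pd.DataFrame:
    """Per-class paired test between two matched groups of rate tables.

    Subjects must be matched by list order.  The default test is a two-sided
    Wilcoxon signed-rank on per-subject rates; ``method='ttest'`` gives the
    parametric paired t alternative.  P values are Bonferroni-adjusted by the
    number of classes tested.
    """
    if len(group_a) != len(group_b):
        raise ValueError("groups must contain matched subjects in the same order")
    if len(group_a) < min_pairs:
        raise ValueError(f"need at least {min_pairs} matched pairs, got {len(group_a)}")
    classes = list(group_a[0].index)
    for t in group_a + group_b:
        if list(t.index) != classes:
            raise ValueError("rate tables have inconsistent class sets")
    n_classes = len(classes)

    rows = []
    for cls in classes:
        a = np.array([t.loc[cls, "rate"] for t in group_a], dtype=float)
        b = np.array([t.loc[cls, "rate"] for t in group_b], dtype=float)
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
        if len(a) < min_pairs:
            stat, p = np.nan, np.nan
        elif method == "wilcoxon":
            if np.allclose(a, b):
                stat, p = 0.0, 1.0
            else:
                res = stats.wilcoxon(a, b, alternative="two-sided",
                                     zero_method="wilcox")
                stat, p = float(res.statistic), float(res.pvalue)
        elif method == "ttest":
            res = stats.ttest_rel(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
        p_adj = min(1.0, n_classes * p) if np.isfinite(p) else np.nan
        rows.append({
            "class": cls, "n_pairs": int(len(a)),
            "mean_a": float(np.mean(a)) if len(a) else np.nan,
            "mean_b": float(np.mean(b)) if len(b) else np.nan,
            "mean_difference": float(np.mean(a - b)) if len(a) else np.nan,
            "statistic": stat, "p_raw": p, "p_adjusted": p_adj,
            "significant": bool(np.isfinite(p_adj) and p_adj < alpha),
            "bonferroni_factor": n_classes,
        })
    return pd.DataFrame(rows).set_index("class")


def snp_concordance(freq_a: np.ndarray, freq_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of paired germline allele frequencies.

    Returns (R, p).  Requires >= 3 SNPs and non-degenerate variance.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired SNP frequencies")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in SNP frequencies; correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
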