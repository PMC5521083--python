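"""Coverage down-sampling and the depth dependence of false positives.

At a fixed per-site error rate, the chance that a background allele crosses a
fixed frequency threshold grows as unique depth falls (binomial tails fatten
at small n), so low-depth data produce more false positives.  This module
provides (i) in-silico down-sampling of read pairs with the full
dedup -> pileup -> background-call chain re-run per subsample, and (ii) a
direct overdispersed per-site error model (gamma-distributed site rates) for
studying threshold-exceedance as a function of depth, which is where the
order-of-magnitude inflation at low coverage comes from: real background
rates are strongly site-specific, not uniform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .background import call_background
from .pileup import FilterThresholds, build_pileup, filter_reads
from .reads import ReadSet
from .simulate import ReferenceBundle


def downsample_reads(records: ReadSet, target_pairs: int,
                     seed: int | np.random.Generator = 0) -> ReadSet:
    """Uniform random subsample of complete read pairs (mates kept together)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pt = records.pair_table()
    n = len(pt["r1"])
    if target_pairs > n:
        raise ValueError(f"requested {target_pairs} pairs but only {n} available")
    pick = rng.choice(n, size=target_pairs, replace=False)
    idx = np.sort(np.concatenate([pt["r1"][pick], pt["r2"][pick]]))
    return records.take(idx)


def fp_curve(samples: dict[str, ReadSet], ref: ReferenceBundle,
             fractions: list[float],
             thresholds: FilterThresholds | None = None,
             freq_thresholds: tuple[float, ...] = (0.005, 0.01, 0.02),
             depth_bins: tuple[int, ...] = (500, 1000),
             seed: int = 0,
             analysis_sample: str = "plasma") -> pd.DataFrame:
    """Exceedance fraction of background alleles vs unique depth.

    For each subsample fraction the pipeline is re-run end to end (dedup,
    pileup, background call); the paired-depth gate is released during
    re-calling so that the low-depth bins exist, and results are binned by
    the analysis sample's realized unique depth.  The reported fraction is
    (background alleles with observed frequency > t) / (all background
    alleles in the bin), zero-count alleles included in the denominator.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    rng = np.random.default_rng(seed)
    call_thr = FilterThresholds(
        qmin=thresholds.qmin, min_depth_pair=0, germline_af=thresholds.germline_af,
        fna_min_depth=0, fna_max_af=thresholds.fna_max_af,
        exclude_clipped=thresholds.exclude_clipped, dedup=thresholds.dedup)
    edges = [0, *depth_bins, np.inf]
    bin_labels = [f"<{depth_bins[0]}"] + [
        f"{depth_bins[i]}-{depth_bins[i + 1]}" for i in range(len(depth_bins) - 1)
    ] + [f">{depth_bins[-1]}"]

    rows = []
    for frac in fractions:
        piles = {}
        for name, rs in samples.items():
            n_pairs = len(rs.pair_table()["r1"])
            sub = downsample_reads(rs, int(round(frac * n_pairs)), rng)
            kept = filter_reads(sub, call_thr).reads
            piles[name] = build_pileup(kept, ref, thresholds=call_thr)
        table = call_background(piles["plasma"], piles["pbl"], piles.get("fna"),
                                thresholds=call_thr, ref_length=len(ref))
        bg = table.background()
        dep = bg[f"{analysis_sample}_depth"].to_numpy()
        freq = bg[f"{analysis_sample}_freq"].to_numpy()
        which = np.digitize(dep, edges[1:-1], right=False)
        mean_depth = float(np.mean(
            piles[analysis_sample].highq_depth)) if len(piles[analysis_sample]) else 0.0
        for b, label in enumerate(bin_labels):
            sel = which == b
            n_alleles = int(sel.sum())
            for t in freq_thresholds:
                n_exc = int((freq[sel] > t).sum())
                rows.append({
                    "fraction": frac, "mean_unique_depth": mean_depth,
                    "depth_bin": label, "threshold": t,
                    "n_alleles": n_alleles, "n_exceeding": n_exc,
                    "exceedance": n_exc / n_alleles if n_alleles else np.nan,
                })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# overdispersed per-site error model
# --------------------------------------------------------------------------

def gamma_site_rates(n_sites: int, mean_rate: float, shape: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Site-specific error rates ~ Gamma(shape, mean/shape).

    Small shape parameters give the heavy-tailed, strongly site-specific rate
    landscape seen in deep-sequencing background noise while preserving the
    configured mean.
    """
    return rng.gamma(shape, mean_rate / shape, size=n_sites)


def exceedance_fraction(site_rates: np.ndarray, depth: int, threshold: float,
                        rng: np.random.Generator | None = None,
                        exact: bool = False) -> float:
    """Fraction of site-alleles whose observed frequency exceeds ``threshold``.

    ``exact`` integrates the binomial tail P(X/depth > t) over the site
    rates; otherwise one alt count is drawn per site.
    """
    k = int(np.floor(threshold * depth))  # exceed means count >= k+1
    if exact:
        return float(np.mean(stats.binom.sf(k, depth, site_rates)))
    if rng is None:
        rng = np.random.default_rng(0)
    x = rng.binomial(depth, site_rates)
    return float(np.mean(x / depth > threshold))
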