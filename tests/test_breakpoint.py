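"""Break-point window, composition and positional-rate tests."""

import numpy as np
import pandas as pd
import pytest

import bgnoise as bg
from bgnoise.breakpoint import fold_changes
from bgnoise.pileup import FilterThresholds
from bgnoise.seqs import decode

from util import make_readset, naive_mono_counts, naive_windows, naive_di_counts


def _ref(length=4000, seed=2):
    cfg = bg.SimConfig(seed=seed, ref_length=max(length, 1000), gc_fraction=0.5)
    return bg.make_reference(cfg)


class TestWindowConventions:
    def test_forward_read_distance_zero_dinucleotide(self):
        ref = _ref()
        a = 1000
        seq = decode(ref.codes[a:a + 100])
        rs = make_readset([dict(pair=0, mate=1, pos=a, seq=seq, qual=37),
                           dict(pair=0, mate=2, pos=a + 70, seq="A" * 30,
                                qual=37, rev=True)])
        wins = bg.end_windows(rs.take([0]), ref, mode="fragment")
        w = wins.windows[0]
        # slot 49 = label -1 (reference base 5' of the read), slot 50 = +1
        assert w[49] == ref.codes[a - 1]
        assert w[50] == ref.codes[a]
        di = bg.di_frequencies(wins)
        d0 = di.loc[0]
        assert d0[decode(ref.codes[a - 1:a + 1])] == 1.0

    def test_reverse_read_fragment_mode_complements(self):
        ref = _ref()
        e = 2000  # half-open end; 5' terminus at e-1
        seq = decode(ref.codes[e - 100:e])
        rs = make_readset([dict(pair=0, mate=1, pos=e - 100, seq=seq, qual=37,
                                rev=True),
                           dict(pair=0, mate=2, pos=e - 170, seq="A" * 30, qual=37)])
        wins = bg.end_windows(rs.take([0]), ref, mode="fragment")
        w = wins.windows[0]
        assert w[50] == 3 - ref.codes[e - 1]   # +1 = complement of plus base
        assert w[49] == 3 - ref.codes[e]       # -1 = complement of next plus base

    def test_plus_strand_mode_keeps_plus_orientation(self):
        ref = _ref()
        e = 2000
        seq = decode(ref.codes[e - 100:e])
        rs = make_readset([dict(pair=0, mate=1, pos=e - 100, seq=seq, qual=37,
                                rev=True),
                           dict(pair=0, mate=2, pos=e - 170, seq="A" * 30, qual=37)])
        wins = bg.end_windows(rs.take([0]), ref, mode="plus_strand")
        w = wins.windows[0]
        assert w[50] == ref.codes[e - 1]  # +1 = 5' terminus, uncomplemented

    def test_clipped_reads_excluded(self):
        ref = _ref()
        rs = make_readset([dict(pair=0, mate=1, pos=1000, seq="A" * 50, clip=True),
                           dict(pair=0, mate=2, pos=1100, seq="A" * 50, rev=True)])
        wins = bg.end_windows(rs, ref)
        assert wins.n_skipped_clipped == 1
        assert len(wins) == 1

    def test_edge_windows_excluded(self):
        ref = _ref()
        rs = make_readset([dict(pair=0, mate=1, pos=10, seq="A" * 50),
                           dict(pair=0, mate=2, pos=1000, seq="A" * 50, rev=True)])
        wins = bg.end_windows(rs, ref)
        assert wins.n_skipped_edge == 1

    def test_low_quality_read_bases_masked(self):
        ref = _ref()
        seq = decode(ref.codes[1000:1050])
        rs = make_readset([dict(pair=0, mate=1, pos=1000, seq=seq,
                                qual=[10] * 50),
                           dict(pair=0, mate=2, pos=1100, seq="A" * 50, rev=True)])
        wins = bg.end_windows(rs.take([0]), ref)
        assert (wins.windows[0][50:] == -1).all()
        assert (wins.windows[0][:50] >= 0).all()  # reference side intact


@pytest.fixture(scope="module")
def pbl_windows():
    cfg = bg.SimConfig(seed=71, ref_length=20_000, gc_fraction=0.5,
                       n_fragments=25_000)
    ref = bg.make_reference(cfg)
    rs, _ = bg.simulate_sample(cfg, ref, "acoustic", "pbl",
                               np.random.default_rng(1))
    kept = bg.filter_reads(rs, FilterThresholds()).reads
    return cfg, ref, kept


class TestComposition:

    def test_rows_normalize(self, pbl_windows):
        _, ref, kept = pbl_windows
        wins = bg.end_windows(kept, ref)
        mono = bg.mono_frequencies(wins)
        assert np.allclose(mono.sum(axis=1), 1.0)
        di = bg.di_frequencies(wins)
        assert np.allclose(di.sum(axis=1), 1.0)

    def test_first_base_a_enrichment_and_cut_ranking(self, pbl_windows):
        """Cuts 5' of A enrich A at +1; forward-window distance-0
        dinucleotides recover the configured cleavage ranking."""
        _, ref, kept = pbl_windows
        fwd = kept.take(~kept.is_reverse)
        wins = bg.end_windows(fwd, ref)
        mono = bg.mono_frequencies(wins)
        background_a = mono.loc[30:, "A"].mean()
        assert mono.loc[1, "A"] > background_a + 0.03
        di = bg.di_frequencies(wins)
        d0 = di.loc[0]
        far = di.loc[[d for d in di.index if abs(d) >= 30]].mean()
        enrich = d0 / far
        assert enrich["CG"] > enrich["CA"] > enrich["TA"]
        assert abs(enrich["TA"] - enrich["GA"]) < 0.45
        others = [d for d in di.columns if d not in ("CG", "CA", "TA", "GA")]
        assert min(enrich["TA"], enrich["GA"]) > enrich[others].max()

    def test_far_positions_match_genomic_background(self, pbl_windows):
        _, ref, kept = pbl_windows
        wins = bg.end_windows(kept, ref)
        mono = bg.mono_frequencies(wins)
        comp = np.bincount(ref.codes, minlength=4) / len(ref)
        far = mono.loc[[-45, -40, 40, 45]].mean()
        for i, b in enumerate("ACGT"):
            assert abs(far[b] - comp[i]) < 0.02

    def test_windows_match_naive_oracle(self, tmp_path):
        cfg = bg.SimConfig(seed=73, ref_length=10_000, n_fragments=900)
        ref = bg.make_reference(cfg)
        rs, _ = bg.simulate_sample(cfg, ref, "acoustic", "s",
                                   np.random.default_rng(5))
        kept = bg.filter_reads(rs, FilterThresholds()).reads
        sam = str(tmp_path / "w.sam")
        kept.to_sam(sam, ref.name, len(ref))
        wins = bg.end_windows(kept, ref, mode="fragment")
        oracle = naive_windows(sam, ref.sequence, qmin=30)
        assert len(oracle) == len(wins)
        mono_o = naive_mono_counts(oracle)
        w = wins.windows
        for k in range(w.shape[1]):
            for b, base in enumerate("ACGT"):
                assert int((w[:, k] == b).sum()) == mono_o.get((k, base), 0)
        di_o = naive_di_counts(oracle)
        di = bg.di_frequencies(wins)
        # spot-check raw dinucleotide tallies at a few distances
        first = w[:, :-1].astype(np.int64)
        second = w[:, 1:].astype(np.int64)
        valid = (first >= 0) & (second >= 0)
        for dist, col in ((0, 49), (1, 50), (-1, 48)):
            for d, dn in enumerate([a + b for a in "ACGT" for b in "ACGT"]):
                got = int(((first[:, col] * 4 + second[:, col] == d)
                           & valid[:, col]).sum())
                assert got == di_o.get((dist, dn), 0)


class TestPositionalRates:
    def test_fold_change_arithmetic(self):
        rates = pd.DataFrame([[5e-4] + [1e-4] * 49],
                             index=["A>G"], columns=range(1, 51))
        fc = fold_changes(rates)
        assert rates.mean(axis=1).iloc[0] == pytest.approx(1.08e-4)
        assert fc.loc["A>G", 1] == pytest.approx(4.6296, abs=1e-3)

    def test_mean_fold_change_is_one(self, sim_pair):
        pr = bg.positional_rates(sim_pair["kept"]["pbl"], sim_pair["table"],
                                 sim_pair["ref"])
        means = pr.fold_change.mean(axis=1).dropna()
        assert np.allclose(means, 1.0)

    def test_first_base_ak_elevated_iff_injected(self):
        """A>K fold change spikes at position 1 when break-point damage is
        injected, and stays inside the positional spread when it is not."""
        base = dict(seed=75, ref_length=15_000, n_fragments=30_000,
                    snp_density=0)
        thr = FilterThresholds(min_depth_pair=100)
        results = {}
        for label, p_bp in (("on", 0.01), ("off", 0.0)):
            cfg = bg.SimConfig(**base, p_bp=p_bp)
            ref = bg.make_reference(cfg)
            rs, _ = bg.simulate_sample(cfg, ref, "acoustic", "s",
                                       np.random.default_rng(9))
            kept = bg.filter_reads(rs, thr).reads
            pile = bg.build_pileup(kept, ref, thresholds=thr)
            table = bg.call_background(pile, pile, thresholds=thr,
                                       ref_length=len(ref))
            results[label] = bg.positional_rates(kept, table, ref)
        for cls in ("A>G", "A>T"):
            fc_on = results["on"].fold_change.loc[cls]
            body = fc_on.loc[2:]
            assert fc_on[1] > body.max()
            fc_off = results["off"].fold_change.loc[cls]
            assert fc_off[1] <= fc_off.loc[2:].max() + 1e-9
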