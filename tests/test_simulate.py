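"""Simulator unit and property tests: composition, fragmentation, damage
accounting, read emission and cohort determinism."""

import filecmp

import numpy as np
import pandas as pd
import pytest

import bgnoise as bg
from bgnoise.seqs import BASES, encode, decode
from bgnoise.simulate import InvalidConfigError, sample_snp_sites, genotype_subject

from util import parse_sam_text


def _frag_cfg(**kw):
    base = dict(seed=3, ref_length=50_000, gc_fraction=0.5, n_fragments=1000)
    base.update(kw)
    return bg.SimConfig(**base)


class TestMakeReference:
    def test_composition_and_independent_cpg(self):
        cfg = bg.SimConfig(seed=1, ref_length=1_000_000, gc_fraction=0.5,
                           cpg_enrichment=1.0)
        ref = bg.make_reference(cfg)
        gc = np.isin(ref.codes, [1, 2]).mean()
        assert abs(gc - 0.5) < 0.01
        cg = np.mean((ref.codes[:-1] == 1) & (ref.codes[1:] == 2))
        assert abs(cg - 0.0625) < 0.001  # independence: freq(C) * freq(G)

    def test_cpg_enrichment_scales_dinucleotide_frequency(self):
        cfg = bg.SimConfig(seed=2, ref_length=300_000, gc_fraction=0.4,
                           cpg_enrichment=2.0)
        ref = bg.make_reference(cfg)
        gc = np.isin(ref.codes, [1, 2]).mean()
        assert abs(gc - 0.4) < 0.01  # stationary composition preserved
        cg = np.mean((ref.codes[:-1] == 1) & (ref.codes[1:] == 2))
        assert abs(cg - 2.0 * 0.2 * 0.2) < 0.004

    def test_gc_zero_gives_at_only(self):
        ref = bg.make_reference(bg.SimConfig(seed=3, ref_length=5000, gc_fraction=0.0))
        assert set(np.unique(ref.codes)) <= {0, 3}

    def test_deterministic_under_seed(self):
        cfg = bg.SimConfig(seed=9, ref_length=10_000)
        a, b = bg.make_reference(cfg), bg.make_reference(cfg)
        assert np.array_equal(a.codes, b.codes)
        assert a.targets == b.targets

    def test_targets_sorted_disjoint_in_bounds(self):
        ref = bg.make_reference(bg.SimConfig(seed=4, ref_length=30_000,
                                             target_fraction=0.3))
        prev_end = 0
        for s, e in ref.targets:
            assert 0 <= prev_end <= s < e <= len(ref)
            prev_end = e
        frac = sum(e - s for s, e in ref.targets) / len(ref)
        assert 0.15 < frac < 0.45

    def test_too_short_reference_rejected(self):
        with pytest.raises(InvalidConfigError):
            bg.make_reference(bg.SimConfig(ref_length=500))


class TestDrawFragments:
    def test_median_follows_configuration(self):
        cfg_a = _frag_cfg(fragment_median=170)
        cfg_b = _frag_cfg(fragment_median=300)
        ref = bg.make_reference(cfg_a)
        rng = np.random.default_rng(0)
        fa = bg.draw_fragments(ref, cfg_a, 5000, rng=rng)
        fb = bg.draw_fragments(ref, cfg_b, 5000, rng=rng)
        assert abs(np.median(fa.lengths) - 170) < 10
        assert np.median(fb.lengths) > np.median(fa.lengths)

    @staticmethod
    def _cut_dinuc_freqs(ref, frags):
        """Independent tally of plus-strand dinucleotides at both cut bonds."""
        seq = ref.sequence
        tally: dict[str, int] = {}
        for i in range(len(frags)):
            for j in (int(frags.start[i]), int(frags.end[i])):
                d = seq[j - 1:j + 1]
                tally[d] = tally.get(d, 0) + 1
        total = sum(tally.values())
        return {d: tally.get(d, 0) / total for d in
                [a + b for a in BASES for b in BASES]}

    def test_uniform_weights_match_genomic_background(self):
        cfg = _frag_cfg()
        for mode in cfg.cleavage_weights:
            cfg.cleavage_weights[mode] = {d: 1.0 for d in cfg.cleavage_weights[mode]}
        ref = bg.make_reference(cfg)
        frags = bg.draw_fragments(ref, cfg, 20_000, rng=np.random.default_rng(1))
        freqs = self._cut_dinuc_freqs(ref, frags)
        seq = ref.sequence
        bgfreq = {d: 0 for d in freqs}
        for k in range(len(seq) - 1):
            bgfreq[seq[k:k + 2]] += 1
        for d in freqs:
            expected = bgfreq[d] / (len(seq) - 1)
            # binomial CI on 40k draws
            se = np.sqrt(expected * (1 - expected) / 40_000)
            assert abs(freqs[d] - expected) < 4 * se + 1e-3

    def test_weighted_cut_sites_rank_like_weights(self):
        cfg = _frag_cfg()
        cfg.cleavage_weights["acoustic"] = {
            d: {"CG": 4.0, "CA": 3.0, "TA": 2.0, "GA": 2.0}.get(d, 1.0)
            for d in cfg.cleavage_weights["acoustic"]
        }
        ref = bg.make_reference(cfg)
        frags = bg.draw_fragments(ref, cfg, 100_000, mode="acoustic",
                                  rng=np.random.default_rng(2))
        freqs = self._cut_dinuc_freqs(ref, frags)
        assert freqs["CG"] > freqs["CA"] > freqs["TA"]
        assert abs(freqs["TA"] - freqs["GA"]) < 0.01
        assert min(freqs["TA"], freqs["GA"]) > max(
            v for d, v in freqs.items() if d not in ("CG", "CA", "TA", "GA"))

    def test_all_zero_weights_rejected(self):
        cfg = _frag_cfg()
        cfg.cleavage_weights["acoustic"] = {d: 0.0 for d in
                                            cfg.cleavage_weights["acoustic"]}
        with pytest.raises(InvalidConfigError):
            bg.make_reference(cfg)


class TestApplyDamage:
    def test_zero_rates_leave_empty_ledger(self):
        cfg = _frag_cfg(p_ox=0, p_ox2=0, p_bp=0)
        ref = bg.make_reference(cfg)
        frags = bg.draw_fragments(ref, cfg, 2000, rng=np.random.default_rng(0))
        _, truth = bg.apply_damage(frags, ref, cfg, mode="acoustic")
        assert len(truth) == 0

    def test_plasma_mode_disables_shear_damage(self):
        cfg = _frag_cfg(p_ox=1e-3, p_ox2=1e-3, p_bp=0.05)
        ref = bg.make_reference(cfg)
        frags = bg.draw_fragments(ref, cfg, 2000, rng=np.random.default_rng(0))
        _, truth = bg.apply_damage(frags, ref, cfg, mode="none")
        assert len(truth) == 0

    def test_breakpoint_rate_matches_a_start_count(self):
        cfg = _frag_cfg(p_ox=0, p_ox2=0, p_bp=0.01, n_fragments=100_000)
        ref = bg.make_reference(cfg)
        frags = bg.draw_fragments(ref, cfg, 100_000, rng=np.random.default_rng(5))
        _, truth = bg.apply_damage(frags, ref, cfg, mode="acoustic",
                                   rng=np.random.default_rng(6))
        # independent tally of A-starting 5' termini (both strands)
        seq = ref.codes
        n_a_ends = int((seq[frags.start] == 0).sum()) + int((seq[frags.end - 1] == 3).sum())
        n_rec = (truth["process"] == "breakpoint_AK").sum()
        expect = 0.01 * n_a_ends
        assert abs(n_rec - expect) < 3 * np.sqrt(expect)

    def test_ncg_context_multiplier_recovered(self):
        cfg = _frag_cfg(p_ox=2e-4, p_ox2=0, p_bp=0, ncg_multiplier=5.0,
                        gc_fraction=0.5)
        ref = bg.make_reference(cfg)
        frags = bg.draw_fragments(ref, cfg, 50_000, rng=np.random.default_rng(7))
        _, truth = bg.apply_damage(frags, ref, cfg, mode="acoustic",
                                   rng=np.random.default_rng(8))
        ox = truth[truth["process"] == "oxidation_CA"]
        # independent context annotation: CpG membership of each G/C position
        codes = ref.codes
        member = np.zeros(len(codes), dtype=bool)
        cg = (codes[:-1] == 1) & (codes[1:] == 2)
        member[:-1] |= cg
        member[1:] |= cg
        # exposure: covered G/C bases by context
        cover = np.zeros(len(codes) + 1, np.int64)
        np.add.at(cover, frags.start, 1)
        np.add.at(cover, frags.end, -1)
        cover = np.cumsum(cover[:-1])
        gcpos = np.isin(codes, [1, 2])
        exp_in = float((cover * (gcpos & member)).sum())
        exp_out = float((cover * (gcpos & ~member)).sum())
        n_in = int(member[ox["pos"]].sum())
        n_out = len(ox) - n_in
        ratio = (n_in / exp_in) / (n_out / exp_out)
        se = ratio * np.sqrt(1 / n_in + 1 / n_out)
        assert abs(ratio - 5.0) < 3 * se


class TestGenerateReads:
    def test_error_free_identity(self):
        cfg = _frag_cfg(p_ox=0, p_ox2=0, p_bp=0, p_hs_CA=0, p_hs_CT=0,
                        p_template=0, p_seq=0, q_low_given_correct=0.1)
        ref = bg.make_reference(cfg)
        frags = bg.draw_fragments(ref, cfg, 3000, rng=np.random.default_rng(1))
        mols, _ = bg.apply_damage(frags, ref, cfg, mode="none")
        rs, truth = bg.generate_reads(mols, ref, cfg, "s", np.random.default_rng(2))
        assert len(truth) == 0
        assert np.array_equal(rs.seq, ref.codes[rs.base_positions()])
        hi = (rs.qual >= 30).mean()
        assert abs(hi - 0.9) < 0.01

    def test_error_quality_split_matches_biphasic_model(self):
        cfg = _frag_cfg(p_ox=0, p_ox2=0, p_bp=0, p_hs_CA=0, p_hs_CT=0,
                        p_template=0, p_seq=1e-3, q_high_given_error=0.05)
        ref = bg.make_reference(cfg)
        frags = bg.draw_fragments(ref, cfg, 20_000, rng=np.random.default_rng(3))
        mols, _ = bg.apply_damage(frags, ref, cfg, mode="none")
        rs, truth = bg.generate_reads(mols, ref, cfg, "s", np.random.default_rng(4))
        mism = rs.seq != ref.codes[rs.base_positions()]
        n_err = int(mism.sum())
        assert n_err == len(truth)  # all mismatches are sequencing-run errors
        frac_hi = (rs.qual[mism] >= 30).mean()
        assert abs(frac_hi - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_err)

    def test_duplication_law(self):
        cfg = _frag_cfg(dup_mean=1.5, p_seq=0, p_template=0, p_hs_CA=0, p_hs_CT=0)
        ref = bg.make_reference(cfg)
        frags = bg.draw_fragments(ref, cfg, 10_000, rng=np.random.default_rng(5))
        mols, _ = bg.apply_damage(frags, ref, cfg, mode="none")
        rs, _ = bg.generate_reads(mols, ref, cfg, "s", np.random.default_rng(6))
        assert len(np.unique(rs.molecule_id)) == 10_000
        n_pairs = len(rs) // 2
        # copies ~ 1 + Poisson(0.5): mean 1.5, var 0.5
        sd = np.sqrt(10_000 * 0.5)
        assert abs(n_pairs - 15_000) < 3 * sd

    def test_short_fragments_truncate_reads_to_total_overlap(self):
        cfg = _frag_cfg(fragment_median=60, fragment_sd=5, p_seq=0, p_template=0,
                        p_hs_CA=0, p_hs_CT=0)
        ref = bg.make_reference(cfg)
        frags = bg.draw_fragments(ref, cfg, 500, rng=np.random.default_rng(7))
        mols, _ = bg.apply_damage(frags, ref, cfg, mode="none")
        rs, _ = bg.generate_reads(mols, ref, cfg, "s", np.random.default_rng(8))
        pt = rs.pair_table()
        lens = rs.lengths
        assert (lens == frags.lengths[rs.molecule_id].clip(max=100)).all()
        # mates of a truncated fragment cover the same interval
        sub = frags.lengths[rs.molecule_id[pt["r1"]]] < 100
        assert np.array_equal(rs.pos[pt["r1"]][sub], rs.pos[pt["r2"]][sub])


class TestFullAccounting:
    def test_every_mismatch_traces_to_one_record(self):
        """Exhaustive cross-join of read mismatches vs the truth ledger on a
        10-kb instance, SNP alleles exempt."""
        cfg = bg.SimConfig(seed=21, ref_length=10_000, n_fragments=4000)
        ref = bg.make_reference(cfg)
        rng = np.random.default_rng(22)
        sites = sample_snp_sites(cfg, ref, rng)
        geno = genotype_subject(sites, rng)
        rs, truth = bg.simulate_sample(cfg, ref, "acoustic", "s",
                                       np.random.default_rng(23), snps=geno)
        snp_set = {(int(p), a) for p, a in zip(geno["pos"], geno["alt"])}
        mol_level = {}
        read_level = {}
        for r in truth.itertuples():
            key = (int(r.molecule_id), int(r.pos), r.alt)
            if r.process == "seqrun":
                read_level.setdefault((key, int(r.copy), int(r.mate)), 0)
                read_level[(key, int(r.copy), int(r.mate))] += 1
            elif r.on_template:
                mol_level[key] = mol_level.get(key, 0) + 1

        pos = rs.base_positions()
        mism = np.flatnonzero(rs.seq != ref.codes[pos])
        ridx = rs.base_read_index()
        n_checked = 0
        for k in mism:
            p = int(pos[k])
            alt = "ACGT"[rs.seq[k]]
            if (p, alt) in snp_set:
                continue
            r = int(ridx[k])
            key = (int(rs.molecule_id[r]), p, alt)
            hits = read_level.get((key, int(rs.copy[r]), int(rs.mate[r])), 0)
            hits += mol_level.get(key, 0)
            assert hits >= 1, f"untraced mismatch at {p} -> {alt}"
            n_checked += 1
        assert n_checked > 100  # the check actually exercised many mismatches


class TestCohort:
    def test_truth_tsvs_deterministic(self, tmp_path):
        cfg = bg.SimConfig(seed=31, ref_length=5000, n_fragments=1500,
                           snp_density=1e-3)
        bg.simulate_cohort(cfg, 1, outdir=str(tmp_path / "a"))
        bg.simulate_cohort(cfg, 1, outdir=str(tmp_path / "b"))
        for f in ("s00_plasma_truth.tsv", "s00_pbl_truth.tsv", "s00_fna_truth.tsv",
                  "reference.fasta", "targets.bed"):
            assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f, shallow=False)

    def test_somatic_spike_recovered_in_fna_pileup(self):
        cfg = bg.SimConfig(seed=33, ref_length=10_000, n_fragments=20_000,
                           snp_density=0.0)
        ref = bg.make_reference(cfg)
        # choose a target position and a genuine non-reference allele
        pos = ref.targets[1][0] + 50
        alt = "ACGT"[(ref.codes[pos] + 1) % 4]
        cfg.somatic_spikes = [(pos, alt, 0.1)]
        res = bg.simulate_cohort(cfg, 1, with_fna=True)
        fna = res["subjects"][0]["samples"]["fna"]["reads"]
        thr = bg.FilterThresholds(min_depth_pair=100, fna_min_depth=50)
        pile = bg.build_pileup(bg.filter_reads(fna, thr).reads, ref, thresholds=thr)
        i = int(np.searchsorted(pile.positions, pos))
        assert pile.positions[i] == pos
        freq = pile.counts[i, "ACGT".index(alt)] / pile.highq_depth[i]
        se = np.sqrt(0.1 * 0.9 / pile.highq_depth[i])
        assert abs(freq - 0.1) < 4 * se

    def test_sam_round_trip(self, tmp_path):
        cfg = bg.SimConfig(seed=35, ref_length=5000, n_fragments=800)
        ref = bg.make_reference(cfg)
        rs, _ = bg.simulate_sample(cfg, ref, "acoustic", "s",
                                   np.random.default_rng(1))
        path = str(tmp_path / "x.sam")
        rs.to_sam(path, ref.name, len(ref))
        back = bg.ReadSet.from_sam(path)
        assert len(back) == len(rs)
        srt = rs.sort_by_coordinate()
        assert np.array_equal(back.pos, srt.pos)
        assert np.array_equal(back.seq, srt.seq)
        assert np.array_equal(back.qual, srt.qual)
        assert np.array_equal(back.is_reverse, srt.is_reverse)
        assert np.array_equal(back.molecule_id, srt.molecule_id)
        # flags parse as proper pairs with sane mate info
        recs = parse_sam_text(path)
        assert all(r["flag"] & 0x1 and r["flag"] & 0x2 for r in recs)
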