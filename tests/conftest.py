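import numpy as np
import pytest

import bgnoise as bg


@pytest.fixture(scope="session")
def small_cfg() -> bg.SimConfig:
    """Fast study conditions: 20-kb panel, moderate depth."""
    return bg.SimConfig(seed=11, ref_length=20_000, n_fragments=30_000,
                        snp_density=2e-3)


@pytest.fixture(scope="session")
def thresholds300() -> bg.FilterThresholds:
    """Analysis thresholds for mid-depth test instances (~300x unique)."""
    return bg.FilterThresholds(min_depth_pair=150, fna_min_depth=75)


@pytest.fixture(scope="session")
def sim_pair(small_cfg, thresholds300):
    """One matched plasma/PBL pair with SNPs, piled up and classified."""
    cfg = small_cfg
    ref = bg.make_reference(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    c = ss.spawn(4)
    sites = bg.simulate.sample_snp_sites(cfg, ref, np.random.default_rng(c[0]))
    geno = bg.simulate.genotype_subject(sites, np.random.default_rng(c[1]))
    rs_p, tr_p = bg.simulate_sample(cfg, ref, "none", "plasma",
                                    np.random.default_rng(c[2]), snps=geno)
    rs_b, tr_b = bg.simulate_sample(cfg, ref, "acoustic", "pbl",
                                    np.random.default_rng(c[3]), snps=geno)
    kept_p = bg.filter_reads(rs_p, thresholds300).reads
    kept_b = bg.filter_reads(rs_b, thresholds300).reads
    pile_p = bg.build_pileup(kept_p, ref, thresholds=thresholds300)
    pile_b = bg.build_pileup(kept_b, ref, thresholds=thresholds300)
    table = bg.call_background(pile_p, pile_b, thresholds=thresholds300,
                               ref_length=len(ref))
    return {
        "cfg": cfg, "ref": ref, "snps": geno,
        "reads": {"plasma": rs_p, "pbl": rs_b},
        "kept": {"plasma": kept_p, "pbl": kept_b},
        "truth": {"plasma": tr_p, "pbl": tr_b},
        "piles": {"plasma": pile_p, "pbl": pile_b},
        "table": table,
    }
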