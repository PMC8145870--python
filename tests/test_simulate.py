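from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from jointscreen.cloning import build_probe_sets, build_recombinants
from jointscreen.counting import count_joint_reads, probe_bias
from jointscreen.errors import ConfigError, JointScreenError
from jointscreen.simulate import (
    PoolState,
    SimConfig,
    SimGene,
    design_from_config,
    make_sim_config,
    run_end_to_end,
    simulate_ligation_pool,
    simulate_reads,
    simulate_transformation,
)


def bare_config(n, **kw):
    genes = [SimGene(gene_id=f"g{i:04d}", fragment_seq="ACGT") for i in range(n)]
    return SimConfig(genes=genes, **kw)


class TestLigationPool:
    def test_zero_dispersion_gives_equal_shares(self):
        pool = simulate_ligation_pool(bare_config(10, ligation_dispersion=0.0))
        assert np.allclose(pool.abundance, 1.0)
        assert np.allclose(pool.shares, 0.1)  # ten genes -> 10% each

    def test_dispersion_sets_log_abundance_sd(self):
        cfg = bare_config(10_000, ligation_dispersion=1.0, seed=7)
        pool = simulate_ligation_pool(cfg)
        assert abs(np.log(pool.abundance).std() - 1.0) < 0.05

    def test_excluded_gene_has_zero_abundance(self):
        cfg = bare_config(5)
        cfg.excluded_genes = ["g0002"]
        pool = simulate_ligation_pool(cfg)
        assert pool.abundance[2] == 0.0
        assert (pool.abundance[[0, 1, 3, 4]] > 0).all()

    def test_fixed_seed_reproducible(self):
        cfg = bare_config(50, ligation_dispersion=0.8, seed=21)
        p1 = simulate_ligation_pool(cfg)
        p2 = simulate_ligation_pool(cfg)
        assert (p1.abundance == p2.abundance).all()


class TestTransformation:
    def test_neutral_pool_shares_preserved(self):
        cfg = bare_config(8, ligation_dispersion=0.5, n_transformants=200_000, seed=3)
        lig = simulate_ligation_pool(cfg)
        trans = simulate_transformation(lig, cfg)
        # multinomial draw: shares agree within sampling noise
        assert trans.abundance.sum() == cfg.n_transformants
        assert np.abs(trans.shares - lig.shares).max() < 0.01

    def test_hard_toxin_absent_from_transformants(self):
        cfg = bare_config(4, ligation_dispersion=0.0, n_transformants=50_000)
        cfg.genes[1].survival = 0.0
        lig = simulate_ligation_pool(cfg)
        trans = simulate_transformation(lig, cfg)
        assert trans.abundance[1] == 0.0
        assert trans.abundance.sum() > 0

    def test_survival_scales_expected_recovery(self):
        cfg = bare_config(2, ligation_dispersion=0.0, n_transformants=100_000, seed=5)
        cfg.genes[0].survival = 0.25
        lig = simulate_ligation_pool(cfg)
        trans = simulate_transformation(lig, cfg)
        # gene 0 recovered at ~25% the rate of gene 1
        rate = trans.abundance[0] / trans.abundance[1]
        assert 0.2 < rate < 0.3

    def test_cotransformation_rescue_requires_partner(self):
        cfg = bare_config(3, ligation_dispersion=0.0, n_transformants=20_000, seed=9,
                          cotransformation_rate=2.0)
        cfg.genes[0].survival = 0.0
        cfg.antitoxin_map = {"g0000": "g0001"}
        lig = simulate_ligation_pool(cfg)
        trans = simulate_transformation(lig, cfg)
        # rescued toxin present despite survival 0
        assert trans.abundance[0] > 0

    def test_wrong_stage_rejected(self):
        cfg = bare_config(3)
        pool = PoolState(cfg.gene_ids, np.ones(3), "transformant")
        with pytest.raises(JointScreenError):
            simulate_transformation(pool, cfg)


@pytest.fixture(scope="module")
def one_gene_setup():
    cfg = make_sim_config(n_genes=1, seed=17, reads_per_sample=1000,
                          error_rate=0.0, plasmid_side_bias=0.0)
    rng = np.random.default_rng(np.random.SeedSequence([17, 1]))
    design = design_from_config(cfg, rng)
    recs = build_recombinants(design)
    probes = build_probe_sets(design)
    return cfg, recs, probes


class TestSimulateReads:
    def test_zero_reads_gives_empty_list(self, one_gene_setup):
        cfg, recs, _ = one_gene_setup
        cfg0 = replace(cfg, reads_per_sample=0)
        pool = simulate_ligation_pool(cfg0)
        assert simulate_reads(pool, recs, cfg0) == []

    def test_read_length_and_determinism(self, one_gene_setup):
        cfg, recs, _ = one_gene_setup
        pool = simulate_ligation_pool(cfg)
        r1 = simulate_reads(pool, recs, cfg, np.random.default_rng(4))
        r2 = simulate_reads(pool, recs, cfg, np.random.default_rng(4))
        assert r1 == r2
        assert all(len(a) == len(b) == cfg.read_length for a, b in r1[:50])

    def test_unbiased_library_balances_strands(self, one_gene_setup):
        """Without library bias the forward/reverse joint counts of each
        joint are binomially balanced (alpha = 0.001)."""
        cfg, recs, probes = one_gene_setup
        pool = simulate_ligation_pool(cfg)
        reads = [r for p in simulate_reads(pool, recs, cfg, np.random.default_rng(8))
                 for r in p]
        table = count_joint_reads(reads, probes)
        counts = table.counts[0]
        assert table.grand_total > 0
        for fwd, rev in ((counts[0], counts[1]), (counts[2], counts[3])):
            n = int(fwd + rev)
            if n:
                assert stats.binomtest(int(fwd), n, 0.5).pvalue > 0.001

    def test_plasmid_side_bias_flags_probe_bias(self, one_gene_setup):
        cfg, recs, probes = one_gene_setup
        flagged = 0
        for seed in range(3):
            biased = replace(cfg, plasmid_side_bias=0.99, reads_per_sample=2000)
            pool = simulate_ligation_pool(biased)
            reads = [r for p in simulate_reads(pool, recs, biased,
                                               np.random.default_rng(100 + seed))
                     for r in p]
            table = count_joint_reads(reads, probes)
            if probe_bias(table)["gene_flagged"].any():
                flagged += 1
        assert flagged == 3

    def test_insert_size_below_read_length_rejected(self):
        with pytest.raises(ConfigError):
            bare_config(2, insert_size_mean=100, read_length=150)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"ligation_dispersion": -0.1},
            {"n_transformants": 0},
            {"cotransformation_rate": -1},
            {"plasmid_side_bias": 1.0},
            {"error_rate": -0.5},
        ],
    )
    def test_out_of_range_rejected(self, kw):
        with pytest.raises(ConfigError):
            bare_config(2, **kw)

    def test_bad_survival_rejected(self):
        with pytest.raises(ConfigError):
            SimGene("g1", "ACGT", survival=1.5)

    def test_unknown_antitoxin_gene_rejected(self):
        with pytest.raises(ConfigError):
            bare_config(2, antitoxin_map={"g0000": "nope"})


class TestEndToEnd:
    def test_excluded_gene_is_dropout_never_candidate(self):
        cfg = make_sim_config(n_genes=4, seed=23, reads_per_sample=4000,
                              n_transformants=10_000)
        cfg.excluded_genes = ["g02"]
        res = run_end_to_end(cfg)
        by = {r.gene_id: r for r in res.screen_results}
        assert by["g02"].call == "dropout"
        assert by["g02"].ratio is None

    def test_lower_survival_gives_lower_recovered_ratio(self):
        """Rank correlation between survival and pipeline ratio is positive
        (equivalently, depletion deepens as survival drops) across seeds."""
        grid = [1.0, 0.6, 0.3, 0.1, 0.03, 0.01]
        rhos = []
        for seed in range(5):
            cfg = make_sim_config(
                n_genes=6,
                toxic={f"g{i + 1:02d}": s for i, s in enumerate(grid)},
                ligation_dispersion=0.3,
                n_transformants=30_000,
                reads_per_sample=15_000,
                seed=200 + seed,
            )
            res = run_end_to_end(cfg)
            t = res.truth.set_index("gene_id")
            rho = stats.spearmanr(t["survival"], t["ratio"]).statistic
            rhos.append(rho)
        assert np.mean(rhos) > 0.8  # survival and ratio co-rank

    def test_fixed_seed_bit_identical(self):
        cfg = make_sim_config(n_genes=3, seed=31, reads_per_sample=2000,
                              n_transformants=5000)
        a = run_end_to_end(cfg)
        b = run_end_to_end(cfg)
        assert a.ligation_reads == b.ligation_reads
        assert a.plasmid_reads == b.plasmid_reads
        assert (a.ligation_counts.counts == b.ligation_counts.counts).all()
        assert a.truth.equals(b.truth)
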