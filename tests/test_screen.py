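import numpy as np
import pytest

from jointscreen.counting import JointCountTable
from jointscreen.errors import EmptySampleError, JointScreenError
from jointscreen.screen import (
    CALL_DROPOUT,
    CALL_NON,
    CALL_TOXIC,
    aggregate_replicates,
    call_toxicity,
    format_ratio,
    joint_read_percentages,
    plating_fractions,
    plating_fractions_batched,
    screen_counts,
    screen_summary,
    toxicity_ratio,
)
import pandas as pd


def table(counts_by_gene, sample_id="s"):
    genes = list(counts_by_gene)
    arr = np.zeros((len(genes), 4), dtype=np.int64)
    for i, g in enumerate(genes):
        arr[i, 0] = counts_by_gene[g]
    return JointCountTable(sample_id, genes, arr)


class TestPercentages:
    def test_simple_shares(self):
        pct = joint_read_percentages(table({"A": 1, "B": 3}))
        assert pct["A"] == 25.0 and pct["B"] == 75.0

    def test_single_gene_is_100(self):
        assert joint_read_percentages(table({"A": 5}))["A"] == 100.0

    def test_sums_to_100(self):
        rng = np.random.default_rng(5)
        counts = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 500, 30))}
        counts["g0"] = max(counts["g0"], 1)
        pct = joint_read_percentages(table(counts))
        assert pct.sum() == pytest.approx(100.0, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptySampleError):
            joint_read_percentages(table({"A": 0, "B": 0}))

    def test_scale_invariance(self):
        counts = {"A": 7, "B": 13, "C": 80}
        p1 = joint_read_percentages(table(counts))
        p2 = joint_read_percentages(table({g: 17 * c for g, c in counts.items()}))
        assert np.allclose(p1, p2)


class TestToxicityRatio:
    @pytest.mark.parametrize(
        "lig,plas,expected,places",
        [
            (0.86, 0.13, 0.15, 2),  # known toxic control
            (3.36, 0.01, 0.003, 3),  # strongest depletion seen
            (2.5, 2.5, 1.0, 9),
        ],
    )
    def test_printed_precision(self, lig, plas, expected, places):
        assert round(toxicity_ratio(lig, plas), places) == expected

    def test_zero_ligation_is_dropout(self):
        assert toxicity_ratio(0.0, 0.0) is None

    def test_zero_plasmid_is_strong_depletion_not_dropout(self):
        assert toxicity_ratio(2.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(JointScreenError):
            toxicity_ratio(-1.0, 0.5)

    def test_report_precision_switches_below_0p01(self):
        assert format_ratio(0.0029761) == "0.003"
        assert format_ratio(1.8081) == "1.81"
        assert format_ratio(None) == "NA"


class TestCallToxicity:
    @pytest.mark.parametrize(
        "ratio,call",
        [(0.003, CALL_TOXIC), (1.12, CALL_NON), (0.5, CALL_TOXIC), (0.500001, CALL_NON)],
    )
    def test_threshold_inclusive(self, ratio, call):
        assert call_toxicity(ratio) == call

    def test_custom_threshold(self):
        assert call_toxicity(0.9, threshold=1.0) == CALL_TOXIC


class TestAggregateReplicates:
    def test_two_point_mean_and_sd(self):
        mean, sd = aggregate_replicates([0.30, 0.34])
        assert mean == pytest.approx(0.32)
        assert sd == pytest.approx(0.0283, abs=1e-4)

    def test_single_replicate_warns_sd_zero(self):
        with pytest.warns(UserWarning):
            mean, sd = aggregate_replicates([0.7])
        assert (mean, sd) == (0.7, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(JointScreenError):
            aggregate_replicates([])

    def test_sampling_check_normal(self):
        rng = np.random.default_rng(99)
        draws = rng.normal(1.0, 0.1, size=1000)
        mean, sd = aggregate_replicates(draws)
        assert abs(mean - 1.0) < 0.01
        assert abs(sd - 0.1) < 0.01


class TestPlating:
    def test_identity_batch(self):
        res = plating_fractions({"gX": [100, 100, 100], "g178": [100, 100, 100]})
        by = {r.gene_id: r for r in res}
        assert by["gX"].fraction == 1.0 and by["gX"].fraction_sd == 0.0
        assert by["g178"].fraction == 1.0  # control vs itself

    def test_hand_arithmetic(self):
        res = plating_fractions({"gX": [50, 60, 70], "g178": [120, 120, 120]})
        gx = {r.gene_id: r for r in res}["gX"]
        assert gx.fraction == pytest.approx(0.5)
        assert gx.fraction_sd == pytest.approx(0.0833, abs=1e-3)

    def test_missing_control_rejected(self):
        with pytest.raises(JointScreenError, match="control"):
            plating_fractions({"gX": [10]})

    def test_zero_control_rejected(self):
        with pytest.raises(JointScreenError, match="zero"):
            plating_fractions({"gX": [10], "g178": [0, 0]})

    def test_batched_table(self):
        cfu = pd.DataFrame(
            {
                "batch": [1, 1, 1, 1, 2, 2, 2, 2],
                "gene_id": ["gA", "gA", "g178", "g178", "gB", "gB", "g178", "g178"],
                "cfu": [50, 70, 100, 100, 30, 30, 200, 200],
            }
        )
        res = plating_fractions_batched(cfu)
        by = {(r.batch_id, r.gene_id): r for r in res}
        assert by[("1", "gA")].fraction == pytest.approx(0.6)
        assert by[("2", "gB")].fraction == pytest.approx(0.15)


class TestScreenCounts:
    def test_identical_arms_give_ratio_one_no_candidates(self):
        t = table({"A": 10, "B": 90})
        results = screen_counts([(t, t)])
        for r in results:
            assert r.ratio == pytest.approx(1.0)
            assert r.call == CALL_NON

    def test_depleted_gene_called(self):
        lig = table({"A": 500, "B": 500})
        plas = table({"A": 10, "B": 990})
        by = {r.gene_id: r for r in screen_counts([(lig, plas)])}
        assert by["A"].call == CALL_TOXIC
        assert by["A"].ratio == pytest.approx(0.02)
        assert by["B"].call == CALL_NON

    def test_dropout_semantics(self):
        lig = table({"A": 0, "B": 100})
        plas = table({"A": 5, "B": 95})
        by = {r.gene_id: r for r in screen_counts([(lig, plas)])}
        assert by["A"].dropout and by["A"].ratio is None
        assert by["A"].call == CALL_DROPOUT

    def test_replicate_aggregation_matches_manual(self):
        lig1, plas1 = table({"A": 50, "B": 50}), table({"A": 25, "B": 75})
        lig2, plas2 = table({"A": 40, "B": 60}), table({"A": 10, "B": 90})
        by = {r.gene_id: r for r in screen_counts([(lig1, plas1), (lig2, plas2)])}
        r1, r2 = 25 / 50, (10 / 100) / (40 / 100)
        assert by["A"].ratio == pytest.approx((r1 + r2) / 2)
        assert by["A"].ratio_sd == pytest.approx(np.std([r1, r2], ddof=1))

    def test_pool_counts_mode(self):
        lig1, plas1 = table({"A": 50, "B": 50}), table({"A": 25, "B": 75})
        lig2, plas2 = table({"A": 40, "B": 60}), table({"A": 10, "B": 90})
        by = {
            r.gene_id: r
            for r in screen_counts([(lig1, plas1), (lig2, plas2)], pool_counts=True)
        }
        assert by["A"].ratio == pytest.approx((35 / 200) / (90 / 200))

    def test_gene_order_permutation_invariant(self):
        lig = table({"A": 10, "B": 20, "C": 70})
        plas = table({"A": 5, "B": 25, "C": 70})
        res1 = {r.gene_id: r.ratio for r in screen_counts([(lig, plas)])}
        perm_l = JointCountTable("s", ["C", "A", "B"], lig.counts[[2, 0, 1]])
        perm_p = JointCountTable("s", ["C", "A", "B"], plas.counts[[2, 0, 1]])
        res2 = {r.gene_id: r.ratio for r in screen_counts([(perm_l, perm_p)])}
        assert res1 == pytest.approx(res2)


class TestSummary:
    def test_single_result(self):
        res = screen_counts([(table({"A": 5}), table({"A": 5}))])
        s = screen_summary(res)
        assert s["min_ratio"] == s["max_ratio"] == s["mean_ratio"] == 1.0
        assert s["sd_ratio"] == 0.0 and s["n_candidates"] == 0

    def test_all_dropouts_rejected(self):
        res = screen_counts([(table({"A": 0, "B": 1}), table({"A": 1, "B": 1}))])
        only_a = [r for r in res if r.gene_id == "A"]
        with pytest.raises(JointScreenError):
            screen_summary(only_a)
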