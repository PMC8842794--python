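import numpy as np
import pandas as pd
import pytest

from pertnet import diffexpr, errors, simulate
from pertnet.io import COUNTS, INTENSITY, ExpressionMatrix


def matrix_from_rows(rows: dict[str, list[float]], n_a: int, flavor=INTENSITY):
    genes = list(rows)
    n = len(next(iter(rows.values())))
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n - n_a)]
    values = pd.DataFrame([rows[g] for g in genes], index=genes, columns=samples)
    if flavor == COUNTS:
        values = values.astype(np.int64)
    groups = {s: s[0].upper() for s in samples}
    return ExpressionMatrix(values=values, group_of=groups, flavor=flavor)


class TestTTest:
    def test_identical_groups_give_null_result(self):
        em = matrix_from_rows({"g": [1, 2, 3, 1, 2, 3]}, 3)
        t = diffexpr.ttest_fold_change(em, "A", "B")
        assert t.loc["g", "statistic"] == 0
        assert t.loc["g", "p"] == 1
        assert t.loc["g", "fc"] == 1

    def test_unit_log2_shift_is_linear_fc_two(self):
        em = matrix_from_rows({"g": [5.0, 6.0, 7.0, 6.0, 7.0, 8.0]}, 3)
        t = diffexpr.ttest_fold_change(em, "A", "B")
        assert t.loc["g", "fc"] == pytest.approx(2.0)
        assert t.loc["g", "direction"] == "up"

    def test_zero_variance_unequal_means_is_degenerate_not_crash(self):
        em = matrix_from_rows({"g": [0, 0, 1, 1]}, 2)
        t = diffexpr.ttest_fold_change(em, "A", "B")
        assert bool(t.loc["g", "degenerate"])
        assert np.isnan(t.loc["g", "p"])

    def test_matches_scipy_pooled_ttest(self):
        from scipy import stats
        rng = np.random.default_rng(8)
        em = matrix_from_rows(
            {f"g{i}": list(rng.normal(8, 1, 7)) for i in range(30)}, 3
        )
        t = diffexpr.ttest_fold_change(em, "A", "B")
        a = em.values[em.samples_in_group("A")].to_numpy()
        b = em.values[em.samples_in_group("B")].to_numpy()
        ref = stats.ttest_ind(b, a, axis=1, equal_var=True)
        np.testing.assert_allclose(t["statistic"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(t["p"], ref.pvalue, rtol=1e-10)

    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(3)
        em = matrix_from_rows(
            {f"g{i}": list(rng.normal(8, 1, 6)) for i in range(10)}, 3
        )
        ab = diffexpr.ttest_fold_change(em, "A", "B")
        ba = diffexpr.ttest_fold_change(em, "B", "A")
        np.testing.assert_allclose(ab["statistic"], -ba["statistic"], rtol=1e-12)
        np.testing.assert_allclose(ab["p"], ba["p"], rtol=1e-12)


class TestCollapseProbes:
    def base(self):
        return pd.DataFrame(
            {
                "p": [0.01, 0.03, 0.5],
                "log2_fc": [np.log2(1.8), np.log2(2.5), 0.1],
                "fc": [1.8, 2.5, 2 ** 0.1],
                "statistic": [1.0, 2.0, 0.1],
                "fdr": [0.1, 0.1, 0.9],
                "direction": ["up", "up", "up"],
                "degenerate": [False] * 3,
                "is_deg": [False] * 3,
            },
            index=["p1", "p2", "p3"],
        )

    def test_most_significant_probe_survives(self):
        out = diffexpr.collapse_probes(
            self.base(), {"p1": "G", "p2": "G", "p3": "H"}
        )
        assert out.loc["G", "probe"] == "p1"
        assert out.loc["G", "p"] == 0.01

    def test_single_probe_unchanged(self):
        t = self.base().iloc[:1]
        out = diffexpr.collapse_probes(t, {"p1": "G"})
        assert len(out) == 1 and out.loc["G", "p"] == 0.01

    def test_tie_broken_by_abs_lfc_then_probe_id(self):
        t = self.base()
        t.loc["p2", "p"] = 0.01  # tie on p: p2 has larger |log2FC|
        out = diffexpr.collapse_probes(t, {"p1": "G", "p2": "G"})
        assert out.loc["G", "probe"] == "p2"
        t.loc["p2", "log2_fc"] = t.loc["p1", "log2_fc"]  # full tie
        out = diffexpr.collapse_probes(t, {"p1": "G", "p2": "G"})
        assert out.loc["G", "probe"] == "p1"

    def test_unmapped_probes_dropped(self):
        out = diffexpr.collapse_probes(self.base(), {"p1": "G"})
        assert list(out.index) == ["G"]

    def test_empty_input_empty_output(self):
        out = diffexpr.collapse_probes(self.base().iloc[:0], {})
        assert out.empty


class TestCallDegs:
    def row(self, p, fc):
        return pd.DataFrame(
            {"p": [p], "fc": [fc], "log2_fc": [np.log2(fc)],
             "statistic": [1.0], "fdr": [p], "degenerate": [False],
             "direction": ["up" if fc > 1 else "down"], "is_deg": [False]},
            index=["g"],
        )

    @pytest.mark.parametrize(
        "p,fc,expected",
        [
            (0.04, 1.6, True),
            (0.05, 1.5, True),       # thresholds inclusive
            (0.05, 1 / 1.5, True),   # symmetric down cutoff
            (0.04, 1.4, False),
            (0.051, 3.0, False),
        ],
    )
    def test_threshold_rules(self, p, fc, expected):
        out = diffexpr.call_degs(self.row(p, fc))
        assert bool(out.loc["g", "is_deg"]) is expected

    def test_bad_fc_min_rejected(self):
        with pytest.raises(errors.ParameterError):
            diffexpr.call_degs(self.row(0.01, 2.0), fc_min=0.5)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(5)
        em, _ = simulate.simulate_perturbation(n_genes=100, seed=5)
        t = diffexpr.ttest_fold_change(em, "control", "treated")
        a = diffexpr.call_degs(t)
        shuffled = t.sample(frac=1, random_state=1)
        b = diffexpr.call_degs(shuffled).loc[a.index]
        assert a["is_deg"].equals(b["is_deg"])


class TestBHFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(
            diffexpr.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        assert diffexpr.bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(diffexpr.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(errors.ParameterError):
            diffexpr.bh_fdr([0.5, 1.2])

    def test_matches_stepup_definition_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            adj = diffexpr.bh_fdr(p)
            # literal step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1
            order = np.argsort(p)
            ps = p[order]
            q = np.minimum.accumulate(
                (ps * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q, 1.0)
            np.testing.assert_allclose(adj, expected, rtol=1e-12)


class TestCountDegs:
    def test_identical_columns_give_zero_degs(self):
        em = matrix_from_rows(
            {"g1": [5, 5, 5, 5], "g2": [9, 9, 9, 9]}, 2, flavor=COUNTS
        )
        out = diffexpr.count_degs(em)
        assert out["is_deg"].sum() == 0

    def test_planted_multiplier_detected(self):
        em, _ = simulate.simulate_cohort(
            n_tumor=200, n_normal=200, n_genes=100, de_fraction=0.0,
            dispersion=0.01, seed=1, lfc_of={"GENE0007": 2.0},
        )
        out = diffexpr.count_degs(em)
        assert out.loc["GENE0007", "fdr"] <= 0.05
        assert out.loc["GENE0007", "is_deg"]
        assert out.loc["GENE0007", "direction"] == "up"

    def test_empty_matrix_empty_table(self):
        em = ExpressionMatrix(
            values=pd.DataFrame(np.empty((0, 4), dtype=np.int64),
                                columns=["a0", "a1", "b0", "b1"]),
            group_of={"a0": "A", "a1": "A", "b0": "B", "b1": "B"},
            flavor=COUNTS,
        )
        out = diffexpr.count_degs(em)
        assert out.empty

    def test_zero_count_sample_rejected(self):
        em = matrix_from_rows({"g1": [0, 3, 2, 4], "g2": [0, 1, 1, 1]}, 2,
                              flavor=COUNTS)
        with pytest.raises(errors.DataError, match="a0"):
            diffexpr.count_degs(em)

    def test_null_fpr_controlled(self):
        em, _ = simulate.simulate_cohort(
            n_tumor=30, n_normal=30, n_genes=500, de_fraction=0.0,
            dispersion=0.1, seed=9,
        )
        out = diffexpr.count_degs(em)
        assert out["is_deg"].sum() <= 5
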