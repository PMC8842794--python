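import numpy as np
import pytest

from conftest import make_deg_table
from pertnet import enrichment, errors, integrate
from pertnet.io import TFTargetMap
from pertnet.survival import CoxResult


def deg(p=0.01, lfc=1.0, direction=None, is_deg=True):
    direction = direction or ("up" if lfc > 0 else "down")
    return (p, lfc, direction, is_deg)


class TestConcordance:
    def test_same_mode_example(self):
        a = make_deg_table({"g1": deg(lfc=1), "g2": deg(lfc=-1), "g3": deg(lfc=1)})
        b = make_deg_table({"g1": deg(lfc=1), "g2": deg(lfc=1), "g4": deg(lfc=-1)})
        r = integrate.intersect_concordant(a, b, mode="same")
        assert r.common == {"g1", "g2"}
        assert r.concordant == {"g1"}
        assert r.discordant == {"g2"}

    def test_disjoint_tables_all_empty(self):
        a = make_deg_table({"g1": deg()})
        b = make_deg_table({"g2": deg()})
        r = integrate.intersect_concordant(a, b)
        assert not r.common and not r.concordant and not r.discordant

    def test_self_intersection_fully_concordant(self):
        a = make_deg_table({"g1": deg(lfc=1), "g2": deg(lfc=-2)})
        r = integrate.intersect_concordant(a, a, mode="same")
        assert r.concordant == {"g1", "g2"}
        assert r.common_down == {"g2"} and r.common_up == {"g1"}

    def test_modes_partition_the_common_set(self):
        rng = np.random.default_rng(0)
        rows_a = {f"g{i}": deg(lfc=float(rng.choice([-1, 1]))) for i in range(30)}
        rows_b = {f"g{i}": deg(lfc=float(rng.choice([-1, 1]))) for i in range(5, 40)}
        a, b = make_deg_table(rows_a), make_deg_table(rows_b)
        same = integrate.intersect_concordant(a, b, mode="same")
        rev = integrate.intersect_concordant(a, b, mode="reversal")
        assert same.concordant | same.discordant == same.common
        assert len(same.concordant) + len(same.discordant) == len(same.common)
        assert rev.concordant == same.discordant

    def test_unknown_mode_rejected(self):
        a = make_deg_table({"g1": deg()})
        with pytest.raises(errors.ParameterError):
            integrate.intersect_concordant(a, a, mode="sideways")


class TestContingency:
    def test_enumeration_example(self):
        # 2x2 [[3,1],[1,3]] -> one-sided p = (C(4,3)C(4,1)+C(4,4))/C(8,4)
        degs = [f"g{i}" for i in range(8)]
        surv = set(degs[:4])
        drug = set(degs[:3]) | {degs[4]}
        r = integrate.survival_contingency(degs, surv, drug)
        assert r.table.tolist() == [[3, 1], [1, 3]]
        assert r.p == pytest.approx(17 / 70)

    def test_saturated_drug_set_gives_p_one(self):
        degs = [f"g{i}" for i in range(6)]
        r = integrate.survival_contingency(degs, set(degs[:3]), set(degs))
        assert r.p == pytest.approx(1.0)
        assert r.warning is not None

    def test_empty_survival_set_degenerate(self):
        degs = [f"g{i}" for i in range(6)]
        r = integrate.survival_contingency(degs, set(), set(degs[:2]))
        assert r.p == pytest.approx(1.0)
        assert r.warning is not None

    def test_empty_background_rejected(self):
        with pytest.raises(errors.ParameterError):
            integrate.survival_contingency([], set(), set())

    def test_agrees_with_hypergeometric_urn(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            N = int(rng.integers(8, 30))
            degs = [f"g{i}" for i in range(N)]
            surv = set(rng.choice(degs, int(rng.integers(1, N)), replace=False))
            drug = set(rng.choice(degs, int(rng.integers(1, N)), replace=False))
            r = integrate.survival_contingency(degs, surv, drug)
            expected = enrichment.hypergeom_overrep(
                N, len(drug), len(surv), len(surv & drug)
            )
            assert r.p == pytest.approx(expected, rel=1e-9)


class TestRegulators:
    TFMAP = TFTargetMap(
        targets={"TF1": {"g1", "g2", "g3"}, "TF2": {"g2"}, "TF3": {"g7"}},
        class_of={"TF1": "TF", "TF2": "cofactor", "TF3": "TF"},
    )

    def test_ranking_by_pathway_target_count(self):
        out = integrate.rank_regulators(self.TFMAP, {"g1", "g2"})
        assert out == [("TF1", 2), ("TF2", 1), ("TF3", 0)]

    def test_empty_degs_all_zero(self):
        out = integrate.rank_regulators(self.TFMAP, set())
        assert all(c == 0 for _, c in out)

    def test_ties_broken_lexicographically(self):
        tfmap = TFTargetMap(
            targets={"B": {"g1", "g2"}, "A": {"g1", "g2"}},
            class_of={"A": "TF", "B": "TF"},
        )
        out = integrate.rank_regulators(tfmap, {"g1", "g2"})
        assert [r for r, _ in out] == ["A", "B"]


class TestNomination:
    def cox(self, gene, p=0.01, beta=0.5):
        return CoxResult(gene, beta, 0.2, beta / 0.2, p,
                         "high expression, worse survival" if beta > 0
                         else "high expression, better survival", True)

    def tables(self):
        tumor = make_deg_table({"R1": deg(lfc=1.0), "R2": deg(lfc=1.0),
                                "R3": deg(lfc=-1.0)})
        drug = make_deg_table({"R1": deg(lfc=-1.0), "R2": deg(lfc=-1.0),
                               "R3": deg(lfc=-1.0)})
        return tumor, drug

    def test_regulator_meeting_all_rules_is_retained(self):
        tumor, drug = self.tables()
        out = integrate.nominate_candidates(
            ["R1"], [self.cox("R1")], tumor, drug
        )
        assert len(out) == 1
        assert out[0].regulator == "R1"
        assert out[0].hazard_ratio > 1

    def test_high_cox_p_excluded(self):
        tumor, drug = self.tables()
        out = integrate.nominate_candidates(
            ["R2"], [self.cox("R2", p=0.2)], tumor, drug
        )
        assert out == []

    def test_wrong_directions_excluded(self):
        tumor, drug = self.tables()
        out = integrate.nominate_candidates(
            ["R3"], [self.cox("R3")], tumor, drug  # tumor-down: fails rule iii
        )
        assert out == []

    def test_protective_hazard_excluded(self):
        tumor, drug = self.tables()
        out = integrate.nominate_candidates(
            ["R1"], [self.cox("R1", beta=-0.5)], tumor, drug
        )
        assert out == []

    def test_missing_evidence_excluded_not_crash(self):
        tumor, drug = self.tables()
        out = integrate.nominate_candidates(
            ["R1", "UNKNOWN"], [self.cox("R1"), self.cox("UNKNOWN")], tumor, drug
        )
        assert [c.regulator for c in out] == ["R1"]

    def test_empty_input_empty_output(self):
        tumor, drug = self.tables()
        assert integrate.nominate_candidates([], [], tumor, drug) == []

    def test_output_order_stable_subset_of_input(self):
        tumor, drug = self.tables()
        out = integrate.nominate_candidates(
            ["R2", "R1"], [self.cox("R1"), self.cox("R2")], tumor, drug
        )
        assert [c.regulator for c in out] == ["R2", "R1"]
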