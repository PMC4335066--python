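import numpy as np
import pandas as pd
import pytest

from conetdiff import (
    ConditionNetwork,
    DesignError,
    compute_pif,
    compute_rif,
    correlation_matrix,
    rank_extreme,
)

from conftest import make_matrix


def net_from(r, condition="X", genes=None):
    genes = genes or [f"g{i}" for i in range(r.shape[0])]
    return ConditionNetwork(condition, genes, np.asarray(r, dtype=float))


class TestPif:
    def test_equal_means_give_zero(self):
        assert compute_pif(np.array([8.0]), np.array([8.0]))[0] == 0.0

    def test_hand_worked_value(self):
        # ((10+8)/2) * (10-8) = 18
        assert compute_pif(np.array([10.0]), np.array([8.0]))[0] == 18.0

    def test_swapping_conditions_negates(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(8, 2, 20), rng.normal(8, 2, 20)
        np.testing.assert_allclose(compute_pif(a, b), -compute_pif(b, a))


def rif_oracle(r_a, r_b, e_a, e_b, t_idx, genes):
    """Independent scalar per-pair evaluation of the RIF sums."""
    rif1, rif2 = [], []
    for i in range(len(genes)):
        s1 = s2 = 0.0
        n = 0
        for j in t_idx:
            if j == i:
                continue
            pif_j = ((e_a[j] + e_b[j]) / 2) * (e_a[j] - e_b[j])
            dw = r_a[i, j] - r_b[i, j]
            s1 += pif_j * dw * dw
            s2 += (e_a[j] * r_a[i, j]) ** 2 - (e_b[j] * r_b[i, j]) ** 2
            n += 1
        rif1.append(s1 / n if n else 0.0)
        rif2.append(s2 / n if n else 0.0)
    return np.array(rif1), np.array(rif2)


class TestComputeRif:
    def test_identical_conditions_zero_raw_scores(self):
        r = np.corrcoef(np.random.default_rng(1).standard_normal((6, 8)))
        e = np.random.default_rng(2).normal(8, 1, 6)
        table = compute_rif(net_from(r), net_from(r), e, e, targets=["g0", "g1"])
        np.testing.assert_allclose(table["rif1_raw"], 0.0)
        np.testing.assert_allclose(table["rif2_raw"], 0.0)

    def test_single_pair_hand_worked_example(self):
        # one regulator, one target: PIF 18, DW 1.4 -> RIF1 35.28; RIF2 65
        r_a = np.array([[1.0, 0.9], [0.9, 1.0]])
        r_b = np.array([[1.0, -0.5], [-0.5, 1.0]])
        e_a, e_b = np.array([4.0, 10.0]), np.array([4.0, 8.0])
        table = compute_rif(net_from(r_a), net_from(r_b), e_a, e_b,
                            targets=["g1"], regulators=["g0"])
        assert table.loc["g0", "rif1_raw"] == pytest.approx(35.28, rel=1e-12)
        assert table.loc["g0", "rif2_raw"] == pytest.approx(65.0, rel=1e-12)

    def test_matches_scalar_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            g = 10
            r_a = np.corrcoef(rng.standard_normal((g, 7)))
            r_b = np.corrcoef(rng.standard_normal((g, 7)))
            e_a, e_b = rng.normal(8, 1.5, g), rng.normal(8, 1.5, g)
            genes = [f"g{i}" for i in range(g)]
            t_idx = [0, 3, 4, 9]  # includes regulators that are targets
            table = compute_rif(net_from(r_a), net_from(r_b), e_a, e_b,
                                targets=[genes[j] for j in t_idx])
            ref1, ref2 = rif_oracle(r_a, r_b, e_a, e_b, t_idx, genes)
            np.testing.assert_allclose(table["rif1_raw"], ref1, rtol=1e-10)
            np.testing.assert_allclose(table["rif2_raw"], ref2, rtol=1e-10)

    def test_z_columns_standardized(self):
        rng = np.random.default_rng(9)
        g = 30
        r_a = np.corrcoef(rng.standard_normal((g, 8)))
        r_b = np.corrcoef(rng.standard_normal((g, 8)))
        table = compute_rif(net_from(r_a), net_from(r_b),
                            rng.normal(8, 1, g), rng.normal(8, 1, g),
                            targets=["g1", "g2", "g3"])
        for col in ("rif1_z", "rif2_z"):
            assert abs(table[col].mean()) < 1e-8
            assert abs(table[col].std(ddof=1) - 1.0) < 1e-8

    def test_swapping_conditions_negates_raw_scores(self, swap_pair):
        fwd, rev = swap_pair
        targets = fwd.gene_ids[:3]
        out = {}
        for m in (fwd, rev):
            lab_a, lab_b = m.conditions
            na, nb = correlation_matrix(m, lab_a), correlation_matrix(m, lab_b)
            ma, mb = m.condition_means()
            out[m.reference] = compute_rif(na, nb, ma, mb, targets=targets)
        np.testing.assert_allclose(out["WT"]["rif1_raw"], -out["null"]["rif1_raw"],
                                   rtol=1e-9)
        np.testing.assert_allclose(out["WT"]["rif2_raw"], -out["null"]["rif2_raw"],
                                   rtol=1e-9)

    def test_empty_target_set_is_a_design_error(self):
        r = np.eye(3)
        with pytest.raises(DesignError):
            compute_rif(net_from(r), net_from(r), np.zeros(3), np.zeros(3),
                        targets=[])


class TestRankExtreme:
    def table(self, z):
        return pd.DataFrame({"rif1_z": z}, index=[f"g{i}" for i in range(len(z))])

    def test_positive_and_negative_extremes(self):
        pos, neg = rank_extreme(self.table([2.0, -3.0, 0.5]), "rif1_z", 1)
        assert pos == ["g0"] and neg == ["g1"]

    def test_ties_break_by_input_order(self):
        pos, _ = rank_extreme(self.table([1.0, 2.0, 2.0]), "rif1_z", 2)
        assert pos == ["g1", "g2"]

    def test_extremes_disjoint_when_2k_fits(self):
        rng = np.random.default_rng(0)
        pos, neg = rank_extreme(self.table(rng.normal(size=20)), "rif1_z", 10)
        assert not set(pos) & set(neg)

    def test_oversized_k_truncates_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            pos, neg = rank_extreme(self.table([1.0, -1.0]), "rif1_z", 5)
        assert len(pos) == 2 and len(neg) == 2
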