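import subprocess
import shutil

import numpy as np
import pytest
from scipy import stats

from conetdiff import DesignError, differential_expression, estimate_qvalues

from conftest import make_matrix


class TestQValues:
    def test_bh_step_up_worked_example(self):
        q = estimate_qvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        for method in ("bh", "storey"):
            np.testing.assert_array_equal(
                estimate_qvalues([1.0] * 6, method=method), np.ones(6)
            )

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(size=300), rng.uniform(0, 1e-3, 60)])
        assert (estimate_qvalues(p, "storey") <= estimate_qvalues(p, "bh") + 1e-15).all()

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=250)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(estimate_qvalues(p, "bh"), expected, rtol=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            estimate_qvalues([0.5, 1.5])

    def test_q_monotone_in_p_order(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        q = estimate_qvalues(p, "storey")
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestTTest:
    def test_identical_groups_give_unit_fold_change_and_p_one(self):
        vals = np.vstack([
            np.full(10, 7.0),                      # zero variance, no difference
            np.random.default_rng(0).normal(8, 1, 10),
        ])
        table = differential_expression(make_matrix(vals), moderated=False)
        assert table["fold_change"].iloc[0] == 1.0
        assert table["p_value"].iloc[0] == 1.0
        assert table["t_stat"].iloc[0] == 0.0

    def test_fold_change_is_two_to_the_mean_difference(self):
        vals = np.vstack([
            np.array([10.0] * 5 + [9.0] * 5),
            np.random.default_rng(1).normal(8, 1, 10),  # supplies variance
        ])
        table = differential_expression(make_matrix(vals), moderated=False)
        assert table["fold_change"].iloc[0] == pytest.approx(2.0, rel=1e-12)
        assert table["direction"].iloc[0] == "Up"

    def test_pooled_t_hand_worked_example(self):
        # A=(1,2,3), B=(3,4,5): pooled sd 1, t = -2*sqrt(3/2), p ~ 0.0705 at 4 df
        vals = np.array([[1.0, 2, 3, 3, 4, 5],
                         [5.0, 7, 6, 1, 2, 0]])
        table = differential_expression(make_matrix(vals, n_a=3), moderated=False)
        assert table["t_stat"].iloc[0] == pytest.approx(-2 * np.sqrt(1.5), rel=1e-12)
        assert table["p_value"].iloc[0] == pytest.approx(0.0705, abs=2e-4)

    def test_plain_t_matches_scipy(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(8, 1, (40, 12))
        m = make_matrix(vals)
        table = differential_expression(m, moderated=False, fdr="bh")
        t_ref, p_ref = stats.ttest_ind(vals[:, :6], vals[:, 6:], axis=1)
        np.testing.assert_allclose(table["t_stat"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(table["p_value"], p_ref, rtol=1e-10)

    def test_swapping_conditions_inverts_fold_change_keeps_p(self, swap_pair):
        fwd, rev = swap_pair
        tf = differential_expression(fwd)
        tr = differential_expression(rev)
        np.testing.assert_allclose(tf["fold_change"], 1.0 / tr["fold_change"],
                                   rtol=1e-10)
        np.testing.assert_allclose(tf["p_value"], tr["p_value"], rtol=1e-10)
        np.testing.assert_allclose(tf["q_value"], tr["q_value"], rtol=1e-10)
        flipped = tf["direction"][tf["fold_change"] != 1.0]
        assert (flipped != tr["direction"][tf["fold_change"] != 1.0]).all()

    def test_condition_with_one_sample_is_a_design_error(self):
        vals = np.random.default_rng(0).normal(size=(3, 3))
        with pytest.raises(DesignError):
            differential_expression(make_matrix(vals, n_a=1))


class TestModeration:
    def test_moderated_collapses_to_plain_when_gene_variances_are_equal(self):
        # identical residual patterns => identical sample variances => the
        # empirical-Bayes prior collapses onto the (bias-corrected) common
        # variance: moderated t is exactly proportional to plain t, and the
        # factor tends to 1 as the residual df grow
        rng = np.random.default_rng(14)
        n = 50
        resid = rng.normal(0, 0.4, 2 * n)
        resid -= resid[:n].mean() if False else 0.0
        shifts = np.linspace(7, 9, 15)[:, None]
        deltas = np.linspace(-1, 1, 15)[:, None]
        vals = shifts + resid[None, :]
        vals[:, :n] += deltas
        m = make_matrix(vals)
        t_mod = differential_expression(m, moderated=True)["t_stat"].to_numpy()
        t_plain = differential_expression(m, moderated=False)["t_stat"].to_numpy()
        ratio = t_mod[np.abs(t_plain) > 1e-9] / t_plain[np.abs(t_plain) > 1e-9]
        # exactly proportional, and within 1% of identity at ~100 df
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)
        np.testing.assert_allclose(t_mod, t_plain, rtol=1e-2)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_moderated_t_matches_limma(self, tmp_path):
        rng = np.random.default_rng(5)
        g, n = 60, 5
        sd = rng.uniform(0.1, 0.6, g)[:, None]
        vals = rng.normal(8, 1.5, g)[:, None] + rng.normal(0, sd, (g, 2 * n))
        vals[:10, :n] += 1.0
        m = make_matrix(vals)
        m.data.to_csv(tmp_path / "mat.tsv", sep="\t")
        script = tmp_path / "cmp.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{tmp_path}/mat.tsv", row.names=1))\n'
            'grp <- ifelse(substr(colnames(x),1,1)=="W",1,0)\n'
            'fit <- eBayes(lmFit(x, cbind(Int=1, A=grp)))\n'
            'write.table(data.frame(t=fit$t[,"A"], p=fit$p.value[,"A"]),\n'
            f'            "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        import pandas as pd

        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        mine = differential_expression(m, moderated=True, fdr="bh")
        np.testing.assert_allclose(mine["t_stat"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(mine["p_value"], ref["p"], rtol=1e-8)

    def test_null_data_discovery_fraction_is_controlled(self):
        # Monte-Carlo over seeds: without planted effects, q < 0.05 calls ~ none
        fracs = []
        for seed in range(5):
            vals = np.random.default_rng(seed).normal(8, 0.3, (150, 10))
            table = differential_expression(make_matrix(vals))
            fracs.append(table["is_de"].mean())
        assert np.mean(fracs) <= 0.05
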