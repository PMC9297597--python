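import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from relq import stats
from relq.errors import UnknownControlError
from relq.plate_io import Experiment


def replicate_frame(obs):
    """obs: list of (sample, target, [dcq values])."""
    rows = []
    for sample, target, values in obs:
        for i, v in enumerate(values):
            rows.append(
                {
                    "plate": "p",
                    "sample": sample,
                    "target": target,
                    "replicate": i + 1,
                    "delta_cq": v,
                }
            )
    return pd.DataFrame(rows)


def experiment_frame(wells):
    rows = [
        {
            "plate": "p",
            "well": f"A{i + 1}",
            "sample": s,
            "target": t,
            "cq": cq,
            "replicate": r,
        }
        for i, (s, t, r, cq) in enumerate(wells)
    ]
    return Experiment(pd.DataFrame(rows))


class TestPerReplicateDeltaCq:
    def test_pairs_replicates_with_reference(self):
        exp = experiment_frame(
            [
                ("C", "g", 1, 22.7),
                ("C", "g", 2, 22.8),
                ("C", "refG", 1, 20.0),
                ("C", "refG", 2, 20.0),
            ]
        )
        out = stats.per_replicate_delta_cq(exp, ["refG"])
        g = out[out["target"] == "g"].sort_values("replicate")
        assert list(g["delta_cq"]) == pytest.approx([2.7, 2.8])

    def test_removed_reference_replicate_falls_back_to_mean(self):
        exp = experiment_frame(
            [
                ("C", "g", 1, 22.0),
                ("C", "g", 2, 22.0),
                ("C", "g", 3, 22.0),
                ("C", "refG", 1, 19.9),
                ("C", "refG", 2, 20.1),
                ("C", "refG", 3, np.nan),
            ]
        )
        out = stats.per_replicate_delta_cq(exp, ["refG"])
        g = out[out["target"] == "g"].set_index("replicate")["delta_cq"]
        assert g[1] == pytest.approx(22.0 - 19.9)
        assert g[2] == pytest.approx(22.0 - 20.1)
        assert g[3] == pytest.approx(22.0 - 20.0)  # fallback: replicate mean

    def test_fully_removed_group_absent(self):
        exp = experiment_frame(
            [
                ("C", "g", 1, np.nan),
                ("C", "refG", 1, 20.0),
            ]
        )
        out = stats.per_replicate_delta_cq(exp, ["refG"])
        assert "g" not in set(out["target"])


class TestFitGeneModels:
    def test_hand_ols_example(self):
        frame = replicate_frame(
            [("T", "g", [4.0, 4.2, 3.8]), ("C", "g", [2.0, 2.1, 1.9])]
        )
        fit = stats.fit_gene_models(frame, "T", "C")[0]
        assert fit.effect == pytest.approx(2.0)
        assert fit.residual_sd**2 == pytest.approx(0.025)
        assert fit.se == pytest.approx(0.1291, abs=1e-4)
        assert fit.effect / fit.se == pytest.approx(15.49, abs=0.01)
        assert fit.residual_df == 4

    def test_identical_groups_zero_effect(self):
        frame = replicate_frame(
            [("T", "g", [2.0, 2.1, 1.9]), ("C", "g", [2.0, 2.1, 1.9])]
        )
        fit = stats.fit_gene_models(frame, "T", "C")[0]
        assert fit.effect == 0.0

    def test_group_swap_flips_sign(self):
        frame = replicate_frame(
            [("T", "g", [4.0, 4.2, 3.8]), ("C", "g", [2.0, 2.1, 1.9])]
        )
        f1 = stats.fit_gene_models(frame, "T", "C")[0]
        f2 = stats.fit_gene_models(frame, "C", "T")[0]
        assert f1.effect == -f2.effect
        assert f1.se == f2.se

    def test_single_replicate_contributes_no_df(self):
        frame = replicate_frame([("T", "g", [4.0]), ("C", "g", [2.0, 2.1, 1.9])])
        fit = stats.fit_gene_models(frame, "T", "C")[0]
        assert fit.residual_df == 2


class TestModeration:
    def make_fits(self, variances, df=4, n=3):
        return [
            stats.GeneFit(f"g{i}", 1.0, math.sqrt(v), df, n, n)
            for i, v in enumerate(variances)
        ]

    def test_equal_variances_unchanged(self):
        fits = self.make_fits([0.04] * 6)
        _, mod_var, _ = stats.moderate_variances(fits)
        assert np.allclose(mod_var, 0.04)

    def test_d0_zero_recovers_ordinary(self):
        fits = self.make_fits([0.01, 0.05, 0.2, 0.4])
        params = stats.ModerationParams(prior_df=0.0, prior_var=1.0)
        _, mod_var, mod_df = stats.moderate_variances(fits, params)
        assert np.allclose(mod_var, [0.01, 0.05, 0.2, 0.4])
        assert np.allclose(mod_df, 4.0)

    def test_d0_infinite_complete_shrinkage(self):
        fits = self.make_fits([0.01, 0.05, 0.2, 0.4])
        params = stats.ModerationParams(prior_df=math.inf, prior_var=0.1)
        _, mod_var, _ = stats.moderate_variances(fits, params)
        assert np.allclose(mod_var, 0.1)

    def test_moderated_between_own_and_prior(self):
        rng = np.random.default_rng(17)
        variances = np.exp(rng.normal(-3, 1.2, 7))
        fits = self.make_fits(list(variances))
        params, mod_var, _ = stats.moderate_variances(fits)
        s0 = params.prior_var
        for v, m in zip(variances, mod_var):
            lo, hi = min(v, s0), max(v, s0)
            assert lo - 1e-12 <= m <= hi + 1e-12

    def test_matches_limma_squeezevar(self, tmp_path):
        """Hyperparameters and posterior variances agree with the
        Bioconductor reference implementation."""
        rng = np.random.default_rng(42)
        s2 = np.exp(rng.normal(-3, 1.5, 12))
        dfs = np.full(12, 4.0)
        infile = tmp_path / "s2.txt"
        np.savetxt(infile, np.c_[s2, dfs])
        outfile = tmp_path / "out.txt"
        script = tmp_path / "squeeze.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"m <- as.matrix(read.table('{infile}'))\n"
            "out <- squeezeVar(m[,1], m[,2])\n"
            "res <- c(out$df.prior, out$var.prior, out$var.post)\n"
            f"write(format(res, digits=15), '{outfile}', ncolumns=1)\n"
        )
        subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True
        )
        ref = np.loadtxt(outfile)
        params = stats.estimate_moderation(s2, dfs)
        d0, s0 = params.prior_df, params.prior_var
        assert d0 == pytest.approx(ref[0], rel=1e-6)
        assert s0 == pytest.approx(ref[1], rel=1e-6)
        mod = (d0 * s0 + dfs * s2) / (d0 + dfs)
        assert np.allclose(mod, ref[2:], rtol=1e-6)


class TestAdjustPvalues:
    def test_bh_step_up(self):
        out = stats.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        assert np.allclose(out, 0.04)

    def test_bonferroni_m1_identity(self):
        assert stats.adjust_pvalues([0.01], "bonferroni")[0] == 0.01

    def test_holm_step_down(self):
        assert np.allclose(stats.adjust_pvalues([0.01, 0.04], "holm"), [0.02, 0.04])

    def test_domain_error(self):
        with pytest.raises(ValueError):
            stats.adjust_pvalues([0.5, 1.2], "BH")

    @pytest.mark.parametrize(
        "method, sm_method",
        [("BH", "fdr_bh"), ("bonferroni", "bonferroni"), ("holm", "holm")],
    )
    def test_against_statsmodels(self, method, sm_method):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(99)
        for _ in range(300):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            expected = multipletests(p, method=sm_method)[1]
            assert np.max(np.abs(stats.adjust_pvalues(p, method) - expected)) < 1e-12

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=25),
        st.sampled_from(["BH", "bonferroni", "holm"]),
    )
    def test_bounds_and_order_preserved(self, p, method):
        adj = stats.adjust_pvalues(p, method)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        # BH output sorted by raw p is monotone non-decreasing
        if method == "BH":
            order = np.argsort(p, kind="stable")
            assert (np.diff(adj[order]) >= -1e-15).all()


class TestRunTests:
    def test_upregulated_genes_have_negative_t(self, sp_experiment):
        out = stats.run_tests(sp_experiment, ["refG"], "C", moderation=False)
        goi = out[out["target"] != "refG"]
        assert (goi["t"] < 0).all()  # 4-fold induction lowers dCq
        assert (goi["p_value"] < 0.05).all()

    def test_two_sided_p_from_t(self, sp_experiment):
        out = stats.run_tests(sp_experiment, ["refG"], "C", moderation=False)
        for row in out.itertuples():
            expected = 2 * (1 - sps.t.cdf(abs(row.t), row.df))
            assert row.p_value == pytest.approx(expected, abs=1e-12)

    def test_moderated_vs_ordinary_interval(self, sp_experiment):
        mod = stats.run_tests(sp_experiment, ["refG"], "C", moderation=True)
        ord_ = stats.run_tests(sp_experiment, ["refG"], "C", moderation=False)
        merged = mod.merge(ord_, on=["sample", "target"], suffixes=("_m", "_o"))
        fits = stats.fit_gene_models(
            stats.per_replicate_delta_cq(sp_experiment, ["refG"]), "S1", "C"
        )
        params, _, _ = stats.moderate_variances(
            [f for f in fits if f.residual_df >= 1]
        )
        s0 = math.sqrt(params.prior_var)
        for row, fit in zip(merged.itertuples(), fits):
            t_own = row.t_o
            se0 = s0 * math.sqrt(1 / fit.n_sample + 1 / fit.n_control)
            t_prior = fit.effect / se0
            lo, hi = sorted((abs(t_own), abs(t_prior)))
            assert lo - 1e-9 <= abs(row.t_m) <= hi + 1e-9

    def test_adjustment_scope_is_per_comparison(self, sp_experiment):
        out = stats.run_tests(sp_experiment, ["refG"], "C")
        m = len(out)
        # Bonferroni bound: adj <= p * m within one comparison
        bonf = stats.run_tests(sp_experiment, ["refG"], "C", method="bonferroni")
        assert np.allclose(
            bonf["adj_p_value"], np.minimum(1.0, bonf["p_value"] * m)
        )

    def test_unknown_control_raises(self, sp_experiment):
        with pytest.raises(UnknownControlError):
            stats.run_tests(sp_experiment, ["refG"], "NOPE")

    def test_stars_match_thresholds(self, sp_experiment):
        out = stats.run_tests(sp_experiment, ["refG"], "C")
        for row in out.itertuples():
            p = row.adj_p_value
            expected = (
                "****" if p < 1e-4 else "***" if p < 1e-3
                else "**" if p < 0.01 else "*" if p < 0.05 else ""
            )
            assert row.significance == expected
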