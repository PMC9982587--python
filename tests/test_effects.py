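"""Effect-size maps: residualization, t-tests, Cohen's d, FDR, PCA summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from braintx import effects, synthetic


def _table(case, ctrl, region="R001"):
    n1, n2 = len(case), len(ctrl)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n1 + n2)],
            "group": ["case"] * n1 + ["control"] * n2,
            region: list(case) + list(ctrl),
        }
    )


class TestCaseControlT:
    def test_hand_computed_example(self):
        # {1,2,3} vs {4,5,6}: pooled sd = 1, se = 0.8165, t = -3/0.8165
        out = effects.case_control_t(_table([1, 2, 3], [4, 5, 6]))
        assert out.loc["R001", "t"] == pytest.approx(-3.674, abs=1e-3)
        assert out.loc["R001", "p"] == pytest.approx(0.0214, abs=5e-4)

    def test_identical_means_give_t_zero_p_one(self):
        out = effects.case_control_t(_table([1, 2, 3], [3, 1, 2]))
        assert out.loc["R001", "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["R001", "p"] == pytest.approx(1.0)

    def test_label_swap_flips_sign_exactly(self, rng):
        case = rng.standard_normal(10)
        ctrl = rng.standard_normal(12)
        a = effects.case_control_t(_table(case, ctrl))
        b = effects.case_control_t(_table(ctrl, case))
        # swapping which group is 'case' negates t for equal group sizes;
        # with unequal sizes the roles swap too, so rebuild symmetric case
        assert a.loc["R001", "t"] != 0
        c = effects.case_control_t(_table(case[:10], ctrl[:10]))
        d = effects.case_control_t(_table(ctrl[:10], case[:10]))
        assert c.loc["R001", "t"] == pytest.approx(-d.loc["R001", "t"], rel=1e-12)

    def test_zero_variance_region_named_in_error(self):
        with pytest.raises(ValueError, match="R001"):
            effects.case_control_t(_table([1, 1, 1], [1, 1, 1]))


class TestTToD:
    def test_known_conversion(self):
        assert effects.t_to_d(2.0, 50, 50) == pytest.approx(0.4)

    def test_zero_maps_to_zero(self):
        assert effects.t_to_d(0.0, 10, 12) == 0.0

    def test_planted_d_recovered_at_study_scale(self):
        # single region, planted standardized difference of 0.2 at n ~ 848/794
        rng = np.random.default_rng(0)
        ds = []
        for s in range(20):
            n1, n2 = 848, 794
            case = rng.standard_normal(n1) + 0.2
            ctrl = rng.standard_normal(n2)
            out = effects.case_control_t(_table(case, ctrl))
            ds.append(effects.t_to_d(out.loc["R001", "t"], n1, n2))
        assert np.mean(ds) == pytest.approx(0.2, abs=0.05)


class TestFdrBh:
    def test_step_up_thresholds_all_significant(self):
        q, sig = effects.fdr_bh([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert sig.all()

    def test_all_ones_none_significant(self):
        q, sig = effects.fdr_bh([1.0, 1.0, 1.0])
        assert not sig.any()
        assert np.allclose(q, 1.0)

    @given(st.permutations(list(range(8))))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_q_values_invariant_to_input_order(self, perm):
        p = np.array([0.001, 0.01, 0.04, 0.2, 0.5, 0.8, 0.9, 1.0])
        q0, _ = effects.fdr_bh(p)
        qp, _ = effects.fdr_bh(p[perm])
        assert np.allclose(qp, q0[perm])


class TestResidualize:
    def test_residuals_orthogonal_to_covariates(self, small_subjects):
        tables, _ = small_subjects
        tab = tables["ALFF"]
        res = effects.residualize(tab)
        regions = [c for c in tab.columns if c.startswith("R")]
        for cov in effects.COVARIATES:
            corrs = [
                abs(np.corrcoef(res[r], res[cov].astype(float))[0, 1])
                for r in regions[:10]
            ]
            assert max(corrs) < 1e-8

    def test_planted_age_effect_removed(self, small_subjects):
        tables, _ = small_subjects
        tab = tables["GMV"]
        regions = [c for c in tab.columns if c.startswith("R")]
        raw = [abs(np.corrcoef(tab[r], tab["motion"])[0, 1]) for r in regions]
        res = effects.residualize(tab)
        cleaned = [abs(np.corrcoef(res[r], res["motion"])[0, 1]) for r in regions]
        assert np.mean(cleaned) < np.mean(raw)
        assert max(cleaned) < 1e-8

    def test_null_covariates_leave_t_essentially_unchanged(self):
        gradient = pd.Series(
            np.random.default_rng(8).standard_normal(30),
            index=synthetic.region_ids(30),
        )
        gradient = (gradient - gradient.mean()) / gradient.std(ddof=0)
        betas = {k: 0.0 for k in synthetic.DEFAULT_COVARIATE_BETAS}
        tables, _ = synthetic.gen_subjects(
            150, 150, gradient, covariate_betas=betas, seed=2
        )
        tab = tables["ReHo"]
        t_raw = effects.case_control_t(tab)["t"]
        t_res = effects.case_control_t(effects.residualize(tab))["t"]
        assert np.corrcoef(t_raw, t_res)[0, 1] > 0.995
        assert np.max(np.abs(t_raw - t_res)) < 0.3

    def test_rank_deficient_design_names_offenders(self, small_subjects):
        tables, _ = small_subjects
        tab = tables["ALFF"].copy()
        tab["education"] = 2 * tab["age"]  # collinear pair
        with pytest.raises(ValueError, match="rank-deficient"):
            effects.residualize(tab)


class TestPc1OfEffects:
    def test_three_identical_maps(self, rng):
        m = rng.standard_normal(50)
        maps = pd.DataFrame({"a": m, "b": m, "c": m})
        pc = effects.pc1_of_effects(maps)
        assert pc.variance_explained == pytest.approx(1.0)
        z = (m - m.mean()) / m.std(ddof=0)
        np.testing.assert_allclose(pc.scores, z, atol=1e-8)

    def test_scores_are_z_scored_and_positively_aligned(self, rng):
        maps = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        shared = rng.standard_normal(80)
        maps = maps.add(shared, axis=0)
        pc = effects.pc1_of_effects(maps)
        assert pc.scores.mean() == pytest.approx(0, abs=1e-10)
        assert pc.scores.std(ddof=0) == pytest.approx(1, abs=1e-10)
        z = (maps - maps.mean()) / maps.std(ddof=0)
        assert np.corrcoef(pc.scores, z.mean(axis=1))[0, 1] > 0

    def test_orthogonal_maps_variance_explained_near_third(self):
        rng = np.random.default_rng(1)
        maps = pd.DataFrame(rng.standard_normal((3000, 3)), columns=list("abc"))
        pc = effects.pc1_of_effects(maps)
        assert 0.30 <= pc.variance_explained <= 0.40

    def test_correlated_maps_variance_explained_in_band(self):
        # pairwise population correlation ~0.57 -> PC1 explains (1+2*0.57)/3
        rng = np.random.default_rng(2)
        shared = rng.standard_normal(5000)
        w = np.sqrt(0.57)
        maps = pd.DataFrame(
            {
                k: w * shared + np.sqrt(1 - w**2) * rng.standard_normal(5000)
                for k in "abc"
            }
        )
        pc = effects.pc1_of_effects(maps)
        assert 0.6 <= pc.variance_explained <= 0.8

    def test_constant_column_rejected(self, rng):
        maps = pd.DataFrame({"a": rng.standard_normal(20), "b": np.ones(20)})
        with pytest.raises(ValueError):
            effects.pc1_of_effects(maps)


class TestPc1OfExpression:
    def test_rank_one_matrix_fully_explained(self):
        g = np.linspace(-2, 2, 30)
        X = pd.DataFrame(
            np.outer(g, [1.0, -0.5, 2.0, 0.3]),
            index=synthetic.region_ids(30),
            columns=list("abcd"),
        )
        pc = effects.pc1_of_expression(X)
        assert pc.variance_explained == pytest.approx(1.0)
        gz = (g - g.mean()) / g.std(ddof=0)
        assert abs(np.corrcoef(pc.scores, gz)[0, 1]) == pytest.approx(1.0)

    def test_duplicating_gene_columns_leaves_scores_unchanged(self):
        X, _ = synthetic.gen_expression(40, 20, 10, seed=3)
        a = effects.pc1_of_expression(X)
        dup = pd.concat([X, X.add_suffix("_copy")], axis=1)
        b = effects.pc1_of_expression(dup)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-8)

    def test_zero_variance_genes_dropped(self):
        X, _ = synthetic.gen_expression(30, 10, 5, seed=4)
        X["flat"] = 1.0
        pc = effects.pc1_of_expression(X)
        assert "flat" not in pc.loadings.index

    def test_sign_convention_reproducible_across_seeds(self):
        # positive-mean loadings orient genePC1 with the planted gradient
        from scipy.stats import spearmanr

        signs = []
        for s in range(10):
            X, truth = synthetic.gen_expression(100, 400, 100, seed=s)
            pc = effects.pc1_of_expression(X)
            signs.append(np.sign(spearmanr(pc.scores, truth.gradient)[0]))
        assert all(s == 1 for s in signs)

    def test_d_and_t_sign_agreement(self, small_subjects):
        tables, _ = small_subjects
        out = effects.effect_size_map(tables["fALFF"], "fALFF")
        nz = out[out["t"] != 0]
        assert (np.sign(nz["d"]) == np.sign(nz["t"])).all()
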