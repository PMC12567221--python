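"""Preprocessing, PCA, OPLS-DA, differential screening and reversal detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import silhouette_score

from herbnet import metabolomics as mx
from herbnet.simulate import gen_metabolomics


def _matrix(values, groups, mets=None):
    values = np.asarray(values, dtype=float)
    mets = mets or [f"M{j}" for j in range(values.shape[1])]
    idx = [f"s{i}" for i in range(values.shape[0])]
    return mx.IntensityMatrix(
        pd.DataFrame(values, index=idx, columns=mets),
        pd.Series(groups, index=idx),
    )


def _separable_fixture(seed=0, n=20, p=20, noise_sd=0.2):
    """One metabolite carries the class code exactly; the rest trace noise."""
    rng = np.random.default_rng(seed)
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    x = rng.normal(scale=noise_sd, size=(n, p))
    x[:, 0] = np.where(y == "a", -1.0, 1.0)
    return x - x.mean(axis=0), y


class TestPreprocess:
    def test_unit_variance_scaling(self, planted_metabolomics):
        im, _ = planted_metabolomics
        out, meta = mx.preprocess(im)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-10)
        assert meta["dropped"] == []

    def test_no_log_no_scaling_is_centering(self):
        im = _matrix([[1, 2], [3, 6], [5, 4]], ["a", "a", "b"])
        out, _ = mx.preprocess(im, log_transform=False, scaling="none")
        expected = im.intensities - im.intensities.mean(axis=0)
        assert np.allclose(out, expected)

    def test_all_zero_column_dropped_and_named(self):
        im = _matrix([[1, 0], [3, 0], [5, 0]], ["a", "a", "b"], ["keep", "zero"])
        out, meta = mx.preprocess(im)
        assert "zero" not in out.columns
        assert meta["dropped"] == ["zero"]

    def test_constant_column_dropped_under_unit_variance(self):
        im = _matrix([[1, 7], [3, 7], [5, 7]], ["a", "a", "b"], ["keep", "const"])
        with pytest.warns(UserWarning, match="zero-variance"):
            out, meta = mx.preprocess(im)
        assert "const" in meta["dropped"]
        assert list(out.columns) == ["keep"]

    def test_zeros_replaced_by_half_minimum_before_log(self):
        im = _matrix([[0, 1], [4, 1], [8, 1]], ["a", "a", "b"], ["m", "c"])
        out, _ = mx.preprocess(im, scaling="none")
        # the zero becomes 2.0 (half of 4), then log and centering apply
        logged = np.log([2.0, 4.0, 8.0])
        assert np.allclose(out["m"], logged - logged.mean())


class TestPCA:
    def test_rank_one_data_single_component(self):
        base = np.outer([1.0, 2.0, 3.0, 4.0], [0.5, -1.0, 2.0])
        centered = base - base.mean(axis=0)
        _, _, evr = mx.pca(centered, 1)
        assert evr[0] == pytest.approx(1.0)

    def test_explained_variance_sums_to_one_at_full_rank(self, rng):
        x = rng.normal(size=(10, 4))
        x -= x.mean(axis=0)
        _, loadings, evr = mx.pca(x, 4)
        assert evr.sum() == pytest.approx(1.0)
        assert np.allclose(loadings.T @ loadings, np.eye(4), atol=1e-10)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            mx.pca(rng.normal(size=(5, 3)), 5)

    def test_separated_groups_split_on_first_component(self, rng):
        labels = np.array([0] * 10 + [1] * 10)
        x = rng.normal(size=(20, 15))
        x[labels == 1, :3] += 5.0
        x -= x.mean(axis=0)
        scores, _, _ = mx.pca(x, 2)
        assert silhouette_score(scores[:, :1], labels) > 0.5


class TestOPLSDA:
    def test_noiseless_separable_fit_and_cv(self):
        x, y = _separable_fixture()
        res = mx.OPLSDA(x, y, n_ortho=1).fit(cv_folds=7, seed=0)
        assert res.r2y > 0.99
        assert res.q2 > 0.9

    def test_vip_normalisation_identity(self):
        x, y = _separable_fixture(seed=3)
        res = mx.oplsda(pd.DataFrame(x), y, n_ortho=1, seed=1)
        assert np.mean(res.vip**2) == pytest.approx(1.0, abs=1e-8)

    def test_predictive_scores_orthogonal_to_orthogonal_scores(self):
        x, y = _separable_fixture(seed=4, noise_sd=1.0)
        res = mx.OPLSDA(x, y, n_ortho=2).fit(cv_folds=5, seed=0)
        for j in range(res.orthogonal_scores.shape[1]):
            dot = res.predictive_scores @ res.orthogonal_scores[:, j]
            assert abs(dot) < 1e-8

    def test_r2y_in_unit_interval_and_bounds_q2(self):
        for seed in range(3):
            im, _ = gen_metabolomics(n_per_group=8, n_metabolites=40, seed=seed)
            sub = im.subset(["control", "model"])
            proc, _ = mx.preprocess(sub)
            res = mx.oplsda(proc, sub.groups.tolist(), seed=seed)
            assert 0.0 <= res.r2y <= 1.0
            assert res.q2 <= res.r2y  # regression guard on synthetic fixtures

    def test_without_orthogonal_components_reduces_to_pls1(self):
        x, y = _separable_fixture(seed=5, noise_sd=1.0)
        res = mx.OPLSDA(x, y, n_ortho=0).fit(cv_folds=2, seed=0)
        ynum = np.where(y == "a", -1.0, 1.0)
        sk = PLSRegression(n_components=1, scale=False).fit(x, ynum - ynum.mean())
        t_sk = sk.x_scores_[:, 0]
        t_sk *= np.sign(t_sk @ res.predictive_scores)
        mine = res.predictive_scores / np.linalg.norm(res.predictive_scores)
        ref = t_sk / np.linalg.norm(t_sk)
        assert np.allclose(mine, ref, atol=1e-8)

    def test_label_permutation_destroys_q2(self):
        x, y = _separable_fixture(seed=6)
        res = mx.OPLSDA(x, y, n_ortho=1).fit(cv_folds=7, seed=0)
        perm_q2 = res.permutation_test(n_permutations=20, seed=1)
        assert np.median(perm_q2) < 0.1
        assert np.median(perm_q2) < res.q2

    def test_single_class_rejected(self):
        x, _ = _separable_fixture()
        with pytest.raises(ValueError):
            mx.OPLSDA(x, ["a"] * x.shape[0])

    def test_small_group_reduces_folds_with_warning(self):
        x, y = _separable_fixture(n=8)
        with pytest.warns(UserWarning, match="reducing cv_folds"):
            res = mx.OPLSDA(x, y, n_ortho=0).fit(cv_folds=7, seed=0)
        assert res.cv_folds == 4

    def test_summary_reports_key_quantities(self):
        x, y = _separable_fixture()
        res = mx.OPLSDA(x, y).fit(seed=0)
        text = res.summary()
        assert "R2Y" in text and "Q2" in text and "VIP" in text


class TestScreenDifferential:
    def test_planted_markers_recovered(self, planted_metabolomics):
        im, truth = planted_metabolomics
        results = mx.screen_differential(im, "control", "model", seed=0)
        flagged = {r.metabolite_id for r in results if r.significant}
        assert truth.differential_metabolites["model_vs_control"] <= flagged

    def test_significance_rule_is_strict_conjunction(self, planted_metabolomics):
        im, _ = planted_metabolomics
        results = mx.screen_differential(im, "control", "model", seed=0)
        for r in results:
            assert r.significant == (r.vip > 1.0 and r.p < 0.05)
        # raising the VIP threshold to the maximum observed VIP (strict >)
        # must clear every flag
        top_vip = max(r.vip for r in results)
        none = mx.screen_differential(
            im, "control", "model", vip_threshold=top_vip, seed=0
        )
        assert not any(r.significant for r in none)

    def test_direction_matches_planted_shift(self, planted_metabolomics):
        im, truth = planted_metabolomics
        results = {
            r.metabolite_id: r
            for r in mx.screen_differential(im, "control", "model", seed=0)
        }
        for met, direction in truth.directions["model_vs_control"].items():
            assert results[met].direction == direction

    def test_every_metabolite_reported(self, planted_metabolomics):
        im, _ = planted_metabolomics
        results = mx.screen_differential(im, "control", "model", seed=0)
        assert [r.metabolite_id for r in results] == im.metabolites

    def test_too_few_samples_rejected(self):
        im = _matrix(np.ones((5, 3)) + np.arange(15).reshape(5, 3),
                     ["a", "a", "b", "b", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            mx.screen_differential(im, "a", "b", seed=0)


class TestThreeGroupCompare:
    def test_dunn_hand_oracle(self):
        # groups [1,2,3], [4,5,6], [7,8,9]: ranks 1..9, mean ranks 2/5/8,
        # se = sqrt(7.5 * 2/3); z_ab = -1.3416408, z_ac = -2.6832816;
        # BH over the three pairs computed by hand
        im = _matrix(
            np.exp(np.array([1, 2, 3, 4, 5, 6, 7, 8, 9.0])[:, None]),
            ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            ["m1"],
        )
        out = mx.three_group_compare(im)
        assert out.loc["m1", "p_a_b"] == pytest.approx(0.1797124949, abs=1e-9)
        assert out.loc["m1", "p_a_c"] == pytest.approx(0.0218710743, abs=1e-9)
        assert out.loc["m1", "p_b_c"] == pytest.approx(0.1797124949, abs=1e-9)
        assert not out.loc["m1", "degenerate"]

    def test_single_shifted_group_flags_its_two_pairs(self, rng):
        base = rng.normal(0.0, 0.1, size=(18, 1))
        base[12:] += 5.0  # third group shifted
        im = _matrix(np.exp(base), ["control"] * 6 + ["model"] * 6 + ["treatment"] * 6)
        out = mx.three_group_compare(im)
        row = out.iloc[0]
        assert row["p_control_treatment"] < 0.05
        assert row["p_model_treatment"] < 0.05
        assert row["p_control_model"] >= 0.05

    def test_constant_metabolite_flagged_degenerate(self):
        values = np.column_stack([np.full(9, 3.0), np.arange(1.0, 10.0)])
        im = _matrix(np.exp(values), ["a"] * 3 + ["b"] * 3 + ["c"] * 3, ["const", "var"])
        out = mx.three_group_compare(im)
        assert out.loc["const", "degenerate"]
        assert out.loc["const", "anova_p"] == 1.0
        assert not out.loc["var", "degenerate"]

    def test_wrong_group_count_rejected(self):
        im = _matrix(np.ones((6, 2)) + np.arange(12).reshape(6, 2), ["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="three groups"):
            mx.three_group_compare(im)


class TestVennAndReversal:
    @staticmethod
    def _diff(met, sig, direction=1, vip=2.0, p=0.01):
        return mx.DifferentialResult(met, vip if sig else 0.5,
                                     p if sig else 0.5, direction, sig)

    def test_venn_partition(self):
        mc = [self._diff(m, m in "abc") for m in "abcd"]
        mt = [self._diff(m, m in "bcd") for m in "abcd"]
        assert mx.venn_differential(mc, mt) == {"only_mc": 1, "only_mt": 1, "both": 2}

    def test_disjoint_sets_share_nothing(self):
        mc = [self._diff("a", True), self._diff("b", False)]
        mt = [self._diff("a", False), self._diff("b", True)]
        assert mx.venn_differential(mc, mt)["both"] == 0

    def test_opposite_directions_detected(self):
        mc = [self._diff("a", True, +1), self._diff("b", True, +1)]
        mt = [self._diff("a", True, -1), self._diff("b", True, +1)]
        out = mx.find_reversed(mc, mt)
        assert [r.metabolite_id for r in out] == ["a"]
        assert out[0].direction_mc == -out[0].direction_mt

    def test_same_sign_not_a_reversal(self):
        mc = [self._diff("a", True, +1)]
        mt = [self._diff("a", True, +1)]
        assert mx.find_reversed(mc, mt) == []

    def test_no_significant_metabolites(self):
        mc = [self._diff("a", False)]
        mt = [self._diff("a", False)]
        assert mx.find_reversed(mc, mt) == []

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            mx.find_reversed([self._diff("a", True)], [self._diff("b", True)])

    def test_planted_reversals_recovered_exactly(self, planted_metabolomics):
        im, truth = planted_metabolomics
        mc = mx.screen_differential(im, "control", "model", seed=0)
        mt = mx.screen_differential(im, "model", "treatment", seed=0)
        rev = {r.metabolite_id for r in mx.find_reversed(mc, mt)}
        assert rev == truth.reversed_metabolites


class TestIntensityMatrix:
    def test_tsv_round_trip(self, tmp_path, planted_metabolomics):
        im, _ = planted_metabolomics
        path = tmp_path / "intensities.tsv"
        im.to_tsv(path)
        back = mx.IntensityMatrix.from_tsv(path)
        assert np.allclose(back.intensities, im.intensities)
        assert (back.groups == im.groups).all()

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[-1.0, 2.0]], ["a"])

    def test_missing_group_label_rejected(self):
        df = pd.DataFrame([[1.0]], index=["s0"], columns=["m"])
        with pytest.raises(ValueError):
            mx.IntensityMatrix(df, pd.Series(dtype=object))
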