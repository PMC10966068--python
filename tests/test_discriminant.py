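import numpy as np
import pandas as pd
import pytest

import asymkit
from asymkit.discriminant import (
    _direction,
    bootstrap_significance,
    cohens_d_map,
    fit_lda,
    fit_multiclass_lda,
    roc_auc,
    shrunk_pooled_covariance,
)
from asymkit.preprocess import POOLED_Z, AsymmetryMatrix, zscore


def _toy_matrix(X, labels, scaling=POOLED_Z):
    idx = pd.Index([f"s{i}" for i in range(len(labels))], name="subject_id")
    cols = [f"r{j}" for j in range(X.shape[1])]
    return AsymmetryMatrix(
        values=pd.DataFrame(X, index=idx, columns=cols),
        groups=pd.Series(labels, index=idx),
        scaling=scaling,
    )


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1.0, 2.0], [0, 1]) == 1.0

    def test_all_scores_equal(self):
        assert roc_auc([3.0, 3.0, 3.0, 3.0], [0, 0, 1, 1]) == 0.5

    def test_four_point_toy_matches_pair_enumeration(self):
        # cases {0.35, 0.8} vs controls {0.1, 0.4}: concordant pairs
        # (0.35>0.1), (0.8>0.1), (0.8>0.4); discordant (0.35<0.4) -> 3/4
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_sklearn_on_random_scores(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.normal(size=50).round(1)  # rounding forces ties
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                sk.roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestDirection:
    def test_closed_form_direction_diagonal_covariance(self):
        """w ~ Sigma^-1 dmu: cosine >= 0.999 against the known quantities."""
        rng = np.random.default_rng(1)
        n = 10_000
        mu = np.array([1.0, 0.5])
        Sigma = np.diag([2.0, 0.5])
        Xa = rng.multivariate_normal(mu, Sigma, n)
        Xb = rng.multivariate_normal(np.zeros(2), Sigma, n)
        X = np.vstack([Xa, Xb])
        y = np.r_[np.ones(n), np.zeros(n)].astype(int)
        w, _ = _direction(X, y, shrinkage=0.0)
        ref = np.linalg.solve(Sigma, mu)
        cos = w @ ref / (np.linalg.norm(w) * np.linalg.norm(ref))
        assert cos >= 0.999

    def test_matches_sklearn_lda_direction(self):
        """Independent route: sklearn LDA coefficients are proportional."""
        sklda = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(2)
        X = rng.standard_normal((400, 6))
        y = rng.integers(0, 2, 400)
        X[y == 1] += 0.5
        w, _ = _direction(X, y, shrinkage=0.0)
        clf = sklda.LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        ref = clf.coef_.ravel()
        cos = w @ ref / (np.linalg.norm(w) * np.linalg.norm(ref))
        assert cos > 0.9999

    def test_shrinkage_interpolates_to_diagonal(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 5)) @ rng.standard_normal((5, 5))
        y = rng.integers(0, 2, 100)
        S_full, _ = shrunk_pooled_covariance(X, y, shrinkage=0.0)
        S_diag, _ = shrunk_pooled_covariance(X, y, shrinkage=1.0)
        assert np.allclose(S_diag, np.diag(np.diag(S_full)))
        S_half, _ = shrunk_pooled_covariance(X, y, shrinkage=0.5)
        assert np.allclose(S_half, 0.5 * S_full + 0.5 * np.diag(np.diag(S_full)))


class TestFitLda:
    def test_requires_pooled_z(self, small_ai):
        with pytest.raises(ValueError, match="pooled_z"):
            fit_lda(small_ai, "16p11.2del")

    def test_coefficient_vector_matches_atlas(self, atlas, small_ai):
        pz = zscore(small_ai.subset(["16p11.2del", "control"]), POOLED_Z)
        pattern = fit_lda(pz, "16p11.2del")
        assert pattern.coefficients.shape == (atlas.n_regions,)
        assert np.all(np.isfinite(pattern.coefficients))
        assert pattern.regions == tuple(atlas.names)

    def test_no_signal_auc_near_half(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((400, 8))
        labels = ["control"] * 200 + ["16p11.2del"] * 200
        pz = zscore(_toy_matrix(X, labels, "raw"), POOLED_Z)
        pattern = fit_lda(pz, "16p11.2del")
        assert abs(pattern.auc - 0.5) < 0.1

    def test_perfectly_separated_toy_auc_one(self):
        X = np.r_[np.zeros(10), np.ones(10)].reshape(-1, 1) + np.linspace(
            0, 0.1, 20
        ).reshape(-1, 1)
        labels = ["control"] * 10 + ["16p11.2del"] * 10
        pz = zscore(_toy_matrix(X, labels, "raw"), POOLED_Z)
        assert fit_lda(pz, "16p11.2del").auc == 1.0

    def test_canonical_orientation_aligned_with_d_map(self, small_ai):
        sub = small_ai.subset(["16p11.2del", "control"])
        pz = zscore(sub, POOLED_Z)
        pattern = fit_lda(pz, "16p11.2del")
        d = cohens_d_map(pz, "16p11.2del")
        assert np.corrcoef(pattern.coefficients, d)[0, 1] >= 0

    def test_subject_order_irrelevant(self, small_ai):
        sub = small_ai.subset(["16p11.2del", "control"])
        pz = zscore(sub, POOLED_Z)
        pattern = fit_lda(pz, "16p11.2del")
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(pz.groups))
        shuffled = AsymmetryMatrix(
            values=pz.values.iloc[perm],
            groups=pz.groups.iloc[perm],
            scaling=POOLED_Z,
        )
        pattern2 = fit_lda(shuffled, "16p11.2del")
        assert np.allclose(pattern.coefficients, pattern2.coefficients, atol=1e-10)
        assert pattern.auc == pytest.approx(pattern2.auc)

    def test_planted_region_carries_largest_coefficient(self, atlas, small_ai):
        pz = zscore(small_ai.subset(["16p11.2del", "control"]), POOLED_Z)
        pattern = fit_lda(pz, "16p11.2del")
        assert int(np.argmax(np.abs(pattern.coefficients))) == atlas.index(
            "Planum Temporale"
        )


class TestCohensDMap:
    def test_antisymmetric_under_label_swap(self, small_ai):
        sub = small_ai.subset(["16p11.2del", "control"])
        d1 = cohens_d_map(sub, "16p11.2del", "control")
        d2 = cohens_d_map(sub, "control", "16p11.2del")
        assert np.allclose(d1, -d2, atol=1e-12)

    def test_matches_scalar_cohens_d(self, small_ai):
        sub = small_ai.subset(["16p11.2del", "control"])
        d = cohens_d_map(sub, "16p11.2del")
        j = 7
        expected = asymkit.cohens_d(
            sub.group_values("16p11.2del")[:, j], sub.group_values("control")[:, j]
        )
        assert d[j] == pytest.approx(expected, abs=1e-12)


@pytest.fixture(scope="module")
def pz(small_ai):
    return zscore(small_ai.subset(["16p11.2del", "control"]), POOLED_Z)


class TestBootstrap:
    def test_sign_alignment_contract(self, pz):
        boot = bootstrap_significance(pz, "16p11.2del", B=100, seed=0)
        d = cohens_d_map(pz, "16p11.2del")
        for draw in boot.draws:
            assert np.corrcoef(draw, d)[0, 1] >= 0

    def test_ci_order_and_significance_definition(self, pz):
        boot = bootstrap_significance(pz, "16p11.2del", B=200, seed=1)
        med = np.median(boot.draws, axis=0)
        assert np.all(boot.ci_low <= med + 1e-12)
        assert np.all(med <= boot.ci_high + 1e-12)
        expected = (boot.ci_low > 0) | (boot.ci_high < 0)
        assert np.array_equal(boot.significant, expected)

    def test_deterministic_given_seed(self, pz):
        b1 = bootstrap_significance(pz, "16p11.2del", B=50, seed=9)
        b2 = bootstrap_significance(pz, "16p11.2del", B=50, seed=9)
        assert np.array_equal(b1.draws, b2.draws)

    def test_planted_region_flagged(self, atlas, pz):
        boot = bootstrap_significance(pz, "16p11.2del", B=500, seed=2)
        assert boot.significant[atlas.index("Planum Temporale")]

    def test_unstratified_mode_runs(self, pz):
        boot = bootstrap_significance(
            pz, "16p11.2del", B=50, seed=3, stratified=False
        )
        assert boot.draws.shape[0] == 50


class TestMulticlass:
    def test_eight_classes_give_seven_axes(self, eight_group_ai):
        carriers = eight_group_ai.subset(
            [g for g in asymkit.pipeline.CNV_GROUPS]
        )
        pz = zscore(carriers, POOLED_Z)
        mc = fit_multiclass_lda(pz)
        assert mc.axes.shape == (7, 65)
        assert len(mc.classes) == 8
        assert np.all(np.diff(mc.eigenvalues) <= 1e-12)  # sorted descending

    def test_two_class_collinear_with_binary_lda(self, small_ai):
        pz = zscore(small_ai.subset(["16p11.2del", "control"]), POOLED_Z)
        pattern = fit_lda(pz, "16p11.2del")
        mc = fit_multiclass_lda(pz)
        assert mc.axes.shape[0] == 1
        a = mc.axes[0]
        b = pattern.coefficients
        cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos >= 0.999

    def test_identical_class_means_no_discriminability(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((300, 5))
        labels = ["16p11.2del"] * 150 + ["22q11.2del"] * 150
        pz = zscore(_toy_matrix(X, labels, "raw"), POOLED_Z)
        mc = fit_multiclass_lda(pz)
        assert mc.eigenvalues[0] < 0.1

    def test_single_class_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 3))
        pz = zscore(_toy_matrix(X, ["16p11.2del"] * 20, "raw"), POOLED_Z)
        with pytest.raises(ValueError, match="two classes"):
            fit_multiclass_lda(pz)

    def test_leading_loadings_shape(self, eight_group_ai):
        carriers = eight_group_ai.subset(list(asymkit.pipeline.CNV_GROUPS))
        mc = fit_multiclass_lda(zscore(carriers, POOLED_Z))
        load = mc.leading_loadings
        assert load.shape == (65, 2)


def test_pattern_tsv_round_trip(small_ai, tmp_path):
    pz = zscore(small_ai.subset(["16p11.2del", "control"]), POOLED_Z)
    pattern = fit_lda(pz, "16p11.2del")
    boot = bootstrap_significance(pz, "16p11.2del", B=50, seed=0)
    path = tmp_path / "p.tsv"
    pattern.to_tsv(path, bootstrap=boot)
    df = pd.read_csv(path, sep="\t")
    assert list(df.columns) == ["region", "coefficient", "ci_low", "ci_high", "significant"]
    assert len(df) == 65
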