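"""Discrimination protocol: featurization, CV accuracy, tuning, PCA."""

import numpy as np
import pytest

from peptarget import (
    ClassifierConfig,
    Peptide,
    PeptideSet,
    Role,
    balanced_cv_accuracy,
    featurize_n_termini,
    pca_projection,
    tp_similarity_score,
    tune_hyperparameters,
)
from peptarget.features import acc_vector
from peptarget.simulate import default_spec, generate_labeled_dataset

CFG_FAST = ClassifierConfig(n_runs=10, seed=7)


@pytest.fixture(scope="module")
def separable():
    sets, _ = generate_labeled_dataset([
        default_spec("MTP_LIKE", 40, seed=101),
        default_spec("CTP_LIKE", 40, seed=102),
    ])
    Xm, _ = featurize_n_termini(sets["MTP_LIKE"])
    Xc, _ = featurize_n_termini(sets["CTP_LIKE"])
    return Xm, Xc


class TestFeaturization:
    def test_full_length_peptide_equals_whole_acc(self):
        p = Peptide("p", "ACDEFGHIKLMNPQR", role=Role.MTP)  # length 15
        X, y = featurize_n_termini(PeptideSet("s", [p]))
        assert np.allclose(X.iloc[0].to_numpy(), acc_vector(p))
        assert y.iloc[0] == "mTP"

    def test_only_prefix_matters(self):
        a = Peptide("a", "ACDEFGHIKLMNPQR" + "WWWW", role=Role.MTP)
        b = Peptide("b", "ACDEFGHIKLMNPQR" + "GGGG", role=Role.CTP)
        X, _ = featurize_n_termini(PeptideSet("s", [a, b]))
        assert np.allclose(X.loc["a"], X.loc["b"])

    def test_matrix_width_36(self, separable):
        Xm, _ = separable
        assert Xm.shape[1] == 36

    def test_short_peptides_dropped(self):
        short = Peptide("s", "ACDEF", role=Role.MTP)
        ok = Peptide("o", "ACDEFGHIKLMNPQR", role=Role.MTP)
        X, _ = featurize_n_termini(PeptideSet("s", [short, ok]))
        assert list(X.index) == ["o"]


class TestBalancedCv:
    def test_separable_classes_high_accuracy(self, separable):
        report = balanced_cv_accuracy(*separable, CFG_FAST)
        assert report.mean_accuracy >= 0.85
        assert all(0.0 <= a <= 1.0 for a in report.per_run_accuracy)
        assert len(report.coefficients) == 36

    def test_null_classes_near_chance(self):
        sets, _ = generate_labeled_dataset([
            default_spec("RANDOM", 40, seed=111),
            default_spec("RANDOM", 40, seed=112),
        ])
        names = list(sets)
        Xa, _ = featurize_n_termini(sets[names[0]])
        Xb, _ = featurize_n_termini(sets[names[1]])
        report = balanced_cv_accuracy(Xa, Xb, CFG_FAST)
        assert 0.35 <= report.mean_accuracy <= 0.65

    def test_same_seed_byte_identical_report(self, separable):
        r1 = balanced_cv_accuracy(*separable, CFG_FAST)
        r2 = balanced_cv_accuracy(*separable, CFG_FAST)
        assert r1.to_json() == r2.to_json()

    def test_balanced_n_cannot_exceed_class_size(self, separable):
        Xm, Xc = separable
        cfg = ClassifierConfig(n_runs=2, balanced_n=100)
        with pytest.raises(ValueError, match="balanced_n"):
            balanced_cv_accuracy(Xm, Xc, cfg)

    def test_separation_monotonicity(self):
        """Widening the class contrast never hurts mean accuracy much.

        Three separation levels built by shifting the cTP-like length and
        upstream parameters toward the mTP-like defaults.
        """
        accs = []
        for level, (length, upstream) in enumerate([(39, 4), (44, 9), (49, 15)]):
            sets, _ = generate_labeled_dataset([
                default_spec("MTP_LIKE", 30, seed=121),
                default_spec("CTP_LIKE", 30, seed=122,
                             length_mean=length, upstream_mean=upstream),
            ])
            Xm, _ = featurize_n_termini(sets["MTP_LIKE"])
            Xc, _ = featurize_n_termini(sets["CTP_LIKE"])
            report = balanced_cv_accuracy(
                Xm, Xc, ClassifierConfig(n_runs=5, seed=9))
            accs.append(report.mean_accuracy)
        assert accs[2] >= accs[0] - 0.05  # non-decreasing up to CV noise


class TestTuning:
    def test_single_point_grid(self, separable):
        Xm, Xc = separable
        X = np.vstack([Xm, Xc])
        y = np.array([0] * len(Xm) + [1] * len(Xc))
        table = tune_hyperparameters(X, y, l1_grid=(0.0,), C_grid=(0.1,),
                                     tune_folds=5)
        assert len(table) == 1 and bool(table["is_best"].iloc[0])

    def test_deterministic_across_repeats(self, separable):
        Xm, Xc = separable
        X = np.vstack([Xm, Xc])
        y = np.array([0] * len(Xm) + [1] * len(Xc))
        t1 = tune_hyperparameters(X, y, l1_grid=(0.0, 0.15), C_grid=(0.1, 1.0),
                                  tune_folds=5)
        t2 = tune_hyperparameters(X, y, l1_grid=(0.0, 0.15), C_grid=(0.1, 1.0),
                                  tune_folds=5)
        assert t1.equals(t2)

    def test_null_data_never_scores_high(self):
        sets, _ = generate_labeled_dataset([
            default_spec("RANDOM", 33, seed=131),
            default_spec("RANDOM", 33, seed=132),
        ])
        names = list(sets)
        Xa, _ = featurize_n_termini(sets[names[0]])
        Xb, _ = featurize_n_termini(sets[names[1]])
        X = np.vstack([Xa, Xb])
        y = np.array([0] * len(Xa) + [1] * len(Xb))
        table = tune_hyperparameters(X, y, l1_grid=(0.0, 0.15),
                                     C_grid=(0.1, 1.0), tune_folds=10)
        assert table["accuracy"].max() <= 0.65


class TestSimilarityScore:
    def test_scores_are_probabilities_and_tp_scores_high(self):
        sets, _ = generate_labeled_dataset([
            default_spec("HARAMP_LIKE", 30, seed=141),
            default_spec("CTP_LIKE", 30, seed=142),
        ])
        amps, tps = sets["HARAMP_LIKE"], sets["CTP_LIKE"]
        scores = tp_similarity_score(tps, amps, tps)
        assert float(scores.min()) >= 0.0 and float(scores.max()) <= 1.0
        assert float(scores.mean()) > 0.5

    def test_label_swap_symmetry(self):
        sets, _ = generate_labeled_dataset([
            default_spec("HARAMP_LIKE", 25, seed=151),
            default_spec("CTP_LIKE", 25, seed=152),
        ])
        amps, tps = sets["HARAMP_LIKE"], sets["CTP_LIKE"]
        cands = list(amps)[:10]
        s = tp_similarity_score(cands, amps, tps, seed=3)
        s_swapped = tp_similarity_score(cands, tps, amps, seed=3)
        assert np.allclose(s.to_numpy(), 1.0 - s_swapped.to_numpy(), atol=1e-4)


class TestPca:
    def test_rank_one_data_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=36)
        X = np.outer(rng.normal(size=30), direction)
        _, ratios = pca_projection(X, n_components=2)
        assert ratios[0] == pytest.approx(1.0, abs=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 36))
        c1, _ = pca_projection(X)
        c2, _ = pca_projection(X + 7.5)
        # coordinates agree up to per-component sign
        for k in range(c1.shape[1]):
            assert (np.allclose(c1[:, k], c2[:, k], atol=1e-8)
                    or np.allclose(c1[:, k], -c2[:, k], atol=1e-8))

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 8))
        from sklearn.decomposition import PCA

        pca = PCA(n_components=8, svd_solver="full")
        Z = pca.fit_transform(X)
        assert np.allclose(pca.inverse_transform(Z), X, atol=1e-9)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            pca_projection(np.zeros((3, 36)), n_components=5)
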