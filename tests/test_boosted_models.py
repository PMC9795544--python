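import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from oatpscreen import boosted_models as bm
from oatpscreen import chem_data as cd


class TestModelGrid:
    def test_exactly_16_specs(self):
        grid = bm.enumerate_model_grid()
        assert len(grid) == 16
        assert len(set(grid)) == 16
        assert sum(1 for s in grid if s.engine == "CP") == 8
        assert sum(1 for s in grid if s.descriptor_mode == "PCM") == 8
        assert sum(1 for s in grid if s.scope == "general") == 4

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "grid.yaml"
        path.write_text(
            "- {engine: GB, descriptor_mode: QSAR, scope: general}\n"
            "- {engine: CP, descriptor_mode: PCM, scope: OATP2B1}\n"
        )
        grid = bm.load_model_grid(path)
        assert grid[0].name == "GB-QSAR-general"
        assert grid[1].scope == "OATP2B1"

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            bm.ModelSpec(engine="SVM", descriptor_mode="QSAR", scope="general")


@pytest.fixture(scope="module")
def scope_label_table():
    rows = [
        # A: active on OATP2B1 only (selective for OATP2B1)
        ("A", "OATP1B1", cd.INACTIVE),
        ("A", "OATP1B3", cd.INACTIVE),
        ("A", "OATP2B1", cd.ACTIVE),
        # B: active on OATP1B1 and OATP1B3 (not selective for either)
        ("B", "OATP1B1", cd.ACTIVE),
        ("B", "OATP1B3", cd.ACTIVE),
        ("B", "OATP2B1", cd.INACTIVE),
        # C: inactive everywhere
        ("C", "OATP1B1", cd.INACTIVE),
        ("C", "OATP1B3", cd.INACTIVE),
        ("C", "OATP2B1", cd.INACTIVE),
        # D: no data on OATP2B1
        ("D", "OATP1B1", cd.ACTIVE),
        ("D", "OATP1B3", cd.INACTIVE),
    ]
    return pd.DataFrame(rows, columns=["compound_id", "target", "label"])


class TestScopeLabels:
    def _y(self, df):
        return df.set_index("compound_id")["y"]

    def test_selective_scope(self, scope_label_table):
        spec = bm.ModelSpec("GB", "QSAR", "OATP2B1")
        y = self._y(bm.make_labels_for_scope(scope_label_table, spec))
        assert y["A"] == 1 and y["B"] == 0 and y["C"] == 0
        assert "D" not in y.index  # no data for the chosen target

    def test_dual_active_not_selective(self, scope_label_table):
        spec = bm.ModelSpec("GB", "QSAR", "OATP1B1")
        y = self._y(bm.make_labels_for_scope(scope_label_table, spec))
        assert y["B"] == 0  # active on two targets: not selective
        assert y["D"] == 1  # active on chosen, inactive elsewhere where known

    def test_general_qsar_any_target(self, scope_label_table):
        spec = bm.ModelSpec("GB", "QSAR", "general")
        y = self._y(bm.make_labels_for_scope(scope_label_table, spec))
        assert y["A"] == 1 and y["B"] == 1 and y["C"] == 0

    def test_general_pcm_row_per_pair(self, scope_label_table):
        spec = bm.ModelSpec("GB", "PCM", "general")
        out = bm.make_labels_for_scope(scope_label_table, spec)
        assert len(out) == len(scope_label_table)


class TestFitGB:
    def test_deterministic_under_seed(self, small_fingerprints, qsar_labels_t1b1):
        X, y = small_fingerprints, qsar_labels_t1b1
        m1 = bm.fit_gb(X, y, bm.GBConfig())
        m2 = bm.fit_gb(X, y, bm.GBConfig())
        assert np.array_equal(bm.gb_scores(m1, X), bm.gb_scores(m2, X))

    def test_separable_data_training_roc_is_one(self):
        rng = np.random.default_rng(0)
        X = rng.random((200, 10))
        y = (X[:, 0] > 0.5).astype(int)
        model = bm.fit_gb(X, y)
        assert roc_auc_score(y, bm.gb_scores(model, X)) == 1.0

    def test_regression_recovers_planted_linear_response(self):
        """Noiseless linear response in 3 planted bits: held-out R^2 >= 0.95."""
        rng = np.random.default_rng(1)
        X = (rng.random((2000, 32)) > 0.7).astype(float)
        y = 5.0 + 1.5 * X[:, 3] - 1.0 * X[:, 10] + 0.8 * X[:, 20]
        model = bm.fit_gb(X[:1500], y[:1500], task="regress")
        pred = bm.gb_scores(model, X[1500:])
        ss_res = np.sum((y[1500:] - pred) ** 2)
        ss_tot = np.sum((y[1500:] - y[1500:].mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.95

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError):
            bm.fit_gb(np.random.rand(20, 3), np.ones(20))


class TestCrossvalidate:
    def test_confusion_arithmetic(self):
        # scores fixed per row: TP=9, FN=1, TN=8, FP=2 -> sens 0.9, spec 0.8
        y = np.array([1] * 10 + [0] * 10)
        scores = np.array([0.9] * 9 + [0.1] + [0.2] * 8 + [0.8] * 2)
        X = scores.reshape(-1, 1)
        rep = bm.crossvalidate(X, y, lambda Xtr, ytr, Xte: Xte[:, 0], k=5, seed=0)
        assert rep.sensitivity == pytest.approx(0.9)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.roc_auc == pytest.approx(roc_auc_score(y, scores))

    def test_perfect_scores(self):
        rng = np.random.default_rng(2)
        X = rng.random((100, 5))
        y = (X[:, 1] > 0.5).astype(int)
        rep = bm.crossvalidate(X, y, lambda Xtr, ytr, Xte: Xte[:, 1], k=5, seed=0)
        assert rep.roc_auc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_random_labels_roc_near_half(self):
        rng = np.random.default_rng(3)
        X = rng.random((2000, 8))
        y = rng.integers(0, 2, 2000)
        rep = bm.crossvalidate(X, y, lambda Xtr, ytr, Xte: rng.random(len(Xte)), k=5)
        assert abs(rep.roc_auc - 0.5) <= 0.05

    def test_stratified_folds_preserve_ratio(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([1] * 40 + [0] * 120)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, te in skf.split(np.zeros((160, 1)), y):
            assert abs(np.sum(y[te] == 1) - 8) <= 1

    def test_k_exceeding_minority_rejected(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            bm.crossvalidate(np.zeros((6, 2)), y, k=3)

    def test_roc_invariant_under_monotone_transform(self, small_fingerprints, qsar_labels_t1b1):
        X, y = small_fingerprints[:200], qsar_labels_t1b1[:200]
        base = bm.crossvalidate(X, y, bm.gb_fit_score(), k=3, seed=7)
        warped = bm.crossvalidate(
            X, y, lambda a, b, c: np.exp(5 * bm.gb_fit_score()(a, b, c)), k=3, seed=7
        )
        assert base.roc_auc == pytest.approx(warped.roc_auc)

    def test_planted_signal_beats_no_signal_baseline(self, small_fingerprints, qsar_labels_t1b1):
        X, y = small_fingerprints, qsar_labels_t1b1
        signal = bm.crossvalidate(X, y, bm.gb_fit_score(), k=5, seed=1)
        rng = np.random.default_rng(11)
        y_perm = rng.permutation(y)
        baseline = bm.crossvalidate(X, y_perm, bm.gb_fit_score(), k=5, seed=1)
        assert signal.roc_auc - baseline.roc_auc >= 0.2
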