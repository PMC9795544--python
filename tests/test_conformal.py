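import numpy as np
import pytest

from oatpscreen import conformal as cp

from .oracles import pvalue_oracle


class TestMemberPvalue:
    @pytest.mark.parametrize(
        "new,calib,expected",
        [
            (0.7, [0.9, 0.8, 0.6, 0.4], 0.6),    # two at or below -> (2+1)/5
            (0.95, [0.9, 0.8, 0.6, 0.4], 1.0),   # above all -> 5/5
            (0.1, [0.9, 0.8, 0.6, 0.4], 0.2),    # below all -> 1/5
            (0.6, [0.9, 0.8, 0.6, 0.4], 0.6),    # tie counts as <=
        ],
    )
    def test_hand_examples(self, new, calib, expected):
        assert cp.member_pvalue(new, np.array(calib)) == pytest.approx(expected)

    def test_strict_variant(self):
        assert cp.member_pvalue(0.6, np.array([0.9, 0.8, 0.6, 0.4]), smoothing=False) == 0.25

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError):
            cp.member_pvalue(0.5, np.array([]))

    @pytest.mark.parametrize("smoothing", [True, False])
    def test_matches_rank_counting_oracle(self, smoothing):
        """1000 random cases against exhaustive rank counting (lists <= 10)."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(1, 11))
            calib = np.round(rng.random(n), 2)
            new = float(np.round(rng.random(), 2))
            assert cp.member_pvalue(new, calib, smoothing=smoothing) == pytest.approx(
                pvalue_oracle(new, list(calib), smoothing=smoothing)
            )


class TestRegion:
    @pytest.mark.parametrize(
        "p_i,p_a,eps,expected",
        [
            (0.05, 0.6, 0.2, cp.REGION_ACTIVE),
            (0.3, 0.6, 0.2, cp.REGION_BOTH),
            (0.15, 0.10, 0.2, cp.REGION_EMPTY),
            (0.6, 0.05, 0.2, cp.REGION_INACTIVE),
            (0.2, 0.2, 0.2, cp.REGION_EMPTY),  # p == eps excluded (strict >)
        ],
    )
    def test_rule(self, p_i, p_a, eps, expected):
        assert cp.region_from_pvalues(p_i, p_a, eps) == expected


class TestEvaluate:
    def test_all_single_correct(self):
        regions = [cp.REGION_ACTIVE] * 3 + [cp.REGION_INACTIVE] * 5
        y = [1, 1, 1, 0, 0, 0, 0, 0]
        ev = cp.evaluate_cp(regions, y)
        assert ev.validity == {0: 1.0, 1: 1.0}
        assert ev.efficiency == {0: 1.0, 1: 1.0}

    def test_both_always_correct_never_efficient(self):
        ev = cp.evaluate_cp([cp.REGION_BOTH] * 4, [0, 1, 0, 1])
        assert ev.validity == {0: 1.0, 1: 1.0}
        assert ev.efficiency == {0: 0.0, 1: 0.0}
        assert ev.n_both == 4 and ev.n_single == 0 and ev.n_empty == 0

    def test_hand_counted_mixture(self):
        # 10 active examples: 6 {active}, 1 {inactive}, 2 {both}, 1 {empty}
        regions = (
            [cp.REGION_ACTIVE] * 6
            + [cp.REGION_INACTIVE]
            + [cp.REGION_BOTH] * 2
            + [cp.REGION_EMPTY]
        )
        ev = cp.evaluate_cp(regions, [1] * 10)
        assert ev.validity[1] == pytest.approx(8 / 10)
        assert ev.efficiency[1] == pytest.approx(7 / 10)
        assert np.isnan(ev.validity[0])  # class absent from truth

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(0)
        regions = rng.choice(
            [cp.REGION_ACTIVE, cp.REGION_INACTIVE, cp.REGION_BOTH, cp.REGION_EMPTY], 57
        )
        ev = cp.evaluate_cp(list(regions), rng.integers(0, 2, 57))
        assert ev.n_total == 57


class TestEnsemble:
    @pytest.fixture(scope="class")
    def fitted(self, small_fingerprints, qsar_labels_t1b1):
        X, y = small_fingerprints[:300], qsar_labels_t1b1[:300]
        config = cp.CPConfig(n_members=5, seed=13)
        return X, y, cp.fit_acp(X, y, config)

    def test_member_count_and_split_sizes(self, fitted):
        X, y, ens = fitted
        assert len(ens.members) == 5
        for m in ens.members:
            n_cal = sum(len(v) for v in m.calib_scores.values())
            assert n_cal == round(0.20 * len(y))
            assert all(len(v) > 0 for v in m.calib_scores.values())
            assert all((v >= 0).all() and (v <= 1).all() for v in m.calib_scores.values())

    def test_same_seed_reproduces_predictions(self, small_fingerprints, qsar_labels_t1b1):
        X, y = small_fingerprints[:200], qsar_labels_t1b1[:200]
        config = cp.CPConfig(n_members=3, seed=99)
        p1 = cp.ensemble_pvalues(X[:30], cp.fit_acp(X, y, config))
        p2 = cp.ensemble_pvalues(X[:30], cp.fit_acp(X, y, config))
        assert np.array_equal(p1, p2)

    def test_median_within_member_range(self, fitted):
        X, y, ens = fitted
        per_member = []
        for m in ens.members:
            single = cp.CPEnsemble(config=ens.config, members=[m])
            per_member.append(cp.ensemble_pvalues(X[:40], single))
        stack = np.stack(per_member)
        med = cp.ensemble_pvalues(X[:40], ens)
        assert (med >= stack.min(axis=0) - 1e-12).all()
        assert (med <= stack.max(axis=0) + 1e-12).all()

    def test_single_member_reduces_to_icp(self, small_fingerprints, qsar_labels_t1b1):
        """A 1-member ensemble's p-values equal plain Mondrian ICP by hand."""
        X, y = small_fingerprints[:200], qsar_labels_t1b1[:200]
        ens = cp.fit_acp(X, y, cp.CPConfig(n_members=1, seed=3))
        member = ens.members[0]
        proba = member.forest.predict_proba(X[:20])
        col = {c: i for i, c in enumerate(member.forest.classes_)}
        p = cp.ensemble_pvalues(X[:20], ens)
        for i in range(20):
            for ci, c in enumerate((0, 1)):
                expected = pvalue_oracle(
                    proba[i, col[c]], list(member.calib_scores[c])
                )
                assert p[i, ci] == pytest.approx(expected)

    def test_region_counts_conserve(self, fitted):
        X, y, ens = fitted
        pred = cp.predict_region(X[:80], ens, 0.2)
        ev = cp.evaluate_cp(pred["region"], y[:80])
        assert ev.n_total == 80

    def test_both_classes_required(self, small_fingerprints):
        with pytest.raises(ValueError):
            cp.fit_acp(small_fingerprints[:50], np.zeros(50, dtype=int), cp.CPConfig())
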