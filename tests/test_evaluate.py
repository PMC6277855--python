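import numpy as np
import pytest

import spiketype as st


def _fm(values, labels):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return st.FeatureMatrix(
        values, "raw", [f"f{i}" for i in range(values.shape[1])], labels=labels
    )


# ---------------------------------------------------------------------------
# J3


def test_j3_equal_class_means_gives_one():
    fm = _fm([[-1.0], [1.0], [-2.0], [2.0]], ["a", "a", "b", "b"])
    summary = st.j3_index(fm)
    assert summary.sb_trace == pytest.approx(0.0, abs=1e-12)
    assert summary.j3 == pytest.approx(1.0, abs=1e-12)


def test_j3_hand_computed_one_dimensional_example():
    fm = _fm([[0.0], [2.0], [10.0], [12.0]], ["a", "a", "b", "b"])
    summary = st.j3_index(fm)
    assert summary.sw_trace == pytest.approx(4.0)
    assert summary.sb_trace == pytest.approx(100.0)
    assert summary.j3 == pytest.approx(26.0)


def test_j3_grows_as_class_means_separate():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(40, 2))
    previous = 0.0
    for shift in (1.0, 3.0, 6.0, 10.0):
        values = np.vstack([base, base + shift])
        j3 = st.j3_index(_fm(values, ["a"] * 40 + ["b"] * 40)).j3
        assert j3 > previous
        previous = j3


def test_j3_invariant_under_rotation_translation_and_scaling():
    rng = np.random.default_rng(1)
    values = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(2, 1, (30, 3))])
    labels = ["a"] * 30 + ["b"] * 30
    j3 = st.j3_index(_fm(values, labels)).j3
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    assert st.j3_index(_fm(values @ Q, labels)).j3 == pytest.approx(j3, rel=1e-9)
    assert st.j3_index(_fm(values + 17.0, labels)).j3 == pytest.approx(j3, rel=1e-9)
    assert st.j3_index(_fm(values * 3.5, labels)).j3 == pytest.approx(j3, rel=1e-9)


def test_j3_degenerate_inputs_raise():
    with pytest.raises(st.ParameterError):
        st.j3_index(_fm([[0.0], [1.0]], ["a", "a"]))
    with pytest.raises(st.ParameterError):
        st.j3_index(_fm([[0.0], [1.0]], ["a", "b"]))  # zero within-class scatter


# ---------------------------------------------------------------------------
# confusion-matrix metrics


def test_hand_computed_three_class_metrics():
    cm = st.ConfusionMatrix(
        counts=np.array([[8, 1, 0], [2, 9, 1], [0, 0, 9]]),
        class_order=["A", "B", "C"],
    )
    out = st.class_metrics(cm)
    a = out["per_class"]["A"]
    assert a["precision"] == pytest.approx(0.8)
    assert a["recall"] == pytest.approx(8 / 9)
    assert a["accuracy"] == pytest.approx(0.9)


def test_perfect_diagonal_matrix_scores_one_everywhere():
    cm = st.ConfusionMatrix(counts=np.eye(3, dtype=int) * 7, class_order=list("abc"))
    out = st.class_metrics(cm)
    for d in out["per_class"].values():
        assert d == {"precision": 1.0, "recall": 1.0, "accuracy": 1.0}
    assert out["overall"] == {"precision": 1.0, "recall": 1.0, "accuracy": 1.0}


def test_metrics_match_direct_counting_on_random_matrices():
    rng = np.random.default_rng(2)
    classes = list("abcd")
    for _ in range(10):
        true = rng.choice(classes, size=200)
        pred = rng.choice(classes, size=200)
        cm = st.ConfusionMatrix.from_labels(true, pred, classes)
        out = st.class_metrics(cm)
        for cls in classes:
            tp = np.sum((true == cls) & (pred == cls))
            fp = np.sum((true != cls) & (pred == cls))
            fn = np.sum((true == cls) & (pred != cls))
            tn = 200 - tp - fp - fn
            d = out["per_class"][cls]
            assert d["precision"] == pytest.approx(tp / (tp + fp))
            assert d["recall"] == pytest.approx(tp / (tp + fn))
            assert d["accuracy"] == pytest.approx((tp + tn) / 200)
            assert 0.0 <= d["accuracy"] <= 1.0
        vals = [out["per_class"][c]["accuracy"] for c in classes]
        assert min(vals) <= out["overall"]["accuracy"] <= max(vals)


def test_never_predicted_class_has_undefined_precision():
    cm = st.ConfusionMatrix(
        counts=np.array([[5, 0], [3, 0]]), class_order=["a", "b"]
    )
    with pytest.warns(UserWarning, match="never predicted"):
        out = st.class_metrics(cm)
    assert out["per_class"]["b"]["precision"] is None
    assert out["overall"]["precision"] == pytest.approx(5 / 8)


# ---------------------------------------------------------------------------
# cross-validation


def _blob_features(n_per_class=60, spread=1.0, gap=50.0, seed=0):
    rng = np.random.default_rng(seed)
    mus = [(0, 0), (gap, 0), (0, gap)]
    values = np.vstack([rng.normal(mu, spread, (n_per_class, 2)) for mu in mus])
    labels = sum([[lab] * n_per_class for lab in ("a", "b", "c")], [])
    return _fm(values, labels)


def test_cross_validation_partitions_every_spike_once():
    fm = _blob_features()
    report = st.cross_validate(fm, k=10, seed=0)
    assert len(report.per_fold) == 10
    assert sum(cm.total for cm in report.per_fold) == fm.n_spikes


def test_fully_separable_classes_reach_perfect_accuracy():
    report = st.cross_validate(_blob_features(), k=10, seed=0)
    assert report.overall["accuracy"][0] == pytest.approx(1.0)
    assert report.correct.all()


def test_permuted_labels_fall_to_chance_level():
    fm = _blob_features(n_per_class=100)
    rng = np.random.default_rng(3)
    shuffled = list(rng.permutation(fm.labels))
    fm_null = _fm(fm.values, shuffled)
    report = st.cross_validate(fm_null, k=10, seed=3)
    rate = report.correct.mean()
    # 99% binomial interval around 1/3 for n=300
    half_width = 2.576 * np.sqrt((1 / 3) * (2 / 3) / 300)
    assert abs(rate - 1 / 3) < half_width


def test_cross_validation_is_bit_reproducible_for_a_seed():
    fm = _blob_features(spread=20.0)  # overlapping classes, non-trivial errors
    a = st.cross_validate(fm, k=5, seed=9)
    b = st.cross_validate(fm, k=5, seed=9)
    assert a.to_dict() == b.to_dict()
    np.testing.assert_array_equal(a.correct, b.correct)
    c = st.cross_validate(fm, k=5, seed=10)
    assert not np.array_equal(a.correct, c.correct)


def test_cross_validation_rejects_classes_smaller_than_k():
    fm = _blob_features(n_per_class=5)
    with pytest.raises(st.ParameterError):
        st.cross_validate(fm, k=10)


def test_group_by_neuron_keeps_each_neuron_in_one_fold(paper3_spikes):
    fm = st.dct_features(paper3_spikes)
    report = st.cross_validate(fm, k=2, seed=0, group_by_neuron=True)
    assert sum(cm.total for cm in report.per_fold) == fm.n_spikes


# ---------------------------------------------------------------------------
# comparison statistics


def test_mcnemar_hand_computed_discordant_counts():
    a = np.array([True] * 15 + [False] * 5 + [True] * 30)
    b = np.array([False] * 15 + [True] * 5 + [True] * 30)
    stat, p = st.mcnemar(a, b)
    assert stat == pytest.approx((10 - 1) ** 2 / 20)  # 4.05
    assert 0 < p < 1


def test_mcnemar_identical_classifiers_yield_p_one():
    a = np.array([True, False, True, True])
    with pytest.warns(UserWarning, match="discordant"):
        stat, p = st.mcnemar(a, a)
    assert p == 1.0


def test_mcnemar_matches_counting_oracle_on_random_vectors():
    rng = np.random.default_rng(4)
    for _ in range(10):
        a = rng.random(100) < 0.8
        b = rng.random(100) < 0.7
        stat, _ = st.mcnemar(a, b)
        bb = int(np.sum(a & ~b))
        cc = int(np.sum(~a & b))
        assert stat == pytest.approx((abs(bb - cc) - 1) ** 2 / (bb + cc))


def test_cochran_q_identical_classifiers_is_degenerate():
    col = np.random.default_rng(5).integers(0, 2, 30)
    M = np.column_stack([col, col, col])
    with pytest.warns(UserWarning):
        q, p = st.cochran_q(M)
    assert q == 0.0 and p == 1.0


def test_cochran_q_matches_formula_oracle():
    rng = np.random.default_rng(6)
    M = rng.integers(0, 2, (50, 3))
    q, p = st.cochran_q(M)
    T = M.sum(axis=1)
    G = M.sum(axis=0)
    k = 3
    oracle = (k - 1) * (k * np.sum(G**2) - np.sum(G) ** 2) / (
        k * np.sum(T) - np.sum(T**2)
    )
    assert q == pytest.approx(oracle, abs=1e-9)
    assert 0 <= p <= 1


def test_bonferroni_adjustment():
    np.testing.assert_allclose(st.bonferroni([0.01, 0.04]), [0.02, 0.08])
    np.testing.assert_allclose(st.bonferroni([0.6, 0.9, 0.2]), [1.0, 1.0, 0.6])
    with pytest.raises(st.ParameterError):
        st.bonferroni([])
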