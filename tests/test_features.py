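import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

import spiketype as st


def dct_oracle(u, alpha):
    """Independent O(N^2) evaluation of the DCT-II definition."""
    u = np.asarray(u, dtype=float)
    N = u.size
    v = np.zeros(N)
    n = np.arange(N)
    for k in range(N):
        if alpha == "ortho":
            a = np.sqrt(1.0 / N) if k == 0 else np.sqrt(2.0 / N)
        else:
            a = np.sqrt((k + 1) / N)
        v[k] = a * np.sum(u * np.cos((2 * n + 1) * np.pi * k / (2 * N)))
    return v


@pytest.mark.parametrize("alpha", ["ortho", "literal"])
@pytest.mark.parametrize("n", [60, 100])
def test_dct_matches_bruteforce_oracle(alpha, n):
    rng = np.random.default_rng(42)
    for _ in range(5):
        u = rng.normal(size=n)
        np.testing.assert_allclose(st.dct(u, alpha), dct_oracle(u, alpha), atol=1e-9)


@pytest.mark.parametrize("alpha", ["ortho", "literal"])
def test_dct_of_constant_input(alpha):
    v = st.dct(np.ones(100), alpha)
    assert v[0] == pytest.approx(10.0, abs=1e-12)
    np.testing.assert_allclose(v[1:], 0.0, atol=1e-10)


def test_dct_orthonormal_preserves_energy():
    rng = np.random.default_rng(3)
    u = rng.normal(size=100)
    v = st.dct(u, "ortho")
    assert np.sum(v**2) == pytest.approx(np.sum(u**2), rel=1e-9)


def test_dct_literal_is_a_columnwise_rescaling_of_orthonormal():
    rng = np.random.default_rng(4)
    u = rng.normal(size=50)
    vo, vl = st.dct(u, "ortho"), st.dct(u, "literal")
    k = np.arange(1, 50)
    np.testing.assert_allclose(vl[1:], vo[1:] * np.sqrt((k + 1) / 2.0), atol=1e-9)
    assert vl[0] == pytest.approx(vo[0])


def test_dct_rejects_empty_input():
    with pytest.raises(st.ParameterError):
        st.dct(np.array([]))


def test_dct_features_pads_to_one_hundred_columns(paper3_spikes):
    fm = st.dct_features(paper3_spikes, n_coeff=100)
    assert fm.d == 100
    assert fm.feature_kind == "dct"
    assert fm.labels == paper3_spikes.labels
    # row equals the DCT of the explicitly padded vector
    padded = np.zeros(100)
    padded[:60] = paper3_spikes.waveforms[0]
    np.testing.assert_allclose(fm.values[0], st.dct(padded), atol=1e-9)


def test_dct_features_of_zero_row_is_zero():
    spikes = st.SpikeSet(
        waveforms=np.zeros((1, 60)), peak_offset=20, fs=20000.0, pre_ms=1.0, post_ms=2.0
    )
    np.testing.assert_array_equal(st.dct_features(spikes).values, np.zeros((1, 100)))


def test_dct_features_rejects_rows_longer_than_n_coeff(paper3_spikes):
    with pytest.raises(st.ParameterError):
        st.dct_features(paper3_spikes, n_coeff=40)


def test_triangular_spike_shape_features_match_analytic_geometry(triangle_spike):
    f = st.ap_shape_features(triangle_spike)
    apt, apd, ahp, rt, ft, rr, fr = f.values[0]
    assert apt == pytest.approx(-60.0, abs=1e-9)
    assert apd == pytest.approx(1.0, abs=1e-9)
    assert ahp == pytest.approx(0.0, abs=1e-9)
    assert rt == pytest.approx(0.8, abs=1e-9)
    assert ft == pytest.approx(0.8, abs=1e-9)
    assert rr == pytest.approx(60.0, abs=1e-9)
    assert fr == pytest.approx(60.0, abs=1e-9)


def test_gaussian_spike_width_matches_closed_form_fwhm():
    fs, sigma_ms = 20000.0, 0.15
    t = (np.arange(60) - 20) / fs * 1000.0
    x = -60.0 + 60.0 * np.exp(-(t**2) / (2 * sigma_ms**2))
    spikes = st.SpikeSet(
        waveforms=x[None, :], peak_offset=20, fs=fs, pre_ms=1.0, post_ms=2.0
    )
    apd = st.ap_shape_features(spikes).values[0, 1]
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_ms
    assert apd == pytest.approx(fwhm, rel=0.02)


def test_undershoot_below_threshold_is_reported_as_ahp(triangle_spike):
    x = triangle_spike.waveforms[0].copy()
    x[45:] = -65.0  # 5 mV below the -60 mV threshold
    spikes = st.SpikeSet(
        waveforms=x[None, :], peak_offset=20, fs=20000.0, pre_ms=1.0, post_ms=2.0
    )
    ahp = st.ap_shape_features(spikes).values[0, 2]
    assert ahp == pytest.approx(5.0, abs=1e-9)


def test_shape_features_offset_invariance(paper3_spikes):
    sub = st.SpikeSet(
        waveforms=paper3_spikes.waveforms[:20],
        peak_offset=paper3_spikes.peak_offset,
        fs=paper3_spikes.fs,
        pre_ms=paper3_spikes.pre_ms,
        post_ms=paper3_spikes.post_ms,
    )
    shifted = st.SpikeSet(
        waveforms=sub.waveforms + 7.0,
        peak_offset=sub.peak_offset,
        fs=sub.fs,
        pre_ms=sub.pre_ms,
        post_ms=sub.post_ms,
    )
    f0 = st.ap_shape_features(sub).values
    f1 = st.ap_shape_features(shifted).values
    np.testing.assert_allclose(f1[:, 0], f0[:, 0] + 7.0, atol=1e-9)  # APT shifts
    np.testing.assert_allclose(f1[:, 1:], f0[:, 1:], atol=1e-9)  # the rest do not


def test_all_invalid_spikes_raise():
    flat = st.SpikeSet(
        waveforms=np.full((3, 60), -65.0),
        peak_offset=20,
        fs=20000.0,
        pre_ms=1.0,
        post_ms=2.0,
    )
    with pytest.raises(st.NumericalError):
        st.ap_shape_features(flat)


# ---------------------------------------------------------------------------
# PCA


def _fm(values, labels=None):
    return st.FeatureMatrix(
        values, "raw", [f"f{i}" for i in range(values.shape[1])], labels=labels
    )


def test_pca_rank_one_correlation_keeps_single_component():
    x = np.linspace(-1, 1, 50)
    model = st.fit_pca(_fm(np.column_stack([x, 2 * x])))
    assert model.q == 1
    np.testing.assert_allclose(model.explained_ratio, [1.0], atol=1e-12)
    scores = st.apply_pca(model, _fm(np.column_stack([x, 2 * x])))
    assert np.var(scores.values[:, 0], ddof=1) == pytest.approx(2.0, rel=1e-9)


def test_correlation_pca_eigenvalues_sum_to_dimension():
    rng = np.random.default_rng(5)
    model = st.fit_pca(_fm(rng.normal(size=(200, 10))))
    assert np.sum(model.eigenvalues) == pytest.approx(10.0, abs=1e-9)


def test_pca_matches_independent_eigendecomposition():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(200, 10)) @ rng.normal(size=(10, 10))
    model = st.fit_pca(_fm(X), cpv=0.999)
    evals, evecs = np.linalg.eigh(np.corrcoef(X, rowvar=False))
    evals, evecs = evals[::-1], evecs[:, ::-1]
    np.testing.assert_allclose(model.eigenvalues, evals, atol=1e-8)
    for i in range(model.q):
        dot = abs(np.dot(model.components[i], evecs[:, i]))
        assert dot == pytest.approx(1.0, abs=1e-8)  # equal up to sign


def test_pca_sign_convention_largest_loading_positive():
    rng = np.random.default_rng(7)
    model = st.fit_pca(_fm(rng.normal(size=(100, 6))), cpv=0.999)
    for row in model.components:
        assert row[np.argmax(np.abs(row))] > 0


def test_apply_pca_centers_training_data():
    rng = np.random.default_rng(8)
    X = rng.normal(5.0, 2.0, size=(150, 8))
    fm = _fm(X)
    model = st.fit_pca(fm)
    scores = st.apply_pca(model, fm)
    np.testing.assert_allclose(scores.values.mean(axis=0), 0.0, atol=1e-9)
    # the training mean itself maps to the origin
    at_mean = st.apply_pca(model, _fm(model.center[None, :]))
    np.testing.assert_allclose(at_mean.values, 0.0, atol=1e-9)
    # transform equals projection of standardized data on stored components
    Z = (X - model.center) / model.scale
    np.testing.assert_allclose(scores.values, Z @ model.components.T, atol=1e-12)


def test_pca_zero_variance_column_warns_and_uses_unit_scale():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(50, 3))
    X[:, 1] = 4.2
    with pytest.warns(UserWarning, match="zero-variance"):
        model = st.fit_pca(_fm(X))
    assert model.scale[1] == 1.0


def test_pca_errors():
    with pytest.raises(st.ParameterError):
        st.fit_pca(_fm(np.zeros((1, 3))))
    model = st.fit_pca(_fm(np.random.default_rng(0).normal(size=(20, 3))))
    with pytest.raises(st.ParameterError):
        st.apply_pca(model, _fm(np.zeros((5, 4))))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(hs.integers(0, 2**31 - 1))
def test_dct_parseval_property(seed):
    u = np.random.default_rng(seed).normal(size=60)
    v = st.dct(u, "ortho")
    assert np.sum(v**2) == pytest.approx(np.sum(u**2), rel=1e-9)
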