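"""The Gaussian naive Bayes core: fitting, scoring, deciding, persisting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppisite import (
    FeatureVector,
    NBCModel,
    encode_windows,
    fit,
    fit_arrays,
    load_model,
    log_posterior_ratio,
    predict,
    predict_chain,
    save_model,
)
from ppisite.nbc import log_posterior_ratios
from conftest import make_chain


def _vectors(X, y):
    return [
        FeatureVector(values=np.asarray(row), center_position=i + 1, chain_id="c", label=int(lab))
        for i, (row, lab) in enumerate(zip(X, y))
    ]


def _symmetric_model(d=3, prior1=0.5, theta=0.0):
    return NBCModel(
        prior_interface=prior1,
        prior_noninterface=1 - prior1,
        means=np.zeros((2, d)),
        variances=np.ones((2, d)),
        window_size=None,
        theta=theta,
    )


class TestFit:
    def test_priors_are_empirical_frequencies(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 21))
        y = np.array([1, 1, 1] + [0] * 7)
        model = fit(_vectors(X, y))
        assert model.prior_interface == pytest.approx(0.3)
        assert model.prior_noninterface == pytest.approx(0.7)

    def test_constant_feature_hits_variance_floor(self):
        X = np.array([[2.0, 1.0], [2.0, 3.0], [0.0, 0.0], [1.0, 1.0]])
        y = np.array([1, 1, 0, 0])
        model = fit_arrays(X, y, variance_floor=1e-6)
        assert model.means[1, 0] == 2.0
        assert model.variances[1, 0] == 1e-6

    def test_single_class_input_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="both classes required"):
            fit_arrays(X, np.ones(4, dtype=int))

    def test_inconsistent_vector_lengths_rejected(self):
        vecs = [
            FeatureVector(np.zeros(21), 1, "c", 0),
            FeatureVector(np.zeros(41), 2, "c", 1),
        ]
        with pytest.raises(ValueError, match="inconsistent"):
            fit(vecs)

    def test_parameter_recovery_on_simulated_gaussians(self):
        rng = np.random.default_rng(42)
        n = 5000
        X = np.concatenate([rng.normal(0, 1, (n, 4)), rng.normal(3, 1, (n, 4))])
        y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
        model = fit_arrays(X, y)
        assert np.all(np.abs(model.means[0] - 0.0) < 0.1)
        assert np.all(np.abs(model.means[1] - 3.0) < 0.1)


class TestLogPosteriorRatio:
    def test_symmetric_model_scores_zero(self):
        model = _symmetric_model()
        assert log_posterior_ratio(model, np.array([0.3, -1.0, 2.0])) == pytest.approx(0.0)

    def test_prior_only_ratio(self):
        model = _symmetric_model(prior1=0.1)
        x = np.array([0.5, 0.5, 0.5])
        assert log_posterior_ratio(model, x) == pytest.approx(math.log(1 / 9), abs=1e-9)

    def test_matches_brute_force_density_product(self):
        # two-feature model with hand-set moments; oracle multiplies raw
        # normal densities and priors, then takes a single log
        from scipy.stats import norm

        model = NBCModel(
            prior_interface=0.3,
            prior_noninterface=0.7,
            means=np.array([[0.0, 1.0], [2.0, -1.0]]),
            variances=np.array([[1.0, 4.0], [0.25, 9.0]]),
            window_size=None,
        )
        x = np.array([0.7, -2.3])
        num = 0.3 * norm.pdf(x[0], 2.0, 0.5) * norm.pdf(x[1], -1.0, 3.0)
        den = 0.7 * norm.pdf(x[0], 0.0, 1.0) * norm.pdf(x[1], 1.0, 2.0)
        assert log_posterior_ratio(model, x) == pytest.approx(
            math.log(num / den), abs=1e-10
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            log_posterior_ratio(_symmetric_model(3), np.zeros(4))

    @given(st.integers(0, 2**31 - 1))
    def test_permuting_features_identically_leaves_ratio_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        d = 8
        model = NBCModel(
            prior_interface=0.4,
            prior_noninterface=0.6,
            means=rng.normal(size=(2, d)),
            variances=rng.uniform(0.1, 2.0, size=(2, d)),
            window_size=None,
        )
        x = rng.normal(size=d)
        perm = rng.permutation(d)
        permuted = NBCModel(
            prior_interface=0.4,
            prior_noninterface=0.6,
            means=model.means[:, perm],
            variances=model.variances[:, perm],
            window_size=None,
        )
        assert log_posterior_ratio(model, x) == pytest.approx(
            log_posterior_ratio(permuted, x[perm]), abs=1e-9
        )


class TestPredict:
    def test_ratio_above_theta_is_interface(self):
        # with only a prior difference the ratio is ln(0.7/0.3) = 0.847;
        # at the operating threshold -0.88 that is an interface call
        model = _symmetric_model(prior1=0.7)
        assert log_posterior_ratio(model, np.zeros(3)) == pytest.approx(
            math.log(7 / 3)
        )
        assert predict(model, np.zeros(3), theta=-0.88) == 1

    def test_tie_with_theta_goes_to_noninterface(self):
        model = _symmetric_model()  # ratio is exactly 0
        assert predict(model, np.zeros(3), theta=0.0) == 0

    def test_huge_theta_silences_all_predictions(self):
        model = _symmetric_model(prior1=0.9)
        rng = np.random.default_rng(1)
        assert all(
            predict(model, rng.normal(size=3), theta=1e9) == 0 for _ in range(20)
        )

    def test_theta_monotonicity_shrinks_positive_set(self):
        rng = np.random.default_rng(2)
        model = _symmetric_model(d=5, prior1=0.3)
        X = rng.normal(size=(50, 5))
        ratios = log_posterior_ratios(model, X)
        pos_low = set(np.flatnonzero(ratios > -0.5))
        pos_high = set(np.flatnonzero(ratios > 0.5))
        assert pos_high <= pos_low


class TestPredictChain:
    def test_one_triple_per_residue_in_order(self):
        chain = make_chain("c", [0, 1] * 5)
        model = fit(encode_windows(chain, 3))
        out = predict_chain(model, chain)
        assert [pos for pos, _, _ in out] == list(range(1, 11))

    def test_deterministic(self):
        chain = make_chain("c", [0, 1] * 5)
        model = fit(encode_windows(chain, 3))
        assert predict_chain(model, chain) == predict_chain(model, chain)

    def test_composes_encode_then_predict(self):
        chain = make_chain("c", [0, 0, 1, 1, 0, 1, 0, 0])
        model = fit(encode_windows(chain, 3))
        direct = [cls for _, _, cls in predict_chain(model, chain, theta=0.1)]
        composed = [
            predict(model, fv, theta=0.1) for fv in encode_windows(chain, 3)
        ]
        assert direct == composed


class TestSklearnOracle:
    def test_log_ratio_matches_gaussian_nb_joint_likelihood_difference(self):
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(7)
        for _ in range(50):
            d = int(rng.integers(1, 30))
            prior1 = float(rng.uniform(0.05, 0.95))
            means = rng.normal(size=(2, d))
            variances = rng.uniform(0.05, 3.0, size=(2, d))
            model = NBCModel(
                prior_interface=prior1,
                prior_noninterface=1 - prior1,
                means=means,
                variances=variances,
                window_size=None,
            )
            clf = GaussianNB()
            clf.classes_ = np.array([0, 1])
            clf.theta_ = means
            clf.var_ = variances
            clf.class_prior_ = np.array([1 - prior1, prior1])
            x = rng.normal(size=d)
            jll = clf._joint_log_likelihood(x[None, :])[0]
            assert log_posterior_ratio(model, x) == pytest.approx(
                jll[1] - jll[0], abs=1e-8
            )


class TestSerialization:
    def test_round_trip_is_lossless(self, tmp_path):
        chain = make_chain("c", [0, 1] * 6)
        model = fit(encode_windows(chain, 3))
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(model.means, loaded.means)
        np.testing.assert_array_equal(model.variances, loaded.variances)
        assert loaded.prior_interface == model.prior_interface
        assert loaded.window_size == model.window_size
        assert loaded.theta == model.theta

    def test_foreign_json_is_rejected(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="not a"):
            load_model(path)


class TestModelValidation:
    def test_priors_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            NBCModel(0.5, 0.4, np.zeros((2, 1)), np.ones((2, 1)), None)

    def test_variances_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            NBCModel(0.5, 0.5, np.zeros((2, 1)), np.zeros((2, 1)), None)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            NBCModel(0.5, 0.5, np.zeros((2, 1)), np.ones((2, 1)), window_size=4)
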