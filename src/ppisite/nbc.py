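"""Gaussian naive Bayes classifier with a log-posterior-ratio threshold.

The residue classification problem is binary: interface (class 1) versus
noninterface (class 0).  Under the naive (conditional-independence)
assumption the posterior for class ``c`` given feature vector
``x = (x_1, ..., x_n)`` factorises as

    p(c | x)  proportional to  p(c) * prod_i p_i(x_i | c),

and the decision statistic is the natural-log posterior ratio

    s(x) = ln p(1) - ln p(0) + sum_i [ ln p_i(x_i | 1) - ln p_i(x_i | 0) ].

The shared normaliser cancels in the ratio.  A residue is called interface
when ``s(x)`` strictly exceeds a threshold theta; theta trades sensitivity
against specificity and is chosen by cross-validation rather than fixed at 0
because the classes are heavily imbalanced.

Each class-conditional density ``p_i(. | c)`` is a univariate Gaussian whose
mean and variance are the per-class sample moments, with a variance floor to
guard degenerate (constant) features.  The sum-of-logs form is used
throughout; raw density products would underflow at 181 features.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .feature_io import Chain, FeatureVector, encode_windows

DEFAULT_WINDOW_SIZE = 9
DEFAULT_THETA = -0.88
DEFAULT_VARIANCE_FLOOR = 1e-6

MODEL_FORMAT = "ppisite-nbc-model"
MODEL_VERSION = 1

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class NBCModel:
    """Fitted classifier: class priors plus per-feature Gaussian moments.

    ``means`` and ``variances`` are ``(2, n_features)`` arrays indexed by
    class (row 0 = noninterface, row 1 = interface).  ``window_size`` records
    the encoder setting the model expects; ``theta`` is the default decision
    threshold on the log posterior ratio.
    """

    prior_interface: float
    prior_noninterface: float
    means: np.ndarray
    variances: np.ndarray
    window_size: int | None = DEFAULT_WINDOW_SIZE
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        variances = np.asarray(self.variances, dtype=float)
        if means.ndim != 2 or means.shape[0] != 2 or means.shape != variances.shape:
            raise ValueError(
                "means and variances must both have shape (2, n_features)"
            )
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "variances", variances)
        if not (0.0 < self.prior_interface < 1.0):
            raise ValueError("prior_interface must lie in (0, 1)")
        if abs(self.prior_interface + self.prior_noninterface - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        if np.any(variances <= 0):
            raise ValueError("all variances must be strictly positive")
        if self.window_size is not None and (
            self.window_size < 1 or self.window_size % 2 == 0
        ):
            raise ValueError("window_size must be odd and >= 1")

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def _as_matrix(vectors: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    lengths = {fv.values.size for fv in vectors}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent feature-vector lengths: {sorted(lengths)}")
    if any(fv.label is None for fv in vectors):
        raise ValueError("all feature vectors must be labeled for fitting")
    X = np.stack([fv.values for fv in vectors])
    y = np.array([fv.label for fv in vectors], dtype=int)
    return X, y


def fit_arrays(
    X: np.ndarray,
    y: np.ndarray,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    window_size: int | None = None,
    theta: float = DEFAULT_THETA,
) -> NBCModel:
    """Fit from a design matrix and 0/1 label vector.

    Priors are the empirical class frequencies (no smoothing; both classes
    must be present).  Per-feature moments are the per-class sample mean and
    population variance, floored at ``variance_floor``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes required in the training data")
    means = np.stack([X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)])
    variances = np.stack([X[y == 0].var(axis=0), X[y == 1].var(axis=0)])
    variances = np.maximum(variances, variance_floor)
    if window_size is None:
        d = X.shape[1]
        if (d - 1) % 20 == 0 and ((d - 1) // 20) % 2 == 1:
            window_size = (d - 1) // 20
    return NBCModel(
        prior_interface=n1 / (n0 + n1),
        prior_noninterface=n0 / (n0 + n1),
        means=means,
        variances=variances,
        window_size=window_size,
        theta=theta,
    )


def fit(
    vectors: Sequence[FeatureVector],
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    theta: float = DEFAULT_THETA,
) -> NBCModel:
    """Fit the classifier from labeled window-encoded feature vectors."""
    if not vectors:
        raise ValueError("no training vectors")
    X, y = _as_matrix(vectors)
    return fit_arrays(X, y, variance_floor=variance_floor, theta=theta)


def log_posterior_ratios(model: NBCModel, X: np.ndarray) -> np.ndarray:
    """Vectorised log posterior ratio for each row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    mu, var = model.means, model.variances
    # log N(x; mu, var) = -0.5*(log 2*pi*var + (x-mu)^2/var), summed per class
    log_dens = -0.5 * (
        _LOG_2PI + np.log(var)[None, :, :] + (X[:, None, :] - mu) ** 2 / var
    ).sum(axis=2)
    prior_term = math.log(model.prior_interface) - math.log(model.prior_noninterface)
    return prior_term + log_dens[:, 1] - log_dens[:, 0]


def log_posterior_ratio(model: NBCModel, x: FeatureVector | np.ndarray) -> float:
    """Log posterior ratio ln[p(1|x)/p(0|x)] for a single feature vector."""
    values = x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    return float(log_posterior_ratios(model, values[None, :])[0])


def predict(
    model: NBCModel, x: FeatureVector | np.ndarray, theta: float | None = None
) -> int:
    """Class decision: 1 iff the log posterior ratio strictly exceeds theta."""
    theta = model.theta if theta is None else theta
    return int(log_posterior_ratio(model, x) > theta)


def predict_chain(
    model: NBCModel, chain: Chain, theta: float | None = None
) -> list[tuple[int, float, int]]:
    """Score every residue of a chain: (position, log_ratio, class) triples."""
    if model.window_size is None:
        raise ValueError("model has no window size; cannot encode a chain")
    theta = model.theta if theta is None else theta
    vectors = encode_windows(chain, model.window_size)
    X = np.stack([fv.values for fv in vectors])
    ratios = log_posterior_ratios(model, X)
    return [
        (fv.center_position, float(r), int(r > theta))
        for fv, r in zip(vectors, ratios)
    ]


# ---------------------------------------------------------------------------
# serialization — versioned JSON text
# ---------------------------------------------------------------------------


def save_model(model: NBCModel, path: str | os.PathLike) -> None:
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "prior_interface": model.prior_interface,
        "prior_noninterface": model.prior_noninterface,
        "means": model.means.tolist(),
        "variances": model.variances.tolist(),
        "window_size": model.window_size,
        "theta": model.theta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path: str | os.PathLike) -> NBCModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise ValueError(f"{path}: unsupported model version {payload.get('version')}")
    return NBCModel(
        prior_interface=payload["prior_interface"],
        prior_noninterface=payload["prior_noninterface"],
        means=np.array(payload["means"]),
        variances=np.array(payload["variances"]),
        window_size=payload["window_size"],
        theta=payload["theta"],
    )
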