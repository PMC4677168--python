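"""Imbalance-aware evaluation: confusion metrics, chain-level LOOCV, sweeps.

Interface residues are a small minority (roughly 12% of residues), so plain
accuracy is dominated by the negative class; the Matthews correlation
coefficient (MCC) is the model-selection criterion.  Cross-validation is
leave-one-chain-out: each protein chain is held out in turn, the classifier
is refit on the remaining chains, and confusion counts are pooled across all
folds before metrics are computed (micro-averaging).

LOOCV is computed with a streaming trick: class counts, per-feature sums and
sums of squares are accumulated once per chain, and each fold's training
moments are obtained by subtracting the held-out chain's statistics from the
totals.  This makes a full sweep over window sizes and thresholds cheap —
the per-fold log ratios are computed once per window size and merely
re-thresholded for each theta.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .feature_io import Chain, encode_windows
from .nbc import DEFAULT_VARIANCE_FLOOR, NBCModel, log_posterior_ratios

logger = logging.getLogger(__name__)

DEFAULT_THETA_GRID = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.02), 10)
DEFAULT_WINDOW_GRID = (1, 3, 5, 7, 9, 11, 13)


# ---------------------------------------------------------------------------
# confusion counts and derived metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """The six derived measures; fractions in [0,1], MCC in [-1,1]."""

    sensitivity: float
    precision: float
    specificity: float
    accuracy: float
    mcc: float
    f_measure: float


def confusion(
    labels: Sequence[int] | np.ndarray, predictions: Sequence[int] | np.ndarray
) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary labels and predictions."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError(
            f"labels and predictions must be equal-length 1-D: {y.shape} vs {p.shape}"
        )
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s has a zero denominator; defined as 0", name)
        return 0.0
    return num / den


def f_measure(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (0 when both are 0)."""
    return _ratio(2.0 * precision * sensitivity, precision + sensitivity, "f_measure")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    den_sq = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den_sq == 0:
        logger.warning("MCC has a zero denominator; defined as 0")
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(den_sq)


def metrics(c: ConfusionCounts) -> MetricSet:
    """All six measures from one set of confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    prec = _ratio(c.tp, c.tp + c.fp, "precision")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    acc = (c.tp + c.tn) / c.total
    return MetricSet(
        sensitivity=sens,
        precision=prec,
        specificity=spec,
        accuracy=acc,
        mcc=mcc(c),
        f_measure=f_measure(prec, sens),
    )


# ---------------------------------------------------------------------------
# leave-one-chain-out cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldScores:
    """Held-out chain id with its true labels and fold-model log ratios."""

    chain_id: str
    labels: np.ndarray
    log_ratios: np.ndarray


def loocv_scores(
    chains: Sequence[Chain],
    w: int,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> list[FoldScores]:
    """Log posterior ratios for every residue under leave-one-chain-out.

    For each chain the training moments are the dataset totals minus that
    chain's per-class count/sum/sum-of-squares, which is algebraically
    identical to refitting on the remaining chains.
    """
    if len(chains) < 2:
        raise ValueError("LOOCV requires at least two chains")
    encoded = []
    for chain in chains:
        labels = chain.labels
        if labels is None:
            raise ValueError(f"chain {chain.chain_id} has unlabeled residues")
        X = np.stack([fv.values for fv in encode_windows(chain, w)])
        encoded.append((chain.chain_id, X, labels))

    d = encoded[0][1].shape[1]
    counts = np.zeros(2)
    sums = np.zeros((2, d))
    sumsqs = np.zeros((2, d))
    per_chain = []
    for chain_id, X, y in encoded:
        c = np.array([np.sum(y == 0), np.sum(y == 1)], dtype=float)
        s = np.stack([X[y == 0].sum(axis=0), X[y == 1].sum(axis=0)])
        q = np.stack([(X[y == 0] ** 2).sum(axis=0), (X[y == 1] ** 2).sum(axis=0)])
        per_chain.append((c, s, q))
        counts += c
        sums += s
        sumsqs += q

    folds = []
    for (chain_id, X, y), (c, s, q) in zip(encoded, per_chain):
        tc = counts - c
        if tc[0] == 0 or tc[1] == 0:
            raise ValueError(
                f"training fold for held-out chain {chain_id} contains a "
                f"single class"
            )
        mu = (sums - s) / tc[:, None]
        var = (sumsqs - q) / tc[:, None] - mu**2
        var = np.maximum(var, variance_floor)
        model = NBCModel(
            prior_interface=tc[1] / tc.sum(),
            prior_noninterface=tc[0] / tc.sum(),
            means=mu,
            variances=var,
            window_size=w,
        )
        folds.append(
            FoldScores(
                chain_id=chain_id,
                labels=y,
                log_ratios=log_posterior_ratios(model, X),
            )
        )
    return folds


def pool_folds(folds: Iterable[FoldScores], theta: float) -> ConfusionCounts:
    """Threshold fold scores at theta and sum confusion counts over folds."""
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold in folds:
        preds = (fold.log_ratios > theta).astype(int)
        pooled = pooled + confusion(fold.labels, preds)
    return pooled


def loocv(
    chains: Sequence[Chain],
    w: int,
    theta: float,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> tuple[ConfusionCounts, MetricSet]:
    """Leave-one-chain-out evaluation at one (window, theta) operating point."""
    folds = loocv_scores(chains, w, variance_floor)
    pooled = pool_folds(folds, theta)
    return pooled, metrics(pooled)


# ---------------------------------------------------------------------------
# (window, theta) sweep and model selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepRow:
    window_size: int
    theta: float
    metric_set: MetricSet


@dataclass(frozen=True)
class SweepResult:
    rows: tuple[SweepRow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))


def sweep(
    chains: Sequence[Chain],
    windows: Sequence[int] = DEFAULT_WINDOW_GRID,
    thetas: Sequence[float] = DEFAULT_THETA_GRID,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> SweepResult:
    """LOOCV over a grid of window sizes and thresholds.

    Fold models and log ratios are computed once per window size; each theta
    merely re-thresholds the stored scores.
    """
    windows = list(windows)
    thetas = list(thetas)
    if not windows or not thetas:
        raise ValueError("window and theta grids must be nonempty")
    rows = []
    for w in windows:
        folds = loocv_scores(chains, w, variance_floor)
        for theta in thetas:
            pooled = pool_folds(folds, theta)
            rows.append(SweepRow(w, float(theta), metrics(pooled)))
    return SweepResult(rows=tuple(rows))


def select_model(result: SweepResult) -> SweepRow:
    """The grid row maximising MCC; ties go to smaller window, then smaller theta."""
    if not result.rows:
        raise ValueError("cannot select from an empty sweep")
    return min(
        result.rows,
        key=lambda r: (-r.metric_set.mcc, r.window_size, r.theta),
    )


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

_SWEEP_HEADER = "window\ttheta\tsensitivity\tprecision\tspecificity\taccuracy\tmcc\tf_measure"


def sweep_to_tsv(result: SweepResult) -> str:
    out = io.StringIO()
    out.write(_SWEEP_HEADER + "\n")
    for r in result.rows:
        m = r.metric_set
        out.write(
            f"{r.window_size}\t{r.theta:.4f}\t{m.sensitivity:.4f}\t"
            f"{m.precision:.4f}\t{m.specificity:.4f}\t{m.accuracy:.4f}\t"
            f"{m.mcc:.4f}\t{m.f_measure:.4f}\n"
        )
    return out.getvalue()


def tradeoff_curve_tsv(result: SweepResult, window_size: int) -> str:
    """Sensitivity-versus-specificity curve for one window size."""
    out = io.StringIO()
    out.write("theta\tsensitivity\tspecificity\n")
    for r in result.rows:
        if r.window_size == window_size:
            m = r.metric_set
            out.write(f"{r.theta:.4f}\t{m.sensitivity:.4f}\t{m.specificity:.4f}\n")
    return out.getvalue()
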