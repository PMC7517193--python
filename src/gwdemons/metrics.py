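"""Image-similarity and information metrics.

All metrics operate on normalized [0, 1] intensity images.  Histogram-based
quantities (joint entropy, mutual information) use equal-width bins on [0, 1]
and report entropies in bits.  MSE is likewise reported on the normalized
scale, so an 8-bit image pair differing by one grey level everywhere scores
(1/255)**2.

Naming note: in parts of the registration literature the joint entropy of an
image pair is labelled "MJE" and the quantity H(X) + H(Y) - H(X,Y) "NMI";
the latter is the standard mutual information, not Studholme's normalized
variant.  The field names below keep both spellings.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import ShapeError, UndefinedMetricError
from .image_io import as_image

__all__ = [
    "DEFAULT_BINS",
    "MetricReport",
    "correlation",
    "mse",
    "joint_entropy",
    "mutual_information",
    "improvement_percent",
    "metric_report",
]

#: Default histogram bin count — one bin per 8-bit grey level.
DEFAULT_BINS = 256


@dataclass(frozen=True)
class MetricReport:
    """Bundle of the four similarity metrics for one image pair.

    ``mje`` is the joint entropy H(X,Y) in bits; ``nmi`` the mutual
    information H(X) + H(Y) - H(X,Y) in bits, computed from the same
    ``n_bins``-wide joint histogram.
    """

    correlation: float
    mse: float
    mje: float
    nmi: float
    n_bins: int

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = as_image(X)
    Y = as_image(Y)
    if X.shape != Y.shape:
        raise ShapeError(f"image shapes differ: {X.shape} vs {Y.shape}")
    return X, Y


def correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Pearson product-moment correlation over all pixels."""
    X, Y = _check_pair(X, Y)
    dx = X - X.mean()
    dy = Y - Y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0.0:
        raise UndefinedMetricError("correlation undefined: at least one image is constant")
    return float((dx * dy).sum() / denom)


def mse(I: np.ndarray, J: np.ndarray) -> float:
    """Mean squared per-pixel difference on the normalized [0, 1] scale."""
    I, J = _check_pair(I, J)
    d = I - J
    return float((d * d).mean())


def _joint_histogram(X: np.ndarray, Y: np.ndarray, n_bins: int) -> np.ndarray:
    # Equal-width bins on [0, 1]; the top edge is inclusive so 1.0 lands in
    # the last bin.
    ix = np.minimum((X * n_bins).astype(np.int64), n_bins - 1)
    iy = np.minimum((Y * n_bins).astype(np.int64), n_bins - 1)
    hist = np.zeros((n_bins, n_bins), dtype=np.float64)
    np.add.at(hist, (ix.ravel(), iy.ravel()), 1.0)
    return hist / X.size


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def joint_entropy(X: np.ndarray, Y: np.ndarray, n_bins: int = DEFAULT_BINS) -> float:
    """Joint entropy H(X, Y) in bits over an ``n_bins`` x ``n_bins`` joint
    histogram; the 0*log(0) convention is 0."""
    X, Y = _check_pair(X, Y)
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    return _entropy_bits(_joint_histogram(X, Y, n_bins))


def mutual_information(X: np.ndarray, Y: np.ndarray, n_bins: int = DEFAULT_BINS) -> float:
    """Mutual information H(X) + H(Y) - H(X, Y) in bits.

    The marginal entropies come from the margins of the same joint histogram
    so the three terms are mutually consistent.
    """
    X, Y = _check_pair(X, Y)
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    joint = _joint_histogram(X, Y, n_bins)
    hx = _entropy_bits(joint.sum(axis=1))
    hy = _entropy_bits(joint.sum(axis=0))
    return hx + hy - _entropy_bits(joint)


def improvement_percent(before: float, after: float) -> tuple[float, str]:
    """Relative change between a metric before and after optimization.

    Returns ``(100 * |after - before| / max(before, after), direction)``
    where direction is ``"Increase"`` if ``after > before`` else
    ``"Decrease"`` (``"Unchanged"`` when equal).  The larger of the two
    values is the denominator, so the figure is symmetric in which side
    improved.
    """
    if not (np.isfinite(before) and np.isfinite(after)):
        raise UndefinedMetricError("improvement undefined for non-finite inputs")
    denom = max(before, after)
    if denom <= 0.0:
        raise UndefinedMetricError("improvement undefined when max(before, after) <= 0")
    pct = 100.0 * abs(after - before) / denom
    if after > before:
        direction = "Increase"
    elif after < before:
        direction = "Decrease"
    else:
        direction = "Unchanged"
    return pct, direction


def metric_report(X: np.ndarray, Y: np.ndarray, n_bins: int = DEFAULT_BINS) -> MetricReport:
    """Compute all four metrics for one image pair."""
    return MetricReport(
        correlation=correlation(X, Y),
        mse=mse(X, Y),
        mje=joint_entropy(X, Y, n_bins),
        nmi=mutual_information(X, Y, n_bins),
        n_bins=n_bins,
    )
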