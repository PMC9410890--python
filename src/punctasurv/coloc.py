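"""Two-channel colocalization metrics on background-subtracted images.

Pearson's r measures how intensity co-varies between channels across pixels;
Manders' coefficients measure what fraction of one channel's signal overlaps
the other channel's positive region. Both an intensity-weighted M1/M2 (the
standard Manders definition) and a pixel-count M2 variant (the fraction of
B-positive pixels that are also A-positive) are reported, since both
readings are in use. Thresholds are explicit parameters, defaulting to 0
after background subtraction; automatic (Costes) thresholding is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedCoefficientError

__all__ = ["TwoChannelImage", "ColocResult", "pearson_r", "manders", "colocalize"]


@dataclass
class TwoChannelImage:
    """Two equal-shape intensity grids (channel A, channel B) with an
    optional boolean analysis mask."""

    a: np.ndarray
    b: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValueError("channel shapes must match")
        for name, ch in (("A", self.a), ("B", self.b)):
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name} must be finite")
            if np.any(ch < 0):
                raise ValueError(
                    f"channel {name} must be non-negative (background-subtracted)"
                )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.a.shape:
                raise ValueError("mask shape must match the channels")

    def masked(self) -> tuple[np.ndarray, np.ndarray]:
        if self.mask is None:
            return self.a.ravel(), self.b.ravel()
        return self.a[self.mask], self.b[self.mask]


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float
    manders_m1: float
    manders_m2: float
    manders_m2_pixel_count: float
    threshold_a: float
    threshold_b: float


def pearson_r(img: TwoChannelImage) -> float:
    """Sample linear correlation of the two channels over masked pixels."""
    a, b = img.masked()
    if a.size < 2:
        raise UndefinedCoefficientError("Pearson's r requires >= 2 pixels")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCoefficientError(
            "Pearson's r undefined for a constant channel"
        )
    return float(np.corrcoef(a, b)[0, 1])


def manders(
    img: TwoChannelImage, threshold_a: float = 0.0, threshold_b: float = 0.0
) -> tuple[float, float, float]:
    """Manders coefficients (M1, M2, pixel-count M2).

    * M1 (intensity-weighted) = sum of A over pixels with B > threshold_b,
      divided by the total sum of A.
    * M2 is symmetric with channel roles swapped.
    * Pixel-count M2 = |{B > tB and A > tA}| / |{B > tB}|: the fraction of
      B-positive pixels that also carry A signal.
    """
    if threshold_a < 0 or threshold_b < 0:
        raise ValueError("thresholds must be >= 0")
    a, b = img.masked()
    sum_a, sum_b = a.sum(), b.sum()
    if sum_a == 0 or sum_b == 0:
        raise UndefinedCoefficientError("a channel has no signal")
    b_pos = b > threshold_b
    a_pos = a > threshold_a
    n_b_pos = int(b_pos.sum())
    if n_b_pos == 0 or not a_pos.any():
        raise UndefinedCoefficientError(
            "no pixels above threshold in one of the channels"
        )
    m1 = float(a[b_pos].sum() / sum_a)
    m2 = float(b[a_pos].sum() / sum_b)
    m2_counts = float((b_pos & a_pos).sum() / n_b_pos)
    return m1, m2, m2_counts


def colocalize(
    img: TwoChannelImage, threshold_a: float = 0.0, threshold_b: float = 0.0
) -> ColocResult:
    """All colocalization metrics for one image pair."""
    m1, m2, m2c = manders(img, threshold_a, threshold_b)
    return ColocResult(
        pearson_r=pearson_r(img),
        manders_m1=m1,
        manders_m2=m2,
        manders_m2_pixel_count=m2c,
        threshold_a=threshold_a,
        threshold_b=threshold_b,
    )
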