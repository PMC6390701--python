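"""Confirmation of primary-screen hits against an independent retest screen.

The primary screen's MAD scoring needs a large, unbiased well population,
which a small retest plate — enriched for predicted positives — cannot
provide.  Instead both screens' raw absorbances are made comparable by
robust standardization with the interquartile range, (x - median) / IQR,
applied to each dataset separately.  Per unordered pair, the geometric mean
of the two normalized orientation values summarizes the interaction; the
confirmation threshold is the smallest such geometric mean among the
primary screen's bidirectional hits (the weakest pair still included), and
a retest pair is confirmed when its geometric mean strictly exceeds that
threshold.  Reproducibility is quantified by the Spearman rank correlation
between primary and retest geometric means, and hit distributions are
compared to pooled prey-only negative controls with a rank-based two-sample
(Mann-Whitney) test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class PairedMeasurement:
    """Raw A650 absorbances of one unordered pair in both screens.

    ``pair`` is lexicographically ordered; ``*_ab`` is the orientation with
    ``pair[0]`` as bait, ``*_ba`` the reverse.  Missing orientations are NaN.
    For self-pairs only ``*_ab`` is meaningful (one well covers both
    directions).
    """

    pair: tuple[str, str]
    primary_ab: float = math.nan
    primary_ba: float = math.nan
    retest_ab: float = math.nan
    retest_ba: float = math.nan
    is_predicted_hit: bool = False

    def __post_init__(self):
        self.pair = tuple(sorted(self.pair))


@dataclass
class ValidationResult:
    """Outcome of confirming primary hits in the retest screen."""

    threshold: float
    confirmed: set = field(default_factory=set)
    confirmation_rate: float = math.nan
    spearman_rho: float = math.nan


class IQRNormalizer(TransformerMixin, BaseEstimator):
    """Robust standardizer (x - median) / IQR with linear-interpolation quantiles.

    The IQR is Q3 - Q1 computed by linear interpolation between order
    statistics (the numpy default).  The quantile convention matters for
    small samples and is fixed here for reproducibility.
    """

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size < 4:
            raise ValueError("IQR normalization requires >= 4 finite values")
        q1, q3 = np.percentile(x, [25, 75])
        self.center_ = float(np.median(x))
        self.scale_ = float(q3 - q1)
        if self.scale_ == 0.0:
            raise ValueError("degenerate distribution: IQR is 0")
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        return (np.asarray(X, dtype=float) - self.center_) / self.scale_


def iqr_normalize(values) -> np.ndarray:
    """Elementwise (x - median) / IQR; wrapper over :class:`IQRNormalizer`."""
    norm = IQRNormalizer().fit(values)
    return norm.transform(np.asarray(values, dtype=float))


def geo_mean_pair(value_ab: float, value_ba: float, self_pair: bool = False) -> float:
    """Geometric mean of two normalized orientation values.

    Defined only when the values are present and strictly positive; two
    negative values must not multiply into a positive summary, and a
    below-median (negative) normalized value is not a signal.  Self-pairs
    are one well, so their single value stands in for the geometric mean,
    under the same positivity guard.
    """
    if self_pair:
        return float(value_ab) if value_ab > 0 else math.nan
    if not (math.isfinite(value_ab) and math.isfinite(value_ba)):
        return math.nan
    if value_ab <= 0 or value_ba <= 0:
        return math.nan
    return math.sqrt(value_ab * value_ba)


def _screen_values(pairs: list[PairedMeasurement], screen: str) -> list[float]:
    ab_attr, ba_attr = f"{screen}_ab", f"{screen}_ba"
    out = []
    for p in pairs:
        self_pair = p.pair[0] == p.pair[1]
        ab, ba = getattr(p, ab_attr), getattr(p, ba_attr)
        if math.isfinite(ab):
            out.append(ab)
        if math.isfinite(ba) and not self_pair:
            out.append(ba)
    return out


def _normalized_geo_means(
    pairs: list[PairedMeasurement], screen: str, normalization: str = "separate"
) -> dict[tuple[str, str], float]:
    """IQR-normalize one screen's pooled raw values, then geo-mean per pair.

    ``normalization="separate"`` (default) fits the median/IQR on this
    screen's values alone; ``"joint"`` fits them on the primary and retest
    values pooled together, so both screens share one scale.
    """
    if screen not in ("primary", "retest"):
        raise ValueError(f"screen must be 'primary' or 'retest', got {screen!r}")
    if normalization not in ("separate", "joint"):
        raise ValueError(
            f"normalization must be 'separate' or 'joint', got {normalization!r}"
        )
    ab_attr, ba_attr = f"{screen}_ab", f"{screen}_ba"
    if normalization == "joint":
        pooled = _screen_values(pairs, "primary") + _screen_values(pairs, "retest")
    else:
        pooled = _screen_values(pairs, screen)
    norm = IQRNormalizer().fit(pooled)
    out = {}
    for p in pairs:
        self_pair = p.pair[0] == p.pair[1]
        ab, ba = getattr(p, ab_attr), getattr(p, ba_attr)
        n_ab = float(norm.transform([ab])[0]) if math.isfinite(ab) else math.nan
        n_ba = float(norm.transform([ba])[0]) if math.isfinite(ba) else math.nan
        out[p.pair] = geo_mean_pair(n_ab, n_ba, self_pair=self_pair)
    return out


def derive_threshold(
    primary_pairs: list[PairedMeasurement],
    primary_hits: pd.DataFrame,
    normalization: str = "separate",
) -> float:
    """Confirmation threshold: the minimum IQR-normalized geometric-mean
    absorbance over the primary screen's bidirectional hits.

    This is the weakest normalized signal still included in the
    bidirectional set, i.e. the parameter-free inclusion threshold.
    """
    bid = primary_hits[primary_hits["hit_class"] == "bidirectional"]
    bid_pairs = {tuple(sorted(t)) for t in zip(bid["id_a"], bid["id_b"])}
    if not bid_pairs:
        raise ValueError("no bidirectional pairs in the primary hit table")
    geo = _normalized_geo_means(primary_pairs, "primary", normalization)
    candidates = [g for pair, g in geo.items() if pair in bid_pairs and math.isfinite(g)]
    if not candidates:
        raise ValueError(
            "no bidirectional hit with a defined normalized geometric mean "
            "among the paired measurements"
        )
    return float(min(candidates))


def confirm_hits(
    pairs: list[PairedMeasurement],
    threshold: float,
    normalization: str = "separate",
) -> ValidationResult:
    """Confirm pairs whose retest normalized geometric mean strictly exceeds
    ``threshold``; the confirmation rate is computed over predicted hits.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    retest_geo = _normalized_geo_means(pairs, "retest", normalization)
    confirmed = {
        pair for pair, g in retest_geo.items() if math.isfinite(g) and g > threshold
    }
    predicted = {p.pair for p in pairs if p.is_predicted_hit}
    rate = len(confirmed & predicted) / len(predicted) if predicted else math.nan
    try:
        rho = spearman_reproducibility(pairs)
    except ValueError:
        rho = math.nan
    return ValidationResult(
        threshold=float(threshold),
        confirmed=confirmed,
        confirmation_rate=rate,
        spearman_rho=rho,
    )


def _raw_geo_means(
    pairs: list[PairedMeasurement], screen: str
) -> dict[tuple[str, str], float]:
    """Geometric mean of the raw (non-negative) orientation absorbances.

    Used for rank-based comparisons: raw absorbances are non-negative so the
    geometric mean is always defined when both orientations were measured,
    and ranks are unchanged by any monotone normalization.
    """
    ab_attr, ba_attr = f"{screen}_ab", f"{screen}_ba"
    out = {}
    for p in pairs:
        ab, ba = getattr(p, ab_attr), getattr(p, ba_attr)
        if p.pair[0] == p.pair[1]:
            out[p.pair] = float(ab)
        elif math.isfinite(ab) and math.isfinite(ba):
            out[p.pair] = math.sqrt(ab * ba)
        else:
            out[p.pair] = math.nan
    return out


def spearman_reproducibility(pairs: list[PairedMeasurement]) -> float:
    """Spearman rank correlation between the primary and retest screens'
    per-pair geometric-mean absorbances (ties by average rank).

    Computed on the raw-value geometric means, which are defined whenever
    both orientations were measured; the result is invariant under any
    strictly monotone transform of either screen's values, so it is
    unaffected by whether or how the screens were normalized.
    """
    primary_geo = _raw_geo_means(pairs, "primary")
    retest_geo = _raw_geo_means(pairs, "retest")
    x, y = [], []
    for p in pairs:
        a, b = primary_geo[p.pair], retest_geo[p.pair]
        if math.isfinite(a) and math.isfinite(b):
            x.append(a)
            y.append(b)
    if len(x) < 3:
        raise ValueError(
            f"Spearman reproducibility requires >= 3 pairs defined in both "
            f"screens, got {len(x)}"
        )
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def compare_distributions(hit_values, control_values) -> dict:
    """Rank-based two-sample comparison of hit vs pooled negative-control
    value distributions (Mann-Whitney U, two-sided).

    Returns a dict with the U statistic (for the hit sample), the two-sided
    p-value, and both sample sizes.
    """
    x = np.asarray(hit_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", use_continuity=False)
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_hits": int(x.size),
        "n_controls": int(y.size),
    }
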