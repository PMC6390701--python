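"""MAD-unit scoring of polish residuals and interaction hit calling.

After median polish the residual distribution is unimodal, centred near
zero, with a right tail holding the true interactions.  Because that tail
would corrupt a mean/standard-deviation standardization, residuals are
scored robustly: each residual is expressed as the number of raw MAD units
(median absolute deviation, *without* the 1.4826 normal-consistency
constant) it sits above the screen-wide residual median.  The fixed cutoff
of 2.5 MAD units is stated in these raw units; users comparing against
robust-z conventions should divide by 1.4826 accordingly.

Each unordered protein pair is measured in two orientations (A as bait vs
B as bait).  A pair is *bidirectional* when the geometric mean of its two
orientation scores strictly exceeds the cutoff — defined only when both
scores are positive, so that two below-median wells can never multiply into
a hit — and *unidirectional* when it is not bidirectional but one
orientation strictly exceeds the cutoff.  Self-pairs are assayed in a
single well that covers both directions, so their lone score doubles as the
geometric mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

#: The screen's fixed hit-calling cutoff, in raw MAD units.
DEFAULT_CUTOFF = 2.5

HIT_CLASSES = ("bidirectional", "unidirectional", "none")


def mad(values) -> float:
    """Median absolute deviation: median(|x - median(x)|), no scale factor."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("mad requires at least one value")
    if not np.isfinite(x).all():
        raise ValueError("mad requires finite values")
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


class MADScorer(TransformerMixin, BaseEstimator):
    """Robust screen-wide standardizer: (x - median) / MAD.

    The median and MAD are pooled over *all* non-missing cells of the
    fitting matrix — not per row or column — so a score of s means "s MAD
    units above the screen-wide residual median".

    Attributes
    ----------
    center_ : float
        Pooled median of the fitting residuals.
    scale_ : float
        Pooled raw MAD (no consistency constant).
    """

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        values = values[np.isfinite(values)]
        if values.size == 0:
            raise ValueError("no finite residuals to score")
        self.center_ = float(np.median(values))
        self.scale_ = float(np.median(np.abs(values - self.center_)))
        if self.scale_ == 0.0:
            raise ValueError(
                "degenerate residual distribution: pooled MAD is 0, "
                "scores are undefined"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        return (X - self.center_) / self.scale_


def score_residuals(residuals: pd.DataFrame) -> pd.DataFrame:
    """Convert residuals to screen-wide MAD-unit scores.

    Missing cells stay missing.  Raises if the pooled MAD is zero.
    """
    return MADScorer().fit(residuals).transform(residuals)


class HitCaller(BaseEstimator):
    """Classify every unordered protein pair from a square score matrix.

    ``fit`` consumes an orientation-resolved score matrix whose bait and
    prey identifier sets are identical and populates ``hits_`` with one row
    per unordered pair (self-pairs included).

    Parameters
    ----------
    cutoff : float, default 2.5
        Strict threshold in MAD units, applied to the geometric-mean score
        (bidirectional class) and to single-orientation scores
        (unidirectional class).

    Attributes
    ----------
    hits_ : pandas.DataFrame
        Columns ``id_a``, ``id_b`` (lexicographically ordered, a <= b),
        ``score_ab`` (a as bait), ``score_ba`` (b as bait), ``geo_mean_score``
        (NaN when undefined), ``hit_class``.  ``hits_.attrs["cutoff"]``
        records the cutoff used.
    """

    def __init__(self, cutoff: float = DEFAULT_CUTOFF):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        if not self.cutoff > 0:
            raise ValueError("cutoff must be > 0")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = X.index
        if set(X.index) != set(X.columns) or X.shape[0] != X.shape[1]:
            raise ValueError(
                "hit calling requires a square score matrix with identical "
                f"bait and prey identifier sets; got {X.shape[0]} baits and "
                f"{X.shape[1]} preys"
            )
        ids = sorted(X.index)
        S = X.loc[ids, ids].to_numpy(dtype=float)
        n = len(ids)
        iu, ju = np.triu_indices(n)
        score_ab = S[iu, ju]  # id_a as bait
        score_ba = S[ju, iu]  # id_b as bait
        is_self = iu == ju

        both_pos = (score_ab > 0) & (score_ba > 0)
        with np.errstate(invalid="ignore"):
            geo = np.where(both_pos, np.sqrt(score_ab * score_ba), np.nan)
        # a self-pair is one well covering both directions: its score is its
        # geometric mean, whatever its sign
        geo = np.where(is_self, score_ab, geo)

        with np.errstate(invalid="ignore"):
            bid = geo > self.cutoff
            best = np.fmax(score_ab, score_ba)  # ignores a missing orientation
            uni = ~bid & (best > self.cutoff)
        classes = np.where(bid, "bidirectional", np.where(uni, "unidirectional", "none"))

        hits = pd.DataFrame(
            {
                "id_a": np.asarray(ids, dtype=object)[iu],
                "id_b": np.asarray(ids, dtype=object)[ju],
                "score_ab": score_ab,
                "score_ba": score_ba,
                "geo_mean_score": geo,
                "hit_class": classes,
            }
        )
        hits.attrs["cutoff"] = float(self.cutoff)
        self.hits_ = hits
        return self


def call_hits(scores: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Call unidirectional/bidirectional hits; wrapper over :class:`HitCaller`."""
    return HitCaller(cutoff=cutoff).fit(scores).hits_


def summarize_hits(hits: pd.DataFrame) -> dict:
    """Summary counts and rates for a hit table.

    Returns a dict with the number of bidirectional and unidirectional
    pairs, the total ordered tests (non-missing orientation measurements),
    the total unordered pairs tested (C(n, 2) + n for a complete n x n
    screen), and the two headline percentages: unidirectional hits per
    ordered test and bidirectional hits per unordered pair.
    """
    if len(hits) == 0:
        return {
            "n_bidirectional": 0,
            "n_unidirectional": 0,
            "total_ordered_tests": 0,
            "total_unordered_tests": 0,
            "pct_unidirectional_of_ordered": 0.0,
            "pct_bidirectional_of_unordered": 0.0,
        }
    n_bid = int((hits["hit_class"] == "bidirectional").sum())
    n_uni = int((hits["hit_class"] == "unidirectional").sum())
    is_self = hits["id_a"] == hits["id_b"]
    ordered = int(
        hits["score_ab"].notna().sum() + (hits["score_ba"].notna() & ~is_self).sum()
    )
    unordered = int(len(hits))
    return {
        "n_bidirectional": n_bid,
        "n_unidirectional": n_uni,
        "total_ordered_tests": ordered,
        "total_unordered_tests": unordered,
        "pct_unidirectional_of_ordered": 100.0 * n_uni / ordered if ordered else 0.0,
        "pct_bidirectional_of_unordered": (
            100.0 * n_bid / unordered if unordered else 0.0
        ),
    }
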