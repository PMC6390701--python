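import math

import numpy as np
import pytest
import pandas as pd
from hypothesis import given
from hypothesis import strategies as st

from ecia import (
    IQRNormalizer,
    PairedMeasurement,
    compare_distributions,
    confirm_hits,
    derive_threshold,
    geo_mean_pair,
    iqr_normalize,
    spearman_reproducibility,
)


class TestIqrNormalize:
    def test_hand_computed_example(self):
        # median 3, Q1 2, Q3 4 (linear interpolation), IQR 2
        out = iqr_normalize([1, 2, 3, 4, 5])
        assert np.allclose(out, [-1, -0.5, 0, 0.5, 1], atol=1e-12)

    def test_fixed_point(self):
        x = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        assert np.allclose(iqr_normalize(x), x, atol=1e-9)

    @given(
        st.floats(min_value=0.01, max_value=100),
        st.floats(min_value=-50, max_value=50),
    )
    def test_affine_invariance(self, a, b):
        x = np.array([0.1, 0.9, 0.3, 2.0, 0.2, 0.4, 1.1])
        assert np.allclose(iqr_normalize(a * x + b), iqr_normalize(x), atol=1e-7)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            iqr_normalize([1, 2, 3])

    def test_zero_iqr_rejected(self):
        with pytest.raises(ValueError, match="IQR is 0"):
            iqr_normalize([5, 5, 5, 5, 5])

    def test_transformer_applies_fitted_params_to_new_data(self):
        norm = IQRNormalizer().fit([1, 2, 3, 4, 5])
        assert norm.transform([3.0])[0] == pytest.approx(0.0)
        assert norm.transform([7.0])[0] == pytest.approx(2.0)


class TestGeoMeanPair:
    def test_product_rule(self):
        assert geo_mean_pair(0.04, 0.25) == pytest.approx(0.1)

    @pytest.mark.parametrize("ab,ba", [(0.0, 0.5), (-0.1, 0.5), (0.5, -2.0)])
    def test_nonpositive_orientation_undefined(self, ab, ba):
        assert math.isnan(geo_mean_pair(ab, ba))

    def test_missing_orientation_undefined(self):
        assert math.isnan(geo_mean_pair(0.5, math.nan))

    def test_self_pair_returns_single_value(self):
        assert geo_mean_pair(0.3, math.nan, self_pair=True) == pytest.approx(0.3)

    def test_self_pair_guarded_against_nonpositive_value(self):
        assert math.isnan(geo_mean_pair(-0.3, math.nan, self_pair=True))


def make_pairs(primary, retest=None, hits=None):
    """Build PairedMeasurements from {pair: (ab, ba)} dicts."""
    retest = retest or {}
    hits = hits or set()
    out = []
    for pair, (ab, ba) in primary.items():
        r_ab, r_ba = retest.get(pair, (math.nan, math.nan))
        out.append(
            PairedMeasurement(
                pair=pair,
                primary_ab=ab,
                primary_ba=ba,
                retest_ab=r_ab,
                retest_ba=r_ba,
                is_predicted_hit=tuple(sorted(pair)) in hits,
            )
        )
    return out


def hit_table(bidirectional_pairs):
    return pd.DataFrame(
        {
            "id_a": [a for a, _ in bidirectional_pairs],
            "id_b": [b for _, b in bidirectional_pairs],
            "score_ab": 5.0,
            "score_ba": 5.0,
            "geo_mean_score": 5.0,
            "hit_class": "bidirectional",
        }
    )


class TestDeriveThreshold:
    def base_pairs(self):
        # spread of background pairs so the pooled IQR is well defined
        primary = {
            ("A", "B"): (0.9, 1.1),
            ("C", "D"): (0.7, 0.8),
            ("E", "F"): (1.5, 1.4),
            ("G", "H"): (0.2, 0.25),
            ("I", "J"): (0.3, 0.35),
        }
        return make_pairs(primary)

    def test_threshold_is_minimum_over_bidirectional_hits(self):
        pairs = self.base_pairs()
        hits = hit_table([("A", "B"), ("C", "D"), ("E", "F")])
        thr = derive_threshold(pairs, hits)
        geo = {}
        from ecia.validation import _normalized_geo_means

        geo = _normalized_geo_means(pairs, "primary")
        expected = min(geo[("A", "B")], geo[("C", "D")], geo[("E", "F")])
        assert thr == pytest.approx(expected, abs=1e-12)

    def test_singleton_hit_set(self):
        pairs = self.base_pairs()
        hits = hit_table([("E", "F")])
        from ecia.validation import _normalized_geo_means

        geo = _normalized_geo_means(pairs, "primary")
        assert derive_threshold(pairs, hits) == pytest.approx(geo[("E", "F")])

    def test_no_bidirectional_pairs_rejected(self):
        pairs = self.base_pairs()
        hits = hit_table([]).iloc[0:0]
        with pytest.raises(ValueError, match="no bidirectional"):
            derive_threshold(pairs, hits)

    @given(
        st.floats(min_value=0.1, max_value=20),
        st.floats(min_value=-2, max_value=2),
    )
    def test_invariant_under_affine_transform_of_raw_values(self, a, b):
        pairs = self.base_pairs()
        hits = hit_table([("A", "B"), ("E", "F")])
        thr0 = derive_threshold(pairs, hits)
        scaled = [
            PairedMeasurement(
                pair=p.pair,
                primary_ab=a * p.primary_ab + b,
                primary_ba=a * p.primary_ba + b,
            )
            for p in pairs
        ]
        thr1 = derive_threshold(scaled, hits)
        # affine shifts move values across the positivity guard only if the
        # normalized values change sign; IQR normalization prevents that
        assert thr1 == pytest.approx(thr0, abs=1e-7)


class TestConfirmHits:
    def paired_screens(self):
        primary = {
            ("A", "B"): (0.9, 1.1),
            ("C", "D"): (0.85, 0.95),
            ("E", "F"): (0.2, 0.25),
            ("G", "H"): (0.3, 0.28),
            ("I", "J"): (0.22, 0.31),
        }
        retest = {
            ("A", "B"): (1.0, 1.05),
            ("C", "D"): (0.9, 1.0),
            ("E", "F"): (0.21, 0.24),
            ("G", "H"): (0.29, 0.3),
            ("I", "J"): (0.25, 0.27),
        }
        return make_pairs(primary, retest, hits={("A", "B"), ("C", "D")})

    def test_strict_threshold_boundary(self):
        pairs = self.paired_screens()
        from ecia.validation import _normalized_geo_means

        geo = _normalized_geo_means(pairs, "retest")
        exactly = geo[("A", "B")]
        result = confirm_hits(pairs, exactly)
        assert ("A", "B") not in result.confirmed

    def test_high_signal_pairs_confirmed(self):
        pairs = self.paired_screens()
        from ecia.validation import _normalized_geo_means

        geo = _normalized_geo_means(pairs, "retest")
        hit_geos = [geo[("A", "B")], geo[("C", "D")]]
        background_geos = [
            g for p, g in geo.items()
            if p not in {("A", "B"), ("C", "D")} and math.isfinite(g)
        ]
        thr = min(hit_geos) - 1e-9
        assert all(g < thr for g in background_geos)  # scenario sanity
        result = confirm_hits(pairs, thr)
        assert result.confirmed == {("A", "B"), ("C", "D")}
        assert result.confirmation_rate == 1.0

    def test_all_below_threshold_gives_zero_rate(self):
        pairs = self.paired_screens()
        result = confirm_hits(pairs, 1e9)
        assert result.confirmed == set()
        assert result.confirmation_rate == 0.0

    def test_monotone_in_threshold(self):
        pairs = self.paired_screens()
        low = confirm_hits(pairs, 0.1)
        high = confirm_hits(pairs, 0.5)
        assert high.confirmed <= low.confirmed

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValueError):
            confirm_hits(self.paired_screens(), math.inf)

    def test_joint_normalization_shares_one_scale(self):
        # under joint normalization a pair with identical raw values in both
        # screens gets identical geometric means; under separate
        # normalization the two screens' scales differ
        pairs = self.paired_screens()
        from ecia.validation import _normalized_geo_means

        shared = pairs[0].pair  # ("A","B"): retest values differ from primary
        same = [
            PairedMeasurement(
                pair=p.pair,
                primary_ab=p.primary_ab,
                primary_ba=p.primary_ba,
                retest_ab=p.primary_ab if p.pair == shared else p.retest_ab,
                retest_ba=p.primary_ba if p.pair == shared else p.retest_ba,
            )
            for p in pairs
        ]
        joint_p = _normalized_geo_means(same, "primary", "joint")
        joint_r = _normalized_geo_means(same, "retest", "joint")
        assert joint_r[shared] == pytest.approx(joint_p[shared], abs=1e-12)
        sep_r = _normalized_geo_means(same, "retest", "separate")
        assert sep_r[shared] != pytest.approx(joint_r[shared], abs=1e-9)


def brute_force_spearman(x, y):
    """Rank (average ties) then Pearson, with plain Python."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


class TestSpearman:
    def screens_with_values(self, primary_vals, retest_vals):
        primary = {}
        retest = {}
        for i, (pv, rv) in enumerate(zip(primary_vals, retest_vals)):
            pair = (f"A{i}", f"B{i}")
            primary[pair] = (pv, pv * 1.01)
            retest[pair] = (rv, rv * 1.01)
        return make_pairs(primary, retest)

    def test_monotone_transform_gives_one(self):
        pv = [0.2, 0.5, 0.9, 1.4, 2.0, 3.3]
        rv = [v**2 + 1 for v in pv]
        pairs = self.screens_with_values(pv, rv)
        assert spearman_reproducibility(pairs) == pytest.approx(1.0)

    def test_reversed_ranking_gives_minus_one(self):
        pv = [0.2, 0.5, 0.9, 1.4, 2.0, 3.3]
        rv = [10.0, 6.0, 4.0, 3.0, 2.5, 2.1]
        pairs = self.screens_with_values(pv, rv)
        assert spearman_reproducibility(pairs) == pytest.approx(-1.0)

    def test_matches_brute_force_rank_oracle(self):
        rng = np.random.default_rng(7)
        pv = list(rng.uniform(0.1, 3.0, size=10))
        rv = list(rng.uniform(0.1, 3.0, size=10))
        pairs = self.screens_with_values(pv, rv)
        geo_p = [math.sqrt(p.primary_ab * p.primary_ba) for p in pairs]
        geo_r = [math.sqrt(p.retest_ab * p.retest_ba) for p in pairs]
        expected = brute_force_spearman(geo_p, geo_r)
        assert spearman_reproducibility(pairs) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        pv = list(rng.uniform(0.1, 3.0, size=8))
        rv = list(rng.uniform(0.1, 3.0, size=8))
        pairs = self.screens_with_values(pv, rv)
        transformed = self.screens_with_values([v**3 for v in pv], rv)
        assert spearman_reproducibility(pairs) == pytest.approx(
            spearman_reproducibility(transformed), abs=1e-12
        )

    def test_too_few_pairs_rejected(self):
        pairs = self.screens_with_values([1.0, 2.0, 0.1, 0.2], [1.0, 2.0, 0.1, 0.2])[:2]
        with pytest.raises(ValueError, match=">= 3"):
            spearman_reproducibility(pairs)


def brute_force_u(x, y):
    """U statistic for sample x by exhaustive pairwise comparison."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1
            elif a == b:
                u += 0.5
    return u


class TestCompareDistributions:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_distributions(x, list(x))
        assert res["U"] == pytest.approx(len(x) ** 2 / 2)  # null mean
        assert res["p_value"] > 0.95

    def test_complete_separation(self):
        res = compare_distributions([10, 11, 12, 13, 14, 15], [1, 2, 3, 4, 5, 6])
        assert res["U"] == 36  # maximum = n_x * n_y
        assert res["p_value"] < 0.05

    def test_u_matches_exhaustive_count(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 1.0, size=12)
        y = rng.normal(0.0, 1.0, size=15)
        res = compare_distributions(x, y)
        assert res["U"] == pytest.approx(brute_force_u(x, y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])
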