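"""Agreement statistics: kappa, interpretation bands, CIs, and group tests."""

import math
import random
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from surveysift.agreement import (
    ConfusionMatrix2x2,
    build_confusion,
    chi_square_test,
    cohen_kappa,
    fraud_proportion_series,
    interpret_kappa,
    mann_whitney,
    mean_ci_normal,
    t_test,
)
from surveysift.types import DataError, Label


def labels_from(ids, fraud_ids):
    return {i: Label.FRAUD if i in fraud_ids else Label.VALID for i in ids}


class TestBuildConfusion:
    def test_identical_maps_diagonal(self):
        ids = [f"r{i}" for i in range(10)]
        fraud = set(ids[:6])
        cm = build_confusion(labels_from(ids, fraud), labels_from(ids, fraud))
        assert (cm.a, cm.b, cm.c, cm.d) == (6, 0, 0, 4)

    def test_complementary_maps_off_diagonal(self):
        ids = [f"r{i}" for i in range(10)]
        fraud = set(ids[:4])
        cm = build_confusion(labels_from(ids, fraud), labels_from(ids, set(ids) - fraud))
        assert cm.b + cm.c == cm.n == 10

    def test_random_maps_match_enumeration_oracle(self):
        rng = random.Random(13)
        ids = [f"r{i}" for i in range(50)]
        fa = {i for i in ids if rng.random() < 0.5}
        fb = {i for i in ids if rng.random() < 0.4}
        cm = build_confusion(labels_from(ids, fa), labels_from(ids, fb))
        assert cm.a == len(fa & fb)
        assert cm.b == len(fa - fb)
        assert cm.c == len(fb - fa)
        assert cm.d == 50 - len(fa | fb)

    def test_mismatched_ids_rejected(self):
        with pytest.raises(DataError):
            build_confusion({"a": Label.VALID}, {"b": Label.VALID})


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionMatrix2x2(10, 0, 0, 10)).kappa == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        assert cohen_kappa(ConfusionMatrix2x2(25, 25, 25, 25)).kappa == pytest.approx(0.0)

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(DataError):
            cohen_kappa(ConfusionMatrix2x2(0, 0, 0, 10))

    def test_matches_sklearn_on_random_tables(self):
        """Independent cross-check of the point estimate against sklearn."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 200, size=4)
            cm = ConfusionMatrix2x2(int(a), int(b), int(c), int(d))
            y1 = [1] * (a + b) + [0] * (c + d)
            y2 = [1] * a + [0] * b + [1] * c + [0] * d
            assert cohen_kappa(cm).kappa == pytest.approx(
                cohen_kappa_score(y1, y2), abs=1e-12
            )

    def test_se_formula(self):
        cm = ConfusionMatrix2x2(40, 10, 15, 35)
        k = cohen_kappa(cm)
        se = math.sqrt(k.po * (1 - k.po) / (cm.n * (1 - k.pe) ** 2))
        assert k.se == pytest.approx(se)
        assert k.ci_low < k.kappa < k.ci_high

    @given(
        st.integers(1, 500), st.integers(0, 500), st.integers(0, 500), st.integers(1, 500)
    )
    @settings(max_examples=100, deadline=None)
    def test_label_swap_invariance(self, a, b, c, d):
        """kappa is unchanged when both raters swap fraud/valid (a<->d, b<->c)."""
        k1 = cohen_kappa(ConfusionMatrix2x2(a, b, c, d)).kappa
        k2 = cohen_kappa(ConfusionMatrix2x2(d, c, b, a)).kappa
        assert k1 == pytest.approx(k2, abs=1e-12)

    @given(
        st.integers(1, 300), st.integers(0, 300), st.integers(0, 300), st.integers(1, 300)
    )
    @settings(max_examples=100, deadline=None)
    def test_kappa_one_iff_no_disagreement_and_bounded_by_po(self, a, b, c, d):
        k = cohen_kappa(ConfusionMatrix2x2(a, b, c, d))
        assert math.isclose(k.kappa, 1.0) == (b == 0 and c == 0)
        assert k.kappa <= k.po + 1e-12

    def test_ci_width_shrinks_as_inverse_sqrt_n(self):
        narrow = cohen_kappa(ConfusionMatrix2x2(400, 100, 150, 350))
        wide = cohen_kappa(ConfusionMatrix2x2(100, 25, 37, 88))
        assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)
        ratio = (wide.ci_high - wide.ci_low) / (narrow.ci_high - narrow.ci_low)
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "kappa, bands",
        [
            (0.25, ("fair", "minimal")),
            (0.13, ("slight", "none")),
            (0.48, ("moderate", "weak")),
            (1.0, ("almost perfect", "almost perfect")),
            (-0.2, ("poor", "none")),
            (0.20, ("slight", "none")),
            (0.85, ("almost perfect", "strong")),
        ],
    )
    def test_bands(self, kappa, bands):
        assert interpret_kappa(kappa) == bands

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)


class TestMeanCiNormal:
    def test_zero_variance_degenerate_interval(self):
        e = mean_ci_normal(0.4, 0.0, 50)
        assert (e.ci_low, e.ci_high) == (0.4, 0.4)

    def test_half_width_formula(self):
        e = mean_ci_normal(0.5, 0.2, 100)
        assert e.ci_high - e.mean == pytest.approx(1.959964 * 0.2 / 10, rel=1e-5)

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            mean_ci_normal(0.5, 0.2, 0)


class TestChiSquare:
    def test_no_association_gives_zero(self):
        r = chi_square_test([[10, 10], [10, 10]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # expected cells are all 15; sum of (O-E)^2/E = 4 * 25/15 = 20/3
        r = chi_square_test([[20, 10], [10, 20]])
        assert r.statistic == pytest.approx(20 / 3)

    def test_random_2x3_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        obs = rng.integers(5, 40, size=(2, 3)).astype(float)
        expected = stats.contingency.expected_freq(obs)
        oracle = ((obs - expected) ** 2 / expected).sum()
        assert chi_square_test(obs).statistic == pytest.approx(oracle)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(DataError):
            chi_square_test([[0, 5], [0, 5]])


class TestTTest:
    def test_identical_samples_null(self):
        r = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_welch_statistic(self):
        # means 0.5, 10.5; each variance 0.5; se = sqrt(0.5/2 + 0.5/2)
        r = t_test([0.0, 1.0], [10.0, 11.0])
        assert r.statistic == pytest.approx(-10.0 / math.sqrt(0.5))

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [2.0, 3.0])


class TestMannWhitney:
    def test_exact_small_sample(self):
        r = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(2 / 6)

    def test_symmetric_interleave_gives_central_u(self):
        r = mann_whitney([2.0, 3.0, 6.0, 7.0], [1.0, 4.0, 5.0, 8.0])
        assert r.statistic == pytest.approx(4 * 4 / 2)
        assert r.p_value == pytest.approx(1.0)

    def test_exact_path_matches_independent_enumeration(self):
        rng = random.Random(21)
        for _ in range(10):
            pooled = rng.sample(range(100), 9)
            x, y = [float(v) for v in pooled[:4]], [float(v) for v in pooled[4:]]
            got = mann_whitney(x, y)
            # independent oracle: enumerate assignments, count >= extreme U
            n = len(pooled)
            mu = len(x) * len(y) / 2
            vals = [float(v) for v in pooled]

            def u_of(idx):
                xs = [vals[i] for i in idx]
                ys = [vals[i] for i in range(n) if i not in idx]
                return sum(1 for a in xs for b in ys if a > b)

            u_obs = u_of(tuple(range(len(x))))
            dist = [u_of(idx) for idx in combinations(range(n), len(x))]
            p = sum(1 for u in dist if abs(u - mu) >= abs(u_obs - mu)) / len(dist)
            assert got.statistic == pytest.approx(u_obs)
            assert got.p_value == pytest.approx(p)

    def test_exact_agrees_with_scipy_exact(self):
        x, y = [3.0, 9.0, 11.0], [1.0, 4.0, 6.0, 8.0]
        got = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert got.statistic == pytest.approx(float(ref.statistic))
        assert got.p_value == pytest.approx(float(ref.pvalue))

    def test_asymptotic_near_permutation_oracle_n30(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.0, 1.0, 15)
        y = rng.normal(0.7, 1.0, 15)
        got = mann_whitney(list(x), list(y))
        pooled = np.concatenate([x, y])
        u_obs = got.statistic
        mu = 15 * 15 / 2
        draws = 100_000
        count = 0
        for _ in range(draws):
            perm = rng.permutation(pooled)
            xs, ys = perm[:15], perm[15:]
            u = (xs[:, None] > ys[None, :]).sum()
            if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                count += 1
        assert got.p_value == pytest.approx(count / draws, abs=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFraudProportionSeries:
    def _labels(self, ids, fraud_ids):
        return labels_from(ids, fraud_ids)

    def test_all_fraud_day_is_one(self):
        import pandas as pd

        ts = {f"r{i}": pd.Timestamp("2021-11-05 10:00") for i in range(4)}
        series = fraud_proportion_series(
            ts, {"m": self._labels(ts, set(ts))}, window_days=1
        )
        assert series.loc["2021-11-05", "m"] == pytest.approx(1.0)

    def test_empty_day_is_missing(self):
        import pandas as pd

        ts = {"a": pd.Timestamp("2021-11-01 09:00"), "b": pd.Timestamp("2021-11-05 09:00")}
        series = fraud_proportion_series(ts, {"m": self._labels(ts, {"a"})}, window_days=1)
        assert np.isnan(series.loc["2021-11-03", "m"])

    def test_step_change_matches_windowed_tally_oracle(self):
        import pandas as pd

        rng = random.Random(17)
        ts, labels = {}, {}
        for i in range(300):
            day = rng.randrange(30)
            rid = f"r{i}"
            ts[rid] = pd.Timestamp("2021-11-01") + pd.Timedelta(days=day, hours=10)
            fraud = rng.random() < (0.2 if day < 15 else 0.8)
            labels[rid] = Label.FRAUD if fraud else Label.VALID
        window = 7
        series = fraud_proportion_series(ts, {"m": labels}, window_days=window)
        for day_idx in (0, 7, 15, 22, 29):
            center = pd.Timestamp("2021-11-01") + pd.Timedelta(days=day_idx)
            lo = center - pd.Timedelta(days=(window - 1) // 2 + 1)
            hi = center + pd.Timedelta(days=window // 2)
            in_win = [r for r, t in ts.items() if lo < t.normalize() <= hi]
            expected = (
                sum(labels[r] is Label.FRAUD for r in in_win) / len(in_win)
                if in_win
                else float("nan")
            )
            got = series.loc[center, "m"]
            assert got == pytest.approx(expected, nan_ok=True)
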