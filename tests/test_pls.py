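import warnings

import numpy as np
import pandas as pd
import pytest

from pulmolip import (
    correlation_circle,
    cross_validate,
    evaluate_categorical,
    fit_pls2,
    minmax_scale,
)
from pulmolip.pls import Q2_SIGNIFICANCE

from conftest import ols_oracle


def frame(values, prefix="v"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )


class TestMinMaxScale:
    def test_affine_map(self):
        block = minmax_scale(frame([[2.0], [4.0], [6.0]]))
        assert list(block.values["v0"]) == pytest.approx([0.0, 0.5, 1.0])

    def test_binary_column_unchanged(self):
        block = minmax_scale(frame([[0.0], [1.0], [0.0]]))
        assert list(block.values["v0"]) == pytest.approx([0.0, 1.0, 0.0])

    def test_constant_column_warns_and_maps_to_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            block = minmax_scale(frame([[3.0], [3.0], [3.0]]))
        assert list(block.values["v0"]) == pytest.approx([0.0, 0.0, 0.0])

    def test_non_numeric_cell_rejected_with_location(self):
        table = frame([[1.0], [2.0], [3.0]])
        table = table.astype(object)
        table.iloc[1, 0] = "oops"
        with pytest.raises(ValueError, match="s1.*v0"):
            minmax_scale(table)

    def test_inverse_recovers_originals(self):
        rng = np.random.default_rng(0)
        table = frame(rng.normal(10.0, 3.0, size=(7, 4)))
        block = minmax_scale(table)
        assert np.allclose(block.inverse().to_numpy(), table.to_numpy(), atol=1e-12)
        assert block.values.to_numpy().min() >= 0.0
        assert block.values.to_numpy().max() <= 1.0


class TestFitPls2:
    def test_rank1_noiseless_r2_one(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=12)
        x = frame(np.outer(t, rng.normal(size=5)), "x")
        y = frame(np.outer(t, np.array([1.0, -2.0, 0.5])), "y")
        model = fit_pls2(x, y, n_components=2)
        assert model.n_components == 1  # residual exhausted, early stop
        assert np.allclose(model.r2.iloc[0].to_numpy(), 1.0, atol=1e-6)

    def test_full_components_match_ols(self):
        rng = np.random.default_rng(2)
        x = frame(rng.normal(size=(20, 5)), "x")
        y = frame(rng.normal(size=(20, 1)), "y")
        model = fit_pls2(x, y, n_components=5)
        x0 = (x - x.mean()) / x.std(ddof=1)
        y0 = (y - y.mean()) / y.std(ddof=1)
        want = ols_oracle(x0.to_numpy(), y0.to_numpy()[:, 0])
        got = model.coefficients.to_numpy()[:, 0]
        assert np.allclose(got, want, atol=1e-8)
        # fitted values agree with the OLS fit on the original scale
        ols_fit = y.mean().to_numpy() + (x0.to_numpy() @ want) * y.std(ddof=1).to_numpy()
        assert np.allclose(model.fitted.to_numpy()[:, 0], ols_fit, atol=1e-8)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(3)
        model = fit_pls2(
            frame(rng.normal(size=(20, 8)), "x"),
            frame(rng.normal(size=(20, 3)), "y"),
            n_components=3,
        )
        t = model.scores.to_numpy()
        for a in range(3):
            for b in range(a + 1, 3):
                dot = abs(t[:, a] @ t[:, b])
                assert dot <= 1e-8 * np.linalg.norm(t[:, a]) * np.linalg.norm(t[:, b])

    def test_weights_unit_norm(self):
        rng = np.random.default_rng(4)
        model = fit_pls2(
            frame(rng.normal(size=(15, 6)), "x"),
            frame(rng.normal(size=(15, 2)), "y"),
            n_components=3,
        )
        norms = np.linalg.norm(model.x_weights.to_numpy(), axis=0)
        assert np.allclose(norms, 1.0, atol=1e-10)

    def test_full_rank_deflation_reconstructs_x(self):
        rng = np.random.default_rng(5)
        x = frame(rng.normal(size=(20, 4)), "x")
        y = frame(rng.normal(size=(20, 2)), "y")
        model = fit_pls2(x, y, n_components=4)
        x0 = ((x - x.mean()) / x.std(ddof=1)).to_numpy()
        rebuilt = model.scores.to_numpy() @ model.x_loadings.to_numpy().T
        assert np.allclose(rebuilt, x0, atol=1e-8)

    def test_r2_cumulative_nondecreasing(self):
        rng = np.random.default_rng(6)
        model = fit_pls2(
            frame(rng.normal(size=(25, 10)), "x"),
            frame(rng.normal(size=(25, 3)), "y"),
            n_components=4,
        )
        r2 = model.r2.to_numpy()
        assert (np.diff(r2, axis=0) >= -1e-10).all()

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_pls2(frame(np.zeros((5, 2)), "x"), frame(np.zeros((4, 2)), "y"))


class TestCorrelationCircle:
    def test_variable_equal_to_t1(self):
        rng = np.random.default_rng(7)
        x = frame(rng.normal(size=(30, 4)), "x")
        y = frame(rng.normal(size=(30, 2)), "y")
        model = fit_pls2(x, y, n_components=2)
        # append t1 itself as a probe variable via manual correlation
        coords = correlation_circle(model, (1, 2))
        t = model.scores.to_numpy()
        probe = t[:, 0]
        r1 = np.corrcoef(probe, t[:, 0])[0, 1]
        r2 = np.corrcoef(probe, t[:, 1])[0, 1]
        assert r1 == pytest.approx(1.0)
        assert abs(r2) < 1e-8

    def test_coordinates_in_unit_disc(self):
        rng = np.random.default_rng(8)
        model = fit_pls2(
            frame(rng.normal(size=(18, 6)), "x"),
            frame(rng.normal(size=(18, 3)), "y"),
            n_components=2,
        )
        coords = correlation_circle(model, (1, 2))
        radii = np.hypot(coords["t1"], coords["t2"])
        assert (radii <= 1.0 + 1e-12).all()

    def test_matches_direct_pearson_oracle(self):
        rng = np.random.default_rng(9)
        x = frame(rng.normal(size=(22, 5)), "x")
        y = frame(rng.normal(size=(22, 2)), "y")
        model = fit_pls2(x, y, n_components=2)
        coords = correlation_circle(model, (1, 2))
        t = model.scores.to_numpy()
        for j, col in enumerate(x.columns):
            for h, tcol in enumerate(["t1", "t2"]):
                want = np.corrcoef(x[col], t[:, h])[0, 1]
                assert coords.loc[col, tcol] == pytest.approx(want, abs=1e-10)

    def test_zero_variance_variable_is_nan_not_zero(self):
        rng = np.random.default_rng(10)
        x = frame(rng.normal(size=(12, 4)), "x")
        y = frame(rng.normal(size=(12, 2)), "y")
        y["y1"] = 5.0  # constant response
        model = fit_pls2(x, y, n_components=2)
        coords = correlation_circle(model, (1, 2))
        assert np.isnan(coords.loc["y1", "t1"])

    def test_unfitted_component_rejected(self):
        rng = np.random.default_rng(11)
        model = fit_pls2(
            frame(rng.normal(size=(10, 3)), "x"),
            frame(rng.normal(size=(10, 1)), "y"),
            n_components=2,
        )
        with pytest.raises(ValueError):
            correlation_circle(model, (1, 5))


class TestCrossValidate:
    def test_q2_is_one_minus_press_over_rss(self):
        rng = np.random.default_rng(22)
        x = frame(rng.normal(size=(24, 5)), "x")
        y = frame(rng.normal(size=(24, 2)), "y")
        report = cross_validate(x, y, n_segments=6, n_components=2, seed=1)
        want = 1.0 - report.press.to_numpy() / report.rss.to_numpy()
        assert np.allclose(report.q2.to_numpy(), want, equal_nan=True)

    def test_patient_grouping_never_splits_pairs(self):
        rng = np.random.default_rng(12)
        n_patients = 15
        groups = [f"P{i}" for i in range(n_patients) for _ in (0, 1)]
        x = frame(rng.normal(size=(30, 6)), "x")
        y = frame(rng.normal(size=(30, 2)), "y")
        report = cross_validate(
            x, y, groups=groups, n_segments=5, n_components=2, seed=0
        )
        assert set(report.segments.index) == set(groups)
        sizes = report.segments.value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_fewer_patients_than_segments_rejected(self):
        rng = np.random.default_rng(13)
        x = frame(rng.normal(size=(6, 3)), "x")
        y = frame(rng.normal(size=(6, 1)), "y")
        with pytest.raises(ValueError):
            cross_validate(x, y, n_segments=10)

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(14)
        flags = 0
        n_rep = 25
        for k in range(n_rep):
            x = frame(rng.normal(size=(40, 100)), "x")
            y = frame(rng.normal(size=(40, 1)), "y")
            report = cross_validate(x, y, n_segments=10, n_components=3, seed=k)
            flags += report.significant["y0"]
        assert flags <= 0.15 * n_rep

    def test_planted_signal_detected(self):
        rng = np.random.default_rng(15)
        flags = 0
        n_rep = 15
        for k in range(n_rep):
            x = frame(rng.normal(size=(40, 30)), "x")
            beta = np.zeros(30)
            beta[:5] = 1.0
            signal = x.to_numpy() @ beta
            noise = rng.normal(size=40) * signal.std() / 3.0
            y = frame((signal + noise)[:, None], "y")
            report = cross_validate(x, y, n_segments=10, n_components=3, seed=k)
            flags += report.significant["y0"]
        assert flags >= 0.9 * n_rep

    def test_q2_below_r2_in_expectation(self):
        rng = np.random.default_rng(16)
        gaps = []
        for k in range(10):
            x = frame(rng.normal(size=(30, 10)), "x")
            y = frame(
                (x.to_numpy()[:, 0] + rng.normal(size=30))[:, None], "y"
            )
            model = fit_pls2(x, y, n_components=2)
            report = cross_validate(x, y, n_segments=10, n_components=2, seed=k)
            gaps.append(
                np.nanmax(report.q2.to_numpy()) - np.nanmax(model.r2.to_numpy())
            )
        assert np.mean(gaps) < 0.05


class TestEvaluateCategorical:
    def test_no_separation_gives_p_near_one(self):
        rng = np.random.default_rng(17)
        x = frame(rng.normal(size=(20, 4)), "x")
        y = frame(np.repeat([0.0, 1.0], 10)[:, None], "y")
        # responses unrelated to x: fitted values overlap between levels
        model = fit_pls2(x, y, n_components=2)
        groups, p = evaluate_categorical(model, "y0", (0.0, 1.0))
        assert set(groups) == {0.0, 1.0}
        assert 0.0 < p <= 1.0

    def test_planted_two_level_effect_detected(self):
        rng = np.random.default_rng(18)
        detected = 0
        n_rep = 20
        for _ in range(n_rep):
            level = np.repeat([0.0, 1.0], 15)
            x = frame(rng.normal(size=(30, 10)), "x")
            x.iloc[:, :5] += level[:, None] * 1.5
            y = frame(level[:, None], "y")
            model = fit_pls2(x, y, n_components=2)
            _, p = evaluate_categorical(model, "y0", (0.0, 1.0))
            detected += p < 0.05
        assert detected >= 0.9 * n_rep

    def test_permuted_labels_not_systematically_significant(self):
        # evaluation uses in-sample fitted values, so the null p is
        # optimistic when predictors are many relative to samples; with
        # overfitting controlled (2 predictors, 1 component, n = 60) the
        # permutation null must not produce systematic significance
        rng = np.random.default_rng(19)
        pvals = []
        for _ in range(40):
            level = rng.permutation(np.repeat([0.0, 1.0], 30))
            x = frame(rng.normal(size=(60, 2)), "x")
            y = frame(level[:, None], "y")
            model = fit_pls2(x, y, n_components=1)
            _, p = evaluate_categorical(model, "y0", (0.0, 1.0))
            pvals.append(p)
        assert np.median(pvals) > 0.1

    def test_unknown_response_rejected(self):
        rng = np.random.default_rng(20)
        model = fit_pls2(
            frame(rng.normal(size=(10, 3)), "x"),
            frame(rng.normal(size=(10, 1)), "y"),
            n_components=1,
        )
        with pytest.raises(ValueError):
            evaluate_categorical(model, "nope", (0.0, 1.0))

    def test_small_level_rejected(self):
        rng = np.random.default_rng(21)
        y_vals = np.array([0.0] * 9 + [1.0])[:, None]
        model = fit_pls2(
            frame(rng.normal(size=(10, 3)), "x"), frame(y_vals, "y"), n_components=1
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            evaluate_categorical(model, "y0", (0.0, 1.0))
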