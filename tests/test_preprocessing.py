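"""Temporal alignment, fill rules, and chained-equation imputation."""

import numpy as np
import pandas as pd
import pytest

import mmrisk
from mmrisk.preprocessing import (
    NULL_CATEGORY,
    AlignedSeries,
    fill_aligned,
    make_grid,
    mean_interval,
    resample,
)
from mmrisk.types import RawSeries


def series(times, values=None, vid="v"):
    values = values if values is not None else [0.0] * len(times)
    return RawSeries(vid, list(zip(map(float, times), values)))


class TestMeanInterval:
    def test_equally_spaced_series(self):
        assert mean_interval([series([0, 1, 2])]) == pytest.approx(1.0)

    def test_pooled_over_patients(self):
        # gaps {1, 3} and {2}: (1 + 3 + 2) / 3 = 2
        a = series([0, 1, 4])
        b = series([5, 7])
        assert mean_interval([a, b]) == pytest.approx(2.0)

    def test_single_point_series_contributes_nothing(self):
        a = series([0, 1, 4])
        b = series([5, 7])
        with_singleton = mean_interval([a, b, series([9])])
        assert with_singleton == pytest.approx(mean_interval([a, b]))

    def test_error_without_any_pair(self):
        with pytest.raises(ValueError, match="two observations"):
            mean_interval([series([1]), series([2])])

    def test_matches_bruteforce_pair_average_on_random_instances(self, rng):
        for _ in range(100):
            group = []
            gaps = []
            for _ in range(rng.integers(1, 5)):
                t = np.sort(rng.uniform(0, 50, size=rng.integers(1, 9)))
                t = np.unique(t)
                group.append(series(t))
                gaps.extend(np.diff(t))
            if not gaps:
                continue
            assert mean_interval(group) == pytest.approx(np.mean(gaps))


class TestResample:
    def test_continuous_window_mean(self):
        grid = make_grid("v", 2.0, origin=0.0, n_points=1)  # window [-1, 1]
        out = resample(series([0.2, 0.8], [4.0, 6.0]), grid)
        assert out.values[0] == pytest.approx(5.0)
        assert out.fill_provenance[0] == "observed"

    def test_discrete_window_mode_with_earliest_tie_break(self):
        grid = make_grid("v", 2.0, origin=0.0, n_points=1)
        s = RawSeries("v", [(0.1, "A"), (0.2, "A"), (0.3, "B")])
        assert resample(s, grid, is_discrete=True).values[0] == "A"
        tie = RawSeries("v", [(0.1, "B"), (0.2, "A")])
        assert resample(tie, grid, is_discrete=True).values[0] == "B"

    def test_empty_window_marked_missing(self):
        grid = make_grid("v", 1.0, origin=0.0, n_points=3)
        out = resample(series([2.1], [7.0]), grid)
        assert np.isnan(out.values[0]) and out.fill_provenance[0] == "missing"
        assert out.values[2] == pytest.approx(7.0)

    def test_idempotent_on_grid_aligned_series(self, rng):
        grid = make_grid("v", 1.0, origin=0.0, n_points=6)
        vals = rng.normal(size=6)
        out = resample(series(grid.grid_points, vals), grid)
        np.testing.assert_allclose(out.values, vals)
        again = resample(series(grid.grid_points, out.values), grid)
        np.testing.assert_allclose(again.values, vals)

    def test_empty_series_gives_all_missing(self):
        grid = make_grid("v", 1.0, origin=0.0, n_points=4)
        out = resample(RawSeries("v", []), grid)
        assert all(np.isnan(v) for v in out.values)


class TestFillAligned:
    def test_interior_gap_linearly_interpolated(self):
        out = fill_aligned(
            AlignedSeries("v", [2.0, np.nan, 4.0], ["observed", "missing", "observed"])
        )
        assert out.values == pytest.approx([2.0, 3.0, 4.0])
        assert out.fill_provenance == ["observed", "interpolated", "observed"]

    def test_leading_gap_backfilled_and_trailing_carried_forward(self):
        out = fill_aligned(
            AlignedSeries(
                "v",
                [np.nan, 5.0, 5.0, np.nan],
                ["missing", "observed", "observed", "missing"],
            )
        )
        assert out.values == pytest.approx([5.0, 5.0, 5.0, 5.0])
        assert out.fill_provenance == ["locf", "observed", "observed", "locf"]

    def test_discrete_gaps_become_null_category(self):
        out = fill_aligned(
            AlignedSeries("v", ["A", None, "B"], ["observed", "missing", "observed"], True)
        )
        assert out.values == ["A", NULL_CATEGORY, "B"]
        assert out.fill_provenance == ["observed", "null-category", "observed"]

    def test_observed_points_never_altered(self, rng):
        for _ in range(25):
            n = rng.integers(3, 10)
            vals = rng.normal(size=n)
            mask = rng.random(n) < 0.5
            vals[mask] = np.nan
            if np.isnan(vals).all():
                continue
            prov = ["missing" if np.isnan(v) else "observed" for v in vals]
            out = fill_aligned(AlignedSeries("v", vals.tolist(), prov))
            for i in range(n):
                if prov[i] == "observed":
                    assert out.values[i] == vals[i]
                    assert out.fill_provenance[i] == "observed"

    def test_fully_missing_numeric_series_errors_with_name(self):
        with pytest.raises(ValueError, match="heart_rate"):
            fill_aligned(AlignedSeries("heart_rate", [np.nan, np.nan], ["missing"] * 2))


class TestChainedImpute:
    def test_complete_table_returned_unchanged(self, rng):
        x = rng.normal(size=(10, 3))
        out = mmrisk.chained_impute(x, mmrisk.ImputationConfig(n_chains=2, n_iterations=2))
        np.testing.assert_array_equal(out, x)

    def test_perfectly_correlated_predictor_recovers_value(self):
        x = np.linspace(-2, 4, 40)
        y = 2.0 * x
        y_obs = y.copy()
        missing_at = 25  # x = 2.0-ish; expected y = 2 * x
        y_obs[missing_at] = np.nan
        table = np.column_stack([x, y_obs])
        out = mmrisk.chained_impute(
            table, mmrisk.ImputationConfig(n_chains=25, n_iterations=5, seed=1)
        )
        assert out[missing_at, 1] == pytest.approx(2.0 * x[missing_at], abs=0.2)

    def test_all_missing_column_rejected(self):
        table = np.column_stack([np.arange(5.0), np.full(5, np.nan)])
        with pytest.raises(ValueError, match="fewer than 2 observed"):
            mmrisk.chained_impute(table, mmrisk.ImputationConfig(n_chains=2))

    def test_observed_entries_pass_through(self, rng):
        x = rng.normal(size=(30, 4))
        mask = rng.random(x.shape) < 0.2
        xm = np.where(mask, np.nan, x)
        out = mmrisk.chained_impute(xm, mmrisk.ImputationConfig(n_chains=3, n_iterations=3))
        np.testing.assert_array_equal(out[~mask], xm[~mask])
        assert np.isfinite(out).all()

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(25, 3))
        x[rng.random(x.shape) < 0.2] = np.nan
        cfg = mmrisk.ImputationConfig(n_chains=3, n_iterations=3, seed=5)
        np.testing.assert_array_equal(
            mmrisk.chained_impute(x, cfg), mmrisk.chained_impute(x, cfg)
        )

    def test_beats_marginal_mean_imputation_on_linear_mcar_data(self, rng):
        n, p = 500, 5
        z = rng.normal(size=n)
        x = np.column_stack([z + 0.3 * rng.normal(size=n) for _ in range(p)])
        mask = rng.random(x.shape) < 0.2
        xm = np.where(mask, np.nan, x)
        out = mmrisk.chained_impute(xm, mmrisk.ImputationConfig(n_chains=5, n_iterations=5))
        mice_err = np.abs(out[mask] - x[mask]).mean()
        col_means = np.nanmean(xm, axis=0)
        mean_err = np.abs(np.broadcast_to(col_means, x.shape)[mask] - x[mask]).mean()
        assert mice_err < mean_err

    def test_dataframe_roundtrip_keeps_index_and_columns(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        df.iloc[3, 1] = np.nan
        out = mmrisk.chained_impute(df, mmrisk.ImputationConfig(n_chains=2, n_iterations=2))
        assert list(out.columns) == list("abc")
        assert np.isfinite(out.to_numpy()).all()


def test_pipeline_aligns_and_standardizes(tiny_cohort):
    _, records = tiny_cohort
    for r in records:
        assert r.aligned_series.shape == (6, 3)
        assert np.isfinite(r.aligned_series).all()
        assert np.isfinite(r.lab).all()
    stacked = np.stack([r.aligned_series for r in records])
    np.testing.assert_allclose(stacked.mean(axis=(0, 1)), 0.0, atol=1e-9)
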