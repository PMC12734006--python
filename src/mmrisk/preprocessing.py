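"""Temporal alignment of irregular monitoring series and lab imputation.

Asynchronous, non-uniformly sampled monitoring variables are converted to
a uniform per-variable grid in three steps:

1. :func:`mean_interval` pools the gaps between successive observations
   across all patients to get the variable's average sampling interval
   ``mean_dt``;
2. :func:`resample` aggregates raw observations onto grid points spaced by
   ``mean_dt`` (mean within a +/- half-width window for continuous
   variables, mode for discrete ones), leaving unobserved grid points
   missing;
3. :func:`fill_aligned` closes the gaps: boundary gaps carry the nearest
   observed value, interior numeric gaps are linearly interpolated, and
   discrete gaps receive a dedicated null category.

Static lab panels are completed with chained-equation multiple imputation
(:func:`chained_impute`): several independent chains of iterative
conditional regression draws, pooled by averaging the chains' point
estimates.

The window half-width defaults to ``mean_dt / 2`` so consecutive windows
partition the timeline without overlap; the grid starts at each patient's
first observation and has a fixed configurable length, truncating or
padding stays of different durations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .types import MultimodalRecord, RawSeries

__all__ = [
    "TimeGrid",
    "AlignedSeries",
    "ImputationConfig",
    "PreprocessConfig",
    "mean_interval",
    "make_grid",
    "resample",
    "fill_aligned",
    "chained_impute",
    "preprocess_cohort",
]

MISSING = None  # marker inside AlignedSeries.values (numeric gaps use NaN)
NULL_CATEGORY = "__null__"


@dataclass
class TimeGrid:
    variable_id: str
    mean_interval: float
    grid_points: np.ndarray
    window_halfwidth: float

    def __post_init__(self):
        if self.mean_interval <= 0:
            raise ValueError("mean_interval must be positive")
        self.grid_points = np.asarray(self.grid_points, dtype=float)
        if len(self.grid_points) > 1:
            steps = np.diff(self.grid_points)
            if not np.allclose(steps, self.mean_interval):
                raise ValueError("grid points must be equally spaced by mean_interval")


@dataclass
class AlignedSeries:
    """Per-grid-point values with provenance tags.

    ``values`` entries are floats (NaN = missing) for continuous series or
    hashables (``None`` = missing) for discrete series.  ``fill_provenance``
    tags each point as observed / locf / interpolated / null-category.
    """

    variable_id: str
    values: list
    fill_provenance: list[str]
    is_discrete: bool = False

    def __post_init__(self):
        if len(self.values) != len(self.fill_provenance):
            raise ValueError("values and provenance length mismatch")


@dataclass
class ImputationConfig:
    n_chains: int = 20
    n_iterations: int = 10
    pooling: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 1 or self.n_iterations < 1:
            raise ValueError("n_chains and n_iterations must be >= 1")
        if self.pooling != "mean":
            raise ValueError("only across-chain mean pooling is supported")


@dataclass
class PreprocessConfig:
    n_grid: int = 12
    standardize: bool = True
    imputation: ImputationConfig = field(default_factory=ImputationConfig)


def mean_interval(all_series_for_variable: list[RawSeries]) -> float:
    """Pooled average gap between successive observations of one variable.

    Sums every consecutive-pair interval over every patient's series and
    divides by the total number of pairs; series with fewer than two
    points contribute nothing.
    """
    total = 0.0
    n_pairs = 0
    for s in all_series_for_variable:
        t = s.times
        if len(t) >= 2:
            total += float(t[-1] - t[0])  # telescoping sum of consecutive gaps
            n_pairs += len(t) - 1
    if n_pairs == 0:
        raise ValueError("no series with at least two observations")
    return total / n_pairs


def make_grid(
    variable_id: str,
    mean_dt: float,
    origin: float,
    n_points: int,
    window_halfwidth: float | None = None,
) -> TimeGrid:
    if window_halfwidth is None:
        window_halfwidth = mean_dt / 2.0
    points = origin + mean_dt * np.arange(n_points)
    return TimeGrid(variable_id, mean_dt, points, window_halfwidth)


def resample(series: RawSeries, grid: TimeGrid, is_discrete: bool = False) -> AlignedSeries:
    """Aggregate raw observations onto the grid.

    At each grid point, observations within the +/- half-width window are
    reduced by mean (continuous) or mode (discrete, ties broken by the
    earliest-observed value).  Grid points with no usable in-window
    observation are marked missing.
    """
    values: list = []
    provenance: list[str] = []
    times = np.array([t for t, _ in series.points], dtype=float)
    for t_l in grid.grid_points:
        in_window = np.abs(times - t_l) <= grid.window_halfwidth
        obs = [series.points[k][1] for k in np.flatnonzero(in_window)]
        if is_discrete:
            obs = [v for v in obs if v is not None]
            if obs:
                counts = Counter(obs)
                best = max(counts.values())
                value = next(v for v in obs if counts[v] == best)
                values.append(value)
                provenance.append("observed")
            else:
                values.append(MISSING)
                provenance.append("missing")
        else:
            obs = [float(v) for v in obs if v is not None and np.isfinite(v)]
            if obs:
                values.append(float(np.mean(obs)))
                provenance.append("observed")
            else:
                values.append(np.nan)
                provenance.append("missing")
    return AlignedSeries(series.variable_id, values, provenance, is_discrete)


def fill_aligned(series: AlignedSeries) -> AlignedSeries:
    """Close the gaps left by :func:`resample`.

    Numeric series: boundary gaps carry the nearest observed value (the
    first observed value is carried backward over a leading gap, the last
    observed value forward over a trailing gap); interior gaps are linearly
    interpolated between the flanking observed grid values.  Discrete
    series: every gap becomes the dedicated null category.  Observed
    points are never altered.
    """
    n = len(series.values)
    if series.is_discrete:
        values = [NULL_CATEGORY if v is MISSING else v for v in series.values]
        prov = [
            "null-category" if p == "missing" else p for p in series.fill_provenance
        ]
        return AlignedSeries(series.variable_id, values, prov, True)

    vals = np.array(
        [np.nan if v is MISSING else float(v) for v in series.values], dtype=float
    )
    observed_idx = np.flatnonzero(np.isfinite(vals))
    if len(observed_idx) == 0:
        raise ValueError(f"series {series.variable_id!r} has no observed values to fill from")
    filled = np.interp(np.arange(n), observed_idx, vals[observed_idx])
    prov = []
    first, last = observed_idx[0], observed_idx[-1]
    for i, p in enumerate(series.fill_provenance):
        if p == "observed":
            prov.append("observed")
        elif first <= i <= last:
            prov.append("interpolated")
        else:
            prov.append("locf")  # boundary carry (backward before first, forward after last)
    return AlignedSeries(series.variable_id, filled.tolist(), prov, False)


def chained_impute(
    lab_table: pd.DataFrame | np.ndarray, config: ImputationConfig
) -> pd.DataFrame | np.ndarray:
    """Complete a lab table by chained-equation multiple imputation.

    Runs ``n_chains`` independent chains of iterative conditional linear
    regressions with posterior draws and pools them into a single
    completed table by averaging the chains' imputed values (point
    estimates only; no between-chain variance is propagated).  Observed
    entries pass through untouched.  Deterministic given ``config.seed``.
    """
    is_frame = isinstance(lab_table, pd.DataFrame)
    x = lab_table.to_numpy(dtype=float) if is_frame else np.asarray(lab_table, dtype=float)
    if x.ndim != 2:
        raise ValueError("lab table must be 2-dimensional")
    n_obs = np.isfinite(x).sum(axis=0)
    if np.any(n_obs < 2):
        bad = np.flatnonzero(n_obs < 2)
        names = list(lab_table.columns[bad]) if is_frame else bad.tolist()
        raise ValueError(f"features with fewer than 2 observed values: {names}")
    if np.all(np.isfinite(x)):
        return lab_table.copy() if is_frame else x.copy()

    chains = np.empty((config.n_chains, *x.shape))
    for c in range(config.n_chains):
        imputer = IterativeImputer(
            max_iter=config.n_iterations,
            sample_posterior=True,
            random_state=config.seed + c,
            keep_empty_features=False,
        )
        chains[c] = imputer.fit_transform(x)
    pooled = chains.mean(axis=0)
    pooled[np.isfinite(x)] = x[np.isfinite(x)]
    if is_frame:
        return pd.DataFrame(pooled, index=lab_table.index, columns=lab_table.columns)
    return pooled


def preprocess_cohort(
    records: list[MultimodalRecord], config: PreprocessConfig | None = None
) -> list[MultimodalRecord]:
    """Full cohort pipeline: align series, impute labs, standardize.

    Mutates and returns ``records``: fills ``aligned_series`` with a
    (n_grid, n_variables) matrix per patient and replaces ``lab`` with the
    imputed (and optionally z-scored) panel.  Per-variable mean intervals
    and standardization moments are estimated on the cohort passed in.
    """
    config = config or PreprocessConfig()
    if not records:
        return records
    variable_ids = [s.variable_id for s in records[0].series]

    mean_dts = {}
    cohort_means = {}
    for j, vid in enumerate(variable_ids):
        mean_dts[vid] = mean_interval([r.series[j] for r in records])
        pooled = np.concatenate([r.series[j].values for r in records])
        cohort_means[vid] = float(np.nanmean(pooled)) if np.isfinite(pooled).any() else 0.0

    for r in records:
        cols = []
        for j, vid in enumerate(variable_ids):
            s = r.series[j]
            origin = s.points[0][0] if s.points else 0.0
            grid = make_grid(vid, mean_dts[vid], origin, config.n_grid)
            resampled = resample(s, grid)
            if not any(p == "observed" for p in resampled.fill_provenance):
                # every measurement of this variable was a missing marker:
                # fall back to the cohort-level mean for the whole stay
                aligned = AlignedSeries(
                    vid,
                    [cohort_means[vid]] * config.n_grid,
                    ["locf"] * config.n_grid,
                )
            else:
                aligned = fill_aligned(resampled)
            cols.append(aligned.values)
        r.aligned_series = np.asarray(cols, dtype=float).T  # (n_grid, n_vars)

    lab_matrix = np.stack([r.lab for r in records])
    lab_matrix = chained_impute(lab_matrix, config.imputation)

    if config.standardize:
        mu, sd = lab_matrix.mean(axis=0), lab_matrix.std(axis=0)
        lab_matrix = (lab_matrix - mu) / np.where(sd > 0, sd, 1.0)
        stacked = np.stack([r.aligned_series for r in records])  # (N, T, V)
        smu = stacked.mean(axis=(0, 1))
        ssd = stacked.std(axis=(0, 1))
        for r in records:
            r.aligned_series = (r.aligned_series - smu) / np.where(ssd > 0, ssd, 1.0)

    for r, lab in zip(records, lab_matrix):
        r.lab = lab
    return records
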