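"""Accuracy-testing machinery for the allometric predictions.

Measured vs predicted biomass is compared with model II (Major Axis)
regression, because both axes carry error: the slope is the direction of the
leading eigenvector of the 2x2 covariance matrix, its 95% CI follows the
standard Major Axis construction (Legendre & Legendre; Jolicoeur), and
significance comes from a one-tailed permutation test on the Pearson
correlation. On top of that sit the species- and sample-level validations,
a train/test bootstrap of the whole modelling pipeline, and a
prediction-error-versus-sample-size resampling analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .allometry import ConvergenceError, MothMassRegressor, extract_parameters
from .predict import dataset_prediction_offset, species_mass_table

logger = logging.getLogger(__name__)

__all__ = [
    "MajorAxisFit",
    "MajorAxisRegression",
    "BootstrapSummary",
    "ErrorCurvePoint",
    "major_axis_fit",
    "ma_permutation_p",
    "species_level_validation",
    "sample_level_validation",
    "bootstrap_validation",
    "prediction_error",
    "error_vs_sample_size",
]


@dataclass
class MajorAxisFit:
    """Model II (Major Axis) regression result."""

    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    r_squared: float
    permutation_p: float | None
    n_points: int

    def slope_ci_excludes(self, value: float = 1.0) -> bool:
        lo, hi = self.slope_ci95
        return value < lo or value > hi


# --------------------------------------------------------------------------
# Major Axis core


def _ma_slope(s_xx: float, s_yy: float, s_xy: float) -> float:
    if s_xy == 0.0:
        if s_xx == s_yy:
            raise ValueError(
                "Major Axis slope undefined: zero covariance with equal variances"
            )
        if s_yy > s_xx:
            raise ValueError("Major Axis is vertical: slope undefined")
        return 0.0
    return (s_yy - s_xx + np.sqrt((s_yy - s_xx) ** 2 + 4.0 * s_xy**2)) / (2.0 * s_xy)


def major_axis_fit(
    x,
    y,
    alpha: float = 0.05,
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> MajorAxisFit:
    """Major Axis regression of ``y`` on ``x``.

    The slope is the first principal axis of the sample covariance matrix;
    the (1-alpha) CI uses the classical angular construction: with
    ``H = F(1-alpha; 1, n-2) / [(l1/l2 + l2/l1 - 2)(n-2)]`` the limits are
    ``(b -+ A)/(1 +- bA)`` for ``A = sqrt(H/(1-H))``, infinite when H >= 1
    (simulated coverage of this construction is checked in the test suite).
    If ``n_perm`` > 0 a one-tailed permutation p-value is attached.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Major Axis regression needs at least 3 points")
    s_xx = float(np.var(x, ddof=1))
    s_yy = float(np.var(y, ddof=1))
    s_xy = float(np.cov(x, y, ddof=1)[0, 1])
    if s_xx == 0.0 and s_yy == 0.0:
        raise ValueError("degenerate data: no variance in x or y")

    slope = _ma_slope(s_xx, s_yy, s_xy)
    xbar, ybar = float(np.mean(x)), float(np.mean(y))
    intercept = ybar - slope * xbar

    # eigenvalues of the covariance matrix
    tr = s_xx + s_yy
    disc = np.sqrt((s_xx - s_yy) ** 2 + 4.0 * s_xy**2)
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)

    if l2 <= 0.0:  # perfectly collinear: CI collapses to the point estimate
        slope_ci = (slope, slope)
    else:
        F = float(stats.f.ppf(1.0 - alpha, 1, n - 2))
        H = F / ((l1 / l2 + l2 / l1 - 2.0) * (n - 2))
        if H >= 1.0:
            slope_ci = (-np.inf, np.inf)
        else:
            A = np.sqrt(H / (1.0 - H))
            denom_lo = 1.0 + slope * A
            denom_hi = 1.0 - slope * A
            lo = (slope - A) / denom_lo if denom_lo != 0 else -np.inf
            hi = (slope + A) / denom_hi if denom_hi > 0 else np.inf
            slope_ci = (lo, hi) if lo <= hi else (-np.inf, np.inf)

    int_candidates = [
        ybar - b * xbar for b in slope_ci if np.isfinite(b)
    ]
    if len(int_candidates) == 2:
        intercept_ci = (min(int_candidates), max(int_candidates))
    else:
        intercept_ci = (-np.inf, np.inf)

    if s_xx == 0.0 or s_yy == 0.0:
        r2 = 0.0
    else:
        r2 = float(s_xy**2 / (s_xx * s_yy))

    p = None
    if n_perm:
        p = ma_permutation_p(x, y, n_perm=n_perm, rng=rng)

    return MajorAxisFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_ci95=(float(slope_ci[0]), float(slope_ci[1])),
        intercept_ci95=(float(intercept_ci[0]), float(intercept_ci[1])),
        r_squared=min(r2, 1.0),
        permutation_p=p,
        n_points=n,
    )


def ma_permutation_p(
    x, y, n_perm: int = 100, rng: np.random.Generator | None = None
) -> float:
    """One-tailed permutation p for a positive association.

    ``y`` is permuted against fixed ``x``; the statistic is the Pearson
    correlation; p = (1 + #{r_perm >= r_obs}) / (n_perm + 1), so the minimum
    attainable value is 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError("permutation test undefined for constant x or y")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    r_obs = float((xc * yc).sum() / denom)
    perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])
    r_perm = perms @ xc / denom
    count = int(np.sum(r_perm >= r_obs - 1e-12))
    return (1.0 + count) / (n_perm + 1.0)


class MajorAxisRegression(BaseEstimator):
    """scikit-learn-style wrapper around :func:`major_axis_fit`.

    ``fit(X, y)`` accepts a 1-d (or single-column) ``X``; fitted attributes
    are ``slope_``, ``intercept_``, ``slope_ci95_``, ``intercept_ci95_``,
    ``r_squared_``, ``permutation_p_`` and ``result_``.
    """

    def __init__(self, alpha: float = 0.05, n_perm: int = 0, random_state=None):
        self.alpha = alpha
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        res = major_axis_fit(
            x,
            y,
            alpha=self.alpha,
            n_perm=self.n_perm,
            rng=np.random.default_rng(self.random_state),
        )
        self.result_ = res
        self.slope_ = res.slope
        self.intercept_ = res.intercept
        self.slope_ci95_ = res.slope_ci95
        self.intercept_ci95_ = res.intercept_ci95
        self.r_squared_ = res.r_squared
        self.permutation_p_ = res.permutation_p
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x


# --------------------------------------------------------------------------
# species- and sample-level validation


def _species_points(records: pd.DataFrame, masses) -> pd.DataFrame:
    lookup = pd.Series(dict(masses))
    measured = records.groupby("species")["dry_mass_mg"].mean()
    missing = sorted(set(measured.index) - set(lookup.index))
    if missing:
        raise KeyError(f"species missing from mass table: {missing}")
    return pd.DataFrame(
        {"measured_mg": measured, "predicted_mg": lookup.reindex(measured.index)}
    )


def species_level_validation(
    records: pd.DataFrame,
    masses,
    min_mass_mg: float | None = None,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> MajorAxisFit:
    """Major Axis fit of predicted vs measured species mass, ln scale.

    The measured species value is the arithmetic mean dry mass of its
    individuals. When ``min_mass_mg`` is set, species with measured mean
    <= threshold are excluded first (the ">15 mg" subset).
    """
    pts = _species_points(records, masses)
    if min_mass_mg is not None:
        pts = pts[pts["measured_mg"] > min_mass_mg]
    if len(pts) < 3:
        raise ValueError("fewer than 3 species after filtering")
    return major_axis_fit(
        np.log(pts["measured_mg"]), np.log(pts["predicted_mg"]), n_perm=n_perm, rng=rng
    )


def sample_level_validation(
    records: pd.DataFrame,
    masses,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> MajorAxisFit:
    """Major Axis fit of predicted vs measured total biomass per sample.

    A sample is all moths captured at one site on one date (across traps).
    """
    lookup = pd.Series(dict(masses))
    missing = sorted(set(records["species"]) - set(lookup.index))
    if missing:
        raise KeyError(f"species missing from mass table: {missing}")
    df = records.assign(predicted_mg=lookup.reindex(records["species"]).to_numpy())
    grouped = df.groupby(["site", "date"])
    measured = grouped["dry_mass_mg"].sum()
    predicted = grouped["predicted_mg"].sum()
    if len(measured) < 3:
        raise ValueError("fewer than 3 samples")
    return major_axis_fit(np.log(measured), np.log(predicted), n_perm=n_perm, rng=rng)


# --------------------------------------------------------------------------
# bootstrap train/test validation


@dataclass
class BootstrapSummary:
    """Aggregate of the train/test bootstrap replicates.

    Percentages are over successful replicates; "significant" means the
    permutation p <= 0.05, "slope not 1" means the 95% CI excludes 1.
    """

    n_replicates: int
    train_n: int
    species_pct_significant: float
    species_pct_slope_not_1: float
    species_pct_slope_not_1_over15mg: float
    species_mean_r2: float
    species_se_r2: float
    sample_pct_significant: float
    sample_pct_slope_not_1: float
    sample_mean_r2: float
    sample_se_r2: float
    n_failed_attempts: int
    replicates: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "level": "sample",
                "subset": "full",
                "n_replicates": self.n_replicates,
                "pct_significant": self.sample_pct_significant,
                "pct_slope_not_1": self.sample_pct_slope_not_1,
                "mean_r2": self.sample_mean_r2,
                "se_r2": self.sample_se_r2,
            },
            {
                "level": "species",
                "subset": "full",
                "n_replicates": self.n_replicates,
                "pct_significant": self.species_pct_significant,
                "pct_slope_not_1": self.species_pct_slope_not_1,
                "mean_r2": self.species_mean_r2,
                "se_r2": self.species_se_r2,
            },
            {
                "level": "species",
                "subset": ">15mg",
                "n_replicates": self.n_replicates,
                "pct_significant": np.nan,
                "pct_slope_not_1": self.species_pct_slope_not_1_over15mg,
                "mean_r2": np.nan,
                "se_r2": np.nan,
            },
        ]
        return pd.DataFrame(rows)


def _bootstrap_replicate(
    records: pd.DataFrame,
    guide: pd.DataFrame,
    train_n: int,
    n_perm: int,
    family_threshold: int,
    min_mass_mg: float,
    rng: np.random.Generator,
) -> dict:
    """One train/test replicate; raises on fit failure or degenerate subsets."""
    n = len(records)
    idx = rng.permutation(n)
    train = records.iloc[idx[:train_n]]
    test = records.iloc[idx[train_n:]]

    est = MothMassRegressor(
        structure="loglog", family_threshold=family_threshold
    ).fit(train)
    params = extract_parameters(est.fit_)
    test_species = sorted(test["species"].unique())
    sub_guide = guide[guide["species"].isin(test_species)]
    masses = species_mass_table(sub_guide, params)

    sp = species_level_validation(test, masses, n_perm=n_perm, rng=rng)
    sp15 = species_level_validation(
        test, masses, min_mass_mg=min_mass_mg, n_perm=n_perm, rng=rng
    )
    sa = sample_level_validation(test, masses, n_perm=n_perm, rng=rng)
    return {
        "species_p": sp.permutation_p,
        "species_r2": sp.r_squared,
        "species_slope_not_1": sp.slope_ci_excludes(1.0),
        "species_slope_not_1_over15mg": sp15.slope_ci_excludes(1.0),
        "sample_p": sa.permutation_p,
        "sample_r2": sa.r_squared,
        "sample_slope_not_1": sa.slope_ci_excludes(1.0),
    }


def bootstrap_validation(
    records: pd.DataFrame,
    guide: pd.DataFrame,
    n_replicates: int = 10_000,
    train_n: int = 480,
    seed: int | None = None,
    n_perm: int = 100,
    family_threshold: int = 5,
    min_mass_mg: float = 15.0,
    keep_replicates: bool = False,
) -> BootstrapSummary:
    """Train/test bootstrap of the whole prediction pipeline.

    Each replicate draws ``train_n`` individuals without replacement, refits
    the simplified loglog model on them (re-deriving the family grouping from
    the training subset only), predicts the held-out individuals through their
    species' field-guide midpoints, and validates at species and sample level
    with Major Axis regressions. Replicate-level failures (non-convergence or
    degenerate subsets) are logged and redrawn, never silently dropped.
    """
    if len(records) < train_n + 3:
        raise ValueError("need at least train_n + 3 records")
    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = master.spawn(n_replicates)
    max_extra = 5 * n_replicates
    extra_pool = master.spawn(1)[0]

    rows = []
    n_failed = 0
    for i in range(n_replicates):
        ss = streams[i]
        while True:
            try:
                rows.append(
                    _bootstrap_replicate(
                        records,
                        guide,
                        train_n,
                        n_perm,
                        family_threshold,
                        min_mass_mg,
                        np.random.default_rng(ss),
                    )
                )
                break
            except (ConvergenceError, ValueError, KeyError) as exc:
                n_failed += 1
                logger.warning("bootstrap replicate %d failed (%s); redrawing", i, exc)
                if n_failed > max_extra:
                    raise RuntimeError(
                        "too many failed bootstrap replicates"
                    ) from exc
                ss = extra_pool.spawn(1)[0]

    rep = pd.DataFrame(rows)
    nr = len(rep)

    def pct(mask) -> float:
        return 100.0 * float(np.mean(mask))

    return BootstrapSummary(
        n_replicates=nr,
        train_n=train_n,
        species_pct_significant=pct(rep["species_p"] <= 0.05),
        species_pct_slope_not_1=pct(rep["species_slope_not_1"]),
        species_pct_slope_not_1_over15mg=pct(rep["species_slope_not_1_over15mg"]),
        species_mean_r2=float(rep["species_r2"].mean()),
        species_se_r2=float(rep["species_r2"].std(ddof=1) / np.sqrt(nr)),
        sample_pct_significant=pct(rep["sample_p"] <= 0.05),
        sample_pct_slope_not_1=pct(rep["sample_slope_not_1"]),
        sample_mean_r2=float(rep["sample_r2"].mean()),
        sample_se_r2=float(rep["sample_r2"].std(ddof=1) / np.sqrt(nr)),
        n_failed_attempts=n_failed,
        replicates=rep if keep_replicates else None,
    )


# --------------------------------------------------------------------------
# prediction error vs sample size


def prediction_error(
    predicted_mg: float, measured_mg: float, offset_pct: float
) -> float:
    """Normalized prediction error, percent.

    100*(predicted - measured)/measured minus the whole-dataset offset
    (``dataset_prediction_offset``), so a sample that errs exactly like the
    full dataset scores 0.
    """
    measured = np.asarray(measured_mg, dtype=float)
    if np.any(measured <= 0):
        raise ValueError("measured biomass must be positive")
    raw = 100.0 * (np.asarray(predicted_mg, dtype=float) - measured) / measured
    out = raw - offset_pct
    return float(out) if out.ndim == 0 else out


@dataclass
class ErrorCurvePoint:
    """Prediction-error summary for one window of sample sizes."""

    window: tuple[int, int]
    n_replicates: int
    mean_error: float
    se_error: float
    min_error: float
    max_error: float


def error_vs_sample_size(
    records: pd.DataFrame,
    masses,
    sizes=range(10, 1001, 10),
    reps_per_size: int = 1000,
    window: int = 100,
    seed: int | None = None,
    offset_pct: float | None = None,
) -> list[ErrorCurvePoint]:
    """Prediction error of resampled sets of individuals, by sample size.

    For each size, individuals are drawn with replacement from ``records``;
    measured biomass is the sum of their dry masses and predicted biomass the
    sum of their species' predicted masses; errors are normalized by the
    full-dataset offset (computed here unless supplied) and summarized as
    mean/SE/range within windows of ``window`` consecutive sizes.
    """
    if len(records) == 0:
        raise ValueError("no records")
    sizes = list(sizes)
    lookup = pd.Series(dict(masses))
    missing = sorted(set(records["species"]) - set(lookup.index))
    if missing:
        raise KeyError(f"species missing from mass table: {missing}")
    if offset_pct is None:
        offset_pct = dataset_prediction_offset(records, masses)

    measured_arr = records["dry_mass_mg"].to_numpy(dtype=float)
    predicted_arr = lookup.reindex(records["species"]).to_numpy(dtype=float)
    n = len(records)
    rng = np.random.default_rng(seed)

    all_sizes = []
    all_errors = []
    for size in sizes:
        idx = rng.integers(0, n, size=(reps_per_size, size))
        measured = measured_arr[idx].sum(axis=1)
        predicted = predicted_arr[idx].sum(axis=1)
        errs = prediction_error(predicted, measured, offset_pct)
        all_sizes.append(np.full(reps_per_size, size))
        all_errors.append(errs)
    size_v = np.concatenate(all_sizes)
    err_v = np.concatenate(all_errors)

    points = []
    lo = min(sizes)
    top = max(sizes)
    while lo <= top:
        hi = lo + window - 10  # e.g. 10..100, 110..200 for step-10 grids
        mask = (size_v >= lo) & (size_v <= hi)
        if mask.any():
            e = err_v[mask]
            points.append(
                ErrorCurvePoint(
                    window=(lo, hi),
                    n_replicates=int(mask.sum()),
                    mean_error=float(e.mean()),
                    se_error=float(e.std(ddof=1) / np.sqrt(len(e))),
                    min_error=float(e.min()),
                    max_error=float(e.max()),
                )
            )
        lo = hi + 10
    return points


def error_curve_frame(points: list[ErrorCurvePoint]) -> pd.DataFrame:
    """Tidy DataFrame view of :func:`error_vs_sample_size` output."""
    return pd.DataFrame(
        {
            "size_min": [p.window[0] for p in points],
            "size_max": [p.window[1] for p in points],
            "n_replicates": [p.n_replicates for p in points],
            "mean_error_pct": [p.mean_error for p in points],
            "se_error_pct": [p.se_error for p in points],
            "min_error_pct": [p.min_error for p in points],
            "max_error_pct": [p.max_error for p in points],
        }
    )
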