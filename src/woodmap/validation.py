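"""Validation of the burner-concentration metric against hourly PM2.5.

Wood smoke has a diagnostic diurnal fingerprint: burning peaks on winter
evenings.  The validation statistic is therefore the difference between
mean PM2.5 during peak burning hours (7pm–1am) and off-peak hours
(5am–5pm), within a season and day-type.  Site-level burner exposure is an
areal apportionment of the small-area estimated counts into a circular
buffer (or 1 km grid square) around each monitor, and the association is a
Spearman rank correlation with a bias-corrected accelerated (BCa)
bootstrap confidence interval resampled over monitoring sites.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, box
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

#: peak burning hours, 7pm to 1am (the 00:xx hour belongs to its own date)
PEAK_HOURS = (19, 20, 21, 22, 23, 0)
#: off-peak hours, 5am to 5pm
OFFPEAK_HOURS = tuple(range(5, 17))
#: season definitions by calendar month
SEASON_MONTHS = {"winter": (12, 1, 2), "summer": (6, 7, 8)}

DEFAULT_RADII = (500.0, 1000.0, 2000.0)


# ---------------------------------------------------------------------------
# spatial apportionment
# ---------------------------------------------------------------------------

def buffer_count(
    est_counts: pd.Series,
    polygons: dict,
    site_xy: tuple[float, float],
    radius: float,
    quad_segs: int = 64,
) -> float:
    """Estimated burners inside a circular buffer around a site.

    The small-area estimate is an LSOA-level count; it is apportioned into
    the disc assuming uniform density within each LSOA:
    ``sum_l est_count[l] * area(l ∩ disc) / area(l)``.  A site whose disc
    touches no polygon returns 0 with a warning.
    """
    disc = Point(*site_xy).buffer(radius, quad_segs=quad_segs)
    codes = list(polygons)
    tree = STRtree([polygons[c] for c in codes])
    hits = tree.query(disc)
    if len(hits) == 0:
        logger.warning("site %s outside boundary coverage", site_xy)
        return 0.0
    total = 0.0
    for i in hits:
        code = codes[i]
        geom = polygons[code]
        frac = geom.intersection(disc).area / geom.area
        if frac > 0 and code in est_counts.index:
            count = est_counts.loc[code]
            if np.isfinite(count):
                total += count * frac
    return float(total)


def points_in_buffer(
    points: pd.DataFrame,
    site_xy: tuple[float, float],
    radius: float,
) -> float:
    """Count point locations (columns ``x, y``) within a circular buffer."""
    dx = points["x"].to_numpy() - site_xy[0]
    dy = points["y"].to_numpy() - site_xy[1]
    return float((dx * dx + dy * dy <= radius * radius).sum())


def grid_counts(
    est_counts: pd.Series,
    polygons: dict,
    cell_size: float = 1000.0,
) -> pd.DataFrame:
    """Apportion small-area counts onto the national grid.

    Cells are the half-open squares ``[i*s, (i+1)*s) × [j*s, (j+1)*s)``
    aligned to the projection origin.  Each polygon's count is split across
    the cells it overlaps in proportion to intersection area, so the grid
    total equals the total estimated count.  Returns ``cell_x, cell_y,
    count`` with cell indices in grid units.
    """
    cells: dict[tuple[int, int], float] = {}
    for code, geom in polygons.items():
        if code not in est_counts.index:
            continue
        count = est_counts.loc[code]
        if not np.isfinite(count) or count == 0:
            continue
        minx, miny, maxx, maxy = geom.bounds
        i0, i1 = int(np.floor(minx / cell_size)), int(np.ceil(maxx / cell_size))
        j0, j1 = int(np.floor(miny / cell_size)), int(np.ceil(maxy / cell_size))
        area = geom.area
        for i in range(i0, i1):
            for j in range(j0, j1):
                cell = box(i * cell_size, j * cell_size,
                           (i + 1) * cell_size, (j + 1) * cell_size)
                frac = geom.intersection(cell).area / area
                if frac > 0:
                    cells[(i, j)] = cells.get((i, j), 0.0) + count * frac
    out = pd.DataFrame(
        [(i, j, v) for (i, j), v in sorted(cells.items())],
        columns=["cell_x", "cell_y", "count"],
    )
    return out


def grid_count_at(
    grid: pd.DataFrame,
    site_xy: tuple[float, float],
    cell_size: float = 1000.0,
) -> float:
    """Count in the grid cell containing the site (half-open convention)."""
    i = int(np.floor(site_xy[0] / cell_size))
    j = int(np.floor(site_xy[1] / cell_size))
    row = grid[(grid["cell_x"] == i) & (grid["cell_y"] == j)]
    return float(row["count"].iloc[0]) if len(row) else 0.0


def site_exposures(
    sites: pd.DataFrame,
    est_counts: pd.Series,
    polygons: dict,
    radii: tuple[float, ...] = DEFAULT_RADII,
    house_counts: pd.Series | None = None,
    cell_size: float = 1000.0,
) -> pd.DataFrame:
    """Burner (and optionally house) counts around each monitoring site.

    ``sites`` needs columns ``site_id, x, y``.  Returns one row per site
    with ``burners_<r>m`` per radius, ``burners_grid`` for the containing
    1 km grid square, and ``houses_1000m`` when house counts are given.
    """
    grid = grid_counts(est_counts, polygons, cell_size)
    rows = []
    for _, s in sites.iterrows():
        xy = (s["x"], s["y"])
        row = {"site_id": s["site_id"]}
        for r in radii:
            row[f"burners_{int(r)}m"] = buffer_count(est_counts, polygons, xy, r)
        row["burners_grid"] = grid_count_at(grid, xy, cell_size)
        if house_counts is not None:
            row["houses_1000m"] = buffer_count(house_counts, polygons, xy, 1000.0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PM2.5 statistics
# ---------------------------------------------------------------------------

def _season_daytype_mask(ts: pd.Series, season: str, daytype: str) -> pd.Series:
    months = SEASON_MONTHS[season]
    mask = ts.dt.month.isin(months)
    if daytype == "weekday":
        mask &= ts.dt.dayofweek < 5
    elif daytype == "weekend":
        mask &= ts.dt.dayofweek >= 5
    elif daytype != "all":
        raise ValueError(f"unknown daytype {daytype!r}")
    return mask


def peak_offpeak_diff(
    series: pd.DataFrame,
    season: str,
    daytype: str = "all",
    peak_hours: tuple[int, ...] = PEAK_HOURS,
    offpeak_hours: tuple[int, ...] = OFFPEAK_HOURS,
    min_hours: int = 24,
) -> pd.Series:
    """Mean peak-hour minus mean off-peak-hour PM2.5 per site.

    ``series`` has columns ``site_id, timestamp, pm25``; missing pm25
    values are skipped; a site needs at least ``min_hours`` valid hours on
    each side or its difference is null.  The 00:xx hour's day-type follows
    its own calendar date.
    """
    df = series[series["pm25"].notna()].copy()
    ts = pd.to_datetime(df["timestamp"])
    df = df[_season_daytype_mask(ts, season, daytype)]
    hours = pd.to_datetime(df["timestamp"]).dt.hour
    peak = df[hours.isin(peak_hours)]
    off = df[hours.isin(offpeak_hours)]

    peak_stats = peak.groupby("site_id")["pm25"].agg(["mean", "size"])
    off_stats = off.groupby("site_id")["pm25"].agg(["mean", "size"])
    sites = peak_stats.index.union(off_stats.index)
    peak_stats = peak_stats.reindex(sites)
    off_stats = off_stats.reindex(sites)
    diff = peak_stats["mean"] - off_stats["mean"]
    valid = (peak_stats["size"].fillna(0) >= min_hours) & (
        off_stats["size"].fillna(0) >= min_hours
    )
    diff[~valid] = np.nan
    return diff.rename("peak_diff")


def site_mean_pm25(
    series: pd.DataFrame,
    season: str,
    daytype: str = "all",
    min_hours: int = 24,
) -> pd.Series:
    """Mean PM2.5 over valid hours per site within a season / day-type."""
    df = series[series["pm25"].notna()].copy()
    ts = pd.to_datetime(df["timestamp"])
    df = df[_season_daytype_mask(ts, season, daytype)]
    g = df.groupby("site_id")["pm25"].agg(["mean", "size"])
    out = g["mean"].where(g["size"] >= min_hours)
    return out.rename("mean_pm25")


# ---------------------------------------------------------------------------
# correlation statistics
# ---------------------------------------------------------------------------

def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties) on paired data.

    Null when fewer than 3 finite pairs remain or either side has zero
    rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        return np.nan
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, _ = stats.spearmanr(x, y)
    return float(r)


class BcaInterval(NamedTuple):
    low: float
    high: float


def bca_ci(
    data: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    B: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    z0_clamp: float = 4.0,
) -> BcaInterval:
    """Bias-corrected accelerated bootstrap interval.

    ``data`` is an ``(n,)`` or ``(n, k)`` array whose ROWS are the
    resampling units; ``statistic`` maps a resampled array to a float.
    The bias term is ``z0 = Phi^-1(#{theta* < theta_hat} / B)`` and the
    acceleration comes from the jackknife third/second-moment ratio;
    endpoints are linear-interpolated bootstrap quantiles at the adjusted
    levels.  A degenerate bootstrap distribution (all replicates equal)
    collapses to ``(theta_hat, theta_hat)``; otherwise z0 is clamped to
    ``±z0_clamp`` with a warning when the clamp binds.
    """
    rng = np.random.default_rng(rng)
    arr = np.asarray(data, dtype=float)
    n = arr.shape[0]
    theta_hat = float(statistic(arr))

    idx = rng.integers(0, n, size=(B, n))
    thetas = np.empty(B)
    for b in range(B):
        thetas[b] = statistic(arr[idx[b]])
    thetas = thetas[np.isfinite(thetas)]
    if thetas.size == 0 or np.all(thetas == theta_hat):
        return BcaInterval(theta_hat, theta_hat)
    if thetas.size < B:
        logger.warning("bca_ci: %d degenerate bootstrap replicates dropped",
                       B - thetas.size)

    frac = np.mean(thetas < theta_hat)
    if frac in (0.0, 1.0):
        logger.warning("bca_ci: bootstrap distribution entirely on one side "
                       "of the estimate; z0 clamped")
    with np.errstate(divide="ignore"):
        z0 = stats.norm.ppf(frac)
    z0 = float(np.clip(z0, -z0_clamp, z0_clamp))

    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = statistic(arr[mask])
        mask[i] = True
    jack = jack[np.isfinite(jack)]
    dev = jack.mean() - jack
    denom = 6.0 * (dev @ dev) ** 1.5
    a = float((dev**3).sum() / denom) if denom > 0 else 0.0

    z_lo, z_hi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    levels = []
    for z in (z_lo, z_hi):
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        levels.append(stats.norm.cdf(adj))
    lo, hi = np.quantile(thetas, levels)
    return BcaInterval(float(lo), float(hi))


def spearman_with_ci(
    x,
    y,
    B: int = 10_000,
    alpha: float = 0.05,
    rng=None,
) -> tuple[float, BcaInterval]:
    """Spearman R with a BCa interval, resampling (x, y) pairs (sites)."""
    arr = np.column_stack([x, y])
    r = spearman(arr[:, 0], arr[:, 1])
    ci = bca_ci(arr, lambda d: spearman(d[:, 0], d[:, 1]), B=B, alpha=alpha,
                rng=rng)
    return r, ci


def season_difference_ci(
    x,
    y_winter,
    y_summer,
    B: int = 10_000,
    alpha: float = 0.05,
    rng=None,
    paired: bool = True,
) -> tuple[float, BcaInterval]:
    """BCa interval for R_winter − R_summer over the same sites.

    With ``paired=True`` (default) each bootstrap replicate resamples
    sites once and computes both correlations on the same resample,
    preserving the within-site coupling of the two seasonal outcomes.
    ``paired=False`` resamples the winter and summer site sets
    independently (the acceleration still comes from the site-level
    jackknife).
    """
    arr = np.column_stack([x, y_winter, y_summer])

    def stat(d: np.ndarray) -> float:
        return spearman(d[:, 0], d[:, 1]) - spearman(d[:, 0], d[:, 2])

    if paired:
        diff = stat(arr)
        ci = bca_ci(arr, stat, B=B, alpha=alpha, rng=rng)
        return diff, ci

    rng = np.random.default_rng(rng)
    n = arr.shape[0]
    theta_hat = stat(arr)
    thetas = np.empty(B)
    for b in range(B):
        iw = rng.integers(0, n, n)
        isu = rng.integers(0, n, n)
        thetas[b] = spearman(arr[iw, 0], arr[iw, 1]) - spearman(
            arr[isu, 0], arr[isu, 2]
        )
    thetas = thetas[np.isfinite(thetas)]
    if thetas.size == 0 or np.all(thetas == theta_hat):
        return theta_hat, BcaInterval(theta_hat, theta_hat)
    frac = np.mean(thetas < theta_hat)
    with np.errstate(divide="ignore"):
        z0 = float(np.clip(stats.norm.ppf(frac), -4.0, 4.0))
    jack = np.array(
        [stat(np.delete(arr, i, axis=0)) for i in range(n)]
    )
    dev = jack.mean() - jack
    denom = 6.0 * (dev @ dev) ** 1.5
    a = float((dev**3).sum() / denom) if denom > 0 else 0.0
    z_lo, z_hi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    levels = [
        stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        for z in (z_lo, z_hi)
    ]
    lo, hi = np.quantile(thetas, levels)
    return theta_hat, BcaInterval(float(lo), float(hi))


def correlation_table(
    exposures: pd.DataFrame,
    series: pd.DataFrame,
    x_col: str = "burners_1000m",
    seasons: tuple[str, ...] = ("summer", "winter"),
    daytypes: tuple[str, ...] = ("all", "weekday", "weekend"),
    B: int = 10_000,
    alpha: float = 0.05,
    rng=None,
    min_hours: int = 24,
) -> pd.DataFrame:
    """Spearman correlations of site exposure with both PM2.5 outcomes.

    One row per outcome × season × day-type (mean PM2.5 is computed over
    all hours, so only the "all" day-type row is emitted for it), with BCa
    confidence intervals resampled over sites.  Substituting a housing
    count for ``x_col`` gives the housing-density negative control.
    """
    rng = np.random.default_rng(rng)
    exp = exposures.set_index("site_id")[x_col]
    rows = []
    for season in seasons:
        outcome_series: dict[tuple[str, str], pd.Series] = {}
        outcome_series[("mean_pm25", "all")] = site_mean_pm25(
            series, season, "all", min_hours=min_hours
        )
        for daytype in daytypes:
            if daytype == "all":
                continue
            outcome_series[("peak_diff", daytype)] = peak_offpeak_diff(
                series, season, daytype, min_hours=min_hours
            )
        for (outcome, daytype), y in outcome_series.items():
            joined = pd.concat([exp, y], axis=1, join="inner").dropna()
            if len(joined) < 3:
                continue
            r, ci = spearman_with_ci(
                joined.iloc[:, 0], joined.iloc[:, 1], B=B, alpha=alpha, rng=rng
            )
            rows.append(
                {
                    "outcome": outcome,
                    "season": season,
                    "daytype": daytype,
                    "x": x_col,
                    "R": r,
                    "ci_low": ci.low,
                    "ci_high": ci.high,
                    "n_sites": len(joined),
                    "B": B,
                }
            )
    return pd.DataFrame(rows)
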