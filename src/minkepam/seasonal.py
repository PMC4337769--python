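"""Daily detection series, season assignment, and rank-based comparisons.

Seasons follow the meteorological calendar (winter = Dec–Feb, spring =
Mar–May, summer = Jun–Aug, autumn = Sep–Nov).  The Kruskal-Wallis and
Wilcoxon rank-sum tests are implemented from the rank formulas with tie
correction; small samples (pooled n ≤ 10) use the exact permutation null
instead of the asymptotic approximation.  Shapiro-Wilk gates the
nonparametric path.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SEASON_OF_MONTH",
    "assign_season",
    "daily_bin",
    "simulate_daily_detections",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "normality_screen",
    "SeasonalError",
]


class SeasonalError(ValueError):
    """Invalid input to a seasonal-statistics operation."""


SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def assign_season(date) -> str:
    """Meteorological season of a date (January → winter)."""
    ts = pd.Timestamp(date)
    return SEASON_OF_MONTH[ts.month]


def daily_bin(
    detections: pd.DataFrame,
    effort_log: pd.DataFrame | None = None,
    min_total_detections: int = 5,
) -> tuple[pd.DataFrame, list[str]]:
    """Bin verified detections per site per calendar day (UTC).

    ``detections`` needs columns ``site`` and ``timestamp``; the optional
    ``effort_log`` (columns ``site``, ``date``, ``effort`` in [0, 1]) marks
    recorded days — detections on days without recorded effort are excluded
    with a warning, and effort-less days carry NaN effort (missing-data
    flag).  Returns the daily series (site, date, n_detections, effort,
    season) and the list of sites admitted to plotting (total detections ≥
    ``min_total_detections``).
    """
    det = detections.copy()
    det["date"] = pd.to_datetime(det["timestamp"], utc=True).dt.normalize().dt.tz_localize(None)
    if effort_log is not None:
        eff = effort_log.copy()
        eff["date"] = pd.to_datetime(eff["date"]).dt.normalize()
        if (eff["effort"].lt(0) | eff["effort"].gt(1)).any():
            raise SeasonalError("effort must be within [0, 1]")
        on = eff[eff["effort"] > 0][["site", "date"]]
        merged = det.merge(on.assign(_ok=True), on=["site", "date"], how="left")
        n_bad = int(merged["_ok"].isna().sum())
        if n_bad:
            warnings.warn(
                f"excluding {n_bad} detections outside recorded effort", stacklevel=2
            )
        det = merged[merged["_ok"].notna()].drop(columns="_ok")
        grid = eff[["site", "date", "effort"]]
    else:
        grid = None

    counts = (
        det.groupby(["site", "date"]).size().rename("n_detections").reset_index()
    )
    if grid is not None:
        daily = grid.merge(counts, on=["site", "date"], how="outer")
        daily["n_detections"] = daily["n_detections"].fillna(0).astype(int)
    else:
        daily = counts.assign(effort=np.nan)
    daily["season"] = daily["date"].map(assign_season)
    totals = daily.groupby("site")["n_detections"].sum()
    plot_sites = sorted(totals[totals >= min_total_detections].index)
    return daily.sort_values(["site", "date"]).reset_index(drop=True), plot_sites


def simulate_daily_detections(
    site: str,
    year: int,
    peak_day_of_year: float,
    concentration: float = 3.0,
    mean_daily_rate: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Season-peaked synthetic daily detection process (von Mises shape).

    Emulates a site whose detection rate peaks around ``peak_day_of_year``;
    returns a detections table (site, timestamp) drawable through
    :func:`daily_bin`.
    """
    rng = np.random.default_rng(seed)
    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    phase = 2.0 * np.pi * (days.dayofyear.to_numpy() - peak_day_of_year) / 365.25
    intensity = np.exp(concentration * (np.cos(phase) - 1.0))
    intensity *= mean_daily_rate * intensity.size / intensity.sum()
    counts = rng.poisson(intensity)
    rows = []
    for day, c in zip(days, counts):
        for _ in range(c):
            rows.append({"site": site, "timestamp": day + pd.Timedelta(hours=float(rng.uniform(0, 24)))})
    return pd.DataFrame(rows, columns=["site", "timestamp"])


# ---------------------------------------------------------------------------
# Rank tests (rank-formula implementations; exact permutation for small n)


def _tie_correction(pooled: np.ndarray) -> float:
    _, t = np.unique(pooled, return_counts=True)
    n = pooled.size
    return 1.0 - (t**3 - t).sum() / (n**3 - n)


def _kw_statistic(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    c = _tie_correction(pooled)
    return h / c if c > 0 else 0.0


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; (H, df, p).

    p is chi-squared with k−1 df, or the exact permutation tail when the
    pooled sample size is ≤ 10.  All-identical data give H = 0, p = 1.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise SeasonalError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise SeasonalError("need >= 3 observations in total")
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    h = _kw_statistic(groups)
    n = pooled.size
    if n <= 10:
        sizes = [g.size for g in groups]
        p = _exact_perm_tail(pooled, sizes, h, _kw_statistic)
    else:
        p = float(stats.chi2.sf(h, df))
    return float(h), df, p


def _exact_perm_tail(pooled, sizes, observed, statistic) -> float:
    """Exhaustive permutation tail P(stat >= observed) for small pooled n."""
    n = pooled.size
    idx_all = np.arange(n)
    count = 0
    total = 0

    def rec(remaining: np.ndarray, k: int, chosen: list[np.ndarray]):
        nonlocal count, total
        if k == len(sizes) - 1:
            groups = [pooled[c] for c in chosen] + [pooled[remaining]]
            total += 1
            if statistic(groups) >= observed - 1e-12:
                count += 1
            return
        for combo in combinations(remaining.tolist(), sizes[k]):
            c = np.array(combo)
            rest = np.setdiff1d(remaining, c)
            rec(rest, k + 1, chosen + [c])

    rec(idx_all, 0, [])
    return count / total


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected normal deviate of the Wilcoxon rank-sum statistic."""
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie = (t**3 - t).sum() / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie)
    if var <= 0:
        return 0.0
    # continuity correction toward the null
    delta = w - mu
    delta -= 0.5 * np.sign(delta)
    return float(delta / np.sqrt(var))


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size + y.size
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    if n <= 10:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[: x.size].sum()
        mu = x.size * (n + 1) / 2.0
        count = 0
        total = comb(n, x.size)
        for combo in combinations(range(n), x.size):
            w = ranks[list(combo)].sum()
            if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                count += 1
        return count / total
    z = _ranksum_z(x, y)
    return float(2.0 * stats.norm.sf(abs(z)))


def pairwise_wilcoxon(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests with Bonferroni adjustment.

    Returns a long-format table (group_a, group_b, p_raw, p_adj) with
    p_adj = min(1, p_raw × n_pairs); adjusted p never falls below raw p.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise SeasonalError("need >= 2 groups")
    labels = labels or [f"group{i}" for i in range(len(groups))]
    pairs = list(combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        p = _ranksum_p(groups[i], groups[j])
        p_adj = min(1.0, p * len(pairs)) if correction == "bonferroni" else p
        rows.append(
            {"group_a": labels[i], "group_b": labels[j], "p_raw": p, "p_adj": p_adj}
        )
    return pd.DataFrame(rows)


def normality_screen(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p; gates the nonparametric path."""
    x = np.asarray(sample, float)
    if not 3 <= x.size <= 5000:
        raise SeasonalError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise SeasonalError("constant sample: normality test is degenerate")
    w, p = stats.shapiro(x)
    return float(w), float(p)
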