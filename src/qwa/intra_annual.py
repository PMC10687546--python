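"""Intra-annual profile statistics: min-max normalization, smoothed group
profiles, Kolmogorov-Smirnov contrasts, Gini inequality with bootstrap
confidence intervals, and drought-legacy comparisons.

Every ring's 100-sector trait profile is normalized to [0, 1] by the
ring's own minimum and maximum, removing between-tree and ontogenetic
level differences so that only the intra-ring shape remains.  Group
profiles are sector-wise means across rings, LOESS-smoothed, with 95%
bands from the pre-smoothing standard error.  Inequality of the pooled
normalized values is quantified by the Gini coefficient with percentile
and bias-corrected-accelerated (BCa) bootstrap intervals, and drought
legacy effects are assessed by comparing the profiles of the year before,
the year of, and the year after each drought.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, norm
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "minmax_normalize",
    "normalize_profiles",
    "GroupProfile",
    "group_mean_profile",
    "KsResult",
    "ks_two_sample",
    "gini",
    "GiniEstimate",
    "gini_bootstrap",
    "drought_phase_profiles",
    "drought_vs_nondrought_gini",
]


def minmax_normalize(values) -> np.ndarray:
    """Scale a ring profile so its minimum is 0 and its maximum 1
    (x - min) / (max - min); missing sectors stay missing.  Constant
    profiles are rejected (zero range)."""
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size < 2:
        raise ValueError("need at least two defined sector values")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise ValueError("constant profile has zero range; ring excluded")
    return (x - lo) / (hi - lo)


def normalize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize every tree x year x trait profile of a long-format
    sector table; constant or near-empty rings are dropped with a count."""
    keys = ["tree_id", "year", "trait"]
    g = profiles.groupby(keys)["value"]
    mn = g.transform("min")
    mx = g.transform("max")
    count = g.transform("count")
    valid = (count >= 2) & (mx > mn)
    dropped = profiles[~valid].groupby(keys).ngroups
    if dropped:
        warnings.warn(f"excluded {dropped} constant or near-empty ring profiles")
    out = profiles[valid].copy()
    if out.empty:
        raise ValueError("all ring profiles were excluded")
    out["value"] = (out["value"] - mn[valid]) / (mx[valid] - mn[valid])
    return out.reset_index(drop=True)


@dataclass
class GroupProfile:
    """Sector-wise mean profile of a group of rings with a 95% band."""

    group: str
    trait: str
    phase: str
    sectors: np.ndarray
    mean: np.ndarray
    low: np.ndarray
    high: np.ndarray
    n_rings: int
    span: float = 0.3


def _loess(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    ok = ~np.isnan(y)
    if ok.sum() < 5:
        return y
    sm = lowess(y[ok], x[ok], frac=span, it=0, return_sorted=False)
    out = np.full_like(y, np.nan)
    out[ok] = sm
    return out


def group_mean_profile(
    profiles: pd.DataFrame,
    group: str = "",
    trait: str = "",
    phase: str = "all",
    span: float = 0.3,
    n_sectors: int = 100,
) -> GroupProfile:
    """Average normalized ring profiles sector-wise and LOESS-smooth.

    The 95% band is mean +/- 1.96 SE computed per sector before smoothing,
    then smoothed with the same local-linear operator as the mean.
    """
    n_rings = profiles.groupby(["tree_id", "year"]).ngroups
    if n_rings < 2:
        raise ValueError("need at least two rings for a group profile")
    per_sector = profiles.groupby("sector")["value"].agg(["mean", "sem"])
    sectors = np.arange(1, n_sectors + 1)
    mean = per_sector["mean"].reindex(sectors).to_numpy()
    sem = per_sector["sem"].reindex(sectors).to_numpy()
    sem = np.where(np.isnan(sem), 0.0, sem)
    low = mean - 1.96 * sem
    high = mean + 1.96 * sem
    x = sectors.astype(float)
    return GroupProfile(
        group=group,
        trait=trait,
        phase=phase,
        sectors=sectors,
        mean=_loess(x, mean, span),
        low=_loess(x, low, span),
        high=_loess(x, high, span),
        n_rings=n_rings,
        span=span,
    )


@dataclass
class KsResult:
    d_stat: float
    p_value: float
    n1: int
    n2: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def ks_two_sample(a, b) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_a - ECDF_b| with
    the asymptotic Kolmogorov p-value at the effective sample size."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 5 or b.size < 5:
        raise ValueError("both samples need at least 5 values")
    res = ks_2samp(a, b, method="asymp")
    return KsResult(d_stat=float(res.statistic), p_value=float(res.pvalue), n1=a.size, n2=b.size)


def gini(values) -> float:
    """Gini inequality coefficient of a non-negative sample.

    G = sum_ij |x_i - x_j| / (2 n^2 xbar), computed via the sorted-sample
    identity G = sum_i (2i - n - 1) x_(i) / (n^2 xbar); 0 is perfect
    equality, 1 maximal inequality.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any(x < 0):
        raise ValueError("Gini requires non-negative values")
    total = x.sum()
    if total <= 0:
        raise ValueError("Gini undefined for an all-zero sample")
    xs = np.sort(x)
    n = xs.size
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * xs) / (n * total))


def _gini_sorted_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise Gini of a 2-D array (rows are resamples)."""
    xs = np.sort(mat, axis=1)
    n = xs.shape[1]
    i = np.arange(1, n + 1)
    return ((2 * i - n - 1) * xs).sum(axis=1) / (n * xs.sum(axis=1))


def _gini_jackknife(values: np.ndarray) -> np.ndarray:
    """Leave-one-out Gini values in O(n) from the sorted sample."""
    xs = np.sort(values)
    n = xs.size
    i = np.arange(1, n + 1)
    total = xs.sum()
    t_weighted = np.sum(i * xs)
    suffix = np.concatenate((np.cumsum(xs[::-1])[::-1][1:], [0.0]))  # sum of x_(k), k > j
    # removing x_(j): ranks above j decrease by one
    t_j = t_weighted - i * xs - suffix
    s_j = total - xs
    return (2 * t_j - n * s_j) / ((n - 1) * s_j)


@dataclass
class GiniEstimate:
    """Point Gini with percentile and BCa bootstrap intervals."""

    point: float
    percentile: tuple[float, float]
    bca: tuple[float, float]
    n_boot: int
    seed: int | None

    def ci(self, method: str = "bca") -> tuple[float, float]:
        if method not in ("bca", "percentile"):
            raise ValueError("method must be 'bca' or 'percentile'")
        return getattr(self, method)


def gini_bootstrap(
    values,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> GiniEstimate:
    """Bootstrap the Gini coefficient: percentile and BCa intervals from a
    single shared resample array.

    BCa: bias correction z0 from the fraction of resamples below the point
    estimate; acceleration from the jackknife skewness of leave-one-out
    estimates.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 10:
        raise ValueError("need at least 10 values to bootstrap")
    point = gini(x)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot = _gini_sorted_rows(x[idx])

    lo_q, hi_q = alpha / 2, 1 - alpha / 2
    perc = (float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q)))

    if np.ptp(boot) == 0:
        warnings.warn("degenerate bootstrap distribution: CI collapses to the point estimate")
        return GiniEstimate(point, (point, point), (point, point), n_boot, seed)

    frac_below = np.mean(boot < point)
    frac_below = min(max(frac_below, 1.0 / (n_boot + 1)), 1 - 1.0 / (n_boot + 1))
    z0 = norm.ppf(frac_below)
    jack = _gini_jackknife(x)
    dev = jack.mean() - jack
    denom = 6.0 * (np.sum(dev**2)) ** 1.5
    a = float(np.sum(dev**3) / denom) if denom > 0 else 0.0

    def _adj(q: float) -> float:
        z = norm.ppf(q)
        adj = norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        return float(np.quantile(boot, adj))

    bca = (_adj(lo_q), _adj(hi_q))
    return GiniEstimate(point, perc, bca, n_boot, seed)


# ---------------------------------------------------------------------------
# drought-phase analytics


def _phase_years(calendar, years: set[int]) -> dict[str, set[int]]:
    """Before/during/after year sets for a drought calendar.  A neighbor
    year that is itself a drought is excluded from before/after."""
    droughts = set(calendar.drought_years)
    before = {d - 1 for d in droughts} - droughts
    after = {d + 1 for d in droughts} - droughts
    return {
        "before": before & years,
        "during": droughts & years,
        "after": after & years,
    }


def _ks_d(a: np.ndarray, b: np.ndarray) -> float:
    """Sup-difference of the two empirical CDFs (no p-value)."""
    a = np.sort(a[~np.isnan(a)])
    b = np.sort(b[~np.isnan(b)])
    both = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, both, side="right") / a.size
    cdf_b = np.searchsorted(b, both, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def drought_phase_profiles(
    norm_profiles: pd.DataFrame,
    calendar,
    trait: str,
    groups: tuple[str, ...] = ("pure", "mixed"),
    span: float = 0.3,
    ks_mode: str = "profile",
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[dict[tuple[str, str], GroupProfile], pd.DataFrame]:
    """Drought-legacy profiles and phase contrasts per group.

    For every drought year d the rings at d-1 (before), d (during) and d+1
    (after) are collected per forest-type group and averaged into phase
    profiles; a before/after year that is itself a drought is excluded
    from that phase.  Phase pairs are compared by the KS D statistic,
    either between the two phase-mean 100-sector profiles
    (``ks_mode='profile'``) or between the pooled normalized sector values
    of the two phases (``ks_mode='pooled'``).

    In profile mode the p-value comes from a year-label permutation test
    (years are reassigned between the two phases, ring counts respected):
    rings of one year share a season and are strongly correlated, so the
    iid-based asymptotic KS p-value would be anti-conservative here;
    permuting whole years keeps the test calibrated under year-level
    exchangeability.  Pooled mode keeps the classical asymptotic p-value.

    Returns ({(group, phase): GroupProfile}, contrast table).
    """
    if ks_mode not in ("profile", "pooled"):
        raise ValueError("ks_mode must be 'profile' or 'pooled'")
    if not calendar.drought_years:
        raise ValueError("empty drought calendar")
    rng = np.random.default_rng(seed)
    sub = norm_profiles[norm_profiles["trait"] == trait]
    years = set(int(y) for y in sub["year"].unique())
    phase_years = _phase_years(calendar, years)

    profiles: dict[tuple[str, str], GroupProfile] = {}
    rows: list[dict] = []
    for group in groups:
        gsub = sub[sub["group"] == group]
        phase_data: dict[str, pd.DataFrame] = {}
        for phase, yrs in phase_years.items():
            sel = gsub[gsub["year"].isin(yrs)]
            if sel.empty or sel.groupby(["tree_id", "year"]).ngroups < 2:
                warnings.warn(f"phase {phase!r} omitted for group {group!r}: no eligible rings")
                continue
            phase_data[phase] = sel
            profiles[(group, phase)] = group_mean_profile(
                sel, group=group, trait=trait, phase=phase, span=span
            )
        # per-year sector-mean matrix for fast phase/permutation profiles
        year_mat = (
            gsub.pivot_table(index="year", columns="sector", values="value", aggfunc="mean")
            .reindex(columns=range(1, 101))
        )
        pairs = [("before", "during"), ("during", "after"), ("before", "after")]
        for p1, p2 in pairs:
            if p1 not in phase_data or p2 not in phase_data:
                continue
            if ks_mode == "profile":
                ya = sorted(phase_years[p1] & set(year_mat.index))
                yb = sorted(phase_years[p2] & set(year_mat.index))
                mat = year_mat.loc[ya + yb].to_numpy(dtype=float)
                na = len(ya)
                a = np.nanmean(mat[:na], axis=0)
                b = np.nanmean(mat[na:], axis=0)
                d_obs = _ks_d(a, b)
                count = 0
                rows_idx = np.arange(mat.shape[0])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN sectors
                    for _ in range(n_perm):
                        perm = rng.permutation(rows_idx)
                        pa = np.nanmean(mat[perm[:na]], axis=0)
                        pb = np.nanmean(mat[perm[na:]], axis=0)
                        count += _ks_d(pa, pb) >= d_obs
                p_value = (1 + count) / (n_perm + 1)
                n1, n2 = len(ya), len(yb)
            else:
                a = phase_data[p1]["value"].to_numpy(dtype=float)
                b = phase_data[p2]["value"].to_numpy(dtype=float)
                res = ks_two_sample(a, b)
                d_obs, p_value = res.d_stat, res.p_value
                n1, n2 = res.n1, res.n2
            rows.append(
                {
                    "group": group,
                    "trait": trait,
                    "phase_a": p1,
                    "phase_b": p2,
                    "mean_a": float(np.nanmean(a)),
                    "mean_b": float(np.nanmean(b)),
                    "d_stat": d_obs,
                    "p_value": p_value,
                    "significant": p_value < 0.05,
                    "ks_mode": ks_mode,
                    "n1": n1,
                    "n2": n2,
                }
            )
    return profiles, pd.DataFrame(rows)


def drought_vs_nondrought_gini(
    norm_profiles: pd.DataFrame,
    calendar,
    rwi: pd.DataFrame | None = None,
    groups: tuple[str, ...] = ("pure", "mixed"),
    traits: tuple[str, ...] = ("DH", "CWT", "AD"),
    site: str = "synthetic",
    n_boot: int = 2000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Gini table per group x trait x {drought, non-drought} stratum.

    Anatomical traits pool the normalized sector values of the stratum's
    rings; ring-width inequality (RWI rows) pools detrended annual
    ring-width indices (``rwi``: tree_id, group, year, rwi).  Each stratum
    gets a bootstrapped Gini with percentile and BCa intervals.
    """
    droughts = set(calendar.drought_years)
    rows: list[dict] = []
    trait_list = list(traits) + (["RWI"] if rwi is not None else [])
    for trait in trait_list:
        for group in groups:
            for phase, in_drought in (("non-drought", False), ("drought", True)):
                if trait == "RWI":
                    sub = rwi[(rwi["group"] == group)
                              & (rwi["year"].isin(droughts) == in_drought)]
                    vals = sub["rwi"].to_numpy(dtype=float)
                else:
                    sub = norm_profiles[
                        (norm_profiles["group"] == group)
                        & (norm_profiles["trait"] == trait)
                        & (norm_profiles["year"].isin(droughts) == in_drought)
                    ]
                    vals = sub["value"].to_numpy(dtype=float)
                vals = vals[~np.isnan(vals)]
                if vals.size < 10:
                    warnings.warn(f"stratum {trait}/{group}/{phase} omitted: too few values")
                    continue
                est = gini_bootstrap(vals, n_boot=n_boot, seed=seed)
                rows.append(
                    {
                        "site": site,
                        "forest_type": group,
                        "trait": trait,
                        "drought": "YES" if in_drought else "NO",
                        "gini": est.point,
                        "ci_low_bca": est.bca[0],
                        "ci_high_bca": est.bca[1],
                        "ci_low_percentile": est.percentile[0],
                        "ci_high_percentile": est.percentile[1],
                        "n": int(vals.size),
                    }
                )
    return pd.DataFrame(rows)
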