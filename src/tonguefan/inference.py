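"""Difference curves, significant-region extraction, coverage agreement,
group-average splines and comparison enumeration."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contours import INTENSITIES, NOTES
from .smoothing import SmoothFit, fit_smooth_1d, predict

__all__ = [
    "DiffCurve",
    "IntervalSet",
    "difference_curve",
    "significant_regions",
    "interval_coverage",
    "group_average_spline",
    "enumerate_comparisons",
]


@dataclass(frozen=True)
class DiffCurve:
    """Estimated difference between two condition smooths on a theta grid."""

    theta: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.ndim != 1 or not np.all(np.diff(th) > 0):
            raise ValueError("theta grid must be 1-D strictly increasing")
        if not (
            np.all(self.ci_low <= self.estimate + 1e-12)
            and np.all(self.estimate <= self.ci_high + 1e-12)
        ):
            raise ValueError("interval must bracket the estimate")


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, disjoint, closed theta intervals (possibly empty)."""

    intervals: tuple = ()

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        for a, b in ivs:
            if not a < b:
                raise ValueError(f"degenerate interval [{a}, {b}]")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if not b1 < a2:
                raise ValueError("intervals must be sorted and pairwise disjoint")
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_length(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def contains(self, x: float) -> bool:
        return any(a <= x <= b for a, b in self.intervals)

    def jaccard(self, other: "IntervalSet") -> float:
        """Length-based Jaccard overlap with another interval set."""
        inter = 0.0
        for a1, b1 in self.intervals:
            for a2, b2 in other.intervals:
                inter += max(0.0, min(b1, b2) - max(a1, a2))
        union = self.total_length() + other.total_length() - inter
        return inter / union if union > 0 else 1.0


def difference_curve(
    fit: SmoothFit,
    level_a: str,
    level_b: str,
    grid: np.ndarray | None = None,
    alpha: float = 0.05,
    simultaneous: bool = False,
    n_draws: int = 10_000,
    seed: int = 0,
    n_grid: int = 100,
) -> DiffCurve:
    """Estimated smooth for ``level_a`` minus ``level_b`` with uncertainty.

    Random terms are excluded from the contrast.  The default grid is
    ``n_grid`` equally spaced points over the intersection of the two
    levels' observed theta supports.  Pointwise ``1 - alpha`` intervals
    by default; ``simultaneous=True`` replaces the normal critical value
    with a seeded max-statistic simulation from the posterior
    covariance.
    """
    info = fit.design
    if info.spec.factor is None:
        raise ValueError("model has no condition factor to contrast")
    for lev in (level_a, level_b):
        if lev not in info.factor_levels:
            raise ValueError(f"unknown factor level {lev!r}")
    if grid is None:
        ra = info.level_ranges[level_a]
        rb = info.level_ranges[level_b]
        lo, hi = max(ra[0], rb[0]), min(ra[1], rb[1])
        if not hi > lo:
            raise ValueError("levels share no theta support")
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    nd_a = pd.DataFrame({info.spec.covariate: grid, info.spec.factor: level_a})
    nd_b = pd.DataFrame({info.spec.covariate: grid, info.spec.factor: level_b})
    C = info.rows(nd_a, include_random=False) - info.rows(nd_b, include_random=False)
    est = C @ fit.beta
    CV = C @ fit.Vb
    se = np.sqrt(np.maximum(np.einsum("ij,ij->i", CV, C), 0.0))
    if level_a == level_b:
        est = np.zeros_like(est)
        se = np.zeros_like(se)
    if simultaneous and np.all(se > 0):
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(fit.Vb + 1e-12 * np.eye(fit.Vb.shape[0]))
        draws = (C @ L) @ rng.standard_normal((fit.Vb.shape[0], n_draws))
        maxstat = np.max(np.abs(draws) / se[:, None], axis=0)
        crit = float(np.quantile(maxstat, 1.0 - alpha))
    else:
        crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return DiffCurve(
        theta=grid,
        estimate=est,
        se=se,
        ci_low=est - crit * se,
        ci_high=est + crit * se,
        label=f"{level_a} - {level_b}",
    )


def significant_regions(curve: DiffCurve, alpha: float = 0.05) -> IntervalSet:
    """Maximal theta runs where the confidence band excludes zero.

    Run endpoints are the outermost grid points of each run; the
    ``alpha`` argument rescales the band from the curve's stored SEs
    using the normal critical value.
    """
    crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    lo = curve.estimate - crit * curve.se
    hi = curve.estimate + crit * curve.se
    sig = (lo > 0) | (hi < 0)
    out = []
    th = curve.theta
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            if j > i:
                out.append((float(th[i]), float(th[j])))
            i = j + 1
        else:
            i += 1
    return IntervalSet(tuple(out))


def interval_coverage(sets, min_count: int) -> IntervalSet:
    """Theta values covered by at least ``min_count`` of the input intervals.

    Input is an iterable of :class:`IntervalSet` (or plain interval
    lists); ``None`` entries contribute nothing.  Closed-endpoint
    convention: shared endpoints count for both intervals.  Implemented
    as a sweep over sorted endpoints; zero-length output pieces are
    dropped.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    events = []
    for s in sets:
        if s is None:
            continue
        ivs = s.intervals if isinstance(s, IntervalSet) else [tuple(iv) for iv in s]
        for a, b in ivs:
            events.append((float(a), 0))   # open (starts sort before ends)
            events.append((float(b), 1))
    if not events:
        return IntervalSet()
    events.sort()
    out = []
    count = 0
    start = None
    for pos, kind in events:
        if kind == 0:
            count += 1
            if count == min_count:
                start = pos
        else:
            if count == min_count and start is not None:
                if pos > start:
                    out.append((start, pos))
                start = None
            count -= 1
    # merge touching pieces
    merged: list[list[float]] = []
    for a, b in out:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return IntervalSet(tuple((a, b) for a, b in merged))


def group_average_spline(
    fit: SmoothFit,
    table: pd.DataFrame,
    grouping: str,
    n_points: int = 100,
    include_random: bool = True,
) -> dict:
    """One smooth curve per group, fit to the model's own predictions.

    Predicts at every ingoing row, partitions the predictions by the
    ``grouping`` column, and smooths each partition with a single
    penalized spline evaluated on an ``n_points`` grid over that group's
    own theta range.  Returns ``{group: (grid, values)}``.
    """
    if grouping not in table.columns:
        raise ValueError(f"grouping column {grouping!r} not in table")
    est, _ = predict(fit, table, include_random=include_random)
    cov = fit.spec.covariate
    out = {}
    for g, idx in table.groupby(grouping, sort=True).indices.items():
        if len(idx) == 0:
            continue
        th = table[cov].to_numpy()[idx]
        yg = est[idx]
        # aggregate to per-theta means first: the smoother then sees the
        # nearly noise-free average and interpolates it rather than
        # shrinking against the between-condition spread
        uniq = np.unique(th)
        if uniq.size > 200:
            edges = np.quantile(th, np.linspace(0, 1, 201))
            bins = np.clip(np.searchsorted(edges, th, side="right") - 1, 0, 199)
            th_m = np.array([th[bins == b].mean() for b in np.unique(bins)])
            y_m = np.array([yg[bins == b].mean() for b in np.unique(bins)])
        else:
            order = np.searchsorted(uniq, th)
            y_m = np.zeros(uniq.size)
            cnt = np.zeros(uniq.size)
            np.add.at(y_m, order, yg)
            np.add.at(cnt, order, 1.0)
            th_m, y_m = uniq, y_m / cnt
        k = int(max(4, min(50, th_m.size)))
        sm = fit_smooth_1d(th_m, y_m, k=k)
        grid = np.linspace(th.min(), th.max(), n_points)
        out[g] = (grid, sm.predict(grid))
    return out


def enumerate_comparisons(cell_manifest: pd.DataFrame) -> pd.DataFrame:
    """Within-language pairwise note comparisons at matched intensity.

    ``cell_manifest`` lists available cells with columns ``language``,
    ``category`` (note) and ``intensity`` (extra columns ignored).  For
    each language and intensity, every unordered pair of notes whose
    cells are both present yields one comparison.  Ordering is
    deterministic: language, intensity (musical order), then note pair
    (pitch order).
    """
    need = {"language", "category", "intensity"}
    if not need <= set(cell_manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(need)}")
    cells = set(
        zip(
            cell_manifest["language"].astype(str),
            cell_manifest["category"].astype(str),
            cell_manifest["intensity"].astype(str),
        )
    )
    langs = sorted({c[0] for c in cells})
    notes = [n for n in NOTES] + sorted(
        {c[1] for c in cells} - set(NOTES)
    )
    intens = [i for i in INTENSITIES] + sorted(
        {c[2] for c in cells} - set(INTENSITIES)
    )
    rows = []
    for lang in langs:
        for inten in intens:
            present = [n for n in notes if (lang, n, inten) in cells]
            for i, na in enumerate(present):
                for nb in present[i + 1 :]:
                    rows.append(
                        {
                            "language": lang,
                            "intensity": inten,
                            "note_a": na,
                            "note_b": nb,
                        }
                    )
    return pd.DataFrame(rows, columns=["language", "intensity", "note_a", "note_b"])
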