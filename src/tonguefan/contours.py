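"""Traced tongue contour data model, CSV I/O, resampling, outlier screening.

A contour is an ordered sequence of polar points ``(theta, rho)`` about
the virtual origin, with metadata identifying the subject, language,
token kind (vowel or note), category, intensity (notes only), phonetic
context (vowels only) and repetition.  The stacked long-format table is
the model input; its CSV schema is documented on
:func:`read_contour_table`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "TongueContour",
    "ContourTable",
    "CSV_COLUMNS",
    "read_contour_table",
    "write_contour_table",
    "resample_contour",
    "flag_outliers",
    "mean_category_contour",
    "read_textgrid_labels",
]

LANGUAGES = ("NZE", "Tongan")
TOKEN_KINDS = ("vowel", "note")
NOTES = ("Bb2", "F3", "Bb3", "D4", "F4")
INTENSITIES = ("piano", "mezzopiano", "mezzoforte", "forte")

CSV_COLUMNS = [
    "subject",
    "language",
    "token_kind",
    "category",
    "intensity",
    "preceding",
    "following",
    "rep_index",
    "point_index",
    "theta",
    "rho",
]

KEY_COLUMNS = ["subject", "token_kind", "category", "intensity", "rep_index"]


@dataclass(frozen=True)
class TongueContour:
    """One traced tongue surface in polar coordinates.

    ``points`` is an (n, 2) array of ``(theta, rho)`` with theta
    strictly increasing (posterior to anterior) and rho positive.
    """

    subject_id: str
    language: str
    token_kind: str
    category: str
    rep_index: int
    points: np.ndarray = field(repr=False)
    intensity: str | None = None
    preceding: str | None = None
    following: str | None = None

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] < 3 or pts.shape[1] != 2:
            raise ValueError("a contour needs >= 3 (theta, rho) points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite contour point")
        if not np.all(np.diff(pts[:, 0]) > 0):
            raise ValueError("theta must be strictly increasing along the contour")
        if not np.all(pts[:, 1] > 0):
            raise ValueError("rho must be positive")
        if self.token_kind not in TOKEN_KINDS:
            raise ValueError(f"token_kind must be one of {TOKEN_KINDS}")
        if self.token_kind == "note" and self.intensity is None:
            raise ValueError("note contours require an intensity")
        if self.token_kind == "vowel" and self.intensity is not None:
            raise ValueError("vowel contours carry no intensity")
        object.__setattr__(self, "points", pts)

    @property
    def theta(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def rho(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def theta_range(self) -> tuple[float, float]:
        return float(self.points[0, 0]), float(self.points[-1, 0])

    def key(self) -> tuple:
        return (
            self.subject_id,
            self.token_kind,
            self.category,
            self.intensity or "",
            self.rep_index,
        )


class ContourTable:
    """Stacked long-format contour dataset.

    Wraps a pandas DataFrame with one row per traced point; the
    contour key ``(subject, token_kind, category, intensity, rep_index)``
    plus ``point_index`` is unique.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s): {missing}")
        df = df.copy()
        df["intensity"] = df["intensity"].fillna("")
        df["preceding"] = df["preceding"].fillna("")
        df["following"] = df["following"].fillna("")
        for col in ("theta", "rho"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(vals.isna().to_numpy())
            if bad.size:
                raise ValueError(
                    f"non-numeric {col} at row(s) {bad[:10].tolist()}"
                )
            df[col] = vals.astype(float)
        df["rep_index"] = df["rep_index"].astype(int)
        df["point_index"] = df["point_index"].astype(int)
        dup = df.duplicated(subset=KEY_COLUMNS + ["point_index"])
        if dup.any():
            first = df.loc[dup.idxmax(), KEY_COLUMNS + ["point_index"]]
            raise ValueError(f"duplicate key: {tuple(first)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_contours(self) -> int:
        return len(self.df.drop_duplicates(subset=KEY_COLUMNS))

    def contours(self):
        """Iterate :class:`TongueContour` objects in table order."""
        for key, g in self.df.groupby(KEY_COLUMNS, sort=False):
            g = g.sort_values("point_index")
            subject, kind, cat, inten, rep = key
            yield TongueContour(
                subject_id=str(subject),
                language=str(g["language"].iloc[0]),
                token_kind=str(kind),
                category=str(cat),
                rep_index=int(rep),
                intensity=str(inten) if inten else None,
                preceding=str(g["preceding"].iloc[0]) or None,
                following=str(g["following"].iloc[0]) or None,
                points=g[["theta", "rho"]].to_numpy(),
            )

    def manifest(self) -> pd.DataFrame:
        """Contour counts per (language, token_kind, category, intensity) cell."""
        one = self.df.drop_duplicates(subset=KEY_COLUMNS)
        return (
            one.groupby(["language", "token_kind", "category", "intensity"])
            .size()
            .rename("n_contours")
            .reset_index()
        )

    @classmethod
    def from_contours(cls, contours) -> "ContourTable":
        rows = []
        for c in contours:
            n = len(c.points)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": c.subject_id,
                        "language": c.language,
                        "token_kind": c.token_kind,
                        "category": c.category,
                        "intensity": c.intensity or "",
                        "preceding": c.preceding or "",
                        "following": c.following or "",
                        "rep_index": c.rep_index,
                        "point_index": np.arange(n),
                        "theta": c.points[:, 0],
                        "rho": c.points[:, 1],
                    }
                )
            )
        if not rows:
            raise ValueError("no contours supplied")
        return cls(pd.concat(rows, ignore_index=True))

    def to_model_frame(self, n_points: int = 100) -> pd.DataFrame:
        """Resample every contour to ``n_points`` and stack for modeling.

        Adds a ``contour_id`` column (one integer per contour, rows of a
        contour consecutive and theta-ordered) and the interaction
        factor columns used by the standard models:
        ``language_note_intensity``, ``language_category``,
        ``note_intensity`` and ``token``.
        """
        fast = self._model_frame_fast(n_points)
        if fast is not None:
            return fast
        frames = []
        for cid, c in enumerate(self.contours()):
            r = resample_contour(c, n_points)
            frames.append(
                pd.DataFrame(
                    {
                        "contour_id": cid,
                        "subject": r.subject_id,
                        "language": r.language,
                        "token_kind": r.token_kind,
                        "category": r.category,
                        "intensity": r.intensity or "",
                        "preceding": r.preceding or "",
                        "following": r.following or "",
                        "rep_index": r.rep_index,
                        "theta": r.theta,
                        "rho": r.rho,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        return self._add_interaction_columns(df)

    @staticmethod
    def _add_interaction_columns(df: pd.DataFrame) -> pd.DataFrame:
        df["token"] = df["category"]
        df["note_intensity"] = df["category"] + "." + df["intensity"]
        df["language_note_intensity"] = (
            df["language"] + "." + df["category"] + "." + df["intensity"]
        )
        df["language_category"] = df["language"] + "." + df["category"]
        return df

    def _model_frame_fast(self, n_points: int) -> pd.DataFrame | None:
        """Vectorized path when every contour already sits on its own
        ``n_points`` grid (the generator's untruncated output); returns
        None when the general resampling loop is needed."""
        df = self.df
        key_codes, _ = pd.factorize(
            pd.MultiIndex.from_frame(df[KEY_COLUMNS]), sort=False
        )
        counts = np.bincount(key_codes)
        if not np.all(counts == n_points):
            return None
        order = np.lexsort((df["point_index"].to_numpy(), key_codes))
        out = df.iloc[order].reset_index(drop=True)
        th = out["theta"].to_numpy().reshape(-1, n_points)
        # already on an even grid? (generator fast path); otherwise resample
        expect = np.linspace(th[:, 0], th[:, -1], n_points).T
        if not np.allclose(th, expect, rtol=0, atol=1e-12):
            return None
        out.insert(0, "contour_id", np.repeat(np.arange(len(counts)), n_points))
        out = out.drop(columns=["point_index"])
        return self._add_interaction_columns(out)


def read_contour_table(path) -> ContourTable:
    """Read the documented contour CSV.

    Columns (header required, UTF-8): subject, language, token_kind,
    category, intensity, preceding, following, rep_index, point_index,
    theta, rho.  ``intensity``/``preceding``/``following`` may be empty.
    Malformed rows raise with their position; duplicate keys raise
    naming the key.
    """
    df = pd.read_csv(path, dtype={"subject": str, "category": str}, keep_default_na=False)
    for col in ("intensity", "preceding", "following"):
        if col in df.columns:
            df[col] = df[col].replace({"": None})
    return ContourTable(df)


def write_contour_table(table: ContourTable, path) -> None:
    """Write the canonical CSV form (round-trips with read_contour_table)."""
    table.df.to_csv(path, index=False, columns=CSV_COLUMNS)


def resample_contour(contour: TongueContour, n_points: int = 100) -> TongueContour:
    """Cubic-spline resampling of rho over theta at ``n_points`` equally
    spaced angles spanning the contour's own theta range (no
    extrapolation).  Endpoint thetas are preserved exactly.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    th, rho = contour.theta, contour.rho
    grid = np.linspace(th[0], th[-1], n_points)
    if th.size == n_points and np.allclose(th, grid, rtol=0, atol=1e-12):
        return contour
    spline = CubicSpline(th, rho)  # not-a-knot: reproduces cubics exactly
    return replace(contour, points=np.column_stack([grid, spline(grid)]))


def flag_outliers(contours, threshold_mad: float = 3.5, grid_size: int = 100):
    """Screen a same-cell group of contours for gross tracing outliers.

    Each contour is resampled onto the group's common theta grid (the
    intersection of ranges); the pointwise median curve is computed, and
    a contour is flagged when its mean absolute distance from the median
    curve, standardized by the MAD of those distances across the group,
    exceeds ``threshold_mad``.  Returns a boolean array aligned with the
    input order; groups of fewer than 5 contours warn and return all
    False (flags only — removal is the caller's decision).
    """
    contours = list(contours)
    flags = np.zeros(len(contours), dtype=bool)
    if len(contours) < 5:
        warnings.warn("outlier screening needs >= 5 contours; returning no flags")
        return flags
    lo = max(c.theta_range[0] for c in contours)
    hi = min(c.theta_range[1] for c in contours)
    if not hi > lo:
        warnings.warn("contours share no theta overlap; returning no flags")
        return flags
    grid = np.linspace(lo, hi, grid_size)
    curves = np.empty((len(contours), grid_size))
    for i, c in enumerate(contours):
        curves[i] = CubicSpline(c.theta, c.rho)(grid)
    median_curve = np.median(curves, axis=0)
    dist = np.mean(np.abs(curves - median_curve), axis=1)
    med = np.median(dist)
    mad = np.median(np.abs(dist - med))
    if mad == 0:
        return flags
    # 1.4826 makes MAD consistent for the normal scale
    flags = np.abs(dist - med) / (1.4826 * mad) > threshold_mad
    return flags


def mean_category_contour(contours, category: str | None = None, n_points: int = 100):
    """Average contour of a category via a single penalized-spline fit.

    Pools the points of all matching contours, smooths rho over theta
    (delegating to the spline engine) and evaluates on an ``n_points``
    grid over the intersection of observed theta ranges.  Returns an
    (n_points, 2) polar array.
    """
    from .smoothing import fit_smooth_1d

    group = [c for c in contours if category is None or c.category == category]
    if not group:
        raise ValueError(f"no contours of category {category!r}")
    lo = max(c.theta_range[0] for c in group)
    hi = min(c.theta_range[1] for c in group)
    if not hi > lo:
        raise ValueError("contours share no theta overlap")
    th = np.concatenate([c.theta for c in group])
    rho = np.concatenate([c.rho for c in group])
    keep = (th >= lo) & (th <= hi)
    # basis dimension adapts to the observed grid so that noise-free
    # replicates are recovered exactly (REML drives lambda to zero)
    k = int(min(n_points, np.unique(th[keep]).size))
    sm = fit_smooth_1d(th[keep], rho[keep], k=max(k, 4))
    grid = np.linspace(lo, hi, n_points)
    return np.column_stack([grid, sm.predict(grid)])


_TG_INTERVAL = re.compile(
    r'intervals\s*\[\d+\]\s*:\s*xmin\s*=\s*([\d.eE+-]+)\s*'
    r'xmax\s*=\s*([\d.eE+-]+)\s*text\s*=\s*"([^"]*)"'
)


def read_textgrid_labels(path, tier: str = "notes") -> pd.DataFrame:
    """Minimal Praat TextGrid (long format) interval reader.

    Returns a DataFrame with columns ``tmin``, ``tmax``, ``label`` for
    the named interval tier, skipping empty labels.  Only the verbose
    long text format is supported; metadata use only.
    """
    text = open(path, encoding="utf-8").read()
    tiers = re.split(r'item\s*\[\d+\]\s*:', text)[1:]
    for block in tiers:
        m = re.search(r'name\s*=\s*"([^"]*)"', block)
        if m and m.group(1) == tier:
            rows = [
                {"tmin": float(a), "tmax": float(b), "label": lab}
                for a, b, lab in _TG_INTERVAL.findall(block)
                if lab.strip()
            ]
            return pd.DataFrame(rows, columns=["tmin", "tmax", "label"])
    raise ValueError(f"tier {tier!r} not found in {path}")
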