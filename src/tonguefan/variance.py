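"""Per-speaker, per-category variance curves over binned theta, and the
variance-response additive model comparing languages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contours import ContourTable
from .smoothing import ModelSpec, SmoothFit, fit

__all__ = [
    "VarianceCurve",
    "bin_variance_curves",
    "variance_curves_frame",
    "fit_variance_model",
]


@dataclass(frozen=True)
class VarianceCurve:
    """Variance of rho per theta bin for one (subject, category) cell.

    ``variance`` is NaN where a bin holds fewer than 2 observations.
    """

    subject_id: str
    language: str
    category: str
    token_kind: str
    bin_centers: np.ndarray
    variance: np.ndarray
    n_per_bin: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.variance, dtype=float)
        if np.any(v[np.isfinite(v)] < 0):
            raise ValueError("variance must be non-negative where defined")


def bin_variance_curves(
    table: ContourTable | pd.DataFrame, n_bins: int = 100
) -> list[VarianceCurve]:
    """Bin theta into ``n_bins`` equal-width bins over the global observed
    range and compute, per (subject, category, bin), the sample variance
    of rho pooled across all repetitions (and, for notes, intensities).
    One curve per (subject, category) cell with data.
    """
    df = table.df if isinstance(table, ContourTable) else table
    th = df["theta"].to_numpy(dtype=float)
    lo, hi = th.min(), th.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    bin_idx = np.clip(np.searchsorted(edges, th, side="right") - 1, 0, n_bins - 1)
    work = pd.DataFrame(
        {
            "subject": df["subject"].astype(str),
            "language": df["language"].astype(str),
            "token_kind": df["token_kind"].astype(str),
            "category": df["category"].astype(str),
            "bin": bin_idx,
            "rho": df["rho"].to_numpy(dtype=float),
        }
    )
    curves = []
    for (subj, lang, kind, cat), g in work.groupby(
        ["subject", "language", "token_kind", "category"], sort=True
    ):
        var = np.full(n_bins, np.nan)
        n = np.zeros(n_bins, dtype=int)
        gb = g.groupby("bin")["rho"]
        counts = gb.size()
        n[counts.index.to_numpy()] = counts.to_numpy()
        v = gb.var(ddof=1)  # NaN for singleton bins
        var[v.index.to_numpy()] = v.to_numpy()
        curves.append(
            VarianceCurve(
                subject_id=subj,
                language=lang,
                category=cat,
                token_kind=kind,
                bin_centers=centers,
                variance=var,
                n_per_bin=n,
            )
        )
    return curves


def variance_curves_frame(curves) -> pd.DataFrame:
    """Tidy frame of the defined bins of each curve (CSV-exportable).

    Columns: subject, language, token_kind, category, language_category,
    theta (bin center), n, var_rho, contour_id (one id per curve; rows
    of a curve are consecutive, supporting AR(1) grouping).
    """
    frames = []
    for cid, c in enumerate(curves):
        ok = np.isfinite(c.variance)
        if not ok.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "contour_id": cid,
                    "subject": c.subject_id,
                    "language": c.language,
                    "token_kind": c.token_kind,
                    "category": c.category,
                    "language_category": f"{c.language}.{c.category}",
                    "theta": c.bin_centers[ok],
                    "n": c.n_per_bin[ok],
                    "var_rho": c.variance[ok],
                }
            )
        )
    if not frames:
        raise ValueError("no defined variance bins")
    return pd.concat(frames, ignore_index=True)


def fit_variance_model(
    curves,
    factor: str = "language",
    factor_levels=None,
    k: int = 10,
    random_subject: bool = True,
    ar_phi="estimate",
    n_points: int = 100,
) -> tuple[SmoothFit, dict]:
    """Model binned variance curves with the spline engine.

    Fits ``var_rho ~ factor + s(theta) + s(theta, by=factor)
    [+ s(theta, subject, by=factor)]`` and returns the fit together with
    per-language group-average variance splines.  With a single observed
    factor level the model reduces to the reference smooth (plus subject
    smooths).
    """
    from .inference import group_average_spline

    df = variance_curves_frame(curves)
    if factor_levels is None:
        factor_levels = tuple(sorted(df[factor].astype(str).unique()))
    use_factor = factor if len(factor_levels) > 1 else None
    random_terms = ()
    if random_subject and df["subject"].nunique() > 1:
        by = factor if use_factor else None
        random_terms = ((("subject"), by),)
    spec = ModelSpec(
        response="var_rho",
        factor=use_factor,
        factor_levels=factor_levels if use_factor else None,
        k=k,
        random_terms=random_terms,
        ar_phi=ar_phi,
    )
    fit_ = fit(spec, df)
    averages = group_average_spline(fit_, df, "language", n_points=n_points)
    return fit_, averages
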