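"""Polar visualization of fitted smooths and significance regions.

Curves live in polar coordinates about the virtual origin; rendering is
Cartesian with the anterior direction at the right and "up" meaning away
from the probe (the image y-axis is flipped for display).  Significant
theta regions are shaded as angular sectors.  Theta tick labels are
printed as fractions of pi.
"""

from __future__ import annotations

from fractions import Fraction

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .inference import IntervalSet

__all__ = ["plot_polar_smooths", "pi_label"]


def pi_label(theta: float) -> str:
    """Format an angle as a fraction of pi (e.g. ``-3/4 pi``)."""
    frac = Fraction(theta / np.pi).limit_denominator(12)
    if frac == 0:
        return "0"
    num, den = frac.numerator, frac.denominator
    sign = "-" if num < 0 else ""
    num = abs(num)
    if den == 1:
        return f"{sign}pi" if num == 1 else f"{sign}{num} pi"
    return f"{sign}{num}/{den} pi"


def _to_xy(theta, rho):
    # flip image-coordinate y so tissue above the origin plots upward
    return rho * np.cos(theta), -rho * np.sin(theta)


def plot_polar_smooths(
    curves: dict,
    regions: IntervalSet | None = None,
    path=None,
    title: str = "",
    rho_max: float | None = None,
):
    """Render polar curves about the virtual origin with shaded sectors.

    ``curves`` maps a label to ``(theta, rho)`` arrays.  ``regions`` are
    theta intervals shaded as wedges; regions outside the union of curve
    supports are clipped with a warning.  Writes to ``path`` (suffix
    selects SVG/PNG) when given; returns the figure.
    """
    import warnings

    if not curves:
        raise ValueError("no curves to plot")
    fig, ax = plt.subplots(figsize=(7, 5))
    lo = min(np.min(th) for th, _ in curves.values())
    hi = max(np.max(th) for th, _ in curves.values())
    if rho_max is None:
        rho_max = 1.1 * max(np.max(r) for _, r in curves.values())
    if regions is not None:
        for a, b in regions:
            if b < lo or a > hi:
                warnings.warn(f"region [{a:.2f}, {b:.2f}] outside curve support; skipped")
                continue
            a_, b_ = max(a, lo), min(b, hi)
            if (a_, b_) != (a, b):
                warnings.warn(f"region [{a:.2f}, {b:.2f}] clipped to curve support")
            wedge_th = np.linspace(a_, b_, 50)
            x, y = _to_xy(wedge_th, np.full_like(wedge_th, rho_max))
            ax.fill(
                np.concatenate([[0.0], x, [0.0]]),
                np.concatenate([[0.0], y, [0.0]]),
                color="0.85",
                zorder=0,
                # gid lets tests recover the shaded sector from the artist
                gid=f"sig-region:{a_:.6f}:{b_:.6f}",
            )
    for label, (th, rho) in curves.items():
        x, y = _to_xy(np.asarray(th, float), np.asarray(rho, float))
        ax.plot(x, y, label=str(label))
    for t in np.arange(np.ceil(lo / (np.pi / 4)), np.floor(hi / (np.pi / 4)) + 1):
        th = t * np.pi / 4
        x, y = _to_xy(th, rho_max)
        ax.plot([0, x], [0, y], color="0.9", lw=0.5, zorder=0)
        ax.annotate(pi_label(th), (x, y), fontsize=8, color="0.4")
    ax.set_aspect("equal")
    ax.set_xlabel("px from virtual origin (anterior at right)")
    ax.set_ylabel("px from virtual origin")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
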