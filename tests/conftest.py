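import numpy as np
import pandas as pd
import pytest

from tonguefan.contours import ContourTable, TongueContour


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_contour(
    subject="S01",
    language="NZE",
    token_kind="vowel",
    category="FLEECE",
    rep=0,
    theta=None,
    rho=None,
    intensity=None,
    **kw,
):
    if theta is None:
        theta = np.linspace(-2.8, -0.5, 50)
    if rho is None:
        rho = 350.0 + 30.0 * np.exp(-0.5 * ((theta + 1.5) / 0.4) ** 2)
    return TongueContour(
        subject_id=subject,
        language=language,
        token_kind=token_kind,
        category=category,
        rep_index=rep,
        intensity=intensity,
        points=np.column_stack([theta, rho]),
        **kw,
    )


@pytest.fixture
def small_table():
    """Three simple contours: two FLEECE reps and one LOT."""
    cs = [
        make_contour(rep=0),
        make_contour(rep=1),
        make_contour(category="LOT", rep=0),
    ]
    return ContourTable.from_contours(cs)


def two_condition_frame(
    n_contours=20,
    n_points=50,
    diff_amplitude=0.0,
    diff_center=-2.3,
    diff_width=0.18,
    noise_sd=3.0,
    phi=0.0,
    seed=0,
):
    """Long-format frame with conditions A/B and an optional planted bump on B."""
    rng = np.random.default_rng(seed)
    rows = []
    cid = 0
    th = np.linspace(-2.8, -0.5, n_points)
    base = 350.0 + 30.0 * np.exp(-0.5 * ((th + 1.5) / 0.4) ** 2)
    for lev in ("A", "B"):
        mu = base.copy()
        if lev == "B" and diff_amplitude:
            mu = mu + diff_amplitude * np.exp(-0.5 * ((th - diff_center) / diff_width) ** 2)
        for _ in range(n_contours):
            if phi > 0:
                e = np.empty(n_points)
                e[0] = rng.standard_normal()
                innov = rng.standard_normal(n_points - 1) * np.sqrt(1 - phi * phi)
                for t in range(1, n_points):
                    e[t] = phi * e[t - 1] + innov[t - 1]
            else:
                e = rng.standard_normal(n_points)
            rows.append(
                pd.DataFrame(
                    {"contour_id": cid, "theta": th, "rho": mu + noise_sd * e, "cond": lev}
                )
            )
            cid += 1
    return pd.concat(rows, ignore_index=True)
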