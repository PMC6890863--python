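"""Synthetic contour datasets with known ground truth.

Prototype tongue shapes are sums of Gaussian bumps over a baseline arc
(analytically convenient, not anatomically faithful).  A configurable
group-difference bump is added to one language's note productions, each
subject carries a rotation/scale offset applied in polar space (which
the geometry module must undo), and residual noise is AR(1) along the
contour.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contours import (
    INTENSITIES,
    NOTES,
    ContourTable,
)
from .inference import IntervalSet

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_dataset",
    "study_mimic_config",
    "distribute_counts",
    "NZE_VOWELS",
    "TONGAN_VOWELS",
]

# 11 monophthong lexical sets plus non-final and final schwa
NZE_VOWELS = (
    "FLEECE",
    "KIT",
    "DRESS",
    "TRAP",
    "START",
    "LOT",
    "THOUGHT",
    "FOOT",
    "GOOSE",
    "NURSE",
    "STRUT",
    "schwa_nonfinal",
    "schwa_final",
)
TONGAN_VOWELS = ("a", "e", "i", "o", "u")

CONTEXTS = ("t", "k")  # closed coronal/velar context set for vowels


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; see module docstring for the data model."""

    n_subjects: int = 10                      # per language
    vowel_categories: dict = field(
        default_factory=lambda: {"NZE": NZE_VOWELS, "Tongan": TONGAN_VOWELS}
    )
    notes: tuple = NOTES
    intensities: tuple = INTENSITIES
    missing_cells: tuple = (("NZE", "F4", "mezzopiano"),)
    reps_vowel: int = 3
    reps_note: int = 3
    note_cell_counts: dict | None = None      # (lang, note, intensity) -> total reps
    vowel_cell_counts: dict | None = None     # (lang, category) -> total reps
    theta_span: tuple = (-2.8, -0.5)
    n_points: int = 100
    baseline_rho: float = 350.0
    bump_amplitude_range: tuple = (20.0, 60.0)
    bump_width_range: tuple = (0.25, 0.6)
    subject_rotation_sd: float = 0.0          # rad
    subject_logscale_sd: float = 0.0
    subject_smooth_sd: float = 0.0            # px, per-subject shape deviation
    diff_language: str = "NZE"
    diff_center: float = -2.3                 # inside the posterior region
    diff_width: float = 0.18
    diff_amplitude: float = 0.0               # px; applied to diff_language notes
    intensity_slope: float = 0.0              # px per dynamic step (centered)
    noise_sd: float = 0.0                     # marginal residual sd, px
    noise_phi: float = 0.0                    # AR(1) along the contour
    truncation: float = 0.0                   # max fraction removable per end
    align_category: dict = field(
        default_factory=lambda: {"NZE": "FLEECE", "Tongan": "i"}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_phi < 1.0):
            raise ValueError("noise_phi must lie in [0, 1)")
        if not (0.0 <= self.truncation < 0.5):
            raise ValueError("truncation must lie in [0, 0.5)")
        for name in ("subject_rotation_sd", "subject_logscale_sd", "noise_sd",
                     "subject_smooth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.theta_span[0] >= self.theta_span[1]:
            raise ValueError("theta_span must be increasing")


@dataclass
class GroundTruth:
    """True generating quantities for recovery testing."""

    grid: np.ndarray
    diff_values: np.ndarray          # note difference, diff_language minus other
    true_region: IntervalSet
    subject_transforms: dict         # (language, subject) -> (rotation, scale)
    prototypes: dict                 # category -> rho values on grid

    def to_json(self, path) -> None:
        payload = {
            "grid": self.grid.tolist(),
            "diff_values": self.diff_values.tolist(),
            "true_region": [list(iv) for iv in self.true_region],
            "subject_transforms": {
                f"{lang}/{subj}": [rot, scale]
                for (lang, subj), (rot, scale) in self.subject_transforms.items()
            },
            "prototypes": {k: v.tolist() for k, v in self.prototypes.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def distribute_counts(cells, total: int) -> dict:
    """Split ``total`` repetitions over ``cells`` as evenly as possible,
    deterministically (earlier cells get the remainder)."""
    cells = list(cells)
    if not cells:
        raise ValueError("no cells")
    base, rem = divmod(total, len(cells))
    return {c: base + (1 if i < rem else 0) for i, c in enumerate(cells)}


def _gauss(theta, center, width, amplitude):
    return amplitude * np.exp(-0.5 * ((theta - center) / width) ** 2)


def _ar1_noise(rng, n, sd, phi):
    if sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - phi * phi) if n > 1 else None
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innov[t - 1]
    return sd * e


def study_mimic_config(scale_factor: float = 1.0, **overrides) -> SynthConfig:
    """Config reproducing the study's cell structure.

    10 subjects per language; 13 NZE and 5 Tongan vowel categories;
    5 notes x 4 intensities with the NZE F4-mezzopiano cell absent.
    ``scale_factor`` scales per-cell repetition counts (floor 2) without
    touching the cell structure; default effect sizes make the planted
    posterior note difference detectable at full scale.
    """
    if not (0.0 < scale_factor <= 1.0):
        raise ValueError("scale_factor must lie in (0, 1]")
    reps = max(2, round(4 * scale_factor))
    defaults = dict(
        reps_vowel=reps,
        reps_note=reps,
        subject_rotation_sd=0.05,
        subject_logscale_sd=0.04,
        subject_smooth_sd=3.0,
        diff_amplitude=12.0,
        intensity_slope=2.0,
        noise_sd=4.0,
        noise_phi=0.6,
        truncation=0.08,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


def _prototype_params(rng, categories, cfg):
    """Per-category bump parameters drawn once, deterministically.

    All alignment categories (the per-language high front vowel labels)
    share a single prototype: they stand for the same articulatory
    target, and cross-language alignment relies on that.
    """
    lo, hi = cfg.theta_span
    align_cats = set(cfg.align_category.values())

    def draw():
        n_bumps = 2
        centers = rng.uniform(lo + 0.2, hi - 0.2, n_bumps)
        widths = rng.uniform(*cfg.bump_width_range, n_bumps)
        amps = rng.uniform(*cfg.bump_amplitude_range, n_bumps)
        return list(zip(centers, widths, amps))

    shared_align = draw()
    params = {}
    for cat in categories:
        params[cat] = shared_align if cat in align_cats else draw()
    return params


def _proto_eval(params, theta, baseline):
    out = np.full_like(theta, baseline, dtype=float)
    for c, w, a in params:
        out += _gauss(theta, c, w, a)
    return out


def generate_dataset(cfg: SynthConfig) -> tuple[ContourTable, GroundTruth]:
    """Generate a long-format contour table plus its ground truth.

    For every contour, ``rho(theta)`` is the category prototype, plus
    the group-difference bump (notes of ``cfg.diff_language`` only), an
    intensity effect (centered dynamic index times the slope), the
    subject's smooth shape deviation, and AR(1) noise — evaluated on a
    randomly truncated theta grid; the subject's rotation/scale offset
    is then applied in polar space.
    """
    rng = np.random.default_rng(cfg.seed)
    languages = sorted(cfg.vowel_categories)
    lo, hi = cfg.theta_span
    grid_full = np.linspace(lo, hi, cfg.n_points)

    all_categories = sorted(
        {c for cats in cfg.vowel_categories.values() for c in cats} | set(cfg.notes)
    )
    proto = _prototype_params(rng, all_categories, cfg)

    # per-subject anatomy: rotation/scale offset + smooth shape deviation
    transforms = {}
    subj_dev = {}
    for lang in languages:
        for s in range(cfg.n_subjects):
            sid = f"{lang}{s + 1:02d}"
            rot = rng.normal(0.0, cfg.subject_rotation_sd)
            scale = float(np.exp(rng.normal(0.0, cfg.subject_logscale_sd)))
            transforms[(lang, sid)] = (float(rot), scale)
            dev_params = [
                (rng.uniform(lo, hi), rng.uniform(0.3, 0.8), rng.normal(0.0, 1.0))
                for _ in range(3)
            ]
            subj_dev[(lang, sid)] = dev_params

    missing = {tuple(m) for m in cfg.missing_cells}
    inten_center = (len(cfg.intensities) - 1) / 2.0

    rows = []

    def emit(lang, sid, kind, cat, inten, prec, foll, rep):
        # truncated theta grid (keep >= 4 points)
        if cfg.truncation > 0:
            span = hi - lo
            a = lo + rng.uniform(0.0, cfg.truncation) * span
            b = hi - rng.uniform(0.0, cfg.truncation) * span
        else:
            a, b = lo, hi
        keep = (grid_full >= a) & (grid_full <= b)
        if keep.sum() < 4:
            keep = np.ones_like(keep)
        th = grid_full[keep]
        rho = _proto_eval(proto[cat], th, cfg.baseline_rho)
        if kind == "note" and lang == cfg.diff_language and cfg.diff_amplitude:
            rho = rho + _gauss(th, cfg.diff_center, cfg.diff_width, cfg.diff_amplitude)
        if kind == "note" and cfg.intensity_slope:
            step = cfg.intensities.index(inten) - inten_center
            rho = rho + cfg.intensity_slope * step
        if cfg.subject_smooth_sd:
            dev = np.zeros_like(th)
            for c, w, a_ in subj_dev[(lang, sid)]:
                dev += _gauss(th, c, w, a_)
            rho = rho + cfg.subject_smooth_sd * dev
        rho = rho + _ar1_noise(rng, th.size, cfg.noise_sd, cfg.noise_phi)
        rot, scale = transforms[(lang, sid)]
        th_out = th + rot
        rho_out = rho * scale
        n = th.size
        rows.append(
            {
                "subject": sid,
                "language": lang,
                "token_kind": kind,
                "category": cat,
                "intensity": inten or "",
                "preceding": prec or "",
                "following": foll or "",
                "rep_index": rep,
                "theta": th_out,
                "rho": rho_out,
                "n": n,
            }
        )

    for lang in languages:
        subjects = [f"{lang}{s + 1:02d}" for s in range(cfg.n_subjects)]
        # vowels
        for cat in cfg.vowel_categories[lang]:
            if cfg.vowel_cell_counts is not None:
                total = cfg.vowel_cell_counts.get((lang, cat), 0)
                per_subj = distribute_counts(subjects, total)
            else:
                per_subj = {s: cfg.reps_vowel for s in subjects}
            for sid in subjects:
                for rep in range(per_subj[sid]):
                    prec = CONTEXTS[int(rng.integers(len(CONTEXTS)))]
                    foll = CONTEXTS[int(rng.integers(len(CONTEXTS)))]
                    emit(lang, sid, "vowel", cat, None, prec, foll, rep)
        # notes
        for note in cfg.notes:
            for inten in cfg.intensities:
                if (lang, note, inten) in missing:
                    continue
                if cfg.note_cell_counts is not None:
                    total = cfg.note_cell_counts.get((lang, note, inten), 0)
                    per_subj = distribute_counts(subjects, total)
                else:
                    per_subj = {s: cfg.reps_note for s in subjects}
                for sid in subjects:
                    for rep in range(per_subj[sid]):
                        emit(lang, sid, "note", note, inten, None, None, rep)

    lengths = np.array([r["n"] for r in rows])
    meta = {
        col: np.repeat(np.array([r[col] for r in rows], dtype=object), lengths)
        for col in (
            "subject",
            "language",
            "token_kind",
            "category",
            "intensity",
            "preceding",
            "following",
        )
    }
    table = ContourTable(
        pd.DataFrame(
            {
                **meta,
                "rep_index": np.repeat([r["rep_index"] for r in rows], lengths),
                "point_index": np.concatenate([np.arange(n) for n in lengths]),
                "theta": np.concatenate([r["theta"] for r in rows]),
                "rho": np.concatenate([r["rho"] for r in rows]),
            }
        )
    )

    diff_values = _gauss(grid_full, cfg.diff_center, cfg.diff_width, cfg.diff_amplitude)
    if cfg.diff_amplitude:
        # region where the bump exceeds 10% of its peak
        half = cfg.diff_width * np.sqrt(2.0 * np.log(10.0))
        region = IntervalSet(
            (
                (
                    max(cfg.diff_center - half, lo),
                    min(cfg.diff_center + half, hi),
                ),
            )
        )
    else:
        region = IntervalSet()
    prototypes = {
        cat: _proto_eval(proto[cat], grid_full, cfg.baseline_rho)
        for cat in all_categories
    }
    truth = GroundTruth(
        grid=grid_full,
        diff_values=diff_values,
        true_region=region,
        subject_transforms=transforms,
        prototypes=prototypes,
    )
    return table, truth
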