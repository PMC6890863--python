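"""End-to-end pipeline: normalize -> fit -> diff -> variance -> plot.

Each stage writes its artifacts into the configured output directory and
registers them in a manifest (name, sha256, byte size) together with the
seed and package version, so a rerun with the same config reproduces
identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .contours import ContourTable, read_contour_table, write_contour_table
from .geometry import apply_alignment, compute_alignment
from .inference import (
    IntervalSet,
    difference_curve,
    enumerate_comparisons,
    group_average_spline,
    interval_coverage,
    significant_regions,
)
from .smoothing import ModelSpec, fit
from .synth import generate_dataset, study_mimic_config
from .variance import bin_variance_curves, fit_variance_model, variance_curves_frame

log = logging.getLogger("tonguefan")

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "normalize_table"]

_FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage {stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    out_dir: str = "tonguefan_out"
    contours_path: str | None = None       # read this CSV, or simulate when None
    simulate_scale: float = 0.25
    synth_overrides: dict = field(default_factory=dict)
    reference_subject: str | None = None   # default: first NZE subject present
    align_category: dict = field(
        default_factory=lambda: {"NZE": "FLEECE", "Tongan": "i"}
    )
    align_overrides: dict = field(default_factory=dict)  # subject -> category
    n_points: int = 100
    model_k: int = 10
    random_subject_smooths: bool = True
    ar_phi: object = "estimate"
    alpha: float = 0.05
    grid_size: int = 100
    agreement_fraction: float = 0.84
    seed: int = 1
    log_level: str = "INFO"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 0.5):
            raise ValueError("alpha must lie in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


def normalize_table(
    table: ContourTable,
    reference_subject: str,
    align_category: dict,
    align_overrides: dict | None = None,
) -> tuple[ContourTable, dict]:
    """Rotate/scale every subject's contours onto the reference subject.

    The per-subject mean contour of the language's alignment category
    (overridable per subject) provides the anchor; the reference
    subject's own mean contour is the target.  Returns the aligned table
    and the per-subject transforms.
    """
    from .contours import mean_category_contour

    align_overrides = align_overrides or {}
    contours = list(table.contours())
    by_subject: dict = {}
    for c in contours:
        by_subject.setdefault(c.subject_id, []).append(c)
    if reference_subject not in by_subject:
        raise ValueError(f"reference subject {reference_subject!r} not in table")

    def ref_contour(subject):
        group = by_subject[subject]
        lang = group[0].language
        cat = align_overrides.get(subject, align_category[lang])
        cands = [c for c in group if c.category == cat]
        if not cands:
            raise ValueError(
                f"subject {subject!r} has no contours of alignment category {cat!r}"
            )
        return mean_category_contour(cands)

    target = ref_contour(reference_subject)
    transforms = {}
    new_contours = []
    for subject, group in by_subject.items():
        tr = compute_alignment(ref_contour(subject), target, reference_subject)
        transforms[subject] = tr
        for c in group:
            pts = apply_alignment(c.points, tr)
            new_contours.append(
                type(c)(
                    subject_id=c.subject_id,
                    language=c.language,
                    token_kind=c.token_kind,
                    category=c.category,
                    rep_index=c.rep_index,
                    intensity=c.intensity,
                    preceding=c.preceding,
                    following=c.following,
                    points=pts,
                )
            )
    return ContourTable.from_contours(new_contours), transforms


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _classify_intervals(regions: IntervalSet, grid_lo: float, grid_hi: float):
    """Posterior/anterior interval columns for the difference table."""
    ivs = list(regions)
    if not ivs:
        return (None, None)
    if len(ivs) == 1:
        mid = (grid_lo + grid_hi) / 2.0
        center = (ivs[0][0] + ivs[0][1]) / 2.0
        return (ivs[0], None) if center <= mid else (None, ivs[0])
    return (ivs[0], ivs[-1])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the manifest dict.

    Stage failures raise :class:`StageError` naming the stage; stages
    that had already written files leave them flagged as partial in the
    exception message.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    artifacts: list[Path] = []
    stage = "setup"

    def write_csv(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        artifacts.append(p)
        return p

    def write_json(obj, name: str) -> Path:
        p = out / name
        p.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))
        artifacts.append(p)
        return p

    try:
        # ---- load / simulate -------------------------------------------
        stage = "load"
        if config.contours_path is not None:
            path = Path(config.contours_path)
            if not path.exists():
                raise FileNotFoundError(f"contour file not found: {path}")
            table = read_contour_table(path)
            truth = None
            out.mkdir(parents=True, exist_ok=True)
        else:
            stage = "simulate"
            synth_cfg = study_mimic_config(
                config.simulate_scale, seed=config.seed, **config.synth_overrides
            )
            table, truth = generate_dataset(synth_cfg)
            out.mkdir(parents=True, exist_ok=True)
            p = out / "contours.csv"
            write_contour_table(table, p)
            artifacts.append(p)
            truth.to_json(out / "ground_truth.json")
            artifacts.append(out / "ground_truth.json")

        # ---- normalize --------------------------------------------------
        stage = "normalize"
        ref = config.reference_subject
        if ref is None:
            subjects = sorted(table.df["subject"].unique())
            ref = subjects[0]
        aligned, transforms = normalize_table(
            table, ref, config.align_category, config.align_overrides
        )
        p = out / "normalized.csv"
        write_contour_table(aligned, p)
        artifacts.append(p)
        write_json(
            {s: {"dtheta": t.dtheta, "scale": t.scale} for s, t in transforms.items()},
            "transforms.json",
        )

        # ---- fit --------------------------------------------------------
        stage = "fit"
        frame = aligned.to_model_frame(config.n_points)
        notes = frame[frame["token_kind"] == "note"].reset_index(drop=True)
        if len(notes) == 0:
            raise ValueError("no note contours to model")
        levels = tuple(sorted(notes["language_note_intensity"].unique()))
        random_terms = (("subject", None),) if config.random_subject_smooths else ()
        spec = ModelSpec(
            response="rho",
            factor="language_note_intensity",
            factor_levels=levels,
            k=config.model_k,
            random_terms=random_terms,
            ar_phi=config.ar_phi,
        )
        note_fit = fit(spec, notes)
        write_json(
            {
                "r2_adj": note_fit.r2_adj,
                "sigma2": note_fit.sigma2,
                "ar_phi": note_fit.ar_phi,
                "edf": note_fit.edf,
                "edf_total": note_fit.edf_total,
                "n_rows": note_fit.n_rows,
                "lambdas": note_fit.lambdas.tolist(),
                "converged": note_fit.converged,
            },
            "model_summary.json",
        )

        # ---- diff -------------------------------------------------------
        stage = "diff"
        cells = notes[["language", "category", "intensity"]].drop_duplicates()
        comparisons = enumerate_comparisons(cells)
        langs = sorted(notes["language"].unique())
        diff_rows = []
        region_sets = []
        if len(langs) == 2:
            la, lb = langs
            shared = sorted(
                set(
                    map(
                        tuple,
                        cells[cells.language == la][["category", "intensity"]].values,
                    )
                )
                & set(
                    map(
                        tuple,
                        cells[cells.language == lb][["category", "intensity"]].values,
                    )
                )
            )
            for note, inten in shared:
                lev_a = f"{la}.{note}.{inten}"
                lev_b = f"{lb}.{note}.{inten}"
                curve = difference_curve(
                    note_fit, lev_a, lev_b, alpha=config.alpha, n_grid=config.grid_size
                )
                regions = significant_regions(curve, config.alpha)
                region_sets.append(regions)
                post, ant = _classify_intervals(
                    regions, curve.theta[0], curve.theta[-1]
                )
                diff_rows.append(
                    {
                        "comparison": f"{note}, {inten}",
                        "posterior_lo": round(post[0], 2) if post else "NA",
                        "posterior_hi": round(post[1], 2) if post else "NA",
                        "anterior_lo": round(ant[0], 2) if ant else "NA",
                        "anterior_hi": round(ant[1], 2) if ant else "NA",
                    }
                )
        write_csv(pd.DataFrame(diff_rows), "language_differences.csv")
        write_csv(comparisons, "note_comparisons.csv")
        if region_sets:
            min_count = max(1, math.floor(config.agreement_fraction * len(region_sets)))
            agreement = interval_coverage(region_sets, min_count)
            write_json(
                {
                    "min_count": min_count,
                    "n_comparisons": len(region_sets),
                    "intervals": [list(iv) for iv in agreement],
                },
                "agreement_region.json",
            )
        else:
            agreement = IntervalSet()

        # ---- variance ---------------------------------------------------
        stage = "variance"
        vowel_df = aligned.df[aligned.df["token_kind"] == "vowel"]
        if len(vowel_df):
            curves = bin_variance_curves(ContourTable(vowel_df.reset_index(drop=True)))
            write_csv(
                variance_curves_frame(curves)[
                    ["subject", "language", "category", "theta", "n", "var_rho"]
                ],
                "variance_curves.csv",
            )
            var_fit, var_avg = fit_variance_model(curves, factor="language")
            write_json(
                {
                    "r2_adj": var_fit.r2_adj,
                    "ar_phi": var_fit.ar_phi,
                    "n_curves": len(curves),
                    "n_rows": var_fit.n_rows,
                },
                "variance_summary.json",
            )
        else:
            var_avg = {}

        # ---- plot -------------------------------------------------------
        stage = "plot"
        if config.make_plots:
            from .plotting import plot_polar_smooths

            averages = group_average_spline(
                note_fit, notes, "language", n_points=config.grid_size
            )
            p = out / "note_averages.png"
            plot_polar_smooths(
                averages, regions=agreement, path=p, title="average note contours"
            )
            artifacts.append(p)
            if var_avg:
                p = out / "variance_averages.png"
                plot_polar_smooths(var_avg, path=p, title="variance curves")
                artifacts.append(p)

        # ---- manifest ---------------------------------------------------
        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "outputs": [
                {"name": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
                for p in artifacts
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except StageError:
        raise
    except Exception as exc:
        partial = [p.name for p in artifacts]
        if partial:
            log.error("stage %s failed; partial artifacts: %s", stage, partial)
        raise StageError(stage, exc) from exc
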