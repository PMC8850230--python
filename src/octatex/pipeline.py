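"""End-to-end orchestration: manifest -> curves -> grading -> patterns -> CFD.

A run is fully described by a :class:`RunConfig` (YAML-serialisable); given
a config, the pipeline is deterministic — all randomness lives in the
synthetic fixture generator, which is seeded.  Unreadable images are
recorded and skipped; an empty post-filter cohort is a hard error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cfd_stats, grading, image_io, patterns, texture

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    manifest: str = "manifest.csv"
    image_root: str = "."
    out_dir: str = "results"
    crop_size: int = 512
    pixel_scale_um: float = 5.0
    min_signal: int = 6
    max_lag_px: int = texture.DEFAULT_MAX_LAG_PX
    plateau_window_um: tuple[float, float] = texture.DEFAULT_PLATEAU_WINDOW_UM
    pattern_order: tuple[str, ...] = patterns.DEFAULT_ORDER
    pattern_cuts: Optional[tuple[float, ...]] = None  # None -> pooled sextiles
    ttest_method: str = "t_pooled"
    cfd_csv: Optional[str] = None
    cfd_summary_csv: Optional[str] = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("plateau_window_um", "pattern_order", "pattern_cuts"):
            if d[k] is not None:
                d[k] = list(d[k])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("plateau_window_um", "pattern_order", "pattern_cuts"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-subject results plus cohort-level summaries and provenance."""

    subjects: pd.DataFrame  # features + grading index + pattern per subject
    curves: pd.DataFrame
    explained_ratio: np.ndarray
    loadings: pd.DataFrame
    pattern_table: pd.DataFrame
    pattern_cuts: np.ndarray
    excluded: list[dict]
    provenance: dict


def _load_and_prepare(row: pd.Series, config: RunConfig) -> image_io.EnFaceImage:
    path = Path(config.image_root) / row["image_path"]
    img = image_io.load_image(
        path,
        pixel_scale_um=row["pixel_scale_um"],
        subject_id=row["subject_id"],
        eye=row["eye"],
        group=row["group"],
        layer=row["layer"],
        signal_strength=(
            None if pd.isna(row["signal_strength"]) else int(row["signal_strength"])
        ),
    )
    return image_io.crop_center(img, config.crop_size)


def compute_cohort_curves(
    manifest: pd.DataFrame, config: RunConfig
) -> tuple[list[texture.AutocorrCurve], list[dict]]:
    """Curves for every manifest row; unreadable images are skipped and
    returned in the exclusion list."""
    curves: list[texture.AutocorrCurve] = []
    excluded: list[dict] = []
    for _, row in manifest.iterrows():
        try:
            img = _load_and_prepare(row, config)
            curves.append(texture.curve_from_image(img, max_lag=config.max_lag_px))
        except (IOError, FileNotFoundError, ValueError) as exc:
            logger.error("skipping %s: %s", row["subject_id"], exc)
            excluded.append({"subject_id": row["subject_id"], "reason": str(exc)})
    return curves, excluded


def run_texture_pipeline(config: RunConfig) -> RunReport:
    """manifest -> quality filter -> curves -> features -> PCA -> patterns."""
    manifest = image_io.read_manifest(config.manifest)
    kept = image_io.filter_quality(manifest, config.min_signal)
    excluded = [
        {"subject_id": sid, "reason": "signal strength below threshold"}
        for sid in set(manifest["subject_id"]) - set(kept["subject_id"])
    ]
    if kept.empty:
        raise RuntimeError("no subjects pass the quality filter")
    curves, load_excluded = compute_cohort_curves(kept, config)
    excluded.extend(load_excluded)
    if not curves:
        raise RuntimeError("no readable images after filtering")

    result = grading.grade_cohort(curves)
    features = texture.features_to_frame(curves, config.plateau_window_um)
    graded = features.merge(
        grading.grading_to_frame(result), on=["subject_id", "group"]
    )

    cuts = (
        np.asarray(config.pattern_cuts, dtype=float)
        if config.pattern_cuts is not None
        else patterns.quantile_cuts(result.scores_pc1)
    )
    clinical = [
        "control" if g == "control" else "NA" for g in result.groups
    ]
    assignments = patterns.classify_by_thresholds(
        result.scores_pc1,
        cuts,
        order=config.pattern_order,
        subject_ids=result.row_ids,
        clinical_types=clinical,
    )
    graded = graded.merge(
        assignments[["subject_id", "pattern", "coarseness_rank", "clinical_type"]],
        on="subject_id",
    )
    return RunReport(
        subjects=graded,
        curves=texture.curves_to_frame(curves),
        explained_ratio=result.explained_ratio,
        loadings=grading.loadings_to_frame(result),
        pattern_table=patterns.pattern_frequency_table(assignments),
        pattern_cuts=cuts,
        excluded=excluded,
        provenance={
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "n_manifest": int(len(manifest)),
            "n_graded": int(len(graded)),
            "pc1_orientation": result.orientation,
        },
    )


def run_cfd_stats(config: RunConfig) -> pd.DataFrame:
    """Per-sector group t-tests from a raw CFD CSV or a summary CSV."""
    if config.cfd_csv:
        records = pd.read_csv(config.cfd_csv)
        required = {"subject_id", "group", "sector", "value"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"CFD CSV is missing columns: {sorted(missing)}")
        return cfd_stats.tests_from_records(records, method=config.ttest_method)
    if config.cfd_summary_csv:
        summary = pd.read_csv(config.cfd_summary_csv)
        return cfd_stats.tests_from_summary_frame(summary, method=config.ttest_method)
    raise ValueError("config names neither cfd_csv nor cfd_summary_csv")


def write_report(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.subjects.to_csv(out / "subjects.csv", index=False)
    report.curves.to_csv(out / "curves.csv", index=False)
    report.loadings.to_csv(out / "pca_loadings.csv", index=False)
    report.pattern_table.to_csv(out / "pattern_frequencies.csv", index=False)
    meta = dict(report.provenance)
    meta["explained_ratio"] = [float(v) for v in report.explained_ratio]
    meta["pattern_cuts"] = [float(v) for v in report.pattern_cuts]
    meta["excluded"] = report.excluded
    (out / "report.json").write_text(json.dumps(meta, indent=2))
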