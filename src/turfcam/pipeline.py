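"""Batch pipeline: read -> correct -> segment -> index -> aggregate -> stats.

`run_batch` turns a manifest of images into a tidy metric CSV; `full_sensitivity_run`
produces the study-level report set: per-variant correlation matrices,
median-shift tables with Kruskal-Wallis/Dunn flags, replicate-CV tables, and
a permutation-ANOVA effects table per metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as tstats
from .colorspace import load_image
from .corrections import ColorCorrectionModel, DistortionModel, apply_color_correction, undistort
from .indices import METRIC_COLUMNS, summarize_image
from .segmentation import DEFAULT_RULES, RoiSpec

__all__ = ["PipelineConfig", "run_batch", "full_sensitivity_run", "VARIANT_LABELS"]

logger = logging.getLogger("turfcam")

#: The eight format x correction variants of the sensitivity design.
VARIANT_LABELS = [
    "JPG", "JPG CC", "JPG LC", "JPG LC CC",
    "TIF", "TIF CC", "TIF LC", "TIF LC CC",
]

CSV_COLUMNS = ["sample_id", "replicate_id", "variant"] + METRIC_COLUMNS + ["n_mask_pixels"]


@dataclass
class PipelineConfig:
    """Batch run configuration.

    ``manifest`` is a DataFrame (or CSV path) with columns
    ``path, sample_id, replicate_id, variant``.  Correction models are
    applied per image when set: color correction always precedes lens
    correction.
    """

    manifest: object = None
    rules: dict = field(default_factory=lambda: dict(DEFAULT_RULES))
    roi_diameter_cm: float = 16.0
    roi_px_per_mm: float = 11.0
    roi_center: tuple | None = None
    color_model: ColorCorrectionModel | None = None
    distortion_model: DistortionModel | None = None
    apply_color: bool = False
    apply_lens: bool = False
    n_perm: int = 1000
    seed: int = 0
    control_variant: str = "JPG"
    alphas: tuple = (0.05, 0.01, 0.001)

    def load_manifest(self) -> pd.DataFrame:
        mf = self.manifest
        if isinstance(mf, (str, Path)):
            mf = pd.read_csv(mf)
        mf = pd.DataFrame(mf)
        required = {"path", "sample_id", "replicate_id", "variant"}
        missing = required - set(mf.columns)
        if missing:
            raise ValueError(f"manifest is missing columns: {sorted(missing)}")
        return mf


def _process_one(cfg: PipelineConfig, path: str):
    img = load_image(path)
    if cfg.apply_color and cfg.color_model is not None:
        img = apply_color_correction(img, cfg.color_model)
    if cfg.apply_lens and cfg.distortion_model is not None:
        img = undistort(img, cfg.distortion_model)
    roi = RoiSpec.from_physical(img.pixels.shape, diameter_cm=cfg.roi_diameter_cm,
                                px_per_mm=cfg.roi_px_per_mm, center=cfg.roi_center)
    return img, roi


def run_batch(config: PipelineConfig, out_csv=None, resume: bool = False) -> pd.DataFrame:
    """Process every manifest row into one MetricRecord.

    Unreadable images are logged and skipped (reported in the return frame's
    ``attrs['skipped']``); a malformed manifest is fatal.  With ``resume``
    and an existing output CSV, rows already present (by sample, replicate
    and variant) are not recomputed.
    """
    manifest = config.load_manifest()
    done = set()
    prior = None
    if resume and out_csv is not None and Path(out_csv).exists():
        prior = pd.read_csv(out_csv)
        done = set(zip(prior["sample_id"].astype(str), prior["replicate_id"].astype(str),
                       prior["variant"].astype(str)))
    rows, skipped = [], []
    for i, row in manifest.iterrows():
        key = (str(row["sample_id"]), str(row["replicate_id"]), str(row["variant"]))
        if key in done:
            continue
        try:
            img, roi = _process_one(config, row["path"])
            rec = summarize_image(img, rules=config.rules, roi=roi,
                                  sample_id=str(row["sample_id"]),
                                  replicate_id=str(row["replicate_id"]),
                                  variant=str(row["variant"]))
            d = rec.as_dict()
            if rec.n_mask_pixels == 0:
                logger.warning("row %d (%s): empty living-cover mask, indices undefined", i, row["path"])
            rows.append(d)
        except (OSError, ValueError) as exc:
            logger.error("row %d (%s): skipped (%s)", i, row["path"], exc)
            skipped.append({"row": int(i), "path": str(row["path"]), "error": str(exc)})
    out = pd.DataFrame(rows, columns=CSV_COLUMNS)
    if prior is not None and len(prior):
        out = pd.concat([prior, out], ignore_index=True)
    out = out.sort_values(["sample_id", "replicate_id", "variant"], kind="stable").reset_index(drop=True)
    out.attrs["skipped"] = skipped
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out


def full_sensitivity_run(study: pd.DataFrame, metrics, references=("VQ", "NDVI"),
                         control: str = "JPG", variant_col: str = "variant",
                         n_perm: int = 1000, seed: int = 0,
                         factors=("mowing_height", "irrigation", "date"),
                         cv_table: pd.DataFrame | None = None) -> dict:
    """Correction-sensitivity report set over a multi-variant study table.

    Returns a dict with:

    * ``correlations`` — per-variant Pearson r and R^2 of each metric against
      each reference covariate;
    * ``medians``/``median_flags``/``median_kw`` — median by variant with
      Dunn-vs-control and omnibus Kruskal-Wallis significance;
    * ``cv``/``cv_flags``/``cv_kw`` — the same layout on replicate CVs when
      ``cv_table`` is given;
    * ``effects`` — permutation-ANOVA effects table per metric (control
      variant rows only, so treatments are tested on one coherent image set).
    """
    variants = list(study[variant_col].unique())
    if control not in variants:
        raise ValueError(f"control variant {control!r} not present")

    corr_rows = []
    for v in variants:
        sub = study[study[variant_col] == v]
        for m in metrics:
            for ref in references:
                if ref not in sub.columns:
                    continue
                r, r2 = tstats.pearson(sub[m], sub[ref])
                corr_rows.append({"variant": v, "metric": m, "reference": ref, "r": r, "r_squared": r2})
    correlations = pd.DataFrame(corr_rows)

    medians, flags, kw = tstats.sensitivity_report(study, metrics, control=control,
                                                   variant_col=variant_col)
    out = {
        "correlations": correlations,
        "medians": medians,
        "median_flags": flags,
        "median_kw": kw,
    }
    if cv_table is not None:
        cv_med, cv_flags, cv_kw = tstats.sensitivity_report(cv_table, metrics, control=control,
                                                            variant_col=variant_col)
        out.update({"cv": cv_med, "cv_flags": cv_flags, "cv_kw": cv_kw})

    effects = {}
    control_set = study[study[variant_col] == control]
    rng = np.random.default_rng(seed)
    for m in metrics:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            res = tstats.perm_anova(control_set, m, n_perm=n_perm, seed=sub_seed, factors=factors)
            effects[m] = res.effects
        except ValueError as exc:
            logger.warning("permutation ANOVA skipped for %s: %s", m, exc)
    out["effects"] = effects
    return out
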