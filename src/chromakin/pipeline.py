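"""End-to-end orchestration: extract -> series -> fit -> predict.

Each stage writes its outputs atomically (temp file + rename) so a failure
in a later stage leaves earlier results intact, and every output row keys
back to manifest rows via (treatment, day, replicate).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .features import ATTRIBUTES, build_time_series, series_from_frame, ColorTimeSeries
from .imaging import ColorMeasurement, load_image, median_filter, segment_roi, summarize_roi
from .kinetics import (
    InsufficientDataError,
    KineticResults,
    fit_first_order,
    fit_fofc,
    fit_zero_order,
    select_model,
)
from .shelf_life import psl_table

log = logging.getLogger("chromakin")

__all__ = ["RunConfig", "run_pipeline", "extract_measurements", "fit_all", "PipelineError"]

#: attributes used for shelf-life prediction unless configured otherwise
DEFAULT_PSL_ATTRIBUTES = ("L", "dE")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the offending record."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    manifest: str
    out_dir: str
    illuminant: str = "D65"
    roi_mode: str = "auto"
    roi_rect: tuple[int, int, int, int] | None = None
    roi_erosion: int = 3
    median_kernel: int = 3
    fit_method: str = "nonlinear"
    cinf_mode: str | float = "fit"
    thresholds: Mapping[str, object] = field(
        default_factory=lambda: {"L": {"fraction_of_C0": 0.8}, "dE": 30.0}
    )
    attributes: tuple[str, ...] = ATTRIBUTES
    psl_attributes: tuple[str, ...] = DEFAULT_PSL_ATTRIBUTES
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sig6(x):
    """Round floats to 6 significant digits for byte-stable diffable output."""
    if isinstance(x, float):
        if not math.isfinite(x):
            return x
        return float(f"{x:.6g}")
    return x


def _atomic_write_df(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False, float_format="%.6g", lineterminator="\r\n")
    os.replace(tmp, path)


def _atomic_write_json(obj, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
    os.replace(tmp, path)


def extract_measurements(config: RunConfig) -> pd.DataFrame:
    """Stage 1: one ColorMeasurement row per manifest image."""
    manifest_path = Path(config.manifest)
    if not manifest_path.exists():
        raise PipelineError(f"extract: manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {"path", "treatment", "day", "replicate"}
    if not required.issubset(manifest.columns):
        raise PipelineError(
            f"extract: manifest must have columns {sorted(required)}, "
            f"got {list(manifest.columns)}"
        )
    base = manifest_path.parent
    rows = []
    for rec in manifest.itertuples(index=False):
        img_path = Path(rec.path)
        if not img_path.is_absolute():
            img_path = base / img_path
        try:
            img = load_image(img_path)
            img = median_filter(img, config.median_kernel)
            mask = segment_roi(
                img,
                mode=config.roi_mode,  # type: ignore[arg-type]
                rect=config.roi_rect,
                erosion=config.roi_erosion,
            )
            m = summarize_roi(
                img,
                mask,
                day=int(rec.day),
                treatment=str(rec.treatment),
                replicate=int(rec.replicate),
                illuminant=config.illuminant,  # type: ignore[arg-type]
            )
        except (OSError, ValueError) as exc:
            raise PipelineError(f"extract: failed on {rec.path!r}: {exc}") from exc
        rows.append(asdict(m))
    return pd.DataFrame(rows)


def _measurements_from_frame(df: pd.DataFrame) -> list[ColorMeasurement]:
    return [
        ColorMeasurement(
            L_mean=float(r.L_mean),
            a_mean=float(r.a_mean),
            b_mean=float(r.b_mean),
            L_sd=float(r.L_sd),
            a_sd=float(r.a_sd),
            b_sd=float(r.b_sd),
            day=int(r.day),
            treatment=str(r.treatment),
            replicate=int(r.replicate),
            n_pixels=int(r.n_pixels),
        )
        for r in df.itertuples(index=False)
    ]


def build_all_series(measurements: pd.DataFrame, attributes=ATTRIBUTES) -> pd.DataFrame:
    """Stage 2: tidy long-format series table across treatments/attributes."""
    frames = []
    for treatment, grp in measurements.groupby("treatment", sort=True):
        ms = _measurements_from_frame(grp)
        for attr in attributes:
            try:
                frames.append(build_time_series(ms, attr).to_frame())
            except ValueError as exc:
                raise PipelineError(
                    f"series: treatment {treatment!r}, attribute {attr!r}: {exc}"
                ) from exc
    return pd.concat(frames, ignore_index=True)


def fit_all(
    series_df: pd.DataFrame,
    *,
    method: str = "nonlinear",
    cinf_mode: str | float = "fit",
) -> list[KineticResults]:
    """Stage 3: zero/first/FOFC fits for every (treatment, attribute) series."""
    fits: list[KineticResults] = []
    for series in series_from_frame(series_df):
        candidates = []
        for fitter in (
            lambda s: fit_zero_order(s),
            lambda s: fit_first_order(s, method=method),
            lambda s: fit_fofc(s, cinf=cinf_mode),
        ):
            try:
                candidates.append(fitter(series))
            except (InsufficientDataError, ValueError) as exc:
                log.debug(
                    "fit skipped for %s/%s: %s", series.treatment, series.attribute, exc
                )
        if not candidates:
            raise PipelineError(
                f"fit: no kinetic model could be fitted for "
                f"{series.treatment!r}/{series.attribute!r}"
            )
        fits.extend(select_model(candidates) if len(candidates) > 1 else candidates)
    return fits


def fits_to_table1(fits: list[KineticResults]) -> pd.DataFrame:
    """Wide goodness-of-fit summary: one row per treatment x attribute."""
    rows: dict[tuple[str, str], dict] = {}
    for f in fits:
        key = (f.treatment or "", f.attribute or "")
        row = rows.setdefault(key, {"treatment": key[0], "attribute": key[1]})
        row[f"{f.model}_R2"] = _sig6(f.rsquared)
        row[f"{f.model}_K"] = _sig6(f.k)
        row[f"{f.model}_RMSE"] = _sig6(f.rmse)
    return pd.DataFrame(sorted(rows.values(), key=lambda r: (r["treatment"], r["attribute"])))


def run_pipeline(config: RunConfig) -> dict:
    """Execute extract -> series -> fit -> predict and write all outputs.

    Returns the run report (also written as ``run_report.json``).
    """
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_digest": config.digest(), "seed": config.seed, "stages": {}}

    t0 = time.perf_counter()
    measurements = extract_measurements(config)
    _atomic_write_df(measurements, out / "measurements.csv")
    report["stages"]["extract"] = {
        "n_images": int(len(measurements)),
        "seconds": round(time.perf_counter() - t0, 3),
    }
    log.info("extract: %d images in %.2fs", len(measurements), time.perf_counter() - t0)

    t0 = time.perf_counter()
    series_df = build_all_series(measurements, config.attributes)
    _atomic_write_df(series_df, out / "series.csv")
    report["stages"]["series"] = {
        "n_series": int(series_df.groupby(["treatment", "attribute"]).ngroups),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = time.perf_counter()
    fits = fit_all(series_df, method=config.fit_method, cinf_mode=config.cinf_mode)
    fits_json = [{k: _sig6(v) for k, v in f.to_dict().items()} for f in fits]
    _atomic_write_json(fits_json, out / "fits.json")
    _atomic_write_df(fits_to_table1(fits), out / "kinetics_summary.csv")
    report["stages"]["fit"] = {
        "n_fits": len(fits),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = time.perf_counter()
    psl_fits = [f for f in fits if f.attribute in config.psl_attributes and not f.degenerate]
    missing = set(config.psl_attributes) - {f.attribute for f in psl_fits}
    if missing:
        raise PipelineError(f"predict: no fits available for attributes {sorted(missing)}")
    table2 = psl_table(psl_fits, config.thresholds)
    table2 = table2.assign(**{c: table2[c].map(_sig6) for c in ("threshold", "C0_used", "k_used", "psl_days")})
    _atomic_write_df(table2, out / "shelf_life.csv")
    report["stages"]["predict"] = {
        "n_predictions": int(len(table2)),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    report["versions"] = {"chromakin": __version__, "numpy": np.__version__, "pandas": pd.__version__}
    _atomic_write_json(report, out / "run_report.json")
    return report
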