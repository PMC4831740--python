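"""End-to-end pipeline: cohort in, profiles/fits/areas/stats out.

Binds the stages together the way a staining study is analysed: read the
slice series, extract and cohort-normalise line profiles, detect sample
edges and stain fronts per day, build depth series and fit the kinetics
models, measure shrinkage, and run the day × stain statistics.  Samples
whose detection fails at some stage propagate as flagged-missing values
rather than crashes, so one bad scan never sinks the cohort.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

from . import kinetics, morphometry, profiles, stats
from .config import PipelineConfig
from .errors import CTStainError, DetectionError, FitError, ValidationError
from .phantom import load_manifest

__all__ = ["PipelineResult", "read_slice_image", "load_cohort", "run_pipeline",
           "predict_report"]

log = logging.getLogger("ctstain")


def read_slice_image(path, pixel_size_mm, sample_id="", stain="other", day=0
                     ) -> profiles.SliceImage:
    """Read a TIFF/PNG slice into a normalised-to-[0,1] SliceImage."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            px = tifffile.imread(path)
        else:
            px = iio.imread(path)
    except OSError as exc:
        raise OSError(f"cannot read slice {path}: {exc}") from exc
    px = np.asarray(px, dtype=float)
    if px.ndim == 3:  # collapse RGB(A) to grayscale
        px = px[..., :3].mean(axis=-1)
    if px.max() > 1.0:
        px = px / (65535.0 if px.max() > 255 else 255.0)
    return profiles.SliceImage(
        pixels=px, pixel_size_mm=pixel_size_mm,
        sample_id=sample_id, stain=stain, day=day,
    )


def load_cohort(manifest_path) -> list[tuple[profiles.SliceImage, dict]]:
    """Read every slice referenced by a cohort manifest."""
    manifest_path = Path(manifest_path)
    records = load_manifest(manifest_path)
    out = []
    for rec in records:
        sl = read_slice_image(
            manifest_path.parent / rec["file"],
            pixel_size_mm=rec["pixel_size_mm"],
            sample_id=rec["sample_id"],
            stain=rec["stain"],
            day=rec["day_index"],
        )
        out.append((sl, rec))
    return out


@dataclass
class PipelineResult:
    """Paths of everything the pipeline wrote, plus in-memory tables."""

    output_dir: Path
    files: dict[str, Path] = field(default_factory=dict)
    front_table: pd.DataFrame | None = None
    depth_series: pd.DataFrame | None = None
    area_table: pd.DataFrame | None = None
    stain_time_models: dict = field(default_factory=dict)
    front_models: dict = field(default_factory=dict)
    bulk_fits: dict = field(default_factory=dict)


def _fit_to_record(fit) -> dict:
    rec = asdict(fit)
    rec["model"] = type(fit).__name__
    return rec


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on the cohort described by ``config.manifest``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logfile = out / "pipeline_log.txt"
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    result = PipelineResult(output_dir=out)
    try:
        _run(config, out, result)
    finally:
        log.removeHandler(handler)
        handler.close()
    result.files["log"] = logfile
    return result


def _run(config: PipelineConfig, out: Path, result: PipelineResult) -> None:
    cohort = load_cohort(config.manifest)
    log.info("loaded %d slices from %s", len(cohort), config.manifest)

    # --- profiles, cohort-wide normalisation -----------------------------
    raw = [profiles.extract_line_profile(sl, width_px=config.width_px)
           for sl, _ in cohort]
    if config.normalisation == "cohort":
        norm = profiles.normalise_cohort(raw)
    else:
        norm = []
        for stain_name in sorted({p.stain for p in raw}):
            group = [p for p in raw if p.stain == stain_name]
            norm.extend(profiles.normalise_cohort(group))
    prof_rows = [
        pd.DataFrame({
            "sample_id": p.sample_id, "stain": p.stain, "day": p.day,
            "position_mm": p.positions_mm, "intensity": p.values,
        })
        for p in norm
    ]
    prof_df = pd.concat(prof_rows, ignore_index=True)
    result.files["profiles"] = out / "profiles.csv"
    prof_df.to_csv(result.files["profiles"], index=False)

    by_sample: dict[str, dict[int, profiles.LineProfile]] = {}
    for p in norm:
        by_sample.setdefault(p.sample_id, {})[p.day] = p

    # --- edges and stain fronts -----------------------------------------
    front_rows, depth_frames = [], []
    for sid, by_day in sorted(by_sample.items()):
        edges_by_day = {}
        for day, p in sorted(by_day.items()):
            try:
                e = profiles.detect_sample_edges(
                    p, zero_tol=config.zero_tol, sigma_px=config.sigma_px
                )
                edges_by_day[day] = e
                log.info("edges %s day %d: left=%.3f right=%.3f mm",
                         sid, day, e.left_mm, e.right_mm)
            except (DetectionError, ValidationError) as exc:
                log.warning("edge detection failed for %s day %d: %s", sid, day, exc)
                continue
            for side in ("left", "right"):
                fl = profiles.detect_stain_front(
                    p, e, side=side, drop_tol=config.drop_tol,
                    zero_tol=config.zero_tol, sigma_px=config.sigma_px,
                )
                front_rows.append({
                    "sample_id": sid, "stain": p.stain, "day": day,
                    "side": side, "found": fl.found, "capped": fl.capped,
                    "depth_mm": fl.depth_mm,
                })
                log.info("front %s day %d %s: found=%s depth=%.3f",
                         sid, day, side, fl.found, fl.depth_mm)
        if len(edges_by_day) >= 2:
            ds = profiles.to_depth_series(
                {d: by_day[d] for d in edges_by_day}, edges_by_day,
                increment_mm=config.increment_mm,
                max_depth_mm=config.max_depth_mm,
                window_mm=config.window_mm,
            )
            depth_frames.append(ds)
        else:
            log.warning("sample %s has < 2 days with edges; no depth series", sid)

    front_df = pd.DataFrame(front_rows)
    result.front_table = front_df
    result.files["front_table"] = out / "front_table.csv"
    front_df.to_csv(result.files["front_table"], index=False)

    depth_df = (pd.concat(depth_frames, ignore_index=True)
                if depth_frames else pd.DataFrame())
    result.depth_series = depth_df
    result.files["depth_series"] = out / "depth_series.csv"
    depth_df.to_csv(result.files["depth_series"], index=False)

    # --- saturation kinetics per stain ----------------------------------
    bulk_fits, stain_time_models = {}, {}
    time_rows = []
    if not depth_df.empty:
        stain_mean = (
            depth_df.groupby(["stain", "day", "depth_mm"], as_index=False)["intensity"]
            .mean()
        )
        for stain_name, sub in stain_mean.groupby("stain"):
            # bulk fit at the reference depth (study convention: 1 mm in)
            ref = sub[np.isclose(sub["depth_mm"], config.reference_depth_mm)]
            ref = ref.dropna(subset=["intensity"])
            if len(ref) >= 3:
                try:
                    bulk_fits[stain_name] = kinetics.fit_saturation(
                        ref["day"].to_numpy(float), ref["intensity"].to_numpy(float),
                        depth_mm=config.reference_depth_mm, stain=stain_name,
                    )
                except FitError as exc:
                    log.warning("bulk fit failed for %s: %s", stain_name, exc)
            # per-depth fits -> saturation times -> staining-time model
            try:
                depth_fits = kinetics.fit_depth_profile(sub)
            except FitError as exc:
                log.warning("depth-profile fit failed for %s: %s", stain_name, exc)
                continue
            for f in config.saturation_levels:
                d_ok, t_ok = [], []
                for depth, fit in sorted(depth_fits.items()):
                    try:
                        # targets below I0 return 0 with a warning; skipped below
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", UserWarning)
                            t = kinetics.saturation_time(fit, f)
                    except ValidationError:
                        continue
                    if t > 0:
                        d_ok.append(depth)
                        t_ok.append(t)
                        time_rows.append({"stain": stain_name, "depth_mm": depth,
                                          "level": f, "t_days": t})
                if len(d_ok) >= 3:
                    try:
                        stain_time_models.setdefault(stain_name, {})[f] = (
                            kinetics.fit_staining_time_model(d_ok, t_ok, f)
                        )
                    except (FitError, ValidationError) as exc:
                        log.warning("staining-time fit failed (%s, f=%.2f): %s",
                                    stain_name, f, exc)
    result.bulk_fits = bulk_fits
    result.stain_time_models = stain_time_models
    times_df = pd.DataFrame(time_rows)
    if not times_df.empty:
        times_df = times_df.pivot_table(
            index=["stain", "depth_mm"], columns="level", values="t_days"
        ).reset_index()
        times_df.columns = [
            c if isinstance(c, str) else f"t{int(round(c * 100))}"
            for c in times_df.columns
        ]
    result.files["staining_times"] = out / "staining_times.csv"
    times_df.to_csv(result.files["staining_times"], index=False)

    # --- front-propagation models per stain ------------------------------
    front_models = {}
    if not front_df.empty:
        per_day = (
            front_df[front_df["found"]]
            .groupby(["stain", "day"], as_index=False)["depth_mm"].mean()
        )
        for stain_name, sub in per_day.groupby("stain"):
            if sub["day"].nunique() < 3:
                log.info("stain %s: fronts on < 3 days; no front model", stain_name)
                continue
            try:
                front_models[stain_name] = kinetics.fit_front_model(
                    sub["day"].to_numpy(float), sub["depth_mm"].to_numpy(float),
                    stain=stain_name,
                )
            except FitError as exc:
                log.warning("front model failed for %s: %s", stain_name, exc)
    result.front_models = front_models

    fits_json = {
        "saturation_bulk": {s: _fit_to_record(f) for s, f in bulk_fits.items()},
        "staining_time": {
            s: {f"{lvl:.2f}": _fit_to_record(m) for lvl, m in per.items()}
            for s, per in stain_time_models.items()
        },
        "front": {s: _fit_to_record(m) for s, m in front_models.items()},
        "max_penetration_depth_mm": {
            s: kinetics.max_penetration_depth(m) for s, m in front_models.items()
        },
    }
    result.files["fits"] = out / "fits.json"
    result.files["fits"].write_text(json.dumps(fits_json, indent=2))

    # --- shrinkage morphometry -------------------------------------------
    slices_by_sample: dict[str, list[profiles.SliceImage]] = {}
    for sl, _ in cohort:
        slices_by_sample.setdefault(sl.sample_id, []).append(sl)
    area_frames = []
    for sid, sls in sorted(slices_by_sample.items()):
        try:
            series = morphometry.measure_area_series(
                sls, method=config.area_method, threshold=config.area_threshold
            )
        except CTStainError as exc:
            log.warning("area measurement failed for %s: %s", sid, exc)
            continue
        t = series.table.copy()
        t.insert(0, "sample_id", sid)
        t.insert(1, "stain", series.stain)
        area_frames.append(t)
    area_df = (pd.concat(area_frames, ignore_index=True)
               if area_frames else pd.DataFrame())
    result.area_table = area_df
    result.files["areas"] = out / "areas.csv"
    area_df.to_csv(result.files["areas"], index=False)

    # --- day x stain statistics ------------------------------------------
    stats_out = {}
    if not depth_df.empty:
        ref = depth_df[np.isclose(depth_df["depth_mm"], config.reference_depth_mm)]
        ref = ref.dropna(subset=["intensity"])
        stats_out["intensity"] = _factor_stats(
            ref, "intensity", out / "stats_intensity", result.files)
    if not area_df.empty:
        stats_out["area"] = _factor_stats(
            area_df, "normalized_area", out / "stats_area", result.files)
    log.info("pipeline complete: %s", ", ".join(sorted(result.files)))


def _factor_stats(df: pd.DataFrame, value_col: str, stem: Path, files: dict):
    """ANOVA (day x stain) + Tukey over stains, written as CSVs."""
    res = {}
    if df["day"].nunique() >= 2 and df["stain"].nunique() >= 2:
        try:
            anova = stats.two_way_anova(df[value_col], df["day"], df["stain"])
            path = stem.with_name(stem.name + "_anova.csv")
            anova.table.to_csv(path)
            files[path.stem] = path
            res["anova"] = anova
        except ValidationError as exc:
            log.warning("ANOVA skipped for %s: %s", value_col, exc)
    try:
        tukey = stats.tukey_hsd(df[value_col], df["stain"])
        path = stem.with_name(stem.name + "_tukey.csv")
        tukey.to_csv(path, index=False)
        files[path.stem] = path
        res["tukey"] = tukey
    except ValidationError as exc:
        log.warning("Tukey skipped for %s: %s", value_col, exc)
    return res


def predict_report(fits_json_path, depth_mm: float | None = None,
                   radius_mm: float | None = None) -> dict:
    """Staining-time predictions and feasibility verdicts from saved fits.

    For each saturation-level model, the predicted time at ``depth_mm``;
    for each front model, whether a sample of ``radius_mm`` can ever be
    stained through (radius vs the asymptotic penetration depth C).
    """
    if depth_mm is not None and depth_mm < 0:
        raise ValidationError("depth_mm must be non-negative")
    if radius_mm is not None and radius_mm < 0:
        raise ValidationError("radius_mm must be non-negative")
    fits = json.loads(Path(fits_json_path).read_text())
    report: dict = {"staining_times": {}, "feasibility": {}}
    if depth_mm is not None:
        for stain_name, per_level in fits.get("staining_time", {}).items():
            report["staining_times"][stain_name] = {
                lvl: rec["A"] * np.exp(rec["c"] * depth_mm)
                for lvl, rec in per_level.items()
            }
    if radius_mm is not None:
        for stain_name, rec in fits.get("front", {}).items():
            c = rec["C"]
            report["feasibility"][stain_name] = {
                "max_penetration_depth_mm": c,
                "radius_mm": radius_mm,
                "feasible": radius_mm <= c,
            }
    return report
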