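"""Single-entry pipeline: generate/ingest -> preprocess -> features ->
stats -> reduction -> selection, with structured CSV/JSON outputs.

Two analysis arms mirror the study design: "ffpe" uses the 48 FFPE samples
with all five channels; "combined" uses all 62 samples with four channels
(NADH excluded, since it cannot be acquired for fixed-frozen samples).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import assemble_sample, brightness_to_frame, channel_brightness
from .selection import (SubsetSearchConfig, correlation_filter,
                        mean_abs_correlation, repeated_selection)
from .stats import brightness_comparison, feature_significance, results_to_frame
from .synthetic import (CHANNELS, FROZEN_CHANNELS, CohortDesign, PhantomParams,
                        generate_cohort, load_config, make_vignette, save_config,
                        write_cohort)
from .texture import FeatureTable, build_feature_table

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "read_feature_table",
    "write_feature_table",
]

log = logging.getLogger("mpmtex")

STAGES = ("generate", "preprocess", "features", "stats", "select")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a pipeline run."""

    design: CohortDesign = field(default_factory=CohortDesign)
    params: PhantomParams = field(default_factory=PhantomParams)
    arm: str = "combined"            # "ffpe" | "combined"
    gray_levels: int = 64
    corr_threshold: float = 0.45
    max_features: int | None = None  # cap retained features for scaled runs
    n_max: int | None = None         # default: 5 for ffpe, 6 for combined
    runs: int = 100
    seed: int = 0
    out_dir: str = "mpmtex_out"
    log_level: str = "INFO"
    write_tiles: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ("ffpe", "combined"):
            raise ValueError(f"unknown arm {self.arm!r}")

    @property
    def channels(self) -> tuple[str, ...]:
        # The combined arm must never include NADH.
        return CHANNELS if self.arm == "ffpe" else FROZEN_CHANNELS

    @property
    def effective_n_max(self) -> int:
        if self.n_max is not None:
            return self.n_max
        return 5 if self.arm == "ffpe" else 6


def _stage(name: str, timings: dict, fn, *args, **kwargs):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        log.error("stage %s: failed: %s", name, exc)
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    timings[name] = time.perf_counter() - t0
    log.info("stage %s: done in %.2fs", name, timings[name])
    return result


def run_pipeline(config: PipelineConfig, until: str = "select") -> dict:
    """Execute the pipeline through stage ``until``; return a report bundle.

    Writes all CSV outputs plus ``manifest.json`` (config echo, seed,
    versions, per-stage timings, output paths) under ``config.out_dir``.
    Deterministic: identical config and seed give byte-identical outputs.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    os.makedirs(config.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.out_dir, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)

    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    bundle: dict = {"config": config}
    try:
        # --- generate ---------------------------------------------------
        def _generate():
            design = (config.design.restricted("FFPE")
                      if config.arm == "ffpe" else config.design)
            cohort = generate_cohort(design, config.params, seed=config.seed)
            if config.write_tiles:
                outputs["cohort_manifest"] = write_cohort(
                    cohort, os.path.join(config.out_dir, "cohort"))
            save_config(design, config.params,
                        os.path.join(config.out_dir, "phantom_config.yaml"))
            outputs["phantom_config"] = os.path.join(config.out_dir,
                                                     "phantom_config.yaml")
            return cohort

        cohort = _stage("generate", timings, _generate)
        bundle["cohort"] = cohort
        if until == "generate":
            return _finalize(config, bundle, timings, outputs)

        # --- preprocess -------------------------------------------------
        def _preprocess():
            flat = None
            if config.params.vignette_strength > 0:
                flat = make_vignette(config.design.grid.tile_size,
                                     config.params.vignette_strength)
            records = []
            for sample in cohort:
                assemble_sample(sample, flat=flat)
                records.append(channel_brightness(sample))
            frame = brightness_to_frame(records)
            path = os.path.join(config.out_dir, "brightness.csv")
            frame.to_csv(path, index=False)
            outputs["brightness"] = path
            return records

        brightness = _stage("preprocess", timings, _preprocess)
        bundle["brightness"] = brightness
        if until == "preprocess":
            return _finalize(config, bundle, timings, outputs)

        # --- features ---------------------------------------------------
        def _features():
            table = build_feature_table(cohort, config.channels,
                                        levels=config.gray_levels)
            path = os.path.join(config.out_dir, "features.csv")
            write_feature_table(table, path)
            outputs["features"] = path
            return table

        table = _stage("features", timings, _features)
        bundle["features"] = table
        if until == "features":
            return _finalize(config, bundle, timings, outputs)

        # --- stats (brightness comparisons + reduction + screening) -----
        def _stats():
            comparisons = []
            comparisons.extend(brightness_comparison(brightness, "class"))
            for cls in ("tumor", "normal"):
                sizes = {p: sum(1 for s in cohort
                                if s.label == cls and s.preparation == p)
                         for p in ("FFPE", "frozen")}
                if min(sizes.values()) < 3:
                    continue  # a preparation group too small to compare
                for r in brightness_comparison(brightness, f"preparation:{cls}"):
                    comparisons.append(dataclasses.replace(
                        r, name=f"{cls}:{r.name}"))
            path = os.path.join(config.out_dir, "brightness_stats.csv")
            results_to_frame(comparisons).to_csv(path, index=False)
            outputs["brightness_stats"] = path

            reduced = correlation_filter(table, config.corr_threshold,
                                         max_features=config.max_features)
            scores = mean_abs_correlation(table)
            rf = pd.DataFrame({
                "feature": reduced.feature_names,
                "mean_abs_correlation": [scores[f] for f in reduced.feature_names],
            })
            path = os.path.join(config.out_dir, "retained_features.csv")
            rf.to_csv(path, index=False)
            outputs["retained_features"] = path

            z = (reduced.features - reduced.features.mean()) / reduced.features.std(ddof=0)
            zt = FeatureTable(reduced.sample_ids, reduced.labels,
                              reduced.preparations, z)
            path = os.path.join(config.out_dir, "zscored_features.csv")
            write_feature_table(zt, path)
            outputs["zscored_features"] = path

            sig = feature_significance(reduced)
            path = os.path.join(config.out_dir, "significance.csv")
            results_to_frame(sig).to_csv(path, index=False)
            outputs["significance"] = path
            return reduced, sig

        reduced, significance = _stage("stats", timings, _stats)
        bundle["reduced"] = reduced
        bundle["significance"] = significance
        if until == "stats":
            return _finalize(config, bundle, timings, outputs)

        # --- select -----------------------------------------------------
        def _select():
            search = SubsetSearchConfig(
                n_max=min(config.effective_n_max, reduced.width),
                runs=config.runs,
                corr_threshold=config.corr_threshold,
                seed=config.seed,
            )
            summary = repeated_selection(reduced, search)
            for path in summary.to_csvs(config.out_dir):
                outputs[os.path.splitext(os.path.basename(path))[0]] = path
            return summary

        bundle["summary"] = _stage("select", timings, _select)
        return _finalize(config, bundle, timings, outputs)
    finally:
        log.removeHandler(handler)
        handler.close()


def _finalize(config: PipelineConfig, bundle: dict, timings: dict,
              outputs: dict) -> dict:
    import scipy
    import sklearn
    import skimage

    for name, path in outputs.items():
        if not (os.path.exists(path) and os.path.getsize(path) > 0):
            raise PipelineError(f"declared output {name!r} missing or empty: {path}")
    manifest = {
        "seed": config.seed,
        "arm": config.arm,
        "gray_levels": config.gray_levels,
        "corr_threshold": config.corr_threshold,
        "max_features": config.max_features,
        "n_max": config.effective_n_max,
        "runs": config.runs,
        "versions": {
            "mpmtex": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
        },
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "outputs": outputs,
    }
    path = os.path.join(config.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    bundle["outputs"] = outputs
    return bundle


# ---------------------------------------------------------------------------
# Feature table round trip
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str) -> None:
    """CSV with columns sample_id,label,preparation then the features.

    Values are serialized at full precision so write-then-read is the
    identity on tables.
    """
    frame = table.to_frame()
    frame.to_csv(path, index=False,
                 float_format=lambda v: np.format_float_scientific(v, unique=True))


def read_feature_table(path: str) -> FeatureTable:
    """Inverse of :func:`write_feature_table`, with validation."""
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("sample_id", "label", "preparation"):
        if col not in frame.columns:
            raise ValueError(f"feature table CSV is missing the {col!r} column")
    ids = frame["sample_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in feature table CSV")
    feats = frame.drop(columns=["sample_id", "label", "preparation"])
    bad = [c for c in feats.columns
           if not np.issubdtype(feats[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric feature column(s): {bad}")
    return FeatureTable(ids, frame["label"].tolist(),
                        frame["preparation"].tolist(), feats)


def load_pipeline_config(path: str, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a phantom YAML plus keyword overrides."""
    design, params = load_config(path)
    return PipelineConfig(design=design, params=params, **overrides)
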