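"""End-to-end study orchestration with manifests and deterministic reruns.

A study run generates one phantom section per developmental stage,
applies background equalization and leakage subtraction to its factor
channels, measures threshold bands, hotmaps and expression domains in
the standard ROIs, converts to optical density for plot profiles,
performs co-localization analysis, and compares expression-domain
fractions across (stage, ROI) groups with the rank tests.  Every
artifact is written under the output directory and check-summed into a
run manifest; all randomness flows from the single root seed, split per
stage with numpy's SeedSequence spawning.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import __version__
from .banding import (
    ROIMask,
    ThresholdSet,
    band_images,
    compose_hotmap,
    domain_size,
    measurements_to_frame,
    sample_unit_bands,
)
from .banding import DomainMeasurement
from .coloc import intensity_correlation, serial_coloc
from .densitometry import (
    build_calibration,
    plot_profile,
    read_calibration_csv,
    synthetic_step_tablet,
    to_od,
)
from .image import GrayImage8, imwrite_gray8
from .phantom import (
    Phantom,
    PhantomSpec,
    generate_phantom,
    negative_marker_points,
    save_phantom,
)
from .preprocess import dark_point_adjust, leakage_subtract
from .stats import compare_domains

STUDY_STAGES = ("late_bud", "cap", "early_bell_cl", "early_bell_iee")
_STAGE_TO_PHANTOM = {
    "late_bud": "bud",
    "cap": "cap",
    "early_bell_cl": "bell_cl",
    "early_bell_iee": "bell_iee",
}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one end-to-end run."""

    out_dir: str
    factors: tuple[str, ...] = ("green", "red")
    stages: tuple[str, ...] = STUDY_STAGES
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    sample_unit_low: int = 15
    sample_unit_high: int = 95
    sample_unit_step: int = 5
    baseline_target: int = 15
    calibration_csv: Optional[str] = None
    seed: int = 0
    width: int = 256
    height: int = 192
    background_level: float = 25.0
    background_noise_sd: float = 3.0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in raw:
            raw["thresholds"] = ThresholdSet(tuple(raw["thresholds"]))
        for key in ("factors", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "out_dir", "factors", "stages", "sample_unit_low", "sample_unit_high",
                "sample_unit_step", "baseline_target", "calibration_csv", "seed",
                "width", "height", "background_level", "background_noise_sd",
            )
        }
        d["thresholds"] = list(self.thresholds.levels)
        d["factors"] = list(self.factors)
        d["stages"] = list(self.stages)
        return d


@dataclass(frozen=True)
class RunManifest:
    """Audit record: config hash, per-artifact checksums, seed registry."""

    config_hash: str
    outputs: dict[str, str]  # relative path -> sha256
    stage_seeds: dict[str, int]
    versions: dict[str, str]
    timestamp: str

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=2, sort_keys=True))


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def validate_config(config: StudyConfig) -> None:
    """Pre-flight validation, before any computation."""
    for stage in config.stages:
        if stage not in STUDY_STAGES:
            raise ValueError(f"unknown stage label {stage!r}; expected one of {STUDY_STAGES}")
    if not config.stages:
        raise ValueError("config.stages must be non-empty")
    for factor in config.factors:
        if factor not in ("green", "red"):
            raise ValueError(f"unknown factor channel {factor!r}")
    if not config.factors:
        raise ValueError("config.factors must be non-empty")
    if config.calibration_csv is not None and not Path(config.calibration_csv).exists():
        raise ValueError(f"calibration file not found: {config.calibration_csv}")


def stage_seeds(root_seed: int, stages: Sequence[str]) -> dict[str, int]:
    """Split the root seed into one integer seed per stage (SeedSequence
    spawning, reduced modulo 2**31)."""
    children = np.random.SeedSequence(root_seed).spawn(len(stages))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(stages, children)
    }


def roi_masks(phantom: Phantom) -> list[ROIMask]:
    """Standard analysis ROIs derived from phantom ground truth: the whole
    tooth germ, the cervical loop, and the inner enamel epithelium with
    its surrounding mesenchymal fringe.  Empty regions (e.g. no loops at
    the bud stage) are omitted."""
    masks = phantom.compartment_masks
    out = [ROIMask(phantom.tissue_mask, "whole_tooth_germ")]
    if masks["cervical_loop"].any():
        out.append(ROIMask(masks["cervical_loop"], "cervical_loop"))
    if masks["iee"].any():
        fringe = ndimage.binary_dilation(masks["iee"], iterations=3) & (
            masks["iee"] | masks["mesenchyme"]
        )
        out.append(ROIMask(fringe, "iee"))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig) -> RunManifest:
    """Execute the full pipeline for every configured stage.

    Writes phantoms, corrected channels, hotmaps, domain and sample-unit
    tables, OD profiles, co-localization JSON and the rank-test report
    under ``config.out_dir``, then a ``manifest.json`` with checksums.
    Any stage failure aborts with the failing stage named.
    """
    validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed, config.stages)

    if config.calibration_csv is not None:
        curve = build_calibration(read_calibration_csv(config.calibration_csv))
    else:
        curve = build_calibration(synthetic_step_tablet()[0])

    measurements: list[DomainMeasurement] = []
    sample_units: list[DomainMeasurement] = []
    coloc_report: dict[str, dict] = {}
    profile_rows = []

    for stage in config.stages:
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            spec = PhantomSpec(
                width=config.width,
                height=config.height,
                stage_label=_STAGE_TO_PHANTOM[stage],
                background_level=config.background_level,
                background_noise_sd=config.background_noise_sd,
                seed=seeds[stage],
            )
            phantom = generate_phantom(spec)
            save_phantom(phantom, stage_dir / "phantom")
        except Exception as exc:
            raise StageError(f"stage 'phantom' failed for {stage}: {exc}") from exc

        try:
            markers = negative_marker_points(phantom, n=32, seed=seeds[stage])
            adjusted: dict[str, GrayImage8] = {}
            for factor in ("green", "red"):
                adjusted[factor], _ = dark_point_adjust(
                    phantom.channels[factor], markers, target=config.baseline_target
                )
            corrected = dict(adjusted)
            corrected["green"], corrected["red"] = leakage_subtract(
                adjusted["green"], adjusted["red"]
            )
            for factor in config.factors:
                imwrite_gray8(stage_dir / f"{factor}_corrected.tif", corrected[factor])
        except Exception as exc:
            raise StageError(f"stage 'preprocess' failed for {stage}: {exc}") from exc

        try:
            rois = roi_masks(phantom)
            for factor in config.factors:
                img = corrected[factor]
                hot = compose_hotmap(band_images(img, config.thresholds), config.thresholds)
                from PIL import Image

                Image.fromarray(hot.to_rgb()).save(stage_dir / f"{factor}_hotmap.png")
                for roi in rois:
                    measurements.append(
                        domain_size(img, roi, config.thresholds, factor=factor, stage=stage)
                    )
                    for band in sample_unit_bands(
                        img, config.sample_unit_low, config.sample_unit_high,
                        config.sample_unit_step,
                    ):
                        area = int((band.mask & roi.mask).sum())
                        sample_units.append(
                            DomainMeasurement(
                                factor=factor,
                                stage=stage,
                                roi_id=roi.id,
                                roi_area=roi.area,
                                domain_area=area,
                                fraction=100.0 * area / roi.area,
                                band_histogram={band.color_label: area},
                            )
                        )
        except Exception as exc:
            raise StageError(f"stage 'banding' failed for {stage}: {exc}") from exc

        try:
            for factor in config.factors:
                grid = to_od(corrected[factor], curve)
                profile = plot_profile(grid, "mean")
                for pos, val in zip(profile.positions, profile.values):
                    profile_rows.append(
                        {"stage": stage, "factor": factor, "distance_cm": pos, "od": val}
                    )
        except Exception as exc:
            raise StageError(f"stage 'densitometry' failed for {stage}: {exc}") from exc

        try:
            stage_coloc: dict[str, dict] = {}
            roi0 = ROIMask(phantom.tissue_mask, "whole_tooth_germ")
            # correlation runs on unsubtracted channels: counter-channel
            # subtraction removes exactly the co-located signal it measures
            for factor in config.factors:
                res = intensity_correlation(
                    adjusted[factor], phantom.channels["nuclear"], roi0
                )
                stage_coloc[f"{factor}_vs_nuclear"] = {
                    "pearson_r": res.pearson_r,
                    "overlap_fraction": res.overlap_fraction,
                    "pattern_call": res.pattern_call,
                }
            if set(("green", "red")) <= set(config.factors):
                series = serial_coloc(adjusted["green"], adjusted["red"])
                stage_coloc["serial_green_ref_red_probe"] = {
                    "probe_thresholds": list(series.probe_thresholds),
                    "overlap_areas": list(series.overlap_areas),
                    "baseline_only": series.baseline_only,
                }
            coloc_report[stage] = stage_coloc
        except Exception as exc:
            raise StageError(f"stage 'coloc' failed for {stage}: {exc}") from exc

    try:
        import pandas as pd

        measurements_to_frame(measurements).to_csv(out / "domains.csv", index=False)
        measurements_to_frame(sample_units).to_csv(out / "sample_units.csv", index=False)
        pd.DataFrame(profile_rows).to_csv(out / "profiles.csv", index=False)
        (out / "coloc.json").write_text(json.dumps(coloc_report, indent=2, sort_keys=True))
        if len(config.stages) >= 2:
            report = compare_domains(sample_units)
            report.to_csv(out / "stats.csv", index=False)
    except Exception as exc:
        raise StageError(f"stage 'stats' failed: {exc}") from exc

    config_hash = hashlib.sha256(
        json.dumps(config.to_jsonable(), sort_keys=True).encode()
    ).hexdigest()
    outputs = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=config_hash,
        outputs=outputs,
        stage_seeds=seeds,
        versions={"toothmap": __version__, "numpy": np.__version__},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.save(out / "manifest.json")
    return manifest
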