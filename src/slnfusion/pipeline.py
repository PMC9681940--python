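"""End-to-end experiment: generate, simulate, segment, register, project, score.

One experiment repeats, over a list of seeds, the full fusion workflow on
the digital phantom:

1. voxelize the phantom and draw a bounded rigid misalignment (the
   unknown repositioning between the preoperative SPECT/CT session and
   the intraoperative CT session);
2. render the intraoperative CT (board frame) and the preoperative
   session's co-registered CT + SPECT (misaligned frame);
3. segment SLNs and detect the calibration-board fiducials in both CTs;
4. register preop -> intraop: closed-form fiducial initialization, then
   mutual-information refinement;
5. project the preoperative SLN segments through the estimated and the
   true transform into an endoscope-like pinhole camera;
6. score each SLN overlay pair (normalized barycenter distance and
   coverage rate) and aggregate medians/IQRs across seeds.
"""

from __future__ import annotations

import json
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import metrics as ovm
from .phantom import (
    ModalityModel,
    PhantomSpec,
    build_phantom_labelmap,
    default_ct_model,
    default_spect_model,
    render_ct,
    render_spect,
    sample_rigid_misalignment,
)
from .projection import CameraModel, default_camera, make_overlay_pair
from .registration import (
    MIOptions,
    centered_init,
    register_points,
    register_rigid_mi,
    target_registration_error,
)
from .segmentation import (
    assign_left_right,
    detect_fiducials,
    segment_ct,
    segment_spect_hotspots,
)
from .transforms import RigidTransform

__all__ = ["ExperimentConfig", "ExperimentReport", "ConfigError", "validate_config", "run_experiment"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid experiment configuration; the message lists every violation."""


class MisalignmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_rotation_deg: float = 10.0
    max_translation_mm: float = 20.0


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ct_thresholds: Optional[Dict[str, Tuple[float, float]]] = None  # None -> defaults
    spect_fraction_of_max: float = 0.10
    min_component_voxels: int = 10


class RegistrationConfig(BaseModel):
    """Initialization mode and MI refinement knobs.

    With ``init_mode='fiducial'`` the MI stage is a bounded local
    refinement around the closed-form fiducial solution (trust region in
    degrees/mm); the other modes run the full coarse-to-fine search.
    ``mi_channel`` selects which preoperative image drives the MI
    refinement: the CT arm of the SPECT/CT (bone-driven, default) or the
    SPECT activity map itself.
    """

    model_config = ConfigDict(extra="forbid")
    init_mode: Literal["fiducial", "centered", "identity"] = "fiducial"
    mi_channel: Literal["ct", "spect"] = "ct"
    n_bins: int = 32
    refine_trust_region_deg: float = 1.0
    refine_trust_region_mm: float = 3.0
    refine_max_evaluations: int = 400
    refine_initial_step: float = 0.05
    refine_smooth_sigma: float = 3.0


class CameraConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    focal_length: float = 1000.0
    principal_point: Tuple[float, float] = (640.0, 360.0)
    image_size: Tuple[int, int] = (1280, 720)
    look_at: Tuple[float, float, float] = (100.0, 90.0, 70.0)
    distance_mm: float = 450.0

    def build(self) -> CameraModel:
        cam = default_camera(look_at=self.look_at, distance_mm=self.distance_mm)
        return CameraModel(
            focal_length=self.focal_length,
            principal_point=self.principal_point,
            image_size=self.image_size,
            pose=cam.pose,
        )


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    phantom: PhantomSpec = Field(default_factory=PhantomSpec)
    phantom_grid_mm: float = 0.35
    ct_model: ModalityModel = Field(default_factory=default_ct_model)
    spect_model: ModalityModel = Field(default_factory=default_spect_model)
    misalignment: MisalignmentConfig = Field(default_factory=MisalignmentConfig)
    seeds: List[int] = Field(default_factory=lambda: list(range(20)))
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    registration: RegistrationConfig = Field(default_factory=RegistrationConfig)
    camera: CameraConfig = Field(default_factory=CameraConfig)
    oracle: bool = False
    save_volumes: bool = True
    output_dir: Optional[str] = None

    def model_post_init(self, _ctx) -> None:
        if len(self.seeds) < 1:
            raise ValueError("at least one seed is required")


def validate_config(path) -> ExperimentConfig:
    """Parse and invariant-check a JSON config file; defaults fill gaps.

    An empty file yields the default configuration.  Unknown keys and
    invalid values raise :class:`ConfigError` listing every violation.
    """
    text = Path(path).read_text().strip()
    if not text:
        return ExperimentConfig()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as e:
        raise ConfigError(f"config is not valid JSON: {e}") from e
    try:
        return ExperimentConfig.model_validate(data)
    except ValidationError as e:
        lines = [f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in e.errors()]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from e


# ---------------------------------------------------------------------- report
@dataclass
class ExperimentReport:
    config: dict
    records: List[dict] = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return sum(1 for r in self.records if r.get("error"))

    def to_dict(self) -> dict:
        return {"config": self.config, "records": self.records, "aggregates": self.aggregates}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def overlay_frame(self):
        reports = []
        for rec in self.records:
            if rec.get("error"):
                continue
            for side in ("sln_left", "sln_right"):
                row = dict(rec["overlays"][side])
                row["seed"] = rec["seed"]
                reports.append(row)
        import pandas as pd

        return pd.DataFrame(reports)


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([int(seed), stage]).generate_state(1)[0] % (2**31))


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def _quartiles(x: List[float]) -> dict:
    if not x:
        return {"median": None, "iqr": None, "q1": None, "q3": None}
    q1, med, q3 = np.percentile(np.asarray(x, dtype=float), [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1), "q1": float(q1), "q3": float(q3)}


def _refine_options(reg: RegistrationConfig, full_search: bool) -> MIOptions:
    if full_search:
        return MIOptions(n_bins=reg.n_bins)
    return MIOptions(
        n_bins=reg.n_bins,
        shrink_factors=(1,),
        max_evaluations=(reg.refine_max_evaluations,),
        initial_steps=(reg.refine_initial_step,),
        xtol=(0.002,),
        trust_region=(reg.refine_trust_region_deg, reg.refine_trust_region_mm),
        final_smooth_sigma=reg.refine_smooth_sigma,
    )


def run_experiment(config: ExperimentConfig, output_dir: Optional[str] = None) -> ExperimentReport:
    """Run the full fusion experiment over every configured seed.

    Stage errors are caught and recorded per seed; remaining seeds still
    run.  With ``output_dir`` (or ``config.output_dir``) set, per-seed
    intermediates (volumes if ``save_volumes``, transforms, masks) and
    the JSON/CSV reports are written there.
    """
    out = Path(output_dir or config.output_dir) if (output_dir or config.output_dir) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    labelmap = build_phantom_labelmap(config.phantom, config.phantom_grid_mm)
    logger.info("phantom labelmap built in %.2f s (hash %s)", time.perf_counter() - t0, _sha(labelmap.volume.values))
    camera = config.camera.build()
    fov_center = config.phantom.fov_center
    sln_centers_board = {
        "sln_left": np.asarray(config.phantom.sln_centers[0], dtype=float),
        "sln_right": np.asarray(config.phantom.sln_centers[1], dtype=float),
    }

    report = ExperimentReport(config=json.loads(config.model_dump_json()))
    for seed in config.seeds:
        rec = {"seed": int(seed), "error": None}
        seed_dir = out / f"seed_{seed:05d}" if out else None
        if seed_dir:
            seed_dir.mkdir(exist_ok=True)
        stage = "misalignment"
        try:
            t_seed = time.perf_counter()
            mis = sample_rigid_misalignment(
                config.misalignment.max_rotation_deg,
                config.misalignment.max_translation_mm,
                seed=_stage_seed(seed, 0),
                center=fov_center,
            )
            t_true = mis.inverse()  # preop(moving) world -> intraop(fixed) world
            rec["true_matrix"] = t_true.matrix.tolist()
            rec["misalignment"] = {"angle_deg": mis.rotation_angle_deg}

            stage = "simulate"
            intraop_ct = render_ct(labelmap, config.ct_model, RigidTransform.identity(), seed=_stage_seed(seed, 1))
            preop_ct = render_ct(labelmap, config.ct_model, mis, seed=_stage_seed(seed, 2))
            preop_spect = render_spect(labelmap, config.spect_model, mis, seed=_stage_seed(seed, 3))
            logger.info(
                "seed %d: renders done (intraop %s, preop %s, spect %s)",
                seed,
                _sha(intraop_ct.values),
                _sha(preop_ct.values),
                _sha(preop_spect.values),
            )
            if seed_dir and config.save_volumes:
                intraop_ct.save(seed_dir / "intraop_ct.nii.gz")
                preop_ct.save(seed_dir / "preop_ct.nii.gz")
                preop_spect.save(seed_dir / "preop_spect.nii.gz")

            stage = "segmentation"
            seg_cfg = config.segmentation
            preop_structs = assign_left_right(
                segment_ct(preop_ct, seg_cfg.ct_thresholds, seg_cfg.min_component_voxels)
            )
            hotspots = assign_left_right(segment_spect_hotspots(preop_spect, seg_cfg.spect_fraction_of_max))
            rec["spect_hotspot_vs_ct_mm"] = {
                side: float(np.linalg.norm(hotspots[side].centroid_mm - preop_structs[side].centroid_mm))
                for side in ("sln_left", "sln_right")
            }

            targets_moving = {side: mis.apply(c) for side, c in sln_centers_board.items()}

            if config.oracle:
                stage = "oracle"
                t_est = t_true
                rec["registration"] = {"mode": "oracle"}
            else:
                stage = "fiducial_registration"
                fid_expected = np.asarray(config.phantom.fiducials, dtype=float)
                fid_fixed = detect_fiducials(intraop_ct, fid_expected)
                fid_moving = detect_fiducials(preop_ct, fid_expected)
                init_res = register_points(fid_moving, fid_fixed)
                rec["fre_mm"] = init_res.fre_mm
                rec["fiducial_matrix"] = init_res.transform.matrix.tolist()
                rec["tre_fiducial_mm"] = {
                    side: float(target_registration_error(init_res.transform, t_true, [p])[0])
                    for side, p in targets_moving.items()
                }

                stage = "mi_registration"
                moving_img = preop_ct if config.registration.mi_channel == "ct" else preop_spect
                if config.registration.init_mode == "fiducial":
                    init = init_res.transform
                    opts = _refine_options(config.registration, full_search=False)
                elif config.registration.init_mode == "centered":
                    init = centered_init(intraop_ct, moving_img)
                    opts = _refine_options(config.registration, full_search=True)
                else:
                    init = RigidTransform.identity()
                    opts = _refine_options(config.registration, full_search=True)
                mi_res = register_rigid_mi(intraop_ct, moving_img, init=init, options=opts)
                t_est = mi_res.transform
                rec["registration"] = {
                    "mode": config.registration.init_mode,
                    "mi_channel": config.registration.mi_channel,
                    "mi_bits": mi_res.final_metric,
                    "converged": mi_res.converged,
                    "n_evaluations": mi_res.n_evaluations,
                }

            rec["estimated_matrix"] = t_est.matrix.tolist()
            rec["tre_mm"] = {
                side: float(target_registration_error(t_est, t_true, [p])[0])
                for side, p in targets_moving.items()
            }
            if seed_dir:
                t_est.to_text(seed_dir / "estimated_transform.txt")
                t_true.to_text(seed_dir / "true_transform.txt")

            stage = "overlay"
            rec["overlays"] = {}
            for side in ("sln_left", "sln_right"):
                s1, s2 = make_overlay_pair(camera, preop_structs[side], preop_ct, t_est, t_true)
                rep = ovm.overlay_report(side, s1, s2)
                rec["overlays"][side] = rep.as_dict()
                if seed_dir:
                    s1.save_png(seed_dir / f"{side}_s1_ar.png")
                    s2.save_png(seed_dir / f"{side}_s2_truth.png")
            logger.info("seed %d finished in %.2f s", seed, time.perf_counter() - t_seed)
        except Exception as e:  # noqa: BLE001 - stage failures are data, not crashes
            logger.warning("seed %d failed at stage %s: %s", seed, stage, e)
            rec["error"] = {"stage": stage, "message": str(e)}
        report.records.append(rec)

    ok = [r for r in report.records if not r.get("error")]
    agg = {
        "n_seeds": len(report.records),
        "n_failed": report.n_failed,
        "ratio_left": _quartiles([r["overlays"]["sln_left"]["ratio"] for r in ok]),
        "ratio_right": _quartiles([r["overlays"]["sln_right"]["ratio"] for r in ok]),
        "coverage_left_pct": _quartiles([100.0 * r["overlays"]["sln_left"]["coverage"] for r in ok]),
        "coverage_right_pct": _quartiles([100.0 * r["overlays"]["sln_right"]["coverage"] for r in ok]),
        "tre_left_mm": _quartiles([r["tre_mm"]["sln_left"] for r in ok if "tre_mm" in r]),
        "tre_right_mm": _quartiles([r["tre_mm"]["sln_right"] for r in ok if "tre_mm" in r]),
        "fre_mm": _quartiles([r["fre_mm"] for r in ok if r.get("fre_mm") is not None]),
    }
    report.aggregates = agg

    if out:
        report.to_json(out / "report.json")
        frame = report.overlay_frame()
        if len(frame):
            frame.to_csv(out / "overlays.csv", index=False)
    return report
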