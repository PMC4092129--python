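"""End-to-end orchestration: scene -> flight -> cube -> ortho -> map -> report.

A single validated configuration drives every stage; each stochastic stage
receives a deterministic sub-seed derived by hashing (master seed, stage
name), so re-running the same config byte-reproduces the report and
inserting a stage never reshuffles the others.  All artifacts are written
with a provenance manifest (stage, seed, content hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field

from gyrospec import accuracy as acc
from gyrospec import classification as cls
from gyrospec import flight_dynamics as fd
from gyrospec import formats
from gyrospec import geocorrection as geo
from gyrospec import pushbroom as pb
from gyrospec import spectral_scene as ss

__all__ = ["RunConfig", "run_pipeline", "default_config", "PipelineStageError",
           "stage_seed"]

log = logging.getLogger("gyrospec")


class SceneConfig(BaseModel):
    width_m: float = 60.0
    height_m: float = 40.0
    g_fine: float = 0.05
    relief: Literal["flat", "ramp", "smooth_random"] = "smooth_random"
    amplitude: float = 5.0
    n_disc_patches: int = 16
    disc_radius_range: tuple[float, float] = (1.5, 3.5)
    n_tendrils: int = 6
    tendril_width: float = 0.2
    tendril_length: float = 8.0
    background_classes: list[str] = Field(
        default_factory=lambda: list(ss.DEFAULT_BACKGROUND))
    target_class: str = ss.DEFAULT_TARGET
    library_sigma: float = 0.01
    n_variants: int = 3


class FlightConfig(BaseModel):
    v: float = 18.06                  # ~65 km/h
    h: float = 300.0
    t_int: float = 0.0277
    sigma_roll_deg: float = 1.0
    sigma_pitch_deg: float = 1.0
    sigma_yaw_deg: float = 1.0
    rho: float = 0.95
    sigma_gps: float = 0.2
    sigma_gyro: float = 0.002
    sigma_b: float = 1e-5
    gps_rate: float = 10.0
    attitude_fix: bool = True
    att_fix_rate: float = 10.0
    sigma_att_fix: float = 3e-4


class SensorConfig(BaseModel):
    n_detectors: int | None = None    # default: one detector per analysis pixel
    n_bands: int = 200
    snr: float | None = 100.0


class GeocorrectionConfig(BaseModel):
    pixel_size: float = 0.5
    pose_source: Literal["ahrs", "true", "dead_reckoning"] = "ahrs"
    n_gcps: int = 8
    gcp_model: Literal["affine", "polynomial-2"] = "affine"
    use_gcps: bool = True


class ClassificationConfig(BaseModel):
    n_per_class: int = 60
    mixed_fraction: float = 0.3
    window_fraction: float = 0.7      # central window side, as image fraction
    standardize: bool = False


class ValidationConfig(BaseModel):
    n_target: int = 100
    n_other: int = 250
    threshold_fraction: float = 0.5


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration with one master seed."""

    scene: SceneConfig = Field(default_factory=SceneConfig)
    flight: FlightConfig = Field(default_factory=FlightConfig)
    sensor: SensorConfig = Field(default_factory=SensorConfig)
    geocorrection: GeocorrectionConfig = Field(default_factory=GeocorrectionConfig)
    classification: ClassificationConfig = Field(default_factory=ClassificationConfig)
    validation: ValidationConfig = Field(default_factory=ValidationConfig)
    seed: int = 0
    outdir: str = "runs/default"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def default_config(**overrides) -> RunConfig:
    return RunConfig.model_validate(overrides)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic sub-seed: stable across runs and stage insertion."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")   # fits legacy 32-bit RNG seeds


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, artifacts: dict, cause: Exception):
        self.stage = stage
        self.artifacts = artifacts
        super().__init__(
            f"pipeline stage {stage!r} failed: {cause}; "
            f"artifacts so far: {sorted(artifacts)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, write_artifacts: bool = True) -> dict:
    """Execute the full simulation + analysis chain.

    Returns a dict with the accuracy report, per-stage objects and the
    manifest.  Stage failures re-raise as PipelineStageError naming the
    stage and the artifacts already written.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.model_validate(config)
    outdir = Path(config.outdir)
    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    artifacts: dict[str, Path] = {}

    def record(stage, seed, name, path):
        artifacts[name] = Path(path)
        manifest.append({"stage": stage, "seed": seed, "name": name,
                         "path": str(path), "sha256": _sha256(Path(path))})

    state: dict = {"config": config}

    # ---- scene ------------------------------------------------------------
    stage = "scene"
    seed = stage_seed(config.seed, stage)
    try:
        sc = config.scene
        shape = (int(round(sc.height_m / sc.g_fine)),
                 int(round(sc.width_m / sc.g_fine)))
        dtm = ss.generate_dtm(shape, sc.relief, sc.amplitude, seed=seed)
        base = ss.Scene(dtm=dtm, class_map=np.zeros(shape, np.int16),
                        class_names=[sc.target_class] + sc.background_classes,
                        g_fine=sc.g_fine, origin=(0.0, 0.0))
        scene = ss.generate_patch_map(
            base, sc.n_disc_patches, sc.disc_radius_range, sc.n_tendrils,
            sc.tendril_width, sc.background_classes, seed=seed + 1,
            target_class=sc.target_class, tendril_length=sc.tendril_length)
        lib = ss.default_library(config.sensor.n_bands, sigma=sc.library_sigma)
        pixel_size = config.geocorrection.pixel_size
        coverage = ss.rasterize_coverage(scene, pixel_size, sc.target_class)
        majority = ss.majority_class_map(scene, pixel_size)
        if write_artifacts:
            record(stage, seed, "dtm", formats.write_geotiff(
                outdir / "dtm.tif", dtm.astype(np.float32), sc.g_fine, scene.origin))
            record(stage, seed, "class_map", formats.write_geotiff(
                outdir / "class_map.tif", scene.class_map.astype(np.uint8),
                sc.g_fine, scene.origin))
            record(stage, seed, "coverage", formats.write_geotiff(
                outdir / "coverage.tif", coverage.coverage.astype(np.float32),
                pixel_size, scene.origin))
            record(stage, seed, "library", formats.write_library_csv(
                outdir / "library.csv", lib))
        state.update(scene=scene, lib=lib, coverage=coverage, majority=majority)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineStageError(stage, artifacts, e) from e

    # ---- flight -----------------------------------------------------------
    stage = "flight"
    seed = stage_seed(config.seed, stage)
    try:
        fc = config.flight
        d2r = np.pi / 180.0
        y_center = -config.scene.height_m / 2.0
        traj = fd.simulate_trajectory(
            config.scene.width_m, fc.v, fc.h, fc.t_int,
            perturbation=dict(sigma_roll=fc.sigma_roll_deg * d2r,
                              sigma_pitch=fc.sigma_pitch_deg * d2r,
                              sigma_yaw=fc.sigma_yaw_deg * d2r, rho=fc.rho),
            seed=seed, start=(0.0, y_center))
        streams = fd.simulate_sensors(
            traj, sigma_gps=fc.sigma_gps, sigma_gyro=fc.sigma_gyro,
            sigma_b=fc.sigma_b, gps_rate=fc.gps_rate,
            attitude_fix=fc.attitude_fix, att_fix_rate=fc.att_fix_rate,
            sigma_att_fix=fc.sigma_att_fix, seed=seed + 1)
        ahrs = fd.kalman_fuse(streams, line_t=traj.t)
        if write_artifacts:
            record(stage, seed, "trajectory", formats.write_pose_csv(
                outdir / "trajectory.csv", traj.t, traj.pos, traj.att))
            record(stage, seed, "ahrs", formats.write_pose_csv(
                outdir / "ahrs.csv", ahrs.t, ahrs.pos, ahrs.att,
                cov_diag=np.einsum("nii->ni", ahrs.cov)))
        state.update(traj=traj, streams=streams, ahrs=ahrs)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineStageError(stage, artifacts, e) from e

    # ---- acquire ----------------------------------------------------------
    stage = "acquire"
    seed = stage_seed(config.seed, stage)
    try:
        pixel_size = config.geocorrection.pixel_size
        n_det = config.sensor.n_detectors or int(
            round(config.scene.height_m / pixel_size))
        fov = 2.0 * np.arctan(config.scene.height_m / 2.0 / config.flight.h)
        sensor = pb.SensorModel(n_detectors=n_det, fov=fov,
                                n_bands=config.sensor.n_bands,
                                t_int=config.flight.t_int)
        cube = pb.acquire_cube(state["scene"], state["lib"], state["traj"],
                               sensor, snr=config.sensor.snr, seed=seed,
                               n_variants=config.scene.n_variants)
        if write_artifacts:
            record(stage, seed, "cube", formats.write_envi(
                outdir / "cube.bil", cube.data, "bil",
                wavelengths=cube.wavelengths))
            record(stage, seed, "cube_pose", formats.write_pose_csv(
                outdir / "cube_pose.csv", state["traj"].t, state["traj"].pos,
                state["traj"].att))
        state.update(cube=cube, sensor=sensor)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineStageError(stage, artifacts, e) from e

    # ---- geocorrect -------------------------------------------------------
    stage = "geocorrect"
    seed = stage_seed(config.seed, stage)
    try:
        gc = config.geocorrection
        scene = state["scene"]
        pose = {"ahrs": state["ahrs"], "true": state["traj"]}.get(gc.pose_source)
        if pose is None:                       # dead-reckoned gyro-only pose
            att = fd.dead_reckon_attitude(state["streams"], state["traj"].att[0],
                                          line_t=state["traj"].t)
            pos = fd.gps_only_position(state["streams"], state["traj"].t)
            pose = fd.AhrsSolution(t=state["traj"].t, pos=pos, att=att,
                                   cov=np.zeros((len(att), 12, 12)))
        k = int(round(gc.pixel_size / scene.g_fine))
        grid_shape = (scene.shape[0] // k, scene.shape[1] // k)
        ortho = geo.parametric_geocorrect(
            state["cube"], pose, scene, gc.pixel_size,
            grid_origin=scene.origin, grid_shape=grid_shape)
        if gc.use_gcps and gc.n_gcps >= 3:
            gcps = simulate_gcps(state["cube"], state["traj"], pose, scene,
                                 n=gc.n_gcps, seed=seed)
            ortho = geo.gcp_residual_correct(ortho, gcps, gc.gcp_model)
            if write_artifacts:
                record(stage, seed, "gcps", formats.write_gcps_csv(
                    outdir / "gcps.csv", gcps))
        if write_artifacts:
            record(stage, seed, "ortho", formats.write_envi(
                outdir / "ortho.bsq", ortho.data, "bsq",
                wavelengths=state["cube"].wavelengths,
                pixel_size=ortho.pixel_size, origin=ortho.origin))
            record(stage, seed, "ortho_preview", formats.write_geotiff(
                outdir / "ortho_preview.tif",
                ortho.data[:, :, ortho.n_bands // 2].astype(np.float32),
                ortho.pixel_size, ortho.origin))
        state.update(ortho=ortho)
    except PipelineStageError:
        raise
    except Exception as e:                                    # noqa: BLE001
        raise PipelineStageError(stage, artifacts, e) from e

    # ---- classify ---------------------------------------------------------
    stage = "classify"
    seed = stage_seed(config.seed, stage)
    try:
        cc = config.classification
        ortho = state["ortho"]
        rows, cols = ortho.shape
        wh = int(rows * cc.window_fraction)
        ww = int(cols * cc.window_fraction)
        window = ((rows - wh) // 2, (cols - ww) // 2, wh, ww)
        labels = cls.select_training_pixels(
            ortho, state["coverage"], state["majority"],
            state["scene"].class_names, window, cc.n_per_class,
            mixed_fraction=cc.mixed_fraction,
            threshold_fraction=config.validation.threshold_fraction,
            seed=seed, target_class=config.scene.target_class)
        clf = cls.train_svm(labels, ortho, standardize=cc.standardize,
                            seed=seed)
        class_map = cls.predict_map(clf, ortho)
        classified = cls.collapse_to_binary(class_map,
                                            target=config.scene.target_class)
        if write_artifacts:
            record(stage, seed, "labels", formats.write_labels_csv(
                outdir / "labels.csv", labels))
            record(stage, seed, "classified", formats.write_geotiff(
                outdir / "classified.tif", classified.astype(np.uint8),
                ortho.pixel_size, ortho.origin))
        state.update(labels=labels, clf=clf, class_map=class_map,
                     classified=classified)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineStageError(stage, artifacts, e) from e

    # ---- validate ---------------------------------------------------------
    stage = "validate"
    seed = stage_seed(config.seed, stage)
    try:
        vc = config.validation
        ortho = state["ortho"]
        reference = acc.apply_detection_threshold(
            state["coverage"], state["coverage"].pixel_area,
            vc.threshold_fraction)
        val = acc.sample_validation_pixels(
            state["classified"], reference, vc.n_target, vc.n_other,
            exclude=state["labels"], valid=~ortho.nodata, seed=seed)
        matrix = acc.build_error_matrix(val, state["classified"], reference)
        report = acc.accuracy_metrics(matrix)
        if write_artifacts:
            report_path = outdir / "report.json"
            report_path.write_text(json.dumps(report.to_dict(), indent=2,
                                              sort_keys=True) + "\n")
            record(stage, seed, "report", report_path)
            (outdir / "report.txt").write_text(report.format_table() + "\n")
            record(stage, seed, "report_txt", outdir / "report.txt")
            record(stage, seed, "validation_labels", formats.write_labels_csv(
                outdir / "validation_labels.csv", val))
        state.update(validation=val, matrix=matrix, report=report,
                     reference=reference)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineStageError(stage, artifacts, e) from e

    if write_artifacts:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(json.loads(config.model_dump_json())))
    state["manifest"] = manifest
    state["artifacts"] = artifacts
    return state


def simulate_gcps(cube, true_pose, est_pose, scene, n: int = 8,
                  seed: int = 0):
    """GCP pairs from salient scene points: as-geocoded vs true positions.

    Samples random valid cube pixels; the reference coordinate is the
    projection through the true trajectory, the image coordinate the
    projection through the estimated pose.
    """
    rng = np.random.default_rng(seed)
    lines = rng.integers(0, cube.n_lines, size=4 * n)
    dets = rng.integers(0, cube.n_detectors, size=4 * n)
    img, ref = [], []
    for i, d in zip(lines, dets):
        p_true, ok_t = geo.project_pixels(true_pose, cube.sensor, scene,
                                          detectors=np.array([d]),
                                          lines=np.array([i]))
        p_est, ok_e = geo.project_pixels(est_pose, cube.sensor, scene,
                                         detectors=np.array([d]),
                                         lines=np.array([i]))
        if ok_t[0, 0] and ok_e[0, 0]:
            ref.append(p_true[0, 0, :2])
            img.append(p_est[0, 0, :2])
        if len(img) >= n:
            break
    if len(img) < 3:
        raise ValueError("could not simulate enough GCPs inside the scene")
    return geo.GcpSet(image_xy=np.array(img), ref_xy=np.array(ref))
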