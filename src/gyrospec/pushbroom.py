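"""Pushbroom forward model: line-ordered cube acquisition from a scene.

Each (line, detector) spectrum is the area-weighted linear mixture of the
fine-cell spectra inside its ground footprint (across-track IFOV width x
along-track v*t_int), computed with the TRUE trajectory, plus additive
Gaussian noise scaled by SNR.  Footprint integration is fine-cell point
sampling, exact for crisp class maps, so mixing weights are exactly
testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from gyrospec.geometry import detector_directions, intersect_rays_dtm
from gyrospec.spectral_scene import Scene, SpectralLibrary, draw_spectrum
from gyrospec.flight_dynamics import Trajectory

__all__ = ["SensorModel", "SceneSpectra", "PushbroomCube",
           "line_of_sight", "realize_spectra", "acquire_cube",
           "default_sensor"]


@dataclass(frozen=True)
class SensorModel:
    """Line-sensor geometry: detector count, total FOV (rad), bands, t_int."""

    n_detectors: int = 700
    fov: float = 2.0 * np.arctan(110.0 / 300.0)   # 220 m swath at 300 m
    n_bands: int = 200
    t_int: float = 0.0277

    def swath(self, h: float) -> float:
        return 2.0 * h * np.tan(self.fov / 2.0)

    def across_track_resolution(self, h: float) -> float:
        return self.swath(h) / self.n_detectors

    def pixel_density(self, h: float, v: float) -> float:
        """Ground pixels per m^2 at height h and speed v."""
        return 1.0 / (self.across_track_resolution(h) * v * self.t_int)


def default_sensor(**kw) -> SensorModel:
    return SensorModel(**kw)


def line_of_sight(pos: np.ndarray, att: np.ndarray, detector: int,
                  sensor: SensorModel) -> tuple[np.ndarray, np.ndarray]:
    """Ray (origin, unit direction) of one detector at one pose.

    The nadir-pointing detector direction is tilted across-track by
    alpha_d = FOV * (d/(D-1) - 1/2) and rotated by the body attitude.
    """
    if not 0 <= detector < sensor.n_detectors:
        raise ValueError(f"detector {detector} outside [0, {sensor.n_detectors})")
    direction = detector_directions(np.asarray(att, float), sensor.fov,
                                    sensor.n_detectors,
                                    np.array([detector]))[0]
    return np.asarray(pos, float), direction


@dataclass(frozen=True)
class SceneSpectra:
    """Realized per-fine-cell spectra: an id map plus the id -> spectrum table."""

    variant_map: np.ndarray      # (H, W) int, index into spectra
    spectra: np.ndarray          # (n_ids, B)
    conditions: np.ndarray       # (n_ids,) stress condition used per id


def realize_spectra(scene: Scene, lib: SpectralLibrary, seed: int = 0,
                    n_variants: int = 3, field_smooth: float = 40.0) -> SceneSpectra:
    """Assign each fine cell a drawn spectrum of its class.

    Within-class variability is spatially coherent: a smoothed random
    field is quantized into ``n_variants`` condition levels per class, so
    neighbouring cells of one patch share a condition (vigorous patches
    vs water-stressed patches), and one spectrum is drawn per
    (class, level).
    """
    rng = np.random.default_rng(seed)
    h, w = scene.shape
    n_cls = len(scene.class_names)
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")

    if n_variants == 1:
        level = np.zeros((h, w), int)
        conditions = np.array([0.5])
    else:
        f = gaussian_filter(rng.standard_normal((h, w)), field_smooth, mode="nearest")
        edges = np.quantile(f, np.linspace(0, 1, n_variants + 1)[1:-1])
        level = np.searchsorted(edges, f).reshape(h, w)
        conditions = np.linspace(0.0, 1.0, n_variants)

    variant_map = scene.class_map.astype(np.int32) * n_variants + level
    spectra = np.empty((n_cls * n_variants, lib.n_bands))
    for c, name in enumerate(scene.class_names):
        for k in range(n_variants):
            spectra[c * n_variants + k] = draw_spectrum(lib, name, conditions[k], rng)
    return SceneSpectra(variant_map=variant_map, spectra=spectra,
                        conditions=np.tile(conditions, n_cls))


@dataclass(frozen=True)
class PushbroomCube:
    """Line-ordered radiance cube with per-line acquisition metadata."""

    data: np.ndarray             # (L, D, B) float32
    t: np.ndarray                # (L,) acquisition time of each line
    sensor: SensorModel
    wavelengths: np.ndarray
    nodata: np.ndarray           # (L, D) bool, True = footprint left the scene

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("cube data must be (lines, detectors, bands)")
        if np.any(~np.isfinite(self.data)):
            raise ValueError("cube contains non-finite radiance")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


def footprint_weights(scene: Scene, cx: float, cy: float, along: float,
                      across: float, n_ids: int,
                      variant_map: np.ndarray) -> np.ndarray | None:
    """Normalized per-spectrum-id area weights inside an axis-aligned footprint.

    A fine cell belongs to the footprint if its center lies in the
    half-open rectangle; weights sum to exactly 1, or None when the
    footprint contains no scene cells.
    """
    g = scene.g_fine
    x0, y0 = scene.origin
    h, w = scene.shape
    c_lo = int(np.ceil((cx - along / 2 - x0) / g - 0.5))
    c_hi = int(np.floor((cx + along / 2 - x0) / g - 0.5))
    r_lo = int(np.ceil((y0 - (cy + across / 2)) / g - 0.5))
    r_hi = int(np.floor((y0 - (cy - across / 2)) / g - 0.5))
    c_lo, c_hi = max(c_lo, 0), min(c_hi, w - 1)
    r_lo, r_hi = max(r_lo, 0), min(r_hi, h - 1)
    if c_lo > c_hi or r_lo > r_hi:
        return None
    block = variant_map[r_lo:r_hi + 1, c_lo:c_hi + 1]
    counts = np.bincount(block.ravel(), minlength=n_ids).astype(float)
    return counts / counts.sum()


def acquire_cube(scene: Scene, lib: SpectralLibrary, traj: Trajectory,
                 sensor: SensorModel | None = None, snr: float | None = 100.0,
                 seed: int = 0, spectra: SceneSpectra | None = None,
                 n_variants: int = 3) -> PushbroomCube:
    """Acquire a cube along the true trajectory.

    The footprint center of each (line, detector) is the ray-DTM
    intersection; the footprint is an axis-aligned rectangle of size
    (along = v*t_int) x (across = swath/D at the local height above
    ground).  ``snr = None`` (or inf) disables noise; otherwise additive
    i.i.d. Gaussian noise with sigma = mean signal / snr is applied.
    Footprints that leave the scene are flagged nodata (zero spectrum),
    never an abort.
    """
    sensor = sensor or SensorModel(n_bands=lib.n_bands)
    if sensor.n_bands != lib.n_bands:
        raise ValueError("sensor band count must match the spectral library")
    if spectra is None:
        spectra = realize_spectra(scene, lib, seed=seed, n_variants=n_variants)
    n_ids = len(spectra.spectra)

    L, D, B = traj.n_lines, sensor.n_detectors, lib.n_bands
    data = np.zeros((L, D, B), dtype=np.float32)
    nodata = np.zeros((L, D), dtype=bool)
    along = traj.v * traj.t_int

    x0, y0 = scene.origin
    for i in range(L):
        dirs = detector_directions(traj.att[i], sensor.fov, D)
        pts, ok = intersect_rays_dtm(traj.pos[i], dirs, scene.dtm,
                                     scene.g_fine, scene.origin)
        agl = traj.pos[i, 2] - np.where(ok, pts[:, 2], 0.0)
        across = 2.0 * agl * np.tan(sensor.fov / 2.0) / D
        for d in range(D):
            if not ok[d]:
                nodata[i, d] = True
                continue
            wts = footprint_weights(scene, pts[d, 0], pts[d, 1], along,
                                    across[d], n_ids, spectra.variant_map)
            if wts is None:
                nodata[i, d] = True
                continue
            data[i, d] = wts @ spectra.spectra

    if snr is not None and np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed + 1)
        sig = float(data[~nodata].mean()) if np.any(~nodata) else 0.0
        data = data + rng.standard_normal(data.shape).astype(np.float32) * (sig / snr)
        data = np.clip(data, 0.0, None)

    return PushbroomCube(data=data, t=traj.t.copy(), sensor=sensor,
                         wavelengths=lib.band_centers.copy(), nodata=nodata)
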