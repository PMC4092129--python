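"""Parametric geocorrection by per-line ray-DTM intersection + GCP refinement.

Each cube pixel is projected through the line-of-sight of its detector at
the (estimated or true) per-line pose and intersected with the terrain
model; the orthoimage grid is then filled by nearest-neighbor *gathering*
(each map cell takes the spectrally unmodified spectrum of the nearest
projected pixel within one ortho pixel, else nodata), preserving spectra
bit-exactly for classification.  Residual errors are removed afterwards
with a least-squares affine or quadratic warp fitted on ground control
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from gyrospec.geometry import (NoIntersectionError, detector_directions,
                               intersect_rays_dtm)
from gyrospec.pushbroom import PushbroomCube, SensorModel
from gyrospec.spectral_scene import Scene

__all__ = [
    "OrthoImage",
    "GcpSet",
    "intersect_dtm",
    "project_pixels",
    "parametric_geocorrect",
    "gcp_residual_correct",
    "NoIntersectionError",
    "EmptyOutputError",
]


class EmptyOutputError(ValueError):
    """No overlap between the projected footprint and the requested grid."""


def intersect_dtm(origin: np.ndarray, direction: np.ndarray,
                  scene: Scene, tol: float = 1e-3) -> np.ndarray:
    """First intersection of one downward ray with the scene's DTM surface.

    Coarse ray marching at the fine-grid step followed by bisection to
    ``tol`` m on the bilinear surface.  Raises NoIntersectionError when the
    ray exits the DTM extent before intersecting.
    """
    pts, ok = intersect_rays_dtm(np.asarray(origin, float)[None, :],
                                 np.asarray(direction, float)[None, :],
                                 scene.dtm, scene.g_fine, scene.origin, tol=tol)
    if not ok[0]:
        raise NoIntersectionError("ray exits the DTM extent before intersecting")
    return pts[0]


@dataclass(frozen=True)
class OrthoImage:
    """Geocorrected cube on a regular map grid.

    ``origin`` is the outer (west, north) corner of cell (0, 0); the
    geotransform round-trips indices <-> map coordinates exactly.
    ``source_index`` records, per cell, the flat (line * D + detector)
    index of the cube pixel whose spectrum it took (-1 for nodata).
    """

    data: np.ndarray              # (rows, cols, B) float32
    pixel_size: float
    origin: tuple[float, float]
    nodata: np.ndarray            # (rows, cols) bool
    source_index: np.ndarray      # (rows, cols) int
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(rows) + 0.5) * self.pixel_size
        return xs, ys

    def index_of(self, x, y):
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.pixel_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col

    def map_of(self, row, col):
        """Cell-center map coordinates of (row, col)."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.pixel_size
        y = y0 - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y


@dataclass(frozen=True)
class GcpSet:
    """Matched (as-geocoded, reference) map coordinates of salient points."""

    image_xy: np.ndarray         # (n, 2)
    ref_xy: np.ndarray           # (n, 2)

    def __post_init__(self):
        a = np.asarray(self.image_xy, float)
        b = np.asarray(self.ref_xy, float)
        if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
            raise ValueError("GCP arrays must both be (n, 2)")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("GCP coordinates must be finite")
        if len(np.unique(a, axis=0)) != len(a):
            raise ValueError("GCP image coordinates must be distinct")

    def __len__(self) -> int:
        return len(self.image_xy)

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.sum(
            (np.asarray(self.ref_xy) - np.asarray(self.image_xy)) ** 2, axis=1))))


def _pose_arrays(pose) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(pose.pos, float), np.asarray(pose.att, float)


def project_pixels(pose, sensor: SensorModel, scene: Scene,
                   detectors: np.ndarray | None = None,
                   lines: np.ndarray | None = None):
    """Ground coordinates of cube pixels for a pose source.

    pose: Trajectory or AhrsSolution (anything with .pos/.att per line).
    Returns (points (n_lines, n_det, 3), valid mask).
    """
    pos, att = _pose_arrays(pose)
    if lines is None:
        lines = np.arange(len(pos))
    if detectors is None:
        detectors = np.arange(sensor.n_detectors)
    pts = np.full((len(lines), len(detectors), 3), np.nan)
    valid = np.zeros((len(lines), len(detectors)), bool)
    for k, i in enumerate(lines):
        dirs = detector_directions(att[i], sensor.fov, sensor.n_detectors,
                                   detectors)
        p, ok = intersect_rays_dtm(pos[i], dirs, scene.dtm, scene.g_fine,
                                   scene.origin)
        pts[k], valid[k] = p, ok
    return pts, valid


def parametric_geocorrect(cube: PushbroomCube, pose, scene: Scene,
                          pixel_size: float = 0.5,
                          grid_origin: tuple[float, float] | None = None,
                          grid_shape: tuple[int, int] | None = None,
                          search_radius_px: float = 1.0) -> OrthoImage:
    """Project every cube pixel onto the DTM and gather onto a map grid.

    The grid defaults to the bounding box of the projected points snapped
    to ``pixel_size``; pass ``grid_origin``/``grid_shape`` to align with an
    existing analysis grid.  Nearest-neighbor gathering within
    ``search_radius_px`` ortho pixels; unfilled cells are nodata.
    """
    pos, att = _pose_arrays(pose)
    if len(pos) < cube.n_lines:
        raise ValueError("pose does not cover all cube lines")
    pts, valid = project_pixels(pose, cube.sensor, scene)
    valid &= ~cube.nodata
    flat_ok = valid.ravel()
    if not np.any(flat_ok):
        raise EmptyOutputError("no cube pixel projects inside the DTM extent")

    xy = pts[:, :, :2].reshape(-1, 2)[flat_ok]
    src = np.flatnonzero(flat_ok)

    if grid_origin is None:
        x0 = np.floor(xy[:, 0].min() / pixel_size) * pixel_size
        y0 = np.ceil(xy[:, 1].max() / pixel_size) * pixel_size
        grid_origin = (x0, y0)
    if grid_shape is None:
        cols = int(np.ceil((xy[:, 0].max() - grid_origin[0]) / pixel_size))
        rows = int(np.ceil((grid_origin[1] - xy[:, 1].min()) / pixel_size))
        grid_shape = (max(rows, 1), max(cols, 1))
    rows, cols = grid_shape

    x0, y0 = grid_origin
    xs = x0 + (np.arange(cols) + 0.5) * pixel_size
    ys = y0 - (np.arange(rows) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    dist, idx = cKDTree(xy).query(centers,
                                  distance_upper_bound=search_radius_px * pixel_size)
    hit = np.isfinite(dist)
    if not np.any(hit):
        raise EmptyOutputError("projected footprint does not overlap the requested grid")

    spectra = cube.data.reshape(-1, cube.n_bands)
    data = np.zeros((rows * cols, cube.n_bands), dtype=cube.data.dtype)
    source = np.full(rows * cols, -1, dtype=np.int64)
    data[hit] = spectra[src[idx[hit]]]
    source[hit] = src[idx[hit]]

    return OrthoImage(
        data=data.reshape(rows, cols, cube.n_bands),
        pixel_size=float(pixel_size),
        origin=(float(x0), float(y0)),
        nodata=~hit.reshape(rows, cols),
        source_index=source.reshape(rows, cols),
        provenance={"pose_source": type(pose).__name__,
                    "n_lines": cube.n_lines, "n_detectors": cube.n_detectors},
    )


def _design(xy: np.ndarray, model: str) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    if model == "affine":
        return np.column_stack([np.ones_like(x), x, y])
    if model == "polynomial-2":
        return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    raise ValueError(f"unknown warp model {model!r}")


_MIN_GCPS = {"affine": 3, "polynomial-2": 6}


def fit_warp(gcps: GcpSet, model: str = "affine"):
    """Least-squares warp coefficients mapping image coords -> reference coords."""
    if len(gcps) < _MIN_GCPS.get(model, 3):
        raise ValueError(
            f"{model} warp needs >= {_MIN_GCPS[model]} GCPs, got {len(gcps)}")
    A = _design(np.asarray(gcps.image_xy, float), model)
    coef, *_ = np.linalg.lstsq(A, np.asarray(gcps.ref_xy, float), rcond=None)
    return coef


def apply_warp(coef: np.ndarray, xy: np.ndarray, model: str = "affine") -> np.ndarray:
    return _design(np.asarray(xy, float), model) @ coef


def gcp_residual_correct(ortho: OrthoImage, gcps: GcpSet,
                         model: str = "affine") -> OrthoImage:
    """Remove residual georeferencing error with a GCP-fitted warp.

    Fits image->reference by least squares (so the post-fit RMS can never
    exceed the pre-fit RMS), then resamples the grid nearest-neighbor
    through the inverse (reference->image) fit.  RMS before/after is
    recorded in the result's provenance.
    """
    coef_fwd = fit_warp(gcps, model)
    rms_before = gcps.rms
    resid = apply_warp(coef_fwd, gcps.image_xy, model) - np.asarray(gcps.ref_xy)
    rms_after = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))

    inv = fit_warp(GcpSet(image_xy=gcps.ref_xy, ref_xy=gcps.image_xy), model)
    xs, ys = ortho.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    src_xy = apply_warp(inv, np.column_stack([gx.ravel(), gy.ravel()]), model)
    r, c = ortho.index_of(src_xy[:, 0], src_xy[:, 1])
    rows, cols = ortho.shape
    ok = (r >= 0) & (r < rows) & (c >= 0) & (c < cols)
    rs = np.where(ok, r, 0)
    cs = np.where(ok, c, 0)

    data = np.zeros_like(ortho.data).reshape(-1, ortho.n_bands)
    nodata = np.ones(rows * cols, bool)
    source = np.full(rows * cols, -1, dtype=ortho.source_index.dtype)
    filled = ok & ~ortho.nodata[rs, cs]
    data[filled] = ortho.data[rs[filled], cs[filled]]
    nodata[filled] = False
    source[filled] = ortho.source_index[rs[filled], cs[filled]]

    prov = dict(ortho.provenance)
    prov.update(gcp_model=model, gcp_rms_before=rms_before,
                gcp_rms_after=rms_after, n_gcps=len(gcps))
    return OrthoImage(data=data.reshape(rows, cols, ortho.n_bands),
                      pixel_size=ortho.pixel_size, origin=ortho.origin,
                      nodata=nodata.reshape(rows, cols),
                      source_index=source.reshape(rows, cols),
                      provenance=prov)
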