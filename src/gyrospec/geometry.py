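"""Imaging geometry shared by the forward model and geocorrection.

Frames: map frame is x east / y north / z up.  Body axes coincide with the
map axes at zero attitude (x along-track, y across-track); attitude is
applied as R = Rz(yaw) @ Ry(pitch) @ Rx(roll).  Detector d of a line
sensor looks down-nadir tilted across-track by
alpha_d = FOV * (d / (D - 1) - 1/2).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_matrix",
    "detector_directions",
    "bilinear_height",
    "intersect_rays_dtm",
    "NoIntersectionError",
]


class NoIntersectionError(RuntimeError):
    """Ray leaves the DTM extent before reaching the surface."""


def rotation_matrix(roll: float, pitch: float, yaw: float) -> np.ndarray:
    """Body-to-map rotation, R = Rz(yaw) @ Ry(pitch) @ Rx(roll)."""
    cr, sr = np.cos(roll), np.sin(roll)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cy, sy = np.cos(yaw), np.sin(yaw)
    rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1]])
    return rz @ ry @ rx


def detector_directions(att: np.ndarray, fov: float, n_detectors: int,
                        detectors: np.ndarray | None = None) -> np.ndarray:
    """Unit view directions in the map frame for one line pose.

    att: (roll, pitch, yaw); returns (k, 3) rays pointing downward
    (z < 0 for attitudes within the small-angle regime).
    """
    if detectors is None:
        detectors = np.arange(n_detectors)
    d = np.asarray(detectors)
    alpha = fov * (d / (n_detectors - 1) - 0.5)
    body = np.column_stack([np.zeros_like(alpha), np.sin(alpha), -np.cos(alpha)])
    return body @ rotation_matrix(*att).T


def bilinear_height(x: np.ndarray, y: np.ndarray, dtm: np.ndarray,
                    g: float, origin: tuple[float, float]) -> np.ndarray:
    """Bilinearly interpolated DTM elevation at map points; NaN outside.

    Pixel-center convention: cell (r, c) center at
    (x0 + (c+0.5) g, y0 - (r+0.5) g).  Points beyond the outermost cell
    centers are NaN (no extrapolation).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    h, w = dtm.shape
    x0, y0 = origin
    fc = (x - x0) / g - 0.5
    fr = (y0 - y) / g - 0.5
    out = np.full(np.broadcast(x, y).shape, np.nan)
    ok = (fc >= 0) & (fc <= w - 1) & (fr >= 0) & (fr <= h - 1)
    if not np.any(ok):
        return out
    fc, fr = fc[ok], fr[ok]
    c0 = np.clip(np.floor(fc).astype(int), 0, w - 2)
    r0 = np.clip(np.floor(fr).astype(int), 0, h - 2)
    tc = fc - c0
    tr = fr - r0
    z = (dtm[r0, c0] * (1 - tr) * (1 - tc) + dtm[r0, c0 + 1] * (1 - tr) * tc
         + dtm[r0 + 1, c0] * tr * (1 - tc) + dtm[r0 + 1, c0 + 1] * tr * tc)
    out[ok] = z
    return out


def intersect_rays_dtm(origins: np.ndarray, dirs: np.ndarray, dtm: np.ndarray,
                       g: float, origin: tuple[float, float],
                       tol: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """First intersection of downward rays with the bilinear DTM surface.

    Vectorized coarse ray marching (vertical step = g) from just above the
    highest terrain down to the lowest, followed by bisection to ``tol``
    meters.  Returns (points (n, 3), valid (n,)); rays that exit the DTM
    extent or never cross the surface are flagged invalid.
    """
    origins = np.atleast_2d(np.asarray(origins, float))
    dirs = np.atleast_2d(np.asarray(dirs, float))
    n = len(dirs)
    if len(origins) == 1 and n > 1:
        origins = np.broadcast_to(origins, (n, 3))
    if np.any(dirs[:, 2] >= 0):
        raise ValueError("rays must point downward (direction z < 0)")

    zmin, zmax = float(dtm.min()), float(dtm.max())
    dz = dirs[:, 2]

    def height_above(t):
        p = origins + t[:, None] * dirs
        surf = bilinear_height(p[:, 0], p[:, 1], dtm, g, origin)
        return p[:, 2] - surf        # NaN outside extent

    # march from just above the peak down past the lowest terrain
    t_hi = (zmax + g - origins[:, 2]) / dz
    t_hi = np.maximum(t_hi, 0.0)
    t_end = (zmin - g - origins[:, 2]) / dz
    n_steps = max(int(np.ceil((zmax - zmin) / g)) + 2, 2)
    dt = (t_end - t_hi) / n_steps

    t_lo = t_hi.copy()
    f_lo = height_above(t_lo)
    t_bracket_lo = np.full(n, np.nan)
    t_bracket_hi = np.full(n, np.nan)
    found = np.zeros(n, bool)
    dead = np.isnan(f_lo)                 # started outside extent laterally
    for k in range(1, n_steps + 1):
        t_new = t_hi + k * dt
        f_new = height_above(t_new)
        crossing = ~found & ~dead & (f_lo > 0) & (f_new <= 0)
        t_bracket_lo[crossing] = t_lo[crossing]
        t_bracket_hi[crossing] = t_new[crossing]
        found |= crossing
        dead |= ~found & np.isnan(f_new)
        t_lo, f_lo = t_new, f_new
        if np.all(found | dead):
            break

    pts = np.full((n, 3), np.nan)
    if np.any(found):
        a = t_bracket_lo[found].copy()
        b = t_bracket_hi[found].copy()
        o = origins[found]
        d = dirs[found]

        def f_sub(t):
            p = o + t[:, None] * d
            surf = bilinear_height(p[:, 0], p[:, 1], dtm, g, origin)
            return p[:, 2] - np.where(np.isnan(surf), -np.inf, surf)

        # interval shrinks by half per iteration; stop below tol in meters
        max_iter = int(np.ceil(np.log2(max((b - a).max(), tol) / tol))) + 2
        for _ in range(max_iter):
            m = 0.5 * (a + b)
            fm = f_sub(m)
            above = fm > 0
            a = np.where(above, m, a)
            b = np.where(above, b, m)
        t_star = 0.5 * (a + b)
        pts[found] = o + t_star[:, None] * d
    return pts, found
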