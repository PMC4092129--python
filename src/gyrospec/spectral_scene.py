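"""Synthetic terrain, species patch maps and reflectance spectra.

Everything downstream (acquisition, geocorrection, classification,
validation) is checked against the scene generated here: a fine-grid DTM,
a crisp per-cell class map with clonal disc patches and sub-pixel linear
"tendril" structures of the target species, and a two-endmember
(vigorous/stressed) spectral library with band-correlated within-class
variability.

Conventions: map coordinates in meters, x east / y north, pixel-center
georeferencing, 0-based indices, row 0 at maximum northing, half-open
extents.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.spatial import cKDTree

__all__ = [
    "SpectralLibrary",
    "Scene",
    "CoverageMap",
    "default_library",
    "generate_dtm",
    "generate_patch_map",
    "draw_spectrum",
    "rasterize_coverage",
    "spectral_angle",
]

N_BANDS = 200
WL_MIN, WL_MAX = 380.0, 1000.0

DEFAULT_TARGET = "carpobrotus"
DEFAULT_BACKGROUND = ["pistacia", "juniperus", "pinus", "crithmum"]


def band_grid(n_bands: int = N_BANDS, wl_min: float = WL_MIN,
              wl_max: float = WL_MAX) -> np.ndarray:
    """Band centers in nm, strictly increasing (~3 nm spacing at defaults)."""
    return np.linspace(wl_min, wl_max, n_bands)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _veg_spectrum(wl: np.ndarray, green: float, red: float, nir: float,
                  edge: float, slope: float = 18.0,
                  brown: float = 0.0) -> np.ndarray:
    """Parametric VNIR vegetation-like reflectance curve.

    Visible part: low baseline with a green bump at 550 nm and an optional
    "brown" bump around 660 nm (senescence / red succulent tissue); a
    logistic red edge lifts the curve onto the NIR plateau.
    """
    vis = red + (green - red) * np.exp(-((wl - 550.0) / 45.0) ** 2)
    vis = vis + brown * np.exp(-((wl - 660.0) / 60.0) ** 2)
    s = _logistic((wl - edge) / slope)
    r = vis * (1.0 - s) + nir * s
    return np.clip(r, 0.0, 1.0)


@dataclass(frozen=True)
class SpectralLibrary:
    """Per-class endmember spectra plus a within-class variability model.

    Each class carries a *vigorous* and a *stressed* endmember; a draw
    interpolates between them by ``condition`` in [0, 1] and adds
    band-correlated Gaussian noise (white noise smoothed along the band
    axis with ``smooth_bands`` sigma, then rescaled to std ``sigma``).
    """

    band_centers: np.ndarray
    classes: list[str]
    endmembers: dict[str, tuple[np.ndarray, np.ndarray]]
    sigma: dict[str, float]
    smooth_bands: float = 5.0

    def __post_init__(self):
        b = np.asarray(self.band_centers, dtype=float)
        if b.ndim != 1 or not np.all(np.diff(b) > 0):
            raise ValueError("band centers must be strictly increasing")
        for name in self.classes:
            if name not in self.endmembers:
                raise KeyError(f"no endmembers for class {name!r}")

    @property
    def n_bands(self) -> int:
        return len(self.band_centers)

    def endmember(self, cls: str, condition: float = 0.0) -> np.ndarray:
        """Noise-free spectrum: condition 0 = vigorous, 1 = stressed."""
        if cls not in self.endmembers:
            raise KeyError(f"unknown class {cls!r}")
        if not 0.0 <= condition <= 1.0:
            raise ValueError("condition must lie in [0, 1]")
        vig, stress = self.endmembers[cls]
        return (1.0 - condition) * vig + condition * stress

    def with_sigma(self, value: float) -> "SpectralLibrary":
        """Copy of the library with every class variance set to ``value``."""
        return dataclasses.replace(self, sigma={c: value for c in self.classes})


def default_library(n_bands: int = N_BANDS, sigma: float = 0.01) -> SpectralLibrary:
    """Five-class coastal library in the high-confusability regime.

    One succulent target class with a strong vigorous->stressed (green->red)
    gradient, two sclerophyll shrubs, a conifer whose stressed endmember is
    withered needles, and a second succulent whose reddish form sits close
    to the stressed target -- the classic mixed-pixel false-positive trap.
    """
    wl = band_grid(n_bands)
    ems = {
        "carpobrotus": (
            _veg_spectrum(wl, green=0.15, red=0.05, nir=0.50, edge=716.0),
            _veg_spectrum(wl, green=0.09, red=0.12, nir=0.31, edge=700.0,
                          brown=0.11),
        ),
        "pistacia": (
            _veg_spectrum(wl, green=0.10, red=0.045, nir=0.43, edge=711.0),
            _veg_spectrum(wl, green=0.085, red=0.05, nir=0.36, edge=707.0,
                          brown=0.02),
        ),
        "juniperus": (
            _veg_spectrum(wl, green=0.08, red=0.05, nir=0.35, edge=709.0),
            _veg_spectrum(wl, green=0.11, red=0.095, nir=0.28, edge=703.0,
                          brown=0.13),
        ),
        "pinus": (
            _veg_spectrum(wl, green=0.09, red=0.04, nir=0.39, edge=712.0),
            _veg_spectrum(wl, green=0.10, red=0.10, nir=0.25, edge=698.0,
                          brown=0.17),
        ),
        "crithmum": (
            _veg_spectrum(wl, green=0.12, red=0.06, nir=0.41, edge=708.0),
            _veg_spectrum(wl, green=0.095, red=0.115, nir=0.33, edge=701.0,
                          brown=0.095),
        ),
    }
    classes = [DEFAULT_TARGET] + DEFAULT_BACKGROUND
    return SpectralLibrary(
        band_centers=wl,
        classes=classes,
        endmembers=ems,
        sigma={c: sigma for c in classes},
    )


def draw_spectrum(lib: SpectralLibrary, cls: str, condition: float,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """One reflectance draw for a class at a given stress condition.

    The perturbation is white Gaussian noise smoothed along the band axis
    (correlated bands, as in real canopy variability) rescaled to the
    class sigma, then the result is clipped to [0, 1].  With sigma 0 the
    draw is exactly the interpolated endmember.
    """
    base = lib.endmember(cls, condition)
    s = lib.sigma[cls]
    if s == 0.0:
        return base.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    noise = rng.standard_normal(lib.n_bands)
    if lib.smooth_bands > 0:
        noise = gaussian_filter1d(noise, lib.smooth_bands, mode="nearest")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return np.clip(base + s * noise, 0.0, 1.0)


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle (rad) between two spectra; the usual SAM similarity measure."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass(frozen=True)
class Scene:
    """Fine-grid DTM + crisp class map in map coordinates.

    ``origin`` is the map coordinate of the *outer corner* of cell (0, 0),
    i.e. (west edge, north edge); cell centers are offset half a cell
    inward.  Extents are half-open.
    """

    dtm: np.ndarray
    class_map: np.ndarray
    class_names: list[str]
    g_fine: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.dtm.shape != self.class_map.shape:
            raise ValueError("dtm and class_map must share shape")
        if self.g_fine <= 0:
            raise ValueError("g_fine must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dtm.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax), half-open."""
        h, w = self.dtm.shape
        x0, y0 = self.origin
        return (x0, y0 - h * self.g_fine, x0 + w * self.g_fine, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x of columns, y of rows) at cell centers."""
        h, w = self.dtm.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(w) + 0.5) * self.g_fine
        ys = y0 - (np.arange(h) + 0.5) * self.g_fine
        return xs, ys

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Fine-cell (row, col) containing map point(s); may be out of range."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.g_fine).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.g_fine).astype(int)
        return row, col

    def class_index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"unknown class {name!r}") from None


def generate_dtm(shape: tuple[int, int], relief: str = "flat",
                 amplitude: float = 0.0, seed: int = 0) -> np.ndarray:
    """Elevation grid (m): flat, west-east ramp, or smoothed random relief.

    ``amplitude`` is the peak-to-peak elevation range; deterministic in seed.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if relief == "flat":
        return np.zeros((h, w))
    if relief == "ramp":
        ramp = np.linspace(0.0, amplitude, w)
        return np.broadcast_to(ramp, (h, w)).copy()
    if relief == "smooth_random":
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((h, w))
        z = gaussian_filter(z, sigma=max(min(h, w) / 8.0, 1.0), mode="nearest")
        zmin, zmax = z.min(), z.max()
        if zmax > zmin:
            z = (z - zmin) / (zmax - zmin) * amplitude
        return z
    raise ValueError(f"unknown relief style {relief!r}")


def _stamp_disc(class_map: np.ndarray, scene: Scene, cx: float, cy: float,
                radius: float, value: int) -> None:
    """Mark every fine cell whose center is within radius of (cx, cy)."""
    g = scene.g_fine
    h, w = class_map.shape
    r0, c0 = scene.index_of(cx, cy)
    n = int(np.ceil(radius / g)) + 1
    rr = np.arange(max(r0 - n, 0), min(r0 + n + 1, h))
    cc = np.arange(max(c0 - n, 0), min(c0 + n + 1, w))
    if rr.size == 0 or cc.size == 0:
        return
    xs, ys = scene.cell_centers()
    dx = xs[cc][None, :] - cx
    dy = ys[rr][:, None] - cy
    inside = dx * dx + dy * dy <= radius * radius
    block = class_map[rr[0]:rr[-1] + 1, cc[0]:cc[-1] + 1]
    block[inside] = value


def generate_patch_map(scene: Scene, n_disc_patches: int,
                       disc_radius_range: tuple[float, float],
                       n_tendrils: int, tendril_width: float,
                       background_classes: list[str], seed: int = 0,
                       target_class: str = DEFAULT_TARGET,
                       n_background_sites: int = 6,
                       tendril_length: float = 10.0) -> Scene:
    """Fill the class map: mosaic background + target discs and tendrils.

    Background classes tile the scene as a Voronoi mosaic of random sites
    (``n_background_sites`` per class).  Clonal target patches are discs
    with radius uniform in ``disc_radius_range``; tendrils are random-walk
    polylines of the stated width, thin enough to cover only part of any
    analysis pixel they cross.  Returns a new Scene with the class map set
    (class 0 = target, then background classes in the given order).
    """
    if not background_classes:
        raise ValueError("at least one background class is required")
    if n_disc_patches > 0 and not (0 < disc_radius_range[0] <= disc_radius_range[1]):
        raise ValueError("disc radii must be positive and ordered")
    if n_tendrils > 0 and tendril_width <= 0:
        raise ValueError("tendril width must be positive")

    rng = np.random.default_rng(seed)
    h, w = scene.shape
    names = [target_class] + list(background_classes)
    class_map = np.zeros((h, w), dtype=np.int16)
    work = dataclasses.replace(scene, class_map=class_map, class_names=names)

    xmin, ymin, xmax, ymax = scene.extent

    # Voronoi background mosaic
    nb = len(background_classes)
    sites = np.column_stack([
        rng.uniform(xmin, xmax, nb * n_background_sites),
        rng.uniform(ymin, ymax, nb * n_background_sites),
    ])
    site_cls = 1 + np.repeat(np.arange(nb), n_background_sites)
    xs, ys = work.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    _, nearest = cKDTree(sites).query(np.column_stack([gx.ravel(), gy.ravel()]))
    class_map[:] = site_cls[nearest].reshape(h, w).astype(np.int16)

    # clonal disc patches
    rmax = disc_radius_range[1] if n_disc_patches > 0 else 0.0
    for _ in range(n_disc_patches):
        r = rng.uniform(*disc_radius_range)
        cx = rng.uniform(xmin + rmax, xmax - rmax)
        cy = rng.uniform(ymin + rmax, ymax - rmax)
        _stamp_disc(class_map, work, cx, cy, r, 0)

    # sub-pixel linear tendrils: short random-walk polylines
    mx = min(tendril_length, (xmax - xmin) / 4.0)
    my = min(tendril_length, (ymax - ymin) / 4.0)
    for _ in range(n_tendrils):
        x = rng.uniform(xmin + mx, xmax - mx)
        y = rng.uniform(ymin + my, ymax - my)
        heading = rng.uniform(0, 2 * np.pi)
        step = scene.g_fine / 2.0
        n_steps = int(tendril_length / step)
        for _k in range(n_steps):
            heading += rng.normal(0.0, 0.08)
            x += step * np.cos(heading)
            y += step * np.sin(heading)
            _stamp_disc(class_map, work, x, y, tendril_width / 2.0, 0)

    return work


@dataclass(frozen=True)
class CoverageMap:
    """Target-species area (m^2) per analysis pixel.

    Same origin as the source scene; ``coverage[i, j]`` is the target area
    within the 0-based analysis pixel (i, j); ``pixel_area`` its ceiling.
    """

    coverage: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def pixel_area(self) -> float:
        return self.pixel_size ** 2

    def presence(self, fraction: float = 0.5) -> np.ndarray:
        """Boolean presence map; threshold is boundary-inclusive."""
        from gyrospec.accuracy import apply_detection_threshold
        return apply_detection_threshold(self, self.pixel_area, fraction)


def rasterize_coverage(scene: Scene, pixel_size: float,
                       target_class: str = DEFAULT_TARGET) -> CoverageMap:
    """Aggregate fine-cell target area into analysis pixels.

    ``pixel_size`` must be an integer multiple of the fine grid so that
    coverage (count of target fine cells x g_fine^2) is exact; the scene
    shape must tile evenly, keeping area conservation exact.
    """
    ratio = pixel_size / scene.g_fine
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"pixel_size {pixel_size} is not an integer multiple of g_fine {scene.g_fine}")
    h, w = scene.shape
    if h % k or w % k:
        raise ValueError(f"scene shape {scene.shape} does not tile into {k}x{k} blocks")
    t = scene.class_index(target_class)
    mask = (scene.class_map == t).astype(np.int64)
    counts = mask.reshape(h // k, k, w // k, k).sum(axis=(1, 3))
    return CoverageMap(coverage=counts * scene.g_fine ** 2,
                       pixel_size=pixel_size, origin=scene.origin)


def majority_class_map(scene: Scene, pixel_size: float) -> np.ndarray:
    """Most frequent fine-cell class per analysis pixel (ties -> lowest index)."""
    k = int(round(pixel_size / scene.g_fine))
    h, w = scene.shape
    blocks = scene.class_map.reshape(h // k, k, w // k, k).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(h // k, w // k, k * k)
    n_cls = len(scene.class_names)
    counts = np.stack([(blocks == c).sum(axis=2) for c in range(n_cls)], axis=2)
    return counts.argmax(axis=2).astype(np.int16)
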