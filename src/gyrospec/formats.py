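"""File formats: ENVI cubes, (Geo)TIFF rasters, CSV sidecars.

ENVI headers are plain text next to a raw binary payload (BIL for
line-ordered cubes, BSQ for orthoimages); GeoTIFFs carry the geotransform
in the ModelPixelScale/ModelTiepoint tags via tifffile.  CSV writers cover
trajectories/poses, label sets, GCP pairs and spectral libraries.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "write_envi", "read_envi",
    "write_geotiff", "read_geotiff",
    "write_pose_csv", "read_pose_csv",
    "write_labels_csv", "read_labels_csv",
    "write_gcps_csv", "read_gcps_csv",
    "write_library_csv", "write_envi_spectral_library",
]

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 1: np.uint8, 2: np.int16, 3: np.int32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_envi(path: str | Path, data: np.ndarray, interleave: str = "bil",
               wavelengths: np.ndarray | None = None,
               pixel_size: float | None = None,
               origin: tuple[float, float] | None = None,
               description: str = "gyrospec cube") -> Path:
    """Write (lines, samples, bands) data + standard ENVI header.

    Returns the binary path; header is written alongside with suffix .hdr.
    """
    path = Path(path)
    data = np.ascontiguousarray(data)
    if data.ndim != 3:
        raise ValueError("ENVI writer expects (lines, samples, bands)")
    lines, samples, bands = data.shape
    interleave = interleave.lower()
    if interleave == "bil":
        arr = data.transpose(0, 2, 1)          # line, band, sample
    elif interleave == "bsq":
        arr = data.transpose(2, 0, 1)          # band, line, sample
    elif interleave == "bip":
        arr = data
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    code = _ENVI_CODES.get(data.dtype)
    if code is None:
        raise ValueError(f"unsupported dtype {data.dtype}")
    arr.astype(data.dtype).tofile(path)

    hdr = [
        "ENVI",
        f"description = {{{description}}}",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if pixel_size is not None and origin is not None:
        hdr.append("map info = {Arbitrary, 1.0, 1.0, "
                   f"{origin[0]}, {origin[1]}, {pixel_size}, {pixel_size}}}")
    if wavelengths is not None:
        wl = ", ".join(f"{w:.4f}" for w in wavelengths)
        hdr.append("wavelength units = Nanometers")
        hdr.append(f"wavelength = {{{wl}}}")
    path.with_suffix(path.suffix + ".hdr").write_text("\n".join(hdr) + "\n")
    return path


def _parse_envi_header(text: str) -> dict:
    meta = {}
    key, buf = None, ""
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            if val.startswith("{") and "}" not in val:
                buf = val[1:]
                continue
            meta[key.lower()] = val.strip("{} ")
            key = None
        else:
            if "}" in line:
                buf += " " + line.split("}")[0]
                meta[key.lower()] = buf.strip()
                key, buf = None, ""
            else:
                buf += " " + line
    return meta


def read_envi(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ENVI cube back as (lines, samples, bands) + header dict."""
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    meta = _parse_envi_header(hdr_path.read_text())
    lines = int(meta["lines"])
    samples = int(meta["samples"])
    bands = int(meta["bands"])
    dtype = _ENVI_DTYPES[int(meta["data type"])]
    interleave = meta.get("interleave", "bil").lower()
    raw = np.fromfile(path, dtype=dtype)
    if interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        data = raw.reshape(lines, samples, bands)
    if "wavelength" in meta:
        meta["wavelengths"] = np.array(
            [float(w) for w in meta["wavelength"].split(",")])
    return data, meta


def write_geotiff(path: str | Path, array: np.ndarray, pixel_size: float,
                  origin: tuple[float, float]) -> Path:
    """Single- or multi-band GeoTIFF with pixel-scale/tiepoint geo tags."""
    path = Path(path)
    extratags = [
        (33550, "d", 3, (float(pixel_size), float(pixel_size), 0.0)),
        (33922, "d", 6, (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0)),
    ]
    tifffile.imwrite(path, array, extratags=extratags)
    return path


def read_geotiff(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float]]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = tif.asarray()
        scale = page.tags[33550].value
        tie = page.tags[33922].value
    return arr, float(scale[0]), (float(tie[3]), float(tie[4]))


def write_pose_csv(path: str | Path, t, pos, att, cov_diag=None) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        head = ["t", "x", "y", "z", "roll", "pitch", "yaw"]
        if cov_diag is not None:
            head += [f"var{i}" for i in range(cov_diag.shape[1])]
        w.writerow(head)
        for i in range(len(t)):
            row = [t[i], *pos[i], *att[i]]
            if cov_diag is not None:
                row += list(cov_diag[i])
            w.writerow([f"{v:.10g}" for v in row])
    return path


def read_pose_csv(path: str | Path):
    data = np.genfromtxt(path, delimiter=",", names=True)
    t = np.atleast_1d(data["t"])
    pos = np.column_stack([data["x"], data["y"], data["z"]])
    att = np.column_stack([data["roll"], data["pitch"], data["yaw"]])
    return t, np.atleast_2d(pos), np.atleast_2d(att)


def write_labels_csv(path: str | Path, labels) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["row", "col", "class", "role"])
        for r, c, lbl, role in zip(labels.rows, labels.cols, labels.labels,
                                   labels.role):
            w.writerow([int(r), int(c), lbl, role])
    return path


def read_labels_csv(path: str | Path):
    from gyrospec.classification import LabelSet
    rows, cols, lbls, roles = [], [], [], []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(int(rec["row"]))
            cols.append(int(rec["col"]))
            lbls.append(rec["class"])
            roles.append(rec["role"])
    return LabelSet(rows=np.array(rows), cols=np.array(cols),
                    labels=np.array(lbls, dtype=str),
                    role=np.array(roles, dtype=str))


def write_gcps_csv(path: str | Path, gcps) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_img", "y_img", "x_ref", "y_ref"])
        for (xi, yi), (xr, yr) in zip(gcps.image_xy, gcps.ref_xy):
            w.writerow([f"{xi:.6f}", f"{yi:.6f}", f"{xr:.6f}", f"{yr:.6f}"])
    return path


def read_gcps_csv(path: str | Path):
    from gyrospec.geocorrection import GcpSet
    data = np.genfromtxt(path, delimiter=",", names=True)
    img = np.column_stack([np.atleast_1d(data["x_img"]), np.atleast_1d(data["y_img"])])
    ref = np.column_stack([np.atleast_1d(data["x_ref"]), np.atleast_1d(data["y_ref"])])
    return GcpSet(image_xy=img, ref_xy=ref)


def write_library_csv(path: str | Path, lib) -> Path:
    """Wavelength column + one column per class/condition endmember."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["wavelength_nm"]
        cols = []
        for name in lib.classes:
            for cond, tag in ((0.0, "vigorous"), (1.0, "stressed")):
                header.append(f"{name}_{tag}")
                cols.append(lib.endmember(name, cond))
        w.writerow(header)
        for i, wl in enumerate(lib.band_centers):
            w.writerow([f"{wl:.4f}"] + [f"{c[i]:.6f}" for c in cols])
    return path


def write_envi_spectral_library(path: str | Path, lib) -> Path:
    """ENVI spectral-library file (.sli + header): one row per endmember."""
    path = Path(path)
    names, rows = [], []
    for name in lib.classes:
        for cond, tag in ((0.0, "vigorous"), (1.0, "stressed")):
            names.append(f"{name}_{tag}")
            rows.append(lib.endmember(name, cond))
    arr = np.asarray(rows, dtype=np.float32)
    arr.tofile(path)
    wl = ", ".join(f"{w:.4f}" for w in lib.band_centers)
    hdr = [
        "ENVI",
        "description = {gyrospec spectral library}",
        f"samples = {arr.shape[1]}",
        f"lines = {arr.shape[0]}",
        "bands = 1",
        "header offset = 0",
        "file type = ENVI Spectral Library",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        f"spectra names = {{{', '.join(names)}}}",
        "wavelength units = Nanometers",
        f"wavelength = {{{wl}}}",
    ]
    path.with_suffix(path.suffix + ".hdr").write_text("\n".join(hdr) + "\n")
    return path
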