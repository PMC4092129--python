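# gyrospec

Desk-scale simulator and analysis pipeline for ultralight airborne imaging
spectroscopy applied to invasive-plant detection.  The package generates
everything it needs synthetically — terrain, species patch maps (clonal
discs plus sub-pixel "tendrils"), a 200-band VNIR spectral library with
strong within-class variability — then flies an unstable pushbroom sensor
over the scene, fuses noisy GPS/IMU streams into a per-line AHRS with a
Kalman filter, orthorectifies the cube by ray–DTM intersection with GCP
residual refinement, classifies every pixel with a full-band RBF SVM, and
assesses the map with a stratified validation sample, 2×2 error matrices,
user's/producer's/overall accuracy and Cohen's kappa under a sub-pixel
detection threshold (0.125 m² for 0.5 m pixels).

## Modules

| module | role |
|---|---|
| `gyrospec.spectral_scene` | DTM, patch maps, spectral library, coverage maps |
| `gyrospec.flight_dynamics` | AR(1) attitude trajectories, GPS/IMU simulation, Kalman AHRS |
| `gyrospec.pushbroom` | forward model: footprint mixing, sensor noise, line-ordered cubes |
| `gyrospec.geocorrection` | ray–DTM orthorectification, nearest-neighbor gathering, GCP warps |
| `gyrospec.classification` | training-pixel selection (incl. mixed pixels), SVM, map prediction |
| `gyrospec.accuracy` | detection threshold, validation sampling, error matrices, kappa |
| `gyrospec.pipeline` / `gyrospec.cli` | configured, seeded, manifested end-to-end runs |
| `gyrospec.formats` | ENVI BIL/BSQ + header, GeoTIFF (tifffile tags), CSV sidecars |

## CLI

```bash
gyrospec run --config run.yaml          # full pipeline, prints the report
gyrospec simulate-scene --out scene/    # scene rasters + spectral library
gyrospec fly --length 500 --out pose    # trajectory + fused AHRS CSVs
gyrospec geocorrect --cube cube.bil --pose pose.csv --dtm dtm.tif \
    --pixel-size 0.5 --fov 0.703 --out ortho.bsq
gyrospec classify --ortho ortho.bsq --labels labels.csv --out map.tif
gyrospec validate --classified map.tif --truth coverage.tif \
    --n-target 100 --n-other 250 --seed 1
gyrospec report --matrix 93 7 9 241     # metrics for a 2x2 error matrix
```

A run configuration is a YAML file with blocks `scene`, `flight`,
`sensor`, `geocorrection`, `classification`, `validation` plus a master
`seed`; every stochastic stage receives a sub-seed hashed from
(master seed, stage name), so identical configs byte-reproduce the
report.  All artifacts are listed in `manifest.json` with their seed and
content hash.

## Conventions

Map coordinates in meters, x east / y north, pixel-center
georeferencing, 0-based indices with row 0 at maximum northing,
half-open extents.  Body axes coincide with map axes at zero attitude;
attitude is applied as Rz(yaw)·Ry(pitch)·Rx(roll).  Spectra pass through
geocorrection bit-unchanged (nearest-neighbor gathering).  Accuracies are
reported in percent rounded half-up to 1 decimal; kappa is truncated to
3 decimals; unrounded values are always retained alongside.
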