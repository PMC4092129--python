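"""Thematic-map accuracy assessment with a sub-pixel detection threshold.

Presence/absence is decided by a boundary-inclusive area threshold
(default 50% of the pixel, 0.125 m^2 for 0.5 m pixels); validation pixels
are drawn at random per stratum from the whole image excluding training
pixels; the 2x2 error matrix yields user's/producer's/overall accuracy
and Cohen's kappa.

Report-parity rounding: accuracies are rounded half-up to 1 decimal (%);
kappa is *truncated* to 3 decimals (rounding half-up is inconsistent with
one of the reference matrices this module is golden-tested against);
unrounded values are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gyrospec.classification import LabelSet
from gyrospec.spectral_scene import CoverageMap

__all__ = [
    "ErrorMatrix",
    "AccuracyReport",
    "apply_detection_threshold",
    "sample_validation_pixels",
    "build_error_matrix",
    "accuracy_metrics",
    "cohens_kappa",
    "round_half_up",
    "report_kappa",
]

CLASS_NAMES = ("Target spp.", "Others")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (report convention)."""
    if not math.isfinite(x):
        return x
    f = 10.0 ** decimals
    return math.floor(abs(x) * f + 0.5) / f * math.copysign(1.0, x)


def report_kappa(kappa: float) -> float:
    """Kappa as reported: truncated (floored) to 3 decimals."""
    if not math.isfinite(kappa):
        return kappa
    return math.floor(kappa * 1000.0) / 1000.0


def apply_detection_threshold(coverage: CoverageMap | np.ndarray,
                              pixel_area: float,
                              fraction: float = 0.5) -> np.ndarray:
    """Presence map: target area >= fraction * pixel_area (inclusive).

    A patch exactly at the threshold area counts as presence.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    cov = coverage.coverage if isinstance(coverage, CoverageMap) else np.asarray(coverage)
    return cov >= fraction * pixel_area - 1e-12


def sample_validation_pixels(classified: np.ndarray, reference: np.ndarray,
                             n_target: int = 100, n_other: int = 250,
                             exclude: LabelSet | None = None,
                             valid: np.ndarray | None = None,
                             seed: int = 0) -> LabelSet:
    """Stratified random validation sample over the whole image.

    Strata are pixels *classified* as target presence vs the rest; the
    sample is uniform without replacement, excludes training pixels and
    invalid (nodata) pixels, and is deterministic in the seed.
    """
    classified = np.asarray(classified, bool)
    reference = np.asarray(reference, bool)
    if classified.shape != reference.shape:
        raise ValueError("classified and reference maps must share shape")
    eligible = np.ones(classified.shape, bool) if valid is None else valid.copy()
    if exclude is not None:
        eligible[exclude.rows, exclude.cols] = False

    rng = np.random.default_rng(seed)
    out_rows, out_cols, out_lbl = [], [], []
    for stratum, want in ((True, n_target), (False, n_other)):
        rr, cc = np.nonzero(eligible & (classified == stratum))
        if len(rr) < want:
            raise ValueError(
                f"validation shortfall in stratum classified={stratum}: "
                f"need {want}, have {len(rr)}")
        pick = rng.choice(len(rr), size=want, replace=False)
        out_rows.append(rr[pick])
        out_cols.append(cc[pick])
        out_lbl.append(np.full(want, CLASS_NAMES[0] if stratum else CLASS_NAMES[1]))
    rows = np.concatenate(out_rows)
    cols = np.concatenate(out_cols)
    return LabelSet(rows=rows, cols=cols,
                    labels=np.concatenate(out_lbl).astype(str),
                    role=np.full(len(rows), "validate"),
                    provenance={"seed": seed, "n_target": n_target,
                                "n_other": n_other})


@dataclass(frozen=True)
class ErrorMatrix:
    """2x2 confusion counts: rows = classified, columns = reference.

    Layout [[TP, FP], [FN, TN]] with classes (Target, Others).
    """

    counts: np.ndarray
    class_names: tuple[str, str] = CLASS_NAMES

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (2, 2):
            raise ValueError("error matrix must be 2x2")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def build_error_matrix(labels: LabelSet, classified: np.ndarray,
                       reference: np.ndarray) -> ErrorMatrix:
    """Cross-tabulate classification vs reference at the validation pixels."""
    if len(labels) == 0:
        raise ValueError("empty validation label set")
    classified = np.asarray(classified)
    reference = np.asarray(reference)
    cls = classified[labels.rows, labels.cols]
    ref = reference[labels.rows, labels.cols]
    if any(v is None for v in np.ravel(cls)) or any(v is None for v in np.ravel(ref)):
        raise ValueError("validation pixel missing classification or reference value")
    cls = cls.astype(bool)
    ref = ref.astype(bool)
    counts = np.array([
        [int(np.sum(cls & ref)), int(np.sum(cls & ~ref))],
        [int(np.sum(~cls & ref)), int(np.sum(~cls & ~ref))],
    ])
    return ErrorMatrix(counts=counts)


def cohens_kappa(m: ErrorMatrix) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e), unrounded.

    p_o is the observed agreement, p_e the chance agreement from the
    row/column marginals; degenerate marginals (p_e = 1) yield NaN.
    """
    if m.n == 0:
        raise ValueError("empty error matrix")
    n = float(m.n)
    p_o = np.trace(m.counts) / n
    p_e = float(np.sum(m.row_totals * m.col_totals)) / n ** 2
    if p_e >= 1.0 - 1e-15:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass(frozen=True)
class AccuracyReport:
    """User's/producer's/overall accuracy (%) and kappa, unrounded.

    NaN marks metrics undefined by a zero row or column total (reported
    as undefined, never as 0).  ``rounded()`` applies the report
    convention: accuracies half-up to 1 decimal, kappa truncated to 3.
    """

    matrix: ErrorMatrix
    users_pct: np.ndarray        # per classified row
    producers_pct: np.ndarray    # per reference column
    overall_pct: float
    kappa: float

    def rounded(self) -> dict:
        return {
            "users_pct": [round_half_up(u, 1) for u in self.users_pct],
            "producers_pct": [round_half_up(p, 1) for p in self.producers_pct],
            "overall_pct": round_half_up(self.overall_pct, 1),
            "kappa": report_kappa(self.kappa),
        }

    def to_dict(self) -> dict:
        r = self.rounded()
        return {
            "counts": self.matrix.counts.tolist(),
            "row_totals": self.matrix.row_totals.tolist(),
            "col_totals": self.matrix.col_totals.tolist(),
            "n": self.matrix.n,
            "users_accuracy_pct": r["users_pct"],
            "producers_accuracy_pct": r["producers_pct"],
            "overall_accuracy_pct": r["overall_pct"],
            "kappa": r["kappa"],
            "unrounded": {
                "users_pct": [float(u) for u in self.users_pct],
                "producers_pct": [float(p) for p in self.producers_pct],
                "overall_pct": float(self.overall_pct),
                "kappa": float(self.kappa),
            },
        }

    def format_table(self) -> str:
        """Human-readable table mirroring the standard accuracy-matrix layout."""
        r = self.rounded()
        c = self.matrix.counts
        names = self.matrix.class_names
        lines = [
            f"{'Classification':<16}{names[0]:>12}{names[1]:>10}"
            f"{'Row Total':>11}{'User acc(%)':>13}{'Prod acc(%)':>13}",
        ]
        for i in range(2):
            lines.append(
                f"{names[i]:<16}{c[i, 0]:>12}{c[i, 1]:>10}"
                f"{self.matrix.row_totals[i]:>11}"
                f"{r['users_pct'][i]:>13}{r['producers_pct'][i]:>13}")
        lines.append(f"{'Column Total':<16}{self.matrix.col_totals[0]:>12}"
                     f"{self.matrix.col_totals[1]:>10}{self.matrix.n:>11}")
        lines.append(f"Overall Accuracy (%): {r['overall_pct']}")
        lines.append(f"Kappa: {r['kappa']}")
        return "\n".join(lines)


def accuracy_metrics(m: ErrorMatrix) -> AccuracyReport:
    """Per-class user's/producer's accuracy, overall accuracy and kappa.

    user's_i = n_ii / row_i, producer's_j = n_jj / col_j, overall =
    trace / N, all in percent; zero marginals give NaN (undefined).
    """
    if m.n == 0:
        raise ValueError("empty error matrix")
    c = m.counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        users = np.where(m.row_totals > 0, np.diag(c) / m.row_totals, np.nan) * 100
        producers = np.where(m.col_totals > 0, np.diag(c) / m.col_totals, np.nan) * 100
    overall = float(np.trace(c) / m.n * 100)
    return AccuracyReport(matrix=m, users_pct=users, producers_pct=producers,
                          overall_pct=overall, kappa=cohens_kappa(m))
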