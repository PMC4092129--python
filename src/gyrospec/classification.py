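"""Training-pixel selection and full-band SVM classification.

All bands of the orthoimage feed the classifier unchanged -- no band
reduction anywhere on the path from cube to decision function.  Training
pixels are drawn from a labeling window on the analysis grid, with a
configurable fraction of *mixed* target pixels (sub-pixel coverage), which
is what makes sub-pixel patches learnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from gyrospec.geocorrection import OrthoImage
from gyrospec.spectral_scene import CoverageMap

__all__ = [
    "LabelSet",
    "TrainedClassifier",
    "ShortfallError",
    "select_training_pixels",
    "train_svm",
    "predict_map",
    "collapse_to_binary",
]

TARGET_LABEL = "target"


class ShortfallError(ValueError):
    """Not enough candidate pixels for a requested class."""


@dataclass(frozen=True)
class LabelSet:
    """Labeled pixel indices with their role (train or validate)."""

    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray            # class name per pixel
    role: np.ndarray              # 'train' | 'validate'
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.rows)
        if not (len(self.cols) == len(self.labels) == len(self.role) == n):
            raise ValueError("label arrays must share length")
        bad = set(np.unique(self.role)) - {"train", "validate"}
        if bad:
            raise ValueError(f"unknown roles {bad}")

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, role: str) -> "LabelSet":
        m = self.role == role
        return LabelSet(self.rows[m], self.cols[m], self.labels[m],
                        self.role[m], dict(self.provenance))

    def index_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    @staticmethod
    def concatenate(parts: list["LabelSet"]) -> "LabelSet":
        return LabelSet(
            rows=np.concatenate([p.rows for p in parts]),
            cols=np.concatenate([p.cols for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            role=np.concatenate([p.role for p in parts]),
        )


def _sample(rng, rows, cols, n, what):
    if len(rows) < n:
        raise ShortfallError(
            f"need {n} {what} pixels, only {len(rows)} available")
    pick = rng.choice(len(rows), size=n, replace=False)
    return rows[pick], cols[pick]


def select_training_pixels(ortho: OrthoImage, coverage: CoverageMap,
                           class_map: np.ndarray, class_names: list[str],
                           window: tuple[int, int, int, int],
                           n_per_class: int, mixed_fraction: float = 0.3,
                           threshold_fraction: float = 0.5,
                           seed: int = 0,
                           target_class: str | None = None) -> LabelSet:
    """Sample training pixels per class from a labeling window.

    window = (row0, col0, height, width) on the analysis grid.  For the
    target class a ``mixed_fraction`` share of the sample comes from mixed
    pixels (coverage above the detection threshold but below a full
    pixel); the rest are pure.  Background classes are sampled from pixels
    with zero target coverage and the given majority class.  Deterministic
    in the seed; a shortfall raises naming the class.
    """
    if not 0.0 <= mixed_fraction <= 1.0:
        raise ValueError("mixed_fraction must lie in [0, 1]")
    r0, c0, hh, ww = window
    rows_total, cols_total = ortho.shape
    if r0 < 0 or c0 < 0 or r0 + hh > rows_total or c0 + ww > cols_total:
        raise ValueError(f"window {window} outside image {ortho.shape}")
    target_class = target_class or class_names[0]

    rng = np.random.default_rng(seed)
    in_win = np.zeros(ortho.shape, bool)
    in_win[r0:r0 + hh, c0:c0 + ww] = True
    usable = in_win & ~ortho.nodata

    cov = coverage.coverage
    area = coverage.pixel_area
    thr = threshold_fraction * area
    eps = 1e-9
    pure = usable & (cov >= area - eps)
    mixed = usable & (cov >= thr - eps) & (cov < area - eps)

    n_mixed = int(round(mixed_fraction * n_per_class))
    n_pure = n_per_class - n_mixed
    parts = []

    pr, pc = np.nonzero(pure)
    mr, mc = np.nonzero(mixed)
    tr = _sample(rng, pr, pc, n_pure, f"pure {target_class}")
    tm = _sample(rng, mr, mc, n_mixed, f"mixed {target_class}")
    rows = np.concatenate([tr[0], tm[0]])
    cols = np.concatenate([tr[1], tm[1]])
    parts.append((rows, cols, target_class))

    t_idx = class_names.index(target_class)
    for c_idx, name in enumerate(class_names):
        if c_idx == t_idx:
            continue
        m = usable & (class_map == c_idx) & (cov <= eps)
        br, bc = np.nonzero(m)
        parts.append((*_sample(rng, br, bc, n_per_class, name), name))

    all_rows = np.concatenate([p[0] for p in parts])
    all_cols = np.concatenate([p[1] for p in parts])
    labels = np.concatenate([np.full(len(p[0]), p[2], dtype=object) for p in parts])
    return LabelSet(rows=all_rows, cols=all_cols,
                    labels=labels.astype(str),
                    role=np.full(len(all_rows), "train"),
                    provenance={"window": window, "seed": seed,
                                "mixed_fraction": mixed_fraction})


@dataclass(frozen=True)
class TrainedClassifier:
    """Fitted decision function over R^B plus training metadata."""

    model: Pipeline | SVC
    classes: list[str]
    n_bands: int
    meta: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.n_bands:
            raise ValueError(
                f"feature dimension {X.shape[1]} != trained {self.n_bands}")
        return self.model.predict(X)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.model.decision_function(X)


DEFAULT_GRID = {"svc__C": [1.0, 10.0, 100.0], "svc__gamma": ["scale", 1.0, 10.0]}


def train_svm(labels: LabelSet, ortho: OrthoImage,
              standardize: bool = False, cv_folds: int = 5,
              param_grid: dict | None = None, seed: int = 0) -> TrainedClassifier:
    """RBF SVM on all bands, hyperparameters by k-fold grid search.

    Deterministic: the SVM training problem is convex and the CV splitter
    is seeded, so retraining on identical inputs reproduces identical
    decision values.
    """
    train = labels.subset("train") if np.any(labels.role == "validate") else labels
    if len(train) == 0:
        raise ValueError("no training pixels")
    classes = sorted(set(train.labels.tolist()))
    if len(classes) < 2:
        raise ValueError(f"degenerate training set: single class {classes}")
    X = ortho.data[train.rows, train.cols].astype(np.float64)
    y = train.labels

    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svc", SVC(kernel="rbf")))
    pipe = Pipeline(steps)
    grid = param_grid or DEFAULT_GRID
    counts = np.unique(y, return_counts=True)[1]
    folds = int(min(cv_folds, counts.min()))
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        search = GridSearchCV(pipe, grid, cv=cv, n_jobs=1)
        search.fit(X, y)
        model = search.best_estimator_
        meta = {"kernel": "rbf", "cv_folds": folds, "seed": seed,
                "best_params": search.best_params_,
                "cv_score": float(search.best_score_)}
    else:
        pipe.fit(X, y)
        model = pipe
        meta = {"kernel": "rbf", "cv_folds": 0, "seed": seed}
    return TrainedClassifier(model=model, classes=classes,
                             n_bands=ortho.n_bands, meta=meta)


def predict_map(clf: TrainedClassifier, ortho: OrthoImage) -> np.ndarray:
    """Per-pixel hard labels; nodata propagates as None (unclassified)."""
    if ortho.n_bands != clf.n_bands:
        raise ValueError(
            f"ortho has {ortho.n_bands} bands, classifier expects {clf.n_bands}")
    out = np.full(ortho.shape, None, dtype=object)
    valid = ~ortho.nodata
    if np.any(valid):
        X = ortho.data[valid].astype(np.float64)
        out[valid] = clf.predict(X)
    return out


def collapse_to_binary(class_map: np.ndarray, target: str = TARGET_LABEL) -> np.ndarray:
    """Target/others presence map; unclassified (None) stays False."""
    flat = class_map.ravel()
    out = np.array([lbl == target for lbl in flat], dtype=bool)
    return out.reshape(class_map.shape)
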