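"""Fisher feature ranking and the two-stage SVM artifact cascade.

Stage 1 separates tumour from hemorrhage/erythrocyte texture; stage 2 looks
for folds, but only inside the area stage 1 called tumour.  Features are
Unser descriptors extracted on configured color planes (by default the
composite u*512 + C plane and luminance), ranked by Fisher's linear
discriminant, with the top-k retained.  Both stages are Gaussian-kernel
SVMs whose hyperparameters come from a small seeded grid search around the
median heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy.spatial.distance import pdist
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, ValidationError
from .masks import MaskRole, RegionMask
from .texture import (
    DEFAULT_TEST_RADIUS,
    DEFAULT_TRAIN_RADIUS,
    PLANE_QUANT_STEPS,
    unser_feature_grid,
    valid_centers,
)

#: Feature planes used by default for artifact classification.
DEFAULT_CLASSIFIER_PLANES = ("composite_uC", "L")
DEFAULT_TOP_K = 8
_GAMMA_FACTORS = (0.1, 1.0, 10.0)
_C_GRID = (0.1, 1.0, 10.0)


def fisher_score(values: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Fisher's discriminant ratio (mu1 - mu2)^2 / (var1 + var2 + eps).

    Population variances; zero when the class means coincide; invariant to
    affine rescaling of the feature.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"fisher_score needs exactly 2 classes, got {len(classes)}")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each class needs >= 2 samples")
    return float((a.mean() - b.mean()) ** 2 / (a.var() + b.var() + eps))


def fisher_ranking(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature Fisher scores and feature indices sorted best-first."""
    X = np.asarray(X, dtype=np.float64)
    scores = np.array([fisher_score(X[:, j], y) for j in range(X.shape[1])])
    order = np.argsort(-scores, kind="stable")
    return scores, order


@dataclass
class CascadeModel:
    """The trained two-stage cascade plus its training metadata."""

    svm_tumour_vs_hemorrhage: SVC
    svm_fold_in_tumour: SVC
    scaler: StandardScaler
    feature_idx: np.ndarray
    fisher_scores: np.ndarray
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "CascadeModel":
        return joblib.load(path)


def extract_patch_features(
    patches: list[np.ndarray],
    planes_fn,
    plane_ids=DEFAULT_CLASSIFIER_PLANES,
    radius_px: int = DEFAULT_TRAIN_RADIUS,
) -> np.ndarray:
    """Unser features at the center of each RGB patch, concatenated over planes.

    ``planes_fn`` maps an RGB patch to a dict of planes (see
    :func:`ki67hotspot.color.color_planes`).
    """
    rows = []
    for patch in patches:
        planes = planes_fn(patch)
        cy, cx = patch.shape[0] // 2, patch.shape[1] // 2
        if cy < radius_px or cx < radius_px:
            raise ValidationError("patch smaller than the neighborhood diameter")
        feats = [
            unser_feature_grid(
                planes[pid], np.array([(cy, cx)]), radius_px,
                step=PLANE_QUANT_STEPS.get(pid),
            )[0]
            for pid in plane_ids
        ]
        rows.append(np.concatenate(feats))
    return np.asarray(rows)


def _fit_svm(X, y, seed):
    """Gaussian-kernel SVC from a small grid search on a seeded held-out split."""
    rng = np.random.default_rng(seed)
    n = len(y)
    order = rng.permutation(n)
    n_val = max(n // 4, 1)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    sq = pdist(X, "sqeuclidean")
    med = np.median(sq[sq > 0]) if np.any(sq > 0) else 1.0
    gamma0 = 1.0 / med
    best = None
    for gf in _GAMMA_FACTORS:
        for c in _C_GRID:
            svm = SVC(kernel="rbf", gamma=gamma0 * gf, C=c, random_state=0)
            svm.fit(X[tr_idx], y[tr_idx])
            acc = float((svm.predict(X[val_idx]) == y[val_idx]).mean())
            if best is None or acc > best[0]:
                best = (acc, svm.gamma, svm.C)
    svm = SVC(kernel="rbf", gamma=best[1], C=best[2], random_state=0)
    svm.fit(X, y)
    return svm, best


def train_cascade(
    features_by_class: dict[str, np.ndarray],
    top_k: int = DEFAULT_TOP_K,
    seed: int = 0,
    metadata: dict | None = None,
) -> CascadeModel:
    """Train the tumour/hemorrhage and tumour/fold SVMs.

    ``features_by_class`` maps class names ('tumour', 'hemorrhage', 'fold')
    to feature matrices extracted at the training radius.  Feature
    selection is Fisher-ranked on the stage-1 problem; the same selection
    feeds both stages so one extraction pass serves the whole cascade.
    """
    for cls in ("tumour", "hemorrhage", "fold"):
        if cls not in features_by_class or len(features_by_class[cls]) == 0:
            raise ValidationError(f"missing training class: {cls}")
    Xt = np.asarray(features_by_class["tumour"], dtype=np.float64)
    Xh = np.asarray(features_by_class["hemorrhage"], dtype=np.float64)
    Xf = np.asarray(features_by_class["fold"], dtype=np.float64)

    X1 = np.vstack([Xt, Xh])
    y1 = np.r_[np.zeros(len(Xt)), np.ones(len(Xh))]
    scores, order = fisher_ranking(X1, y1)
    sel = order[: min(top_k, X1.shape[1])]

    scaler = StandardScaler().fit(np.vstack([Xt, Xh, Xf])[:, sel])
    svm1, grid1 = _fit_svm(scaler.transform(X1[:, sel]), y1, seed)
    X2 = np.vstack([Xt, Xf])
    y2 = np.r_[np.zeros(len(Xt)), np.ones(len(Xf))]
    svm2, grid2 = _fit_svm(scaler.transform(X2[:, sel]), y2, seed + 1)

    meta = dict(metadata or {})
    meta.update(
        {
            "top_k": int(top_k),
            "seed": int(seed),
            "stage1_val_accuracy": grid1[0],
            "stage2_val_accuracy": grid2[0],
            "n_samples": {"tumour": len(Xt), "hemorrhage": len(Xh), "fold": len(Xf)},
        }
    )
    return CascadeModel(
        svm_tumour_vs_hemorrhage=svm1,
        svm_fold_in_tumour=svm2,
        scaler=scaler,
        feature_idx=np.asarray(sel),
        fisher_scores=scores,
        metadata=meta,
    )


def classify_tissue(
    planes: dict[str, np.ndarray],
    tissue_mask: np.ndarray,
    model: CascadeModel,
    stride: int | None = None,
    radius_px: int = DEFAULT_TEST_RADIUS,
    plane_ids=DEFAULT_CLASSIFIER_PLANES,
) -> dict[str, RegionMask]:
    """Run the cascade over a stride grid and rasterize masks back.

    Grid locations whose neighborhood exits the tissue mask are skipped
    (treated as tumour); predictions are rasterized by nearest-grid-point
    assignment.  Returns hemorrhage and fold masks plus the cleaned tumour
    mask (tissue minus both).
    """
    for pid in plane_ids:
        if pid not in planes:
            raise ConfigError(f"plane {pid!r} required by the model is missing")
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    H, W = tissue_mask.shape
    if stride is None:
        stride = radius_px
    hem = np.zeros((H, W), bool)
    fold = np.zeros((H, W), bool)
    if not tissue_mask.any():
        return _package(hem, fold, tissue_mask)

    gy = np.arange(stride // 2, H, stride)
    gx = np.arange(stride // 2, W, stride)
    centers = np.array([(y, x) for y in gy for x in gx], dtype=np.int64)
    on_tissue = tissue_mask[centers[:, 0], centers[:, 1]]
    centers = centers[on_tissue]
    ok = valid_centers((H, W), centers, radius_px, mask=tissue_mask)
    centers = centers[ok]
    if len(centers) == 0:
        return _package(hem, fold, tissue_mask)

    feats = np.concatenate(
        [
            unser_feature_grid(
                planes[pid], centers, radius_px, step=PLANE_QUANT_STEPS.get(pid)
            )
            for pid in plane_ids
        ],
        axis=1,
    )
    Xs = model.scaler.transform(feats[:, model.feature_idx])
    is_hem = model.svm_tumour_vs_hemorrhage.predict(Xs) == 1
    is_fold = np.zeros(len(centers), bool)
    tumour_pts = ~is_hem
    if tumour_pts.any():
        is_fold[tumour_pts] = model.svm_fold_in_tumour.predict(Xs[tumour_pts]) == 1

    # nearest-grid-point rasterization over the tissue area
    label = np.zeros(len(gy) * len(gx), dtype=np.int8)  # 0 tumour, 1 hem, 2 fold
    flat_idx = (
        np.searchsorted(gy, centers[:, 0]) * len(gx) + np.searchsorted(gx, centers[:, 1])
    )
    label[flat_idx[is_hem]] = 1
    label[flat_idx[is_fold]] = 2
    yy, xx = np.nonzero(tissue_mask)
    iy = np.clip(np.round((yy - gy[0]) / stride).astype(int), 0, len(gy) - 1)
    ix = np.clip(np.round((xx - gx[0]) / stride).astype(int), 0, len(gx) - 1)
    pix_label = label[iy * len(gx) + ix]
    hem[yy, xx] = pix_label == 1
    fold[yy, xx] = pix_label == 2
    return _package(hem, fold, tissue_mask)


def _package(hem, fold, tissue_mask):
    tumour = tissue_mask & ~hem & ~fold
    return {
        "hemorrhage": RegionMask(hem, MaskRole.HEMORRHAGE),
        "fold": RegionMask(fold, MaskRole.FOLD),
        "tumour": RegionMask(tumour, MaskRole.TISSUE, meta={"cleaned": True}),
    }
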