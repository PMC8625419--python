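"""Background/foreground pixel classification from local texture features.

Alpha-actinin images are z-scored per image and described per pixel by four
texture planes — local entropy, local standard deviation, local range and a
Gaussian-smoothed intensity (sigma = 5) — then classified by a decision
tree trained on balanced subsamples of labeled images (about 2.5% of each
image's pixels, split equally across classes).  Window sizes default to
9x9 for entropy (on 8-bit-quantized intensities, 256 gray levels) and 5x5
for std and range; all are configurable.  Hyperparameters are chosen by a
seeded 5-fold cross-validated grid search.

The three-way manual annotation (Background / Striated Myocyte / Other)
collapses to Background vs Foreground at this stage; resolving foreground
into striated vs other is structural and lives in `striation_classifier`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters.rank import entropy as rank_entropy
from skimage.morphology import footprint_rectangle
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.tree import DecisionTreeClassifier

from .imaging_io import CLASS_BACKGROUND, CLASS_FOREGROUND, LabelMap

FEATURE_NAMES = ("local_entropy", "local_std", "local_range", "gaussian_smoothed")

DEFAULT_GRID = {
    "max_depth": [4, 6, 8, 12, 16],
    "min_samples_leaf": [1, 5, 20, 100],
}


@dataclass
class TextureParams:
    entropy_window: int = 9
    std_window: int = 5
    range_window: int = 5
    gaussian_sigma: float = 5.0
    standardize: bool = True

    def __post_init__(self) -> None:
        for w in (self.entropy_window, self.std_window, self.range_window):
            if w < 1 or w % 2 == 0:
                raise ValueError("window sizes must be odd and >= 1")


@dataclass
class TextureFeatureStack:
    planes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) != 1:
            raise ValueError("feature planes must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    def as_matrix(self) -> np.ndarray:
        """(n_pixels, 4) feature matrix in canonical feature order."""
        return np.column_stack([self.planes[name].ravel() for name in FEATURE_NAMES])


@dataclass
class PixelTrainingSet:
    features: np.ndarray  # (n, 4)
    labels: np.ndarray
    fraction: float
    class_counts: dict[int, int]
    shortfalls: dict[int, int]
    seed: int


def per_image_budget(shape: tuple[int, int], fraction: float) -> int:
    """Number of training pixels drawn from one image: floor(fraction * H * W)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return int(np.floor(fraction * shape[0] * shape[1]))


def compute_texture_features(
    image: np.ndarray, params: TextureParams | None = None
) -> TextureFeatureStack:
    """Four same-shape texture planes; borders handled by reflection."""
    params = params or TextureParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if max(params.entropy_window, params.std_window, params.range_window) > min(img.shape):
        raise ValueError("texture window larger than image")
    if params.standardize:
        # robust per-image standardization: median/MAD anchors the background
        # mode of the intensity distribution, so images differing only in how
        # much signal they contain still agree on what background looks like
        med = np.median(img)
        mad = np.median(np.abs(img - med))
        scale = 1.4826 * mad if mad > 0 else (img.std() or 1.0)
        img = (img - med) / scale

    # entropy operates on 8-bit gray levels; quantize the (possibly z-scored)
    # intensities over their own range so a constant image maps to one bin
    lo, hi = img.min(), img.max()
    if hi > lo:
        q = np.round((img - lo) / (hi - lo) * 255).astype(np.uint8)
    else:
        q = np.zeros(img.shape, dtype=np.uint8)
    ent = rank_entropy(q, footprint_rectangle((params.entropy_window, params.entropy_window)))

    mean = ndimage.uniform_filter(img, params.std_window, mode="reflect")
    meansq = ndimage.uniform_filter(img * img, params.std_window, mode="reflect")
    local_std = np.sqrt(np.clip(meansq - mean * mean, 0.0, None))

    local_range = ndimage.maximum_filter(
        img, params.range_window, mode="reflect"
    ) - ndimage.minimum_filter(img, params.range_window, mode="reflect")

    smoothed = ndimage.gaussian_filter(img, params.gaussian_sigma, mode="reflect")
    return TextureFeatureStack(
        {
            "local_entropy": ent.astype(float),
            "local_std": local_std,
            "local_range": local_range,
            "gaussian_smoothed": smoothed,
        }
    )


def subsample_balanced(
    feature_stacks: list[TextureFeatureStack],
    label_maps: list[np.ndarray],
    fraction: float = 0.025,
    seed: int = 0,
) -> PixelTrainingSet:
    """Balanced per-image pixel subsample.

    Each image contributes ``floor(fraction * n_pixels)`` training pixels,
    split equally across the classes present overall; a class with fewer
    pixels than its share in some image is sampled exhaustively there and
    the shortfall recorded.
    """
    if len(feature_stacks) != len(label_maps) or not feature_stacks:
        raise ValueError("need matching, nonempty feature and label lists")
    all_labels = np.concatenate([np.asarray(lm).ravel() for lm in label_maps])
    classes = np.unique(all_labels)
    if classes.size < 2:
        raise ValueError("labels must cover at least two classes")

    rng = np.random.default_rng(seed)
    rows, labs = [], []
    class_counts = {int(c): 0 for c in classes}
    shortfalls = {int(c): 0 for c in classes}
    for stack, lm in zip(feature_stacks, label_maps):
        lm = np.asarray(lm)
        if lm.shape != stack.shape:
            raise ValueError("label map shape must match feature shape")
        budget = per_image_budget(lm.shape, fraction)
        share = budget // classes.size
        mat = stack.as_matrix()
        flat = lm.ravel()
        for c in classes:
            idx = np.flatnonzero(flat == c)
            take = min(share, idx.size)
            if take < share:
                shortfalls[int(c)] += share - take
            if take == 0:
                continue
            chosen = rng.choice(idx, size=take, replace=False)
            rows.append(mat[chosen])
            labs.append(flat[chosen])
            class_counts[int(c)] += take
    return PixelTrainingSet(
        features=np.vstack(rows),
        labels=np.concatenate(labs).astype(np.int64),
        fraction=fraction,
        class_counts=class_counts,
        shortfalls=shortfalls,
        seed=seed,
    )


@dataclass
class PixelClassifierModel:
    """A fitted decision tree stored as plain arrays.

    Prediction traverses the serialized arrays directly, so a model written
    to JSON and read back produces bit-identical label maps.
    """

    feature_idx: np.ndarray  # split feature per node, -2 for leaves
    threshold: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    leaf_class: np.ndarray  # majority class per node
    classes: list[int]
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    hyperparameters: dict = field(default_factory=dict)
    training_accuracy: float = float("nan")
    seed: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature_idx[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            feat = self.feature_idx[node[idx]]
            go_left = X[idx, feat] <= self.threshold[node[idx]]
            node[idx[go_left]] = self.children_left[node[idx[go_left]]]
            node[idx[~go_left]] = self.children_right[node[idx[~go_left]]]
            active = self.feature_idx[node] >= 0
        return self.leaf_class[node]

    def to_json(self, path: str) -> None:
        payload = {
            "feature_idx": self.feature_idx.tolist(),
            "threshold": self.threshold.tolist(),
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "leaf_class": self.leaf_class.tolist(),
            "classes": list(map(int, self.classes)),
            "feature_names": list(self.feature_names),
            "hyperparameters": self.hyperparameters,
            "training_accuracy": self.training_accuracy,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "PixelClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_idx=np.asarray(d["feature_idx"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=float),
            children_left=np.asarray(d["children_left"], dtype=np.int64),
            children_right=np.asarray(d["children_right"], dtype=np.int64),
            leaf_class=np.asarray(d["leaf_class"], dtype=np.int64),
            classes=list(d["classes"]),
            feature_names=list(d["feature_names"]),
            hyperparameters=d["hyperparameters"],
            training_accuracy=d["training_accuracy"],
            seed=d["seed"],
        )


def train_pixel_classifier(
    training_set: PixelTrainingSet,
    search_grid: dict | None = None,
    seed: int = 0,
    cv_folds: int = 5,
) -> PixelClassifierModel:
    """Fit a decision tree with hyperparameters chosen by seeded k-fold CV."""
    classes = np.unique(training_set.labels)
    if classes.size < 2:
        raise ValueError("training set is degenerate: a single class present")
    grid = search_grid or DEFAULT_GRID
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        DecisionTreeClassifier(random_state=seed),
        param_grid=grid,
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
    )
    search.fit(training_set.features, training_set.labels)
    tree = search.best_estimator_.tree_
    sk = search.best_estimator_
    leaf_class = sk.classes_[np.argmax(tree.value[:, 0, :], axis=1)].astype(np.int64)
    model = PixelClassifierModel(
        feature_idx=tree.feature.astype(np.int64),
        threshold=tree.threshold.astype(float),
        children_left=tree.children_left.astype(np.int64),
        children_right=tree.children_right.astype(np.int64),
        leaf_class=leaf_class,
        classes=list(map(int, sk.classes_)),
        hyperparameters=dict(search.best_params_),
        seed=seed,
    )
    model.training_accuracy = float(
        np.mean(model.predict(training_set.features) == training_set.labels)
    )
    return model


def classify_foreground(model: PixelClassifierModel, features: TextureFeatureStack) -> LabelMap:
    """Per-pixel Background vs Foreground-unresolved labels."""
    if list(features.planes.keys()) != list(model.feature_names):
        raise ValueError(
            f"feature-name mismatch: model expects {model.feature_names}, "
            f"got {list(features.planes.keys())}"
        )
    pred = model.predict(features.as_matrix()).reshape(features.shape)
    out = np.where(pred == CLASS_BACKGROUND, CLASS_BACKGROUND, CLASS_FOREGROUND)
    return LabelMap(out.astype(np.int64), "class")
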