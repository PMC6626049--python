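"""Conduit autofluorescence segmentation and subtraction.

The chitosan conduit wall retains autofluorescence that interferes with the
fiber signal. We segment it by supervised pixel classification — per-voxel
intensity/texture features feeding a random forest, mirroring the behaviour of
interactive pixel-classification tools — and replace conduit voxels with the
stack's robust background level. Replacing with the background median rather
than zero avoids carving dark edges into the image that would later trigger
false spot detections.

Classes are fixed: 0 = background, 1 = conduit, 2 = fiber-signal.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .errors import ParameterError, ShapeError
from .io import CalibratedStack

CLASS_NAMES = ("background", "conduit", "fiber")
BACKGROUND, CONDUIT, FIBER = 0, 1, 2


@dataclass(frozen=True)
class VoxelLabelMask:
    """Per-voxel class labels aligned to a source stack."""

    labels: np.ndarray  # uint8, values in {0, 1, 2}
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ShapeError(f"labels must be 3D, got ndim={lab.ndim}")
        if lab.size and int(lab.max()) >= len(self.class_names):
            raise ShapeError("labels contain values outside the class set")
        object.__setattr__(self, "labels", lab.astype(np.uint8))


def feature_names(scales_um) -> list[str]:
    names = ["intensity"]
    for s in scales_um:
        names += [f"gauss_{s}um", f"gradmag_{s}um", f"var_{s}um"]
    return names


def extract_features(stack: CalibratedStack, scales_um) -> np.ndarray:
    """Per-voxel features: raw intensity plus, per physical scale, Gaussian-
    smoothed intensity, gradient magnitude and local (windowed) variance.

    Scales are in µm and converted per axis via the voxel spacing. Returns an
    ``(n_features, z, y, x)`` float32 array. The local variance at scale *s*
    uses a uniform window of half-width *s* per axis (at least one voxel).
    """
    scales_um = tuple(float(s) for s in scales_um)
    if len(scales_um) < 1:
        raise ParameterError("extract_features needs at least one scale")
    half_voxel = 0.5 * min(stack.spacing_um)
    for s in scales_um:
        if s < half_voxel:
            raise ParameterError(
                f"feature scale {s} µm is below half a voxel ({half_voxel} µm)"
            )
    img = stack.intensities.astype(np.float64)
    spacing = stack.spacing_um
    feats = [img]
    for s in scales_um:
        sigma = tuple(s / d for d in spacing)
        feats.append(ndimage.gaussian_filter(img, sigma))
        feats.append(ndimage.gaussian_gradient_magnitude(img, sigma))
        size = tuple(2 * max(1, int(round(s / d))) + 1 for d in spacing)
        mean = ndimage.uniform_filter(img, size)
        mean2 = ndimage.uniform_filter(img * img, size)
        feats.append(np.clip(mean2 - mean * mean, 0.0, None))
    return np.stack(feats).astype(np.float32)


def _feature_spec_hash(scales_um, n_features: int) -> str:
    payload = repr((tuple(float(s) for s in scales_um), int(n_features))).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PixelClassifierModel:
    """A trained voxel classifier plus the feature specification it expects."""

    forest: RandomForestClassifier
    scales_um: tuple[float, ...]
    class_names: tuple[str, ...]
    seed: int
    n_samples: int

    @property
    def feature_spec(self) -> str:
        return _feature_spec_hash(self.scales_um, 1 + 3 * len(self.scales_um))

    def save(self, path) -> None:
        joblib.dump(
            {
                "forest": self.forest,
                "scales_um": self.scales_um,
                "class_names": self.class_names,
                "seed": self.seed,
                "n_samples": self.n_samples,
                "feature_spec": self.feature_spec,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "PixelClassifierModel":
        d = joblib.load(path)
        model = cls(d["forest"], tuple(d["scales_um"]), tuple(d["class_names"]), d["seed"], d["n_samples"])
        if d.get("feature_spec") != model.feature_spec:
            raise ParameterError("serialized model feature spec does not match its scales")
        return model


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int,
    scales_um,
    samples_per_class: int | None = 4000,
    n_estimators: int = 50,
) -> PixelClassifierModel:
    """Fit a random forest on labelled voxels.

    ``labels`` is a 3D int array aligned with the feature grid; voxels with
    label < 0 are unlabelled and ignored. ``samples_per_class`` caps (and
    balances) the training set; ``None`` uses every labelled voxel.
    """
    if features.ndim != 4:
        raise ShapeError(f"features must be (n_features, z, y, x), got ndim={features.ndim}")
    labels = np.asarray(labels)
    if labels.shape != features.shape[1:]:
        raise ShapeError(
            f"label grid {labels.shape} does not match feature grid {features.shape[1:]}"
        )
    flat_labels = labels.reshape(-1)
    flat_feats = features.reshape(features.shape[0], -1).T
    idx = np.flatnonzero(flat_labels >= 0)
    present = np.unique(flat_labels[idx])
    if present.size < 2:
        raise ParameterError(
            f"training set must contain at least two classes, found {present.tolist()}"
        )
    rng = np.random.default_rng(seed)
    if samples_per_class is not None:
        chosen = []
        for c in present:
            pool = idx[flat_labels[idx] == c]
            if pool.size > samples_per_class:
                pool = rng.choice(pool, size=samples_per_class, replace=False)
            chosen.append(pool)
        idx = np.concatenate(chosen)
    X = flat_feats[idx]
    y = flat_labels[idx]
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=int(seed) % (2**31), n_jobs=1
    )
    forest.fit(X, y)
    return PixelClassifierModel(
        forest, tuple(float(s) for s in scales_um), CLASS_NAMES, int(seed), int(idx.size)
    )


def _predict_volume(model: PixelClassifierModel, features: np.ndarray) -> np.ndarray:
    expected = 1 + 3 * len(model.scales_um)
    if features.shape[0] != expected:
        raise ParameterError(
            f"feature count {features.shape[0]} does not match model spec ({expected} features "
            f"for scales {model.scales_um})"
        )
    shape = features.shape[1:]
    flat = features.reshape(features.shape[0], -1).T
    out = np.empty(flat.shape[0], dtype=np.uint8)
    chunk = 1_000_000
    for start in range(0, flat.shape[0], chunk):
        out[start : start + chunk] = model.forest.predict(flat[start : start + chunk])
    return out.reshape(shape)


def classify_conduit(
    stack: CalibratedStack,
    model: PixelClassifierModel,
    closing_radius_um: float = 2.0,
    features: np.ndarray | None = None,
) -> VoxelLabelMask:
    """Per-voxel argmax classification followed by morphological closing of
    the conduit class, yielding a contiguous wall.

    ``features`` may pass precomputed output of :func:`extract_features` with
    the model's scales to avoid recomputation.
    """
    if features is None:
        features = extract_features(stack, model.scales_um)
    labels = _predict_volume(model, features)
    if closing_radius_um > 0:
        struct_shape = tuple(
            2 * max(1, int(round(closing_radius_um / d))) + 1 for d in stack.spacing_um
        )
        zz, yy, xx = np.indices(struct_shape)
        centers = [(s - 1) / 2 for s in struct_shape]
        dist = (
            ((zz - centers[0]) * stack.spacing_um[0]) ** 2
            + ((yy - centers[1]) * stack.spacing_um[1]) ** 2
            + ((xx - centers[2]) * stack.spacing_um[2]) ** 2
        )
        struct = dist <= closing_radius_um**2
        conduit = ndimage.binary_closing(labels == CONDUIT, structure=struct)
        # closing may only add conduit voxels; never overwrite fiber signal
        labels = np.where(conduit & (labels != FIBER), CONDUIT, labels)
    return VoxelLabelMask(labels)


def read_scribbles(path, shape) -> np.ndarray:
    """Sparse training scribbles from CSV (columns z,y,x,label in voxel
    indices) to a dense label grid with −1 for unlabelled voxels."""
    import pandas as pd

    from .errors import ParseError

    df = pd.read_csv(path)
    for col in ("z", "y", "x", "label"):
        if col not in df.columns:
            raise ParseError(f"{path}: scribble CSV missing column {col!r}")
    labels = np.full(shape, -1, dtype=np.int16)
    z, y, x = (df[c].to_numpy(dtype=int) for c in ("z", "y", "x"))
    if (z < 0).any() or (z >= shape[0]).any() or (y < 0).any() or (y >= shape[1]).any() \
            or (x < 0).any() or (x >= shape[2]).any():
        raise ParseError(f"{path}: scribble coordinates outside the stack shape {shape}")
    labels[z, y, x] = df["label"].to_numpy(dtype=int)
    return labels


def write_mask(mask: VoxelLabelMask, path) -> None:
    """Store a label mask as an 8-bit TIFF."""
    import tifffile

    tifffile.imwrite(path, mask.labels, photometric="minisblack")


def read_mask(path) -> VoxelLabelMask:
    import tifffile

    return VoxelLabelMask(tifffile.imread(path))


def subtract_conduit(stack: CalibratedStack, mask: VoxelLabelMask) -> CalibratedStack:
    """Replace conduit-labelled voxels with the background-class median.

    Voxels outside the conduit class are returned bit-identically; the output
    remains non-negative. With no background-labelled voxel the replacement
    level falls back to the stack's global median.
    """
    if mask.labels.shape != stack.intensities.shape:
        raise ShapeError(
            f"mask shape {mask.labels.shape} does not match stack shape {stack.intensities.shape}"
        )
    out = stack.intensities.copy()
    conduit = mask.labels == CONDUIT
    if conduit.any():
        bg = mask.labels == BACKGROUND
        level = float(np.median(stack.intensities[bg])) if bg.any() else float(np.median(stack.intensities))
        out[conduit] = max(level, 0.0)
    return CalibratedStack(out, stack.spacing_um)
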