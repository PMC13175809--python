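"""Deterministic cleaning, validation, standardization and sampling.

The pipeline turns raw variable-depth three-view studies into
fixed-shape exam tensors ``(3, S, R, R)``:

1. de-duplicate studies by (exam id, content hash);
2. validate: all three views present, finite values, positive dims;
3. per-study min-max scaling to [0, 1];
4. per-slice bilinear resize + center crop to R x R;
5. uniform slice sampling to S slices per view (index ``floor(k*n/S)``);
6. per-study z-score normalization over all pixels of all three views
   (population sd, floored at 1e-8; constant studies map to zeros and
   are flagged degenerate).

Training-time augmentation (small in-plane rotations, horizontal flips)
samples one transform per view per call and applies it to every slice of
that view, keeping anatomy coherent across the stack.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .exceptions import ConfigurationError, InputError
from .synthetic import LABELS, VIEWS

_SD_FLOOR = 1e-8


@dataclass
class RawStudy:
    exam_id: str
    view_arrays: dict[str, np.ndarray]
    labels: dict[str, int] | None = None


@dataclass(frozen=True)
class NormalizationRecord:
    mean: float
    sd: float
    degenerate: bool = False


@dataclass
class ExamTensor:
    """One preprocessed study: views stacked (3, S, R, R) in fixed
    (sagittal, coronal, axial) order."""

    exam_id: str
    views: np.ndarray
    normalization: NormalizationRecord
    labels: dict[str, int] | None = None

    @property
    def label_vector(self) -> np.ndarray:
        if self.labels is None:
            raise InputError(f"exam {self.exam_id} carries no labels")
        return np.array([self.labels[k] for k in LABELS], dtype=np.int64)


@dataclass(frozen=True)
class PreprocessConfig:
    S: int = 32
    R: int = 224
    crop_fraction: float = 1.0
    max_rotation_deg: float = 10.0
    flip_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.S < 1:
            raise ConfigurationError("S must be >= 1")
        if self.R < 8:
            raise ConfigurationError("R must be >= 8")
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ConfigurationError("crop_fraction must be in (0, 1]")


# -- loading -----------------------------------------------------------------

def read_mrnet_layout(root: str | os.PathLike, split: str) -> list[RawStudy]:
    """Read ``<root>/<split>/<view>/<exam>.npy`` and the headerless
    ``<split>-<label>.csv`` label files."""
    root = os.fspath(root)
    labels: dict[str, dict[str, int]] = {}
    for label in LABELS:
        path = os.path.join(root, f"{split}-{label}.csv")
        if os.path.exists(path):
            table = pd.read_csv(path, header=None, names=["exam_id", "value"],
                                dtype={"exam_id": str})
            for _, row in table.iterrows():
                labels.setdefault(row["exam_id"], {})[label] = int(row["value"])
    exam_ids: set[str] = set()
    for view in VIEWS:
        view_dir = os.path.join(root, split, view)
        if os.path.isdir(view_dir):
            exam_ids.update(os.path.splitext(f)[0]
                            for f in os.listdir(view_dir) if f.endswith(".npy"))
    exam_ids = sorted(exam_ids)
    studies = []
    for exam_id in exam_ids:
        arrays = {}
        for view in VIEWS:
            path = os.path.join(root, split, view, f"{exam_id}.npy")
            if os.path.exists(path):
                arrays[view] = np.load(path)
        studies.append(RawStudy(exam_id=exam_id, view_arrays=arrays,
                                labels=labels.get(exam_id)))
    return studies


# -- cleaning ----------------------------------------------------------------

def study_content_hash(study: RawStudy) -> str:
    h = hashlib.sha256()
    h.update(study.exam_id.encode())
    for view in sorted(study.view_arrays):
        h.update(view.encode())
        arr = np.ascontiguousarray(study.view_arrays[view])
        h.update(str(arr.shape).encode())
        h.update(arr.tobytes())
    return h.hexdigest()


def dedupe_studies(studies: list[RawStudy]) -> list[RawStudy]:
    """Keep the first occurrence of each (exam id, content hash); idempotent."""
    seen: set[str] = set()
    survivors = []
    for study in studies:
        key = study_content_hash(study)
        if key not in seen:
            seen.add(key)
            survivors.append(study)
    return survivors


def validate_study(study: RawStudy) -> list[str]:
    """Return the list of failed checks; empty means accepted."""
    reasons = []
    for view in VIEWS:
        if view not in study.view_arrays:
            reasons.append(f"missing view: {view}")
            continue
        arr = study.view_arrays[view]
        if arr.ndim != 3 or min(arr.shape) < 1:
            reasons.append(f"view {view}: non-positive spatial dimensions")
        elif not np.all(np.isfinite(arr)):
            reasons.append(f"view {view}: non-finite values")
    return reasons


# -- standardization ---------------------------------------------------------

def sample_slices(volume: np.ndarray, S: int) -> np.ndarray:
    """Uniform slice indexing: output slice k is input slice floor(k*n/S)."""
    if volume.ndim != 3 or volume.shape[0] < 1:
        raise InputError("volume must be a non-empty rank-3 array")
    n = volume.shape[0]
    idx = (np.arange(S, dtype=np.int64) * n) // S
    return volume[idx]


def resize_and_crop(volume: np.ndarray, R: int,
                    crop_fraction: float = 1.0) -> np.ndarray:
    """Bilinear-resize every slice to R/crop_fraction per side, then
    center-crop to R x R; identical transform for all slices."""
    if not 0.0 < crop_fraction <= 1.0:
        raise ConfigurationError("crop_fraction must be in (0, 1]")
    target = int(round(R / crop_fraction))
    if target < R:
        raise ConfigurationError(
            f"crop size {R} exceeds post-resize extent {target}")
    out = np.empty((volume.shape[0], target, target), dtype=np.float32)
    for k in range(volume.shape[0]):
        out[k] = _sk_resize(volume[k].astype(np.float32), (target, target),
                            order=1, mode="edge", anti_aliasing=False,
                            preserve_range=True)
    off = (target - R) // 2
    return out[:, off:off + R, off:off + R]


def scale_to_unit(views: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-study min-max scaling of intensities to [0, 1]."""
    lo = min(float(v.min()) for v in views.values())
    hi = max(float(v.max()) for v in views.values())
    span = hi - lo
    if span < _SD_FLOOR:
        return {k: np.zeros_like(v, dtype=np.float32) for k, v in views.items()}
    return {k: ((v - lo) / span).astype(np.float32) for k, v in views.items()}


def normalize_study(views: dict[str, np.ndarray]
                    ) -> tuple[dict[str, np.ndarray], NormalizationRecord]:
    """Z-score using one mean/sd over all pixels of all views
    (population sd).  Constant studies map to all zeros, flagged."""
    allpix = np.concatenate([v.ravel() for v in views.values()])
    if allpix.size == 0:
        raise InputError("study contains no pixels")
    mean = float(allpix.mean())
    sd = float(allpix.std())  # population convention
    degenerate = sd < _SD_FLOOR
    denom = max(sd, _SD_FLOOR)
    if degenerate:
        normed = {k: np.zeros_like(v, dtype=np.float32)
                  for k, v in views.items()}
    else:
        normed = {k: ((v - mean) / denom).astype(np.float32)
                  for k, v in views.items()}
    return normed, NormalizationRecord(mean=mean, sd=sd, degenerate=degenerate)


def preprocess_study(study: RawStudy,
                     config: PreprocessConfig) -> ExamTensor:
    """Scale, resize/crop, slice-sample, z-score one accepted study."""
    reasons = validate_study(study)
    if reasons:
        raise InputError(f"study {study.exam_id} rejected: {reasons}")
    scaled = scale_to_unit(study.view_arrays)
    shaped = {view: sample_slices(
        resize_and_crop(scaled[view], config.R, config.crop_fraction),
        config.S) for view in VIEWS}
    normed, record = normalize_study(shaped)
    stacked = np.stack([normed[v] for v in VIEWS], axis=0)
    return ExamTensor(exam_id=study.exam_id, views=stacked,
                      normalization=record, labels=study.labels)


def preprocess_dataset(studies: list[RawStudy], config: PreprocessConfig,
                       manifest_path: str | None = None
                       ) -> tuple[list[ExamTensor], list[dict]]:
    """Dedupe, validate and standardize a set of studies; returns the
    accepted exam tensors and a JSON-lines-style manifest."""
    manifest = []
    exams = []
    for study in dedupe_studies(studies):
        reasons = validate_study(study)
        if reasons:
            manifest.append({"exam_id": study.exam_id, "accepted": False,
                             "reasons": reasons})
            continue
        exam = preprocess_study(study, config)
        manifest.append({"exam_id": study.exam_id, "accepted": True,
                         "reasons": [],
                         "mean": exam.normalization.mean,
                         "sd": exam.normalization.sd,
                         "degenerate": exam.normalization.degenerate})
        exams.append(exam)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            for entry in manifest:
                fh.write(json.dumps(entry) + "\n")
    return exams, manifest


# -- augmentation ------------------------------------------------------------

def augment_exam(exam: ExamTensor, rng: np.random.Generator,
                 max_rotation_deg: float = 10.0,
                 flip_probability: float = 0.5) -> ExamTensor:
    """One rotation angle and one flip decision per view, applied
    identically to all slices of that view; labels unchanged."""
    views = exam.views.copy()
    for v in range(views.shape[0]):
        angle = float(rng.uniform(-max_rotation_deg, max_rotation_deg))
        flip = bool(rng.random() < flip_probability)
        vol = views[v]
        if angle != 0.0:
            vol = ndimage.rotate(vol, angle, axes=(2, 1), reshape=False,
                                 order=1, mode="nearest")
        if flip:
            vol = vol[:, :, ::-1]
        views[v] = vol
    return ExamTensor(exam_id=exam.exam_id, views=views,
                      normalization=exam.normalization, labels=exam.labels)
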