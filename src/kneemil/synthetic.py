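"""Synthetic three-view knee-MRI exam generator.

Emulates the public knee-MRI benchmark layout — one stacked grayscale
slice array per view (sagittal/coronal/axial) per exam plus three
study-level binary labels (abnormal, ACL tear, meniscus tear) — with a
planted, label-dependent intensity signal so the full pipeline is
testable without any download.

Positive exams carry a contiguous bright ellipsoid (intensity raised by
``signal_delta * noise_sd`` over a Gaussian mid-gray background) in a
label-specific subset of views: ACL signal in sagittal+coronal, meniscus
signal in coronal+axial, and tear-free abnormal exams in one random
view.  The view subsets overlap but differ, so the three views carry
complementary evidence and learned view fusion has something to exploit
over single-view pooling.  The label hierarchy (any tear implies
abnormal) holds by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

VIEWS = ("sagittal", "coronal", "axial")
LABELS = ("abnormal", "acl", "meniscus")

#: which views receive planted signal for each tear label
_SIGNAL_VIEWS = {"acl": ("sagittal", "coronal"), "meniscus": ("coronal", "axial")}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    n_exams: int = 200
    prevalence_acl: float = 0.25
    prevalence_meniscus: float = 0.35
    p_abnormal_extra: float = 0.5
    slice_count_range: tuple[int, int] = (20, 48)
    base_resolution: int = 64
    signal_delta: float = 2.0     # lesion offset in units of background sd
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_exams < 1:
            raise ConfigurationError("n_exams must be >= 1")
        for name in ("prevalence_acl", "prevalence_meniscus", "p_abnormal_extra"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.slice_count_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"slice_count_range must satisfy 1 <= min <= max, "
                f"got {self.slice_count_range}")
        if self.base_resolution < 8:
            raise ConfigurationError("base_resolution must be >= 8")
        if self.signal_delta < 0:
            raise ConfigurationError("signal_delta must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")


@dataclass
class SynthExam:
    exam_id: str
    views: dict[str, np.ndarray]          # view -> (slices, H, W) float32
    labels: dict[str, int]                # abnormal / acl / meniscus
    lesion_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        assert set(self.views) == set(VIEWS)
        if self.labels["acl"] or self.labels["meniscus"]:
            assert self.labels["abnormal"] == 1


@dataclass
class SynthDataset:
    exams: list[SynthExam]
    labels: pd.DataFrame                  # columns: exam_id, abnormal, acl, meniscus
    config: SynthConfig


def _ellipsoid_mask(rng: np.random.Generator, n_slices: int,
                    res: int) -> np.ndarray:
    """Random axis-aligned ellipsoid within a central margin."""
    cz = rng.uniform(0.3, 0.7) * n_slices
    cy = rng.uniform(0.3, 0.7) * res
    cx = rng.uniform(0.3, 0.7) * res
    rz = max(1.0, rng.uniform(0.15, 0.30) * n_slices)
    ry = rng.uniform(0.10, 0.20) * res
    rx = rng.uniform(0.10, 0.20) * res
    z, y, x = np.ogrid[:n_slices, :res, :res]
    return (((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2
            + ((x - cx) / rx) ** 2) <= 1.0


def _generate_exam(config: SynthConfig, index: int) -> SynthExam:
    # one substream per exam keyed by (dataset seed, exam counter):
    # insertion-order independent and reproducible
    rng = np.random.default_rng([config.seed, index])
    acl = int(rng.random() < config.prevalence_acl)
    men = int(rng.random() < config.prevalence_meniscus)
    extra = int(rng.random() < config.p_abnormal_extra) if not (acl or men) else 0
    abnormal = int(acl or men or extra)
    labels = {"abnormal": abnormal, "acl": acl, "meniscus": men}

    signal_views: dict[str, bool] = {v: False for v in VIEWS}
    if acl:
        for v in _SIGNAL_VIEWS["acl"]:
            signal_views[v] = True
    if men:
        for v in _SIGNAL_VIEWS["meniscus"]:
            signal_views[v] = True
    if extra:
        signal_views[VIEWS[rng.integers(3)]] = True

    lo, hi = config.slice_count_range
    res = config.base_resolution
    delta = config.signal_delta * config.noise_sd
    views, masks = {}, {}
    for view in VIEWS:
        n_slices = int(rng.integers(lo, hi + 1))
        vol = rng.normal(0.5, config.noise_sd,
                         size=(n_slices, res, res)).astype(np.float32)
        if signal_views[view]:
            mask = _ellipsoid_mask(rng, n_slices, res)
            vol[mask] += delta
            masks[view] = mask
        views[view] = vol
    return SynthExam(exam_id=f"{index:04d}", views=views, labels=labels,
                     lesion_masks=masks)


def generate_dataset(config: SynthConfig, id_offset: int = 0) -> SynthDataset:
    """Generate ``config.n_exams`` exams, deterministic given the seed.

    ``id_offset`` shifts exam numbering (and the per-exam substreams) so
    disjoint splits can be drawn from one seed without id collisions.
    """
    exams = [_generate_exam(config, id_offset + i)
             for i in range(config.n_exams)]
    table = pd.DataFrame(
        [{"exam_id": e.exam_id, **e.labels} for e in exams],
        columns=["exam_id", *LABELS])
    return SynthDataset(exams=exams, labels=table, config=config)


def write_mrnet_layout(dataset: SynthDataset, root: str | os.PathLike,
                       split: str = "train") -> None:
    """Write ``<root>/<split>/<view>/<exam_id>.npy`` plus headerless
    ``<split>-<label>.csv`` files (exam_id, value) at the root."""
    if not dataset.exams:
        raise InputError("refusing to write an empty dataset")
    root = os.fspath(root)
    for view in VIEWS:
        os.makedirs(os.path.join(root, split, view), exist_ok=True)
    for exam in dataset.exams:
        for view in VIEWS:
            np.save(os.path.join(root, split, view, f"{exam.exam_id}.npy"),
                    exam.views[view])
    for label in LABELS:
        dataset.labels[["exam_id", label]].to_csv(
            os.path.join(root, f"{split}-{label}.csv"),
            header=False, index=False)
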