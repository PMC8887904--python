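"""Core in-memory containers for grey-matter images and labelled cohorts.

Grey-matter (GM) maps are per-pixel tissue density/probability images, bounded
in [0, 1].  A :class:`GMSlice` is a single 2D coronal slice; a :class:`GMVolume`
is a 3D stack indexed along its coronal axis (axis 0, 1-based plane numbers).
A :class:`LabeledDataset` pairs slices with :class:`SubjectRecord` metadata and
is the unit that flows through balancing, training and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import ClassBalanceError, ConfigurationError

#: group label encoding used throughout: healthy control = 0, patient = 1
GROUP_LABELS = {"HC": 0, "TLE": 1}


@dataclass
class GMSlice:
    """A single 2D grey-matter density image.

    Parameters
    ----------
    pixels : 2D float array in [0, 1]
    voxel_size_mm : in-plane voxel size (isotropic), millimetres
    plane_index : 1-based coronal plane number this slice came from, if any
    smoothed : whether Gaussian smoothing has been applied
    """

    pixels: np.ndarray
    voxel_size_mm: float = 1.0
    plane_index: Optional[int] = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("GMSlice.pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("GMSlice.pixels must be finite")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def copy(self) -> "GMSlice":
        return replace(self, pixels=self.pixels.copy())


@dataclass
class GMVolume:
    """A 3D grey-matter map; axis 0 is the coronal axis (1-based plane index)."""

    voxels: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("GMVolume.voxels must be 3D")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def n_coronal_planes(self) -> int:
        return self.voxels.shape[0]


@dataclass
class SubjectRecord:
    """Demographic / clinical metadata for one participant.

    ``lesional`` (visually identified hippocampal atrophy) and ``seizure_free``
    (post-surgical outcome, the diagnostic gold standard) are meaningful only
    for patients and must be None for controls.
    """

    subject_id: str
    group: str  # "HC" or "TLE"
    lesional: Optional[bool] = None
    seizure_free: Optional[bool] = None
    site: str = "site1"

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.group == "HC" and (self.lesional is not None or self.seizure_free is not None):
            raise ConfigurationError("lesional/seizure_free flags are TLE-only")

    @property
    def label(self) -> int:
        return GROUP_LABELS[self.group]


@dataclass
class LabeledDataset:
    """Images paired one-to-one with subject records."""

    images: Sequence[GMSlice]
    records: Sequence[SubjectRecord]

    def __post_init__(self) -> None:
        if len(self.images) != len(self.records):
            raise ConfigurationError("images and records must have equal length")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def subject_ids(self) -> list:
        return [r.subject_id for r in self.records]

    def pixel_array(self) -> np.ndarray:
        """Stack all images into an (n, H, W) array."""
        return np.stack([im.pixels for im in self.images])

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices, dtype=int)
        return LabeledDataset(
            images=[self.images[i] for i in indices],
            records=[self.records[i] for i in indices],
        )

    def class_counts(self) -> dict:
        labels = self.labels
        return {"HC": int(np.sum(labels == 0)), "TLE": int(np.sum(labels == 1))}

    @property
    def is_trainable(self) -> bool:
        """True when both classes are represented (required for training)."""
        counts = self.class_counts()
        return counts["HC"] > 0 and counts["TLE"] > 0

    def require_two_classes(self) -> None:
        if not self.is_trainable:
            raise ClassBalanceError(
                f"dataset has a single class: {self.class_counts()}"
            )
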