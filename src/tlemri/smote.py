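"""k-nearest-neighbour SMOTE for image samples.

The study's class imbalance (95 patients vs 202 controls) would let a
classifier reach ~68% accuracy by always predicting "control".  SMOTE
(synthetic minority over-sampling) removes that shortcut by synthesizing
minority-class images until the classes are equal.  For a minority image Xm,
its k = 5 nearest minority neighbours (Euclidean distance over flattened
pixels) are found, one neighbour X̂ is drawn at random, and a synthetic image

    Xs = Xm + (Xm - X̂) * Rd          ("as printed" mode)

is formed, with Rd drawn from the uniform distribution with mean 0 and
standard deviation 1, i.e. U(-√3, √3) — the unique uniform with those
moments.  Classic SMOTE instead interpolates toward the neighbour,
Xs = Xm + (X̂ - Xm) * Rd with Rd ~ U(0, 1); both modes are supported and the
"as printed" form is the default.  Outputs are clipped to [0, 1] because the
inputs are density maps.

Balancing is only ever applied to training data (after the train/test split),
never to validation or test samples; every synthetic sample is logged with
its parent, neighbour and displacement for auditability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import GMSlice, LabeledDataset, SubjectRecord
from .exceptions import PoolSizeError, ShapeError

SQRT3 = math.sqrt(3.0)

AS_PRINTED = "as_printed_uniform_mean0_sd1"
CLASSIC = "classic_uniform01"


@dataclass
class SmoteConfig:
    k: int = 5
    rd_mode: str = AS_PRINTED
    seed: int = 0
    parent_mode: str = "round_robin"  # or "random"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.rd_mode not in (AS_PRINTED, CLASSIC):
            raise ValueError(f"unknown rd_mode {self.rd_mode!r}")
        if self.parent_mode not in ("round_robin", "random"):
            raise ValueError(f"unknown parent_mode {self.parent_mode!r}")


@dataclass
class SyntheticSampleLog:
    """One row per synthesized image: which parent, which neighbour, what Rd."""

    parent_index: List[int] = field(default_factory=list)
    neighbour_index: List[int] = field(default_factory=list)
    rd_value: List[float] = field(default_factory=list)
    parent_subject_id: List[str] = field(default_factory=list)
    neighbour_subject_id: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.parent_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parent_index": self.parent_index,
                "neighbour_index": self.neighbour_index,
                "rd_value": self.rd_value,
                "parent_subject_id": self.parent_subject_id,
                "neighbour_subject_id": self.neighbour_subject_id,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def nearest_neighbours(
    sample: GMSlice,
    pool: Sequence[GMSlice],
    k: int,
    exclude_index: int | None = None,
) -> np.ndarray:
    """Indices of the k pool images closest to ``sample`` in Euclidean distance.

    Distances are over flattened pixels; ties break deterministically by
    ascending pool index (stable sort).  ``exclude_index`` removes the
    sample's own pool slot when querying from within the pool.
    """
    candidates = [i for i in range(len(pool)) if i != exclude_index]
    if len(candidates) < k:
        raise PoolSizeError(f"pool of {len(candidates)} candidates is smaller than k={k}")
    q = sample.pixels.ravel()
    dists = np.array(
        [np.linalg.norm(pool[i].pixels.ravel() - q) for i in candidates]
    )
    order = np.argsort(dists, kind="stable")[:k]
    return np.array([candidates[i] for i in order], dtype=int)


def synthesize_sample(xm: GMSlice, xhat: GMSlice, rd: float, mode: str = AS_PRINTED) -> GMSlice:
    """Form one synthetic sample from parent ``xm`` and neighbour ``xhat``."""
    if xm.pixels.shape != xhat.pixels.shape:
        raise ShapeError(
            f"parent shape {xm.pixels.shape} != neighbour shape {xhat.pixels.shape}"
        )
    if mode == AS_PRINTED:
        pixels = xm.pixels + (xm.pixels - xhat.pixels) * rd
    elif mode == CLASSIC:
        pixels = xm.pixels + (xhat.pixels - xm.pixels) * rd
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GMSlice(
        pixels=np.clip(pixels, 0.0, 1.0),
        voxel_size_mm=xm.voxel_size_mm,
        plane_index=xm.plane_index,
        smoothed=xm.smoothed,
    )


def _draw_rd(rng: np.random.Generator, mode: str) -> float:
    if mode == AS_PRINTED:
        return float(rng.uniform(-SQRT3, SQRT3))
    return float(rng.uniform(0.0, 1.0))


def balance(
    train_set: LabeledDataset, config: SmoteConfig
) -> Tuple[LabeledDataset, SyntheticSampleLog]:
    """Oversample the minority class of a training set until classes are equal.

    Original samples (both classes) are retained untouched; synthetic samples
    carry the minority group label and a ``synthetic`` site tag.  Parents are
    cycled round-robin over the minority samples by default (drawn at random
    in ``parent_mode="random"``).  Deterministic for a fixed config seed.
    """
    train_set.require_two_classes()
    labels = train_set.labels
    counts = train_set.class_counts()
    if counts["HC"] == counts["TLE"]:
        return train_set, SyntheticSampleLog()
    minority_label = 1 if counts["TLE"] < counts["HC"] else 0
    minority_group = "TLE" if minority_label == 1 else "HC"
    minority_idx = np.flatnonzero(labels == minority_label)
    n_needed = abs(counts["HC"] - counts["TLE"])
    if len(minority_idx) < config.k + 1:
        raise PoolSizeError(
            f"minority class of {len(minority_idx)} too small for k={config.k}"
        )

    rng = np.random.default_rng(config.seed)
    pool = [train_set.images[i] for i in minority_idx]
    # precompute each minority member's k neighbours within the minority pool
    neighbour_table = [
        nearest_neighbours(pool[j], pool, config.k, exclude_index=j)
        for j in range(len(pool))
    ]

    log = SyntheticSampleLog()
    new_images = list(train_set.images)
    new_records = list(train_set.records)
    for s in range(n_needed):
        if config.parent_mode == "round_robin":
            j = s % len(minority_idx)
        else:
            j = int(rng.integers(len(minority_idx)))
        neigh_local = int(neighbour_table[j][int(rng.integers(config.k))])
        rd = _draw_rd(rng, config.rd_mode)
        parent_global = int(minority_idx[j])
        neigh_global = int(minority_idx[neigh_local])
        synth = synthesize_sample(
            train_set.images[parent_global],
            train_set.images[neigh_global],
            rd,
            config.rd_mode,
        )
        new_images.append(synth)
        new_records.append(
            SubjectRecord(
                subject_id=f"SMOTE{s + 1:04d}",
                group=minority_group,
                lesional=None if minority_group == "HC" else False,
                seizure_free=None if minority_group == "HC" else False,
                site="synthetic",
            )
        )
        log.parent_index.append(parent_global)
        log.neighbour_index.append(neigh_global)
        log.rd_value.append(rd)
        log.parent_subject_id.append(train_set.records[parent_global].subject_id)
        log.neighbour_subject_id.append(train_set.records[neigh_global].subject_id)

    return LabeledDataset(images=new_images, records=new_records), log
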