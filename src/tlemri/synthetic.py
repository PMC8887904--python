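"""Synthetic grey-matter cohort generator.

Generates 2D coronal grey-matter density slices (and optional 3D stacks) with
the statistical structure of a two-group epilepsy imaging study:

* a procedural anatomical template — an elliptical cortical ribbon, central
  subcortical nuclei and bilateral medial-temporal blobs — standing in for a
  normalized, segmented coronal slice;
* controls (HC) and patients (TLE) drawn from the template with per-subject
  spatial jitter and additive noise;
* a left-lateralized medial-temporal intensity reduction in patients, strong
  in a "lesional" subgroup (visually apparent atrophy) and subtle in a
  "non-lesional" subgroup, plus a weaker distributed extra-hippocampal
  reduction;
* site strata with small global intensity offsets and the study's group
  imbalance (95 patients vs 202 controls by default).

The generator is fully deterministic for a fixed seed, which makes every
downstream stage (balancing, training, evaluation, visualization) testable
without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import GMSlice, GMVolume, LabeledDataset, SubjectRecord
from .exceptions import ConfigurationError, SizingError

MIN_TEMPLATE_SIZE = 64


@dataclass
class GMTemplate:
    """Anatomical substrate shared by all subjects of a cohort.

    ``base_map`` holds grey-matter density in [0, 1]; ``roi_masks`` names the
    binary regions used for effect placement and for localization checks:
    ``left_medial_temporal``, ``right_medial_temporal``, ``neocortex``,
    ``subcortical``.  The left/right medial-temporal masks are disjoint and
    excluded from the other masks, so multiplicative effects on any one mask
    change exactly that region.
    """

    base_map: np.ndarray
    roi_masks: dict
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.base_map.min() < 0 or self.base_map.max() > 1:
            raise ValueError("base_map values must lie in [0, 1]")
        for name, mask in self.roi_masks.items():
            if mask.shape != self.base_map.shape:
                raise ValueError(f"roi mask {name!r} shape mismatch")
        lm = self.roi_masks.get("left_medial_temporal")
        rm = self.roi_masks.get("right_medial_temporal")
        if lm is not None and rm is not None and np.any(lm & rm):
            raise ValueError("left/right medial-temporal masks must be disjoint")

    @property
    def shape(self) -> tuple:
        return self.base_map.shape

    def roi_mean(self, roi: str) -> float:
        mask = self.roi_masks[roi]
        return float(self.base_map[mask].mean())


@dataclass
class EffectConfig:
    """Per-subgroup atrophy / nuisance parameters.

    medial_temporal_effect : fractional intensity reduction in [0, 1) applied
        to the *left* medial-temporal ROI of patients (left-lateralized).
    extrahippocampal_effect : fractional reduction in [0, 1) applied to the
        distributed neocortical + subcortical grey matter of patients.
    noise_sd : SD of additive Gaussian pixel noise (applied to everyone).
    jitter_px : max |integer translation| per axis, emulating residual
        misregistration / individual sulcal-gyral positioning.
    erosion_px : optional erosion depth of the medial-temporal blob boundary;
        boundary pixels receive the reduction a second time (volume loss).
    """

    medial_temporal_effect: float = 0.0
    extrahippocampal_effect: float = 0.0
    noise_sd: float = 0.0
    jitter_px: int = 0
    erosion_px: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.medial_temporal_effect < 1:
            raise ConfigurationError("medial_temporal_effect must be in [0, 1)")
        if not 0 <= self.extrahippocampal_effect < 1:
            raise ConfigurationError("extrahippocampal_effect must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.jitter_px < 0 or int(self.jitter_px) != self.jitter_px:
            raise ConfigurationError("jitter_px must be a non-negative integer")


def _gaussian_blob(shape, center, sigma):
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return np.exp(-0.5 * (((rows - center[0]) / sigma) ** 2 + ((cols - center[1]) / sigma) ** 2))


def make_template(height: int, width: int, seed: int, voxel_size_mm: float = 1.0) -> GMTemplate:
    """Build a procedural coronal grey-matter template.

    The anatomy is an elliptical cortical ribbon, two central subcortical
    nuclei, and two dense medial-temporal blobs in the inferior half.  Deep
    medial-temporal grey matter is rendered as the densest structure, as it
    appears on smoothed GM probability maps where hippocampus, amygdala and
    parahippocampal cortex pack closely.  A low-frequency seeded texture adds
    anatomical variation; the result is deterministic for a fixed seed.
    """
    if height < MIN_TEMPLATE_SIZE or width < MIN_TEMPLATE_SIZE:
        raise SizingError(
            f"template must be at least {MIN_TEMPLATE_SIZE}x{MIN_TEMPLATE_SIZE}, "
            f"got {height}x{width}"
        )
    rng = np.random.default_rng(seed)
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0

    # cortical ribbon: elliptical annulus
    r = np.sqrt(((rows - cy) / (0.44 * height)) ** 2 + ((cols - cx) / (0.46 * width)) ** 2)
    ribbon = np.exp(-0.5 * ((r - 0.92) / 0.055) ** 2)
    base = 0.68 * ribbon

    # subcortical nuclei (thalamus / basal ganglia analogue)
    s_sigma = 0.055 * min(height, width)
    for dx in (-0.10, 0.10):
        base += 0.55 * _gaussian_blob(
            (height, width), (cy - 0.06 * height, cx + dx * width), s_sigma
        )

    # medial-temporal blobs, inferior half, bilateral; densest structure
    mt_sigma = 0.05 * min(height, width)
    mt_row = 0.66 * height
    left_c = (mt_row, 0.36 * width)
    right_c = (mt_row, 0.64 * width)
    left_blob = _gaussian_blob((height, width), left_c, mt_sigma)
    right_blob = _gaussian_blob((height, width), right_c, mt_sigma)
    base += 0.85 * left_blob + 0.85 * right_blob

    # low-frequency anatomical texture (seeded)
    texture = ndimage.gaussian_filter(rng.standard_normal((height, width)), 0.06 * min(height, width))
    texture = 0.03 * texture / max(np.abs(texture).max(), 1e-12)
    base = np.clip(base + texture, 0.0, 1.0)
    base = np.clip(ndimage.gaussian_filter(base, 1.0), 0.0, 1.0)

    left_mask = left_blob > 0.4
    right_mask = right_blob > 0.4
    if left_mask.sum() == 0 or right_mask.sum() == 0:
        raise SizingError("dimensions too small to place medial-temporal ROIs")
    mt_union = left_mask | right_mask
    neocortex = (ribbon > 0.45) & ~mt_union
    subcortical = np.zeros((height, width), dtype=bool)
    for dx in (-0.10, 0.10):
        subcortical |= (
            _gaussian_blob((height, width), (cy - 0.06 * height, cx + dx * width), s_sigma) > 0.5
        )
    subcortical &= ~mt_union

    return GMTemplate(
        base_map=base,
        roi_masks={
            "left_medial_temporal": left_mask,
            "right_medial_temporal": right_mask,
            "neocortex": neocortex,
            "subcortical": subcortical,
        },
        voxel_size_mm=voxel_size_mm,
    )


def _apply_atrophy(img: np.ndarray, template: GMTemplate, effects: EffectConfig) -> np.ndarray:
    """Multiplicative intensity reduction on the effect ROIs (patients only)."""
    out = img.copy()
    e = effects.medial_temporal_effect
    if e > 0:
        mask = template.roi_masks["left_medial_temporal"]
        out[mask] *= 1.0 - e
        if effects.erosion_px > 0:
            eroded = ndimage.binary_erosion(mask, iterations=effects.erosion_px)
            out[mask & ~eroded] *= 1.0 - e  # boundary volume loss
    if effects.extrahippocampal_effect > 0:
        distributed = template.roi_masks["neocortex"] | template.roi_masks["subcortical"]
        out[distributed] *= 1.0 - effects.extrahippocampal_effect
    return out


def sample_subject(
    template: GMTemplate,
    group: str,
    effects: EffectConfig,
    rng: np.random.Generator,
) -> GMSlice:
    """Draw one subject's slice: atrophy (TLE only), then jitter, then noise.

    With zero noise and jitter the left medial-temporal ROI mean of a patient
    equals (1 - medial_temporal_effect) times the template ROI mean exactly;
    with noise it holds in expectation (clipping aside).
    """
    if group not in ("HC", "TLE"):
        raise ConfigurationError(f"unknown group {group!r}")
    img = template.base_map.copy()
    if group == "TLE":
        img = _apply_atrophy(img, template, effects)
    if effects.jitter_px > 0:
        shift = rng.integers(-effects.jitter_px, effects.jitter_px + 1, size=2)
        img = ndimage.shift(img, shift, order=0, mode="constant", cval=0.0)
    if effects.noise_sd > 0:
        img = img + rng.normal(0.0, effects.noise_sd, size=img.shape)
    return GMSlice(pixels=np.clip(img, 0.0, 1.0), voxel_size_mm=template.voxel_size_mm)


def sample_volume(
    template: GMTemplate,
    group: str,
    effects: EffectConfig,
    rng: np.random.Generator,
    n_planes: int = 156,
) -> GMVolume:
    """Stack a subject's anatomy into a synthetic coronal volume.

    Planes are the subject's 2D slice modulated by a symmetric smooth
    anterior-posterior profile (peaking mid-volume), with independent noise
    per plane.  This is a deliberately simple stand-in for true 3D anatomy.
    """
    base = template.base_map.copy()
    if group == "TLE":
        base = _apply_atrophy(base, template, effects)
    if effects.jitter_px > 0:
        shift = rng.integers(-effects.jitter_px, effects.jitter_px + 1, size=2)
        base = ndimage.shift(base, shift, order=0, mode="constant", cval=0.0)
    t = np.arange(1, n_planes + 1, dtype=float)
    center = (n_planes + 1) / 2.0
    profile = 0.2 + 0.8 * np.exp(-0.5 * ((t - center) / (0.25 * n_planes)) ** 2)
    voxels = profile[:, None, None] * base[None, :, :]
    if effects.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, effects.noise_sd, size=voxels.shape)
    vs = template.voxel_size_mm
    return GMVolume(voxels=np.clip(voxels, 0.0, 1.0), voxel_size_mm=(vs, vs, vs))


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

#: default per-subgroup effects: lesional atrophy is visually obvious (~35%
#: ROI intensity loss), non-lesional is subtle (~12%), both carry a weak
#: distributed extra-hippocampal reduction; everyone gets the same noise and
#: jitter.  These defaults define the study conditions of the generator.
DEFAULT_LESIONAL = EffectConfig(
    medial_temporal_effect=0.35, extrahippocampal_effect=0.05, noise_sd=0.06, jitter_px=2
)
DEFAULT_NONLESIONAL = EffectConfig(
    medial_temporal_effect=0.12, extrahippocampal_effect=0.05, noise_sd=0.06, jitter_px=2
)
DEFAULT_CONTROL = EffectConfig(noise_sd=0.06, jitter_px=2)


@dataclass
class CohortConfig:
    """Cohort composition; defaults mirror the study's printed counts.

    95 patients (48 lesional / 47 non-lesional; 29 and 28 of them respectively
    seizure-free after surgery) versus 202 controls, recruited across three
    sites.  Sites carry small multiplicative intensity offsets emulating
    scanner differences.
    """

    n_tle: int = 95
    n_hc: int = 202
    n_lesional: int = 48
    n_seizure_free_lesional: int = 29
    n_seizure_free_nonlesional: int = 28
    sites: Tuple[str, ...] = ("MUSC", "Emory", "Bonn")
    tle_site_counts: Optional[Tuple[int, ...]] = (30, 33, 32)
    hc_site_counts: Optional[Tuple[int, ...]] = (49, 74, 79)
    site_intensity: Tuple[float, ...] = (1.0, 0.98, 1.02)
    lesional_effects: EffectConfig = field(default_factory=lambda: DEFAULT_LESIONAL)
    nonlesional_effects: EffectConfig = field(default_factory=lambda: DEFAULT_NONLESIONAL)
    control_effects: EffectConfig = field(default_factory=lambda: DEFAULT_CONTROL)

    def __post_init__(self) -> None:
        if min(self.n_tle, self.n_hc, self.n_lesional) < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_lesional > self.n_tle:
            raise ConfigurationError("n_lesional cannot exceed n_tle")
        if self.n_seizure_free_lesional > self.n_lesional:
            raise ConfigurationError("seizure-free lesional count exceeds lesional count")
        if self.n_seizure_free_nonlesional > self.n_tle - self.n_lesional:
            raise ConfigurationError("seizure-free non-lesional count exceeds subgroup")
        if self.tle_site_counts is None:
            self.tle_site_counts = _even_split(self.n_tle, len(self.sites))
        if self.hc_site_counts is None:
            self.hc_site_counts = _even_split(self.n_hc, len(self.sites))
        if sum(self.tle_site_counts) != self.n_tle:
            raise ConfigurationError("tle_site_counts must sum to n_tle")
        if sum(self.hc_site_counts) != self.n_hc:
            raise ConfigurationError("hc_site_counts must sum to n_hc")
        if len(self.site_intensity) != len(self.sites):
            raise ConfigurationError("site_intensity must match sites")
        if (
            self.n_tle - self.n_lesional > 0
            and self.n_lesional > 0
            and self.lesional_effects.medial_temporal_effect
            < self.nonlesional_effects.medial_temporal_effect
        ):
            raise ConfigurationError(
                "lesional medial-temporal effect must be >= non-lesional effect"
            )

    def scaled(self, n_tle: int, n_hc: int, n_lesional: Optional[int] = None) -> "CohortConfig":
        """A copy with different sample sizes (site allocation near-even)."""
        if n_lesional is None:
            n_lesional = n_tle // 2
        return dataclasses.replace(
            self,
            n_tle=n_tle,
            n_hc=n_hc,
            n_lesional=n_lesional,
            n_seizure_free_lesional=min(self.n_seizure_free_lesional, n_lesional),
            n_seizure_free_nonlesional=min(
                self.n_seizure_free_nonlesional, n_tle - n_lesional
            ),
            tle_site_counts=_even_split(n_tle, len(self.sites)),
            hc_site_counts=_even_split(n_hc, len(self.sites)),
        )


def _even_split(n: int, parts: int) -> Tuple[int, ...]:
    base = n // parts
    extra = n % parts
    return tuple(base + (1 if i < extra else 0) for i in range(parts))


def _site_sequence(sites, counts):
    seq = []
    for s, c in zip(sites, counts):
        seq.extend([s] * c)
    return seq


def generate_cohort(template: GMTemplate, config: CohortConfig, seed: int) -> LabeledDataset:
    """Draw a full labelled cohort; deterministic for a fixed seed.

    Controls come first, then lesional patients, then non-lesional patients.
    Seizure-freedom flags are assigned to the leading members of each patient
    subgroup.  (Downstream splits shuffle, so ordering carries no information.)
    """
    rng = np.random.default_rng(seed)
    intensity = dict(zip(config.sites, config.site_intensity))
    images, records = [], []

    hc_sites = _site_sequence(config.sites, config.hc_site_counts)
    for i in range(config.n_hc):
        site = hc_sites[i]
        sl = sample_subject(template, "HC", config.control_effects, rng)
        sl.pixels = np.clip(sl.pixels * intensity[site], 0.0, 1.0)
        images.append(sl)
        records.append(SubjectRecord(subject_id=f"HC{i + 1:03d}", group="HC", site=site))

    tle_sites = _site_sequence(config.sites, config.tle_site_counts)
    for i in range(config.n_tle):
        lesional = i < config.n_lesional
        if lesional:
            seizure_free = i < config.n_seizure_free_lesional
            effects = config.lesional_effects
        else:
            j = i - config.n_lesional
            seizure_free = j < config.n_seizure_free_nonlesional
            effects = config.nonlesional_effects
        site = tle_sites[i]
        sl = sample_subject(template, "TLE", effects, rng)
        sl.pixels = np.clip(sl.pixels * intensity[site], 0.0, 1.0)
        images.append(sl)
        records.append(
            SubjectRecord(
                subject_id=f"TLE{i + 1:03d}",
                group="TLE",
                lesional=lesional,
                seizure_free=seizure_free,
                site=site,
            )
        )
    return LabeledDataset(images=images, records=records)


# --------------------------------------------------------------------------
# dataset I/O
# --------------------------------------------------------------------------

def _records_frame(dataset: LabeledDataset) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "lesional": r.lesional,
                "seizure_free": r.seizure_free,
                "site": r.site,
            }
            for r in dataset.records
        ]
    )


def save_dataset_nifti(dataset: LabeledDataset, outdir) -> pd.DataFrame:
    """Write one .nii.gz per subject plus a CSV sidecar table; returns the table."""
    import nibabel as nib

    outdir = Path(outdir)
    if not outdir.parent.exists():
        raise FileNotFoundError(f"parent of output directory does not exist: {outdir}")
    outdir.mkdir(exist_ok=True)
    table = _records_frame(dataset)
    filenames = []
    for img, rec in zip(dataset.images, dataset.records):
        vs = img.voxel_size_mm
        affine = np.diag([vs, vs, 1.0, 1.0])
        nii = nib.Nifti1Image(img.pixels[:, :, None].astype(np.float32), affine)
        fname = f"{rec.subject_id}.nii.gz"
        nib.save(nii, str(outdir / fname))
        filenames.append(fname)
    table["filename"] = filenames
    table.to_csv(outdir / "subjects.csv", index=False)
    return table


def load_dataset_nifti(indir) -> LabeledDataset:
    """Load a dataset written by :func:`save_dataset_nifti`."""
    import nibabel as nib

    indir = Path(indir)
    table = pd.read_csv(indir / "subjects.csv")
    images, records = [], []
    for _, row in table.iterrows():
        nii = nib.load(str(indir / row["filename"]))
        vs = float(nii.header.get_zooms()[0])
        pixels = np.asarray(nii.dataobj, dtype=float)[:, :, 0]
        images.append(GMSlice(pixels=np.clip(pixels, 0.0, 1.0), voxel_size_mm=vs))
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                lesional=None if pd.isna(row["lesional"]) else bool(row["lesional"]),
                seizure_free=None if pd.isna(row["seizure_free"]) else bool(row["seizure_free"]),
                site=str(row["site"]),
            )
        )
    return LabeledDataset(images=images, records=records)


def save_archive(dataset: LabeledDataset, path) -> None:
    """Compressed single-file dataset (fast test/interchange format)."""
    table = _records_frame(dataset)
    np.savez_compressed(
        path,
        pixels=dataset.pixel_array().astype(np.float32),
        voxel_size_mm=np.array([im.voxel_size_mm for im in dataset.images]),
        records_csv=table.to_csv(index=False),
    )


def load_archive(path) -> LabeledDataset:
    import io

    with np.load(path, allow_pickle=False) as npz:
        pixels = np.asarray(npz["pixels"], dtype=float)
        voxel = np.asarray(npz["voxel_size_mm"], dtype=float)
        table = pd.read_csv(io.StringIO(str(npz["records_csv"])))
    images = [
        GMSlice(pixels=np.clip(pixels[i], 0.0, 1.0), voxel_size_mm=float(voxel[i]))
        for i in range(pixels.shape[0])
    ]
    records = [
        SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            lesional=None if pd.isna(row["lesional"]) else bool(row["lesional"]),
            seizure_free=None if pd.isna(row["seizure_free"]) else bool(row["seizure_free"]),
            site=str(row["site"]),
        )
        for _, row in table.iterrows()
    ]
    return LabeledDataset(images=images, records=records)
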