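"""Forward-activation map visualization.

For each test image and each convolution layer: take the layer's activation
maps, apply the absolute value (only the magnitude of the response matters),
select the map with the largest summed total, and normalize it to [0, 1] by
its maximum.  Normalized maps are then summed across test images and repeats
and renormalized, yielding one aggregate localization map per layer.  Peaks
of the aggregate maps indicate grey-matter structures driving classification.

Coarse maps are upsampled to slice resolution by nearest-neighbour block
expansion aligned to the stride grid (stride = kernel, so each coarse cell
corresponds to an exact block of the input); peak coordinates are reported at
block centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .datatypes import GMSlice
from .exceptions import ShapeError


@dataclass
class ActivationMap:
    """A non-negative 2D localization map for one layer."""

    values: np.ndarray
    layer: int = 1
    normalized: bool = False
    zero_map: bool = False  # all-zero input flagged rather than divided by 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("activation map must be 2D")
        if np.any(self.values < 0):
            raise ValueError("activation map must be non-negative (apply abs first)")


def select_max_activation_map(stack: np.ndarray, layer: int = 1) -> ActivationMap:
    """Pick the filter map with the largest total absolute activation.

    ``stack`` is (n_filters, h, w); the absolute value is applied before
    summation.  Ties resolve to the lowest filter index.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a non-empty (n_filters, h, w) stack")
    abs_stack = np.abs(stack)
    sums = abs_stack.sum(axis=(1, 2))
    best = int(np.argmax(sums))  # argmax returns the first maximal index
    return ActivationMap(values=abs_stack[best], layer=layer)


def normalize01(amap: ActivationMap) -> ActivationMap:
    """Divide by the largest value so the maximum becomes 1.

    An all-zero map is returned unchanged with ``zero_map`` set (dividing by
    zero would be meaningless); normalization is idempotent.
    """
    peak = float(amap.values.max())
    if peak == 0.0:
        return ActivationMap(values=amap.values.copy(), layer=amap.layer,
                             normalized=True, zero_map=True)
    return ActivationMap(values=amap.values / peak, layer=amap.layer, normalized=True)


def aggregate_maps(maps) -> ActivationMap:
    """Elementwise sum of normalized maps, renormalized to [0, 1]."""
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to aggregate")
    shape = maps[0].values.shape
    total = np.zeros(shape)
    for m in maps:
        if m.values.shape != shape:
            raise ShapeError(f"map shape {m.values.shape} != {shape}")
        if not m.normalized:
            raise ValueError("aggregate_maps expects normalized maps")
        total += m.values
    return normalize01(ActivationMap(values=total, layer=maps[0].layer))


def image_activation_map(trained, image, layer) -> ActivationMap:
    """abs -> max-sum selection -> normalization for one image and layer."""
    stack = trained.layer_activations(image, layer)
    sel = select_max_activation_map(stack, layer=layer if isinstance(layer, int) else 0)
    return normalize01(sel)


def aggregate_layer_map(trained, images, layer) -> ActivationMap:
    """Aggregate the per-image normalized maps of one layer over many images."""
    return aggregate_maps(image_activation_map(trained, im, layer) for im in images)


# --------------------------------------------------------------------------
# upsampling / localization
# --------------------------------------------------------------------------

def upsample_nearest(amap: ActivationMap, target_shape) -> np.ndarray:
    """Block-expand a coarse map to slice resolution (stride-grid aligned)."""
    h, w = amap.values.shape
    th, tw = target_shape
    ri = np.clip(np.floor((np.arange(th) + 0.5) * h / th).astype(int), 0, h - 1)
    ci = np.clip(np.floor((np.arange(tw) + 0.5) * w / tw).astype(int), 0, w - 1)
    return amap.values[ri[:, None], ci[None, :]]


def peak_coordinate(amap: ActivationMap, target_shape) -> tuple:
    """Slice-resolution (row, col) of the map's peak, at its block center."""
    h, w = amap.values.shape
    th, tw = target_shape
    r, c = np.unravel_index(int(np.argmax(amap.values)), (h, w))
    return (int((r + 0.5) * th / h), int((c + 0.5) * tw / w))


def render_overlay(amap: ActivationMap, gm_slice: GMSlice, out_path) -> None:
    """Write a PNG of the slice with red intensity proportional to the map.

    Output bytes are deterministic for fixed inputs (pure array composition,
    no metadata).
    """
    target = gm_slice.pixels.shape
    overlay = upsample_nearest(amap, target)
    if overlay.max() > 0:
        overlay = overlay / overlay.max()
    gray = np.clip(gm_slice.pixels, 0.0, 1.0)
    red = np.clip(gray + (1.0 - gray) * overlay, 0.0, 1.0)
    green = gray * (1.0 - overlay)
    blue = gray * (1.0 - overlay)
    rgb = (np.stack([red, green, blue], axis=-1) * 255.0).round().astype(np.uint8)
    Image.fromarray(rgb, mode="RGB").save(out_path, format="PNG")
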