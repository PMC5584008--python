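"""Torso preprocessing: outside air, lungs, bones, and colonic lumen.

The colon shares attenuation ranges with air outside the body, with the
lungs, and (for tagged material) with bone, so those structures are removed
first by seeded region growing, and the colonic lumen is then the
morphological dilation of the remaining air and tagging masks.

All region growing uses 6-connectivity in 3-D, which prevents diagonal
leakage through one-voxel walls.  Removal writes the soft-tissue floor
(-100 HU) into the removed voxels, which is enough for every downstream
threshold while keeping the volume a valid CT image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import HUVolume, LabelMap

log = logging.getLogger(__name__)

__all__ = [
    "ThresholdTable",
    "NoOutsideAirWarning",
    "EmptyLumenWarning",
    "remove_outside_air",
    "remove_lungs",
    "remove_bones",
    "detect_colonic_lumen",
    "ball",
]

_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ThresholdTable:
    """Observed per-material HU ranges and the working cut-offs.

    The (min, max) ranges are the standard observed attenuations of lumen
    air, soft tissue, tagged material and the air-tagging artifact layer;
    ``lumen_air_cut``/``ftm_cut`` are the single thresholds used to build the
    air and tagging masks for lumen detection, and ``st_floor`` is the lower
    bound of soft tissue used by the removal steps.
    """

    lumen_air: tuple[float, float] = (-1000.0, -800.0)
    soft_tissue: tuple[float, float] = (-100.0, 100.0)
    ftm: tuple[float, float] = (200.0, 1400.0)
    at_layer: tuple[float, float] = (-800.0, 600.0)
    lumen_air_cut: float = -600.0
    ftm_cut: float = 200.0
    st_floor: float = -100.0

    def __post_init__(self) -> None:
        for name in ("lumen_air", "soft_tissue", "ftm", "at_layer"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"threshold range {name} must have min < max, got ({lo}, {hi})")


class NoOutsideAirWarning(UserWarning):
    """The volume boundary holds no sub-soft-tissue voxel to seed from."""


class EmptyLumenWarning(UserWarning):
    """Neither lumen air nor tagged material found; lumen is empty."""


def _boundary_mask(shape: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for ax in range(3):
        sl: list = [slice(None)] * 3
        sl[ax] = 0
        m[tuple(sl)] = True
        sl[ax] = shape[ax] - 1
        m[tuple(sl)] = True
    return m


def _grow_from_seeds(candidate: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """All candidate voxels 6-connected to any seed voxel (seeds ⊆ candidate)."""
    labels, n = ndimage.label(candidate, structure=_CONN6)
    if n == 0:
        return np.zeros_like(candidate)
    hit = np.unique(labels[seeds & candidate])
    hit = hit[hit > 0]
    if hit.size == 0:
        return np.zeros_like(candidate)
    return np.isin(labels, hit)


def remove_outside_air(
    vol: HUVolume, thr: ThresholdTable = ThresholdTable()
) -> tuple[HUVolume, LabelMap]:
    """Flood-fill outside air from the image boundary and flatten it to the ST floor.

    Seeds are boundary voxels below the soft-tissue floor; growth covers every
    voxel below the floor reachable from them.  If the boundary holds no seed a
    :class:`NoOutsideAirWarning` is emitted and the volume returned unchanged.
    """
    out = vol.copy()
    candidate = out.data < thr.st_floor
    seeds = _boundary_mask(out.shape) & candidate
    if not seeds.any():
        warnings.warn("no outside air found at the volume boundary", NoOutsideAirWarning)
        return out, LabelMap(np.zeros(out.shape, dtype=np.int32), {1: "outside_air"})
    outside = _grow_from_seeds(candidate, seeds)
    out.data[outside] = thr.st_floor
    return out, LabelMap(outside.astype(np.int32), {1: "outside_air"})


def _segment_slices(n_slices: int, seg_len: int = 10) -> tuple[slice, slice, int]:
    if n_slices < 2 * seg_len:
        seg_len = max(1, n_slices // 2)
        log.warning("fewer than %d slices; shrinking lung segments to %d", 20, seg_len)
    return slice(0, seg_len), slice(n_slices - seg_len, n_slices), seg_len


def remove_lungs(
    vol: HUVolume, outside: LabelMap, thr: ThresholdTable = ThresholdTable()
) -> tuple[HUVolume, LabelMap, slice]:
    """Remove lung air by region growing seeded in the air-richer end segment.

    Inside air (below the ST floor, excluding the outside-air mask) is counted
    in the first-10-slice and last-10-slice segments; the segment with more
    inside air hosts the lungs (ties go to the first segment).  Every inside
    air region touching that segment is grown and flattened to the ST floor.
    Returns the modified volume, the lung mask, and the winning slice range.

    Without any detected outside air the scan is a cropped block with no
    visible body boundary; lung segmentation is then meaningless (the only
    end-segment air would be colonic) and the volume is returned unchanged.
    """
    out = vol.copy()
    first, last, _ = _segment_slices(out.shape[0])
    if not outside.mask().any():
        log.info("no outside air; skipping lung removal on a cropped volume")
        return out, LabelMap(np.zeros(out.shape, dtype=np.int32), {1: "lungs"}), first
    inside_air = (out.data < thr.st_floor) & ~outside.mask()
    n_first = int(inside_air[first].sum())
    n_last = int(inside_air[last].sum())
    if n_first == n_last:
        log.info("lung segment tie (%d voxels each); choosing the first segment", n_first)
    seg = first if n_first >= n_last else last

    if not inside_air.any() or (n_first == 0 and n_last == 0):
        return out, LabelMap(np.zeros(out.shape, dtype=np.int32), {1: "lungs"}), seg

    seeds = np.zeros(out.shape, dtype=bool)
    seeds[seg] = inside_air[seg]
    lungs = _grow_from_seeds(inside_air, seeds)
    out.data[lungs] = thr.st_floor
    return out, LabelMap(lungs.astype(np.int32), {1: "lungs"}), seg


def remove_bones(
    vol: HUVolume, lung_slices: slice, thr: ThresholdTable = ThresholdTable()
) -> tuple[HUVolume, LabelMap]:
    """Remove bone by region growing over the >200 HU set, seeded in the lung slices.

    Ribs surround the lungs, so every above-tagging-cut voxel in the lung
    slice range seeds the growth; tagged colonic pools in distal slices are
    not connected to those seeds and survive.
    """
    out = vol.copy()
    candidate = out.data > thr.ftm_cut
    seeds = np.zeros(out.shape, dtype=bool)
    seeds[lung_slices] = candidate[lung_slices]
    if not seeds.any():
        return out, LabelMap(np.zeros(out.shape, dtype=np.int32), {1: "bones"})
    bones = _grow_from_seeds(candidate, seeds)
    out.data[bones] = thr.st_floor
    return out, LabelMap(bones.astype(np.int32), {1: "bones"})


def ball(radius: int) -> np.ndarray:
    """Discrete voxel-isotropic Euclidean ball structuring element."""
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (zz * zz + yy * yy + xx * xx) <= r * r


def detect_colonic_lumen(
    vol: HUVolume, thr: ThresholdTable = ThresholdTable(), dilation_radius: int = 3
) -> LabelMap:
    """Merge air and tagged-material masks into the colonic lumen mask.

    Air is everything below ``lumen_air_cut`` and tagging everything above
    ``ftm_cut``; their union is dilated with a spherical structuring element
    whose radius matches the assumed 3-voxel thickness of the partial-volume
    layer, bridging the artifact band between an air pocket and the pool
    beneath it.  All later computation is restricted to this mask.
    """
    air = vol.data < thr.lumen_air_cut
    ftm = vol.data > thr.ftm_cut
    union = air | ftm
    if not union.any():
        warnings.warn("no lumen air or tagged material present", EmptyLumenWarning)
        return LabelMap(np.zeros(vol.shape, dtype=np.int32), {1: "lumen"})
    lumen = ndimage.binary_dilation(union, structure=ball(dilation_radius))
    return LabelMap(lumen.astype(np.int32), {1: "lumen"})
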