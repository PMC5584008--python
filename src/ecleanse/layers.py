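"""Thin-layer detection and classification around tagged pools.

At the interface between intraluminal air and a tagged pool sits a thin
layer of intermediate attenuation.  It is *ambiguous*: either a
partial-volume artifact (an air-tagging "AT" layer, to be removed) or a
genuine thin soft-tissue membrane sandwiched between air and tagging (an
"ATT" layer, to be preserved).  With the scanner table at the image bottom,
tagged fluid settles under gravity, so an artifact layer lies horizontally
*on top of* its pool while a real membrane drapes *along the bend* of the
pool.  The classifier exploits exactly this: from every layer voxel it
probes sideways (left/right) and downward (toward the table) with a fixed
leaping distance and compares how often each orientation reaches the
adjacent pool.  More horizontal hits than vertical means the pool lies
beside the layer - a membrane; otherwise the pool lies beneath it - an
artifact.

Classification runs per axial slice in 2-D (8-connected components), and the
3-D result is the union of the per-slice decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import ThresholdTable, ball
from .volume_io import HUVolume, LabelMap

__all__ = [
    "LayerComponent",
    "LayerClassificationError",
    "detect_ambiguous_layers",
    "classify_layer",
    "classify_slicewise",
    "ftm_vicinity",
    "detect_stt_layers",
]

_CONN26 = ndimage.generate_binary_structure(3, 3)
_CONN8 = ndimage.generate_binary_structure(2, 2)

AMBIGUOUS = "ambiguous"
AT = "AT"
ATT = "ATT"
STT = "STT"


class LayerClassificationError(RuntimeError):
    """A layer was classified without any adjacent tagged pool."""


@dataclass
class LayerComponent:
    """A connected thin layer with its class and pool-connectivity counts."""

    id: int
    voxels: np.ndarray  # (N, 3) integer grid indices
    cls: str = AMBIGUOUS
    adjacent_ftm: set[int] = field(default_factory=set)
    conn_horizontal: int = 0
    conn_vertical: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=np.intp))
        if self.voxels.size == 0:
            raise ValueError("a layer component needs at least one voxel")

    def __len__(self) -> int:
        return self.voxels.shape[0]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


def _components(mask: np.ndarray, cls: str, structure: np.ndarray) -> list[LayerComponent]:
    labels, n = ndimage.label(mask, structure=structure)
    out = []
    for obj_id, slc in enumerate(ndimage.find_objects(labels), start=1):
        if slc is None:
            continue
        local = np.argwhere(labels[slc] == obj_id)
        local += np.array([s.start for s in slc])
        out.append(LayerComponent(id=obj_id, voxels=local, cls=cls))
    return out


def detect_ambiguous_layers(
    vol: HUVolume,
    lumen: LabelMap,
    thr: ThresholdTable = ThresholdTable(),
) -> list[LayerComponent]:
    """Find the thin interface layers that may be artifact or membrane.

    The boundary of air is the one-voxel shell of non-air lumen voxels
    26-adjacent to lumen air.  Shell voxels with no tagged voxel among their
    26 neighbors belong to the plain air/soft-tissue edge and are dropped;
    what remains touches both air and tagging and is returned as 26-connected
    ambiguous components.
    """
    inside = lumen.mask()
    air = inside & (vol.data < thr.lumen_air_cut)
    ftm = inside & (vol.data > thr.ftm_cut)
    near_air = ndimage.binary_dilation(air, structure=_CONN26)
    near_ftm = ndimage.binary_dilation(ftm, structure=_CONN26)
    shell = inside & ~air & near_air
    ambiguous = shell & near_ftm
    return _components(ambiguous, AMBIGUOUS, _CONN26)


def _probe_counts(
    voxels_rc: np.ndarray, pools2d: np.ndarray, leap: int
) -> dict[int, list[int]]:
    """Horizontal/vertical pool-hit counts for 2-D layer voxels.

    ``voxels_rc`` holds (down, right) coordinates within one axial slice and
    ``pools2d`` the per-slice pool labels.  For each voxel, each of the two
    horizontal probe directions and the single downward probe contributes one
    hit to every pool it reaches within the leaping distance (probing leaps
    over intervening air or soft tissue).
    """
    h, w = pools2d.shape
    counts: dict[int, list[int]] = {}
    rs, cs = voxels_rc[:, 0], voxels_rc[:, 1]
    steps = np.arange(1, leap + 1)

    def pools_hit(rr: np.ndarray, cc: np.ndarray) -> list[set[int]]:
        valid = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        labs = np.zeros(rr.shape, dtype=pools2d.dtype)
        labs[valid] = pools2d[rr[valid], cc[valid]]
        return [set(row[row > 0].tolist()) for row in labs]

    right = pools_hit(rs[:, None].repeat(leap, 1), cs[:, None] + steps)
    left = pools_hit(rs[:, None].repeat(leap, 1), cs[:, None] - steps)
    down = pools_hit(rs[:, None] + steps, cs[:, None].repeat(leap, 1))

    for i in range(len(rs)):
        for pool in right[i]:
            counts.setdefault(pool, [0, 0])[0] += 1
        for pool in left[i]:
            counts.setdefault(pool, [0, 0])[0] += 1
        for pool in down[i]:
            counts.setdefault(pool, [0, 0])[1] += 1
    return counts


def _decide(counts: dict[int, list[int]]) -> tuple[str, int, int]:
    """ATT iff any adjacent pool sees strictly more horizontal than vertical hits."""
    best_h = best_v = 0
    cls = AT
    for h_cnt, v_cnt in counts.values():
        if h_cnt > v_cnt:
            cls = ATT
        if h_cnt + v_cnt > best_h + best_v:
            best_h, best_v = h_cnt, v_cnt
    return cls, best_h, best_v


def _slice_view(arr: np.ndarray, k: int, down_axis: int) -> np.ndarray:
    """Axial slice k as a 2-D (down, right) array."""
    sl = arr[k]
    return sl if down_axis == 1 else sl.T


def classify_layer(
    layer: LayerComponent,
    ftm_pools: LabelMap,
    leap: int = 5,
    down_axis: int = 1,
) -> str:
    """Classify one layer component as artifact (AT) or membrane (ATT).

    Probe counts are accumulated over the component's voxels slice by slice
    against per-slice pool labels; ties (including the no-hit case) fall to
    AT, matching the strict removal inequality.  Raises
    :class:`LayerClassificationError` if the layer touches no pool at all.
    """
    pools3d = ftm_pools.data
    mask = layer.mask(pools3d.shape)
    near = ndimage.binary_dilation(mask, structure=_CONN26)
    adjacent = set(np.unique(pools3d[near]).tolist()) - {0}
    if not adjacent:
        raise LayerClassificationError("layer has no adjacent tagged pool (caller bug)")

    merged: dict[int, list[int]] = {}
    for k in np.unique(layer.voxels[:, 0]):
        in_slice = layer.voxels[layer.voxels[:, 0] == k]
        rc = in_slice[:, [1, 2]] if down_axis == 1 else in_slice[:, [2, 1]]
        pools2d = _slice_view(pools3d, int(k), down_axis)
        for pool, (h_cnt, v_cnt) in _probe_counts(rc, pools2d, leap).items():
            acc = merged.setdefault(pool, [0, 0])
            acc[0] += h_cnt
            acc[1] += v_cnt

    cls, h_cnt, v_cnt = _decide(merged)
    layer.cls, layer.conn_horizontal, layer.conn_vertical = cls, h_cnt, v_cnt
    layer.adjacent_ftm = adjacent
    return cls


def classify_slicewise(
    vol: HUVolume,
    lumen: LabelMap,
    thr: ThresholdTable = ThresholdTable(),
    leap: int = 5,
) -> tuple[np.ndarray, np.ndarray, list[LayerComponent]]:
    """Run ambiguous-layer detection and per-slice AT/ATT classification.

    Returns the 3-D AT mask, the 3-D ATT mask, and the per-slice 2-D
    components (with slice-local counts) that produced them.  Every ambiguous
    voxel ends in exactly one of the two masks.
    """
    inside = lumen.mask()
    air = inside & (vol.data < thr.lumen_air_cut)
    ftm = inside & (vol.data > thr.ftm_cut)
    shell = inside & ~air & ndimage.binary_dilation(air, structure=_CONN26)
    ambiguous = shell & ndimage.binary_dilation(ftm, structure=_CONN26)

    down_axis = vol.down_axis
    at_mask = np.zeros(vol.shape, dtype=bool)
    att_mask = np.zeros(vol.shape, dtype=bool)
    components: list[LayerComponent] = []
    next_id = 1

    for k in range(vol.shape[0]):
        amb2d = _slice_view(ambiguous, k, down_axis)
        if not amb2d.any():
            continue
        pools2d, n_pools = ndimage.label(_slice_view(ftm, k, down_axis), structure=_CONN8)
        labels2d, n_comp = ndimage.label(amb2d, structure=_CONN8)
        for comp_id in range(1, n_comp + 1):
            rc = np.argwhere(labels2d == comp_id)
            counts = _probe_counts(rc, pools2d, leap) if n_pools else {}
            cls, h_cnt, v_cnt = _decide(counts)
            target = att_mask if cls == ATT else at_mask
            t2d = _slice_view(target, k, down_axis)
            t2d[rc[:, 0], rc[:, 1]] = True
            if down_axis == 1:
                vox = np.column_stack([np.full(len(rc), k), rc[:, 0], rc[:, 1]])
            else:
                vox = np.column_stack([np.full(len(rc), k), rc[:, 1], rc[:, 0]])
            components.append(
                LayerComponent(
                    id=next_id,
                    voxels=vox,
                    cls=cls,
                    adjacent_ftm=set(counts),
                    conn_horizontal=h_cnt,
                    conn_vertical=v_cnt,
                )
            )
            next_id += 1
    return at_mask, att_mask, components


def ftm_vicinity(ftm_mask: np.ndarray, thickness: int = 3) -> np.ndarray:
    """The 3-voxel shell straddling the tagged-pool boundary.

    Two voxel layers outside the pool plus the pool's own outermost layer:
    thick enough to hold both the interface artifact and the adjacent
    pseudo-enhanced soft tissue.
    """
    outside = max(1, thickness - 1)
    dilated = ndimage.binary_dilation(ftm_mask, structure=ball(outside))
    eroded = ndimage.binary_erosion(ftm_mask, structure=ball(1))
    return dilated & ~eroded


def detect_stt_layers(
    ftm_vicinity_map: LabelMap, at_layers: list[LayerComponent]
) -> list[LayerComponent]:
    """Soft-tissue/tagging transition layers: pool vicinity minus AT layers.

    Membrane (ATT) layers remain inside the result by construction; only the
    identified artifact layers are carved out.
    """
    stt = ftm_vicinity_map.mask().copy()
    for layer in at_layers:
        if layer.cls == AT:
            stt[tuple(layer.voxels.T)] = False
    return _components(stt, STT, _CONN26)
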