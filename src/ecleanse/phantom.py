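"""Digital colonography phantoms with per-voxel ground truth.

The generator emulates the image model the cleansing pipeline assumes: a
piecewise-pure material scene (lumen air, soft tissue, tagged fluid) whose
partial-volume fractions come from supersampled geometry, pseudo-enhancement
added to soft tissue near tagging, Gaussian point-spread blur, and additive
Gaussian noise.  Gravity points along the down axis (axis 1): tagged pools
have flat tops and the scanner table is at the image bottom.

Scenes are built inside a soft-tissue block (or an air-surrounded torso)
from a straight colonic tube plus optional features:

- ``pool``        gravity-settled tagged fluid filling the tube below a level
- ``att_layer``   a thin soft-tissue membrane draped along the tube wall with
                  a tagged pocket trapped behind it (the membrane case that
                  must be preserved)
- ``fold``        an annular soft-tissue ridge on the lower wall, submerged
                  under the pool
- ``polyp``       a spherical soft-tissue excrescence on the lower wall
- ``t_junction``  marker requesting the pool (junction loci arise wherever
                  the pool surface meets the wall)
- ``torso``       body/lungs/ribs layout for the preprocessing stages

Ground truth carries the material label map, the subvoxel fractions, the
artifact (AT) and membrane (ATT) layer masks, feature masks with their
tagged-facing surfaces, the pseudo-enhancement field and, for torsos, lung
and bone masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .material_model import FractionField
from .volume_io import HUVolume, LabelMap

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomSpecError",
    "generate_phantom",
    "make_test_suite_scenes",
    "composite_scene",
]

# supersampled geometry ids
_AIR, _ST, _FTM, _MEMBRANE, _FOLD, _POLYP, _BONE, _LUNG = range(8)
_AIR_IDS = (_AIR, _LUNG)
_ST_IDS = (_ST, _MEMBRANE, _FOLD, _POLYP)

_TABLE_RANGES = {"air": (-1000.0, -800.0), "st": (-100.0, 100.0), "ftm": (200.0, 1400.0)}


class PhantomSpecError(ValueError):
    """Inconsistent phantom description (bad means, colliding features, ...)."""


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic colonography scene.

    Material means sit inside the observed per-material attenuation ranges;
    lumen air in a well-distended, well-tagged colon reads within a few tens
    of HU of -1000, soft tissue near water, and iodine/barium tagging around
    700 HU.  ``psf_sigma`` models the scanner point-spread function (about a
    1-1.5 voxel FWHM for modern abdominal protocols), ``noise_sigma`` the
    reconstruction noise of a standard-dose soft-kernel scan, and the
    pseudo-enhancement field raises soft tissue near tagging by
    ``peh_amplitude`` with an exponential decay over ``peh_decay`` voxels
    (cut off at 5 voxels).
    """

    shape: tuple[int, int, int] = (40, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tube_radius: float = 20.0
    pool_level_offset: float = 0.5  # voxels below tube centre, breaks grid alignment
    mu_air: float = -980.0
    mu_st: float = 20.0
    mu_ftm: float = 700.0
    mu_bone: float = 1000.0
    psf_sigma: float = 0.5
    noise_sigma: float = 10.0
    peh_amplitude: float = 150.0
    peh_decay: float = 2.0
    features: list[dict] = field(default_factory=list)
    supersample: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mu_air < self.mu_st < self.mu_ftm):
            raise PhantomSpecError("material means must be ordered air < ST < FTM")
        for name, mu in (("air", self.mu_air), ("st", self.mu_st), ("ftm", self.mu_ftm)):
            lo, hi = _TABLE_RANGES[name]
            if not lo <= mu <= hi:
                raise PhantomSpecError(f"mu_{name}={mu} outside the observed range [{lo}, {hi}]")
        if self.psf_sigma < 0:
            raise PhantomSpecError("psf_sigma must be non-negative")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be non-negative")
        if self.supersample < 1:
            raise PhantomSpecError("supersample must be >= 1")
        for f in self.features:
            if f.get("kind") == "att_layer" and f.get("thickness", 1.2) < 1.0:
                raise PhantomSpecError("membrane thickness must be at least 1 voxel")


@dataclass
class PhantomTruth:
    """Ground truth for one phantom scene."""

    material: LabelMap  # 0 air, 1 ST, 2 FTM (majority vote of fractions)
    fractions: FractionField
    at: np.ndarray  # air-tagging interface (artifact) voxels
    att: np.ndarray  # thin-membrane centerline voxels between air and tagging
    fold: np.ndarray
    fold_surface: np.ndarray
    polyp: np.ndarray
    polyp_surface: np.ndarray
    tjunction: np.ndarray
    peh: np.ndarray  # HU added by pseudo-enhancement (pre-blur)
    lungs: np.ndarray
    bones: np.ndarray

    @property
    def pure_ftm(self) -> np.ndarray:
        return self.fractions.t_tr >= 1.0 - 1e-9


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _subgrid(n: int, ss: int) -> np.ndarray:
    """Supersample coordinates: voxel i covers [i-1/2, i+1/2)."""
    base = np.arange(n, dtype=np.float64)
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    return (base[:, None] + offs[None, :]).ravel()


def _tube_params(spec: PhantomSpec) -> tuple[float, float, float]:
    cy = (spec.shape[1] - 1) / 2.0
    cx = (spec.shape[2] - 1) / 2.0
    return cy, cx, float(spec.tube_radius)


def _feature(spec: PhantomSpec, kind: str) -> dict | None:
    for f in spec.features:
        if f.get("kind") == kind:
            return f
    return None


def _label_chunk(spec: PhantomSpec, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Material/feature ids on broadcast coordinate arrays (voxel units)."""
    cy, cx, R = _tube_params(spec)
    torso = _feature(spec, "torso")
    zz, yy, xx = np.broadcast_arrays(z, y, x)
    ids = np.full(zz.shape, _ST, dtype=np.int8)

    if torso is not None:
        ry = 0.42 * spec.shape[1]
        rx = 0.46 * spec.shape[2]
        body = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        ids[~body] = _AIR
        # lungs: two enclosed air ellipsoids confined to the first 10 slices,
        # kept two slices off the z=0 face so that neither the geometry nor
        # its PSF-blurred, noisy image connects them to outside air
        for sx in (-1.0, 1.0):
            lung = (
                ((zz - 5.5) / 3.5) ** 2
                + ((yy - (cy - 0.15 * ry)) / (0.45 * ry)) ** 2
                + ((xx - (cx + sx * 0.45 * rx)) / (0.32 * rx)) ** 2
            ) <= 1.0
            ids[lung & body & (zz < 9.5)] = _LUNG
        # rib shell around the lungs
        e = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
        ids[(e >= 0.82) & (e <= 0.92) & (zz >= 2) & (zz <= 8) & body] = _BONE
        # distal colon tube with a tagged pool
        tube_r = torso.get("tube_radius", 0.22 * ry)
        ty, tx = cy + 0.25 * ry, cx
        in_tube = (
            ((yy - ty) ** 2 + (xx - tx) ** 2 <= tube_r**2)
            & (zz >= 14)
            & (zz <= spec.shape[0] - 3)  # capped: the colon never reaches the scan boundary
            & body
        )
        ids[in_tube] = _AIR
        ids[in_tube & (yy > ty + 0.2 * tube_r)] = _FTM
        return ids

    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    # soft-tissue caps keep the tube off the scan boundary, as in a real colon
    in_tube = (r2 <= R * R) & (zz >= 2) & (zz <= spec.shape[0] - 3)
    ids[in_tube] = _AIR

    if _feature(spec, "pool") is not None or _feature(spec, "t_junction") is not None:
        level = cy + spec.pool_level_offset
        ids[in_tube & (yy > level)] = _FTM

    att = _feature(spec, "att_layer")
    if att is not None:
        t = float(att.get("thickness", 1.2))
        depth = float(att.get("depth", 6.0))
        th0 = np.deg2rad(att.get("angle_deg", 40.0))
        thw = np.deg2rad(att.get("half_width_deg", 25.0))
        z0, z1 = att.get("z_range", (2, spec.shape[0] - 2))
        r = np.sqrt(r2)
        theta = np.arctan2(-(yy - cy), xx - cx)  # positive = up from 3 o'clock
        prof = np.cos(0.5 * np.pi * np.clip((theta - th0) / thw, -1.0, 1.0))
        d = depth * prof
        sector = (np.abs(theta - th0) < thw) & (zz >= z0) & (zz <= z1) & (d > 0.5)
        pocket = sector & (r > R - d) & in_tube
        membrane = sector & (r > R - d - t) & (r <= R - d) & in_tube
        ids[pocket] = _FTM
        ids[membrane] = _MEMBRANE

    fold = _feature(spec, "fold")
    if fold is not None:
        h = float(fold.get("height", 8.0))
        w = float(fold.get("width", 12.0))
        z0 = float(fold.get("slice", spec.shape[0] / 2.0))
        prof = np.cos(np.pi * np.clip((zz - z0) / w, -0.5, 0.5)) ** 2
        lower = (yy - cy) > 0.15 * R
        ids[in_tube & lower & (np.sqrt(r2) > R - h * prof) & (np.abs(zz - z0) < w / 2)] = _FOLD

    polyp = _feature(spec, "polyp")
    if polyp is not None:
        rho = float(polyp.get("radius", 5.0))
        z0 = float(polyp.get("slice", spec.shape[0] / 2.0))
        stalk = R - 0.55 * rho
        py, px = cy + stalk, cx
        inside = (zz - z0) ** 2 + (yy - py) ** 2 + (xx - px) ** 2 <= rho**2
        ids[inside & in_tube] = _POLYP

    return ids


def _membrane_centerline(spec: PhantomSpec) -> np.ndarray:
    """Voxels containing the membrane's medial surface (its centerline)."""
    att = _feature(spec, "att_layer")
    center = np.zeros(spec.shape, dtype=bool)
    if att is None:
        return center
    cy, cx, R = _tube_params(spec)
    t = float(att.get("thickness", 1.2))
    depth = float(att.get("depth", 6.0))
    th0 = np.deg2rad(att.get("angle_deg", 40.0))
    thw = np.deg2rad(att.get("half_width_deg", 25.0))
    z0, z1 = att.get("z_range", (2, spec.shape[0] - 2))
    zc = np.arange(spec.shape[0], dtype=np.float64)[:, None, None]
    yc = np.arange(spec.shape[1], dtype=np.float64)[None, :, None]
    xc = np.arange(spec.shape[2], dtype=np.float64)[None, None, :]
    r = np.sqrt((yc - cy) ** 2 + (xc - cx) ** 2)
    theta = np.arctan2(-(yc - cy), xc - cx)
    prof = np.cos(0.5 * np.pi * np.clip((theta - th0) / thw, -1.0, 1.0))
    d = depth * prof
    sector = (np.abs(theta - th0) < thw) & (zc >= z0) & (zc <= z1) & (d > 0.5)
    return sector & (np.abs(r - (R - d - t / 2.0)) <= 0.5)


def _feature_regions(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Coarse-grid (voxel-centre) masks of each requested feature, for collision checks."""
    zc = np.arange(spec.shape[0], dtype=np.float64)[:, None, None]
    yc = np.arange(spec.shape[1], dtype=np.float64)[None, :, None]
    xc = np.arange(spec.shape[2], dtype=np.float64)[None, None, :]
    regions: dict[str, np.ndarray] = {}
    for kind, fid in (("att_layer", _MEMBRANE), ("fold", _FOLD), ("polyp", _POLYP)):
        if _feature(spec, kind) is None:
            continue
        solo = replace(spec, features=[f for f in spec.features if f.get("kind") in (kind, "pool")])
        regions[kind] = _label_chunk(solo, zc, yc, xc) == fid
    return regions


# ---------------------------------------------------------------------------
# image formation
# ---------------------------------------------------------------------------


def _fractions(spec: PhantomSpec) -> np.ndarray:
    """Per-voxel fractions of the 8 geometry ids, from supersampled labels."""
    nz, ny, nx = spec.shape
    ss = spec.supersample
    ysub = _subgrid(ny, ss)[None, :, None]
    xsub = _subgrid(nx, ss)[None, None, :]
    fr = np.zeros((8, nz, ny, nx), dtype=np.float32)
    for i in range(nz):
        zsub = _subgrid(1, ss).reshape(-1, 1, 1) + i
        ids = _label_chunk(spec, zsub, ysub, xsub)
        # (ss, ny*ss, nx*ss) -> per-coarse-voxel histogram
        ids = ids.reshape(ss, ny, ss, nx, ss)
        for m in range(8):
            fr[m, i] = (ids == m).mean(axis=(0, 2, 4))
    return fr


def generate_phantom(spec: PhantomSpec) -> tuple[HUVolume, PhantomTruth]:
    """Render one scene: supersampled fractions -> HU -> PEH -> PSF blur -> noise."""
    regions = _feature_regions(spec)
    names = list(regions)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if (regions[a] & regions[b]).any():
                raise PhantomSpecError(f"features {a!r} and {b!r} collide geometrically")

    fr = _fractions(spec)
    t_air = fr[_AIR] + fr[_LUNG]
    t_st = sum(fr[i] for i in _ST_IDS) + fr[_BONE]
    t_tr = fr[_FTM]

    mu_map = np.array(
        [spec.mu_air, spec.mu_st, spec.mu_ftm, spec.mu_st, spec.mu_st, spec.mu_st,
         spec.mu_bone, spec.mu_air],
        dtype=np.float64,
    )
    hu = np.einsum("m,mzyx->zyx", mu_map, fr.astype(np.float64))

    # pseudo-enhancement: soft tissue within 5 voxels of tagging is raised
    ftm_major = t_tr >= 0.5
    peh = np.zeros(spec.shape, dtype=np.float64)
    if spec.peh_amplitude > 0 and ftm_major.any():
        dist = ndimage.distance_transform_edt(~ftm_major)
        st_frac = np.asarray(t_st, dtype=np.float64)
        peh = np.where(dist <= 5.0, spec.peh_amplitude * np.exp(-dist / spec.peh_decay), 0.0)
        peh *= st_frac
        hu = hu + peh

    if spec.psf_sigma > 0:
        hu = ndimage.gaussian_filter(hu, sigma=spec.psf_sigma, mode="mirror")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    vol = HUVolume(data=hu, spacing=spec.spacing, down_axis=1)

    # ---- truth -------------------------------------------------------------
    frac = FractionField(
        t_air=np.clip(t_air, 0, 1).astype(np.float64),
        t_st=np.clip(t_st, 0, 1).astype(np.float64),
        t_tr=np.clip(t_tr, 0, 1).astype(np.float64),
    )
    material = np.argmax(np.stack([t_air, t_st, t_tr]), axis=0).astype(np.int32)
    conn26 = ndimage.generate_binary_structure(3, 3)
    air_major = material == 0
    near_air = ndimage.binary_dilation(air_major, structure=conn26)
    near_ftm = ndimage.binary_dilation(ftm_major, structure=conn26)

    at = (t_air > 0.05) & (t_tr > 0.05) & (t_st < 0.05)
    # the membrane centerline: voxels holding the medial surface, which is
    # what preservation is judged on (the membrane's air-mixed skin is dark
    # in the input already)
    membrane = fr[_MEMBRANE] >= 0.5
    att = membrane & _membrane_centerline(spec) & near_air & near_ftm
    fold = fr[_FOLD] >= 0.5
    polyp = fr[_POLYP] >= 0.5
    tj = (t_air > 0.1) & (t_st > 0.1) & (t_tr > 0.1)

    truth = PhantomTruth(
        material=LabelMap(material, {0: "air", 1: "soft_tissue", 2: "ftm"}),
        fractions=frac,
        at=at,
        att=att,
        fold=fold,
        fold_surface=fold & near_ftm,
        polyp=polyp,
        polyp_surface=polyp & near_ftm,
        tjunction=tj,
        peh=peh,
        lungs=fr[_LUNG] >= 0.5,
        bones=fr[_BONE] >= 0.5,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# canonical scenes
# ---------------------------------------------------------------------------


def make_test_suite_scenes(
    seed: int = 0,
    shape: tuple[int, int, int] = (40, 64, 64),
    names: tuple[str, ...] | None = None,
) -> dict[str, tuple[HUVolume, PhantomTruth]]:
    """The named scenes every stage is tested against.

    ``at_layer``   flat artifact layer atop a tagged pool
    ``att_layer``  membrane along the wall with a trapped pocket (no open pool)
    ``fold``       submerged annular fold
    ``polyp``      submerged spherical polyp
    ``t_junction`` pool meeting the wall (junction ring)
    ``torso``      body with lungs, ribs, and a distal tagged colon segment

    ``names`` restricts generation to a subset of scenes (generation is the
    expensive part).
    """
    base = dict(shape=shape, tube_radius=0.31 * shape[1], seed=seed)
    mid = shape[0] / 2.0
    scenes = {
        "at_layer": PhantomSpec(features=[{"kind": "pool"}], **base),
        "att_layer": PhantomSpec(
            features=[{"kind": "att_layer", "z_range": (-1, shape[0])}], **base
        ),
        "fold": PhantomSpec(
            features=[{"kind": "pool"}, {"kind": "fold", "slice": mid, "height": 7, "width": 12}],
            **base,
        ),
        "polyp": PhantomSpec(
            features=[{"kind": "pool"}, {"kind": "polyp", "slice": mid, "radius": 5,
                       "submerged": True}],
            **base,
        ),
        "t_junction": PhantomSpec(features=[{"kind": "t_junction"}], **base),
        "torso": PhantomSpec(
            shape=(24, 72, 72), tube_radius=8.0, features=[{"kind": "torso"}], seed=seed
        ),
    }
    if names is not None:
        unknown = set(names) - set(scenes)
        if unknown:
            raise PhantomSpecError(f"unknown scene names: {', '.join(sorted(unknown))}")
        scenes = {k: v for k, v in scenes.items() if k in names}
    return {name: generate_phantom(spec) for name, spec in scenes.items()}


def composite_scene(
    seed: int = 0, shape: tuple[int, int, int] = (128, 128, 128)
) -> tuple[HUVolume, PhantomTruth, PhantomSpec]:
    """A full-size scene holding every cleansing challenge at once.

    One tagged pool along the whole tube, a wall membrane with a trapped
    pocket in the proximal third, a submerged fold and a submerged polyp in
    the distal half.
    """
    nz = shape[0]
    spec = PhantomSpec(
        shape=shape,
        tube_radius=0.23 * shape[1],
        seed=seed,
        features=[
            {"kind": "pool"},
            {"kind": "att_layer", "z_range": (int(0.1 * nz), int(0.4 * nz)),
             "depth": 6.0, "thickness": 1.2},
            {"kind": "fold", "slice": 0.62 * nz, "height": 8, "width": 13},
            {"kind": "polyp", "slice": 0.82 * nz, "radius": 6, "submerged": True},
        ],
    )
    vol, truth = generate_phantom(spec)
    return vol, truth, spec
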