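"""Replacement rules and the end-to-end electronic-cleansing pipeline.

Cleansing rewrites three voxel populations inside the colonic lumen:

- Soft-tissue/tagging transition (STT) voxels that are pseudo-enhanced
  (directional second derivative positive, attenuation above the 100 HU
  gate) are rewritten from the tissue-pair fractions, with the tagged
  fraction's base blended from the tagging base toward the air base by the
  second-derivative weight:

      I_peh = t_L_TT * L_TT + t_H_TT * (f_ww * L_TA + (1 - f_ww) * H_TA)

- Tagged material, identified artifact (AT) layers and T-junction voxels
  are rewritten from the three-material fractions, with the tagged fraction
  sent to the air base:

      I_tj = (t_air + t_TR) * L_TA + t_ST * L_TT

- The freshly exposed colonic wall (the former tagging boundary) is
  smoothed with a narrow Gaussian so the new air/wall edge matches the
  appearance of native air/wall edges.

Membrane (ATT) voxels are excluded from removal outright - preserving them
is the point of the layer classification - and a voxel eligible for the
pseudo-enhancement rule is never also removed (preservation wins).

Everything outside the lumen and the wall band is returned bit-identical:
the torso preprocessing needed to find the lumen operates on an internal
copy only.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from . import layers as _layers
from . import material_model as mm
from .config import CleanseConfig
from .gdsd import GDSDField, compute_gdsd
from .preprocess import (
    EmptyLumenWarning,
    NoOutsideAirWarning,
    ball,
    detect_colonic_lumen,
    remove_bones,
    remove_lungs,
    remove_outside_air,
)
from .volume_io import HUVolume, LabelMap

log = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "StageError",
    "replace_stt",
    "replace_tjunction",
    "enhance_wall",
    "edge_response_gain",
    "run_ec",
]

_CONN26 = ndimage.generate_binary_structure(3, 3)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class QCReport:
    """Per-run bookkeeping: voxel counts, layer classes, model estimates, timings."""

    counts: dict[str, int] = dc_field(default_factory=dict)
    layer_classes: list[dict] = dc_field(default_factory=list)
    bases: dict[str, dict[str, float]] = dc_field(default_factory=dict)
    thetas: dict[str, float] = dc_field(default_factory=dict)
    timings_s: dict[str, float] = dc_field(default_factory=dict)
    warnings: list[str] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "layer_classes": self.layer_classes,
            "bases": self.bases,
            "thetas": self.thetas,
            "timings_s": self.timings_s,
            "warnings": self.warnings,
        }


def _as_mask(obj, shape) -> np.ndarray:
    if isinstance(obj, LabelMap):
        return obj.mask()
    if isinstance(obj, np.ndarray):
        return obj.astype(bool)
    if isinstance(obj, (list, tuple)):  # layer components
        m = np.zeros(shape, dtype=bool)
        for comp in obj:
            m[tuple(comp.voxels.T)] = True
        return m
    raise TypeError(f"cannot interpret {type(obj).__name__} as a mask")


def replace_stt(
    vol: HUVolume,
    stt,
    pair_tt: tuple[np.ndarray, np.ndarray],
    f_ww,
    m: dict[str, mm.TransitionModel],
    hu_gate: float = 100.0,
) -> HUVolume:
    """Rewrite pseudo-enhanced transition voxels from the tissue-pair fractions.

    Only STT voxels with positive directional second derivative *and*
    attenuation above ``hu_gate`` are rewritten; all other voxels are
    untouched.  ``pair_tt`` holds full-volume ``(t_low, t_high)`` arrays,
    ``f_ww`` the (possibly edge-normalised) second-derivative weight.
    """
    if "TA" not in m or "TT" not in m:
        raise StageError("replace_stt", KeyError("need TA and TT transition models"))
    fww = f_ww.f_ww if isinstance(f_ww, GDSDField) else np.asarray(f_ww)
    mask = _as_mask(stt, vol.shape) & (fww > 0) & (vol.data > hu_gate)
    out = vol.copy()
    t_low, t_high = pair_tt
    ta, tt = m["TA"], m["TT"]
    inner = fww[mask] * ta.L + (1.0 - fww[mask]) * ta.H
    out.data[mask] = np.asarray(t_low)[mask] * tt.L + np.asarray(t_high)[mask] * inner
    return out


def replace_tjunction(
    vol: HUVolume,
    targets,
    frac: mm.FractionField,
    m: dict[str, mm.TransitionModel],
) -> HUVolume:
    """Rewrite tagging/artifact voxels from the three-material fractions.

    The tagged fraction goes to the air base alongside the air fraction,
    which is what removes the tagging's influence; pure tagged voxels land
    far below the soft-tissue range.
    """
    mask = _as_mask(targets, vol.shape)
    out = vol.copy()
    ta, tt = m["TA"], m["TT"]
    out.data[mask] = (frac.t_air[mask] + frac.t_tr[mask]) * ta.L + frac.t_st[mask] * tt.L
    return out


def enhance_wall(vol: HUVolume, new_edges, sigma: float = 0.5) -> HUVolume:
    """Gaussian-smooth the freshly exposed wall band; identity elsewhere."""
    band = _as_mask(new_edges, vol.shape)
    if not band.any():
        return vol.copy()
    out = vol.copy()
    smoothed = ndimage.gaussian_filter(vol.data, sigma=sigma, mode="mirror")
    out.data[band] = smoothed[band]
    return out


def edge_response_gain(cfg: CleanseConfig, m_tt: mm.TransitionModel) -> float:
    """Scale that maps the GDSD of a tissue-tagging step edge onto (-1, 1).

    The peak directional second derivative of a unit step blurred at scale
    sigma is 1 / (sigma^2 sqrt(2 pi e)); the gain inverts that peak for an
    edge whose amplitude is the tissue-tagging span expressed in window
    units, so the blend weight in the pseudo-enhancement rule sweeps the
    full (-1, 1) range across exactly the edges it is meant to correct.
    """
    lo, hi = cfg.hu_window
    window = hi - lo
    peak_unit_step = 1.0 / (cfg.sigma_gdsd**2 * np.sqrt(2.0 * np.pi * np.e))
    amplitude = (m_tt.H - m_tt.L) / window
    return float(1.0 / (peak_unit_step * amplitude))


def _central_gradient_magnitude(data: np.ndarray) -> np.ndarray:
    gz, gy, gx = np.gradient(data)
    return np.sqrt(gz * gz + gy * gy + gx * gx)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage name
        raise StageError(name, exc) from exc


def run_ec(vol: HUVolume, cfg: CleanseConfig | None = None) -> tuple[HUVolume, QCReport]:
    """Run the full cleansing pipeline on one volume.

    Deterministic for fixed input and configuration.  Returns the cleansed
    volume (original data modified only inside the lumen and the wall band)
    and a QC report.
    """
    cfg = cfg or CleanseConfig()
    thr = cfg.thresholds
    report = QCReport()
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t0
        now = time.perf_counter()
        report.timings_s[stage] = round(now - t0, 4)
        t0 = now

    # --- 1. torso preprocessing (internal working copy only) ---------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        work, outside = _stage("remove_outside_air", remove_outside_air, vol, thr)
        work, lungs, lung_slices = _stage("remove_lungs", remove_lungs, work, outside, thr)
        if lungs.mask().any():
            work, bones = _stage("remove_bones", remove_bones, work, lung_slices, thr)
        else:
            # bone growth is seeded in the lung slices; without lungs the
            # seeds would hit colonic tagging instead of ribs
            bones = LabelMap(np.zeros(work.shape, dtype=np.int32), {1: "bones"})

        # --- 2. colonic lumen ----------------------------------------------
        lumen = _stage("detect_colonic_lumen", detect_colonic_lumen, work, thr, cfg.dilation_radius)
    report.warnings.extend(
        str(w.message) for w in caught if issubclass(w.category, (NoOutsideAirWarning, EmptyLumenWarning))
    )
    tick("preprocess")

    inside = lumen.mask()
    if not inside.any():
        report.counts["lumen"] = 0
        log.warning("empty lumen; volume returned unchanged")
        report.warnings.append("empty lumen; volume returned unchanged")
        return vol.copy(), report

    data = work.data
    air = inside & (data < thr.lumen_air_cut)
    ftm = inside & (data > thr.ftm_cut)
    st_range = (data >= thr.soft_tissue[0]) & (data <= thr.soft_tissue[1])

    # --- 3/4. ambiguous layers and AT identification -----------------------
    at_mask, att_mask, comps = _stage(
        "classify_layers", _layers.classify_slicewise, work, lumen, thr, cfg.leap_distance
    )
    report.layer_classes = [
        {
            "id": c.id,
            "cls": c.cls,
            "n_voxels": len(c),
            "conn_horizontal": c.conn_horizontal,
            "conn_vertical": c.conn_vertical,
        }
        for c in comps
    ]
    tick("layers")

    # --- 5. transition (STT) layers ----------------------------------------
    vicinity = _stage("ftm_vicinity", _layers.ftm_vicinity, ftm)
    stt_mask = vicinity & ~at_mask

    # --- 6a. transition bases ----------------------------------------------
    air_pure = inside & (data >= thr.lumen_air[0]) & (data <= thr.lumen_air[1])
    if not air_pure.any():
        air_pure = air
    # soft-tissue reference: in range, near the lumen, away from tagging so
    # pseudo-enhancement does not bias the base
    near_lumen = ndimage.binary_dilation(inside, structure=ball(2))
    st_ref = st_range & near_lumen & ~ndimage.binary_dilation(ftm, structure=ball(3))
    if not st_ref.any():
        st_ref = st_range & near_lumen
    models = _stage(
        "estimate_bases",
        mm.estimate_bases,
        work,
        {"air": air_pure, "ST": st_ref, "FTM": ftm},
        cfg.sigma_omega,
    )
    report.bases = {k: {"L": m.L, "H": m.H} for k, m in models.items()}

    # --- 6b. gradient samples and the noise/scale factor theta --------------
    gmag = _central_gradient_magnitude(data)
    near_air26 = ndimage.binary_dilation(air, structure=_CONN26)
    near_ftm26 = ndimage.binary_dilation(ftm, structure=_CONN26)
    sa_edges = inside & ~air & near_air26 & ~near_ftm26  # plain air / soft-tissue edge
    theta_samples = {"TA": at_mask | att_mask, "TT": stt_mask, "SA": sa_edges}
    for key, m in models.items():
        if cfg.theta_mode == "fixed":
            m.theta = cfg.theta_fixed
            continue
        try:
            m.theta = mm.estimate_theta(gmag[theta_samples[key]], m)
        except ValueError as exc:
            log.warning("theta calibration for %s fell back to 1: %s", key, exc)
            report.warnings.append(f"theta[{key}] fallback: {exc}")
            m.theta = 1.0
    report.thetas = {k: m.theta for k, m in models.items()}
    tick("models")

    # --- 7. directional second derivative -----------------------------------
    fld = _stage("compute_gdsd", compute_gdsd, work, cfg.sigma_gdsd, cfg.gdsd_eps, cfg.hu_window)
    gain = edge_response_gain(cfg, models["TT"])
    f_eff = np.clip(fld.f_ww * gain, -1.0, 1.0)
    tick("gdsd")

    # --- 8. replacement ------------------------------------------------------
    # T-junction voxels: artifact-range lumen voxels touching all three materials
    tj = (
        inside
        & (data >= thr.at_layer[0])
        & (data <= thr.at_layer[1])
        & near_air26
        & near_ftm26
        & ndimage.binary_dilation(st_range, structure=_CONN26)
    )
    peh_mask = stt_mask & (f_eff > 0) & (data > cfg.peh_hu_gate) & ~att_mask
    removal_mask = (ftm | at_mask | tj) & ~att_mask & ~peh_mask

    out = vol.copy()  # replacements apply to the original attenuations

    if peh_mask.any():
        idx = np.where(peh_mask)
        _, t_low, t_high = mm.project_to_arch(
            (data[idx], gmag[idx]), models["TT"], n_samples=cfg.projection_samples
        )
        tl = np.zeros(vol.shape)
        th = np.zeros(vol.shape)
        tl[idx], th[idx] = t_low, t_high
        out = _stage(
            "replace_stt", replace_stt, out, peh_mask, (tl, th), f_eff, models, cfg.peh_hu_gate
        )

    if removal_mask.any():
        idx = np.where(removal_mask)
        pairs = {}
        for key in ("TA", "TT", "SA"):
            _, t_low, t_high = mm.project_to_arch(
                (data[idx], gmag[idx]), models[key], n_samples=cfg.projection_samples
            )
            pairs[key] = (t_low, t_high)
        fr = mm.three_fractions(pairs)
        # full-volume fields; voxels outside the target keep a pure-air placeholder
        full = mm.FractionField(
            t_air=np.ones(vol.shape), t_st=np.zeros(vol.shape), t_tr=np.zeros(vol.shape)
        )
        full.t_air[idx], full.t_st[idx], full.t_tr[idx] = fr.t_air, fr.t_st, fr.t_tr
        out = _stage("replace_tjunction", replace_tjunction, out, removal_mask, full, models)
    tick("replace")

    # --- 9. colonic wall enhancement ----------------------------------------
    # the exposed wall layer at the former tagging boundary; the pool side is
    # freshly synthesized from pure bases and must not be smoothed back up,
    # and preserved membranes are never touched
    band = ndimage.binary_dilation(ftm, structure=ball(1)) & ~ftm & ~att_mask
    out = _stage("enhance_wall", enhance_wall, out, band, cfg.sigma_wall)
    tick("wall")

    report.counts = {
        "lumen": int(inside.sum()),
        "air": int(air.sum()),
        "ftm": int(ftm.sum()),
        "outside_air": int(outside.mask().sum()),
        "lungs": int(lungs.mask().sum()),
        "bones": int(bones.mask().sum()),
        "at": int(at_mask.sum()),
        "att": int(att_mask.sum()),
        "stt": int(stt_mask.sum()),
        "tjunction": int(tj.sum()),
        "rewritten_peh": int(peh_mask.sum()),
        "rewritten_removal": int(removal_mask.sum()),
        "wall_band": int(band.sum()),
    }
    return out, report
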