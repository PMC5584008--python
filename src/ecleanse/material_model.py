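"""Two- and three-material partial-volume fraction estimation.

A CT edge between two pure materials is modeled as a unit step blurred by a
Gaussian point-spread function.  Along the gradient direction the intensity
follows an erf profile and the first derivative a Gaussian bump, so in the
(intensity, scaled-gradient) plane every edge voxel lies on a single
arch-shaped curve

    arch(x) = (1 / sqrt(2*pi)) * exp(-(erfinv(2x - 1))**2),   x in [0, 1],

where x is the fraction of the brighter material.  Projecting a measured
(I, theta * sigma_w * I_w) sample orthogonally onto the arch recovers the two
material fractions; theta rescales the gradient axis so that real (noisy,
re-blurred) samples sit on the model curve.

Three pairwise transitions - air/tagging (TA), soft-tissue/tagging (TT) and
air/soft-tissue (SA) - are combined into per-voxel three-material fractions
by averaging:

    t_air = (t_L_SA + t_L_TA) / 3
    t_ST  = (t_H_SA + t_L_TT) / 3
    t_TR  = 1 - t_air - t_ST

The SA pair reuses the air and soft-tissue bases (its low base is air, its
high base soft tissue), which is the only reading under which t_air collects
exclusively air-side fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import erfinv

from .volume_io import HUVolume, LabelMap

__all__ = [
    "TransitionModel",
    "EdgeSample",
    "FractionField",
    "BaseEstimationError",
    "arch",
    "project_to_arch",
    "estimate_bases",
    "estimate_theta",
    "three_fractions",
]

_SQRT2PI = float(np.sqrt(2.0 * np.pi))
ARCH_APEX = 1.0 / _SQRT2PI  # arch(1/2)


class BaseEstimationError(RuntimeError):
    """A required material mask was empty; the message names the material."""


@dataclass
class TransitionModel:
    """One material-pair transition: bases, gradient scale, and noise factor.

    ``pair`` is one of ``TA`` (air-tagging), ``TT`` (soft tissue-tagging) or
    ``SA`` (air-soft tissue); ``L``/``H`` are the low/high pure-material
    attenuations in HU, ``sigma_omega`` the Gaussian scale (voxels) assumed
    along the gradient direction and ``theta`` the dimensionless factor that
    makes the scaled gradient noise/scale invariant.
    """

    pair: str
    L: float
    H: float
    sigma_omega: float = 1.0
    theta: float = 1.0

    def __post_init__(self) -> None:
        if not self.L < self.H:
            raise ValueError(f"{self.pair}: need L < H, got L={self.L}, H={self.H}")
        if self.sigma_omega <= 0:
            raise ValueError("sigma_omega must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")


@dataclass
class EdgeSample:
    """One edge measurement: attenuation I (HU) and gradient-direction first derivative."""

    I: float
    gI: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.I) and np.isfinite(self.gI)):
            raise ValueError("edge samples must be finite")


@dataclass
class FractionField:
    """Per-voxel air / soft-tissue / tagging fractions, each in [0, 1], summing to 1."""

    t_air: np.ndarray
    t_st: np.ndarray
    t_tr: np.ndarray

    def __post_init__(self) -> None:
        self.t_air = np.asarray(self.t_air, dtype=np.float64)
        self.t_st = np.asarray(self.t_st, dtype=np.float64)
        self.t_tr = np.asarray(self.t_tr, dtype=np.float64)
        for name, t in (("t_air", self.t_air), ("t_st", self.t_st), ("t_tr", self.t_tr)):
            if t.min() < -1e-9 or t.max() > 1 + 1e-9:
                raise ValueError(f"{name} outside [0, 1]")
        if np.abs(self.t_air + self.t_st + self.t_tr - 1.0).max() > 1e-9:
            raise ValueError("fractions do not sum to 1")


def arch(x):
    """The arch curve: scaled gradient of a blurred unit step versus intensity fraction.

    Symmetric about x = 1/2 with apex 1/sqrt(2*pi); zero at both endpoints
    (the erfinv argument diverges there and the Gaussian tail wins).
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("arch is defined on [0, 1]")
    with np.errstate(over="ignore"):
        z = erfinv(2.0 * x - 1.0)
        out = np.exp(-(z * z)) / _SQRT2PI
    out = np.where(np.isfinite(z), out, 0.0)
    return out if out.ndim else float(out)


def _nearest_x_on_arch(
    I: np.ndarray, y: np.ndarray, m: TransitionModel, n_samples: int = 4096, refine: int = 40
) -> np.ndarray:
    """Curve parameter x minimising the Euclidean distance to (I, y) samples.

    Dense sampling of the curve followed by vectorised golden-section
    refinement inside the winning bracket; deterministic.
    """
    span = m.H - m.L
    xs = np.linspace(0.0, 1.0, n_samples)
    cx = m.L + xs * span
    cy = span * arch(xs)

    best = np.empty(I.shape, dtype=np.intp)
    chunk = max(1, int(2**22 // n_samples))
    flat_I, flat_y = I.ravel(), y.ravel()
    flat_best = best.ravel()
    for lo in range(0, flat_I.size, chunk):
        hi = min(lo + chunk, flat_I.size)
        d2 = (flat_I[lo:hi, None] - cx[None, :]) ** 2 + (flat_y[lo:hi, None] - cy[None, :]) ** 2
        flat_best[lo:hi] = np.argmin(d2, axis=1)

    step = 1.0 / (n_samples - 1)
    a = np.clip(xs[best] - step, 0.0, 1.0)
    b = np.clip(xs[best] + step, 0.0, 1.0)

    invphi = (np.sqrt(5.0) - 1.0) / 2.0

    def d2_at(x):
        return (I - (m.L + x * span)) ** 2 + (y - span * arch(x)) ** 2

    for _ in range(refine):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        take_left = d2_at(c) < d2_at(d)
        b = np.where(take_left, d, b)
        a = np.where(take_left, a, c)
    return 0.5 * (a + b)


def project_to_arch(
    s, m: TransitionModel, n_samples: int = 4096
):
    """Orthogonal projection of edge samples onto the arch; returns (I', t_low, t_high).

    ``s`` is either a single :class:`EdgeSample` or a pair of arrays
    ``(I, gI)``.  Intensities are clamped into [L, H] first so fractions stay
    in [0, 1]; the gradient axis is scaled by ``theta * sigma_omega`` before
    the Euclidean nearest-point search.  ``t_high = (I' - L) / (H - L)`` is
    the fraction of the brighter material.
    """
    if m.H == m.L:
        raise ValueError("degenerate transition model: H == L")
    scalar = isinstance(s, EdgeSample)
    if scalar:
        I = np.asarray([s.I], dtype=np.float64)
        gI = np.asarray([s.gI], dtype=np.float64)
    else:
        I = np.asarray(s[0], dtype=np.float64)
        gI = np.asarray(s[1], dtype=np.float64)

    I_cl = np.clip(I, m.L, m.H)
    y = m.theta * m.sigma_omega * np.abs(gI)
    x = _nearest_x_on_arch(I_cl, y, m, n_samples=n_samples)
    I_prime = m.L + x * (m.H - m.L)
    t_high = x
    t_low = 1.0 - x
    if scalar:
        return float(I_prime[0]), float(t_low[0]), float(t_high[0])
    return I_prime, t_low, t_high


_CONN6 = ndimage.generate_binary_structure(3, 1)


def _interior_mean(vol: HUVolume, mask: np.ndarray, name: str) -> float:
    """Mean HU over the 1-voxel-eroded mask, falling back to the raw mask.

    Erosion drops the partial-volume rim so the base reflects the pure
    material.
    """
    if not mask.any():
        raise BaseEstimationError(f"empty mask for material {name!r}")
    interior = ndimage.binary_erosion(mask, structure=_CONN6)
    if not interior.any():
        interior = mask
    return float(vol.data[interior].mean())


def estimate_bases(
    vol: HUVolume,
    masks: dict[str, np.ndarray | LabelMap],
    sigma_omega: float = 1.0,
) -> dict[str, TransitionModel]:
    """Per-volume transition bases from interior material means.

    ``masks`` must provide boolean (or label) masks under the keys ``air``,
    ``ST`` and ``FTM``.  The tagging pair (TA) runs air->tagging, the tissue
    pair (TT) soft tissue->tagging, and the air/soft-tissue pair (SA) reuses
    the air base as its low base and the soft-tissue base as its high base.
    """
    means = {}
    for name in ("air", "ST", "FTM"):
        if name not in masks:
            raise BaseEstimationError(f"empty mask for material {name!r}")
        raw = masks[name]
        mask = raw.mask() if isinstance(raw, LabelMap) else np.asarray(raw, dtype=bool)
        means[name] = _interior_mean(vol, mask, name)

    return {
        "TA": TransitionModel("TA", L=means["air"], H=means["FTM"], sigma_omega=sigma_omega),
        "TT": TransitionModel("TT", L=means["ST"], H=means["FTM"], sigma_omega=sigma_omega),
        "SA": TransitionModel("SA", L=means["air"], H=means["ST"], sigma_omega=sigma_omega),
    }


def estimate_theta(samples, m: TransitionModel, q: float = 95.0) -> float:
    """Apex-matching estimate of the gradient-axis scale factor theta.

    The model apex is (H - L) * arch(1/2); the empirical apex is the ``q``-th
    percentile of the scaled gradient magnitudes over the transition samples
    (robust to outliers while ignoring off-apex samples).  Their ratio makes
    measured edge samples lie on the arch.  Requires at least 50 samples;
    the result is clamped to [0.1, 10].
    """
    if isinstance(samples, (list, tuple)) and samples and isinstance(samples[0], EdgeSample):
        gI = np.array([s.gI for s in samples], dtype=np.float64)
    else:
        gI = np.asarray(samples, dtype=np.float64)
    if gI.size < 50:
        raise ValueError(f"need at least 50 transition samples, got {gI.size}")
    apex_emp = float(np.percentile(m.sigma_omega * np.abs(gI), q))
    if apex_emp <= 0:
        raise ValueError("empirical gradient apex is zero")
    theta = (m.H - m.L) * ARCH_APEX / apex_emp
    return float(np.clip(theta, 0.1, 10.0))


def three_fractions(pairs: dict[str, tuple[np.ndarray, np.ndarray]]) -> FractionField:
    """Combine the three pairwise fraction tuples into per-voxel material fractions.

    ``pairs`` maps ``TA``/``TT``/``SA`` to ``(t_low, t_high)``; each pair must
    sum to one (tolerance 1e-9).  The tagging fraction is the complement, so
    the three outputs sum to one identically.
    """
    vals = {}
    for key in ("TA", "TT", "SA"):
        if key not in pairs:
            raise ValueError(f"missing pair {key!r}")
        t_low = np.asarray(pairs[key][0], dtype=np.float64)
        t_high = np.asarray(pairs[key][1], dtype=np.float64)
        if np.abs(t_low + t_high - 1.0).max() > 1e-9:
            raise ValueError(f"pair {key!r} fractions do not sum to 1")
        vals[key] = (t_low, t_high)

    t_air = (vals["SA"][0] + vals["TA"][0]) / 3.0
    t_st = (vals["SA"][1] + vals["TT"][0]) / 3.0
    t_tr = 1.0 - t_air - t_st
    return FractionField(t_air=t_air, t_st=t_st, t_tr=t_tr)
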