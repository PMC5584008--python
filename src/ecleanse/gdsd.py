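"""Gaussian scale-space derivatives and the gradient-directional second derivative.

The gradient-directional second derivative (GDSD)

    f_ww = (fx^2 fxx + fy^2 fyy + fz^2 fzz
            + 2 fx fy fxy + 2 fx fz fxz + 2 fy fz fyz) / |grad f|^2

is the second derivative of the Gaussian-smoothed image along the local
gradient direction.  Across an edge it is positive on the darker side,
negative on the brighter side, and crosses zero at the edge centre, which is
what lets a cleansing rule tell pseudo-enhanced soft tissue (dark side of
the tissue-tagging edge) from tagging proper (bright side).

Intensities are normalised to [0, 1] over a fixed HU window before
differentiation so that f_ww is a bounded, dimensionless quantity usable as
a blend weight; residual excursions are clamped to [-1, 1] and voxels whose
gradient magnitude sits below a small floor (no local edge) are set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .volume_io import HUVolume

__all__ = ["GDSDField", "GaussianDerivatives", "gaussian_derivatives", "compute_gdsd"]

DEFAULT_HU_WINDOW = (-1000.0, 1400.0)


class GaussianDerivatives(NamedTuple):
    f_x: np.ndarray
    f_y: np.ndarray
    f_z: np.ndarray
    f_xx: np.ndarray
    f_yy: np.ndarray
    f_zz: np.ndarray
    f_xy: np.ndarray
    f_xz: np.ndarray
    f_yz: np.ndarray


@dataclass
class GDSDField:
    """Per-voxel GDSD in [-1, 1]; 0 where the gradient magnitude is below the floor."""

    f_ww: np.ndarray
    sigma: float = 1.0
    eps: float = 1e-4


def _deriv(data: np.ndarray, sigma: float, order: tuple[int, int, int]) -> np.ndarray:
    return ndimage.gaussian_filter(data, sigma=sigma, order=order, mode="mirror")


def gaussian_derivatives(vol: HUVolume | np.ndarray, sigma: float) -> GaussianDerivatives:
    """First and second Gaussian-derivative partials at scale ``sigma`` (voxels).

    Axis names follow the canonical order: x = axis 0 (slice), y = axis 1,
    z = axis 2.  Boundaries are mirrored.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    data = vol.data if isinstance(vol, HUVolume) else np.asarray(vol, dtype=np.float64)
    return GaussianDerivatives(
        f_x=_deriv(data, sigma, (1, 0, 0)),
        f_y=_deriv(data, sigma, (0, 1, 0)),
        f_z=_deriv(data, sigma, (0, 0, 1)),
        f_xx=_deriv(data, sigma, (2, 0, 0)),
        f_yy=_deriv(data, sigma, (0, 2, 0)),
        f_zz=_deriv(data, sigma, (0, 0, 2)),
        f_xy=_deriv(data, sigma, (1, 1, 0)),
        f_xz=_deriv(data, sigma, (1, 0, 1)),
        f_yz=_deriv(data, sigma, (0, 1, 1)),
    )


def compute_gdsd(
    vol: HUVolume,
    sigma: float = 1.0,
    eps: float = 1e-4,
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
) -> GDSDField:
    """GDSD of a HU volume at scale ``sigma`` after window normalisation.

    ``hu_window`` spans the full material range so the normalised image lies
    in [0, 1]; ``eps`` is the gradient-magnitude floor (normalised units per
    voxel) below which f_ww is defined as 0.
    """
    lo, hi = hu_window
    if not hi > lo:
        raise ValueError("hu_window must be increasing")
    norm = np.clip((vol.data - lo) / (hi - lo), 0.0, 1.0)
    d = gaussian_derivatives(norm, sigma)

    grad2 = d.f_x**2 + d.f_y**2 + d.f_z**2
    num = (
        d.f_x * d.f_x * d.f_xx
        + d.f_y * d.f_y * d.f_yy
        + d.f_z * d.f_z * d.f_zz
        + 2.0 * d.f_x * d.f_y * d.f_xy
        + 2.0 * d.f_x * d.f_z * d.f_xz
        + 2.0 * d.f_y * d.f_z * d.f_yz
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        f_ww = np.where(grad2 > eps * eps, num / grad2, 0.0)
    f_ww = np.clip(f_ww, -1.0, 1.0)
    return GDSDField(f_ww=f_ww, sigma=sigma, eps=eps)
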