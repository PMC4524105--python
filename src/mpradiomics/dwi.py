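"""Derived diffusion modalities: ADC, computed high-b DWI, and CDI.

Diffusion-weighted signal under the mono-exponential model is

    S(b) = S0 * exp(-b * D)

where ``b`` (s/mm^2) encodes the diffusion-sensitizing gradient and ``D``
(mm^2/s) the apparent diffusion coefficient.  From a series acquired at
several b-values this module fits per-voxel (S0, D) maps, extrapolates a
computed high-b-value image (CHB-DWI, default b = 2000 s/mm^2), and mixes
the acquired signals into a correlated diffusion image (CDI) that amplifies
tumour/healthy delineation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "DwiSeries",
    "ModalityVolume",
    "fit_adc",
    "compute_chb_dwi",
    "compute_cdi",
    "tumour_contrast",
]

#: smallest signal admitted into the log-linear fit
LOG_CLAMP = 1e-6

MODALITY_NAMES = ("T2w", "ADC", "CHB-DWI", "CDI", "b1", "b2", "b3", "b4")


@dataclass
class ModalityVolume:
    """One scalar volume (T2w, ADC, CHB-DWI, CDI, or a single-b image)."""

    name: str
    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class DwiSeries:
    """Co-registered diffusion volumes indexed by b-value for one patient."""

    b_values: Sequence[float]
    volumes: Sequence[np.ndarray]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=np.float64)
        if len(self.b_values) != len(self.volumes):
            raise ValueError("one volume per b-value required")
        if len(self.b_values) < 2:
            raise ValueError("at least two b-values required")
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b_values must be strictly increasing")
        vols = [np.asarray(v, dtype=np.float64) for v in self.volumes]
        shapes = {v.shape for v in vols}
        if len(shapes) != 1:
            raise ValueError(f"volumes are not co-registered: shapes {shapes}")
        for b, v in zip(self.b_values, vols):
            if np.any(v < 0):
                raise ValueError(f"negative signal in b={b:g} volume")
        self.volumes = vols
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[0].shape

    def stacked(self) -> np.ndarray:
        """All volumes as one (n_b, *grid) array."""
        return np.stack(self.volumes, axis=0)


def fit_adc(series: DwiSeries, mask: np.ndarray) -> tuple[ModalityVolume, ModalityVolume]:
    """Fit per-voxel mono-exponential decay by log-linear least squares.

    ln S is regressed on b at every masked voxel: slope = -D, intercept =
    ln S0.  Signals are clamped to ``LOG_CLAMP`` before the log; negative
    fitted D is clamped to 0.  Voxels outside the mask are set to 0.

    Returns
    -------
    (adc, s0) : tuple of ModalityVolume
        ADC map in mm^2/s and the extrapolated b=0 signal map.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape:
        raise ValueError("mask shape does not match series grid")

    b = series.b_values
    signals = series.stacked()[:, mask]  # (n_b, n_vox)

    dead = np.all(signals <= 0, axis=0)
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} masked voxel(s) with all-zero signal; D and S0 set to 0",
            RuntimeWarning,
            stacklevel=2,
        )

    log_s = np.log(np.clip(signals, LOG_CLAMP, None))
    # closed-form simple linear regression of log S on b
    b_mean = b.mean()
    b_var = np.sum((b - b_mean) ** 2)
    y_mean = log_s.mean(axis=0)
    slope = (b - b_mean) @ (log_s - y_mean) / b_var
    intercept = y_mean - slope * b_mean

    d = np.clip(-slope, 0.0, None)
    s0 = np.exp(intercept)
    d[dead] = 0.0
    s0[dead] = 0.0

    adc_vol = np.zeros(series.shape)
    s0_vol = np.zeros(series.shape)
    adc_vol[mask] = d
    s0_vol[mask] = s0
    return (
        ModalityVolume("ADC", adc_vol, series.spacing),
        ModalityVolume("S0", s0_vol, series.spacing),
    )


def compute_chb_dwi(
    series: DwiSeries, mask: np.ndarray, b_target: float = 2000.0
) -> ModalityVolume:
    """Extrapolate a computed high-b-value image from the fitted decay model.

    CHB-DWI(x) = S0(x) * exp(-b_target * D(x)) using the maps from
    :func:`fit_adc`.  ``b_target`` must exceed the largest acquired b-value:
    this operation is strictly an extrapolator.
    """
    if b_target <= series.b_values.max():
        raise ValueError(
            f"b_target={b_target:g} must exceed the largest acquired "
            f"b-value ({series.b_values.max():g}); CHB-DWI is an extrapolation"
        )
    adc, s0 = fit_adc(series, mask)
    data = s0.data * np.exp(-b_target * adc.data)
    return ModalityVolume("CHB-DWI", data, series.spacing)


def compute_cdi(
    series: DwiSeries,
    mask: np.ndarray,
    subvolume_radius: tuple[int, int, int] | int = (1, 1, 0),
    rescale: bool = False,
) -> ModalityVolume:
    """Correlated diffusion imaging by local signal mixing.

    The CDI signal at x mixes the acquired signals across all b-values
    within a local subvolume V(x).  With the empirical (delta-mass)
    estimator of the joint signal density over V(x), the mixing integral
    reduces to a local mean of cross-b products:

        CDI(x) = mean_{y in V(x)}  prod_i S_i(y)

    V(x) is a box of half-widths ``subvolume_radius`` clipped at the image
    border (no padding).  The default (1, 1, 0) mixes over 3x3 in-plane
    neighbourhoods only: at 3 mm slice thickness there is no through-plane
    mixing.

    Parameters
    ----------
    rescale : bool
        If True, linearly rescale the output to [0, 1] over the mask.
    """
    if isinstance(subvolume_radius, (int, np.integer)):
        subvolume_radius = (int(subvolume_radius),) * 3
    radius = tuple(int(r) for r in subvolume_radius)
    if any(r < 0 for r in radius):
        raise ValueError("subvolume_radius must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape:
        raise ValueError("mask shape does not match series grid")

    product = np.prod(series.stacked(), axis=0)

    # clipped box mean: sum over the clipped neighbourhood / its voxel count
    ones = np.ones_like(product)
    box_sum = _clipped_box_sum(product, radius)
    box_cnt = _clipped_box_sum(ones, radius)
    if np.any(box_cnt <= 0):  # unreachable with border clipping
        raise RuntimeError("empty CDI subvolume encountered")
    cdi = box_sum / box_cnt

    if rescale:
        inside = cdi[mask]
        lo, hi = inside.min(), inside.max()
        if hi > lo:
            cdi = (cdi - lo) / (hi - lo)
        else:
            cdi = np.zeros_like(cdi)
    return ModalityVolume("CDI", cdi, series.spacing)


def tumour_contrast(
    volume: np.ndarray, tumour_mask: np.ndarray, healthy_mask: np.ndarray
) -> dict[str, float]:
    """Tumour/healthy delineation summary for one modality volume.

    ``ratio`` is the tumour-to-healthy mean-intensity ratio and
    ``relative_contrast`` the normalized absolute mean difference
    |mu_t - mu_h| / mu_h; both are scale-free and well defined even on
    noiseless input (where within-class variance can vanish).
    """
    t = np.asarray(volume)[np.asarray(tumour_mask, dtype=bool)]
    h = np.asarray(volume)[np.asarray(healthy_mask, dtype=bool)]
    if t.size == 0 or h.size == 0:
        raise ValueError("both tumour and healthy masks must be non-empty")
    mu_t, mu_h = float(t.mean()), float(h.mean())
    return {
        "mean_tumour": mu_t,
        "mean_healthy": mu_h,
        "ratio": mu_t / mu_h,
        "relative_contrast": abs(mu_t - mu_h) / mu_h,
    }


def _clipped_box_sum(volume: np.ndarray, radius: tuple[int, int, int]) -> np.ndarray:
    """Sum over a (2r+1)^3 box around each voxel, clipped at the borders."""
    out = volume
    for axis, r in enumerate(radius):
        if r == 0:
            continue
        padded = np.concatenate(
            [np.zeros_like(out.take(range(r), axis=axis)), out,
             np.zeros_like(out.take(range(r), axis=axis))],
            axis=axis,
        )
        win = sliding_window_view(padded, 2 * r + 1, axis=axis)
        out = win.sum(axis=-1)
    return out
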