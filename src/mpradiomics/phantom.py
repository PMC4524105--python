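"""Synthetic MP-MRI phantom cohorts with known ground truth.

Each synthetic patient carries a T2-weighted volume, a multi-b-value DWI
series, a prostate-gland mask and a tumour mask on a common voxel grid.
The gland is an ellipsoid; 0-2 lesions are smaller ellipsoids nested inside
it.  Noiseless DWI follows the mono-exponential decay S(b) = S0*exp(-b*D)
with restricted diffusion (smaller D) inside lesions; T2w shows a mild
signal drop in lesions.  Acquisition noise is Rician, as appropriate for
magnitude MR images.  Everything is deterministic given (seed,
patient_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .dwi import DwiSeries, ModalityVolume

__all__ = ["PhantomConfig", "PatientStudy", "generate_study", "generate_cohort"]


@dataclass
class PhantomConfig:
    """Study-generation parameters.

    Diffusion coefficients are in mm^2/s and are sampled per patient from
    the given (low, high) ranges; prostate tumours show restricted
    diffusion, so ``D_tumour`` must lie strictly below ``D_healthy``.
    ``tumour_fraction`` is the target fraction of gland voxels that are
    cancerous (clinical prostate data is extremely imbalanced, ~1-1.5 %).
    """

    n_patients: int = 20
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    voxel_spacing: tuple[float, float, float] = (1.56, 1.56, 3.0)
    b_values: tuple[float, ...] = (0.0, 100.0, 400.0, 1000.0)
    D_healthy: tuple[float, float] = (1.4e-3, 2.0e-3)
    D_tumour: tuple[float, float] = (5.0e-4, 9.0e-4)
    S0_range: tuple[float, float] = (800.0, 1200.0)
    t2w_tumour_drop: float = 0.25
    noise_sigma: float = 10.0
    tumour_fraction: float = 0.015
    lesion_count_probs: tuple[float, ...] = (0.15, 0.45, 0.40)  # P(0), P(1), P(2) lesions
    bias_field_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b[0] != 0.0 or np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing and start at 0")
        if not (0.0 < self.D_tumour[0] and self.D_tumour[1] < self.D_healthy[0]):
            raise ValueError(
                "tumour diffusion must be restricted: 0 < D_tumour < D_healthy"
            )
        if not (0.0 < self.tumour_fraction < 0.1):
            raise ValueError("tumour_fraction must lie in (0, 0.1)")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"degenerate grid {self.grid_shape}: every axis needs >= 8 voxels")
        if abs(sum(self.lesion_count_probs) - 1.0) > 1e-9:
            raise ValueError("lesion_count_probs must sum to 1")


@dataclass
class PatientStudy:
    """All volumes, masks and ground truth for one (synthetic) patient."""

    patient_id: str
    dwi: DwiSeries
    t2w: ModalityVolume
    gland_mask: np.ndarray
    tumour_mask: np.ndarray
    derived: dict[str, ModalityVolume] = field(default_factory=dict)
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gland_mask = np.asarray(self.gland_mask, dtype=bool)
        self.tumour_mask = np.asarray(self.tumour_mask, dtype=bool)
        if np.any(self.tumour_mask & ~self.gland_mask):
            raise ValueError("tumour_mask must be nested inside gland_mask")

    def modality(self, name: str) -> ModalityVolume:
        """Look up a modality volume by name (T2w, ADC, CHB-DWI, CDI, b1..b4)."""
        if name == "T2w":
            return self.t2w
        if name in self.derived:
            return self.derived[name]
        if name.startswith("b") and name[1:].isdigit():
            idx = int(name[1:]) - 1
            if 0 <= idx < len(self.dwi.b_values):
                return ModalityVolume(name, self.dwi.volumes[idx], self.dwi.spacing)
        raise KeyError(f"modality {name!r} not present on study {self.patient_id}")


def _ellipsoid(shape, centre, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, centre, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return signal.copy()
    real = signal + rng.normal(0.0, sigma, signal.shape)
    imag = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(real**2 + imag**2)


def _bias_field(rng: np.random.Generator, shape, amplitude: float) -> np.ndarray:
    """Smooth multiplicative inhomogeneity field around 1."""
    if amplitude == 0:
        return np.ones(shape)
    noise = rng.normal(0.0, 1.0, shape)
    smooth = ndimage.gaussian_filter(noise, sigma=[s / 4 for s in shape])
    span = smooth.max() - smooth.min()
    if span == 0:
        return np.ones(shape)
    return 1.0 + amplitude * (2 * (smooth - smooth.min()) / span - 1.0)


def generate_study(config: PhantomConfig, patient_index: int) -> PatientStudy:
    """Generate one synthetic patient study.

    Deterministic given (config.seed, patient_index).
    """
    if patient_index >= config.n_patients:
        raise ValueError(
            f"patient_index {patient_index} out of range for n_patients={config.n_patients}"
        )
    rng = np.random.default_rng([config.seed, patient_index])
    shape = tuple(config.grid_shape)

    # gland: jittered ellipsoid around the grid centre
    centre = [n / 2 + rng.uniform(-0.05, 0.05) * n for n in shape]
    semi = [
        rng.uniform(0.30, 0.40) * shape[0],
        rng.uniform(0.28, 0.38) * shape[1],
        rng.uniform(0.28, 0.38) * shape[2],
    ]
    gland = _ellipsoid(shape, centre, semi)
    n_gland = int(gland.sum())

    # lesions: ellipsoids nested in the gland, sized to the target fraction
    n_lesions = int(rng.choice(len(config.lesion_count_probs), p=config.lesion_count_probs))
    tumour = np.zeros(shape, dtype=bool)
    lesion_params: list[dict[str, Any]] = []
    if n_lesions > 0:
        target_voxels = config.tumour_fraction * n_gland / n_lesions
        for _ in range(n_lesions):
            # semi-axes: flat ellipsoid (few slices thick), volume ~ target
            cz = max(1.0, rng.uniform(0.8, 1.4))
            ab = np.sqrt(target_voxels / (4.0 / 3.0 * np.pi * cz))
            ax = ab * rng.uniform(0.8, 1.25)
            ay = ab**2 / ax
            # centre at a point well inside the gland
            frac = rng.uniform(0.0, 0.55, size=3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            lc = [c + f * s * d for c, s, f, d in zip(centre, semi, frac, direction)]
            lesion = _ellipsoid(shape, lc, (ax, ay, cz)) & gland
            tumour |= lesion
            lesion_params.append(
                {"centre": [float(v) for v in lc], "semi_axes": [float(ax), float(ay), float(cz)]}
            )

    # per-patient tissue parameters
    d_healthy = rng.uniform(*config.D_healthy)
    d_tumour = rng.uniform(*config.D_tumour)
    s0_level = rng.uniform(*config.S0_range)
    t2w_level = rng.uniform(0.4, 0.6) * s0_level

    bias = _bias_field(rng, shape, config.bias_field_amplitude)

    d_map = np.full(shape, 2.2e-3)  # peri-prostatic background diffuses freely
    d_map[gland] = d_healthy
    d_map[tumour] = d_tumour
    s0_map = s0_level * bias
    s0_map[~gland] *= 0.5  # darker background tissue

    b = np.asarray(config.b_values, dtype=float)
    noiseless = [s0_map * np.exp(-bv * d_map) for bv in b]
    volumes = [_rician(rng, v, config.noise_sigma) for v in noiseless]
    dwi = DwiSeries(b, volumes, config.voxel_spacing)

    t2w_clean = t2w_level * bias
    t2w_clean[~gland] *= 0.5
    t2w_clean[tumour] *= 1.0 - config.t2w_tumour_drop
    t2w = ModalityVolume("T2w", _rician(rng, t2w_clean, config.noise_sigma), config.voxel_spacing)

    gt = {
        "D_healthy": float(d_healthy),
        "D_tumour": float(d_tumour),
        "S0": float(s0_level),
        "t2w_level": float(t2w_level),
        "n_lesions": n_lesions,
        "lesions": lesion_params,
        "n_gland_voxels": n_gland,
        "n_tumour_voxels": int(tumour.sum()),
        "tumour_fraction_realized": float(tumour.sum() / max(n_gland, 1)),
    }
    return PatientStudy(
        patient_id=f"P{patient_index:03d}",
        dwi=dwi,
        t2w=t2w,
        gland_mask=gland,
        tumour_mask=tumour,
        ground_truth=gt,
    )


def generate_cohort(config: PhantomConfig) -> list[PatientStudy]:
    """Generate the full synthetic cohort (one study per patient)."""
    if config.n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    return [generate_study(config, i) for i in range(config.n_patients)]
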