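"""NIfTI study I/O, grid resampling, and pipeline configuration.

A study directory holds one NIfTI volume per modality::

    t2w.nii.gz  dwi_b0.nii.gz  dwi_b100.nii.gz  dwi_b400.nii.gz
    dwi_b1000.nii.gz  gland_mask.nii.gz  tumour_mask.nii.gz
    [adc.nii.gz  chb_dwi.nii.gz  cdi.nii.gz ...]   study.json

plus a JSON sidecar with the patient id, b-values and (for phantom
studies) the ground-truth generation parameters.  All volumes of one
study share a grid; the T2w volume, natively on a finer grid in clinical
acquisitions, is resampled onto the DWI grid before feature extraction so
that multi-modal windows align.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

from .dwi import DwiSeries, ModalityVolume
from .phantom import PatientStudy, PhantomConfig

__all__ = ["PipelineConfig", "read_study", "write_study", "resample_to_grid"]


@dataclass
class PipelineConfig:
    """Fully serializable run configuration; its hash stamps output artifacts."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    b_target: float = 2000.0
    cdi_radius: int = 1
    window_size: int = 3
    window_stride: int = 1
    glcm_levels: int = 16
    m_grid: tuple[int, ...] = (10, 30, 60, 96)
    criterion: str = "auc"
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    max_train_samples: int | None = 3000
    bootstrap_reps: int = 2000
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        phantom = PhantomConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("phantom").items()
        })
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(phantom=phantom, **raw)

_DERIVED_FILES = {"ADC": "adc.nii.gz", "CHB-DWI": "chb_dwi.nii.gz", "CDI": "cdi.nii.gz",
                  "S0": "s0.nii.gz"}


def _affine(spacing) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def _save(path: Path, data: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(spacing))
    nib.save(img, str(path))


def _load(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=np.float64), spacing


def write_study(study: PatientStudy, directory) -> None:
    """Write all volumes and the ground-truth sidecar of one study."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sp = study.dwi.spacing
    _save(d / "t2w.nii.gz", study.t2w.data, study.t2w.spacing)
    for b, vol in zip(study.dwi.b_values, study.dwi.volumes):
        _save(d / f"dwi_b{int(b)}.nii.gz", vol, sp)
    _save(d / "gland_mask.nii.gz", study.gland_mask.astype(np.float64), sp)
    _save(d / "tumour_mask.nii.gz", study.tumour_mask.astype(np.float64), sp)
    for name, vol in study.derived.items():
        fname = _DERIVED_FILES.get(name, name.lower().replace("-", "_") + ".nii.gz")
        _save(d / fname, vol.data, vol.spacing)
    sidecar = {
        "patient_id": study.patient_id,
        "b_values": [float(b) for b in study.dwi.b_values],
        "derived": sorted(study.derived),
        # NIfTI-1 headers hold pixdim as float32; keep exact spacings here
        "spacing": list(study.dwi.spacing),
        "t2w_spacing": list(study.t2w.spacing),
        "ground_truth": study.ground_truth,
    }
    (d / "study.json").write_text(json.dumps(sidecar, indent=1))


def read_study(directory) -> PatientStudy:
    """Read a study directory back; inverse of :func:`write_study`."""
    d = Path(directory)
    sidecar_path = d / "study.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing study sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    b_values = sorted(float(b) for b in sidecar["b_values"])

    volumes = []
    spacing = None
    for b in b_values:
        path = d / f"dwi_b{int(b)}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing DWI volume for b={int(b)}: {path}")
        data, sp = _load(path)
        if spacing is None:
            spacing = sp
        elif sp != spacing:
            raise ValueError(f"inconsistent voxel spacing in {path}")
        volumes.append(data)
    if "spacing" in sidecar:
        spacing = tuple(float(s) for s in sidecar["spacing"])

    shapes = {v.shape for v in volumes}
    for required in ("t2w", "gland_mask", "tumour_mask"):
        if not (d / f"{required}.nii.gz").exists():
            raise FileNotFoundError(f"missing required volume {required}.nii.gz in {d}")
    t2w_data, t2w_sp = _load(d / "t2w.nii.gz")
    if "t2w_spacing" in sidecar:
        t2w_sp = tuple(float(s) for s in sidecar["t2w_spacing"])
    gland, _ = _load(d / "gland_mask.nii.gz")
    tumour, _ = _load(d / "tumour_mask.nii.gz")
    shapes |= {gland.shape, tumour.shape}
    if len(shapes) != 1:
        raise ValueError(f"volumes in {d} have inconsistent shapes: {shapes}")

    study = PatientStudy(
        patient_id=sidecar["patient_id"],
        dwi=DwiSeries(b_values, volumes, spacing),
        t2w=ModalityVolume("T2w", t2w_data, t2w_sp),
        gland_mask=gland > 0.5,
        tumour_mask=tumour > 0.5,
        ground_truth=sidecar.get("ground_truth", {}),
    )
    inverse = {v: k for k, v in _DERIVED_FILES.items()}
    for path in sorted(d.glob("*.nii.gz")):
        name = inverse.get(path.name)
        if name is not None:
            data, _ = _load(path)
            study.derived[name] = ModalityVolume(name, data, spacing)
    return study


def resample_to_grid(
    volume: ModalityVolume,
    target_shape: tuple[int, int, int],
    target_spacing: tuple[float, float, float],
    interpolation: str = "linear",
) -> ModalityVolume:
    """Resample a volume onto a target grid (axis-aligned, shared origin).

    Voxel centres follow the half-voxel convention: index i maps to world
    coordinate (i + 0.5) * spacing.  ``interpolation`` is 'linear' for
    intensity volumes and 'nearest' for masks (output stays binary).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    src_spacing = np.asarray(volume.spacing, dtype=np.float64)
    tgt_spacing = np.asarray(target_spacing, dtype=np.float64)
    if np.any(src_spacing <= 0) or np.any(tgt_spacing <= 0):
        raise ValueError("voxel spacings must be positive (non-invertible grid mapping)")
    if tuple(target_shape) == volume.data.shape and np.allclose(src_spacing, tgt_spacing):
        return ModalityVolume(volume.name, volume.data.copy(), tuple(tgt_spacing))

    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in target_shape], indexing="ij")
    coords = [
        (g + 0.5) * ts / ss - 0.5 for g, ts, ss in zip(grids, tgt_spacing, src_spacing)
    ]
    order = 1 if interpolation == "linear" else 0
    data = ndimage.map_coordinates(
        volume.data, np.stack(coords), order=order, mode="nearest"
    )
    return ModalityVolume(volume.name, data, tuple(float(s) for s in tgt_spacing))
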