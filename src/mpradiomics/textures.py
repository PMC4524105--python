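"""96-feature texture vectors in sliding windows over the prostate gland.

Per imaging modality the feature vector has four families:

* 4 first-order statistics (mean, std, skewness, excess kurtosis),
* 72 Haralick statistics from grey-level co-occurrence matrices (18
  statistics x 4 directions at offset distance 1),
* 12 Gabor magnitudes (3 spatial frequencies x 4 orientations),
* 8 Kirsch compass-gradient maxima,

for 4 + 72 + 12 + 8 = 96 features.  Features are computed for a small 2-D
window (default 3x3 pixels) sliding slice-wise over the gland mask; windows
are 2-D because slices are much thicker (3 mm) than the in-plane spacing.
A window inherits the tumour/healthy label of its centre voxel, matching
pixel-based evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

from .phantom import PatientStudy

__all__ = [
    "WindowSpec",
    "FeatureMatrix",
    "first_order_features",
    "glcm_features",
    "gabor_features",
    "kirsch_features",
    "extract_features",
    "quantize_volume",
    "GLCM_FEATURE_NAMES",
    "GLCM_DIRECTIONS",
    "GABOR_FREQUENCIES",
    "GABOR_ORIENTATIONS_DEG",
    "KIRSCH_DIRECTIONS",
]

FIRST_ORDER_NAMES = ("mean", "std", "skewness", "kurtosis")

#: the 18 co-occurrence statistics, in inventory order
GLCM_FEATURE_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "homogeneity",
    "autocorrelation",
    "dissimilarity",
    "cluster_shade",
    "cluster_prominence",
    "maximum_probability",
)

#: direction label -> (row, col) offset of the co-occurring pixel
GLCM_DIRECTIONS = {
    "d000": (0, 1),
    "d045": (-1, 1),
    "d090": (-1, 0),
    "d135": (-1, -1),
}

GABOR_FREQUENCIES = (0.1, 0.25, 0.4)  # cycles/pixel
GABOR_ORIENTATIONS_DEG = (0, 45, 90, 135)

#: classic 3x3 compass kernels (+-5 / +-3), one per direction
_KIRSCH_N = np.array([[5, 5, 5], [-3, 0, -3], [-3, -3, -3]])
KIRSCH_DIRECTIONS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


def _kirsch_kernels() -> list[np.ndarray]:
    ring = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
    base = [_KIRSCH_N[r, c] for r, c in ring]
    kernels = []
    for k in range(8):
        rot = base[-k:] + base[:-k] if k else list(base)
        kern = np.zeros((3, 3))
        for (r, c), v in zip(ring, rot):
            kern[r, c] = v
        kernels.append(kern)
    return kernels


_KIRSCH_KERNELS = _kirsch_kernels()

_EPS = np.finfo(float).tiny


@dataclass
class WindowSpec:
    """Sliding-window geometry and labelling rule."""

    size: int = 3
    stride: int = 1
    label_rule: str = "centre"

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("window size must be odd and >= 3")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.label_rule != "centre":
            raise ValueError(f"unknown label rule {self.label_rule!r}")


@dataclass
class FeatureMatrix:
    """Samples x named features with labels, patient ids and coordinates."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    patient_ids: np.ndarray
    sample_coords: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=bool)
        self.patient_ids = np.asarray(self.patient_ids)
        self.sample_coords = np.asarray(self.sample_coords)
        self.feature_names = list(self.feature_names)
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match value columns")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if not (len(self.labels) == len(self.patient_ids) == len(self.sample_coords) == n):
            raise ValueError("per-sample metadata lengths disagree")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given order."""
        index = {name: i for i, name in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"unknown feature(s): {missing}")
        cols = [index[n] for n in names]
        return FeatureMatrix(
            self.values[:, cols], list(names), self.labels, self.patient_ids, self.sample_coords
        )

    def rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[idx],
            self.feature_names,
            self.labels[idx],
            self.patient_ids[idx],
            self.sample_coords[idx],
        )

    @classmethod
    def hstack(cls, matrices: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        """Concatenate feature columns of sample-aligned matrices."""
        first = matrices[0]
        for m in matrices[1:]:
            if (
                len(m.labels) != len(first.labels)
                or np.any(m.labels != first.labels)
                or np.any(m.patient_ids != first.patient_ids)
                or np.any(m.sample_coords != first.sample_coords)
            ):
                raise ValueError("matrices are not sample-aligned")
        return cls(
            np.hstack([m.values for m in matrices]),
            [n for m in matrices for n in m.feature_names],
            first.labels,
            first.patient_ids,
            first.sample_coords,
        )

    @classmethod
    def vstack(cls, matrices: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        """Concatenate samples of matrices sharing one feature set."""
        names = matrices[0].feature_names
        for m in matrices[1:]:
            if m.feature_names != names:
                raise ValueError("matrices do not share a feature set")
        return cls(
            np.vstack([m.values for m in matrices]),
            names,
            np.concatenate([m.labels for m in matrices]),
            np.concatenate([m.patient_ids for m in matrices]),
            np.vstack([m.sample_coords for m in matrices]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "x": self.sample_coords[:, 0],
                "y": self.sample_coords[:, 1],
                "z": self.sample_coords[:, 2],
                "label": np.where(self.labels, "cancerous", "healthy"),
            }
        )
        return pd.concat([meta, pd.DataFrame(self.values, columns=self.feature_names)], axis=1)

    def save_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        sidecar = {
            "feature_names": self.feature_names,
            "n_samples": int(self.n_samples),
            "n_cancerous": int(self.labels.sum()),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["patient_id", "x", "y", "z", "label"]
        names = [c for c in df.columns if c not in meta_cols]
        return cls(
            df[names].to_numpy(dtype=np.float64),
            names,
            df["label"].to_numpy() == "cancerous",
            df["patient_id"].to_numpy(dtype=str),
            df[["x", "y", "z"]].to_numpy(dtype=int),
        )


# ---------------------------------------------------------------------------
# per-window feature families


def first_order_features(window: np.ndarray) -> dict[str, float]:
    """Mean, population std, skewness and excess kurtosis of a patch.

    Constant patches get skewness = kurtosis = 0 by convention (the moment
    ratios are otherwise undefined).
    """
    x = np.asarray(window, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty window")
    mean = x.mean()
    centred = x - mean
    var = np.mean(centred**2)
    std = np.sqrt(var)
    if std <= 1e-12 * (1.0 + abs(mean)):
        return {"mean": float(mean), "std": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    skew = np.mean(centred**3) / std**3
    kurt = np.mean(centred**4) / std**4 - 3.0
    return {"mean": float(mean), "std": float(std), "skewness": float(skew), "kurtosis": float(kurt)}


def quantize_volume(data: np.ndarray, mask: np.ndarray, levels: int = 16) -> np.ndarray:
    """Min-max quantize to integer grey levels 0..levels-1.

    The scaling range is taken over ``mask`` (the gland) so that windows
    keep their inter-window contrast; values outside the range clip.
    """
    data = np.asarray(data, dtype=np.float64)
    inside = data[np.asarray(mask, dtype=bool)]
    lo, hi = float(inside.min()), float(inside.max())
    if hi <= lo:
        return np.zeros(data.shape, dtype=np.int64)
    q = np.floor((data - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _quantize_patch(patch: np.ndarray, levels: int) -> np.ndarray:
    lo, hi = float(patch.min()), float(patch.max())
    if hi <= lo:
        return np.zeros(patch.shape, dtype=np.int64)
    return np.clip(np.floor((patch - lo) / (hi - lo) * levels), 0, levels - 1).astype(np.int64)


def _glcm_from_patch(q: np.ndarray, offset: tuple[int, int], levels: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix of one integer patch."""
    dr, dc = offset
    h, w = q.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.zeros((levels, levels))
    np.add.at(counts, (a, b), 1.0)
    sym = counts + counts.T
    total = sym.sum()
    if total == 0:
        raise ValueError("patch too small for this co-occurrence offset")
    return sym / total


def _log2(p: np.ndarray) -> np.ndarray:
    return np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)


@lru_cache(maxsize=8)
def _haralick_weights(L: int) -> dict[str, np.ndarray]:
    """Flat (L*L,) weight vectors and marginal indicator maps for level count L."""
    i = np.arange(L, dtype=np.float64)
    I = np.repeat(i, L)
    J = np.tile(i, L)
    sum_idx = (I + J).astype(int)
    diff_idx = np.abs(I - J).astype(int)
    A_sum = np.zeros((L * L, 2 * L - 1))
    A_sum[np.arange(L * L), sum_idx] = 1.0
    A_diff = np.zeros((L * L, L))
    A_diff[np.arange(L * L), diff_idx] = 1.0
    return {
        "i": i,
        "contrast": (I - J) ** 2,
        "idm": 1.0 / (1.0 + (I - J) ** 2),
        "homog": 1.0 / (1.0 + np.abs(I - J)),
        "dissim": np.abs(I - J),
        "autocorr": I * J,
        "A_sum": A_sum,
        "A_diff": A_diff,
        "k_sum": np.arange(2 * L - 1, dtype=np.float64),
        "k_diff": np.arange(L, dtype=np.float64),
        "A_px": np.kron(np.eye(L), np.ones((L, 1))),  # flat -> row marginal
        "A_py": np.kron(np.ones((L, 1)), np.eye(L)),  # flat -> col marginal
    }


def haralick_statistics(glcms: np.ndarray) -> np.ndarray:
    """The 18 co-occurrence statistics for a batch of normalized GLCMs.

    Parameters
    ----------
    glcms : (n, L, L) array of symmetric matrices, each summing to 1.

    Returns
    -------
    (n, 18) array ordered as ``GLCM_FEATURE_NAMES``.  Entropies are in
    bits.  For a single-cell (constant-window) matrix the conventions are
    energy = 1, contrast = 0, and correlation and the entropy-type
    statistics 0.
    """
    P = np.asarray(glcms, dtype=np.float64)
    if P.ndim == 2:
        P = P[None]
    n, L, _ = P.shape
    W = _haralick_weights(L)
    i = W["i"]
    flat = P.reshape(n, L * L)

    px = flat @ W["A_px"]  # marginal over j
    py = flat @ W["A_py"]
    mu_x = px @ i
    mu_y = py @ i
    var_x = px @ (i**2) - mu_x**2
    var_y = py @ (i**2) - mu_y**2

    energy = (flat**2).sum(axis=1)
    contrast = flat @ W["contrast"]
    denom = np.sqrt(np.clip(var_x * var_y, 0.0, None))
    autocorrelation = flat @ W["autocorr"]
    corr_num = autocorrelation - mu_x * mu_y  # E[IJ] - E[I]E[J]
    correlation = np.where(denom > 0, corr_num / np.where(denom > 0, denom, 1.0), 0.0)
    variance = var_x
    idm = flat @ W["idm"]

    p_sum = flat @ W["A_sum"]  # distribution of i+j
    p_diff = flat @ W["A_diff"]  # distribution of |i-j|
    k_sum, k_diff = W["k_sum"], W["k_diff"]

    sum_average = p_sum @ k_sum
    sum_variance = p_sum @ (k_sum**2) - sum_average**2
    sum_entropy = -(p_sum * _log2(p_sum)).sum(axis=1)
    entropy = -(flat * _log2(flat)).sum(axis=1)
    diff_average = p_diff @ k_diff
    difference_variance = p_diff @ (k_diff**2) - diff_average**2
    difference_entropy = -(p_diff * _log2(p_diff)).sum(axis=1)

    hx = -(px * _log2(px)).sum(axis=1)
    hy = -(py * _log2(py)).sum(axis=1)
    # HXY1 = -sum_ij p_ij log2(px_i py_j) collapses exactly to HX + HY
    hmax = np.maximum(hx, hy)
    imc1 = np.where(hmax > 0, (entropy - hx - hy) / np.where(hmax > 0, hmax, 1.0), 0.0)

    homogeneity = flat @ W["homog"]
    dissimilarity = flat @ W["dissim"]
    # central moments of T = i+j around mu_x + mu_y, by binomial expansion
    m = mu_x + mu_y
    t1, t2 = sum_average, p_sum @ (k_sum**2)
    t3, t4 = p_sum @ (k_sum**3), p_sum @ (k_sum**4)
    cluster_shade = t3 - 3 * m * t2 + 3 * m**2 * t1 - m**3
    cluster_prominence = t4 - 4 * m * t3 + 6 * m**2 * t2 - 4 * m**3 * t1 + m**4
    maximum_probability = flat.max(axis=1)

    return np.column_stack(
        [
            energy,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            homogeneity,
            autocorrelation,
            dissimilarity,
            cluster_shade,
            cluster_prominence,
            maximum_probability,
        ]
    )


def glcm_features(
    window: np.ndarray,
    levels: int = 16,
    directions: Iterable[str] = tuple(GLCM_DIRECTIONS),
    quantize: bool = True,
) -> dict[str, float]:
    """The 18 co-occurrence statistics per direction for one patch.

    With the four default directions this yields 72 named values.  Set
    ``quantize=False`` to treat the patch as already holding integer grey
    levels in [0, levels).
    """
    patch = np.asarray(window, dtype=np.float64)
    q = _quantize_patch(patch, levels) if quantize else patch.astype(np.int64)
    if q.min() < 0 or q.max() >= levels:
        raise ValueError("pre-quantized patch values must lie in [0, levels)")
    out: dict[str, float] = {}
    for direction in directions:
        glcm = _glcm_from_patch(q, GLCM_DIRECTIONS[direction], levels)
        stats = haralick_statistics(glcm)[0]
        for name, value in zip(GLCM_FEATURE_NAMES, stats):
            out[f"{name}/{direction}"] = float(value)
    return out


@lru_cache(maxsize=64)
def _cached_gabor_kernel(frequency: float, theta: float) -> np.ndarray:
    return np.asarray(gabor_kernel(frequency, theta=theta))


def _gabor_magnitude(image: np.ndarray, frequency: float, theta: float) -> np.ndarray:
    """|complex Gabor response| with reflect boundary handling."""
    kernel = _cached_gabor_kernel(float(frequency), float(theta))
    kh, kw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((kh, kh), (kw, kw)), mode="symmetric")
    resp = fftconvolve(padded, kernel, mode="valid")
    return np.abs(resp)


def gabor_features(
    patch: np.ndarray,
    frequencies: Sequence[float] = GABOR_FREQUENCIES,
    orientations_deg: Sequence[float] = GABOR_ORIENTATIONS_DEG,
) -> dict[str, float]:
    """Mean Gabor magnitude per (frequency, orientation) over a patch.

    The patch is filtered as an image (reflect boundary) and the response
    magnitude averaged over it; 3 frequencies x 4 orientations = 12 values.
    """
    image = np.asarray(patch, dtype=np.float64)
    out: dict[str, float] = {}
    for f in frequencies:
        for deg in orientations_deg:
            mag = _gabor_magnitude(image, f, np.deg2rad(deg))
            out[f"f{f:g}_o{int(deg):03d}"] = float(mag.mean())
    return out


def kirsch_features(patch: np.ndarray) -> dict[str, float]:
    """Maximum absolute Kirsch compass response per direction over a patch."""
    image = np.asarray(patch, dtype=np.float64)
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("Kirsch features need a patch of at least 3x3")
    out: dict[str, float] = {}
    for name, kern in zip(KIRSCH_DIRECTIONS, _KIRSCH_KERNELS):
        resp = ndimage.convolve(image, kern, mode="reflect")
        out[name] = float(np.abs(resp).max())
    return out


# ---------------------------------------------------------------------------
# vectorized slice-wise extraction


def modality_feature_names(modality: str) -> list[str]:
    """Provenance-encoded names of the 96 features of one modality."""
    names = [f"{modality}/first_order/{n}" for n in FIRST_ORDER_NAMES]
    for direction in GLCM_DIRECTIONS:
        names += [f"{modality}/glcm/{n}/{direction}" for n in GLCM_FEATURE_NAMES]
    for f in GABOR_FREQUENCIES:
        names += [f"{modality}/gabor/f{f:g}_o{int(deg):03d}" for deg in GABOR_ORIENTATIONS_DEG]
    names += [f"{modality}/kirsch/{n}" for n in KIRSCH_DIRECTIONS]
    return names


def _windows_at(image: np.ndarray, centres: np.ndarray, size: int) -> np.ndarray:
    half = size // 2
    sw = sliding_window_view(image, (size, size))
    return sw[centres[:, 0] - half, centres[:, 1] - half]


def _slice_glcms(q: np.ndarray, centres: np.ndarray, size: int, levels: int) -> np.ndarray:
    """Per-window symmetric normalized GLCMs, one batch per direction.

    Returns an array of shape (4, n_windows, levels, levels).
    """
    h, w = q.shape
    n = len(centres)
    half = size // 2
    out = np.empty((len(GLCM_DIRECTIONS), n, levels, levels))
    for d_idx, (dr, dc) in enumerate(GLCM_DIRECTIONS.values()):
        code = np.zeros((h, w), dtype=np.int64)
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        code[r0:r1, c0:c1] = q[r0:r1, c0:c1] * levels + q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        wr, wc = size - abs(dr), size - abs(dc)
        sw = sliding_window_view(code, (wr, wc))
        codes = sw[centres[:, 0] - half + max(0, -dr), centres[:, 1] - half + max(0, -dc)]
        codes = codes.reshape(n, -1)
        flat = (np.arange(n)[:, None] * (levels * levels) + codes).ravel()
        counts = np.bincount(flat, minlength=n * levels * levels).astype(np.float64)
        counts = counts.reshape(n, levels, levels)
        sym = counts + counts.transpose(0, 2, 1)
        out[d_idx] = sym / sym.sum(axis=(1, 2), keepdims=True)
    return out


def _first_order_batch(windows: np.ndarray) -> np.ndarray:
    x = windows.reshape(len(windows), -1)
    mean = x.mean(axis=1)
    centred = x - mean[:, None]
    var = np.mean(centred**2, axis=1)
    std = np.sqrt(var)
    ok = std > 1e-12 * (1.0 + np.abs(mean))
    safe = np.where(ok, std, 1.0)
    skew = np.where(ok, np.mean(centred**3, axis=1) / safe**3, 0.0)
    kurt = np.where(ok, np.mean(centred**4, axis=1) / safe**4 - 3.0, 0.0)
    return np.column_stack([mean, np.where(ok, std, 0.0), skew, kurt])


def extract_slice_features(
    image: np.ndarray,
    quantized: np.ndarray,
    centres: np.ndarray,
    size: int = 3,
    levels: int = 16,
    frequencies: Sequence[float] = GABOR_FREQUENCIES,
    orientations_deg: Sequence[float] = GABOR_ORIENTATIONS_DEG,
) -> np.ndarray:
    """All 96 features of one modality slice at the given window centres.

    ``image`` is the raw slice (used for first-order, Gabor and Kirsch
    features), ``quantized`` its grey-level quantization (used for the
    co-occurrence features).  Gabor and Kirsch filters are applied to the
    whole slice and pooled per window, which avoids window-edge artefacts.
    """
    n = len(centres)
    blocks = [_first_order_batch(_windows_at(image, centres, size))]

    glcms = _slice_glcms(quantized, centres, size, levels)
    for d_idx in range(glcms.shape[0]):
        blocks.append(haralick_statistics(glcms[d_idx]))
    # interleave: names are direction-major, so reorder blocks accordingly
    first_order, g0, g45, g90, g135 = blocks
    blocks = [first_order, g0, g45, g90, g135]

    gabor_cols = []
    for f in frequencies:
        for deg in orientations_deg:
            mag = _gabor_magnitude(image, f, np.deg2rad(deg))
            gabor_cols.append(_windows_at(mag, centres, size).reshape(n, -1).mean(axis=1))
    blocks.append(np.column_stack(gabor_cols))

    kirsch_cols = []
    for kern in _KIRSCH_KERNELS:
        resp = np.abs(ndimage.convolve(image, kern, mode="reflect"))
        kirsch_cols.append(_windows_at(resp, centres, size).reshape(n, -1).max(axis=1))
    blocks.append(np.column_stack(kirsch_cols))

    return np.hstack(blocks)


def extract_features(
    study: PatientStudy,
    modalities: Sequence[str],
    spec: WindowSpec | None = None,
    levels: int = 16,
    frequencies: Sequence[float] = GABOR_FREQUENCIES,
    orientations_deg: Sequence[float] = GABOR_ORIENTATIONS_DEG,
) -> FeatureMatrix:
    """Texture feature matrix of a study over the gland mask.

    One sample per sliding window whose centre voxel lies in the gland
    mask (and far enough from the slice border to fit the window); exactly
    96 features per requested modality, concatenated in the given modality
    order.  Labels come from the tumour mask at the window centre.
    """
    spec = spec or WindowSpec()
    half = spec.size // 2
    gland = study.gland_mask
    shape = gland.shape

    volumes = {}
    for name in modalities:
        try:
            vol = study.modality(name)
        except KeyError as exc:
            raise KeyError(
                f"modality {name!r} is not available on study {study.patient_id}; "
                "derive it first"
            ) from exc
        if vol.data.shape != shape:
            raise ValueError(
                f"modality {name!r} grid {vol.data.shape} does not match the mask grid {shape}"
            )
        volumes[name] = vol.data

    eligible = np.zeros(shape, dtype=bool)
    eligible[half : shape[0] - half, half : shape[1] - half, :] = True
    eligible &= gland
    if spec.stride > 1:
        lattice = np.zeros(shape, dtype=bool)
        lattice[half :: spec.stride, half :: spec.stride, :] = True
        eligible &= lattice
    coords = np.argwhere(eligible)
    if len(coords) == 0:
        raise ValueError("no eligible window centres inside the gland mask")

    labels = study.tumour_mask[tuple(coords.T)]
    quantized = {name: quantize_volume(vol, gland, levels) for name, vol in volumes.items()}

    all_names: list[str] = []
    all_blocks: list[np.ndarray] = []
    order = np.arange(len(coords))
    for name in modalities:
        feats = np.empty((len(coords), 96))
        for z in np.unique(coords[:, 2]):
            sel = coords[:, 2] == z
            centres = coords[sel][:, :2]
            feats[sel] = extract_slice_features(
                volumes[name][:, :, z],
                quantized[name][:, :, z],
                centres,
                size=spec.size,
                levels=levels,
                frequencies=frequencies,
                orientations_deg=orientations_deg,
            )
        all_blocks.append(feats)
        all_names.extend(modality_feature_names(name))

    return FeatureMatrix(
        np.hstack(all_blocks)[order],
        all_names,
        labels,
        np.full(len(coords), study.patient_id),
        coords,
    )
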