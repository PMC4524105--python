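"""mRMR feature ranking and exhaustive subset-size search.

Maximum-relevance/minimum-redundancy selection ranks features greedily:
the first feature maximizes the mutual information MI(f; c) with the class
c; each subsequent feature f maximizes

    MI(f; c) - (1/|S|) * sum_{g in S} MI(f; g)

over the not-yet-selected features (the "difference" combination of
relevance and redundancy).  The optimal subset size is then found by an
exhaustive search over sizes along the ranking, scoring each prefix with a
patient-grouped cross-validated classifier under a switchable clinical
criterion (sensitivity, specificity, or AUC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .textures import FeatureMatrix

__all__ = ["SelectionResult", "mutual_information", "mrmr_rank", "select_best_m", "default_m_grid"]

CRITERIA = ("sensitivity", "specificity", "auc", "accuracy")


@dataclass
class SelectionResult:
    """Outcome of the subset-size search along an mRMR ranking."""

    criterion: str
    ranked_features: list[str]
    best_m: int
    best_subset: list[str]
    score_curve: dict[int, float]

    def __post_init__(self) -> None:
        if self.best_subset != self.ranked_features[: self.best_m]:
            raise ValueError("best_subset must be a prefix of ranked_features")
        if not (1 <= self.best_m <= len(self.ranked_features)):
            raise ValueError("best_m out of range")

    def to_json(self) -> str:
        return json.dumps(
            {
                "criterion": self.criterion,
                "ranked_features": self.ranked_features,
                "best_m": self.best_m,
                "best_subset": self.best_subset,
                "score_curve": {str(m): v for m, v in self.score_curve.items()},
            },
            indent=1,
        )


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width binning of a numeric column over its observed range."""
    x = np.asarray(x, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.zeros(len(x), dtype=np.int64)
    idx = np.floor((x - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def _mi_from_codes(a: np.ndarray, b: np.ndarray, ka: int, kb: int) -> float:
    """Plug-in mutual information (bits) from two integer code vectors."""
    joint = np.bincount(a * kb + b, minlength=ka * kb).astype(np.float64)
    joint /= joint.sum()
    joint = joint.reshape(ka, kb)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pa[:, None] * pb[None, :])[nz])))


def _mi_many(code_a: np.ndarray, codes: np.ndarray, ka: int, kb: int) -> np.ndarray:
    """MI (bits) of one code vector against every column of a code matrix.

    One shared bincount over all columns replaces per-pair histogramming.
    """
    n, r = codes.shape
    if r == 0:
        return np.zeros(0)
    cell = ka * kb
    flat = (np.arange(r, dtype=np.int32)[None, :] * cell
            + code_a[:, None].astype(np.int32) * kb + codes.astype(np.int32))
    counts = np.bincount(flat.ravel(), minlength=r * cell).astype(np.float64)
    joint = counts.reshape(r, ka, kb) / n
    pa = joint.sum(axis=2)
    pb = joint.sum(axis=1)
    denom = pa[:, :, None] * pb[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / denom)
    return np.nansum(term, axis=(1, 2))


def mutual_information(feature_column: np.ndarray, target: np.ndarray, bins: int = 16) -> float:
    """Histogram plug-in mutual information between two columns, in bits.

    Continuous columns are discretized into ``bins`` equal-width bins over
    their observed range.  A constant column carries no information:
    MI = 0 with any target.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(feature_column)
    y = np.asarray(target)
    if len(x) != len(y):
        raise ValueError("columns must have equal length")
    a = _discretize(x.astype(np.float64), bins)
    if y.dtype == bool or not np.issubdtype(y.dtype, np.number):
        _, b = np.unique(y, return_inverse=True)
        kb = int(b.max()) + 1
    else:
        b = _discretize(y.astype(np.float64), bins)
        kb = bins
    return _mi_from_codes(a, b.astype(np.int64), bins, kb)


def mrmr_rank(
    features: FeatureMatrix,
    max_m: int | None = None,
    bins: int = 16,
    greedy_depth: int | None = None,
    max_mi_samples: int | None = None,
    mi_seed: int = 0,
) -> list[str]:
    """Greedy mRMR ranking of the feature columns against the binary label.

    Ties are broken by lexicographic feature name for determinism.

    ``greedy_depth`` bounds the expensive greedy stage: positions beyond it
    are filled in descending marginal-relevance order (any prefix up to the
    depth is still an exact mRMR prefix).  ``max_mi_samples`` estimates all
    mutual informations from a deterministic row subsample, which changes
    little for the large sample counts of whole-cohort matrices.
    """
    labels = np.unique(features.labels)
    if len(labels) != 2:
        raise ValueError("mRMR ranking requires binary labels with both classes present")
    p = features.n_features
    max_m = p if max_m is None else int(max_m)
    if not (1 <= max_m <= p):
        raise ValueError("max_m must lie in [1, n_features]")
    depth = max_m if greedy_depth is None else min(int(greedy_depth), max_m)

    values = features.values
    y_full = features.labels
    if max_mi_samples is not None and len(y_full) > max_mi_samples:
        pos = np.flatnonzero(y_full)
        neg = np.flatnonzero(~y_full)
        rng = np.random.default_rng([mi_seed, len(y_full)])
        n_neg = max(max_mi_samples - len(pos), 1)
        keep = np.sort(np.concatenate([pos, rng.choice(neg, size=min(n_neg, len(neg)),
                                                       replace=False)]))
        values = values[keep]
        y_full = y_full[keep]

    codes = np.column_stack([_discretize(values[:, j], bins) for j in range(p)])
    y = y_full.astype(np.int64)

    relevance = _mi_many(y, codes, 2, bins)
    names = features.feature_names

    selected: list[int] = []
    remaining = list(range(p))
    redundancy_sum = np.zeros(p)

    for step in range(depth):
        idx = np.asarray(remaining)
        if step == 0:
            scores = relevance[idx]
        else:
            scores = relevance[idx] - redundancy_sum[idx] / len(selected)
        ties = np.flatnonzero(scores == scores.max())
        best = int(min(ties, key=lambda k: names[remaining[k]]))
        chosen = remaining.pop(best)
        selected.append(chosen)
        if step < depth - 1 and remaining:
            rem = np.asarray(remaining)
            redundancy_sum[rem] += _mi_many(codes[:, chosen], codes[:, rem], bins, bins)
    # completion beyond the greedy depth: descending marginal relevance
    tail = sorted(remaining, key=lambda j: (-relevance[j], names[j]))
    return [names[j] for j in selected + tail[: max_m - depth]]


def default_m_grid(n_features: int, step: int = 10) -> tuple[int, ...]:
    """Subset-size sweep: step, 2*step, ... plus the full feature count."""
    grid = list(range(step, n_features, step))
    if not grid or grid[-1] != n_features:
        grid.append(n_features)
    return tuple(grid)


def select_best_m(
    features: FeatureMatrix,
    criterion: str,
    evaluator: Callable[[FeatureMatrix], dict[str, float]],
    m_grid: Sequence[int] | None = None,
    bins: int = 16,
    ranked: Sequence[str] | None = None,
    max_mi_samples: int | None = 8000,
) -> SelectionResult:
    """Exhaustive search over subset size along the mRMR ranking.

    For each m in ``m_grid`` the first m ranked features are scored with
    ``evaluator`` (a patient-grouped cross-validated scorer returning a
    metric dict); the best m maximizes the chosen criterion, ties going to
    the smallest m.  Pass ``ranked`` to reuse a precomputed ranking.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    p = features.n_features
    if m_grid is None:
        m_grid = default_m_grid(p)
    m_grid = sorted({int(m) for m in m_grid})
    if m_grid[0] < 1 or m_grid[-1] > p:
        raise ValueError("m_grid entries must lie in [1, n_features]")

    if ranked is not None:
        ranking = list(ranked)
    else:
        # a prefix of size p is the full feature set regardless of order, so
        # the greedy stage only needs to reach the largest smaller grid entry
        inner = [m for m in m_grid if m < p]
        depth = max(inner) if inner else 1
        ranking = mrmr_rank(
            features, max_m=m_grid[-1], bins=bins,
            greedy_depth=depth, max_mi_samples=max_mi_samples,
        )

    curve: dict[int, float] = {}
    for m in m_grid:
        subset = features.select(ranking[:m])
        try:
            metrics = evaluator(subset)
        except Exception as exc:
            raise RuntimeError(f"evaluator failed at subset size m={m}") from exc
        curve[m] = float(metrics[criterion])

    best_m = max(m_grid, key=lambda m: (curve[m], -m))
    return SelectionResult(
        criterion=criterion,
        ranked_features=ranking,
        best_m=best_m,
        best_subset=ranking[:best_m],
        score_curve=curve,
    )
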