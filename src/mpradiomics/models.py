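"""Texture feature models: modality combinations built in two stages.

A texture feature model (TFM) is a named combination of imaging
modalities with a selected feature subset and a trained classifier.  The
six published combinations are

    TFM1 = T2w + ADC                      (conventional MP-MRI)
    TFM2 = TFM1 + CHB-DWI
    TFM3 = T2w + CDI
    TFM4 = T2w + ADC + CDI
    TFM5 = TFM4 + CHB-DWI
    TFM6 = TFM5 + b1 + b2 + b3 + b4      (all eight modalities)

Construction is staged: (1) per modality, mRMR-rank the 96 texture
features and pick the best subset size under the clinical criterion;
(2) pool the per-modality best subsets; (3) run the same selection on the
pool and train the final SVM on the surviving features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .evaluate import (
    CrossValidatedScorer,
    EvaluationReport,
    SvmConfig,
    train_classifier,
    TrainedClassifier,
)
from .selection import SelectionResult, select_best_m
from .textures import FeatureMatrix

__all__ = [
    "TFM_DEFINITIONS",
    "TextureFeatureModel",
    "build_tfm",
    "compare_models",
    "wilcoxon_signed_rank",
]

TFM_DEFINITIONS: dict[str, tuple[str, ...]] = {
    "TFM1": ("T2w", "ADC"),
    "TFM2": ("T2w", "ADC", "CHB-DWI"),
    "TFM3": ("T2w", "CDI"),
    "TFM4": ("T2w", "ADC", "CDI"),
    "TFM5": ("T2w", "ADC", "CHB-DWI", "CDI"),
    "TFM6": ("T2w", "ADC", "CHB-DWI", "CDI", "b1", "b2", "b3", "b4"),
}


@dataclass
class TextureFeatureModel:
    """A modality combination with its selected features and classifier."""

    name: str
    modalities: tuple[str, ...]
    criterion: str
    per_modality_results: dict[str, SelectionResult]
    final_result: SelectionResult
    classifier: TrainedClassifier | None = None

    def __post_init__(self) -> None:
        if self.name in TFM_DEFINITIONS and tuple(self.modalities) != TFM_DEFINITIONS[self.name]:
            raise ValueError(
                f"{self.name} must combine {TFM_DEFINITIONS[self.name]}, got {self.modalities}"
            )
        pool = {f for r in self.per_modality_results.values() for f in r.best_subset}
        if not set(self.final_subset) <= pool:
            raise ValueError("final_subset must be drawn from the per-modality best subsets")

    @property
    def per_modality_subsets(self) -> dict[str, list[str]]:
        return {m: r.best_subset for m, r in self.per_modality_results.items()}

    @property
    def final_subset(self) -> list[str]:
        return self.final_result.best_subset

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "modalities": list(self.modalities),
                "criterion": self.criterion,
                "per_modality_subsets": self.per_modality_subsets,
                "final_subset": self.final_subset,
                "threshold": None if self.classifier is None else self.classifier.threshold,
            },
            indent=1,
        )


def build_tfm(
    cohort_features: Mapping[str, FeatureMatrix],
    model_name: str,
    criterion: str,
    evaluator: CrossValidatedScorer | None = None,
    m_grid: Sequence[int] | None = None,
    svm_config: SvmConfig | None = None,
    modalities: Sequence[str] | None = None,
    train_final: bool = True,
) -> TextureFeatureModel:
    """Build a texture feature model with the staged selection procedure.

    Parameters
    ----------
    cohort_features : mapping modality name -> FeatureMatrix
        Per-modality matrices over identical samples (same windows, same
        patients) for the whole cohort.
    model_name : a key of ``TFM_DEFINITIONS`` or a custom name (then pass
        ``modalities`` explicitly).
    criterion : the clinical criterion driving both selection stages.
    m_grid : subset sizes swept per modality; defaults to steps of 10 up
        to the 96 features.  The combined stage reuses the same step.
    """
    if modalities is None:
        if model_name not in TFM_DEFINITIONS:
            raise ValueError(f"unknown model {model_name!r}; pass modalities explicitly")
        modalities = TFM_DEFINITIONS[model_name]
    evaluator = evaluator or CrossValidatedScorer()

    missing = [m for m in modalities if m not in cohort_features]
    if missing:
        raise KeyError(f"feature matrices missing for modalities: {missing}")
    reference = cohort_features[modalities[0]]
    for m in modalities[1:]:
        fm = cohort_features[m]
        if (
            fm.n_samples != reference.n_samples
            or np.any(fm.labels != reference.labels)
            or np.any(fm.patient_ids != reference.patient_ids)
            or np.any(fm.sample_coords != reference.sample_coords)
        ):
            raise ValueError(f"samples of modality {m!r} are not aligned with {modalities[0]!r}")

    # stage 1: best subset per modality
    per_modality: dict[str, SelectionResult] = {}
    for m in modalities:
        per_modality[m] = select_best_m(cohort_features[m], criterion, evaluator, m_grid=m_grid)

    # stage 2: pool the winners
    pooled = FeatureMatrix.hstack(
        [cohort_features[m].select(per_modality[m].best_subset) for m in modalities]
    )

    # stage 3: select again on the pool, under the same criterion; the pool
    # can be several hundred features wide, so sweep a compact log-spaced
    # size grid rather than every multiple of ten
    pool_size = pooled.n_features
    lo = min(10, pool_size)
    pool_grid = sorted({int(round(v)) for v in np.geomspace(lo, pool_size, num=4)})
    final = select_best_m(pooled, criterion, evaluator, m_grid=pool_grid)

    classifier = None
    if train_final:
        classifier = train_classifier(pooled, final.best_subset, svm_config)

    return TextureFeatureModel(
        name=model_name,
        modalities=tuple(modalities),
        criterion=criterion,
        per_modality_results=per_modality,
        final_result=final,
        classifier=classifier,
    )


def wilcoxon_signed_rank(differences: np.ndarray) -> dict[str, float | bool]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Exact null distribution for n <= 12 pairs, normal approximation with
    continuity correction above.  All-zero differences are a degenerate
    case: reported as p = 1 with a flag rather than an error.
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[~np.isnan(d)]
    if len(d) == 0 or np.all(d == 0):
        return {"p_value": 1.0, "statistic": 0.0, "degenerate": True, "n": int(len(d))}
    nz = d[d != 0]
    method = "exact" if len(nz) <= 12 else "approx"
    res = sstats.wilcoxon(nz, alternative="two-sided", method=method, correction=True)
    return {
        "p_value": float(res.pvalue),
        "statistic": float(res.statistic),
        "degenerate": False,
        "n": int(len(nz)),
    }


def compare_models(
    reports: Mapping[str, EvaluationReport],
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Pairwise Wilcoxon signed-rank comparison of evaluated models.

    All reports must come from identical patient folds.  Per metric the
    per-patient values are paired across models; patients with an
    undefined rate (e.g. no cancerous samples -> undefined sensitivity)
    drop out of that metric's pairing only.
    """
    names = list(reports)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    patient_sets = {n: set(reports[n].per_patient) for n in names}
    ref = patient_sets[names[0]]
    for n in names[1:]:
        if patient_sets[n] != ref:
            raise ValueError(f"model {n!r} was evaluated on different patient folds")
    patients = sorted(ref)

    out: dict[str, dict] = {}
    metrics = ("sensitivity", "specificity", "accuracy", "auc")
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pair: dict[str, dict] = {}
            for metric in metrics:
                va = np.array([reports[a].per_patient[p][metric] for p in patients])
                vb = np.array([reports[b].per_patient[p][metric] for p in patients])
                ok = ~np.isnan(va) & ~np.isnan(vb)
                test = wilcoxon_signed_rank(va[ok] - vb[ok])
                test["significant"] = bool(
                    (not test["degenerate"]) and test["p_value"] < alpha
                )
                test["mean_difference"] = (
                    float(np.mean(va[ok] - vb[ok])) if ok.any() else float("nan")
                )
                pair[metric] = test
            out[f"{a} vs {b}"] = pair
    return out
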