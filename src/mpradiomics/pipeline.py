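"""End-to-end orchestration: phantom cohort to evaluated texture models.

This is the programmatic equivalent of running the CLI subcommands in
sequence, kept in one place so that tests, scripts and the ``run-all``
command share a single code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dwi import compute_cdi, compute_chb_dwi, fit_adc
from .evaluate import CrossValidatedScorer, EvaluationReport, SvmConfig, evaluate_lopo
from .models import TFM_DEFINITIONS, TextureFeatureModel, build_tfm
from .phantom import PatientStudy, PhantomConfig, generate_cohort
from .textures import FeatureMatrix, WindowSpec, extract_features

__all__ = ["PipelineResult", "derive_modalities", "cohort_feature_matrices", "run_pipeline"]


@dataclass
class PipelineResult:
    cohort: list[PatientStudy]
    features: dict[str, FeatureMatrix]
    models: dict[str, TextureFeatureModel]
    reports: dict[str, EvaluationReport]


def derive_modalities(
    study: PatientStudy, b_target: float = 2000.0, cdi_radius: int = 1
) -> PatientStudy:
    """Attach ADC, S0, CHB-DWI and CDI volumes to a study in place."""
    mask = study.gland_mask
    adc, s0 = fit_adc(study.dwi, mask)
    study.derived["ADC"] = adc
    study.derived["S0"] = s0
    study.derived["CHB-DWI"] = compute_chb_dwi(study.dwi, mask, b_target)
    study.derived["CDI"] = compute_cdi(study.dwi, mask, (cdi_radius, cdi_radius, 0))
    return study


def cohort_feature_matrices(
    cohort: Sequence[PatientStudy],
    modalities: Sequence[str],
    spec: WindowSpec | None = None,
) -> dict[str, FeatureMatrix]:
    """Per-modality cohort feature matrices over identical windows.

    Features for all modalities of one study are extracted in a single
    pass (shared window lattice), then split by modality provenance and
    stacked across patients.
    """
    per_study = [extract_features(study, modalities, spec) for study in cohort]
    combined = FeatureMatrix.vstack(per_study)
    out: dict[str, FeatureMatrix] = {}
    for m in modalities:
        cols = [n for n in combined.feature_names if n.startswith(f"{m}/")]
        out[m] = combined.select(cols)
    return out


def run_pipeline(
    config: PhantomConfig,
    model_names: Sequence[str] = ("TFM1", "TFM6"),
    criterion: str = "auc",
    seed: int = 0,
    window: WindowSpec | None = None,
    m_grid: Sequence[int] = (10, 30, 60, 96),
    b_target: float = 2000.0,
    cdi_radius: int = 1,
    scorer: CrossValidatedScorer | None = None,
    svm_config: SvmConfig | None = None,
    n_boot: int = 2000,
) -> PipelineResult:
    """Run the full detection pipeline on a synthetic cohort.

    Generates the cohort, derives the computed diffusion modalities,
    extracts per-modality texture features, builds the requested texture
    feature models by staged mRMR selection, and evaluates each final
    subset with leave-one-patient-out SVM classification.
    """
    cohort = [derive_modalities(s, b_target, cdi_radius) for s in generate_cohort(config)]

    needed = sorted({m for name in model_names for m in TFM_DEFINITIONS[name]})
    features = cohort_feature_matrices(cohort, needed, window)

    svm_config = svm_config or SvmConfig(max_train_samples=3000, seed=seed)
    scorer = scorer or CrossValidatedScorer(
        n_splits=3, svm_config=svm_config, max_eval_samples=12000, seed=seed
    )

    models: dict[str, TextureFeatureModel] = {}
    reports: dict[str, EvaluationReport] = {}
    for name in model_names:
        model = build_tfm(
            features, name, criterion, evaluator=scorer, m_grid=m_grid,
            svm_config=svm_config, train_final=False,
        )
        models[name] = model
        pooled = FeatureMatrix.hstack([features[m] for m in model.modalities])
        reports[name] = evaluate_lopo(
            pooled, model.final_subset, svm_config, n_boot=n_boot, seed=seed
        )
    return PipelineResult(cohort=cohort, features=features, models=models, reports=reports)
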