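"""End-to-end pipeline: normalize -> differential expression -> augment ->
train -> evaluate -> deploy on the real pooled replicates."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import diffexpr
from .augment import CohortAugmenter, export_centroids_and_sds
from .classify import (ConfusionMatrix, ShallowNeuralNetClassifier, SplitSpec,
                       deploy_on_real, evaluate, split_cohort, train_nn)
from .quantio import QuantMatrix, total_area_normalize


@dataclass
class PipelineResult:
    candidate_table: pd.DataFrame
    candidates: list[str]
    model: ShallowNeuralNetClassifier
    synthetic_confusion: ConfusionMatrix
    real_confusion: ConfusionMatrix
    info: dict = field(default_factory=dict)

    @property
    def synthetic_test_accuracy(self) -> float:
        return self.synthetic_confusion.correct_rate

    @property
    def real_deploy_accuracy(self) -> float:
        return self.real_confusion.correct_rate


def run_pipeline(matrices: dict[str, QuantMatrix],
                 de_config: diffexpr.DEConfig | None = None,
                 reference_arm: str = "none",
                 panel: list[str] | None = None,
                 n_per_class: int = 1000, k_sd: float = 10.0,
                 hidden_units: int = 10, max_epochs: int = 400,
                 seed: int = 17, deploy_unit: str = "replicate",
                 normalize: bool = True) -> PipelineResult:
    """Run the full analysis on per-arm quantitation matrices.

    Candidate proteins are selected per arm and consolidated; centroids and
    replicate SDs come from the reference arm (the non-depleted one by
    default, which retains every protein), which also supplies the real
    replicate observations for deployment.  ``panel`` overrides the candidate
    list (e.g. for a minimized panel); ``normalize=False`` accepts matrices
    already on a common per-run scale, such as the fixture generator's.
    """
    de_config = de_config or diffexpr.DEConfig()
    normalized: dict[str, QuantMatrix] = {}
    for arm, m in matrices.items():
        normalized[arm] = total_area_normalize(m) if normalize else m
    per_arm_sel = {}
    for arm, m in normalized.items():
        stats = diffexpr.protein_stats(m, arm=arm, cfg=de_config)
        per_arm_sel[arm] = diffexpr.select_candidates(stats, de_config)
    table = diffexpr.consolidate_arms(per_arm_sel)
    candidates = diffexpr.default_candidates(table)

    real = normalized[reference_arm]
    used_panel = list(panel) if panel is not None else \
        [p for p in candidates if p in real.values.index]
    if not used_panel:
        raise ValueError("no candidate proteins available in the reference arm")

    centroids, sds = export_centroids_and_sds(real, used_panel)
    cohort = CohortAugmenter(n_per_class=n_per_class, k_sd=k_sd,
                             random_state=seed).fit_sample(centroids, sds)
    splits = split_cohort(cohort, SplitSpec(seed=seed))
    model = train_nn((splits.X_train, splits.y_train),
                     (splits.X_val, splits.y_val),
                     hidden_units=hidden_units, max_epochs=max_epochs,
                     random_state=seed)
    synth_cm = evaluate(model, splits.X_test, splits.y_test)
    real_cm = deploy_on_real(model, real, used_panel, unit=deploy_unit)
    return PipelineResult(table, candidates, model, synth_cm, real_cm,
                          info={"panel": used_panel, "seed": seed,
                                "n_per_class": n_per_class, "k_sd": k_sd})
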