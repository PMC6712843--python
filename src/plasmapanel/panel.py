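"""Panel narrowing: protein-profile grouping plus retrain-evaluate search.

The candidate list is first organized by average-linkage hierarchical
clustering of protein-profile dissimilarities (stage-response shapes), and a
greedy forward search — seeded by each group's most representative protein —
then adds whichever candidate gives the best marginal median synthetic-test
accuracy until a target accuracy is met.  Accuracy per panel is the median
over a seed set of the full augment -> split -> train -> evaluate pipeline,
plus deployment on the real pooled replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .augment import CohortAugmenter
from .classify import SplitSpec, deploy_on_real, evaluate, split_cohort, train_nn
from .quantio import QuantMatrix
from .structure import DissimilarityMatrix


def rank_protein_groups(D: DissimilarityMatrix,
                        n_groups: int | None = None) -> list[list[str]]:
    """Average-linkage grouping of protein profiles.

    Within each group proteins are ordered by representativeness (ascending
    mean distance to the rest of the group, ties broken lexicographically);
    groups are ordered by their representative's id for determinism.  With
    ``n_groups=None`` the tree is cut at the largest merge-height gap.
    """
    labels = list(D.labels)
    n = len(labels)
    if n < 2:
        return [labels]
    Z = linkage(squareform(D.D, checks=False), method="average")
    if n_groups is None:
        heights = Z[:, 2]
        if len(heights) > 1:
            gaps = np.diff(heights)
            cut_after = int(np.argmax(gaps))
            n_groups = n - (cut_after + 1)
        else:
            n_groups = 1
        n_groups = max(1, n_groups)
    assignment = fcluster(Z, t=n_groups, criterion="maxclust")
    groups: list[list[str]] = []
    for g in np.unique(assignment):
        members = [labels[i] for i in np.nonzero(assignment == g)[0]]
        idx = [labels.index(mbr) for mbr in members]
        if len(members) == 1:
            groups.append(members)
            continue
        sub = D.D[np.ix_(idx, idx)]
        rep_score = sub.sum(axis=1) / (len(members) - 1)
        order = sorted(range(len(members)), key=lambda i: (rep_score[i], members[i]))
        groups.append([members[i] for i in order])
    return sorted(groups, key=lambda g: g[0])


@dataclass
class PanelEvaluation:
    """Accuracy of a protein panel: synthetic test (median with IQR over the
    seed set) and real-data deployment (median over the seed set)."""

    proteins: list[str]
    synthetic_test_accuracy: float
    synthetic_iqr: tuple[float, float]
    real_deploy_accuracy: float
    seeds: list[int]
    per_seed: pd.DataFrame = field(repr=False, default=None)
    met: bool | None = None


def evaluate_panel(proteins: list[str], centroids: pd.DataFrame, sds: pd.DataFrame,
                   real: QuantMatrix | None = None,
                   n_per_class: int = 1000, k_sd: float = 10.0,
                   hidden_units: int = 10, max_epochs: int = 400,
                   seeds=(0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
                   deploy_unit: str = "replicate") -> PanelEvaluation:
    """Run augment -> split -> train NN -> evaluate (-> deploy) restricted to
    a panel, reporting medians over the seed set."""
    absent = [p for p in proteins if p not in centroids.columns]
    if absent:
        raise KeyError(f"panel proteins missing from centroids: {absent}")
    proteins = list(proteins)
    rows = []
    for seed in seeds:
        cohort = CohortAugmenter(n_per_class=n_per_class, k_sd=k_sd,
                                 random_state=seed).fit_sample(
            centroids[proteins], sds[proteins])
        splits = split_cohort(cohort, SplitSpec(seed=seed))
        model = train_nn((splits.X_train, splits.y_train),
                         (splits.X_val, splits.y_val),
                         hidden_units=hidden_units, max_epochs=max_epochs,
                         random_state=seed)
        test_acc = evaluate(model, splits.X_test, splits.y_test).correct_rate
        row = {"seed": seed, "test_accuracy": test_acc}
        if real is not None:
            row["deploy_accuracy"] = deploy_on_real(model, real, proteins,
                                                    unit=deploy_unit).correct_rate
        rows.append(row)
    per_seed = pd.DataFrame(rows)
    accs = per_seed["test_accuracy"]
    deploy = (float(per_seed["deploy_accuracy"].median())
              if "deploy_accuracy" in per_seed else float("nan"))
    return PanelEvaluation(proteins, float(accs.median()),
                           (float(accs.quantile(0.25)), float(accs.quantile(0.75))),
                           deploy, list(seeds), per_seed)


def minimize_panel(candidates: list[str], centroids: pd.DataFrame, sds: pd.DataFrame,
                   target_accuracy: float,
                   dissimilarity: DissimilarityMatrix | None = None,
                   real: QuantMatrix | None = None,
                   exhaustive: bool = False, max_panel_size: int | None = None,
                   **eval_kwargs) -> tuple[PanelEvaluation, pd.DataFrame]:
    """Smallest panel meeting a target median synthetic-test accuracy.

    Greedy forward selection: the candidate pool is ordered with each
    dissimilarity group's representative first; at every step each remaining
    candidate is evaluated as an addition and the best marginal median
    accuracy wins (ties to the lexicographically smaller id).  With
    ``exhaustive=True`` (candidates <= 12) all subsets are evaluated in order
    of size.  Returns ``(evaluation, search_log)``; if the target is
    unreachable the best panel found is returned with ``met=False``.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if not 0 < target_accuracy <= 100:
        raise ValueError("target_accuracy must be in (0, 100]")
    candidates = sorted(candidates)
    log_rows: list[dict] = []

    def assess(panel: list[str]) -> PanelEvaluation:
        ev = evaluate_panel(panel, centroids, sds, real=real, **eval_kwargs)
        log_rows.append({"panel": ",".join(panel), "size": len(panel),
                         "median_test_accuracy": ev.synthetic_test_accuracy,
                         "real_deploy_accuracy": ev.real_deploy_accuracy})
        return ev

    if exhaustive:
        if len(candidates) > 12:
            raise ValueError("exhaustive search limited to <= 12 candidates")
        best = None
        for size in range(1, len(candidates) + 1):
            met_this_size = None
            for panel in combinations(candidates, size):
                ev = assess(list(panel))
                if best is None or ev.synthetic_test_accuracy > best.synthetic_test_accuracy:
                    best = ev
                if ev.synthetic_test_accuracy >= target_accuracy and met_this_size is None:
                    met_this_size = ev
            if met_this_size is not None:
                met_this_size.met = True
                return met_this_size, pd.DataFrame(log_rows)
        best.met = False
        return best, pd.DataFrame(log_rows)

    # pool order: group representatives first, then the remainder
    if dissimilarity is not None:
        groups = rank_protein_groups(dissimilarity)
        reps = [g[0] for g in groups if g[0] in candidates]
        rest = [p for p in candidates if p not in reps]
        pool = reps + rest
    else:
        pool = list(candidates)

    panel: list[str] = []
    best_ev: PanelEvaluation | None = None
    limit = max_panel_size or len(pool)
    while pool and len(panel) < limit:
        step_best = None
        for cand in pool:
            ev = assess(panel + [cand])
            if step_best is None or ev.synthetic_test_accuracy > step_best[1].synthetic_test_accuracy:
                step_best = (cand, ev)
        cand, ev = step_best
        panel.append(cand)
        pool.remove(cand)
        best_ev = ev
        if ev.synthetic_test_accuracy >= target_accuracy:
            ev.met = True
            return ev, pd.DataFrame(log_rows)
    best_ev.met = False
    return best_ev, pd.DataFrame(log_rows)
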