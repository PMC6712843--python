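"""Synthetic patient-population augmentation.

Pooled samples give one centroid per (condition, protein) plus a technical
replicate SD.  A synthetic patient is drawn per protein independently as

    value ~ Normal(class centroid, k_sd * replicate SD)

with ``k_sd = 10`` by default — a deliberately conservative inflation of the
technical variance meant to cover the biological spread of a heterogeneous
population.  Negative draws are truncated at zero by default (concentrations
are non-negative); ``resample`` and ``allow`` policies are available, and the
distributional moment checks use ``allow``.

The draw order is fixed as (class, patient, protein) from a single seeded
generator, so a cohort is bit-reproducible from (config, centroids, SDs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .quantio import CONDITIONS, QuantMatrix

logger = logging.getLogger(__name__)

_POLICIES = ("truncate_zero", "resample", "allow")


@dataclass
class ReplicateVarianceReport:
    """Per-condition technical-replicate CV summary (percent, linear scale)."""

    per_condition: pd.DataFrame  # index condition: mean_cv_percent, sd_cv_percent, n
    cv_table: pd.DataFrame       # protein x condition percent CVs

    def mean_cv(self, condition: str) -> float:
        return float(self.per_condition.loc[condition, "mean_cv_percent"])


def replicate_variance_report(m: QuantMatrix, proteins=None) -> ReplicateVarianceReport:
    """Per-protein percent CV (sample SD / mean * 100) over technical
    replicates, per condition, on the linear scale; plus per-condition
    mean +/- SD across proteins.  Proteins with zero mean are skipped."""
    linear = m.linear_values()
    if proteins is not None:
        linear = linear.loc[list(proteins)]
    cols, rows = {}, []
    for cond in CONDITIONS:
        runs = m.runs_for(condition=cond)
        if len(runs) < 2:
            continue
        sub = linear[runs]
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        cv = 100.0 * sd / mean
        n_zero = int((mean == 0).sum())
        if n_zero:
            logger.warning("%d proteins with zero mean skipped in condition %s", n_zero, cond)
        cv[mean == 0] = np.nan
        cols[cond] = cv
        rows.append({"condition": cond,
                     "mean_cv_percent": float(cv.mean(skipna=True)),
                     "sd_cv_percent": float(cv.std(ddof=1, skipna=True)),
                     "n_proteins": int(cv.notna().sum())})
    per_cond = pd.DataFrame(rows).set_index("condition")
    return ReplicateVarianceReport(per_cond, pd.DataFrame(cols))


@dataclass
class SyntheticCohort:
    """Augmented patient population: values (patient x protein) plus labels."""

    values: pd.DataFrame
    labels: pd.Series
    config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts()

    def to_tsv(self, path, config_path=None) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels.to_numpy())
        out.index.name = "patient_id"
        out.to_csv(path, sep="\t")
        if config_path is not None:
            with open(config_path, "w") as fh:
                json.dump({"config": self.config, "provenance": self.provenance},
                          fh, indent=2, default=str)


class CohortAugmenter(BaseEstimator):
    """Generates a synthetic cohort from class centroids and replicate SDs.

    Parameters
    ----------
    n_per_class : patients drawn per class (default 1000 -> 5000 total).
    k_sd : noise multiplier on the replicate SD (default 10).
    negative_policy : ``truncate_zero`` (clip, default), ``resample``
        (redraw negatives) or ``allow``.
    random_state : seed for the single generator; draw order is
        (class, patient, protein).
    """

    def __init__(self, n_per_class: int = 1000, k_sd: float = 10.0,
                 negative_policy: str = "truncate_zero", random_state: int = 0):
        self.n_per_class = n_per_class
        self.k_sd = k_sd
        self.negative_policy = negative_policy
        self.random_state = random_state

    def fit(self, centroids: pd.DataFrame, sds: pd.DataFrame):
        """Validate and store aligned class x protein centroid and SD tables."""
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.k_sd < 0:
            raise ValueError("k_sd must be >= 0")
        if self.negative_policy not in _POLICIES:
            raise ValueError(f"negative_policy must be one of {_POLICIES}")
        if list(centroids.columns) != list(sds.columns) or \
                list(centroids.index) != list(sds.index):
            raise ValueError("centroids and sds must share index and columns")
        if (sds.to_numpy(dtype=float) < 0).any():
            raise ValueError("SDs must be non-negative")
        self.classes_ = [c for c in CONDITIONS if c in centroids.index]
        if not self.classes_:
            raise ValueError("no recognized condition labels in centroid index")
        self.centroids_ = centroids.loc[self.classes_].astype(float)
        self.sds_ = sds.loc[self.classes_].astype(float)
        self.proteins_ = list(centroids.columns)
        return self

    def sample(self, random_state: int | None = None) -> SyntheticCohort:
        """Draw the cohort; bit-reproducible for fixed (fit inputs, seed)."""
        check_is_fitted(self, "centroids_")
        seed = self.random_state if random_state is None else random_state
        rng = np.random.default_rng(seed)
        n, p = self.n_per_class, len(self.proteins_)
        blocks, labels = [], []
        for cls in self.classes_:
            mu = self.centroids_.loc[cls].to_numpy()
            sd = self.k_sd * self.sds_.loc[cls].to_numpy()
            vals = mu + sd * rng.standard_normal((n, p))
            if self.negative_policy == "truncate_zero":
                np.clip(vals, 0.0, None, out=vals)
            elif self.negative_policy == "resample":
                neg = vals < 0
                while neg.any():
                    idx = np.nonzero(neg)
                    vals[idx] = mu[idx[1]] + sd[idx[1]] * rng.standard_normal(len(idx[0]))
                    neg = vals < 0
            blocks.append(vals)
            labels.extend([cls] * n)
        values = pd.DataFrame(np.vstack(blocks), columns=self.proteins_,
                              index=[f"S{i:05d}" for i in range(n * len(self.classes_))])
        cohort = SyntheticCohort(
            values, pd.Series(labels, index=values.index, name="label"),
            config={"n_per_class": n, "k_sd": self.k_sd, "seed": seed,
                    "negative_policy": self.negative_policy},
            provenance={"classes": self.classes_, "n_proteins": p})
        return cohort

    def fit_sample(self, centroids, sds, random_state=None) -> SyntheticCohort:
        return self.fit(centroids, sds).sample(random_state)


def augment_cohort(centroids: pd.DataFrame, sds: pd.DataFrame,
                   n_per_class: int = 1000, k_sd: float = 10.0, seed: int = 0,
                   negative_policy: str = "truncate_zero") -> SyntheticCohort:
    """Functional wrapper over :class:`CohortAugmenter`."""
    return CohortAugmenter(n_per_class=n_per_class, k_sd=k_sd,
                           negative_policy=negative_policy,
                           random_state=seed).fit_sample(centroids, sds)


def export_centroids_and_sds(m: QuantMatrix, proteins=None
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class x protein replicate means and sample SDs on the linear scale.

    The bridge from a quantitation matrix (real or fixture) to the augmenter;
    the two outputs share index (conditions) and columns (proteins).
    """
    linear = m.linear_values()
    if proteins is not None:
        absent = [p for p in proteins if p not in linear.index]
        if absent:
            raise KeyError(f"proteins absent from matrix: {absent}")
        linear = linear.loc[list(proteins)]
    cents, sds = {}, {}
    for cond in CONDITIONS:
        runs = m.runs_for(condition=cond)
        if not runs:
            continue
        sub = linear[runs]
        cents[cond] = sub.mean(axis=1, skipna=True)
        sds[cond] = sub.std(axis=1, ddof=1, skipna=True).fillna(0.0)
    return pd.DataFrame(cents).T, pd.DataFrame(sds).T
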