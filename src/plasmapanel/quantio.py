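"""Protein quantitation matrices: data model, IO, normalization and replicate QC.

The universal input of the pipeline is a protein x run table of SWATH peak
areas together with run metadata (disease condition, depletion arm, technical
replicate index).  Missing values are encoded as NaN.  Values live on one of
three scales:

``raw``
    peak areas as extracted (non-negative).
``linear_normalized``
    total-area normalized: every run's sum over observed values equals the
    mean of the original run totals, so values stay on a peak-area-like scale.
``log``
    logarithm (default base 2) of linear-normalized values; zeros are masked
    as missing at the transform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical condition order: healthy control then AJCC stages I-IV.
CONDITIONS: tuple[str, ...] = ("healthy", "I", "II", "III", "IV")

#: Depletion arms: non-depleted, MARS-14 only, and the two tandem orders.
ARMS: tuple[str, ...] = ("none", "MARS14", "MARS14_API", "API_MARS14")

META_COLUMNS = ("condition", "arm", "replicate")


@dataclass
class QuantMatrix:
    """Protein x run quantitation matrix with run metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by protein accession, columns by run id.  NaN marks a
        missing (unobserved) value.
    meta : pandas.DataFrame
        Indexed by run id with columns ``condition`` (one of
        :data:`CONDITIONS`), ``arm`` (one of :data:`ARMS`) and ``replicate``
        (1-based integer).
    scale : str
        ``raw``, ``linear_normalized`` or ``log``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scale: str = "raw"
    normalization_method: str | None = None
    log_base: float | None = None
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        missing_meta = [r for r in self.values.columns if r not in self.meta.index]
        if missing_meta:
            raise ValueError(f"runs without metadata: {missing_meta}")
        # align metadata to column order; extra metadata rows are tolerated
        self.meta = self.meta.loc[list(self.values.columns), list(META_COLUMNS)].copy()
        bad_cond = set(self.meta["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
        bad_arm = set(self.meta["arm"]) - set(ARMS)
        if bad_arm:
            raise ValueError(f"unknown depletion arms: {sorted(bad_arm)}")
        if (self.meta["replicate"].astype(int) < 1).any():
            raise ValueError("replicate indices must be >= 1")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("values must be finite or NaN")
        if self.scale != "log":
            neg = np.argwhere(vals < 0)
            if neg.size:
                i, j = neg[0]
                raise ValueError(
                    f"negative value {vals[i, j]} at protein "
                    f"{self.values.index[i]!r}, run {self.values.columns[j]!r}"
                )
        empty = self.values.columns[self.values.notna().sum(axis=0) == 0].tolist()
        if empty:
            raise ValueError(f"runs with no observed values: {empty}")

    # -- convenience accessors -------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.values.columns)

    def runs_for(self, condition: str | None = None, arm: str | None = None) -> list[str]:
        """Run ids matching a condition and/or arm."""
        sel = pd.Series(True, index=self.meta.index)
        if condition is not None:
            sel &= self.meta["condition"] == condition
        if arm is not None:
            sel &= self.meta["arm"] == arm
        return list(self.meta.index[sel])

    def subset(self, proteins: Sequence[str] | None = None,
               runs: Sequence[str] | None = None) -> "QuantMatrix":
        vals = self.values
        if proteins is not None:
            absent = [p for p in proteins if p not in vals.index]
            if absent:
                raise KeyError(f"proteins absent from matrix: {absent}")
            vals = vals.loc[list(proteins)]
        if runs is not None:
            vals = vals[list(runs)]
        return QuantMatrix(vals.copy(), self.meta.copy(), scale=self.scale,
                           normalization_method=self.normalization_method,
                           log_base=self.log_base)

    def linear_values(self) -> pd.DataFrame:
        """Values on the linear scale (exponentiates a log matrix)."""
        if self.scale == "log":
            return pd.DataFrame(
                np.power(self.log_base, self.values.to_numpy(dtype=float)),
                index=self.values.index, columns=self.values.columns)
        return self.values


def read_quant_table(path, meta_path) -> QuantMatrix:
    """Read a delimited quantitation table plus run metadata.

    The table's first column holds protein accessions; remaining columns are
    runs.  The metadata file maps ``run_id`` to condition / arm / replicate.
    Delimiter is sniffed (TSV or CSV).
    """
    values = pd.read_csv(path, sep=None, engine="python", index_col=0)
    values.index = values.index.astype(str)
    meta = pd.read_csv(meta_path, sep=None, engine="python", index_col="run_id")
    meta.index = meta.index.astype(str)
    values.columns = values.columns.astype(str)
    return QuantMatrix(values, meta)


def write_quant_table(m: QuantMatrix, path, meta_path) -> None:
    """Write a matrix and its metadata as TSV (round-trips with read_quant_table)."""
    out = m.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")
    meta = m.meta.copy()
    meta.index.name = "run_id"
    meta.to_csv(meta_path, sep="\t")


def total_area_normalize(m: QuantMatrix, per_arm: bool = True) -> QuantMatrix:
    """Total-area normalization: scale each run so its observed total equals
    the mean of the original run totals.

    ``per_arm=True`` (default) normalizes each depletion arm independently,
    matching a design in which each depletion experiment is an independent MS
    acquisition; ``per_arm=False`` normalizes all runs jointly.
    """
    if m.scale == "log":
        raise ValueError("normalize before log transform")
    vals = m.values.copy()
    groups: Iterable[list[str]]
    if per_arm:
        groups = [list(g) for _, g in m.meta.groupby("arm", sort=False).groups.items()]
    else:
        groups = [m.run_ids]
    for runs in groups:
        totals = vals[runs].sum(axis=0, skipna=True)
        zero = totals.index[totals <= 0].tolist()
        if zero:
            raise ValueError(f"runs with zero total signal: {zero}")
        vals[runs] = vals[runs] * (totals.mean() / totals)
    return QuantMatrix(vals, m.meta.copy(), scale="linear_normalized",
                       normalization_method="total_area")


def log_transform(m: QuantMatrix, base: float = 2.0,
                  pseudo_count: float = 0.0) -> QuantMatrix:
    """Log-transform a linear-normalized matrix (default base 2).

    Zeros (after adding ``pseudo_count``, default 0) are masked as missing;
    the count of newly masked cells is recorded under
    ``info["n_zeros_masked"]`` and logged.
    """
    if m.scale != "linear_normalized":
        raise ValueError("log_transform expects a linear_normalized matrix")
    vals = m.values.to_numpy(dtype=float) + pseudo_count
    newly_masked = int(((vals <= 0) & ~np.isnan(vals)).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.log(vals) / np.log(base)
    logged[vals <= 0] = np.nan
    if newly_masked:
        logger.warning("log_transform masked %d non-positive cells", newly_masked)
    out = QuantMatrix(pd.DataFrame(logged, index=m.values.index, columns=m.values.columns),
                      m.meta.copy(), scale="log",
                      normalization_method=m.normalization_method, log_base=base)
    out.info["n_zeros_masked"] = newly_masked
    return out


@dataclass
class QCReport:
    """Replicate-consistency summary.

    Attributes
    ----------
    group_correlations : per-(condition, arm) mean pairwise Pearson r between
        replicate runs.
    cv_table : per-protein percent CV within each (condition, arm) group,
        computed on the linear scale.
    cv_summary : per-group mean and SD of the per-protein CVs.
    pca_coordinates : run scores on the first principal components of the
        (log-scale) run profiles, for plotting.
    """

    group_correlations: pd.DataFrame
    cv_table: pd.DataFrame
    cv_summary: pd.DataFrame
    pca_coordinates: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps({
            "group_correlations": self.group_correlations.reset_index().to_dict("records"),
            "cv_summary": self.cv_summary.reset_index().to_dict("records"),
        }, default=float)


def qc_replicate_summary(m: QuantMatrix) -> QCReport:
    """Replicate QC: pairwise replicate correlations, CV distributions and PCA
    coordinates per (condition, arm) group; groups with < 2 runs are skipped
    with a warning."""
    from sklearn.decomposition import PCA

    linear = m.linear_values()
    corr_rows, cv_cols, summary_rows = [], {}, []
    for (cond, arm), runs in m.meta.groupby(["condition", "arm"], sort=False).groups.items():
        runs = list(runs)
        if len(runs) < 2:
            logger.warning("group (%s, %s) has < 2 replicates; skipped", cond, arm)
            continue
        sub = linear[runs]
        r = sub.corr(method="pearson")
        iu = np.triu_indices(len(runs), k=1)
        corr_rows.append({"condition": cond, "arm": arm, "n_runs": len(runs),
                          "mean_pairwise_r": float(r.to_numpy()[iu].mean())})
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        cv = 100.0 * sd / mean
        cv[mean == 0] = np.nan
        cv_cols[(cond, arm)] = cv
        summary_rows.append({"condition": cond, "arm": arm,
                             "mean_cv_percent": float(cv.mean(skipna=True)),
                             "sd_cv_percent": float(cv.std(ddof=1, skipna=True))})
    cv_table = pd.DataFrame(cv_cols)
    # PCA of run profiles on complete proteins, log scale
    if m.scale == "log":
        logged = m.values
    else:
        with np.errstate(divide="ignore"):
            logged = np.log2(linear.where(linear > 0))
    complete = logged.dropna(axis=0)
    X = complete.to_numpy(dtype=float).T
    n_comp = min(3, X.shape[0] - 1, X.shape[1]) if X.shape[0] > 1 else 1
    scores = PCA(n_components=n_comp, random_state=0).fit_transform(X)
    pca_coords = pd.DataFrame(scores, index=m.run_ids,
                              columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    return QCReport(pd.DataFrame(corr_rows), cv_table, pd.DataFrame(summary_rows), pca_coords)
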