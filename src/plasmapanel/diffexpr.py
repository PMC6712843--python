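"""Differential expression and candidate selection.

Per protein: a one-way fixed-effects ANOVA across the five condition groups
(healthy, stages I-IV) on log-scale values, unpaired stage-vs-healthy t-tests,
and stage fold changes on the linear normalized scale.  A candidate passes
when ANOVA p < alpha, the maximum symmetric fold change max(FC, 1/FC) over the
four stages exceeds the cutoff (strictly), and — by default — the direction of
change is the same in all four stages.  Per-arm selections are consolidated
into a single candidate table; proteins selected with opposite directions in
different depletion arms are conflict-flagged and excluded from the default
list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .quantio import CONDITIONS, QuantMatrix

logger = logging.getLogger(__name__)

STAGES: tuple[str, ...] = ("I", "II", "III", "IV")


@dataclass
class DEConfig:
    """Selection thresholds and test variants."""

    alpha: float = 0.05
    fc_threshold: float = 1.5
    require_consistent_trend: bool = True
    ttest_variant: str = "welch"  # or "student"
    multiple_testing: str = "none"  # or "BH"
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.ttest_variant not in ("welch", "student"):
            raise ValueError("ttest_variant must be 'welch' or 'student'")
        if self.multiple_testing not in ("none", "BH"):
            raise ValueError("multiple_testing must be 'none' or 'BH'")


# ---------------------------------------------------------------------------
# group extraction helpers

def _log_values(m: QuantMatrix, base: float) -> pd.DataFrame:
    if m.scale == "log":
        return m.values
    linear = m.linear_values()
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(linear.where(linear > 0)) / np.log(base)
    return out


def _condition_runs(m: QuantMatrix, arm: str | None) -> dict[str, list[str]]:
    return {c: m.runs_for(condition=c, arm=arm) for c in CONDITIONS}


def _group_arrays(values: pd.DataFrame, runs: dict[str, list[str]]
                  ) -> dict[str, np.ndarray]:
    """Per condition: (n_replicates, n_proteins) float arrays (NaN = missing)."""
    return {c: values[runs[c]].to_numpy(dtype=float).T for c in CONDITIONS}


def anova_per_protein(m: QuantMatrix, arm: str | None = None,
                      log_base: float = 2.0) -> pd.DataFrame:
    """One-way ANOVA across the five condition groups, per protein.

    Returns a DataFrame (protein_id, F, p).  Proteins with fewer than two
    observed replicates in any condition group are excluded and logged.
    Degenerate cases: identical group means -> (F=0, p=1); zero within-group
    variation with distinct means -> p reported as 0.
    """
    logged = _log_values(m, log_base)
    groups = _group_arrays(logged, _condition_runs(m, arm))
    counts = np.vstack([(~np.isnan(groups[c])).sum(axis=0) for c in CONDITIONS])
    valid = (counts >= 2).all(axis=0)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.debug("%d proteins excluded from ANOVA (a group has < 2 values)",
                     n_excluded)
    arrays = [groups[c][:, valid] for c in CONDITIONS]
    # nan-aware sums of squares, for the degenerate-case policy
    stacked = np.vstack(arrays)
    grand = np.nanmean(stacked, axis=0)
    ss_tot = np.nansum((stacked - grand) ** 2, axis=0)
    ss_within = sum(np.nansum((g - np.nanmean(g, axis=0)) ** 2, axis=0)
                    for g in arrays)
    ss_between = ss_tot - ss_within
    scale = np.maximum(ss_tot, 1.0)
    flat = ss_between <= 1e-12 * scale
    exact = (ss_within <= 1e-12 * scale) & ~flat
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*arrays, axis=0, nan_policy="omit")
    F = np.where(flat, 0.0, np.where(exact, np.inf, F))
    p = np.where(flat, 1.0, np.where(exact, 0.0, p))
    ids = np.asarray(m.protein_ids, dtype=object)[valid]
    return pd.DataFrame({"protein_id": ids, "F": F, "p": p})


def pairwise_ttests(m: QuantMatrix, arm: str | None = None,
                    variant: str = "welch", log_base: float = 2.0) -> pd.DataFrame:
    """Stage-vs-healthy unpaired t-tests per protein (two-sided, on log scale).

    Returns a DataFrame indexed by protein with columns ``t_<stage>`` and
    ``p_<stage>``; contrasts with < 2 observations on either side are NaN.
    Zero variance in both groups gives p = 1 for equal means, p = 0 otherwise.
    """
    logged = _log_values(m, log_base)
    groups = _group_arrays(logged, _condition_runs(m, arm))
    healthy = groups["healthy"]
    n_h = (~np.isnan(healthy)).sum(axis=0)
    out = {}
    for s in STAGES:
        g = groups[s]
        n_g = (~np.isnan(g)).sum(axis=0)
        ok = (n_h >= 2) & (n_g >= 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = stats.ttest_ind(g, healthy, axis=0, nan_policy="omit",
                                   equal_var=(variant == "student"))
            # both groups constant: equal means -> p=1, unequal -> p=0
            var_g = np.nanvar(g, axis=0)
            var_h = np.nanvar(healthy, axis=0)
            both_const = (var_g == 0) & (var_h == 0)
            means_eq = np.nanmean(g, axis=0) == np.nanmean(healthy, axis=0)
        t = np.where(both_const, np.where(means_eq, 0.0, np.inf), t)
        p = np.where(both_const, np.where(means_eq, 1.0, 0.0), p)
        out[f"t_{s}"] = np.where(ok, t, np.nan)
        out[f"p_{s}"] = np.where(ok, p, np.nan)
    res = pd.DataFrame(out, index=m.protein_ids)
    res.index.name = "protein_id"
    return res


def stage_fold_changes(m: QuantMatrix, arm: str | None = None) -> pd.DataFrame:
    """Stage-vs-healthy fold changes on the linear normalized scale.

    FC_s = mean(stage s) / mean(healthy); trend sign is +1 for FC > 1,
    -1 for FC < 1, 0 for exactly equal means.  A zero healthy mean leaves the
    fold change undefined (NaN) and sets ``undefined_fc``.
    """
    linear = m.linear_values()
    groups = _group_arrays(linear, _condition_runs(m, arm))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        h_mean = np.nanmean(groups["healthy"], axis=0)
        out = {}
        h_bad = ~np.isfinite(h_mean) | (h_mean == 0)
        undefined = h_bad.copy()
        for s in STAGES:
            g_mean = np.nanmean(groups[s], axis=0)
            bad = h_bad | ~np.isfinite(g_mean)
            fc = np.where(bad, np.nan, g_mean / np.where(h_mean == 0, np.nan, h_mean))
            out[f"FC_{s}"] = fc
            out[f"trend_{s}"] = np.where(bad, 0, np.sign(fc - 1.0)).astype(int)
            undefined |= bad
    res = pd.DataFrame(out, index=m.protein_ids)
    res["undefined_fc"] = undefined
    res.index.name = "protein_id"
    return res


def protein_stats(m: QuantMatrix, arm: str | None = None,
                  cfg: DEConfig | None = None) -> pd.DataFrame:
    """Full per-protein statistics table for one depletion arm.

    Combines ANOVA, pairwise t-tests, fold changes and the pass flag.
    """
    cfg = cfg or DEConfig()
    anova = anova_per_protein(m, arm, cfg.log_base).set_index("protein_id")
    tt = pairwise_ttests(m, arm, cfg.ttest_variant, cfg.log_base)
    fc = stage_fold_changes(m, arm)
    out = anova.join(tt, how="inner").join(fc, how="inner")
    out = out.rename(columns={"F": "anova_F", "p": "anova_p"})
    if cfg.multiple_testing == "BH":
        out["anova_q"] = multipletests(out["anova_p"].to_numpy(), method="fdr_bh")[1]
        p_used = out["anova_q"]
    else:
        p_used = out["anova_p"]
    fc_cols = [f"FC_{s}" for s in STAGES]
    fc_vals = out[fc_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sym = np.maximum(fc_vals, 1.0 / fc_vals)
    out["max_abs_fc"] = np.nanmax(sym, axis=1)
    trends = out[[f"trend_{s}" for s in STAGES]].to_numpy(dtype=int)
    consistent = (np.abs(trends.sum(axis=1)) == len(STAGES))
    out["consistent_trend"] = consistent
    out["direction"] = np.where(trends.sum(axis=1) > 0, "up", "down")
    passes = (p_used < cfg.alpha) & (out["max_abs_fc"] > cfg.fc_threshold) & ~out["undefined_fc"]
    if cfg.require_consistent_trend:
        passes &= consistent
    out["passes"] = passes.fillna(False).astype(bool)
    out["arm"] = arm if arm is not None else "all"
    return out


def select_candidates(stats: pd.DataFrame, cfg: DEConfig | None = None) -> pd.DataFrame:
    """Proteins with ``passes`` true, ordered by ascending ANOVA p then accession."""
    sel = stats[stats["passes"]].copy()
    sel = sel.sort_values(["anova_p", "protein_id"],
                          key=lambda s: s if s.name != "protein_id" else s.astype(str))
    return sel


def consolidate_arms(per_arm: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union the per-arm candidate selections into a single candidate table.

    One row per protein with the supporting arms; opposite directions across
    arms set ``conflict_flag`` (such proteins are excluded from
    :func:`default_candidates`).
    """
    if not per_arm:
        raise ValueError("at least one arm required")
    records: dict[str, dict] = {}
    for arm, sel in per_arm.items():
        for pid, row in sel.iterrows():
            rec = records.setdefault(pid, {"protein_id": pid, "arms": [],
                                           "directions": [], "min_anova_p": np.inf})
            rec["arms"].append(arm)
            rec["directions"].append(row["direction"])
            rec["min_anova_p"] = min(rec["min_anova_p"], float(row["anova_p"]))
    rows = []
    for pid in sorted(records):
        rec = records[pid]
        dirs = set(rec["directions"])
        rows.append({
            "protein_id": pid,
            "direction": rec["directions"][0] if len(dirs) == 1 else "conflict",
            "arms": ",".join(rec["arms"]),
            "n_arms": len(rec["arms"]),
            "min_anova_p": rec["min_anova_p"],
            "conflict_flag": len(dirs) > 1,
        })
    cols = ["protein_id", "direction", "arms", "n_arms", "min_anova_p", "conflict_flag"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["min_anova_p", "protein_id"]).reset_index(drop=True)


def default_candidates(table: pd.DataFrame) -> list[str]:
    """Candidate ids from a consolidated table, excluding conflict-flagged rows."""
    return table.loc[~table["conflict_flag"], "protein_id"].tolist()


def run_de(m: QuantMatrix, cfg: DEConfig | None = None,
           arms: list[str] | None = None) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-arm statistics + consolidation in one call.

    Returns ``(candidate_table, per_arm_stats)``.
    """
    cfg = cfg or DEConfig()
    if arms is None:
        arms = list(m.meta["arm"].unique())
    per_arm_stats = {arm: protein_stats(m, arm, cfg) for arm in arms}
    per_arm_sel = {arm: select_candidates(s, cfg) for arm, s in per_arm_stats.items()}
    return consolidate_arms(per_arm_sel), per_arm_stats


# ---------------------------------------------------------------------------
# estimator interface

class DifferentialExpressionSelector(BaseEstimator, TransformerMixin):
    """Feature selector running the ANOVA / fold-change / trend filter.

    Scikit-learn style: ``X`` is a runs x proteins table of linear normalized
    peak areas (DataFrame; columns are protein ids) and ``y`` the condition
    label per run (healthy / I / II / III / IV).  ``transform`` keeps the
    selected proteins.

    Attributes
    ----------
    stats_ : DataFrame of per-protein statistics (see :func:`protein_stats`).
    support_ : boolean mask over input features.
    selected_proteins_ : selected ids ordered by ascending ANOVA p.
    """

    def __init__(self, alpha: float = 0.05, fc_threshold: float = 1.5,
                 require_consistent_trend: bool = True, ttest_variant: str = "welch",
                 multiple_testing: str = "none", log_base: float = 2.0):
        self.alpha = alpha
        self.fc_threshold = fc_threshold
        self.require_consistent_trend = require_consistent_trend
        self.ttest_variant = ttest_variant
        self.multiple_testing = multiple_testing
        self.log_base = log_base

    def _config(self) -> DEConfig:
        return DEConfig(alpha=self.alpha, fc_threshold=self.fc_threshold,
                        require_consistent_trend=self.require_consistent_trend,
                        ttest_variant=self.ttest_variant,
                        multiple_testing=self.multiple_testing, log_base=self.log_base)

    @staticmethod
    def _as_matrix(X, y) -> QuantMatrix:
        if isinstance(X, pd.DataFrame):
            values = X.T.copy()
            values.columns = values.columns.astype(str)
        else:
            X = np.asarray(X, dtype=float)
            values = pd.DataFrame(X.T, index=[f"f{i}" for i in range(X.shape[1])],
                                  columns=[f"run{i}" for i in range(X.shape[0])])
        y = np.asarray(y, dtype=object)
        if len(y) != values.shape[1]:
            raise ValueError("X and y have inconsistent lengths")
        counts: dict = {}
        rep_idx = []
        for c in y:
            counts[c] = counts.get(c, 0) + 1
            rep_idx.append(counts[c])
        meta = pd.DataFrame({"condition": y, "arm": "none", "replicate": rep_idx},
                            index=values.columns)
        return QuantMatrix(values, meta, scale="linear_normalized",
                           normalization_method="external")

    def fit(self, X, y):
        m = self._as_matrix(X, y)
        cfg = self._config()
        self.stats_ = protein_stats(m, arm=None, cfg=cfg)
        sel = select_candidates(self.stats_, cfg)
        self.selected_proteins_ = list(sel.index)
        order = list(m.protein_ids)
        chosen = set(self.selected_proteins_)
        self.support_ = np.array([pid in chosen for pid in order])
        self.feature_names_in_ = np.asarray(order, dtype=object)
        self.n_features_in_ = len(order)
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]
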