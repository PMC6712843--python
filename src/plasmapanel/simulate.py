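"""Fixture generator emulating the study design end-to-end.

Generates pooled-sample quantitation matrices for five conditions (healthy,
stages I-IV) in technical triplicate across depletion arms, with:

* healthy centroids log-uniform over a wide abundance range (default 10
  decades, mimicking the plasma dynamic range);
* a planted subset of differentially expressed proteins whose stage centroids
  are healthy x FC with a stage-consistent direction; the largest-FC planted
  proteins form a recoverable "driver" panel;
* multiplicative technical-replicate noise, value = centroid * (1 + N(0, s))
  truncated at zero, with per-stage noise calibrated so that the EXPECTED
  triplicate sample CV (SD/mean, n replicates) equals the configured percent
  CV — the printed replicate-CV figures are themselves small-n sample
  statistics, so matching them requires undoing the c4-style bias of the
  sample SD (done numerically against a fixed z-sample, truncation included);
* per-arm protein subsets drawn by retention probability (the non-depleted
  arm retains everything).

Everything is drawn from one seeded generator, so a fixture is
bit-reproducible from its config.
"""

from __future__ import annotations

import functools
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .quantio import ARMS, CONDITIONS, QuantMatrix

STAGES = ("I", "II", "III", "IV")

#: Printed per-stage technical-replicate CVs (percent): healthy, I, II, III, IV.
DEFAULT_STAGE_CV = (33.0, 36.0, 42.0, 45.0, 31.0)
#: Printed spread (SD) of those CVs across proteins, used by the optional
#: heteroscedastic mode.
DEFAULT_STAGE_CV_SD = (28.0, 34.0, 34.0, 34.0, 18.0)


@dataclass
class FixtureConfig:
    """Generator parameters; defaults emulate the study conditions."""

    n_proteins: int = 300
    abundance_decades: float = 10.0
    n_de: int = 37
    de_fc_low: float = 1.5
    de_fc_high: float = 8.0
    monotone_fc: bool = False
    per_stage_cv_percent: tuple = DEFAULT_STAGE_CV
    n_replicates: int = 3
    arms: tuple = ARMS
    arm_retention: tuple = (1.0, 0.85, 0.85, 0.85)
    driver_panel_size: int = 5
    heteroscedastic_cv: bool = False
    per_stage_cv_sd_percent: tuple = DEFAULT_STAGE_CV_SD
    noise_model: str = "truncated_normal"  # or "lognormal"
    plant_de: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_proteins:
            raise ValueError("n_de cannot exceed n_proteins")
        if self.driver_panel_size > self.n_de:
            raise ValueError("driver_panel_size cannot exceed n_de")
        if any(cv < 0 for cv in self.per_stage_cv_percent):
            raise ValueError("CVs must be >= 0")
        if self.de_fc_low <= 1:
            raise ValueError("fold-change range lower bound must be > 1")
        if len(self.arms) != len(self.arm_retention):
            raise ValueError("arms and arm_retention must align")
        if self.noise_model not in ("truncated_normal", "lognormal"):
            raise ValueError("unknown noise model")


@dataclass
class GroundTruth:
    """Planted truths for oracle tests."""

    de_table: pd.DataFrame          # protein_id, direction, FC_I..FC_IV, is_driver
    drivers: list[str]
    arm_proteins: dict[str, list[str]]
    config: FixtureConfig

    @property
    def de_proteins(self) -> list[str]:
        return list(self.de_table["protein_id"])

    def to_json(self) -> str:
        return json.dumps({
            "de_table": self.de_table.to_dict("records"),
            "drivers": self.drivers,
            "arm_proteins": self.arm_proteins,
            "config": asdict(self.config),
        })


@functools.lru_cache(maxsize=64)
def _calibrated_sigma(target_cv_percent: float, n_replicates: int) -> float:
    """Multiplicative noise sigma whose expected n-replicate sample CV
    (with truncation at zero) equals the target percent CV.

    Solved by bisection against a fixed deterministic z-sample, so the
    calibration itself carries no seed-dependence.
    """
    target = target_cv_percent / 100.0
    if target == 0:
        return 0.0
    z = np.random.default_rng(123456789).standard_normal((200_000, n_replicates))

    def expected_sample_cv(s: float) -> float:
        vals = np.clip(1.0 + s * z, 0.0, None)
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        ok = mean > 0
        return float((sd[ok] / mean[ok]).mean())

    lo, hi = 0.5 * target, 2.5 * target
    while expected_sample_cv(hi) < target:
        hi *= 1.5
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if expected_sample_cv(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _lognormal_sigma(target_cv_percent: float) -> float:
    cv = target_cv_percent / 100.0
    return float(np.sqrt(np.log1p(cv * cv)))


def generate_fixture(cfg: FixtureConfig | None = None
                     ) -> tuple[dict[str, QuantMatrix], GroundTruth]:
    """Generate per-arm quantitation matrices plus the planted ground truth."""
    cfg = cfg or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"PROT{i:04d}" for i in range(cfg.n_proteins)]

    healthy = 10.0 ** rng.uniform(0.0, cfg.abundance_decades, size=cfg.n_proteins)

    # planted DE structure
    fc = np.ones((cfg.n_proteins, len(STAGES)))
    directions = np.zeros(cfg.n_proteins, dtype=int)
    de_idx = np.array([], dtype=int)
    drivers: list[str] = []
    if cfg.plant_de and cfg.n_de > 0:
        de_idx = rng.choice(cfg.n_proteins, size=cfg.n_de, replace=False)
        log_lo, log_hi = np.log(cfg.de_fc_low), np.log(cfg.de_fc_high)
        mags = np.exp(rng.uniform(log_lo, log_hi, size=(cfg.n_de, len(STAGES))))
        if cfg.monotone_fc:
            mags = np.sort(mags, axis=1)
        directions[de_idx] = rng.choice([-1, 1], size=cfg.n_de)
        fc[de_idx] = np.where(directions[de_idx, None] > 0, mags, 1.0 / mags)
        # drivers: the planted proteins with the largest mean log magnitude
        mean_logmag = np.log(mags).mean(axis=1)
        driver_pos = de_idx[np.argsort(mean_logmag)[::-1][:cfg.driver_panel_size]]
        drivers = sorted(proteins[i] for i in driver_pos)

    centroids = np.empty((cfg.n_proteins, len(CONDITIONS)))
    centroids[:, 0] = healthy
    for j, _ in enumerate(STAGES):
        centroids[:, j + 1] = healthy * fc[:, j]

    # per-stage noise scale, calibrated (fixed-CV mode) per protein x stage
    sigmas = np.empty((cfg.n_proteins, len(CONDITIONS)))
    for j, cv in enumerate(cfg.per_stage_cv_percent):
        if cfg.heteroscedastic_cv:
            draw = rng.normal(cv, cfg.per_stage_cv_sd_percent[j], size=cfg.n_proteins)
            draw = np.clip(draw, 2.0, None)
            if cfg.noise_model == "lognormal":
                sigmas[:, j] = [_lognormal_sigma(c) for c in draw]
            else:
                # approximate small-n debias (c4 + mean-inverse terms)
                c4 = _c4(cfg.n_replicates)
                sigmas[:, j] = (draw / 100.0) / (c4 * (1 + (draw / 100.0) ** 2
                                                       / cfg.n_replicates))
        else:
            if cfg.noise_model == "lognormal":
                sigmas[:, j] = _lognormal_sigma(cv)
            else:
                sigmas[:, j] = _calibrated_sigma(float(cv), cfg.n_replicates)

    # replicate values per arm (independent acquisitions share the centroids)
    matrices: dict[str, QuantMatrix] = {}
    arm_proteins: dict[str, list[str]] = {}
    for arm, retention in zip(cfg.arms, cfg.arm_retention):
        keep = rng.random(cfg.n_proteins) < retention
        kept = [p for p, k in zip(proteins, keep) if k]
        arm_proteins[arm] = kept
        cols, run_ids, meta_rows = [], [], []
        for j, cond in enumerate(CONDITIONS):
            for r in range(1, cfg.n_replicates + 1):
                z = rng.standard_normal(cfg.n_proteins)
                if cfg.noise_model == "lognormal":
                    vals = centroids[:, j] * np.exp(sigmas[:, j] * z
                                                    - sigmas[:, j] ** 2 / 2.0)
                else:
                    vals = centroids[:, j] * np.clip(1.0 + sigmas[:, j] * z, 0.0, None)
                cols.append(vals[keep])
                run_ids.append(f"{arm}_{cond}_r{r}")
                meta_rows.append({"condition": cond, "arm": arm, "replicate": r})
        values = pd.DataFrame(np.column_stack(cols), index=kept, columns=run_ids)
        meta = pd.DataFrame(meta_rows, index=run_ids)
        matrices[arm] = QuantMatrix(values, meta, scale="raw")

    de_rows = []
    for i in sorted(de_idx):
        de_rows.append({"protein_id": proteins[i],
                        "direction": "up" if directions[i] > 0 else "down",
                        **{f"FC_{s}": float(fc[i, j]) for j, s in enumerate(STAGES)},
                        "is_driver": proteins[i] in drivers})
    truth = GroundTruth(
        pd.DataFrame(de_rows, columns=["protein_id", "direction",
                                       *[f"FC_{s}" for s in STAGES], "is_driver"]),
        drivers, arm_proteins, cfg)
    return matrices, truth


def _c4(n: int) -> float:
    from scipy.special import gammaln
    return float(np.sqrt(2.0 / (n - 1)) *
                 np.exp(gammaln(n / 2.0) - gammaln((n - 1) / 2.0)))


def write_fixture(matrices: dict[str, QuantMatrix], truth: GroundTruth,
                  outdir) -> None:
    """Write per-arm TSVs (quantio dialect) plus the ground-truth JSON."""
    import os

    from .quantio import write_quant_table

    os.makedirs(outdir, exist_ok=True)
    for arm, m in matrices.items():
        write_quant_table(m, os.path.join(outdir, f"{arm}_matrix.tsv"),
                          os.path.join(outdir, f"{arm}_runs.tsv"))
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        fh.write(truth.to_json())
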