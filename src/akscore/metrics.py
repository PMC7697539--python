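"""Scoring, ranking and docking power metrics (CASF-2016 style), plus a
bootstrap comparison between two predictors.

Scoring power is the Pearson correlation between predicted and experimental
affinities over a benchmark set.  Ranking power is rank agreement within
receptor clusters of five complexes, measured by Spearman's rho, Kendall's
tau-b and the Predictive Index (PI).  Docking power is the fraction of cases
in which the native pose scores within the best k of {native} + decoys.

Ties are declared on values rounded to 6 decimals so that tie counts are
reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "UndefinedMetricError",
    "RankingGroup",
    "DockingCase",
    "MetricsReport",
    "BootstrapComparison",
    "mae",
    "rmse",
    "pearson_r",
    "spearman_rho",
    "kendall_tau",
    "predictive_index",
    "ranking_power",
    "docking_power",
    "bootstrap_compare",
    "scoring_report",
]

TIE_DECIMALS = 6


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given input (e.g. zero variance)."""


def _validate_pair(x, y, min_n=2):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} points, got {len(x)}")
    return x, y


def mae(pred, y) -> float:
    """Mean absolute error."""
    pred, y = _validate_pair(pred, y, min_n=1)
    return float(np.mean(np.abs(pred - y)))


def rmse(pred, y) -> float:
    """Root mean squared error."""
    pred, y = _validate_pair(pred, y, min_n=1)
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient."""
    x, y = _validate_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("Pearson r undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks)."""
    x, y = _validate_pair(x, y)
    x = np.round(x, TIE_DECIMALS)
    y = np.round(y, TIE_DECIMALS)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("Spearman rho undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def kendall_tau(x, y) -> float:
    """Kendall's tau-b: (Nc - Nd) / sqrt((Nc+Nd+T)(Nc+Nd+U)).

    T counts pairs tied only in x, U pairs tied only in y; pairs tied in
    both contribute to neither.
    """
    x, y = _validate_pair(x, y)
    x = np.round(x, TIE_DECIMALS)
    y = np.round(y, TIE_DECIMALS)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("Kendall tau undefined for constant input")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def predictive_index(pred, y_exp, mode: str = "binary") -> float:
    """Affinity-difference-weighted concordance.

    PI = sum_{j>i} w_ij S_ij / sum_{j>i} w_ij with w_ij = |y_i - y_j|.
    In ``binary`` mode S_ij is 1 for concordant pairs and 0 otherwise, so
    PI falls in [0, 1].  The ``pearlman`` mode scores discordant pairs -1
    (ties 0), giving the classical [-1, 1] range.
    """
    if mode not in ("binary", "pearlman"):
        raise ValueError(f"unknown PI mode {mode!r}")
    pred, y_exp = _validate_pair(pred, y_exp)
    pred = np.round(pred, TIE_DECIMALS)
    y_exp = np.round(y_exp, TIE_DECIMALS)
    i, j = np.triu_indices(len(pred), k=1)
    w = np.abs(y_exp[j] - y_exp[i])
    if w.sum() == 0:
        raise UndefinedMetricError("PI undefined: all experimental values tied")
    prod = np.sign(pred[j] - pred[i]) * np.sign(y_exp[j] - y_exp[i])
    if mode == "binary":
        s = (prod > 0).astype(float)
    else:
        s = np.sign(prod)
    return float((w * s).sum() / w.sum())


@dataclass
class RankingGroup:
    """A receptor cluster: (complex id, experimental pK, prediction) triples."""

    group_id: str
    members: list[tuple[str, float, float]]

    @property
    def experimental(self) -> np.ndarray:
        return np.array([m[1] for m in self.members], dtype=float)

    @property
    def predicted(self) -> np.ndarray:
        return np.array([m[2] for m in self.members], dtype=float)


def ranking_power(groups: Sequence[RankingGroup], group_size: int | None = 5,
                  pi_mode: str = "binary"):
    """Mean within-group Spearman, Kendall tau-b and PI across clusters.

    Each metric is computed inside every group on (predicted, experimental)
    and then averaged over groups.  ``group_size`` enforces the
    five-complexes-per-cluster convention; pass None to accept any size.
    """
    if not groups:
        raise ValueError("no ranking groups given")
    sp, kt, pi = [], [], []
    for g in groups:
        if group_size is not None and len(g.members) != group_size:
            raise ValueError(
                f"group {g.group_id} has {len(g.members)} members, "
                f"expected {group_size}")
        sp.append(spearman_rho(g.predicted, g.experimental))
        kt.append(kendall_tau(g.predicted, g.experimental))
        pi.append(predictive_index(g.predicted, g.experimental, mode=pi_mode))
    return float(np.mean(sp)), float(np.mean(kt)), float(np.mean(pi))


@dataclass
class DockingCase:
    """Native-pose score and ~100 decoy-pose scores for one complex."""

    case_id: str
    native_score: float
    decoy_scores: list[float]


def docking_power(cases: Sequence[DockingCase], larger_is_better: bool = False):
    """Fractions of cases with the native pose ranked in the top 1, 2, 3.

    By default scores are binding free energies (lower = better); set
    ``larger_is_better`` for pK-scaled scores.  Decoys tied with the native
    pose count against it.
    """
    if not cases:
        raise ValueError("no docking cases given")
    tops = np.zeros(3)
    for case in cases:
        if not case.decoy_scores:
            raise ValueError(f"case {case.case_id} has no decoys")
        decoys = np.round(np.asarray(case.decoy_scores, dtype=float), TIE_DECIMALS)
        native = round(case.native_score, TIE_DECIMALS)
        if larger_is_better:
            better = np.sum(decoys >= native)
        else:
            better = np.sum(decoys <= native)
        rank = 1 + int(better)
        for k in range(3):
            if rank <= k + 1:
                tops[k] += 1
    frac = tops / len(cases)
    return float(frac[0]), float(frac[1]), float(frac[2])


@dataclass
class MetricsReport:
    """Bundle of scoring/ranking/docking numbers for one model."""

    pearson_r: Optional[float] = None
    spearman_rho: Optional[float] = None
    kendall_tau: Optional[float] = None
    predictive_index: Optional[float] = None
    mae: Optional[float] = None
    rmse: Optional[float] = None
    docking_top1: Optional[float] = None
    docking_top2: Optional[float] = None
    docking_top3: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def __str__(self) -> str:
        return "\n".join(f"{k:>18s}: {v: .4f}" for k, v in self.to_dict().items())


def scoring_report(pred, y, groups: Sequence[RankingGroup] | None = None,
                   docking: Sequence[DockingCase] | None = None,
                   **docking_kw) -> MetricsReport:
    """Full report: scoring errors + correlation, optional ranking/docking."""
    report = MetricsReport(
        pearson_r=pearson_r(pred, y),
        mae=mae(pred, y),
        rmse=rmse(pred, y),
    )
    if groups:
        sp, kt, pi = ranking_power(groups)
        report.spearman_rho, report.kendall_tau, report.predictive_index = sp, kt, pi
    if docking:
        t1, t2, t3 = docking_power(docking, **docking_kw)
        report.docking_top1, report.docking_top2, report.docking_top3 = t1, t2, t3
    return report


@dataclass
class BootstrapComparison:
    """Bootstrap means/sds of Pearson R and RMSE for two predictors, with
    Welch-combined t statistics for the difference."""

    r_mean: tuple[float, float]
    r_sd: tuple[float, float]
    rmse_mean: tuple[float, float]
    rmse_sd: tuple[float, float]
    t_pearson: float
    t_rmse: float
    n_boot: int
    resample_size: int
    n_redrawn: int


def bootstrap_compare(pred_a, pred_b, y, n_boot: int = 1000,
                      frac: float = 2.0 / 3.0, seed: int = 0) -> BootstrapComparison:
    """Compare two predictors by resampling the evaluation set.

    ``ceil(frac * n)`` samples are drawn with replacement ``n_boot`` times;
    Pearson R and RMSE are computed for both predictors on every resample.
    The t value combines the bootstrap means and standard deviations in the
    Welch style: t = (mean_a - mean_b) / sqrt(sd_a^2 + sd_b^2).  Degenerate
    resamples (zero variance) are redrawn and counted.
    """
    pred_a, y = _validate_pair(pred_a, y)
    pred_b, _ = _validate_pair(pred_b, y)
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    n = len(y)
    m = int(np.ceil(frac * n))
    r = np.empty((2, n_boot))
    e = np.empty((2, n_boot))
    redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=m)
            ys = y[idx]
            if np.ptp(ys) > 0 and np.ptp(pred_a[idx]) > 0 and np.ptp(pred_b[idx]) > 0:
                break
            redrawn += 1
        for k, pred in enumerate((pred_a, pred_b)):
            r[k, b] = pearson_r(pred[idx], ys)
            e[k, b] = rmse(pred[idx], ys)
    r_mean, r_sd = r.mean(axis=1), r.std(axis=1, ddof=1)
    e_mean, e_sd = e.mean(axis=1), e.std(axis=1, ddof=1)
    return BootstrapComparison(
        r_mean=(float(r_mean[0]), float(r_mean[1])),
        r_sd=(float(r_sd[0]), float(r_sd[1])),
        rmse_mean=(float(e_mean[0]), float(e_mean[1])),
        rmse_sd=(float(e_sd[0]), float(e_sd[1])),
        t_pearson=float((r_mean[0] - r_mean[1]) / np.sqrt(r_sd[0] ** 2 + r_sd[1] ** 2)),
        t_rmse=float((e_mean[0] - e_mean[1]) / np.sqrt(e_sd[0] ** 2 + e_sd[1] ** 2)),
        n_boot=n_boot, resample_size=m, n_redrawn=redrawn)
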