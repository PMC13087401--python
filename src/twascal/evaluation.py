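"""Calibration and discovery diagnostics.

Covers the standard read-outs for a correction method: QQ data and
Kolmogorov-Smirnov distance of p values against Uniform(0,1), empirical
type-I error at fixed alpha levels, the genomic inflation factor, Bonferroni
discovery sets with precision/recall, and the regression of Z^2 summaries on
N*h2_delta whose slope should vanish after a successful correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .correction import _CHI2_MEDIAN
from .errors import DomainError, RankError

__all__ = [
    "CalibrationReport",
    "DiscoveryReport",
    "RegressionSummary",
    "bonferroni_threshold",
    "precision_recall",
    "calibration_report",
    "inflation_regression",
    "write_qq_points",
]


@dataclass
class CalibrationReport:
    """How close a set of p values is to the uniform null."""

    n_tests: int
    ks_statistic: float
    ks_p: float
    typeI_at_alpha: dict
    qq_points: np.ndarray  # columns: expected, observed (-log10 p), ascending
    lambda_gc: float
    qq_method: str = "rank/(n+1)"

    def to_dict(self) -> dict:
        return {
            "n_tests": self.n_tests,
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
            "typeI_at_alpha": {str(a): r for a, r in self.typeI_at_alpha.items()},
            "lambda_gc": self.lambda_gc,
            "qq_method": self.qq_method,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class DiscoveryReport:
    """Discovery set at a p-value threshold, with precision and recall."""

    threshold: float
    n_discoveries: int
    precision: float | None  # None when no discoveries were made
    recall: float
    causal_ids: list = field(default_factory=list)
    discovered_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_discoveries": self.n_discoveries,
            "precision": self.precision,
            "recall": self.recall,
            "causal_ids": list(self.causal_ids),
            "discovered_ids": list(self.discovered_ids),
        }


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r2: float
    p_value: float
    slope_se: float


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if not (0 < alpha < 1):
        raise DomainError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise DomainError("n_tests must be >= 1")
    return alpha / n_tests


def _pvalue_of(res) -> float:
    for attr in ("p_corrected", "p"):
        if hasattr(res, attr):
            return getattr(res, attr)
    raise DomainError("result object carries no p value")


def precision_recall(results, causal_ids, threshold: float) -> DiscoveryReport:
    """Precision and recall of the discovery set {p < threshold}.

    ``results`` may be association or corrected results (the corrected p is
    used when present).  Precision is None — an explicit undefined flag —
    when nothing is discovered.
    """
    results = list(results)
    tested = {r.mediator_id for r in results}
    causal = set(causal_ids)
    stray = causal - tested
    if stray:
        raise DomainError(f"causal ids not among tested mediators: {sorted(stray)}")
    discovered = [r.mediator_id for r in results if _pvalue_of(r) < threshold]
    hits = [d for d in discovered if d in causal]
    precision = len(hits) / len(discovered) if discovered else None
    recall = len(hits) / len(causal) if causal else 0.0
    return DiscoveryReport(
        threshold=threshold,
        n_discoveries=len(discovered),
        precision=precision,
        recall=recall,
        causal_ids=sorted(causal),
        discovered_ids=sorted(discovered),
    )


def calibration_report(pvalues, alphas=(0.05, 0.01, 1e-3)) -> CalibrationReport:
    """KS vs Uniform(0,1), type-I rates, QQ points, and lambda_GC.

    QQ expected quantiles use rank/(n+1).  lambda_GC converts each p back
    to a squared Z via the normal quantile, matching the genomic-control
    factor computed from Z scores directly.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DomainError("empty p-value collection")
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p values must lie in (0, 1]")
    ks = stats.kstest(p, "uniform")
    typeI = {a: float(np.mean(p < a)) for a in alphas}
    order = np.argsort(p)[::-1]  # largest p = smallest -log10 first
    expected = -np.log10(np.arange(p.size, 0, -1) / (p.size + 1))
    observed = -np.log10(p[order])
    z = stats.norm.isf(p / 2)
    lam = float(np.median(z * z) / _CHI2_MEDIAN)
    return CalibrationReport(
        n_tests=int(p.size),
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        typeI_at_alpha=typeI,
        qq_points=np.column_stack([expected, observed]),
        lambda_gc=lam,
    )


def inflation_regression(points, statistic: str = "mean") -> RegressionSummary:
    """OLS of a Z^2 summary on N*h2_delta.

    ``points`` is either a collection of
    :class:`~twascal.association.ReplicateSummary` (x = n*h2, y = mean Z^2)
    or an iterable of (nh2, z2_summary) pairs where the caller has already
    taken the mean, median, or first-quartile summary of Z^2.
    """
    xs, ys = [], []
    for pt in points:
        if hasattr(pt, "mean_z2"):
            xs.append(pt.n * pt.h2_delta)
            if statistic == "mean":
                ys.append(pt.mean_z2)
            elif statistic in ("median", "q1"):
                if getattr(pt, "zscores", None) is None:
                    raise DomainError(f"{statistic} summary needs per-replicate z scores")
                q = 0.5 if statistic == "median" else 0.25
                ys.append(float(np.quantile(np.asarray(pt.zscores) ** 2, q)))
            else:
                raise DomainError(f"unknown statistic {statistic!r}")
        else:
            x, y = pt
            xs.append(float(x))
            ys.append(float(y))
    x, y = np.asarray(xs), np.asarray(ys)
    if x.size < 3:
        raise RankError("inflation regression needs >= 3 points")
    if len(np.unique(x)) < 2:
        raise RankError("inflation regression needs >= 2 distinct predictor values")
    fit = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        slope_se=float(fit.stderr) if np.isfinite(fit.stderr) else 0.0,
    )


def write_qq_points(report: CalibrationReport, path) -> None:
    """QQ points as a two-column TSV (expected, observed -log10 p)."""
    with open(path, "w") as fh:
        fh.write("expected_neglog10p\tobserved_neglog10p\n")
        for e, o in report.qq_points:
            fh.write(f"{float(e)!r}\t{float(o)!r}\n")
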