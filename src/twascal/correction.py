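"""Variance control of TWAS Z scores, with a genomic-control baseline.

The variance-control correction divides each mediator's Z score by the
square root of its expected null variance,

    Z_corr = Z / sqrt(1 + Phi * N * h2_delta),

using the mediator-specific inflation slope Phi, the GWAS sample size N,
and the target trait's polygenic heritability h2_delta (a user input,
typically from LD score regression).  Genomic control — a single global
rescaling by the median chi-square ratio — is provided for comparison; it
cannot be right for every mediator when inflation is mediator specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult
from .errors import DomainError
from .phi import PhiEstimate

__all__ = [
    "CorrectionContext",
    "CorrectedResult",
    "variance_control",
    "genomic_control",
    "lambda_gc",
    "write_corrected",
    "read_corrected",
]

logger = logging.getLogger(__name__)

_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class CorrectionContext:
    """Everything the correction needs: N, h2_delta, and a phi per mediator."""

    n: int
    h2_delta: float
    phi_table: Mapping[str, object] = field(default_factory=dict)
    missing_policy: str = "warn"  # or "error"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if not (0 <= self.h2_delta <= 1):
            raise DomainError("h2_delta must lie in [0, 1]")
        if self.missing_policy not in ("warn", "error"):
            raise DomainError("missing_policy must be 'warn' or 'error'")

    def phi_for(self, mediator_id: str) -> float | None:
        entry = self.phi_table.get(mediator_id)
        if entry is None:
            return None
        if isinstance(entry, PhiEstimate):
            return entry.phi
        return float(entry)


@dataclass
class CorrectedResult:
    """Raw and corrected statistics for one mediator."""

    mediator_id: str
    z_raw: float
    z_corrected: float
    p_raw: float
    p_corrected: float
    correction_factor: float
    phi: float = float("nan")
    corrected: bool = True


def _p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def variance_control(results, ctx: CorrectionContext) -> list[CorrectedResult]:
    """Apply Z / sqrt(1 + phi * N * h2_delta) with each mediator's own phi.

    Mediators without a phi entry pass through uncorrected with
    ``corrected=False`` (default policy) or raise (``missing_policy='error'``).
    """
    results = list(results)
    if not results:
        raise DomainError("no association results to correct")
    out = []
    for res in results:
        phi = ctx.phi_for(res.mediator_id)
        if phi is None:
            if ctx.missing_policy == "error":
                raise DomainError(f"no phi entry for mediator {res.mediator_id}")
            logger.warning("no phi for %s; emitting uncorrected", res.mediator_id)
            out.append(
                CorrectedResult(
                    mediator_id=res.mediator_id,
                    z_raw=res.z,
                    z_corrected=res.z,
                    p_raw=res.p,
                    p_corrected=res.p,
                    correction_factor=1.0,
                    corrected=False,
                )
            )
            continue
        if phi < 0:
            raise DomainError(f"negative phi for {res.mediator_id}")
        factor = float(np.sqrt(1.0 + phi * ctx.n * ctx.h2_delta))
        zc = res.z / factor
        out.append(
            CorrectedResult(
                mediator_id=res.mediator_id,
                z_raw=res.z,
                z_corrected=zc,
                p_raw=res.p,
                p_corrected=_p(zc),
                correction_factor=factor,
                phi=phi,
            )
        )
    return out


def lambda_gc(zscores) -> float:
    """Genomic inflation factor: median(Z^2) / median of chi-square(1)."""
    z2 = np.asarray(zscores, dtype=float) ** 2
    if z2.size < 2:
        raise DomainError("lambda_gc needs at least 2 statistics")
    return float(np.median(z2) / _CHI2_MEDIAN)


def genomic_control(results) -> list[CorrectedResult]:
    """Scale all Z by 1/sqrt(lambda_GC) when lambda_GC > 1; otherwise no-op.

    The one-sided clip at 1 is the conventional behavior: genomic control
    corrects inflation but never sharpens deflated statistics.
    """
    results = list(results)
    if len(results) < 2:
        raise DomainError("genomic control needs at least 2 results")
    lam = lambda_gc([r.z for r in results])
    factor = float(np.sqrt(lam)) if lam > 1 else 1.0
    out = []
    for res in results:
        zc = res.z / factor
        out.append(
            CorrectedResult(
                mediator_id=res.mediator_id,
                z_raw=res.z,
                z_corrected=zc,
                p_raw=res.p,
                p_corrected=_p(zc),
                correction_factor=factor,
            )
        )
    return out


# --- corrected table I/O ---------------------------------------------------

_COLUMNS = [
    "mediator_id",
    "z_raw",
    "z_corrected",
    "p_raw",
    "p_corrected",
    "correction_factor",
    "phi",
]


def write_corrected(results, path) -> None:
    df = pd.DataFrame({c: [getattr(r, c) for r in results] for c in _COLUMNS})
    df.to_csv(path, sep="\t", index=False)


def read_corrected(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
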