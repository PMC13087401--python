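"""The per-mediator inflation slope Phi.

Under a polygenic null target trait, the squared TWAS statistic inflates
linearly in the product of GWAS sample size and trait heritability:

    E[Z^2] ~= 1 + N * h2_delta * Phi.

Phi is estimated empirically per mediator by simulating null traits over a
grid of (N, h2_delta) combinations, averaging Z^2 per cell, and regressing
the cell means on N * h2_delta; one standard error is added to the fitted
slope as a conservative adjustment.  The analytic counterpart

    Phi = (1/M) * (w' S^2 w) / (w' S w),

with S the SNP correlation (LD) matrix, w the prediction weights, and M the
effective number of causal SNPs for the target trait, is exposed as a
validation oracle: for independent SNPs it reduces to 1/M, and with the
realized sample LD it predicts the simulated inflation cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng, child_seed
from .association import ReplicateSummary, batch_null_associations
from .errors import DegenerateInputError, DomainError, RankError
from .genotype_sim import GenotypeMatrix, LDMatrix, subsample
from .trait_sim import NullTraitSpec
from .weights_io import PredictedMediator, WeightSet

__all__ = [
    "InflationGrid",
    "PhiEstimate",
    "AltExpectationInput",
    "run_inflation_grid",
    "estimate_phi",
    "theoretical_phi",
    "expected_z2",
    "expected_z2_alt",
    "write_phi_table",
    "read_phi_table",
]


class GridPoint(NamedTuple):
    n: int
    h2_delta: float
    mean_z2: float
    se: float
    seed: int


@dataclass
class InflationGrid:
    """Mean Z^2 over null replicates at each (N, h2_delta) combination."""

    points: list
    n_replicates: int
    mediator_id: str
    seed: int = 0

    @property
    def nh2(self) -> np.ndarray:
        return np.array([p.n * p.h2_delta for p in self.points])

    @property
    def mean_z2(self) -> np.ndarray:
        return np.array([p.mean_z2 for p in self.points])


@dataclass
class PhiEstimate:
    """Fitted inflation slope and its conservative one-SE adjustment."""

    mediator_id: str
    slope: float
    slope_se: float
    phi: float
    intercept: float
    r2: float
    grid: InflationGrid | None = None
    n_replicates: int = 0


@dataclass
class AltExpectationInput:
    """Parameters of the expected Z^2 under a nonzero mediator effect."""

    n: int
    h2_delta: float
    phi: float
    tau2: float  # prediction precision var(T)/var(T~)
    h2_gene: float  # beta^2 var(T)/var(Y)

    def __post_init__(self) -> None:
        if self.n < 0 or self.phi < 0:
            raise DomainError("n and phi must be nonnegative")
        if not (0 <= self.h2_delta <= 1) or not (0 <= self.tau2 <= 1) or self.h2_gene < 0:
            raise DomainError("h2_delta and tau2 must lie in [0, 1]; h2_gene >= 0")
        if self.tau2 * self.h2_gene >= 1:
            raise DomainError("tau2 * h2_gene must be < 1")


def run_inflation_grid(
    g: GenotypeMatrix,
    t: PredictedMediator,
    n_values: list[int],
    h2_values: list[float],
    n_replicates: int,
    seed: int = 0,
    prop_nonzero: float = 1.0,
) -> InflationGrid:
    """Simulate null traits at every (n, h2) combination and summarize Z^2.

    For n below the available sample count, individuals are subsampled
    without replacement (one subsample per n, shared across h2 values, as
    when a biobank subset is fixed and traits are re-simulated); the
    mediator values are carried along and the genotype columns
    re-standardized within the subset.
    """
    if not g.standardized:
        raise DomainError("run_inflation_grid requires standardized genotypes")
    n_avail = g.n_samples
    points = []
    for n in n_values:
        if n > n_avail:
            raise DomainError(f"requested n={n} exceeds available samples ({n_avail})")
        if n < 3:
            raise DomainError("grid sample sizes must be >= 3")
        idx = child_rng(seed, "subsample", n).choice(n_avail, size=n, replace=False)
        g_sub = subsample(g, idx)
        t_sub = PredictedMediator(
            mediator_id=t.mediator_id,
            values=np.asarray(t.values)[idx],
            n_variants_used=t.n_variants_used,
            n_variants_missing=t.n_variants_missing,
        )
        for h2 in h2_values:
            if not (0 <= h2 <= 1):
                raise DomainError("h2 values must lie in [0, 1]")
            cell_seed = child_seed(seed, "cell", n, int(round(h2 * 1e6)))
            spec = NullTraitSpec(h2_delta=h2, prop_nonzero=prop_nonzero, seed=cell_seed)
            summary = batch_null_associations(
                g_sub, t_sub, spec, n_replicates, keep_zscores=False
            )
            points.append(GridPoint(n, h2, summary.mean_z2, summary.se_mean_z2, cell_seed))
    return InflationGrid(
        points=points, n_replicates=n_replicates, mediator_id=t.mediator_id, seed=seed
    )


def estimate_phi(grid: InflationGrid) -> PhiEstimate:
    """OLS of mean Z^2 on N*h2_delta; phi = max(slope + SE, 0).

    The regression keeps a free intercept (reported, not forced to 1); the
    one-SE adjustment makes the downstream correction conservative.
    """
    x, y = grid.nh2, grid.mean_z2
    if len(np.unique(x)) < 2:
        raise RankError("inflation grid needs >= 2 distinct values of N*h2")
    fit = stats.linregress(x, y)
    se = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    slope = float(fit.slope)
    return PhiEstimate(
        mediator_id=grid.mediator_id,
        slope=slope,
        slope_se=se,
        phi=max(slope + se, 0.0),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        grid=grid,
        n_replicates=grid.n_replicates,
    )


def theoretical_phi(weights, sigma, m_causal: int) -> float:
    """Analytic inflation slope (1/M) * (w' S^2 w) / (w' S w).

    ``weights`` may be a plain vector aligned with ``sigma`` or a
    :class:`WeightSet`, in which case entries are aligned by variant id and
    variants absent from the LD matrix contribute zero weight.  ``sigma``
    may be an :class:`LDMatrix` or a correlation matrix array.
    """
    if m_causal < 1:
        raise DomainError("m_causal must be >= 1")
    if isinstance(sigma, LDMatrix):
        sig, vids = sigma.sigma, sigma.variant_ids
    else:
        sig, vids = np.asarray(sigma, dtype=float), None
    if isinstance(weights, WeightSet):
        if vids is None:
            raise DomainError("aligning a WeightSet requires an LDMatrix with variant ids")
        pos = {v: j for j, v in enumerate(vids)}
        w = np.zeros(sig.shape[0])
        for vid, wt in zip(weights.variant_ids, weights.weights):
            j = pos.get(vid)
            if j is not None:
                w[j] = wt
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape[0] != sig.shape[0]:
        raise DomainError("weight vector length does not match LD dimension")
    sw = sig @ w
    denom = float(w @ sw)
    if denom <= 0:
        raise DegenerateInputError("w' S w is zero: no weight falls in the LD matrix")
    return float(sw @ sw) / denom / m_causal


def expected_z2(n: float, h2_delta: float, phi: float) -> float:
    """Expected squared Z under the polygenic null: 1 + N * h2_delta * Phi."""
    if phi < 0:
        raise DomainError("phi must be nonnegative")
    if n < 0 or not (0 <= h2_delta <= 1):
        raise DomainError("n must be >= 0 and h2_delta in [0, 1]")
    return 1.0 + n * h2_delta * phi


def expected_z2_alt(inp: AltExpectationInput) -> float:
    """Expected squared Z with a nonzero mediator-target effect.

    1 + [N h2_delta / (1 - tau2 h2_gene)] Phi + N tau2 h2_gene / (1 - tau2 h2_gene).
    With h2_gene = 0 this reduces to :func:`expected_z2` for any tau2 —
    prediction precision affects power only, never null calibration.
    """
    denom = 1.0 - inp.tau2 * inp.h2_gene
    return 1.0 + (inp.n * inp.h2_delta / denom) * inp.phi + inp.n * inp.tau2 * inp.h2_gene / denom


# --- phi table I/O ---------------------------------------------------------

_PHI_COLUMNS = ["mediator_id", "phi", "slope", "slope_se", "intercept", "r2", "n_replicates"]


def write_phi_table(estimates, path) -> None:
    df = pd.DataFrame(
        {
            "mediator_id": [e.mediator_id for e in estimates],
            "phi": [e.phi for e in estimates],
            "slope": [e.slope for e in estimates],
            "slope_se": [e.slope_se for e in estimates],
            "intercept": [e.intercept for e in estimates],
            "r2": [e.r2 for e in estimates],
            "n_replicates": [e.n_replicates for e in estimates],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_phi_table(path) -> dict[str, PhiEstimate]:
    from .errors import FormatError

    df = pd.read_csv(path, sep="\t")
    if "mediator_id" not in df.columns or "phi" not in df.columns:
        raise FormatError("phi table needs columns mediator_id and phi")
    out = {}
    for _, row in df.iterrows():
        out[str(row["mediator_id"])] = PhiEstimate(
            mediator_id=str(row["mediator_id"]),
            slope=float(row.get("slope", row["phi"])),
            slope_se=float(row.get("slope_se", 0.0)),
            phi=float(row["phi"]),
            intercept=float(row.get("intercept", float("nan"))),
            r2=float(row.get("r2", float("nan"))),
            n_replicates=int(row.get("n_replicates", 0)),
        )
    return out
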