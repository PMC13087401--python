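"""Mediator prediction weights: containers, file dialects, and prediction.

A mediating molecular trait (gene expression, metabolite level, imaging
feature) is modeled as a linear combination of genotype dosages,
T = sum_k X_k * w_k.  Weights travel either as a flat TSV
(``gene rsid ref_allele eff_allele weight``) or as a PredictDB-style SQLite
file whose ``extra`` table can carry the per-mediator inflation slope phi.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_rng
from .errors import DomainError, EmptyOverlapError, FormatError
from .genotype_sim import GenotypeMatrix

__all__ = [
    "WeightSet",
    "PredictedMediator",
    "MEDIATOR_CLASSES",
    "load_weights",
    "save_weights",
    "predict_mediator",
    "simulate_true_weights",
]

MEDIATOR_CLASSES = ("gene", "metabolite", "brain_feature", "other")


@dataclass
class WeightSet:
    """Prediction weights for one mediator, with allele orientation."""

    mediator_id: str
    variant_ids: np.ndarray
    ref_allele: np.ndarray
    eff_allele: np.ndarray
    weights: np.ndarray
    mediator_class: str = "gene"

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.eff_allele = np.asarray(self.eff_allele, dtype=object)
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.variant_ids)
        if not (len(self.ref_allele) == len(self.eff_allele) == len(self.weights) == k):
            raise DomainError("weight entry arrays must share one length")
        if len(set(self.variant_ids)) != k:
            raise DomainError(f"duplicate variant in weights for {self.mediator_id}")
        if k == 0 or not np.any(self.weights != 0):
            raise DomainError(f"weight set for {self.mediator_id} has no nonzero weight")
        if self.mediator_class not in MEDIATOR_CLASSES:
            raise DomainError(f"unknown mediator_class {self.mediator_class!r}")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightSet):
            return NotImplemented
        return (
            self.mediator_id == other.mediator_id
            and self.mediator_class == other.mediator_class
            and list(self.variant_ids) == list(other.variant_ids)
            and list(self.ref_allele) == list(other.ref_allele)
            and list(self.eff_allele) == list(other.eff_allele)
            and np.array_equal(self.weights, other.weights)
        )


@dataclass
class PredictedMediator:
    """Genetically predicted mediator values for N samples."""

    mediator_id: str
    values: np.ndarray
    n_variants_used: int
    n_variants_missing: int
    dropped_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DomainError("predicted mediator values must be finite")


# --- file dialects ---------------------------------------------------------

_TSV_COLUMNS = ["gene", "rsid", "ref_allele", "eff_allele", "weight"]


def _weightsets_from_frame(df: pd.DataFrame, classes: dict | None = None) -> list[WeightSet]:
    if df.empty:
        raise FormatError("weight table is empty")
    dup = df.duplicated(subset=["gene", "rsid"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["gene", "rsid"]].tolist()
        raise FormatError(f"repeated (mediator, variant) pair: {tuple(pair)}")
    out = []
    for gene, grp in df.groupby("gene", sort=True):
        out.append(
            WeightSet(
                mediator_id=str(gene),
                variant_ids=grp["rsid"].to_numpy(dtype=object),
                ref_allele=grp["ref_allele"].to_numpy(dtype=object),
                eff_allele=grp["eff_allele"].to_numpy(dtype=object),
                weights=grp["weight"].to_numpy(dtype=float),
                mediator_class=(classes or {}).get(str(gene), "gene"),
            )
        )
    return out


def load_weights(path, dialect: str = "tsv") -> list[WeightSet]:
    """Read a weight table; one :class:`WeightSet` per mediator, ordered by id."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"weights file not found: {path}")
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns) != _TSV_COLUMNS:
            raise FormatError(f"weights TSV must have columns {_TSV_COLUMNS}")
        return _weightsets_from_frame(df)
    if dialect == "predictdb":
        with sqlite3.connect(path) as conn:
            try:
                df = pd.read_sql_query(
                    "SELECT gene, rsid, ref_allele, eff_allele, weight FROM weights", conn
                )
            except (sqlite3.DatabaseError, pd.errors.DatabaseError) as exc:
                raise FormatError(f"not a PredictDB-style database: {path}") from exc
            try:
                extra = pd.read_sql_query("SELECT gene, mediator_class FROM extra", conn)
                classes = dict(zip(extra["gene"].astype(str), extra["mediator_class"]))
            except (sqlite3.DatabaseError, pd.errors.DatabaseError):
                classes = {}
        return _weightsets_from_frame(df, classes)
    raise DomainError(f"unknown weights dialect {dialect!r}")


def save_weights(weight_sets, path, dialect: str = "tsv", phi_table: dict | None = None) -> None:
    """Write weight sets as TSV or a PredictDB-style SQLite file.

    ``phi_table`` maps mediator_id -> (phi, phi_se) and is stored in the
    ``extra`` table of the SQLite dialect (ignored for TSV).
    """
    weight_sets = sorted(weight_sets, key=lambda w: w.mediator_id)
    rows = [
        (w.mediator_id, v, r, e, float(wt))
        for w in weight_sets
        for v, r, e, wt in zip(w.variant_ids, w.ref_allele, w.eff_allele, w.weights)
    ]
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    if dialect == "tsv":
        df.to_csv(path, sep="\t", index=False)
        return
    if dialect == "predictdb":
        phi_table = phi_table or {}
        Path(path).unlink(missing_ok=True)
        with sqlite3.connect(path) as conn:
            df.to_sql("weights", conn, index=False)
            extra = pd.DataFrame(
                {
                    "gene": [w.mediator_id for w in weight_sets],
                    "mediator_class": [w.mediator_class for w in weight_sets],
                    "n_snps_in_model": [len(w) for w in weight_sets],
                    "phi": [
                        float(phi_table.get(w.mediator_id, (np.nan, np.nan))[0])
                        for w in weight_sets
                    ],
                    "phi_se": [
                        float(phi_table.get(w.mediator_id, (np.nan, np.nan))[1])
                        for w in weight_sets
                    ],
                }
            )
            extra.to_sql("extra", conn, index=False)
        return
    raise DomainError(f"unknown weights dialect {dialect!r}")


# --- prediction ------------------------------------------------------------


def predict_mediator(
    g: GenotypeMatrix,
    w: WeightSet,
    allele_policy: str = "flip",
    strict: bool = False,
) -> PredictedMediator:
    """T-tilde = sum over matched variants of oriented dosage column x weight.

    Variants absent from ``g`` are skipped and counted; when the weight's
    ref/eff alleles are swapped relative to the genotype metadata the weight
    sign is flipped (``allele_policy='flip'``) or the variant is dropped
    (``'drop'``).  ``strict=True`` turns any skip into an error.
    """
    if allele_policy not in ("flip", "drop"):
        raise DomainError(f"unknown allele_policy {allele_policy!r}")
    if not g.standardized:
        raise DomainError("predict_mediator requires a standardized genotype matrix")
    col = {v: j for j, v in enumerate(g.variant_ids)}
    use_cols, use_wts, dropped = [], [], []
    for vid, ref, eff, wt in zip(w.variant_ids, w.ref_allele, w.eff_allele, w.weights):
        j = col.get(vid)
        if j is None:
            dropped.append(vid)
            continue
        if ref == g.ref_allele[j] and eff == g.eff_allele[j]:
            sign = 1.0
        elif ref == g.eff_allele[j] and eff == g.ref_allele[j]:
            if allele_policy == "drop":
                dropped.append(vid)
                continue
            sign = -1.0
        else:
            dropped.append(vid)  # allele labels irreconcilable
            continue
        use_cols.append(j)
        use_wts.append(sign * wt)
    if strict and dropped:
        raise DomainError(
            f"{w.mediator_id}: {len(dropped)} model variants unusable in strict mode"
        )
    if not use_cols:
        raise EmptyOverlapError(f"no model variants of {w.mediator_id} matched the genotypes")
    values = g.dosages[:, use_cols] @ np.asarray(use_wts)
    return PredictedMediator(
        mediator_id=w.mediator_id,
        values=values,
        n_variants_used=len(use_cols),
        n_variants_missing=len(dropped),
        dropped_ids=dropped,
    )


def simulate_true_weights(
    n_snps: int,
    sparsity: float = 1.0,
    seed: int = 0,
    template: GenotypeMatrix | None = None,
    mediator_id: str = "sim_mediator",
    mediator_class: str = "gene",
) -> WeightSet:
    """i.i.d. standard-normal weights on a uniform subset of SNPs.

    ``round(sparsity * n_snps)`` entries (at least one) are nonzero.  When a
    ``template`` genotype matrix is given, its variant ids and alleles are
    reused so the weights align with it by construction.
    """
    if not (0 < sparsity <= 1):
        raise DomainError("sparsity must lie in (0, 1]")
    if n_snps < 1:
        raise DomainError("n_snps must be >= 1")
    if template is not None and template.n_snps != n_snps:
        raise DomainError("template has a different number of SNPs")
    rng = child_rng(seed, "simulate_true_weights")
    k = max(1, round(sparsity * n_snps))
    weights = np.zeros(n_snps)
    support = rng.choice(n_snps, size=k, replace=False)
    weights[support] = rng.standard_normal(k)
    if template is not None:
        vids, ref, eff = template.variant_ids, template.ref_allele, template.eff_allele
    else:
        vids = np.array([f"snp_{i:05d}" for i in range(n_snps)], dtype=object)
        ref = np.array(["A"] * n_snps, dtype=object)
        eff = np.array(["G"] * n_snps, dtype=object)
    return WeightSet(
        mediator_id=mediator_id,
        variant_ids=vids.copy(),
        ref_allele=ref.copy(),
        eff_allele=eff.copy(),
        weights=weights,
        mediator_class=mediator_class,
    )
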