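"""Synthetic genotype dosage matrices.

Genotypes are additively coded allele counts in {0, 1, 2}.  Independent SNPs
are drawn as Binomial(2, maf) under Hardy-Weinberg equilibrium; correlated
SNPs are built from two haplotypes obtained by thresholding a correlated
Gaussian (a Gaussian copula), so the realized dosage correlation tracks a
requested LD matrix.  Standardization uses the population form of the
standard deviation (divisor n, not n-1) so that (1/n) X'X of a standardized
matrix is exactly a correlation matrix; this keeps the correlation-based Z
score and the LD-based inflation formula on the same scale.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .errors import DegenerateInputError, DomainError, FormatError

__all__ = [
    "GenotypeMatrix",
    "LDMatrix",
    "simulate_genotypes",
    "simulate_ld_genotypes",
    "standardize",
    "subsample",
    "write_dosages",
    "read_dosages",
]

_EIG_TOL = 1e-8


@dataclass
class GenotypeMatrix:
    """An N x M dosage matrix with per-variant metadata.

    ``dosages`` holds allele counts on the 0-2 scale before standardization
    and centered/scaled columns afterwards; ``standardized`` records which.
    """

    dosages: np.ndarray
    variant_ids: np.ndarray
    ref_allele: np.ndarray
    eff_allele: np.ndarray
    maf: np.ndarray
    sample_ids: np.ndarray
    standardized: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DomainError("dosages must be a 2-D (samples x variants) array")
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.maf = np.asarray(self.maf, dtype=float)
        n, m = self.dosages.shape
        if len(self.variant_ids) != m or len(self.maf) != m:
            raise DomainError("variant metadata length does not match n_snps")
        if len(self.sample_ids) != n:
            raise DomainError("sample_ids length does not match n_samples")
        if len(set(self.variant_ids)) != m:
            raise DomainError("variant_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise DomainError("sample_ids must be unique")
        if not self.standardized:
            if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
                raise DomainError("raw dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class LDMatrix:
    """A symmetric positive-semidefinite SNP correlation matrix."""

    sigma: np.ndarray
    variant_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 2 or self.sigma.shape[0] != self.sigma.shape[1]:
            raise DomainError("LD matrix must be square")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise DomainError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.sigma), 1.0, atol=1e-10):
            raise DomainError("LD matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.sigma).min() < -_EIG_TOL:
            raise DomainError("LD matrix must be positive semidefinite")
        if self.variant_ids is None:
            self.variant_ids = np.array(
                [f"snp_{i:05d}" for i in range(self.sigma.shape[0])], dtype=object
            )
        else:
            self.variant_ids = np.asarray(self.variant_ids, dtype=object)
            if len(self.variant_ids) != self.sigma.shape[0]:
                raise DomainError("variant_ids length does not match LD dimension")

    @property
    def n_snps(self) -> int:
        return self.sigma.shape[0]


def _check_maf(maf: np.ndarray) -> None:
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise DomainError("maf must lie in (0, 0.5]")


def _variant_ids(m: int) -> np.ndarray:
    return np.array([f"snp_{i:05d}" for i in range(m)], dtype=object)


def _sample_ids(n: int) -> np.ndarray:
    return np.array([f"s_{i:06d}" for i in range(n)], dtype=object)


def simulate_genotypes(
    n_samples: int, n_snps: int, maf: float | np.ndarray, seed: int = 0
) -> GenotypeMatrix:
    """Draw independent Binomial(2, maf) dosages for ``n_samples`` x ``n_snps``.

    ``maf`` may be a scalar or a length-``n_snps`` vector of per-variant
    frequencies in (0, 0.5].  The same seed yields a bit-identical matrix.
    """
    if n_samples < 1 or n_snps < 1:
        raise DomainError("n_samples and n_snps must be >= 1")
    maf_arr = np.broadcast_to(np.asarray(maf, dtype=float), (n_snps,)).copy()
    _check_maf(maf_arr)
    rng = child_rng(seed, "simulate_genotypes")
    dosages = rng.binomial(2, maf_arr, size=(n_samples, n_snps)).astype(float)
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=_variant_ids(n_snps),
        ref_allele=np.array(["A"] * n_snps, dtype=object),
        eff_allele=np.array(["G"] * n_snps, dtype=object),
        maf=maf_arr,
        sample_ids=_sample_ids(n_samples),
        seed=seed,
    )


def simulate_ld_genotypes(
    n_samples: int, ld: LDMatrix, maf: float = 0.5, seed: int = 0
) -> GenotypeMatrix:
    """Dosages from two haplotypes of a Gaussian copula with correlation ``ld``.

    Each haplotype carries the effect allele when a correlated standard
    normal falls below the maf quantile; the dosage is the sum of the two
    haplotypes.  The realized dosage correlation is attenuated relative to
    the latent Gaussian correlation (dichotomization) but is monotone in it
    and zero when ``ld`` is the identity.
    """
    if n_samples < 1:
        raise DomainError("n_samples must be >= 1")
    if not (0 < maf <= 0.5):
        raise DomainError("maf must lie in (0, 0.5]")
    m = ld.n_snps
    evals, evecs = np.linalg.eigh(ld.sigma)
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
    rng = child_rng(seed, "simulate_ld_genotypes")
    threshold = stats.norm.ppf(maf)
    dosages = np.zeros((n_samples, m))
    for _ in range(2):  # two haplotypes per individual
        latent = rng.standard_normal(size=(n_samples, m)) @ factor.T
        dosages += (latent < threshold).astype(float)
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=ld.variant_ids.copy(),
        ref_allele=np.array(["A"] * m, dtype=object),
        eff_allele=np.array(["G"] * m, dtype=object),
        maf=np.full(m, maf),
        sample_ids=_sample_ids(n_samples),
        seed=seed,
    )


def standardize(g: GenotypeMatrix) -> GenotypeMatrix:
    """Center and scale every column to mean 0, SD 1 (divisor n).

    Raises on an already-standardized input and on zero-variance columns
    (their variant ids are listed in the error message).
    """
    if g.standardized:
        raise DomainError("genotype matrix is already standardized")
    sd = g.dosages.std(axis=0)
    dead = sd == 0
    if dead.any():
        ids = ", ".join(map(str, g.variant_ids[dead]))
        raise DegenerateInputError(f"zero-variance variants cannot be standardized: {ids}")
    dosages = (g.dosages - g.dosages.mean(axis=0)) / sd
    return replace(g, dosages=dosages, standardized=True)


def subsample(g: GenotypeMatrix, idx: np.ndarray) -> GenotypeMatrix:
    """Row subset of ``g``; standardized inputs are re-standardized in the subset.

    Columns that become constant in the subset are set to zero (they carry
    no association signal) rather than raising, since random subsamples of
    common variants hit this only pathologically.
    """
    idx = np.asarray(idx)
    dosages = g.dosages[idx]
    if g.standardized:
        mu = dosages.mean(axis=0)
        sd = dosages.std(axis=0)
        safe = np.where(sd == 0, 1.0, sd)
        dosages = (dosages - mu) / safe
        dosages[:, sd == 0] = 0.0
    return replace(g, dosages=dosages, sample_ids=g.sample_ids[idx])


# --- dosage file I/O -------------------------------------------------------
# Tab-delimited, one variant per row:
#   variant_id  ref  eff  maf  <sample_1> ... <sample_N>


def _opener(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_dosages(g: GenotypeMatrix, path) -> None:
    with _opener(path, "w") as fh:
        header = ["variant_id", "ref", "eff", "maf"] + [str(s) for s in g.sample_ids]
        fh.write("\t".join(header) + "\n")
        for j in range(g.n_snps):
            row = [
                str(g.variant_ids[j]),
                str(g.ref_allele[j]),
                str(g.eff_allele[j]),
                repr(float(g.maf[j])),
            ] + [repr(float(v)) for v in g.dosages[:, j]]
            fh.write("\t".join(row) + "\n")


def read_dosages(path) -> GenotypeMatrix:
    with _opener(path, "r") as fh:
        df = pd.read_csv(fh, sep="\t")
    required = ["variant_id", "ref", "eff", "maf"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"dosage file must start with columns {required}")
    sample_ids = np.array(df.columns[4:], dtype=object)
    if len(sample_ids) == 0:
        raise FormatError("dosage file has no sample columns")
    dosages = df.iloc[:, 4:].to_numpy(dtype=float).T
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=df["variant_id"].to_numpy(dtype=object),
        ref_allele=df["ref"].to_numpy(dtype=object),
        eff_allele=df["eff"].to_numpy(dtype=object),
        maf=df["maf"].to_numpy(dtype=float),
        sample_ids=sample_ids,
    )
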