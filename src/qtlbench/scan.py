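"""Baseline single-SNP genome scans.

Two least-squares models per SNP:

- additive: phenotype ~ allele dosage (0/1/2), the standard Mendelian test on
  unordered genotypes;
- maternal imprinting: phenotype ~ paternal-allele indicator (0/1), the true
  generating model for maternally silenced loci, requiring ordered genotypes.

Genome-wide significance uses the permutation procedure: the phenotype is
permuted against the genotypes, the genome-wide minimum p-value is recorded
per permutation, and the threshold is the lower empirical alpha-quantile of
that null distribution.  Family structure is deliberately ignored (no
polygenic correction): these scans are the naive baseline the benchmark is
designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genome import LocusMap

MODEL_ADDITIVE = "additive"
MODEL_IMPRINTING = "imprinting_maternal"


@dataclass
class ScanResult:
    model: str
    chrom: np.ndarray
    pos: np.ndarray
    effect: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    p_value: np.ndarray
    monomorphic: np.ndarray
    threshold: Optional[float] = None  # genome-wide p threshold, if computed

    @property
    def n_snps(self) -> int:
        return self.effect.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos_bp": self.pos,
                "model": self.model,
                "effect": self.effect,
                "se": self.se,
                "stat": self.stat,
                "p": self.p_value,
                "monomorphic": self.monomorphic,
            }
        )

    def min_p_in_window(self, chrom: int, position_bp: int, window_mb: float = 1.0) -> float:
        w = window_mb * 1_000_000
        sel = (self.chrom == chrom) & (np.abs(self.pos - position_bp) <= w)
        if not sel.any():
            raise ValueError(f"no SNPs within {window_mb} Mb of chr{chrom}:{position_bp}")
        return float(np.min(self.p_value[sel]))


def _residualize(y: np.ndarray, covariates: np.ndarray):
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta, X.shape[1] - 1


def _marker_regression(X: np.ndarray, y: np.ndarray, df_lost: int = 0):
    """Vectorised per-column simple regression of y on X columns."""
    n = y.size
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    sxy = Xc.T @ yc
    syy = float(yc @ yc)
    mono = sxx <= 0
    safe_sxx = np.where(mono, 1.0, sxx)
    slope = sxy / safe_sxx
    dof = n - 2 - df_lost
    if dof < 1:
        raise ValueError("not enough observations for the regression")
    rss = np.maximum(syy - slope * sxy, 0.0)
    sigma2 = rss / dof
    se = np.sqrt(np.where(sigma2 > 0, sigma2 / safe_sxx, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), np.inf * np.sign(slope))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    slope[mono] = 0.0
    se[mono] = np.nan
    t[mono] = 0.0
    p[mono] = 1.0
    return slope, se, t, p, mono


def _check_inputs(X: np.ndarray, y: np.ndarray):
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X)
    if X.shape[0] != y.size:
        raise ValueError(f"genotype rows ({X.shape[0]}) != phenotype length ({y.size})")
    if np.unique(y).size < 3:
        raise ValueError("phenotype must take at least 3 distinct values")
    return X.astype(np.float64), y


def _loci_arrays(loci: Optional[LocusMap], n_markers: int):
    if loci is None:
        return np.ones(n_markers, dtype=int), np.arange(1, n_markers + 1)
    snp = loci.snp_indices
    if snp.size == n_markers:
        return loci.chrom[snp], loci.pos[snp]
    if loci.n_loci == n_markers:
        return loci.chrom, loci.pos
    raise ValueError("locus map does not match the marker matrix")


def additive_scan(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    loci: Optional[LocusMap] = None,
    covariates: Optional[np.ndarray] = None,
) -> ScanResult:
    """Per-SNP regression of the phenotype on allele dosage (0/1/2)."""
    X, y = _check_inputs(genotypes, phenotype)
    df_lost = 0
    if covariates is not None:
        y, df_lost = _residualize(y, np.asarray(covariates, dtype=float))
    slope, se, t, p, mono = _marker_regression(X, y, df_lost)
    chrom, pos = _loci_arrays(loci, X.shape[1])
    return ScanResult(MODEL_ADDITIVE, chrom, pos, slope, se, t, p, mono)


def imprinting_scan(
    paternal: np.ndarray,
    phenotype: np.ndarray,
    loci: Optional[LocusMap] = None,
    covariates: Optional[np.ndarray] = None,
) -> ScanResult:
    """Per-SNP regression of the phenotype on the paternal-allele indicator.

    Requires ordered genotypes (parental origin): the maternal copy is
    treated as silenced, so only the paternally inherited allele carries
    signal under the model.
    """
    if paternal is None:
        raise ValueError("imprinting scan needs parental-origin labels (ordered genotypes)")
    X, y = _check_inputs(paternal, phenotype)
    if X.size and X.max() > 1:
        raise ValueError("paternal matrix must contain 0/1 alleles, not dosages")
    df_lost = 0
    if covariates is not None:
        y, df_lost = _residualize(y, np.asarray(covariates, dtype=float))
    slope, se, t, p, mono = _marker_regression(X, y, df_lost)
    chrom, pos = _loci_arrays(loci, X.shape[1])
    return ScanResult(MODEL_IMPRINTING, chrom, pos, slope, se, t, p, mono)


@dataclass
class PermutationThreshold:
    threshold: float       # genome-wide p-value threshold at the given alpha
    null_min_p: np.ndarray  # one genome-wide minimum p per permutation
    alpha: float
    n_perm: int
    model: str


def permutation_threshold(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    model: str = MODEL_ADDITIVE,
    n_perm: int = 100,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> PermutationThreshold:
    """Genome-wide p-value threshold from phenotype permutations.

    For each permutation the genome-wide minimum p is recorded; the returned
    threshold is the k-th smallest with k = max(1, floor(alpha·n_perm))
    (lower empirical quantile).  Deterministic given the seed.

    ``genotypes`` is the dosage matrix for the additive model or the paternal
    0/1 matrix for the imprinting model — the test statistic machinery is
    identical.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if model not in (MODEL_ADDITIVE, MODEL_IMPRINTING):
        raise ValueError(f"unknown model {model!r}")
    X, y = _check_inputs(genotypes, phenotype)
    rng = np.random.default_rng(rng_seed)
    n = y.size

    Xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    poly = sxx > 0
    Xc = Xc[:, poly]
    sxx = sxx[poly]
    if Xc.shape[1] == 0:
        raise ValueError("all markers are monomorphic")

    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = y[rng.permutation(n)]
    perms -= perms.mean(axis=0)
    syy = np.einsum("ij,ij->j", perms, perms)

    sxy = Xc.T @ perms                      # (markers, n_perm)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy ** 2 / (sxx[:, None] * syy[None, :])
    r2max = np.clip(r2.max(axis=0), 0.0, 1.0 - 1e-15)
    dof = n - 2
    tmax = np.sqrt(dof * r2max / (1.0 - r2max))
    min_p = np.clip(2.0 * stats.t.sf(tmax, dof), np.finfo(float).tiny, 1.0)

    k = max(1, int(np.floor(alpha * n_perm)))
    threshold = float(np.sort(min_p)[k - 1])
    return PermutationThreshold(threshold=threshold, null_min_p=min_p,
                                alpha=alpha, n_perm=n_perm, model=model)
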