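"""Genetic values and phenotypes.

Quantitative trait:  QT = A + E + M + e, where

- A = Σ_k a_k (x_k − 2 p_k)                  (additive, centred dosages)
- E = Σ_pairs e (x_1 − 2 p_1)(x_2 − 2 p_2)   (epistatic; zero marginal effects
                                              under linkage equilibrium)
- M = Σ_k i_k (h_pat,k − p_k)                (maternal imprinting: the
                                              maternal copy is silenced, only
                                              the paternal allele counts)

Binary trait: liability = Σ over the 22 binary-affecting additive QTL of
a_k (x_k − 2 p_k) plus its own Gaussian residual; status = liability above a
threshold set from the configured prevalence under a normal approximation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import (
    ACTION_ADDITIVE,
    ACTION_IMPRINTED,
    QTLArchitecture,
)
from .popsim import HaplotypeSet


def _component_values(paternal: np.ndarray, maternal: np.ndarray, arch: QTLArchitecture):
    """Components from allele matrices aligned to ``arch.records`` order."""
    p = np.array([r.allele_freq for r in arch.records])
    if np.any(~np.isfinite(p)):
        raise ValueError("architecture allele frequencies are unset; calibrate first")
    x = paternal.astype(np.float64) + maternal.astype(np.float64)
    cx = x - 2 * p

    a = np.array([r.additive_effect if r.action == ACTION_ADDITIVE else 0.0
                  for r in arch.records])
    additive = cx @ a

    epistatic = np.zeros(x.shape[0])
    idx = {r.qtl_id: k for k, r in enumerate(arch.records)}
    for ra, rb in arch.epistatic_pairs():
        ka, kb = idx[ra.qtl_id], idx[rb.qtl_id]
        epistatic += ra.interaction_coeff * cx[:, ka] * cx[:, kb]

    imprinting = np.zeros(x.shape[0])
    for r in arch.records:
        if r.action == ACTION_IMPRINTED:
            k = idx[r.qtl_id]
            imprinting += r.imprint_effect * (paternal[:, k].astype(np.float64) - p[k])

    a_bin = np.array([r.additive_effect if r.affects_binary else 0.0 for r in arch.records])
    liability_genetic = cx @ a_bin
    return additive, epistatic, imprinting, liability_genetic


def extract_qtl_haplotypes(haps: HaplotypeSet, arch: QTLArchitecture):
    """Paternal/maternal allele matrices at the QTL, in ``arch.records`` order."""
    cols = np.array([haps.loci.index_of(r.chrom, r.position_bp) for r in arch.records])
    return haps.paternal[:, cols], haps.maternal[:, cols]


def genetic_value_qt(haps: HaplotypeSet, arch: QTLArchitecture) -> pd.DataFrame:
    """Per-individual genetic-value components (ordered genotypes required).

    Parental origin must be available because the imprinting component reads
    the paternal allele only.
    """
    if haps.paternal is None or haps.maternal is None:
        raise ValueError("imprinted sites need parental-origin labels (ordered genotypes)")
    pat, mat = extract_qtl_haplotypes(haps, arch)
    additive, epistatic, imprinting, lg = _component_values(pat, mat, arch)
    return pd.DataFrame(
        {
            "id": haps.ids,
            "additive": additive,
            "epistatic": epistatic,
            "imprinting": imprinting,
            "total": additive + epistatic + imprinting,
            "liability_genetic": lg,
        }
    )


def simulate_phenotypes(
    values: pd.DataFrame,
    arch: QTLArchitecture,
    rng_seed: int,
) -> pd.DataFrame:
    """Add residuals and threshold the liability.

    QT = total genetic value + Gaussian residual; liability = binary-QTL
    additive value + its own residual; the two residuals are correlated by
    ``arch.residual_corr``.  With zero residual variance the phenotype equals
    the genetic value exactly.
    """
    if not np.isfinite(arch.residual_var_qt) or not np.isfinite(arch.residual_var_liability):
        raise ValueError("residual variances unset; calibrate the architecture first")
    rng = np.random.default_rng(rng_seed)
    n = len(values)
    z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
    rho = arch.residual_corr
    e_qt = np.sqrt(arch.residual_var_qt) * z1
    e_l = np.sqrt(arch.residual_var_liability) * (rho * z1 + np.sqrt(1 - rho ** 2) * z2)

    qt = values["total"].to_numpy() + e_qt
    liability = values["liability_genetic"].to_numpy() + e_l
    status = (liability > arch.liability_threshold).astype(int)
    return pd.DataFrame(
        {
            "id": values["id"].to_numpy(),
            "qt": qt,
            "binary": status,
            "liability": liability,
            "additive": values["additive"].to_numpy(),
            "epistatic": values["epistatic"].to_numpy(),
            "imprinting": values["imprinting"].to_numpy(),
            "genetic_total": values["total"].to_numpy(),
        }
    )


def variance_decomposition(
    arch: QTLArchitecture,
    haps: HaplotypeSet,
    n_mc: int,
    rng_seed: int,
) -> pd.DataFrame:
    """Monte-Carlo realized variance fractions over the given population.

    Samples ``n_mc`` individuals as random unions of two gametes from the
    population's haplotype pool and reports, per QTL (per pair for epistatic
    loci) and per component, the variance contribution as a percentage of
    phenotypic and of additive-genetic variance.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000")
    if not arch.calibrated:
        raise ValueError("architecture must be calibrated before decomposition")
    rng = np.random.default_rng(rng_seed)
    pool = haps.haplotype_pool()
    cols = np.array([haps.loci.index_of(r.chrom, r.position_bp) for r in arch.records])
    gi = rng.integers(0, pool.shape[0], size=n_mc)
    gj = rng.integers(0, pool.shape[0], size=n_mc)
    pat = pool[gi][:, cols]
    mat = pool[gj][:, cols]

    additive, epistatic, imprinting, lg = _component_values(pat, mat, arch)
    total = additive + epistatic + imprinting
    VP = float(np.var(total)) + arch.residual_var_qt
    VA = float(np.var(additive))

    p = np.array([r.allele_freq for r in arch.records])
    x = pat.astype(np.float64) + mat.astype(np.float64)
    cx = x - 2 * p
    idx = {r.qtl_id: k for k, r in enumerate(arch.records)}

    rows = []
    for r in arch.records:
        k = idx[r.qtl_id]
        if r.action == ACTION_ADDITIVE:
            v = float(np.var(r.additive_effect * cx[:, k]))
            rows.append(("qtl", r.qtl_id, v, 100 * v / VP, 100 * v / VA))
        elif r.action == ACTION_IMPRINTED:
            v = float(np.var(r.imprint_effect * (pat[:, k].astype(float) - p[k])))
            rows.append(("qtl", r.qtl_id, v, 100 * v / VP, np.nan))
    for ra, rb in arch.epistatic_pairs():
        ka, kb = idx[ra.qtl_id], idx[rb.qtl_id]
        v = float(np.var(ra.interaction_coeff * cx[:, ka] * cx[:, kb]))
        rows.append(("pair", f"{ra.qtl_id}+{rb.qtl_id}", v, 100 * v / VP, np.nan))
    for name, comp in (("additive", additive), ("epistatic", epistatic),
                       ("imprinting", imprinting), ("genetic_total", total)):
        v = float(np.var(comp))
        rows.append(("component", name, v, 100 * v / VP, np.nan))

    return pd.DataFrame(rows, columns=["kind", "unit", "variance", "pct_phenotypic", "pct_additive"])
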