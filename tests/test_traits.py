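import numpy as np
import pandas as pd
import pytest

from qtlbench.architecture import (
    ACTION_ADDITIVE,
    ACTION_EPISTATIC,
    ACTION_IMPRINTED,
    QTLArchitecture,
    QTLRecord,
)
from qtlbench.genome import LocusMap
from qtlbench.popsim import HaplotypeSet
from qtlbench.traits import genetic_value_qt, simulate_phenotypes, variance_decomposition


def _loci(n, chrom=2):
    return LocusMap(chrom=np.full(n, chrom), pos=np.arange(1, n + 1) * 1_000_000,
                    is_snp=np.zeros(n, bool), ids=np.array([f"q{i}" for i in range(n)], object))


def _haps(pat_rows, mat_rows, loci):
    return HaplotypeSet(ids=np.arange(1, len(pat_rows) + 1),
                        paternal=np.array(pat_rows, np.uint8),
                        maternal=np.array(mat_rows, np.uint8), loci=loci)


def _imprint_arch(p=0.5):
    rec = QTLRecord("imp", 2, 1_000_000, ACTION_IMPRINTED, imprint_effect=3.0,
                    allele_freq=p)
    arch = QTLArchitecture(records=[rec])
    arch.residual_var_qt = 0.0
    arch.residual_var_liability = 0.0
    arch.liability_threshold = 0.0
    arch.calibrated = True
    return arch


def test_imprinting_origin_swap_changes_qt_by_exactly_the_effect():
    """Two individuals heterozygous at an imprinted locus, carrying allele 1
    paternally vs maternally: QT genetic values differ by exactly 3.00 and
    the binary liability by 0."""
    arch = _imprint_arch()
    haps = _haps([[1], [0]], [[0], [1]], _loci(1))
    v = genetic_value_qt(haps, arch)
    assert v["total"][0] - v["total"][1] == pytest.approx(3.0, abs=1e-12)
    assert v["liability_genetic"][0] == v["liability_genetic"][1] == 0.0


def test_component_additivity_is_exact(default_run):
    ph = default_run.phenotypes
    total = ph["additive"] + ph["epistatic"] + ph["imprinting"]
    assert np.allclose(total, ph["genetic_total"], atol=1e-12)


def test_flipping_nonbinary_loci_leaves_liability_unchanged(default_run):
    """The binary liability responds only to its 22 additive QTL: flipping
    every individual's genotype at each imprinted or epistatic locus must not
    move it."""
    arch = default_run.architecture
    haps = default_run.haplotypes
    base = genetic_value_qt(haps, arch)["liability_genetic"].to_numpy()
    flipped = HaplotypeSet(haps.ids, haps.paternal.copy(), haps.maternal.copy(), haps.loci)
    for r in arch.records:
        if r.action in (ACTION_EPISTATIC, ACTION_IMPRINTED):
            col = haps.loci.index_of(r.chrom, r.position_bp)
            flipped.paternal[:, col] = 1 - flipped.paternal[:, col]
            flipped.maternal[:, col] = 1 - flipped.maternal[:, col]
    after = genetic_value_qt(flipped, arch)["liability_genetic"].to_numpy()
    assert np.array_equal(base, after)


def test_epistatic_pair_has_zero_marginal_effects(default_run):
    """9-cell enumeration oracle: weighting the two-locus genotype classes by
    the product of single-locus HWE frequencies at founder allele
    frequencies, the marginal regression of the interaction value on either
    locus' dosage is 0."""
    arch = default_run.architecture
    for ra, rb in arch.epistatic_pairs():
        pa, pb, e = ra.allele_freq, rb.allele_freq, ra.interaction_coeff
        xa = np.repeat([0, 1, 2], 3).astype(float)
        xb = np.tile([0, 1, 2], 3).astype(float)
        hwe = lambda p: np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        w = np.repeat(hwe(pa), 3) * np.tile(hwe(pb), 3)
        val = e * (xa - 2 * pa) * (xb - 2 * pb)
        for x in (xa, xb):
            mx = np.sum(w * x)
            cov = np.sum(w * val * x) - np.sum(w * val) * mx
            assert cov / np.sum(w * (x - mx) ** 2) == pytest.approx(0.0, abs=1e-10)


def test_noiseless_phenotype_equals_genetic_value():
    arch = _imprint_arch()
    haps = _haps([[1], [0], [1]], [[1], [0], [0]], _loci(1))
    v = genetic_value_qt(haps, arch)
    ph = simulate_phenotypes(v, arch, rng_seed=0)
    assert np.array_equal(ph["qt"].to_numpy(), v["total"].to_numpy())


def test_components_are_centred(default_run):
    """Centred coding: every genetic component has mean ≈ 0 over the
    reference (founder-pool) genotype distribution."""
    arch = default_run.architecture
    dec_pool = default_run.founder_sim.pool
    rng = np.random.default_rng(0)
    pool = dec_pool.haplotype_pool()
    cols = np.array([dec_pool.loci.index_of(r.chrom, r.position_bp) for r in arch.records])
    gi, gj = rng.integers(0, len(pool), 20000), rng.integers(0, len(pool), 20000)
    from qtlbench.traits import _component_values
    add, epi, imp, lg = _component_values(pool[gi][:, cols], pool[gj][:, cols], arch)
    sd = np.sqrt(arch.phenotypic_variance)
    for comp in (add, epi, imp, lg):
        assert abs(comp.mean()) < 0.05 * sd


def test_realized_prevalence_matches_normal_cdf_threshold(default_run):
    """10,000 individuals drawn from the reference genotype distribution:
    realized binary prevalence within ±2% (absolute) of the configured one."""
    arch = default_run.architecture
    pool = default_run.founder_sim.pool
    rng = np.random.default_rng(11)
    H = pool.haplotype_pool()
    cols = np.array([pool.loci.index_of(r.chrom, r.position_bp) for r in arch.records])
    n = 10_000
    gi, gj = rng.integers(0, len(H), n), rng.integers(0, len(H), n)
    from qtlbench.traits import _component_values
    _, _, _, lg = _component_values(H[gi][:, cols], H[gj][:, cols], arch)
    liab = lg + rng.normal(0, np.sqrt(arch.residual_var_liability), n)
    prev = float((liab > arch.liability_threshold).mean())
    assert abs(prev - arch.prevalence) <= 0.02


def test_single_locus_closed_form_variance_fraction():
    """One additive QTL, a=1, p=0.5, residual 0.5: the QTL's phenotypic
    variance fraction is 2p(1-p)a² / (2p(1-p)a² + 0.5) = 0.5."""
    rec = QTLRecord("q", 1, 1_000_000, ACTION_ADDITIVE, additive_effect=1.0,
                    allele_freq=0.5, true_var_pct_additive=100.0)
    arch = QTLArchitecture(records=[rec])
    arch.residual_var_qt = 0.5
    arch.calibrated = True
    loci = LocusMap(chrom=np.array([1]), pos=np.array([1_000_000]),
                    is_snp=np.array([False]), ids=np.array(["q"], object))
    pool = HaplotypeSet(ids=np.array([1, 2]),
                        paternal=np.array([[0], [1]], np.uint8),
                        maternal=np.array([[0], [1]], np.uint8), loci=loci)
    dec = variance_decomposition(arch, pool, n_mc=60_000, rng_seed=4)
    frac = dec[(dec.kind == "qtl") & (dec.unit == "q")]["pct_phenotypic"].iloc[0]
    assert frac == pytest.approx(50.0, abs=1.5)


def test_variance_decomposition_component_accounting(default_run):
    """Disjoint component fractions account for (at most) the genetic
    variance, and the epistatic pair rows match the published shares."""
    dec = variance_decomposition(default_run.architecture, default_run.founder_sim.pool,
                                 n_mc=20_000, rng_seed=1)
    comp = dec[dec.kind == "component"].set_index("unit")["pct_phenotypic"]
    parts = comp[["additive", "epistatic", "imprinting"]].sum()
    assert parts <= comp["genetic_total"] * 1.05 + 2.0
    assert comp["genetic_total"] == pytest.approx(50.0, abs=3.0)


def test_variance_decomposition_input_validation(default_run):
    with pytest.raises(ValueError, match="n_mc"):
        variance_decomposition(default_run.architecture, default_run.founder_sim.pool,
                               n_mc=10, rng_seed=0)


def test_uncalibrated_frequencies_rejected():
    rec = QTLRecord("q", 1, 1_000_000, ACTION_ADDITIVE, additive_effect=1.0)
    arch = QTLArchitecture(records=[rec])
    haps = _haps([[1]], [[0]], LocusMap(np.array([1]), np.array([1_000_000]),
                                        np.array([False]), np.array(["q"], object)))
    with pytest.raises(ValueError, match="frequencies"):
        genetic_value_qt(haps, arch)
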