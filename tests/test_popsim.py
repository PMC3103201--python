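import numpy as np
import pytest

from qtlbench.genome import GenomeLayout, build_locus_map, default_layout
from qtlbench.pedigree import PedigreeDesign, generate_pedigree
from qtlbench.popsim import (
    BurnInConfig,
    HaplotypeSet,
    adjacent_r2,
    gene_drop,
    meiosis,
    simulate_founder_haplotypes,
)


# ------------------------------------------------------------ founder burn-in

def test_ld_profile_matches_textbook_formula(small_founder_sim):
    """Every reported adjacent r² equals D²/(p1 q1 p2 q2) recomputed directly
    from the raw haplotype matrix."""
    fs = small_founder_sim
    H = fs.pool.haplotype_pool().astype(float)
    loci = fs.loci
    for ci, c in enumerate(np.unique(loci.chrom)):
        sel = (loci.chrom == c) & loci.is_snp
        Hc = H[:, sel]
        for j in range(Hc.shape[1] - 1):
            x, y = Hc[:, j], Hc[:, j + 1]
            p1, p2 = x.mean(), y.mean()
            D = (x * y).mean() - p1 * p2
            expected = D * D / (p1 * (1 - p1) * p2 * (1 - p2))
            assert fs.ld.per_chromosome[ci][j] == pytest.approx(expected, abs=1e-12)


def test_zero_burnin_gives_independent_loci():
    """With 0 burn-in generations and fixed frequency 0.5, adjacent r² sits
    at the finite-sample noise floor (~1/2N)."""
    layout = default_layout(n_chromosomes=2, chrom_length=50_000_000, n_snps=400, rng_seed=1)
    cfg = BurnInConfig(pop_size=100, n_generations=0, init_freq_range=(0.5, 0.5))
    fs = simulate_founder_haplotypes(layout, cfg, rng_seed=2)
    assert fs.ld.mean_adjacent_r2 < 0.03


def test_default_burnin_hits_ld_target(default_runs):
    """Calibrated burn-in: mean adjacent r² within [0.07, 0.13] for each of
    three seeds at the default genome scale."""
    for run in default_runs.values():
        assert 0.07 <= run.summary["mean_adjacent_r2"] <= 0.13


def test_no_monomorphic_loci(small_founder_sim):
    freq = small_founder_sim.pool.haplotype_pool().mean(axis=0)
    assert np.all((freq > 0) & (freq < 1))


def test_founder_sim_determinism():
    layout = default_layout(n_chromosomes=2, chrom_length=20_000_000, n_snps=100, rng_seed=0)
    cfg = BurnInConfig(pop_size=30, n_generations=10)
    a = simulate_founder_haplotypes(layout, cfg, rng_seed=7)
    b = simulate_founder_haplotypes(layout, cfg, rng_seed=7)
    assert np.array_equal(a.pool.haplotype_pool(), b.pool.haplotype_pool())
    assert np.array_equal(a.founders.paternal, b.founders.paternal)


def test_burnin_config_validation():
    with pytest.raises(ValueError):
        BurnInConfig(pop_size=1)
    with pytest.raises(ValueError):
        BurnInConfig(init_freq_range=(0.0, 0.9))


# ------------------------------------------------------------------- meiosis

def _tiny_layout(cm_per_mb=1.0):
    return default_layout(n_chromosomes=1, chrom_length=100_000_000, n_snps=20,
                          cm_per_mb=cm_per_mb, rng_seed=0)


def test_meiosis_zero_map_returns_one_parent_haplotype():
    layout = _tiny_layout(cm_per_mb=0.0)
    loci = build_locus_map(layout)
    rng = np.random.default_rng(0)
    pat = np.zeros(20, dtype=np.uint8)
    mat = np.ones(20, dtype=np.uint8)
    picks = set()
    for _ in range(20):
        g = meiosis(pat, mat, loci, layout, rng)
        assert np.array_equal(g, pat) or np.array_equal(g, mat)
        picks.add(int(g[0]))
    assert picks == {0, 1}  # both parents get picked


def test_meiosis_crossover_count_is_poisson_with_map_length():
    """100 Mb at 1 cM/Mb = 1 Morgan: the mean number of template switches
    over many gametes is 1.0 (within 3 standard errors)."""
    layout = default_layout(n_chromosomes=1, chrom_length=100_000_000, n_snps=1000, rng_seed=0)
    loci = build_locus_map(layout)
    rng = np.random.default_rng(123)
    pat = np.zeros(1000, dtype=np.uint8)
    mat = np.ones(1000, dtype=np.uint8)
    n = 10_000
    switches = 0
    for _ in range(n):
        g = meiosis(pat, mat, loci, layout, rng)
        switches += int(np.sum(np.abs(np.diff(g.astype(int)))))
    mean = switches / n
    se = np.sqrt(1.0 / n)  # Poisson(1) variance = 1
    # observable switches slightly undercount crossovers (those between the
    # same tracked loci cancel); with 1000 loci the loss is tiny
    assert abs(mean - 1.0) < 3 * se + 0.02


def test_meiosis_homozygous_parent_invariance():
    layout = _tiny_layout()
    loci = build_locus_map(layout)
    rng = np.random.default_rng(5)
    hap = np.array([0, 1] * 10, dtype=np.uint8)
    for _ in range(5):
        assert np.array_equal(meiosis(hap, hap.copy(), loci, layout, rng), hap)


# ----------------------------------------------------------------- gene drop

def _two_founder_set(loci):
    # founder 1 homozygous 0, founder 2 homozygous 1
    L = loci.n_loci
    return HaplotypeSet(
        ids=np.array([1, 2]),
        paternal=np.vstack([np.zeros(L, np.uint8), np.ones(L, np.uint8)]),
        maternal=np.vstack([np.zeros(L, np.uint8), np.ones(L, np.uint8)]),
        loci=loci,
    )


def test_gene_drop_forced_heterozygosity():
    """Offspring of homozygous-opposite parents is heterozygous everywhere
    with known parental origin."""
    from qtlbench.pedigree import Pedigree

    layout = _tiny_layout()
    loci = build_locus_map(layout)
    founders = _two_founder_set(loci)
    ped = Pedigree(id=[1, 2, 3], sire=[0, 0, 1], dam=[0, 0, 2],
                   sex=[1, 2, 1], generation=[0, 0, 1])
    haps = gene_drop(ped, founders, layout, rng_seed=0)
    off = haps.row_of(3)
    assert np.all(haps.paternal[off] == 0)   # sire is homozygous 0
    assert np.all(haps.maternal[off] == 1)   # dam is homozygous 1
    assert np.all(haps.dosage()[off] == 1)


def test_gene_drop_determinism(small_founder_sim):
    layout = default_layout(n_chromosomes=2, chrom_length=50_000_000, n_snps=200, rng_seed=3)
    design = PedigreeDesign(n_sires_per_gen=2, n_dams_per_gen=4, progeny_per_dam=5,
                            n_generations=2, target_phenotyped=None)
    ped = generate_pedigree(design, rng_seed=1)
    a = gene_drop(ped, small_founder_sim.founders, layout, rng_seed=42)
    b = gene_drop(ped, small_founder_sim.founders, layout, rng_seed=42)
    assert np.array_equal(a.paternal, b.paternal)
    assert np.array_equal(a.maternal, b.maternal)


def _mendel_ok(haps, ped):
    row = {int(i): k for k, i in enumerate(haps.ids)}
    for k in range(ped.n_individuals):
        s, d = int(ped.sire[k]), int(ped.dam[k])
        if s == 0:
            continue
        i, si, di = row[int(ped.id[k])], row[s], row[d]
        if not np.all((haps.paternal[i] == haps.paternal[si])
                      | (haps.paternal[i] == haps.maternal[si])):
            return False
        if not np.all((haps.maternal[i] == haps.paternal[di])
                      | (haps.maternal[i] == haps.maternal[di])):
            return False
    return True


def test_gene_drop_mendelian_consistency(small_founder_sim):
    """Exhaustive trio check: every transmitted allele exists in the
    corresponding parent at that locus."""
    layout = default_layout(n_chromosomes=2, chrom_length=50_000_000, n_snps=200, rng_seed=3)
    design = PedigreeDesign(n_sires_per_gen=3, n_dams_per_gen=6, progeny_per_dam=8,
                            n_generations=3, target_phenotyped=None)
    ped = generate_pedigree(design, rng_seed=8)
    haps = gene_drop(ped, small_founder_sim.founders, layout, rng_seed=17)
    assert _mendel_ok(haps, ped)


def test_gene_drop_missing_parent_haplotypes():
    from qtlbench.pedigree import Pedigree

    layout = _tiny_layout()
    loci = build_locus_map(layout)
    founders = _two_founder_set(loci)  # covers ids 1, 2 only
    ped = Pedigree(id=[1, 2, 4, 5], sire=[0, 0, 0, 1], dam=[0, 0, 0, 4],
                   sex=[1, 2, 2, 1], generation=[0, 0, 0, 1])
    with pytest.raises(KeyError):
        gene_drop(ped, founders, layout, rng_seed=0)


def test_allele_frequency_drift_is_moderate(default_run):
    """Founder vs generation-4 allele frequencies drift with the magnitude
    expected for the family sizes (loose band on the standardised change)."""
    haps = default_run.haplotypes
    ped = default_run.pedigree
    f_rows = np.isin(haps.ids, ped.id[ped.generation == 0])
    l_rows = np.isin(haps.ids, ped.id[ped.generation == ped.generation.max()])
    pool_f = np.concatenate([haps.paternal[f_rows], haps.maternal[f_rows]]).mean(axis=0)
    pool_l = np.concatenate([haps.paternal[l_rows], haps.maternal[l_rows]]).mean(axis=0)
    keep = (pool_f > 0.05) & (pool_f < 0.95)
    z2 = (pool_l[keep] - pool_f[keep]) ** 2 / (pool_f[keep] * (1 - pool_f[keep]))
    ratio = float(np.mean(z2))
    # ~4 generations through bottlenecked parent sets: expect a few percent
    # of p(1-p) of cumulative drift, far from 0 and far from fixation
    assert 0.005 < ratio < 0.5
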