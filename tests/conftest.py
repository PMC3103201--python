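import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qtlbench.pipeline import RunConfig, run_simulation
from qtlbench.scan import additive_scan, imprinting_scan, permutation_threshold

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SIM_SEEDS = (1, 2, 3)  # seed 1 is the package default


@pytest.fixture(scope="session")
def default_runs():
    """Full-scale default simulations for three seeds (shared by the LD,
    drift, scan-power and bookkeeping tests)."""
    return {seed: run_simulation(RunConfig(seed=seed)) for seed in SIM_SEEDS}


@pytest.fixture(scope="session")
def default_run(default_runs):
    """The default-configuration dataset (master seed = RunConfig default)."""
    return default_runs[RunConfig().seed]


@pytest.fixture(scope="session")
def default_scans(default_runs):
    """Additive and imprinting scans (QT phenotype, phenotyped individuals)
    plus permutation thresholds, per seed."""
    out = {}
    for seed, run in default_runs.items():
        haps, pheno, loci = run.haplotypes, run.phenotypes, run.haplotypes.loci
        rows = np.isin(haps.ids, pheno["id"].to_numpy())
        snp = loci.snp_indices
        dosage = haps.dosage()[rows][:, snp]
        paternal = haps.paternal[rows][:, snp]
        y = pheno["qt"].to_numpy()
        out[seed] = {
            "additive": additive_scan(dosage, y, loci=loci),
            "imprinting": imprinting_scan(paternal, y, loci=loci),
            "thr_additive": permutation_threshold(
                dosage, y, model="additive", n_perm=100, alpha=0.05, rng_seed=0),
            "thr_imprinting": permutation_threshold(
                paternal, y, model="imprinting_maternal", n_perm=100, alpha=0.05, rng_seed=0),
        }
    return out


@pytest.fixture(scope="session")
def small_founder_sim():
    """A small founder simulation for LD-formula and repair tests."""
    from qtlbench.genome import default_layout
    from qtlbench.popsim import BurnInConfig, simulate_founder_haplotypes

    layout = default_layout(n_chromosomes=2, chrom_length=50_000_000, n_snps=200, rng_seed=3)
    cfg = BurnInConfig(pop_size=50, n_generations=20)
    return simulate_founder_haplotypes(layout, cfg, rng_seed=5)
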