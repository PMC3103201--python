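"""End-to-end simulation runs and directory-level evaluation.

A run is a pure function of (config, seed): the master seed is expanded into
independent per-stage child seeds (layout jitter, architecture, burn-in,
pedigree, gene drop, phenotypes) so each stage is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io_formats as io
from .architecture import (
    QTLArchitecture,
    build_default_architecture,
    calibrate_architecture,
    imprinted_pairwise_r2,
    snp_window_counts,
)
from .evaluation import EvaluationReport, evaluate
from .genome import (
    DEFAULT_CHROM_LENGTH,
    DEFAULT_CM_PER_MB,
    DEFAULT_N_CHROMOSOMES,
    DEFAULT_N_SNPS,
    GenomeLayout,
    default_layout,
)
from .pedigree import DEFAULT_TARGET_PHENOTYPED, PedigreeDesign, generate_pedigree
from .popsim import (
    DEFAULT_BURNIN_GENERATIONS,
    DEFAULT_BURNIN_POP_SIZE,
    DEFAULT_MAP_INFLATION,
    BurnInConfig,
    FounderSim,
    HaplotypeSet,
    gene_drop,
    simulate_founder_haplotypes,
)
from .traits import genetic_value_qt, simulate_phenotypes

log = logging.getLogger("qtlbench.pipeline")

SNP_WINDOW_RANGE = (19, 47)  # required SNPs within 1 Mb of every QTL
_MAX_LAYOUT_TRIES = 5


@dataclass
class RunConfig:
    """Everything a simulation run needs besides the master seed."""

    seed: int = 1
    scale: float = 1.0
    # genome
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES
    chrom_length: int = DEFAULT_CHROM_LENGTH
    n_snps: int = DEFAULT_N_SNPS
    cm_per_mb: float = DEFAULT_CM_PER_MB
    # pedigree
    n_sires_per_gen: int = 5
    n_dams_per_gen: int = 15
    progeny_per_dam: int = 30
    n_generations: int = 4
    target_phenotyped: Optional[int] = DEFAULT_TARGET_PHENOTYPED
    # burn-in
    burnin_pop_size: int = DEFAULT_BURNIN_POP_SIZE
    burnin_generations: int = DEFAULT_BURNIN_GENERATIONS
    burnin_map_inflation: float = DEFAULT_MAP_INFLATION
    # traits
    h2_qt: float = 0.5
    h2_binary: float = 0.5
    prevalence: float = 0.5
    residual_corr: float = 0.0
    imprint_share_phenotypic: float = 0.06
    # exports
    write_haplotypes: bool = False

    def scaled(self) -> "RunConfig":
        """Apply the --scale factor (marker count and population size)."""
        if self.scale == 1.0:
            return self
        c = dataclasses.replace(self)
        c.n_snps = max(self.n_chromosomes, int(round(self.n_snps * self.scale)))
        if self.scale < 1.0:
            # shrink the parent sets too, or small litters cannot supply the
            # next generation's dams
            c.n_sires_per_gen = max(2, int(round(self.n_sires_per_gen * self.scale)))
            c.n_dams_per_gen = max(4, int(round(self.n_dams_per_gen * self.scale)))
        if self.target_phenotyped is not None:
            c.target_phenotyped = max(
                self.n_generations * c.n_dams_per_gen,
                int(round(self.target_phenotyped * self.scale)),
            )
        return c

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError(f"{path}: config must set a seed")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def stage_seeds(master_seed: int, n: int = 6) -> List[int]:
    """Expand one master seed into independent per-stage child seeds."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


@dataclass
class SimulationRun:
    config: RunConfig
    layout: GenomeLayout
    architecture: QTLArchitecture
    founder_sim: FounderSim
    pedigree: "object"
    haplotypes: HaplotypeSet
    phenotypes: pd.DataFrame
    manifest: Optional[io.FileManifest] = None
    summary: dict = field(default_factory=dict)


def _layout_with_window_check(cfg: RunConfig, arch_seed: int, layout_seed: int):
    """Draw the SNP placement; re-jitter if any QTL's ±1 Mb window falls
    outside the required SNP-count range (only enforceable when the marker
    density makes the range attainable at all)."""
    density_expected = 2e6 * cfg.n_snps / (cfg.n_chromosomes * cfg.chrom_length)
    enforce = SNP_WINDOW_RANGE[0] <= density_expected <= SNP_WINDOW_RANGE[1] + 6
    last = None
    for attempt in range(_MAX_LAYOUT_TRIES):
        layout = default_layout(cfg.n_chromosomes, cfg.chrom_length, cfg.n_snps,
                                cfg.cm_per_mb, rng_seed=layout_seed + attempt)
        arch = build_default_architecture(layout, rng_seed=arch_seed)
        counts = snp_window_counts(layout, arch)
        if not enforce or (counts.min() >= SNP_WINDOW_RANGE[0] and counts.max() <= SNP_WINDOW_RANGE[1]):
            return layout, arch
        last = counts
        log.info("layout attempt %d: SNP window counts %d-%d outside %s; re-jittering",
                 attempt + 1, counts.min(), counts.max(), SNP_WINDOW_RANGE)
    raise RuntimeError(f"could not satisfy SNP window counts {SNP_WINDOW_RANGE}; last {last.min()}-{last.max()}")


def run_simulation(cfg: RunConfig, architecture: Optional[QTLArchitecture] = None,
                   layout: Optional[GenomeLayout] = None) -> SimulationRun:
    """Simulate genotypes and phenotypes in memory (no files written)."""
    cfg = cfg.scaled()
    s_layout, s_arch, s_burnin, s_ped, s_drop, s_pheno = stage_seeds(cfg.seed)

    if architecture is not None and layout is not None:
        arch = architecture
    elif architecture is None and layout is None:
        layout, arch = _layout_with_window_check(cfg, s_arch, s_layout)
    else:
        raise ValueError("provide architecture and layout together, or neither")
    arch.h2_qt = cfg.h2_qt
    arch.h2_binary = cfg.h2_binary
    arch.prevalence = cfg.prevalence
    arch.residual_corr = cfg.residual_corr
    arch.imprint_share_phenotypic = cfg.imprint_share_phenotypic

    burnin = BurnInConfig(pop_size=cfg.burnin_pop_size,
                          n_generations=cfg.burnin_generations,
                          map_inflation=cfg.burnin_map_inflation)
    fs = simulate_founder_haplotypes(layout, burnin, rng_seed=s_burnin,
                                     extra_loci=arch.hidden_loci_for_simulation())
    calibrate_architecture(arch, fs.pool, rng_seed=s_arch)

    design = PedigreeDesign(
        n_sires_per_gen=cfg.n_sires_per_gen, n_dams_per_gen=cfg.n_dams_per_gen,
        progeny_per_dam=cfg.progeny_per_dam, n_generations=cfg.n_generations,
        target_phenotyped=cfg.target_phenotyped)
    pedigree = generate_pedigree(design, rng_seed=s_ped)
    haps = gene_drop(pedigree, fs.founders, layout, rng_seed=s_drop)

    values = genetic_value_qt(haps, arch)
    pheno = simulate_phenotypes(values, arch, rng_seed=s_pheno)
    # founders are genotyped but unphenotyped
    pheno = pheno[~np.isin(pheno["id"].to_numpy(), pedigree.id[pedigree.is_founder])]
    pheno = pheno.reset_index(drop=True)

    summary = {
        "n_individuals": int(pedigree.n_individuals),
        "n_phenotyped": int(pedigree.n_phenotyped),
        "n_snps": int(layout.n_snps),
        "mean_adjacent_r2": float(fs.ld.mean_adjacent_r2),
        "imprinted_max_pairwise_r2": float(imprinted_pairwise_r2(arch, fs.pool)),
        "realized_prevalence": float(pheno["binary"].mean()),
        "phenotypic_variance": float(arch.phenotypic_variance),
        "seed": int(cfg.seed),
    }
    log.info("simulated %(n_individuals)d individuals, %(n_snps)d SNPs, "
             "mean adjacent r2=%(mean_adjacent_r2).3f, prevalence=%(realized_prevalence).3f",
             summary)
    return SimulationRun(cfg, layout, arch, fs, pedigree, haps, pheno, summary=summary)


ARTIFACTS = ("genotypes_tsv", "genotypes_ped", "genotypes_map",
             "pedigree_tsv", "phenotypes_tsv", "truth_tsv")


def write_run(run: SimulationRun, outdir) -> io.FileManifest:
    """Write all artifacts and the checksum manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    io.write_dosage_tsv(run.haplotypes, outdir / "genotypes.tsv", outdir / "snps.tsv")
    files["genotypes_tsv"] = ("genotypes.tsv", "dosage_tsv")
    files["snps_tsv"] = ("snps.tsv", "snp_info_tsv")
    io.write_ped_map(run.haplotypes, run.pedigree, outdir / "genotypes", run.phenotypes)
    files["genotypes_ped"] = ("genotypes.ped", "plink_ped")
    files["genotypes_map"] = ("genotypes.map", "plink_map")
    io.write_pedigree(run.pedigree, outdir / "pedigree.tsv")
    files["pedigree_tsv"] = ("pedigree.tsv", "pedigree_tsv")
    io.write_phenotypes(run.phenotypes, outdir / "phenotypes.tsv",
                        outdir / "phenotype_components.tsv")
    files["phenotypes_tsv"] = ("phenotypes.tsv", "phenotype_tsv")
    files["phenotype_components_tsv"] = ("phenotype_components.tsv", "phenotype_truth_tsv")
    io.write_truth(run.architecture, outdir / "truth.tsv", extra_params=run.summary)
    files["truth_tsv"] = ("truth.tsv", "truth_tsv")
    if run.config.write_haplotypes:
        io.write_haplotypes_tsv(run.haplotypes, outdir / "haplotypes.tsv")
        files["haplotypes_tsv"] = ("haplotypes.tsv", "haplotype_truth_tsv")
    run.config.to_yaml(outdir / "config.yaml")
    files["config_yaml"] = ("config.yaml", "run_config_yaml")

    manifest = io.build_manifest(files, base_dir=outdir)
    io.write_manifest(manifest, outdir / "manifest.json")
    run.manifest = manifest
    return manifest


def simulate_to_dir(cfg: RunConfig, outdir) -> SimulationRun:
    run = run_simulation(cfg)
    write_run(run, outdir)
    return run


def evaluate_directory(truth_path, submissions, window_mb: float = 1.0,
                       outdir=None, variance_policy: str = "nearest"):
    """Evaluate every submission file against a truth file.

    Returns (reports, skipped) where skipped lists (path, error message) for
    unparsable submissions.  When ``outdir`` is set, writes the comparison
    table and one JSON report per submission.
    """
    log.info("evaluation defaults: window=%.2f Mb (inclusive), variance policy=%s, "
             "rates rounded half-up to 2 dp at reporting", window_mb, variance_policy)
    params, truth = io.read_truth(truth_path)
    va = params.get("additive_variance")
    sub_paths = sorted(Path(submissions).glob("*.tsv")) \
        if Path(submissions).is_dir() else [Path(submissions)]
    reports: List[EvaluationReport] = []
    skipped = []
    for p in sub_paths:
        try:
            for sub in io.read_submission(p):
                reports.append(evaluate(truth, sub, window_mb=window_mb,
                                        total_additive_variance=va,
                                        variance_policy=variance_policy))
        except Exception as exc:  # noqa: BLE001 - deliberate: skip bad files
            log.error("skipping %s: %s", p, exc)
            skipped.append((str(p), str(exc)))
    if outdir is not None and reports:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_comparison_tsv(reports, outdir / "comparison.tsv")
        for r in reports:
            io.write_report_json(r, outdir / f"report_{r.participant}_{r.trait}.json")
    return reports, skipped
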