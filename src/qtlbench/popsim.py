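"""Forward population simulation.

Two phases:

1. A random-mating historical burn-in that builds linkage disequilibrium by
   drift.  The burn-in uses a population-scaled map (recombination inflated by
   a constant factor), the standard rescaling trick that lets a small
   simulated population reproduce the LD profile of a much larger one: with
   the shipped constants, r² between adjacent SNPs (~50 kb) averages ≈0.1
   while loci a few Mb apart are effectively independent.  Recombination in
   the burn-in is applied as a per-interval Haldane switch process, which is
   exactly the Poisson-crossover model marginalized onto the locus grid.

2. A gene drop through the benchmark pedigree, with explicit Poisson
   crossover counts and uniform crossover positions (no interference),
   tracking parental origin of every allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genome import GenomeLayout, LocusMap, build_locus_map
from .pedigree import Pedigree

# Shipped burn-in calibration (see docs/methods.md).  The number of burn-in
# generations was calibrated once so that mean adjacent-SNP r² ≈ 0.1 under the
# default genome layout; it is not re-fit per run.
DEFAULT_BURNIN_POP_SIZE = 200
DEFAULT_BURNIN_GENERATIONS = 90
DEFAULT_MAP_INFLATION = 15.0


@dataclass(frozen=True)
class BurnInConfig:
    """Historical random-mating population used to generate founder LD."""

    pop_size: int = DEFAULT_BURNIN_POP_SIZE          # diploid individuals
    n_generations: int = DEFAULT_BURNIN_GENERATIONS
    map_inflation: float = DEFAULT_MAP_INFLATION     # burn-in-only cM multiplier
    init_freq_range: tuple = (0.1, 0.9)
    max_resample_rounds: int = 50

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        lo, hi = self.init_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("init_freq_range must satisfy 0 < lo <= hi < 1")


@dataclass
class HaplotypeSet:
    """Ordered haplotypes for a set of individuals over a locus map.

    ``paternal[i, l]`` / ``maternal[i, l]`` are 0/1 alleles; for pedigree
    founders the labels are arbitrary but consistent.  The unordered dosage
    (paternal + maternal) is what genotype exports contain; ordered data only
    leaves the package through the truth channel.
    """

    ids: np.ndarray
    paternal: np.ndarray
    maternal: np.ndarray
    loci: LocusMap

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.paternal = np.asarray(self.paternal, dtype=np.uint8)
        self.maternal = np.asarray(self.maternal, dtype=np.uint8)
        n, L = self.paternal.shape
        if self.maternal.shape != (n, L) or self.ids.size != n or self.loci.n_loci != L:
            raise ValueError("inconsistent HaplotypeSet shapes")

    @property
    def n_individuals(self) -> int:
        return self.ids.size

    def dosage(self) -> np.ndarray:
        return (self.paternal.astype(np.int16) + self.maternal).astype(np.uint8)

    def haplotype_pool(self) -> np.ndarray:
        """All haplotypes stacked, shape (2n, L)."""
        return np.concatenate([self.paternal, self.maternal], axis=0)

    def subset_loci(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx)
        sub = LocusMap(self.loci.chrom[idx], self.loci.pos[idx],
                       self.loci.is_snp[idx], self.loci.ids[idx])
        return HaplotypeSet(self.ids, self.paternal[:, idx], self.maternal[:, idx], sub)

    def row_of(self, iid: int) -> int:
        hit = np.flatnonzero(self.ids == iid)
        if hit.size == 0:
            raise KeyError(f"individual {iid} not in HaplotypeSet")
        return int(hit[0])


@dataclass
class LDProfile:
    """Adjacent-SNP r² per chromosome, computed from raw haplotypes."""

    per_chromosome: list  # list of float arrays (one value per adjacent SNP pair)

    @property
    def mean_adjacent_r2(self) -> float:
        allv = np.concatenate([v for v in self.per_chromosome if v.size]) \
            if any(v.size for v in self.per_chromosome) else np.array([])
        return float(np.mean(allv)) if allv.size else float("nan")


def adjacent_r2(haplotypes: np.ndarray, loci: LocusMap, snps_only: bool = True) -> LDProfile:
    """r² = D² / (p1 q1 p2 q2) for every adjacent pair, per chromosome."""
    H = haplotypes.astype(np.float64)
    per_chrom = []
    for c in np.unique(loci.chrom):
        sel = loci.chrom == c
        if snps_only:
            sel &= loci.is_snp
        Hc = H[:, sel]
        if Hc.shape[1] < 2:
            per_chrom.append(np.array([]))
            continue
        p = Hc.mean(axis=0)
        x1, x2 = Hc[:, :-1], Hc[:, 1:]
        D = (x1 * x2).mean(axis=0) - p[:-1] * p[1:]
        denom = p[:-1] * (1 - p[:-1]) * p[1:] * (1 - p[1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(denom > 0, D * D / denom, np.nan)
        per_chrom.append(r2)
    return LDProfile(per_chrom)


def pairwise_r2(haplotypes: np.ndarray, i: int, j: int) -> float:
    """r² between two locus columns of a haplotype matrix."""
    x, y = haplotypes[:, i].astype(float), haplotypes[:, j].astype(float)
    px, py = x.mean(), y.mean()
    denom = px * (1 - px) * py * (1 - py)
    if denom == 0:
        return float("nan")
    D = (x * y).mean() - px * py
    return float(D * D / denom)


@dataclass
class FounderSim:
    """Output of the founder burn-in."""

    founders: HaplotypeSet        # the pedigree founders (sampled individuals)
    ld: LDProfile                 # adjacent-SNP r² of the final burn-in generation
    pool: HaplotypeSet            # full final burn-in generation (reference population)
    loci: LocusMap


def _interval_switch_probs(loci: LocusMap, layout: GenomeLayout, inflation: float) -> np.ndarray:
    """Haldane switch probability per locus interval; 0.5 at chromosome starts."""
    r = np.full(loci.n_loci, 0.5)
    d = np.diff(loci.pos).astype(np.float64)
    same = np.diff(loci.chrom) == 0
    morg = layout.morgans(d[same]) * inflation
    r[1:][same] = 0.5 * (1.0 - np.exp(-2.0 * morg))
    return r


def simulate_founder_haplotypes(
    layout: GenomeLayout,
    burnin: BurnInConfig,
    rng_seed: int,
    extra_loci=None,
    n_founders: int = 20,
) -> FounderSim:
    """Run the historical burn-in and sample the pedigree founders.

    Tracks per-locus founder ancestry so that loci that drift to fixation can
    be repaired by redrawing the initial alleles on the same genealogy (which
    preserves the LD structure).  Raises if the requested number of
    polymorphic loci cannot be reached within ``max_resample_rounds``.
    """
    rng = np.random.default_rng(rng_seed)
    loci = build_locus_map(layout, extra_loci)
    L = loci.n_loci
    N = burnin.pop_size
    H = 2 * N
    if n_founders > N:
        raise ValueError("cannot sample more founders than the burn-in population size")

    r = _interval_switch_probs(loci, layout, burnin.map_inflation)

    # ancestry matrix: which initial haplotype each final allele descends from
    anc = np.broadcast_to(np.arange(H, dtype=np.int32)[:, None], (H, L)).copy()
    for _ in range(burnin.n_generations):
        parents = rng.integers(0, N, size=H)  # parent of each gamete
        switches = rng.random((H, L)) < r[None, :]
        state = np.cumsum(switches, axis=1, dtype=np.int32) & 1
        anc = np.where(state == 1, anc[2 * parents + 1], anc[2 * parents])

    lo, hi = burnin.init_freq_range
    p0 = rng.uniform(lo, hi, size=L)
    init = (rng.random((H, L)) < p0[None, :]).astype(np.uint8)
    cols = np.arange(L)
    alleles = init[anc, cols[None, :]]

    freq = alleles.mean(axis=0)
    mono = (freq == 0) | (freq == 1)
    # a fully coalesced locus (all alleles identical by descent) cannot be
    # repaired by redrawing founder alleles: rescue it with a recurrent
    # mutation in the final generation instead (such loci are rare — usually
    # none — and carry no LD with their neighbours)
    stuck = mono & (anc.min(axis=0) == anc.max(axis=0))
    for l in np.flatnonzero(stuck):
        p_new = rng.uniform(lo, hi)
        carriers = rng.random(H) < p_new
        if not carriers.any():
            carriers[rng.integers(0, H)] = True
        if carriers.all():
            carriers[rng.integers(0, H)] = False
        alleles[:, l] = np.where(carriers, 1 - alleles[0, l], alleles[0, l])
        mono[l] = False
    rounds = 0
    while mono.any():
        if rounds >= burnin.max_resample_rounds:
            raise RuntimeError(
                f"{int(mono.sum())} loci still monomorphic after "
                f"{burnin.max_resample_rounds} resampling rounds"
            )
        idx = np.flatnonzero(mono)
        p_new = rng.uniform(lo, hi, size=idx.size)
        init[:, idx] = rng.random((H, idx.size)) < p_new[None, :]
        alleles[:, idx] = init[anc[:, idx], idx[None, :]]
        f = alleles[:, idx].mean(axis=0)
        mono = np.zeros(L, dtype=bool)
        mono[idx] = (f == 0) | (f == 1)
        rounds += 1

    pool = HaplotypeSet(np.arange(1, N + 1), alleles[0::2], alleles[1::2], loci)
    ld = adjacent_r2(alleles, loci, snps_only=True)

    pick = rng.choice(N, size=n_founders, replace=False)
    founders = HaplotypeSet(
        np.arange(1, n_founders + 1),
        alleles[2 * pick], alleles[2 * pick + 1], loci,
    )
    return FounderSim(founders=founders, ld=ld, pool=pool, loci=loci)


def meiosis(
    paternal: np.ndarray,
    maternal: np.ndarray,
    loci: LocusMap,
    layout: GenomeLayout,
    rng: np.random.Generator,
    return_origin: bool = False,
):
    """One gamete from a parent's haplotype pair.

    Crossover count per chromosome is Poisson with mean equal to the
    chromosome's genetic length in Morgans (no interference); crossover
    positions are uniform on the physical map (constant cM/Mb).
    """
    gamete = np.empty(loci.n_loci, dtype=np.uint8)
    origin = np.empty(loci.n_loci, dtype=np.uint8) if return_origin else None
    morg = layout.chrom_morgans
    for c in np.unique(loci.chrom):
        sl = loci.chrom_slice(int(c))
        pos = loci.pos[sl]
        k = rng.poisson(morg) if morg > 0 else 0
        cross = np.sort(rng.uniform(0, layout.chrom_length, size=k)) if k else np.empty(0)
        start = int(rng.integers(0, 2))
        parity = (start + np.searchsorted(cross, pos)) & 1
        gamete[sl] = np.where(parity == 0, paternal[sl], maternal[sl])
        if return_origin:
            origin[sl] = parity
    if return_origin:
        return gamete, origin
    return gamete


def gene_drop(
    pedigree: Pedigree,
    founders: HaplotypeSet,
    layout: GenomeLayout,
    rng_seed: int,
) -> HaplotypeSet:
    """Drop founder haplotypes through the pedigree.

    Every non-founder's paternal haplotype is a recombinant of its sire's
    pair, the maternal one of its dam's pair.  Deterministic given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    loci = founders.loci
    n, L = pedigree.n_individuals, loci.n_loci
    pat = np.zeros((n, L), dtype=np.uint8)
    mat = np.zeros((n, L), dtype=np.uint8)
    row = {}
    filled = np.zeros(n, dtype=bool)

    for i in range(n):
        iid = int(pedigree.id[i])
        s, d = int(pedigree.sire[i]), int(pedigree.dam[i])
        if s == 0:
            fr = founders.row_of(iid)
            pat[i] = founders.paternal[fr]
            mat[i] = founders.maternal[fr]
        else:
            if s not in row or d not in row:
                raise ValueError(f"individual {iid}: parent haplotypes missing (cycle or bad order)")
            si, di = row[s], row[d]
            if not (filled[si] and filled[di]):
                raise ValueError(f"individual {iid}: parent haplotypes not yet simulated")
            pat[i] = meiosis(pat[si], mat[si], loci, layout, rng)
            mat[i] = meiosis(pat[di], mat[di], loci, layout, rng)
        row[iid] = i
        filled[i] = True

    return HaplotypeSet(pedigree.id.copy(), pat, mat, loci)
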