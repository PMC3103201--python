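"""Genome layout and locus bookkeeping.

The simulated genome is a set of autosomes with biallelic SNPs at fixed
physical positions plus optional hidden (non-genotyped) causal loci.  All
positions are 1-based base pairs; genetic distances use a constant cM/Mb
scaling (Haldane map, no interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_CHROMOSOMES = 5
DEFAULT_CHROM_LENGTH = 100_000_000
DEFAULT_N_SNPS = 10_031
DEFAULT_CM_PER_MB = 1.0


@dataclass(frozen=True)
class GenomeLayout:
    """Physical map: SNP positions per chromosome, all chromosomes equal length.

    snp_positions : tuple of int arrays, one per chromosome, strictly
        increasing, values in [1, chrom_length].
    """

    snp_positions: tuple
    chrom_length: int = DEFAULT_CHROM_LENGTH
    cm_per_mb: float = DEFAULT_CM_PER_MB

    def __post_init__(self):
        if len(self.snp_positions) == 0:
            raise ValueError("layout needs at least one chromosome")
        frozen = []
        for c, pos in enumerate(self.snp_positions, start=1):
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size == 0:
                raise ValueError(f"chromosome {c} has no SNPs")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"chromosome {c}: SNP positions not strictly increasing")
            if pos[0] < 1 or pos[-1] > self.chrom_length:
                raise ValueError(f"chromosome {c}: SNP positions outside [1, {self.chrom_length}]")
            frozen.append(pos)
        object.__setattr__(self, "snp_positions", tuple(frozen))

    @property
    def n_chromosomes(self) -> int:
        return len(self.snp_positions)

    @property
    def n_snps(self) -> int:
        return int(sum(p.size for p in self.snp_positions))

    def morgans(self, bp: float) -> float:
        """Genetic length of a physical span, in Morgans."""
        return bp / 1e6 * self.cm_per_mb / 100.0

    @property
    def chrom_morgans(self) -> float:
        return self.morgans(self.chrom_length)


def default_layout(
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    n_snps: int = DEFAULT_N_SNPS,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
    rng_seed: int = 0,
) -> GenomeLayout:
    """Build a layout with jittered-grid SNP placement.

    SNPs sit on a near-regular grid (one per ``chrom_length / m`` window,
    uniform jitter of ±35% of the spacing), which keeps local SNP density
    nearly constant: every 2-Mb window around a causal locus then holds a
    stable number of markers, as expected of a commercial genotyping panel.
    """
    if n_snps < n_chromosomes:
        raise ValueError("need at least one SNP per chromosome")
    rng = np.random.default_rng(rng_seed)
    base = n_snps // n_chromosomes
    counts = [base + (1 if c < n_snps % n_chromosomes else 0) for c in range(n_chromosomes)]
    chroms = []
    for m in counts:
        spacing = chrom_length / m
        centers = (np.arange(m) + 0.5) * spacing
        jitter = rng.uniform(-0.35, 0.35, size=m) * spacing
        pos = np.clip(np.round(centers + jitter).astype(np.int64), 1, chrom_length)
        # jitter < half spacing, so order is preserved; guard against rounding ties
        for i in range(1, m):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        chroms.append(pos)
    return GenomeLayout(tuple(chroms), chrom_length=chrom_length, cm_per_mb=cm_per_mb)


@dataclass
class LocusMap:
    """All simulated loci (genotyped SNPs + hidden causal sites), genome order."""

    chrom: np.ndarray  # int, 1-based chromosome index
    pos: np.ndarray    # int, 1-based bp
    is_snp: np.ndarray  # bool: True for exported/genotyped SNPs
    ids: np.ndarray     # str locus identifiers

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.is_snp = np.asarray(self.is_snp, dtype=bool)
        self.ids = np.asarray(self.ids, dtype=object)

    @property
    def n_loci(self) -> int:
        return self.chrom.size

    @property
    def snp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_snp)

    def chrom_slice(self, c: int) -> slice:
        idx = np.flatnonzero(self.chrom == c)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def index_of(self, chrom: int, pos: int) -> int:
        hit = np.flatnonzero((self.chrom == chrom) & (self.pos == pos))
        if hit.size == 0:
            raise KeyError(f"no locus at chr{chrom}:{pos}")
        return int(hit[0])


def build_locus_map(layout: GenomeLayout, extra_loci=None) -> LocusMap:
    """Merge layout SNPs with hidden causal sites into one sorted locus map.

    extra_loci : iterable of (chrom, pos_bp, locus_id).  A site that coincides
    with an existing SNP is not duplicated (the SNP itself is the causal
    locus — an "observed" QTL).
    """
    chroms, poss, is_snp, ids = [], [], [], []
    extra = sorted(extra_loci or [], key=lambda t: (t[0], t[1]))
    snp_counter = 0
    for c, snp_pos in enumerate(layout.snp_positions, start=1):
        snp_set = set(int(p) for p in snp_pos)
        here = [(p, lid) for (cc, p, lid) in extra if cc == c and int(p) not in snp_set]
        for (cc, p, lid) in extra:
            if cc == c and (p < 1 or p > layout.chrom_length):
                raise ValueError(f"extra locus {lid} outside chromosome {c}")
        merged = [(int(p), f"snp{c}_{i}", True) for i, p in enumerate(snp_pos, start=1)]
        merged += [(int(p), str(lid), False) for p, lid in here]
        merged.sort(key=lambda t: (t[0], not t[2]))
        for p, lid, snp in merged:
            chroms.append(c)
            poss.append(p)
            is_snp.append(snp)
            ids.append(lid)
            if snp:
                snp_counter += 1
    return LocusMap(np.array(chroms), np.array(poss), np.array(is_snp), np.array(ids, dtype=object))
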