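"""QTL architecture: truth definition and calibration against founder LD.

The default architecture carries 37 causal loci for the quantitative trait:

- 30 additive QTL on chromosomes 1-4 — two major ones on chromosome 3 (22.4 Mb
  and 71.6 Mb, the latter being an observed/genotyped SNP), intermediate
  effects on chromosomes 1-2, many small effects on chromosome 4 (including
  26.7 Mb and 97.7 Mb);
- 2 epistatic pairs (chr1, ~1.1 Mb apart; chr2, ~0.5 Mb apart) parameterised
  as a product of centred dosages, which has zero marginal additive effects
  under linkage equilibrium at founder allele frequencies;
- 3 maternally imprinted QTL on chromosome 2 (one anchored at 78.6 Mb), each
  with a paternal-allele effect of 3.00 (the maternal copy is silenced);
  mutually independent (pairwise r² < 0.008 in the founder population).

Chromosome 5 carries no QTL.  A binary trait shares 22 of the 30 additive QTL
through a liability threshold; epistatic and imprinted loci never touch it.

Effect sizes are expressed on a scale fixed by design: the three imprinted
QTL jointly contribute 6% of the phenotypic variance (their effect is pinned
at 3.00), the epistatic pairs contribute 7% and 4.2%, and the additive
variance fills the remainder of the genetic variance implied by the trait
heritability.  Calibration is exact (closed-form on the founder haplotype
pool), not fitted by iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout
from .popsim import HaplotypeSet, pairwise_r2

ACTION_ADDITIVE = "additive"
ACTION_EPISTATIC = "epistatic_member"
ACTION_IMPRINTED = "imprinted_maternal"

MB = 1_000_000

# default placements (Mb), chromosome-length fraction of a 100-Mb chromosome
_CHR1_ADDITIVE = [5.3, 17.8, 29.4, 41.2, 52.7, 68.9, 81.3, 93.6]
_CHR2_ADDITIVE = [6.1, 14.9, 24.8, 39.5, 47.2, 63.8, 86.4, 95.2]
_CHR3_MAJORS = [22.4, 71.6]          # 71.6 is an observed SNP
_CHR4_SMALL = [3.5, 11.2, 19.8, 26.7, 35.4, 44.1, 53.9, 62.6, 72.3, 81.7, 90.5, 97.7]
_CHR1_EPISTATIC = [60.0, 61.1]       # ~1.1 Mb apart
_CHR2_EPISTATIC = [33.0, 33.5]       # ~0.5 Mb apart
_CHR2_IMPRINTED = [55.0, 71.5, 78.6]  # 78.6 anchored
# alternate placements for the two non-anchored imprinted QTL, used when the
# realized founder LD between the defaults exceeds the independence bound
_CHR2_IMPRINTED_ALTERNATES = [44.1, 51.8, 59.3, 67.4, 75.2, 83.9]

IMPRINTED_INDEPENDENCE_R2 = 0.008
IMPRINT_EFFECT = 3.0

# additive variance split across chromosome classes (% of additive variance)
_MAJOR_SHARES = (20.0, 16.0)
_INTERMEDIATE_TOTAL = 51.2   # 16 loci on chr1-2
_SMALL_TOTAL = 12.8          # 12 loci on chr4


@dataclass
class QTLRecord:
    qtl_id: str
    chrom: int
    position_bp: int
    action: str
    partner_id: Optional[str] = None
    affects_qt: bool = True
    affects_binary: bool = False
    additive_effect: float = 0.0
    interaction_coeff: float = 0.0
    imprint_effect: float = 0.0
    allele_freq: float = float("nan")
    true_var_pct_additive: float = float("nan")
    true_var_pct_phenotypic: float = float("nan")
    is_observed_snp: bool = False

    def validate(self):
        if self.action not in (ACTION_ADDITIVE, ACTION_EPISTATIC, ACTION_IMPRINTED):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action in (ACTION_EPISTATIC, ACTION_IMPRINTED) and self.affects_binary:
            raise ValueError(f"{self.qtl_id}: only additive QTL may affect the binary trait")
        if self.action == ACTION_EPISTATIC and self.partner_id is None:
            raise ValueError(f"{self.qtl_id}: epistatic member needs a partner")


@dataclass
class QTLArchitecture:
    records: List[QTLRecord]
    h2_qt: float = 0.5
    h2_binary: float = 0.5
    prevalence: float = 0.5
    residual_corr: float = 0.0
    imprint_share_phenotypic: float = 0.06
    # filled at calibration
    phenotypic_variance: float = float("nan")
    genetic_variance: float = float("nan")
    additive_variance: float = float("nan")
    residual_var_qt: float = float("nan")
    residual_var_liability: float = float("nan")
    liability_threshold: float = float("nan")
    calibrated: bool = False
    imprinted_alternates: List[int] = field(default_factory=list)  # bp on chr2

    def __post_init__(self):
        for h in (self.h2_qt, self.h2_binary):
            if not (0 < h < 1):
                raise ValueError("heritability must lie in (0, 1)")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        for r in self.records:
            r.validate()
        for r in self.records:
            if r.action == ACTION_EPISTATIC:
                partner = self.record(r.partner_id)
                if partner.chrom != r.chrom:
                    raise ValueError(f"epistatic pair {r.qtl_id}/{r.partner_id} spans chromosomes")

    def record(self, qtl_id: str) -> QTLRecord:
        for r in self.records:
            if r.qtl_id == qtl_id:
                return r
        raise KeyError(qtl_id)

    def by_action(self, action: str) -> List[QTLRecord]:
        return [r for r in self.records if r.action == action]

    @property
    def qt_records(self) -> List[QTLRecord]:
        return [r for r in self.records if r.affects_qt]

    @property
    def binary_records(self) -> List[QTLRecord]:
        return [r for r in self.records if r.affects_binary]

    def epistatic_pairs(self):
        """Unique (member, partner) record pairs, ordered by qtl_id."""
        pairs = []
        for r in self.by_action(ACTION_EPISTATIC):
            if r.qtl_id < r.partner_id:
                pairs.append((r, self.record(r.partner_id)))
        return pairs

    def hidden_loci_for_simulation(self):
        """(chrom, pos, id) of every locus the founder simulation must carry:
        all non-observed QTL plus alternate imprinted placements."""
        out = [(r.chrom, r.position_bp, r.qtl_id) for r in self.records if not r.is_observed_snp]
        out += [(2, int(p), f"imp_alt{k}") for k, p in enumerate(self.imprinted_alternates, 1)]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def _scaled(mb: float, layout: GenomeLayout) -> int:
    """Map a position quoted on a 100-Mb chromosome to this layout's length."""
    return max(1, int(round(mb * MB * layout.chrom_length / (100 * MB))))


def _avoid_snps(pos: int, snp_pos: np.ndarray, chrom_length: int) -> int:
    """Hidden QTL must not collide with a genotyped SNP position."""
    p = pos
    while np.any(snp_pos == p):
        p = p + 1 if p < chrom_length else p - 1
    return p


def _draw_shares(rng: np.random.Generator):
    """Per-QTL percentages of additive variance: 2 major, 16 intermediate,
    12 small; gamma-jittered magnitudes, class totals fixed."""
    for _ in range(100):
        major = np.array(_MAJOR_SHARES) * rng.gamma(30.0, 1.0 / 30.0, size=2)
        major *= sum(_MAJOR_SHARES) / major.sum()
        inter = rng.gamma(8.0, 1.0, size=16)
        inter *= _INTERMEDIATE_TOTAL / inter.sum()
        small = rng.gamma(8.0, 1.0, size=12)
        small *= _SMALL_TOTAL / small.sum()
        if major.min() > inter.max() and inter.mean() > small.mean():
            return major, inter, small
    raise RuntimeError("could not draw additive variance shares with the required ordering")


def build_default_architecture(layout: GenomeLayout, rng_seed: int) -> QTLArchitecture:
    """Default 37-QTL architecture on the given layout.

    Positions are the shipped defaults (scaled to the layout's chromosome
    length); effect magnitudes are drawn from the seed.  Effects are
    provisional (allele frequencies 0.5) until
    :func:`calibrate_architecture` fixes them against a founder population.
    """
    if layout.n_chromosomes < 4:
        raise ValueError("default architecture needs at least 4 chromosomes")
    rng = np.random.default_rng(rng_seed)
    major, inter, small = _draw_shares(rng)

    records: List[QTLRecord] = []
    shares = {}

    def add(qtl_id, chrom, mb, share, binary, observed=False):
        pos = _scaled(mb, layout)
        snp_pos = layout.snp_positions[chrom - 1]
        if observed:
            pos = int(snp_pos[np.argmin(np.abs(snp_pos - pos))])
        else:
            pos = _avoid_snps(pos, snp_pos, layout.chrom_length)
        records.append(QTLRecord(
            qtl_id=qtl_id, chrom=chrom, position_bp=pos, action=ACTION_ADDITIVE,
            affects_binary=binary, is_observed_snp=observed,
            true_var_pct_additive=float(share), allele_freq=0.5,
        ))
        shares[qtl_id] = float(share)

    k = 0
    for i, mb in enumerate(_CHR1_ADDITIVE):
        add(f"add_c1_{i+1}", 1, mb, inter[k], binary=True); k += 1
    for i, mb in enumerate(_CHR2_ADDITIVE):
        add(f"add_c2_{i+1}", 2, mb, inter[k], binary=True); k += 1
    add("add_c3_1", 3, _CHR3_MAJORS[0], major[0], binary=True)
    add("add_c3_2", 3, _CHR3_MAJORS[1], major[1], binary=True, observed=True)
    for i, mb in enumerate(_CHR4_SMALL):
        add(f"add_c4_{i+1}", 4, mb, small[i], binary=(i < 4))

    def add_special(qtl_id, chrom, mb, action, partner=None, imprint=0.0):
        pos = _avoid_snps(_scaled(mb, layout), layout.snp_positions[chrom - 1], layout.chrom_length)
        records.append(QTLRecord(
            qtl_id=qtl_id, chrom=chrom, position_bp=pos, action=action,
            partner_id=partner, imprint_effect=imprint,
            true_var_pct_additive=0.0, allele_freq=0.5,
        ))

    add_special("epi_c1_a", 1, _CHR1_EPISTATIC[0], ACTION_EPISTATIC, partner="epi_c1_b")
    add_special("epi_c1_b", 1, _CHR1_EPISTATIC[1], ACTION_EPISTATIC, partner="epi_c1_a")
    add_special("epi_c2_a", 2, _CHR2_EPISTATIC[0], ACTION_EPISTATIC, partner="epi_c2_b")
    add_special("epi_c2_b", 2, _CHR2_EPISTATIC[1], ACTION_EPISTATIC, partner="epi_c2_a")
    for i, mb in enumerate(_CHR2_IMPRINTED):
        add_special(f"imp_c2_{i+1}", 2, mb, ACTION_IMPRINTED, imprint=IMPRINT_EFFECT)

    alternates = [
        _avoid_snps(_scaled(mb, layout), layout.snp_positions[1], layout.chrom_length)
        for mb in _CHR2_IMPRINTED_ALTERNATES
    ]

    # provisional additive effects at p = 0.5 so the truth ordering (chr3
    # majors largest) holds even before calibration
    for r in records:
        if r.action == ACTION_ADDITIVE:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            r.additive_effect = sign * float(np.sqrt(shares[r.qtl_id] / 100.0 / 0.5))

    arch = QTLArchitecture(records=records, imprinted_alternates=alternates)
    _check_chromosome5(arch, layout)
    return arch


def _check_chromosome5(arch: QTLArchitecture, layout: GenomeLayout):
    if layout.n_chromosomes >= 5 and any(r.chrom == 5 for r in arch.records):
        raise ValueError("chromosome 5 must stay QTL-free")


def snp_window_counts(layout: GenomeLayout, arch: QTLArchitecture, window_mb: float = 1.0) -> np.ndarray:
    """Number of genotyped SNPs within ±window of each QTL."""
    w = int(window_mb * MB)
    counts = []
    for r in arch.records:
        snp_pos = layout.snp_positions[r.chrom - 1]
        lo = np.searchsorted(snp_pos, r.position_bp - w, side="left")
        hi = np.searchsorted(snp_pos, r.position_bp + w, side="right")
        counts.append(hi - lo)
    return np.asarray(counts)


def _qtl_columns(arch: QTLArchitecture, haps: HaplotypeSet) -> np.ndarray:
    return np.array([haps.loci.index_of(r.chrom, r.position_bp) for r in arch.records])


def imprinted_pairwise_r2(arch: QTLArchitecture, haps: HaplotypeSet) -> float:
    """Largest pairwise r² among the imprinted QTL in the given population."""
    pool = haps.haplotype_pool()
    idx = [haps.loci.index_of(r.chrom, r.position_bp) for r in arch.by_action(ACTION_IMPRINTED)]
    worst = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            worst = max(worst, pairwise_r2(pool, idx[a], idx[b]))
    return worst


def _select_independent_imprinted(arch: QTLArchitecture, haps: HaplotypeSet):
    """If the default imprinted placements violate the independence bound,
    move the two non-anchored ones to alternate placements (chosen to
    minimise the worst pairwise r²)."""
    if imprinted_pairwise_r2(arch, haps) < IMPRINTED_INDEPENDENCE_R2:
        return
    pool = haps.haplotype_pool()
    imprinted = arch.by_action(ACTION_IMPRINTED)
    anchored = imprinted[-1]  # the 78.6 Mb record
    movable = imprinted[:-1]
    candidates = [r.position_bp for r in movable] + list(arch.imprinted_alternates)
    candidates = [p for p in candidates
                  if any(haps.loci.chrom[i] == 2 and haps.loci.pos[i] == p
                         for i in range(haps.loci.n_loci))]
    anchor_idx = haps.loci.index_of(anchored.chrom, anchored.position_bp)
    best, best_worst = None, np.inf
    for a in range(len(candidates)):
        for b in range(a + 1, len(candidates)):
            ia = haps.loci.index_of(2, candidates[a])
            ib = haps.loci.index_of(2, candidates[b])
            worst = max(pairwise_r2(pool, ia, ib),
                        pairwise_r2(pool, ia, anchor_idx),
                        pairwise_r2(pool, ib, anchor_idx))
            if worst < best_worst:
                best, best_worst = (candidates[a], candidates[b]), worst
    if best_worst >= IMPRINTED_INDEPENDENCE_R2:
        raise RuntimeError(
            f"no imprinted placement with pairwise r² < {IMPRINTED_INDEPENDENCE_R2} "
            f"found (best {best_worst:.4f})"
        )
    movable[0].position_bp, movable[1].position_bp = sorted(best)


def calibrate_architecture(
    arch: QTLArchitecture,
    founder_population: HaplotypeSet,
    rng_seed: int = 0,
) -> QTLArchitecture:
    """Fix effect sizes against the founder haplotype pool (in place).

    The reference genotype distribution is a random union of two gametes
    drawn from the pool, so all moments are computed exactly by enumerating
    ordered haplotype pairs.  Solves, in closed form:

    - the phenotypic variance VP from the pinned imprinted effects and the
      design share (imprinting = ``imprint_share_phenotypic`` of VP),
    - the interaction coefficients from the 7% / 4.2% pair shares of VP,
    - the additive scale from VG = h² VP.
    """
    haps = founder_population
    _select_independent_imprinted(arch, haps)

    pool = haps.haplotype_pool().astype(np.float64)
    cols = _qtl_columns(arch, haps)
    Hq = pool[:, cols]                      # (2N, n_qtl) haplotype alleles
    p = Hq.mean(axis=0)
    for r, pk in zip(arch.records, p):
        if pk <= 0 or pk >= 1:
            raise RuntimeError(f"QTL {r.qtl_id} is monomorphic in the founder pool")
        r.allele_freq = float(pk)

    idx = {r.qtl_id: k for k, r in enumerate(arch.records)}
    add = [r for r in arch.records if r.action == ACTION_ADDITIVE]
    imp = arch.by_action(ACTION_IMPRINTED)
    pairs = arch.epistatic_pairs()

    # unit-scale additive effects from the target variance shares
    a_unit = np.zeros(len(arch.records))
    for r in add:
        k = idx[r.qtl_id]
        share = r.true_var_pct_additive / 100.0
        sign = np.sign(r.additive_effect) or 1.0
        a_unit[k] = sign * np.sqrt(share / (2.0 * p[k] * (1 - p[k])))

    centred = Hq - p                        # per-haplotype centred alleles
    s_add = centred @ a_unit                # additive half-score per haplotype
    bin_mask = np.array([r.affects_binary for r in arch.records], dtype=float)
    s_bin = centred @ (a_unit * bin_mask)
    i_vec = np.zeros(len(arch.records))
    for r in imp:
        i_vec[idx[r.qtl_id]] = r.imprint_effect
    v_imp = centred @ i_vec                 # imprinting score of a paternal haplotype

    # exact moments under ordered-pair sampling (paternal i, maternal j)
    n = pool.shape[0]
    gi, gj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    gi, gj = gi.ravel(), gj.ravel()
    A_u = s_add[gi] + s_add[gj]
    Lg_u = s_bin[gi] + s_bin[gj]
    I = v_imp[gi]
    C_u = []
    for (ra, rb) in pairs:
        ka, kb = idx[ra.qtl_id], idx[rb.qtl_id]
        c1 = centred[gi, ka] + centred[gj, ka]
        c2 = centred[gi, kb] + centred[gj, kb]
        C_u.append(c1 * c2)

    VI = float(np.var(I))
    if VI <= 0:
        raise RuntimeError("imprinting variance is zero; cannot set the trait scale")
    VP = VI / arch.imprint_share_phenotypic
    VG = arch.h2_qt * VP

    pair_shares = (0.07, 0.042)
    e = []
    for share, Cu in zip(pair_shares, C_u):
        vc = float(np.var(Cu))
        if vc <= 0:
            raise RuntimeError("epistatic interaction variance is zero in the founder pool")
        e.append(np.sqrt(share * VP / vc))
    R = I + sum(ek * Cu for ek, Cu in zip(e, C_u))
    va, vr = float(np.var(A_u)), float(np.var(R))
    if not add:
        # no additive loci: the genetic variance is whatever the fixed
        # non-additive shares produce; the requested h² is overridden
        scale = 0.0
        VG = vr
        arch.h2_qt = VG / VP
    else:
        # solve s² Var(A) + 2 s Cov(A, R) + Var(R) = VG for the additive scale s
        cov = float(np.mean(A_u * R) - np.mean(A_u) * np.mean(R))
        disc = cov * cov - va * (vr - VG)
        if disc <= 0 or va <= 0:
            raise RuntimeError("heritability and component shares are incompatible "
                               "(non-additive components already exceed VG)")
        scale = (-cov + np.sqrt(disc)) / va
        if scale <= 0:
            raise RuntimeError("additive scale came out non-positive")

    for r in add:
        k = idx[r.qtl_id]
        r.additive_effect = float(scale * a_unit[k])
    for (share, (ra, rb), ek) in zip(pair_shares, pairs, e):
        ra.interaction_coeff = rb.interaction_coeff = float(ek)
        ra.true_var_pct_phenotypic = rb.true_var_pct_phenotypic = 100.0 * share
        ra.true_var_pct_additive = rb.true_var_pct_additive = 0.0

    G = scale * A_u + R
    VA = float(np.var(scale * A_u))
    arch.phenotypic_variance = VP
    arch.genetic_variance = float(np.var(G))   # equals VG by construction
    arch.additive_variance = VA
    arch.residual_var_qt = VP - arch.genetic_variance
    for r in add:
        k = idx[r.qtl_id]
        marg = r.additive_effect ** 2 * 2 * p[k] * (1 - p[k])
        r.true_var_pct_additive = 100.0 * marg / VA
        r.true_var_pct_phenotypic = 100.0 * marg / VP
    for r in imp:
        k = idx[r.qtl_id]
        marg = r.imprint_effect ** 2 * p[k] * (1 - p[k])
        r.true_var_pct_additive = 0.0
        r.true_var_pct_phenotypic = 100.0 * marg / VP

    VLg = float(np.var(scale * Lg_u))
    arch.residual_var_liability = VLg * (1 - arch.h2_binary) / arch.h2_binary
    sd_l = np.sqrt(VLg + arch.residual_var_liability)
    arch.liability_threshold = float(stats.norm.ppf(1 - arch.prevalence) * sd_l)
    arch.calibrated = True
    return arch
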