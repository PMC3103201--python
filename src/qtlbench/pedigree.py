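"""Pedigree design and generation.

The benchmark population descends from a small founder group (5 sires, 15
dams by default) through discrete generations.  Every dam is mated exactly
once; sires may serve several dams.  All non-founders are phenotyped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

MALE = 1
FEMALE = 2

DEFAULT_TARGET_PHENOTYPED = 2326


@dataclass(frozen=True)
class PedigreeDesign:
    n_sires_per_gen: int = 5
    n_dams_per_gen: int = 15
    progeny_per_dam: int = 30
    n_generations: int = 4
    # When set, per-litter sizes are derived so the number of non-founders
    # matches exactly (litters of ~39); when None, every litter has
    # progeny_per_dam offspring.
    target_phenotyped: Optional[int] = DEFAULT_TARGET_PHENOTYPED

    def __post_init__(self):
        for f in ("n_sires_per_gen", "n_dams_per_gen", "progeny_per_dam", "n_generations"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        if self.target_phenotyped is not None and self.target_phenotyped < self.n_generations * self.n_dams_per_gen:
            raise ValueError("target_phenotyped smaller than one offspring per litter")


@dataclass
class Pedigree:
    """Columnar pedigree; parents always precede offspring in record order."""

    id: np.ndarray          # int, 1-based
    sire: np.ndarray        # int, 0 = unknown (founder)
    dam: np.ndarray         # int, 0 = unknown
    sex: np.ndarray         # 1 male, 2 female
    generation: np.ndarray  # 0 = founder

    def __post_init__(self):
        for f in ("id", "sire", "dam", "sex", "generation"):
            setattr(self, f, np.asarray(getattr(self, f), dtype=np.int64))
        self.validate()

    @property
    def n_individuals(self) -> int:
        return self.id.size

    @property
    def is_founder(self) -> np.ndarray:
        return self.generation == 0

    @property
    def n_phenotyped(self) -> int:
        """Phenotyped individuals = all non-founders."""
        return int(np.sum(~self.is_founder))

    def validate(self):
        seen = {}
        for i in range(self.n_individuals):
            iid, s, d = int(self.id[i]), int(self.sire[i]), int(self.dam[i])
            if iid in seen:
                raise ValueError(f"duplicate id {iid}")
            if (s == 0) != (d == 0):
                raise ValueError(f"id {iid}: exactly one parent unknown")
            if s != 0:
                if s not in seen or d not in seen:
                    raise ValueError(f"id {iid}: parent precedes offspring violated")
                if self.sex[seen[s]] != MALE:
                    raise ValueError(f"id {iid}: sire {s} is not male")
                if self.sex[seen[d]] != FEMALE:
                    raise ValueError(f"id {iid}: dam {d} is not female")
            seen[iid] = i
        # each dam mated once: all offspring of a dam share the same sire
        mate = {}
        for i in range(self.n_individuals):
            d = int(self.dam[i])
            if d == 0:
                continue
            s = int(self.sire[i])
            if d in mate and mate[d] != s:
                raise ValueError(f"dam {d} mated to more than one sire")
            mate[d] = s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.id, "sire": self.sire, "dam": self.dam,
             "sex": self.sex, "generation": self.generation}
        )


def _litter_sizes(design: PedigreeDesign, rng: np.random.Generator) -> np.ndarray:
    """Per-litter offspring counts, shape (n_generations, n_dams_per_gen)."""
    g, d = design.n_generations, design.n_dams_per_gen
    if design.target_phenotyped is None:
        return np.full((g, d), design.progeny_per_dam, dtype=np.int64)
    total = design.target_phenotyped
    base = total // (g * d)
    sizes = np.full(g * d, base, dtype=np.int64)
    sizes[: total - base * g * d] += 1
    return sizes.reshape(g, d)


def generate_pedigree(design: PedigreeDesign, rng_seed: int) -> Pedigree:
    """Generate the benchmark pedigree.

    Generation-g parents are sampled from generation g-1 (founders for g=1).
    Raises if a generation does not contain enough candidate parents of the
    required sex.
    """
    rng = np.random.default_rng(rng_seed)
    litters = _litter_sizes(design, rng)

    ids, sires, dams, sexes, gens = [], [], [], [], []
    next_id = 1

    founders_m, founders_f = [], []
    for _ in range(design.n_sires_per_gen):
        ids.append(next_id); sires.append(0); dams.append(0)
        sexes.append(MALE); gens.append(0)
        founders_m.append(next_id); next_id += 1
    for _ in range(design.n_dams_per_gen):
        ids.append(next_id); sires.append(0); dams.append(0)
        sexes.append(FEMALE); gens.append(0)
        founders_f.append(next_id); next_id += 1

    prev_m, prev_f = founders_m, founders_f
    for g in range(1, design.n_generations + 1):
        if len(prev_m) < design.n_sires_per_gen:
            raise ValueError(
                f"generation {g}: only {len(prev_m)} candidate sires available, "
                f"{design.n_sires_per_gen} required"
            )
        if len(prev_f) < design.n_dams_per_gen:
            raise ValueError(
                f"generation {g}: only {len(prev_f)} candidate dams available, "
                f"{design.n_dams_per_gen} required"
            )
        gen_sires = list(rng.choice(prev_m, size=design.n_sires_per_gen, replace=False))
        gen_dams = list(rng.choice(prev_f, size=design.n_dams_per_gen, replace=False))
        # spread dams evenly over sires, randomized assignment
        order = rng.permutation(design.n_dams_per_gen)
        cur_m, cur_f = [], []
        for k, dam_idx in enumerate(order):
            dam_id = gen_dams[dam_idx]
            sire_id = gen_sires[k % design.n_sires_per_gen]
            n_off = int(litters[g - 1, dam_idx])
            off_sex = rng.integers(0, 2, size=n_off)  # 0 male, 1 female
            for s in off_sex:
                ids.append(next_id); sires.append(sire_id); dams.append(dam_id)
                sexes.append(FEMALE if s else MALE); gens.append(g)
                (cur_f if s else cur_m).append(next_id)
                next_id += 1
        prev_m, prev_f = cur_m, cur_f

    return Pedigree(np.array(ids), np.array(sires), np.array(dams),
                    np.array(sexes), np.array(gens))
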