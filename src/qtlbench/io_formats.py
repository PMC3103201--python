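"""Readers and writers for every on-disk artifact.

All formats are plain text, tab-separated unless noted.  Positions on disk
are integer 1-based bp; Mb only ever appears in reports.  Writers are
deterministic: stable ordering, rates and distances formatted to 2 decimals,
positions as integers.  Unordered genotype exports (dosage TSV, .ped/.map)
never leak phase; ordered haplotypes leave only through the truth channel.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .architecture import QTLArchitecture, QTLRecord
from .evaluation import EvaluationReport, Submission, VARIANCE_SCALES
from .genome import GenomeLayout, LocusMap
from .pedigree import Pedigree
from .popsim import HaplotypeSet

log = logging.getLogger("qtlbench.io")

MISSING_PARENT = 0  # PLINK convention


def _round2(v: float) -> str:
    return str(Decimal(repr(float(v))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------- genotypes

def write_dosage_tsv(haps: HaplotypeSet, path, snp_info_path=None):
    """Unordered dosage matrix: one row per individual, one column per SNP."""
    snp = haps.loci.snp_indices
    dosage = haps.dosage()[:, snp]
    ids = haps.loci.ids[snp]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(str(s) for s in ids) + "\n")
        for i in range(haps.n_individuals):
            fh.write(str(int(haps.ids[i])) + "\t" + "\t".join(map(str, dosage[i])) + "\n")
    if snp_info_path is not None:
        info = pd.DataFrame({"snp_id": ids, "chrom": haps.loci.chrom[snp],
                             "pos_bp": haps.loci.pos[snp]})
        info.to_csv(snp_info_path, sep="\t", index=False)


def read_dosage_tsv(path, layout: Optional[GenomeLayout] = None):
    """Returns (ids, snp_ids, dosage uint8 matrix). Malformed values raise
    with the offending line and field named."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ValueError(f"{path}: first header column must be 'id'")
        snp_ids = np.array(header[1:], dtype=object)
        ids, rows = [], []
        for ln, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(snp_ids) + 1:
                raise ValueError(f"{path}:{ln}: expected {len(snp_ids)+1} fields, got {len(fields)}")
            ids.append(int(fields[0]))
            row = np.empty(len(snp_ids), dtype=np.uint8)
            for j, v in enumerate(fields[1:]):
                if v not in ("0", "1", "2"):
                    raise ValueError(f"{path}:{ln}: field {j+2}: dosage must be 0/1/2, got {v!r}")
                row[j] = int(v)
            rows.append(row)
    return np.array(ids), snp_ids, np.vstack(rows) if rows else np.empty((0, len(snp_ids)), np.uint8)


def write_ped_map(haps: HaplotypeSet, pedigree: Pedigree, prefix,
                  phenotype: Optional[pd.DataFrame] = None):
    """PLINK-style .ped/.map pair with alleles coded 1/2.

    Heterozygotes are written with alleles in a fixed (1 2) order regardless
    of parental origin, so the files carry no phase information.
    """
    prefix = str(prefix)
    snp = haps.loci.snp_indices
    dosage = haps.dosage()[:, snp]
    cm = haps.loci.pos[snp] / 1e6  # 1 cM/Mb default map for the .map file
    with open(prefix + ".map", "w") as fh:
        for k, li in enumerate(snp):
            fh.write(f"{haps.loci.chrom[li]}\t{haps.loci.ids[li]}\t{cm[k]:.4f}\t{haps.loci.pos[li]}\n")
    ped_row = {int(pedigree.id[i]): i for i in range(pedigree.n_individuals)}
    qt = {}
    if phenotype is not None:
        qt = dict(zip(phenotype["id"].astype(int), phenotype["qt"]))
    geno_str = {0: "1 1", 1: "1 2", 2: "2 2"}
    with open(prefix + ".ped", "w") as fh:
        for i in range(haps.n_individuals):
            iid = int(haps.ids[i])
            pi = ped_row.get(iid)
            sire = int(pedigree.sire[pi]) if pi is not None else MISSING_PARENT
            dam = int(pedigree.dam[pi]) if pi is not None else MISSING_PARENT
            sex = int(pedigree.sex[pi]) if pi is not None else 0
            ph = f"{qt[iid]:.6g}" if iid in qt else "-9"
            alleles = " ".join(geno_str[int(d)] for d in dosage[i])
            fh.write(f"1\t{iid}\t{sire}\t{dam}\t{sex}\t{ph}\t{alleles}\n")


def read_ped_map(prefix):
    """Returns (ids, dosage matrix, map DataFrame, ped DataFrame).

    Dosage is the count of allele '2'; allele order within a genotype is
    ignored (no phase is assumed).
    """
    prefix = str(prefix)
    map_rows = []
    with open(prefix + ".map") as fh:
        for ln, line in enumerate(fh, start=1):
            f = line.split()
            if len(f) != 4:
                raise ValueError(f"{prefix}.map:{ln}: expected 4 fields, got {len(f)}")
            map_rows.append((int(f[0]), f[1], float(f[2]), int(f[3])))
    map_df = pd.DataFrame(map_rows, columns=["chrom", "snp_id", "cm", "pos_bp"])
    n_snps = len(map_df)
    ids, rows, ped_rows = [], [], []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, start=1):
            f = line.split()
            if len(f) != 6 + 2 * n_snps:
                raise ValueError(f"{prefix}.ped:{ln}: expected {6 + 2*n_snps} fields, got {len(f)}")
            ids.append(int(f[1]))
            ped_rows.append((f[0], int(f[1]), int(f[2]), int(f[3]), int(f[4]), f[5]))
            alleles = f[6:]
            row = np.empty(n_snps, dtype=np.uint8)
            for j in range(n_snps):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                for v in (a, b):
                    if v not in ("1", "2"):
                        raise ValueError(f"{prefix}.ped:{ln}: SNP {j+1}: allele must be 1/2, got {v!r}")
                row[j] = (a == "2") + (b == "2")
            rows.append(row)
    ped_df = pd.DataFrame(ped_rows, columns=["fam", "id", "sire", "dam", "sex", "phenotype"])
    return (np.array(ids), np.vstack(rows) if rows else np.empty((0, n_snps), np.uint8),
            map_df, ped_df)


def write_haplotypes_tsv(haps: HaplotypeSet, path):
    """Ordered (phased) genotypes — truth channel only.  One row per
    individual; per locus two columns <locus>_P and <locus>_M."""
    with open(path, "w") as fh:
        cols = []
        for lid in haps.loci.ids:
            cols += [f"{lid}_P", f"{lid}_M"]
        fh.write("id\t" + "\t".join(cols) + "\n")
        for i in range(haps.n_individuals):
            inter = np.empty(2 * haps.loci.n_loci, dtype=np.uint8)
            inter[0::2] = haps.paternal[i]
            inter[1::2] = haps.maternal[i]
            fh.write(str(int(haps.ids[i])) + "\t" + "\t".join(map(str, inter)) + "\n")


def read_haplotypes_tsv(path):
    """Returns (ids, locus_ids, paternal, maternal)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        locus_ids = [c[:-2] for c in header[0::2]]
        ids, pats, mats = [], [], []
        for ln, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != 1 + 2 * len(locus_ids):
                raise ValueError(f"{path}:{ln}: wrong field count")
            ids.append(int(f[0]))
            vals = np.array(f[1:], dtype=np.uint8)
            pats.append(vals[0::2])
            mats.append(vals[1::2])
    return np.array(ids), np.array(locus_ids, dtype=object), np.vstack(pats), np.vstack(mats)


# ----------------------------------------------------------------- pedigree

def write_pedigree(pedigree: Pedigree, path):
    """5-column TSV (id, sire, dam, sex, generation); 0 = unknown parent."""
    pedigree.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t")
    required = ["id", "sire", "dam", "sex", "generation"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pedigree columns {missing}")
    return Pedigree(df["id"].to_numpy(), df["sire"].to_numpy(), df["dam"].to_numpy(),
                    df["sex"].to_numpy(), df["generation"].to_numpy())


# --------------------------------------------------------------- phenotypes

def write_phenotypes(pheno: pd.DataFrame, path, components_path=None):
    """Public phenotype file (id, qt, binary); truth-only columns (liability
    and genetic components) go to a separate file."""
    pub = pheno[["id", "qt", "binary"]].copy()
    pub["qt"] = pub["qt"].map(lambda v: f"{v:.6f}")
    pub.to_csv(path, sep="\t", index=False)
    if components_path is not None:
        comp_cols = ["id", "liability", "additive", "epistatic", "imprinting", "genetic_total"]
        comp = pheno[[c for c in comp_cols if c in pheno.columns]]
        comp.to_csv(components_path, sep="\t", index=False, float_format="%.6f")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for c in ("id", "qt"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing phenotype column {c!r}")
    return df


# -------------------------------------------------------------------- truth

_TRUTH_COLUMNS = [
    "qtl_id", "chrom", "position_bp", "action", "partner_id", "affects_qt",
    "affects_binary", "additive_effect", "interaction_coeff", "imprint_effect",
    "allele_freq", "true_var_pct_additive", "true_var_pct_phenotypic",
    "is_observed_snp",
]


def write_truth(arch: QTLArchitecture, path, extra_params: Optional[dict] = None):
    """Truth table: '#key=value' header block with trait-level parameters,
    then one TSV row per QTL."""
    params = {
        "h2_qt": arch.h2_qt,
        "h2_binary": arch.h2_binary,
        "prevalence": arch.prevalence,
        "residual_corr": arch.residual_corr,
        "imprint_share_phenotypic": arch.imprint_share_phenotypic,
        "phenotypic_variance": arch.phenotypic_variance,
        "genetic_variance": arch.genetic_variance,
        "additive_variance": arch.additive_variance,
        "residual_var_qt": arch.residual_var_qt,
        "residual_var_liability": arch.residual_var_liability,
        "liability_threshold": arch.liability_threshold,
    }
    params.update(extra_params or {})
    df = arch.to_frame()[_TRUTH_COLUMNS]
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_truth(path):
    """Returns (params dict, truth DataFrame)."""
    params = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            k, _, v = line[1:].rstrip("\n").partition("=")
            try:
                params[k] = float(v)
            except ValueError:
                params[k] = v
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in ("qtl_id", "chrom", "position_bp") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: truth table missing columns {missing}")
    return params, df


def truth_to_architecture(params: dict, df: pd.DataFrame) -> QTLArchitecture:
    """Rebuild a (calibrated) architecture from a truth file."""
    records = []
    for _, r in df.iterrows():
        records.append(QTLRecord(
            qtl_id=str(r["qtl_id"]), chrom=int(r["chrom"]), position_bp=int(r["position_bp"]),
            action=str(r["action"]),
            partner_id=None if pd.isna(r.get("partner_id")) else str(r["partner_id"]),
            affects_qt=bool(r["affects_qt"]), affects_binary=bool(r["affects_binary"]),
            additive_effect=float(r["additive_effect"]),
            interaction_coeff=float(r["interaction_coeff"]),
            imprint_effect=float(r["imprint_effect"]),
            allele_freq=float(r["allele_freq"]),
            true_var_pct_additive=float(r["true_var_pct_additive"]),
            true_var_pct_phenotypic=float(r["true_var_pct_phenotypic"]),
            is_observed_snp=bool(r["is_observed_snp"]),
        ))
    arch = QTLArchitecture(
        records=records,
        h2_qt=float(params.get("h2_qt", 0.5)),
        h2_binary=float(params.get("h2_binary", 0.5)),
        prevalence=float(params.get("prevalence", 0.5)),
        residual_corr=float(params.get("residual_corr", 0.0)),
    )
    for f in ("phenotypic_variance", "genetic_variance", "additive_variance",
              "residual_var_qt", "residual_var_liability", "liability_threshold"):
        if f in params:
            setattr(arch, f, float(params[f]))
    arch.calibrated = True
    return arch


# -------------------------------------------------------------- submissions

_SUBMISSION_REQUIRED = ["participant", "trait", "chrom", "pos_bp"]


def read_submission(path, layout: Optional[GenomeLayout] = None) -> List[Submission]:
    """Parse a submission TSV into one Submission per (participant, trait).

    Unknown columns are ignored with a warning; a missing required column or
    a non-numeric position is an error naming the row.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SUBMISSION_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: submission missing required columns {missing}")
    known = set(_SUBMISSION_REQUIRED) | {"variance", "variance_scale"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        log.warning("%s: ignoring unknown submission columns %s", path, unknown)
        df = df.drop(columns=unknown)
    for i, v in enumerate(df["pos_bp"]):
        try:
            int(v)
        except (TypeError, ValueError):
            raise ValueError(f"{path}: row {i + 1}: position {v!r} is not numeric")
    if "variance_scale" in df.columns:
        bad = set(df["variance_scale"].dropna()) - set(VARIANCE_SCALES)
        if bad:
            raise ValueError(f"{path}: unknown variance_scale values {sorted(bad)}")
    if "variance" not in df.columns:
        log.info("%s: no variance column; variance recovery will be skipped", path)
    if layout is not None:
        for i, (c, p) in enumerate(zip(df["chrom"], df["pos_bp"])):
            if not (1 <= int(c) <= layout.n_chromosomes):
                raise ValueError(f"{path}: row {i + 1}: chromosome {c} outside the layout")
            if not (1 <= int(p) <= layout.chrom_length):
                raise ValueError(f"{path}: row {i + 1}: position {p} exceeds chromosome length")
    subs = []
    for (participant, trait), grp in df.groupby(["participant", "trait"], sort=True):
        subs.append(Submission(participant=str(participant), trait=str(trait),
                               entries=grp.drop(columns=["participant", "trait"])))
    return subs


def write_submission(subs: List[Submission], path):
    frames = []
    for s in subs:
        df = s.entries.copy()
        df.insert(0, "participant", s.participant)
        df.insert(1, "trait", s.trait)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ reports

_COMPARISON_COLUMNS = ["participant", "n_reported", "n_mapped", "mean_distance_mb",
                       "n_false_positives", "success_rate", "error_rate"]


def write_report_json(report: EvaluationReport, path):
    with open(path, "w") as fh:
        json.dump(report.rounded(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_comparison_tsv(reports: List[EvaluationReport], path):
    """Comparison table, one row per submission: participant, reported,
    mapped, mean distance (Mb), false positives, success rate, error rate."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COMPARISON_COLUMNS) + "\n")
        for r in sorted(reports, key=lambda r: (r.trait, r.participant)):
            md = "NA" if r.mean_distance_mb is None else _round2(r.mean_distance_mb)
            fh.write("\t".join([
                r.participant, str(r.n_reported), str(r.n_mapped), md,
                str(r.n_false_positives), _round2(r.success_rate), _round2(r.error_rate),
            ]) + "\n")


def read_comparison_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ----------------------------------------------------------------- manifest

@dataclass
class FileManifest:
    """Paths, format tags and checksums of one simulation run's artifacts."""

    entries: dict  # name -> {"path": str, "format": str, "sha256": str}

    def verify(self, base_dir=None) -> bool:
        for name, e in self.entries.items():
            p = Path(e["path"])
            if base_dir is not None and not p.is_absolute():
                p = Path(base_dir) / p
            if not p.exists():
                raise FileNotFoundError(f"manifest entry {name}: {p} missing")
            if _sha256(p) != e["sha256"]:
                raise ValueError(f"manifest entry {name}: checksum mismatch for {p}")
        return True


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(files: dict, base_dir=None) -> FileManifest:
    """files: name -> (path, format_tag)."""
    entries = {}
    for name, (path, fmt) in files.items():
        p = Path(path)
        full = p if base_dir is None or p.is_absolute() else Path(base_dir) / p
        entries[name] = {"path": str(path), "format": fmt, "sha256": _sha256(full)}
    return FileManifest(entries)


def write_manifest(manifest: FileManifest, path):
    with open(path, "w") as fh:
        json.dump(manifest.entries, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> FileManifest:
    with open(path) as fh:
        return FileManifest(json.load(fh))
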