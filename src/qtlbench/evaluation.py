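"""Scoring submitted QTL positions against the simulated truth.

Mapping rule: a true QTL is mapped iff at least one submitted position on the
same chromosome lies within the matching window (1 Mb by default, inclusive).
One submitted position may map two different QTL; several positions inside
one QTL's window still count that QTL once.  A submitted position is a false
positive iff its distance to every true QTL of the trait exceeds the window.

Metrics: success rate = mapped / total simulated QTL for the trait;
error rate = false positives / reported positions; mean distance = average,
over mapped QTL, of the distance to the nearest submitted position.
Rates are kept at full precision internally and rounded (half-up, 2 dp) only
at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Optional

import numpy as np
import pandas as pd

MB = 1_000_000
TRAITS = ("qt", "binary")
VARIANCE_SCALES = ("absolute", "pct_genetic", "none")


@dataclass
class Submission:
    """One participant's reported positions for one trait."""

    participant: str
    trait: str
    entries: pd.DataFrame  # columns: chrom, pos_bp, variance, variance_scale

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        df = self.entries.copy()
        for col in ("chrom", "pos_bp"):
            if col not in df.columns:
                raise ValueError(f"submission missing column {col!r}")
        if "variance" not in df.columns:
            df["variance"] = np.nan
        if "variance_scale" not in df.columns:
            df["variance_scale"] = "none"
        df["chrom"] = df["chrom"].astype(int)
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        self.entries = df.reset_index(drop=True)

    @property
    def n_reported(self) -> int:
        return len(self.entries)


def truth_for_trait(truth: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Filter a truth table to the QTL affecting one trait."""
    if trait == "qt":
        return truth[truth["affects_qt"].astype(bool)].reset_index(drop=True)
    if trait == "binary":
        return truth[truth["affects_binary"].astype(bool)].reset_index(drop=True)
    raise ValueError(f"unknown trait {trait!r}")


@dataclass
class MatchResult:
    mapped: pd.DataFrame          # qtl_id, chrom, position_bp, distance_mb, nearest_entry
    false_positive_entries: pd.DataFrame
    n_reported: int
    window_mb: float

    @property
    def n_mapped(self) -> int:
        return len(self.mapped)

    @property
    def n_false_positives(self) -> int:
        return len(self.false_positive_entries)


def match_positions(truth: pd.DataFrame, submission: Submission, window_mb: float = 1.0) -> MatchResult:
    """Apply the mapping window rule.

    ``truth`` must already be restricted to the submission's trait (see
    :func:`truth_for_trait`).  Distances are computed in bp and reported in
    Mb; positions on different chromosomes never match.
    """
    entries = submission.entries
    window_bp = window_mb * MB

    mapped_rows = []
    tpos = truth["position_bp"].to_numpy(dtype=np.int64)
    tchrom = truth["chrom"].to_numpy(dtype=int)
    epos = entries["pos_bp"].to_numpy(dtype=np.int64)
    echrom = entries["chrom"].to_numpy(dtype=int)

    entry_is_fp = np.ones(len(entries), dtype=bool)
    for q in range(len(truth)):
        same = echrom == tchrom[q]
        if not same.any():
            continue
        d = np.abs(epos[same] - tpos[q])
        j = int(np.argmin(d))
        if d[j] <= window_bp:
            entry_idx = np.flatnonzero(same)[j]
            mapped_rows.append(
                {
                    "qtl_id": truth["qtl_id"].iloc[q],
                    "chrom": int(tchrom[q]),
                    "position_bp": int(tpos[q]),
                    "distance_mb": float(d[j]) / MB,
                    "nearest_entry": int(entry_idx),
                }
            )
        entry_is_fp[same] &= np.abs(epos[same] - tpos[q]) > window_bp

    mapped = pd.DataFrame(mapped_rows,
                          columns=["qtl_id", "chrom", "position_bp", "distance_mb", "nearest_entry"])
    fps = entries[entry_is_fp].reset_index(drop=True)
    return MatchResult(mapped=mapped, false_positive_entries=fps,
                       n_reported=len(entries), window_mb=window_mb)


def success_rate(n_mapped: int, n_total_simulated: int) -> float:
    if n_total_simulated < 1:
        raise ValueError("n_total_simulated must be >= 1")
    if n_mapped > n_total_simulated:
        raise ValueError("cannot map more QTL than were simulated")
    return n_mapped / n_total_simulated


def error_rate(n_false_positives: int, n_reported: int) -> float:
    if n_reported < 1:
        raise ValueError("error rate undefined for an empty submission")
    if n_false_positives > n_reported:
        raise ValueError("more false positives than reported positions")
    return n_false_positives / n_reported


def mean_distance(match: MatchResult) -> float:
    if match.n_mapped < 1:
        raise ValueError("mean distance undefined: no QTL mapped")
    return float(match.mapped["distance_mb"].mean())


def variance_recovery(
    truth: pd.DataFrame,
    submission: Submission,
    match: MatchResult,
    total_additive_variance: Optional[float] = None,
    policy: str = "nearest",
):
    """Summed true and estimated variance (% of additive variance) over the
    mapped additive QTL.

    Submitted variances on the 'absolute' scale are converted as
    100·v / (true additive variance); 'pct_genetic' is taken as a percentage
    of the additive genetic variance already.  When a QTL is mapped by
    several entries, ``policy`` selects which variance counts
    (nearest | sum | max).
    """
    if policy not in ("nearest", "sum", "max"):
        raise ValueError(f"unknown policy {policy!r}")
    entries = submission.entries
    true_sum, est_sum = 0.0, 0.0
    window_bp = match.window_mb * MB
    truth_add = truth[truth["action"] == "additive"] if "action" in truth.columns else truth
    add_ids = set(truth_add["qtl_id"])
    for _, row in match.mapped.iterrows():
        if row["qtl_id"] not in add_ids:
            continue
        trow = truth_add[truth_add["qtl_id"] == row["qtl_id"]].iloc[0]
        true_sum += float(trow["true_var_pct_additive"])
        same = entries[(entries["chrom"] == row["chrom"])
                       & ((entries["pos_bp"] - row["position_bp"]).abs() <= window_bp)]
        if same.empty:
            continue
        converted = []
        for _, e in same.iterrows():
            v, scale_tag = e["variance"], e["variance_scale"]
            if pd.isna(v) or scale_tag == "none":
                continue
            if scale_tag == "pct_genetic":
                converted.append((abs(e["pos_bp"] - row["position_bp"]), float(v)))
            elif scale_tag == "absolute":
                if total_additive_variance is None:
                    raise ValueError("absolute-scale variances need the true additive variance")
                converted.append((abs(e["pos_bp"] - row["position_bp"]),
                                  100.0 * float(v) / total_additive_variance))
            else:
                raise ValueError(f"unknown variance scale {scale_tag!r}")
        if not converted:
            continue
        if policy == "nearest":
            est_sum += min(converted)[1]
        elif policy == "sum":
            est_sum += sum(v for _, v in converted)
        else:
            est_sum += max(v for _, v in converted)
    return true_sum, est_sum


@dataclass
class EvaluationReport:
    participant: str
    trait: str
    n_reported: int
    n_mapped: int
    n_false_positives: int
    n_total_simulated: int
    success_rate: float
    error_rate: float
    mean_distance_mb: Optional[float]
    variance_recovery_true: Optional[float] = None
    variance_recovery_estimated: Optional[float] = None
    window_mb: float = 1.0

    def rounded(self) -> dict:
        """Reporting-layer view: rates and distances rounded half-up to 2 dp."""
        r2 = lambda v: None if v is None else float(
            Decimal(repr(v)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
        return {
            "participant": self.participant,
            "trait": self.trait,
            "n_reported": self.n_reported,
            "n_mapped": self.n_mapped,
            "mean_distance_mb": r2(self.mean_distance_mb),
            "n_false_positives": self.n_false_positives,
            "success_rate": r2(self.success_rate),
            "error_rate": r2(self.error_rate),
            "variance_recovery_true": r2(self.variance_recovery_true),
            "variance_recovery_estimated": r2(self.variance_recovery_estimated),
        }


def evaluate(
    truth: pd.DataFrame,
    submission: Submission,
    window_mb: float = 1.0,
    total_additive_variance: Optional[float] = None,
    variance_policy: str = "nearest",
) -> EvaluationReport:
    """Full per-submission report.

    ``truth`` is the full truth table; the trait's QTL subset (and hence the
    success-rate denominator — 37 for QT, 22 for the binary trait under the
    default architecture) is taken from it, never hard-coded.
    """
    trait_truth = truth_for_trait(truth, submission.trait)
    if trait_truth.empty:
        raise ValueError(f"truth table has no QTL for trait {submission.trait!r}")
    match = match_positions(trait_truth, submission, window_mb=window_mb)
    has_var = submission.entries["variance"].notna().any()
    vr_true = vr_est = None
    if has_var and submission.trait == "qt":
        vr_true, vr_est = variance_recovery(
            trait_truth, submission, match,
            total_additive_variance=total_additive_variance, policy=variance_policy)
    return EvaluationReport(
        participant=submission.participant,
        trait=submission.trait,
        n_reported=match.n_reported,
        n_mapped=match.n_mapped,
        n_false_positives=match.n_false_positives,
        n_total_simulated=len(trait_truth),
        success_rate=success_rate(match.n_mapped, len(trait_truth)),
        error_rate=error_rate(match.n_false_positives, match.n_reported)
        if match.n_reported else float("nan"),
        mean_distance_mb=mean_distance(match) if match.n_mapped else None,
        variance_recovery_true=vr_true,
        variance_recovery_estimated=vr_est,
        window_mb=window_mb,
    )
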