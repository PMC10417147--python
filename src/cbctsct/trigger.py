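"""Coverage-change monitoring and adaptive plan-review triggering.

A case is flagged for physician/physicist review when the plan-to-evaluation
D99 loss exceeds 3 percentage points on a high-risk CTV or 5 percentage
points on a standard-risk CTV (strict inequalities).  ΔD99 is computed as
plan minus evaluation in percentage points of plan-normalized relative dose,
so positive values are coverage loss.  Cohort summaries compare each
surrogate image (vfCT, corrCBCT, virtCT) against the ground-truth CT and test
paired accuracy differences with the Wilcoxon signed-rank test (significance
at p < 0.05).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field as dfield
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .core_images import StructureRole

log = logging.getLogger("cbctsct")

__all__ = [
    "ImageKind",
    "CoverageRecord",
    "TriggerThresholds",
    "TriggerReport",
    "AccuracySummary",
    "delta_d99",
    "apply_trigger",
    "summarize_cohort",
    "wilcoxon_signed_rank",
]

#: image sets a coverage record can refer to
IMAGE_KINDS = ("PLAN", "GTCT", "VFCT", "CORRCBCT", "VIRTCT")
ImageKind = str

SURROGATES = ("VFCT", "CORRCBCT", "VIRTCT")
_CTV_ROLES = (StructureRole.CTV_HIGH, StructureRole.CTV_STANDARD)


@dataclass(frozen=True)
class CoverageRecord:
    case_id: str
    image_kind: ImageKind
    role: StructureRole
    d99: float  # relative %, plan-normalized

    def __post_init__(self) -> None:
        if self.image_kind not in IMAGE_KINDS:
            raise ValueError(f"unknown image kind '{self.image_kind}'")
        if self.d99 < 0:
            raise ValueError("D99 must be non-negative")


@dataclass(frozen=True)
class TriggerThresholds:
    """Review thresholds in percentage points of D99 loss (strict >)."""

    high: float = 3.0
    standard: float = 5.0

    def for_role(self, role: StructureRole) -> float:
        if role == StructureRole.CTV_HIGH:
            return self.high
        if role == StructureRole.CTV_STANDARD:
            return self.standard
        raise ValueError(f"no trigger threshold for role {role}")


@dataclass
class TriggerReport:
    case_id: str
    deltas: Dict[StructureRole, float]
    triggered: Dict[StructureRole, bool]
    review: bool
    thresholds: TriggerThresholds

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "deltas": {r.value: d for r, d in self.deltas.items()},
            "triggered": {r.value: bool(t) for r, t in self.triggered.items()},
            "review": bool(self.review),
            "thresholds": {"high": self.thresholds.high, "standard": self.thresholds.standard},
        }


def delta_d99(plan: CoverageRecord, evaluation: CoverageRecord) -> float:
    """Plan-minus-evaluation D99 in percentage points; positive = loss."""
    if plan.case_id != evaluation.case_id or plan.role != evaluation.role:
        raise ValueError(
            f"mismatched records: {plan.case_id}/{plan.role.value} vs "
            f"{evaluation.case_id}/{evaluation.role.value}"
        )
    return plan.d99 - evaluation.d99


def apply_trigger(
    deltas: Mapping[StructureRole, float],
    thresholds: Optional[TriggerThresholds] = None,
    case_id: str = "",
) -> TriggerReport:
    """Apply the review rule: loss > threshold for the structure's risk level.

    The comparison is strict, following the printed '>' wording; a loss at
    exactly the threshold does not trigger and is logged for attention.
    """
    thresholds = thresholds or TriggerThresholds()
    if not deltas:
        raise ValueError("at least one CTV delta is required")
    triggered: Dict[StructureRole, bool] = {}
    for role, d in deltas.items():
        thr = thresholds.for_role(role)  # raises on unknown role
        triggered[role] = d > thr
        if d == thr:
            log.info("case %s: %s loss exactly at threshold %.1f — not triggered", case_id, role.value, thr)
    return TriggerReport(
        case_id=case_id,
        deltas=dict(deltas),
        triggered=triggered,
        review=any(triggered.values()),
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def _exact_wplus_distribution(ranks: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W+ by subset-sum enumeration over the
    (mid)ranks; returns (support, counts).  Ranks are doubled so midranks
    become integers."""
    scaled = np.rint(2 * ranks).astype(np.int64)
    total = int(scaled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in scaled:
        counts[r:] += counts[: total + 1 - r].copy()
    support = np.arange(total + 1) / 2.0
    return support, counts


def wilcoxon_signed_rank(differences: Sequence[float], exact_max_n: int = 15) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are discarded (Wilcoxon's convention) and ties receive midranks.
    For n <= ``exact_max_n`` the p-value comes from exact enumeration of all
    2^n sign assignments; above that, from the normal approximation with tie
    correction.  Returns ``(statistic, p)`` with the statistic
    ``min(W+, W-)``.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero — the signed-rank test is undefined")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)
    if n <= exact_max_n:
        support, counts = _exact_wplus_distribution(ranks)
        total = counts.sum()  # 2^n
        p_le = counts[support <= w_plus + 1e-9].sum() / total
        p_ge = counts[support >= w_plus - 1e-9].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, t_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(t_counts**3 - t_counts)) / 48.0
        z = (w_plus - mu) / math.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return stat, p


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------


@dataclass
class AccuracySummary:
    """Per image kind / structure role accuracy vs the ground-truth CT."""

    table: pd.DataFrame  # columns: image_kind, role, n, mean_abs_dd99, sd_abs_dd99
    wilcoxon: pd.DataFrame  # pairwise comparisons of |ΔD99 vs gtCT|
    gt_loss_iqr: Dict[str, Tuple[float, float]]  # per role, IQR of gtCT coverage loss
    gt_mean_loss: Dict[str, float]
    trigger_counts: Dict[str, int]
    n_cases: int

    def to_frames(self) -> Dict[str, pd.DataFrame]:
        return {"accuracy": self.table, "wilcoxon": self.wilcoxon}


def _records_frame(records: Iterable[CoverageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"case_id": r.case_id, "image_kind": r.image_kind, "role": r.role.value, "d99": r.d99}
            for r in records
        ]
    )


def summarize_cohort(
    records: Sequence[CoverageRecord],
    thresholds: Optional[TriggerThresholds] = None,
) -> AccuracySummary:
    """Cohort accuracy statistics: |ΔD99| of each surrogate vs the gtCT
    (mean ± SD per image kind and role), paired Wilcoxon comparisons between
    surrogates, IQR of gtCT coverage loss, and trigger counts.

    Cases without a gtCT record for a structure are excluded from that
    structure's statistics with a logged warning.
    """
    thresholds = thresholds or TriggerThresholds()
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no coverage records")
    wide = df.pivot_table(index=["case_id", "role"], columns="image_kind", values="d99")
    if "GTCT" not in wide.columns:
        raise ValueError("cohort has no ground-truth records")
    missing_gt = wide["GTCT"].isna()
    if missing_gt.any():
        for (case, role) in wide.index[missing_gt]:
            log.warning("case %s/%s has no gtCT record — excluded", case, role)
        wide = wide[~missing_gt]

    rows = []
    errors: Dict[Tuple[str, str], pd.Series] = {}
    for kind in SURROGATES:
        if kind not in wide.columns:
            continue
        for role in (StructureRole.CTV_HIGH.value, StructureRole.CTV_STANDARD.value):
            sel = wide.xs(role, level="role")
            err = (sel[kind] - sel["GTCT"]).abs().dropna()
            if err.empty:
                continue
            errors[(kind, role)] = err
            rows.append(
                {
                    "image_kind": kind,
                    "role": role,
                    "n": int(err.size),
                    "mean_abs_dd99": float(err.mean()),
                    "sd_abs_dd99": float(err.std(ddof=1)) if err.size > 1 else float("nan"),
                }
            )
    table = pd.DataFrame(rows)

    wrows = []
    for (a, b) in itertools.combinations(SURROGATES, 2):
        for role in (StructureRole.CTV_HIGH.value, StructureRole.CTV_STANDARD.value):
            if (a, role) not in errors or (b, role) not in errors:
                continue
            paired = pd.concat([errors[(a, role)], errors[(b, role)]], axis=1, join="inner")
            diffs = (paired.iloc[:, 0] - paired.iloc[:, 1]).to_numpy()
            if np.all(diffs == 0):
                stat, p = float("nan"), 1.0
            else:
                stat, p = wilcoxon_signed_rank(diffs)
            wrows.append(
                {"comparison": f"{a}_vs_{b}", "role": role, "n": int(diffs.size),
                 "statistic": stat, "p_value": p, "significant": p < 0.05}
            )
    wilcoxon_df = pd.DataFrame(wrows)

    gt_iqr: Dict[str, Tuple[float, float]] = {}
    gt_mean: Dict[str, float] = {}
    trig_counts = {"CTV_HIGH": 0, "CTV_STANDARD": 0, "any": 0}
    if "PLAN" in wide.columns:
        loss = wide["PLAN"] - wide["GTCT"]
        per_case_review = {}
        for role in (StructureRole.CTV_HIGH, StructureRole.CTV_STANDARD):
            vals = loss.xs(role.value, level="role").dropna()
            if vals.empty:
                continue
            gt_iqr[role.value] = (float(vals.quantile(0.25)), float(vals.quantile(0.75)))
            gt_mean[role.value] = float(vals.mean())
            thr = thresholds.for_role(role)
            hits = vals > thr
            trig_counts[role.value] = int(hits.sum())
            for case, hit in hits.items():
                per_case_review[case] = per_case_review.get(case, False) or bool(hit)
        trig_counts["any"] = int(sum(per_case_review.values()))
    n_cases = int(wide.reset_index()["case_id"].nunique())
    return AccuracySummary(
        table=table,
        wilcoxon=wilcoxon_df,
        gt_loss_iqr=gt_iqr,
        gt_mean_loss=gt_mean,
        trigger_counts=trig_counts,
        n_cases=n_cases,
    )
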