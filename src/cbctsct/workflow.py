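"""End-to-end case evaluation and cohort reporting.

Mirrors the proposed clinical monitoring loop: from a planning CT, a same-day
CBCT and (optionally) a verification CT, build the synthetic CTs, recompute
the plan's dose proxy on every image set, extract D99 per target, apply the
review-trigger rules, and aggregate cohort accuracy statistics.  The vfCT is
optional by design — the CBCT-only path is exactly the workflow that removes
the need for routine mid-course rescans; without it the gtCT reference and
the accuracy statistics are simply absent.
"""

from __future__ import annotations

import base64
import dataclasses
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .core_images import (
    GeometryError,
    IntensityKind,
    StructureRole,
    StructureSet,
    VolumeImage,
    read_structures,
    read_volume,
    write_structures,
    write_volume,
)
from .registration import DirConfig, map_contours
from .synthetic_ct import CorrCbctConfig, make_corrcbct, make_gtct, make_virtct
from .dose import DoseConfig, compute_dvh, d_metric, evaluate_dose, hu_to_spr, make_plan
from .trigger import (
    CoverageRecord,
    TriggerThresholds,
    apply_trigger,
    summarize_cohort,
)
from .phantoms import CohortCase, generate_cohort, materialize_case

log = logging.getLogger("cbctsct")

__all__ = [
    "RunConfig",
    "CaseReport",
    "evaluate_case",
    "evaluate_cohort_records",
    "simulate_cohort",
    "write_case",
    "load_case",
    "cohort_report",
    "validate_case_report",
    "CASE_REPORT_SCHEMA",
]


@dataclass
class RunConfig:
    """All pipeline settings with their defaults.

    Threshold defaults are the published ones: density masking at
    |Δρ| > 0.3 g/cm³ with min ρ < 0.6 g/cm³, review triggers at D99 loss
    > 3 pp (high-risk) / > 5 pp (standard-risk).
    """

    grid_preset: str = "test"
    arrangement: str = "anterior_plus_posterior_obliques"
    delta_rho: float = 0.3
    low_rho: float = 0.6
    trigger: TriggerThresholds = dfield(default_factory=TriggerThresholds)
    corrcbct: CorrCbctConfig = dfield(default_factory=CorrCbctConfig)
    dose: DoseConfig = dfield(default_factory=DoseConfig)
    dir: DirConfig = dfield(default_factory=DirConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_rho <= 0 or self.low_rho <= 0:
            raise ValueError("density thresholds must be positive")
        if self.trigger.high <= 0 or self.trigger.standard <= 0:
            raise ValueError("trigger thresholds must be positive")
        self.corrcbct.dir = self.dir

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "trigger" in kwargs and isinstance(kwargs["trigger"], dict):
            kwargs["trigger"] = TriggerThresholds(**kwargs["trigger"])
        for key, klass in (("corrcbct", CorrCbctConfig), ("dose", DoseConfig), ("dir", DirConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                if key == "corrcbct" and isinstance(sub.get("dir"), dict):
                    sub["dir"] = DirConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in sub["dir"].items()})
                sub = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
                if key == "dose" and "arrangements" in sub:
                    sub["arrangements"] = {k: tuple(v) for k, v in dict(sub["arrangements"]).items()}
                kwargs[key] = klass(**sub)
        return cls(**kwargs)


CASE_REPORT_SCHEMA: Dict[str, type] = {
    # minimal structural contract of a case report JSON
    "case_id": str,
    "config_hash": str,
    "d99": dict,  # image kind -> {role: value}
    "delta_d99": dict,  # image kind -> {role: value}
    "trigger": dict,
    "convergence": dict,
}


def validate_case_report(report: dict) -> None:
    """Raise ``ValueError`` if a case report does not match the schema."""
    for key, typ in CASE_REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"case report missing required key '{key}'")
        if not isinstance(report[key], typ):
            raise ValueError(f"case report key '{key}' must be {typ.__name__}")
    for kind, vals in report["d99"].items():
        if not isinstance(vals, dict):
            raise ValueError(f"d99[{kind}] must map roles to values")
    trig = report["trigger"]
    for key in ("review", "triggered", "thresholds", "deltas"):
        if key not in trig:
            raise ValueError(f"trigger report missing '{key}'")


@dataclass
class CaseReport:
    case_id: str
    d99: Dict[str, Dict[str, float]]
    delta_d99: Dict[str, Dict[str, float]]
    trigger: dict
    convergence: dict
    config_hash: str
    records: List[CoverageRecord]

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "config_hash": self.config_hash,
            "d99": self.d99,
            "delta_d99": self.delta_d99,
            "trigger": self.trigger,
            "convergence": self.convergence,
        }


_CTV_ROLES = (StructureRole.CTV_HIGH, StructureRole.CTV_STANDARD)


def _target_d99(dose, structures: StructureSet) -> Dict[str, float]:
    out = {}
    for role in _CTV_ROLES:
        for name, mask in structures.by_role(role).items():
            out[role.value] = d_metric(compute_dvh(dose, mask), 0.99)
    return out


def evaluate_case(
    pct: VolumeImage,
    cbct: VolumeImage,
    fov: np.ndarray,
    structures: StructureSet,
    vfct: Optional[VolumeImage] = None,
    config: Optional[RunConfig] = None,
    case_id: str = "case",
    out_dir=None,
) -> CaseReport:
    """Run the full monitoring pipeline on one case.

    corrCBCT → virtCT → (gtCT when a vfCT is supplied) → dose proxy on every
    image set with the plan's beams → per-target D99 → trigger report.
    Planning contours are mapped to the CBCT frame with the corrCBCT's
    deformation.  All intermediate images are persisted when ``out_dir`` is
    given.
    """
    config = config or RunConfig()
    if not pct.same_grid_as(cbct):
        raise GeometryError("pCT and CBCT must share a grid (resample first)")

    corr = make_corrcbct(pct, cbct, fov, config.corrcbct)
    virtct, override = make_virtct(
        pct, corr.corrcbct, corr.field, fov, config.delta_rho, config.low_rho
    )
    mapped = map_contours(structures, corr.field)

    plan = make_plan(structures, hu_to_spr(pct), config.arrangement, config.dose)
    d99: Dict[str, Dict[str, float]] = {
        "PLAN": _target_d99(plan.plan_dose, structures)
    }
    eval_sets: Dict[str, Tuple[VolumeImage, StructureSet]] = {
        "CORRCBCT": (corr.corrcbct, mapped),
        "VIRTCT": (virtct, mapped),
    }
    convergence = {
        "corrcbct_converged": corr.converged,
        "corrcbct_trace": corr.trace,
        "dir_info": {k: v for k, v in corr.field.info.items() if k != "trace"},
    }
    gtct = None
    if vfct is not None:
        gtct, gt_field = make_gtct(vfct, cbct, fov, config.corrcbct)
        eval_sets["GTCT"] = (gtct, mapped)
        eval_sets["VFCT"] = (vfct, mapped)
    for kind, (img, structs_k) in eval_sets.items():
        dose_k = evaluate_dose(plan, hu_to_spr(img), config.dose)
        d99[kind] = _target_d99(dose_k, structs_k)

    delta: Dict[str, Dict[str, float]] = {}
    records: List[CoverageRecord] = []
    for role in _CTV_ROLES:
        records.append(CoverageRecord(case_id, "PLAN", role, d99["PLAN"][role.value]))
    for kind in eval_sets:
        delta[kind] = {
            r.value: d99["PLAN"][r.value] - d99[kind][r.value] for r in _CTV_ROLES
        }
        for role in _CTV_ROLES:
            records.append(CoverageRecord(case_id, kind, role, max(d99[kind][role.value], 0.0)))

    # the trigger decision uses the best available estimate of the delivered
    # dose: the gtCT when present, otherwise the virtCT
    decision_kind = "GTCT" if "GTCT" in delta else "VIRTCT"
    trig = apply_trigger(
        {r: delta[decision_kind][r.value] for r in _CTV_ROLES}, config.trigger, case_id
    )
    report = CaseReport(
        case_id=case_id,
        d99=d99,
        delta_d99=delta,
        trigger={**trig.to_dict(), "decision_image": decision_kind},
        convergence=convergence,
        config_hash=config.config_hash(),
        records=records,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_volume(corr.corrcbct, out_dir / "corrcbct.nii.gz")
        write_volume(virtct, out_dir / "virtct.nii.gz")
        write_volume(
            VolumeImage(override.astype(np.int16), virtct.spacing, virtct.origin, IntensityKind.HU),
            out_dir / "override_mask.nii.gz",
        )
        if gtct is not None:
            write_volume(gtct, out_dir / "gtct.nii.gz")
        (out_dir / "conversion.json").write_text(json.dumps(corr.conversion.to_dict(), indent=2))
        (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# Cohort-level drivers
# ---------------------------------------------------------------------------


def simulate_cohort(n: int, config: Optional[RunConfig] = None, out_dir=None, materialize: int = 0):
    """Generate a synthetic cohort (specs + coverage records; optionally
    write the first ``materialize`` cases' images to disk)."""
    config = config or RunConfig()
    cases = generate_cohort(
        n, seed=config.seed, thresholds=config.trigger, grid_preset=config.grid_preset, out_dir=out_dir
    )
    if out_dir is not None and materialize > 0:
        for case in cases[:materialize]:
            write_case(case, Path(out_dir) / case.case_id)
    return cases


def write_case(case: CohortCase, case_dir) -> Path:
    """Materialize one case's images into a directory."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    pct, structures, vfct, vf_structs, true_field, cbct, fov, true_inverse = materialize_case(case)
    write_volume(pct, case_dir / "pct.nii.gz")
    write_volume(vfct, case_dir / "vfct.nii.gz")
    write_volume(cbct, case_dir / "cbct.nii.gz")
    write_volume(
        VolumeImage(fov.astype(np.int16), cbct.spacing, cbct.origin, IntensityKind.HU),
        case_dir / "fov.nii.gz",
    )
    write_structures(structures, case_dir / "structures.nii.gz", case_dir / "structures.json")
    (case_dir / "manifest.json").write_text(json.dumps(case.manifest(), indent=2, sort_keys=True))
    return case_dir


def load_case(case_dir):
    """Read a materialized case directory back into memory."""
    case_dir = Path(case_dir)
    for required in ("pct.nii.gz", "cbct.nii.gz", "fov.nii.gz", "structures.nii.gz"):
        if not (case_dir / required).exists():
            raise FileNotFoundError(f"case is missing required file: {case_dir / required}")
    pct = read_volume(case_dir / "pct.nii.gz", IntensityKind.HU)
    cbct = read_volume(case_dir / "cbct.nii.gz", IntensityKind.CBCT_GRAY)
    fov = read_volume(case_dir / "fov.nii.gz").voxels > 0
    structures = read_structures(case_dir / "structures.nii.gz", case_dir / "structures.json")
    vfct = None
    if (case_dir / "vfct.nii.gz").exists():
        vfct = read_volume(case_dir / "vfct.nii.gz", IntensityKind.HU)
    return pct, cbct, fov, structures, vfct


def evaluate_cohort_records(cases: List[CohortCase], config: Optional[RunConfig] = None):
    """Trigger reports + accuracy summary over a cohort's coverage records."""
    config = config or RunConfig()
    records = [r for case in cases for r in case.coverage_records]
    summary = summarize_cohort(records, config.trigger)
    reports = []
    for case in cases:
        gt = {r.role: r.d99 for r in case.coverage_records if r.image_kind == "GTCT"}
        plan = {r.role: r.d99 for r in case.coverage_records if r.image_kind == "PLAN"}
        deltas = {role: plan[role] - gt[role] for role in gt}
        reports.append(apply_trigger(deltas, config.trigger, case.case_id))
    return reports, summary


def cohort_report(cases: List[CohortCase], config: Optional[RunConfig] = None, out_dir=None):
    """Aggregate a cohort into summary tables (CSV), trigger-rate JSON, and
    an HTML report with the per-image accuracy distributions."""
    if not cases:
        raise ValueError("no evaluated cases to report on")
    config = config or RunConfig()
    reports, summary = evaluate_cohort_records(cases, config)
    n_review = sum(r.review for r in reports)
    out = {
        "n_cases": len(cases),
        "n_review": n_review,
        "review_rate": n_review / len(cases),
        "trigger_counts": summary.trigger_counts,
        "gt_mean_loss": summary.gt_mean_loss,
        "gt_loss_iqr": summary.gt_loss_iqr,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.table.to_csv(out_dir / "accuracy_summary.csv", index=False)
        summary.wilcoxon.to_csv(out_dir / "wilcoxon.csv", index=False)
        (out_dir / "trigger_summary.json").write_text(json.dumps(out, indent=2, sort_keys=True))
        for rep in reports:
            (out_dir / f"trigger_{rep.case_id}.json").write_text(
                json.dumps(rep.to_dict(), indent=2, sort_keys=True)
            )
        _write_html_report(cases, summary, out, out_dir / "report.html")
    return out, summary


def _write_html_report(cases, summary, overview: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    records = [r for case in cases for r in case.coverage_records]
    df = pd.DataFrame(
        [{"case": r.case_id, "kind": r.image_kind, "role": r.role.value, "d99": r.d99} for r in records]
    )
    wide = df.pivot_table(index=["case", "role"], columns="kind", values="d99")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, role in zip(axes, ("CTV_HIGH", "CTV_STANDARD")):
        sel = wide.xs(role, level="role")
        data = [(sel[k] - sel["GTCT"]).abs().dropna() for k in ("VFCT", "CORRCBCT", "VIRTCT") if k in sel]
        ax.boxplot(data, tick_labels=["vfCT", "corrCBCT", "virtCT"][: len(data)])
        ax.set_title(role.replace("_", " ").title())
        ax.set_ylabel("|ΔD99| vs gtCT (pp)")
    fig.tight_layout()
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=100)
    plt.close(fig)
    img64 = base64.b64encode(buf.getvalue()).decode()
    html = (
        "<html><head><title>Cohort report</title></head><body>"
        "<h1>CBCT synthetic-CT cohort report</h1>"
        f"<p>Cases: {overview['n_cases']} — plan reviews triggered: "
        f"{overview['n_review']} ({100 * overview['review_rate']:.1f}%)</p>"
        "<h2>Surrogate accuracy vs ground truth</h2>"
        + summary.table.to_html(index=False)
        + "<h2>Paired Wilcoxon comparisons</h2>"
        + summary.wilcoxon.to_html(index=False)
        + f'<h2>Distributions</h2><img src="data:image/png;base64,{img64}"/>'
        "</body></html>"
    )
    path.write_text(html)
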