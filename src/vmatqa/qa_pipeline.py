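"""Pretreatment and on-treatment patient-specific QA orchestration.

Pretreatment QA recomputes the RT plan with an independent engine
configuration and compares it to the reference (planning-system-like)
dose.  On-treatment QA first reconstructs the RT log file plan from the
delivery log, then recomputes and compares; it therefore checks the
planning calculation, the data transfer to the machine, and the delivery
itself.  Reports carry the clinical metric set (PTV Dmean/V95/V107/D2/
D98; rectum D15-D50; bladder D15-Dmax; femoral Dmax) plus overall and
per-structure gamma passing rates, and are classified against a 90% GPR
pass limit and a 2% PTV Dmean tolerance (both boundaries inclusive).

The two engine roles — "TPS-like" reference and "QA-like" recalculation —
are played by the same simplified engine under slightly different physics
(attenuation, penumbra, noise level, seed), the desk-scale analogue of
two independently commissioned beam models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .compare import (GammaCriteria, MetricSpec, dvh_metric, gamma_index,
                      metric_difference, passing_rate)
from .delivery_log import DeliveryLog, log_to_plan
from .dose_engine import EngineConfig, compute_dose
from .exceptions import ValidationError
from .grids import DoseGrid, PhantomVolume, StructureSet
from .plan import VmatPlan

__all__ = [
    "QaLimits", "QaReport", "CohortSummary", "REPORT_METRICS",
    "GAMMA_VOLUMES", "default_tps_config", "default_qa_config",
    "pretreatment_qa", "ontreatment_qa", "classify", "cohort_stats",
    "pearson_category",
]

#: clinical DVH metric set reported per structure
REPORT_METRICS: dict[str, tuple[str, ...]] = {
    "PTV": ("Dmean", "V95", "V107", "D2", "D98"),
    "rectum": ("D15", "D20", "D25", "D35", "D50"),
    "bladder": ("D15", "D25", "D35", "D50", "Dmax"),
    "femur_right": ("Dmax",),
    "femur_left": ("Dmax",),
}

#: structures evaluated as individual gamma volumes (plus "overall")
GAMMA_VOLUMES: tuple[str, ...] = ("PTV", "rectum", "bladder")


def default_tps_config(grid_spacing_mm: float = 3.0, seed: int = 0,
                       **overrides) -> EngineConfig:
    """Reference ("planning-system-like") engine configuration."""
    kw = dict(mu_eff_per_cm=0.050, sigma_mm=3.0, uncertainty="extra_fine",
              grid_spacing_mm=grid_spacing_mm, seed=seed)
    kw.update(overrides)
    return EngineConfig(**kw)


def default_qa_config(grid_spacing_mm: float = 3.0, seed: int = 1,
                      **overrides) -> EngineConfig:
    """Independent-recalculation engine configuration.

    Attenuation and penumbra are deliberately offset from the reference
    configuration (0.0505 vs 0.050 /cm; 3.3 vs 3.0 mm) to emulate two
    independently commissioned beam models whose systematic differences
    are well under the 2% clinical criterion.
    """
    kw = dict(mu_eff_per_cm=0.0505, sigma_mm=3.3, uncertainty="fine",
              grid_spacing_mm=grid_spacing_mm, seed=seed)
    kw.update(overrides)
    return EngineConfig(**kw)


@dataclass(frozen=True)
class QaLimits:
    """Classification limits; pass boundaries are inclusive."""

    gpr_pass_limit_pct: float = 90.0
    ptv_dmean_tolerance_pct: float = 2.0
    criteria: GammaCriteria = field(default_factory=GammaCriteria)

    def __post_init__(self) -> None:
        if self.gpr_pass_limit_pct <= 0 or self.ptv_dmean_tolerance_pct <= 0:
            raise ValidationError("limits must be positive")


@dataclass
class QaReport:
    """Per-plan QA result: gamma volumes, metric differences, pass/fail."""

    mode: str                                   # pretreatment | ontreatment
    gamma_pct: dict[str, float]                 # overall + GAMMA_VOLUMES
    metric_diff_pct: dict[str, dict[str, float | None]]
    metrics_reference: dict[str, dict[str, float]]
    metrics_evaluated: dict[str, dict[str, float]]
    prescription_gy: float
    passed: bool
    reasons: list[str]

    @property
    def ptv_dmean_diff_pct(self) -> float:
        return self.metric_diff_pct["PTV"]["Dmean"]

    SCHEMA = "vmatqa-report v1"

    def to_dict(self) -> dict:
        """JSON-serializable form (schema-versioned)."""
        return {
            "schema": self.SCHEMA,
            "mode": self.mode,
            "gamma_pct": self.gamma_pct,
            "metric_diff_pct": self.metric_diff_pct,
            "metrics_reference": self.metrics_reference,
            "metrics_evaluated": self.metrics_evaluated,
            "prescription_gy": self.prescription_gy,
            "passed": self.passed,
            "reasons": self.reasons,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "QaReport":
        if data.get("schema") != cls.SCHEMA:
            raise ValidationError(f"unknown report schema: {data.get('schema')}")
        return cls(
            mode=data["mode"], gamma_pct=data["gamma_pct"],
            metric_diff_pct=data["metric_diff_pct"],
            metrics_reference=data["metrics_reference"],
            metrics_evaluated=data["metrics_evaluated"],
            prescription_gy=data["prescription_gy"],
            passed=data["passed"], reasons=data["reasons"],
        )


def classify(report: QaReport, limits: QaLimits) -> tuple[bool, list[str]]:
    """Pass/fail against the QA limits; reasons list every violated rule.

    A report fails iff the overall GPR is below the pass limit or the
    absolute PTV Dmean difference exceeds the tolerance; values exactly
    at a limit pass.
    """
    reasons = []
    gpr = report.gamma_pct["overall"]
    if gpr < limits.gpr_pass_limit_pct:
        reasons.append(
            f"overall GPR {gpr:.1f}% below pass limit "
            f"{limits.gpr_pass_limit_pct:g}%")
    dmean = report.ptv_dmean_diff_pct
    if dmean is None or abs(dmean) > limits.ptv_dmean_tolerance_pct:
        reasons.append(
            f"PTV Dmean difference {dmean if dmean is None else round(dmean, 3)}% "
            f"beyond tolerance {limits.ptv_dmean_tolerance_pct:g}%")
    return (len(reasons) == 0, reasons)


def _compare_doses(reference: DoseGrid, evaluated: DoseGrid,
                   structures: StructureSet, prescription_gy: float,
                   limits: QaLimits, mode: str) -> QaReport:
    masks_ref = structures.mask_on(reference.geometry, reference.dose.shape)
    masks_ev = structures.mask_on(evaluated.geometry, evaluated.dose.shape)

    gmap = gamma_index(reference, evaluated, limits.criteria)
    gamma_pct = {"overall": passing_rate(gmap)}
    for roi in GAMMA_VOLUMES:
        gamma_pct[roi] = passing_rate(gmap, masks_ref[roi])

    diffs: dict[str, dict[str, float | None]] = {}
    m_ref: dict[str, dict[str, float]] = {}
    m_ev: dict[str, dict[str, float]] = {}
    for roi, names in REPORT_METRICS.items():
        diffs[roi], m_ref[roi], m_ev[roi] = {}, {}, {}
        for name in names:
            spec = MetricSpec.parse(name, prescription_gy=prescription_gy)
            rv = dvh_metric((reference, masks_ref[roi]), spec)
            ev = dvh_metric((evaluated, masks_ev[roi]), spec)
            m_ref[roi][name] = rv
            m_ev[roi][name] = ev
            if rv == 0.0:
                diffs[roi][name] = 0.0 if ev == 0.0 else None
            else:
                diffs[roi][name] = metric_difference(rv, ev, rv)

    report = QaReport(mode=mode, gamma_pct=gamma_pct, metric_diff_pct=diffs,
                      metrics_reference=m_ref, metrics_evaluated=m_ev,
                      prescription_gy=prescription_gy, passed=False,
                      reasons=[])
    report.passed, report.reasons = classify(report, limits)
    return report


def pretreatment_qa(plan: VmatPlan, phantom: PhantomVolume,
                    structures: StructureSet, reference_dose: DoseGrid,
                    cfg: EngineConfig | None = None,
                    limits: QaLimits | None = None,
                    prescription_gy: float = 2.0) -> QaReport:
    """Independent recalculation of the RT plan vs the reference dose."""
    cfg = cfg if cfg is not None else default_qa_config()
    limits = limits if limits is not None else QaLimits()
    recalculated = compute_dose(plan, phantom, cfg)
    return _compare_doses(reference_dose, recalculated, structures,
                          prescription_gy, limits, mode="pretreatment")


def ontreatment_qa(plan: VmatPlan, log: DeliveryLog, phantom: PhantomVolume,
                   structures: StructureSet, reference_dose: DoseGrid,
                   cfg: EngineConfig | None = None,
                   limits: QaLimits | None = None,
                   prescription_gy: float = 2.0) -> QaReport:
    """Recalculation of the RT log file plan vs the reference dose.

    Checks the planning calculation, the transfer to the machine, and the
    delivery itself: the log is first reconstructed into a plan with one
    control point per record, then recomputed with the independent engine
    configuration.
    """
    cfg = cfg if cfg is not None else default_qa_config()
    limits = limits if limits is not None else QaLimits()
    reconstructed = log_to_plan(log, plan)
    recalculated = compute_dose(reconstructed, phantom, cfg)
    return _compare_doses(reference_dose, recalculated, structures,
                          prescription_gy, limits, mode="ontreatment")


# ---------------------------------------------------------------------------
# cohort statistics


def pearson_category(r: float) -> str:
    """Correlation strength label: weak < 0.4 <= moderate <= 0.7 < strong."""
    if not np.isfinite(r):
        return "degenerate"
    if abs(r) < 0.4:
        return "weak"
    if abs(r) <= 0.7:
        return "moderate"
    return "strong"


@dataclass
class CohortSummary:
    """Per-metric cohort table: mean +/- SD per mode, paired p, Pearson r."""

    table: pd.DataFrame
    method: str
    n: int


def _flatten(report: QaReport) -> dict[str, float]:
    out = {f"gpr_{k}": v for k, v in report.gamma_pct.items()}
    for roi, metrics in report.metric_diff_pct.items():
        for name, v in metrics.items():
            out[f"{roi}_{name}_diff"] = np.nan if v is None else v
    for roi, metrics in report.metrics_evaluated.items():
        for name, v in metrics.items():
            out[f"{roi}_{name}_eval"] = v
    return out


def cohort_stats(pre_reports: list[QaReport], on_reports: list[QaReport],
                 method: str = "ttest") -> CohortSummary:
    """Paired cohort summary of pretreatment vs on-treatment QA.

    For every flattened metric: mean +/- SD per mode, a paired two-sided
    p-value (paired t-test by default, Wilcoxon signed-rank with
    ``method="wilcoxon"``) and the Pearson correlation between the paired
    values with its strength category.  Identical or constant samples are
    reported as degenerate (p and/or r undefined -> NaN).
    """
    if len(pre_reports) != len(on_reports):
        raise ValidationError("pre/on report lists must be paired")
    if len(pre_reports) < 3:
        raise ValidationError("need at least 3 paired plans")
    if method not in ("ttest", "wilcoxon"):
        raise ValidationError("method must be 'ttest' or 'wilcoxon'")

    pre = pd.DataFrame([_flatten(r) for r in pre_reports])
    on = pd.DataFrame([_flatten(r) for r in on_reports])
    rows = []
    for col in pre.columns:
        a, b = pre[col].to_numpy(), on[col].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < 3:
            continue
        diff = a - b
        if np.allclose(diff, 0.0):
            p = np.nan  # identical paired samples: test degenerate
        elif method == "ttest":
            p = float(stats.ttest_rel(a, b).pvalue)
        else:
            p = float(stats.wilcoxon(a, b).pvalue)
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            r = np.nan  # constant sample: correlation undefined
        else:
            r = float(stats.pearsonr(a, b).statistic)
        rows.append({
            "metric": col,
            "pre_mean": float(a.mean()), "pre_sd": float(a.std(ddof=1)),
            "on_mean": float(b.mean()), "on_sd": float(b.std(ddof=1)),
            "p_value": p, "significant": bool(p < 0.05) if np.isfinite(p) else False,
            "pearson_r": r, "r_category": pearson_category(r),
        })
    return CohortSummary(table=pd.DataFrame(rows).set_index("metric"),
                         method=method, n=len(pre_reports))
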