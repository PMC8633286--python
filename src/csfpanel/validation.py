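"""SRM assay validation framework.

Seven method-validation criteria protect the quantification: calibration
linearity over a heavy-peptide dilution series (fits with R-squared below 0.7
are excluded) and six coefficient-of-variation suites — intra-assay (five
same-day injections), inter-assay (ten measurement days), sample preparation
(five identical aliquots digested in parallel), autosampler stability (one
sample re-injected every 4 h for 24 h), and freeze/thaw stability of the
digested and the pre-digestion sample. A CV of at most 20% is regarded as
acceptable; thresholds are boundary-inclusive by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

CRITERIA = ("LINEARITY", "INTRA_ASSAY", "INTER_ASSAY", "PREP",
            "AUTOSAMPLER", "FREEZE_THAW_DIGESTED", "FREEZE_THAW_PREDIGEST")

#: Minimum replicate counts per CV criterion (design of the validation runs):
#: 5 same-day injections, 10 days, 5 aliquots, 7 time points (0-24 h / 4 h),
#: freeze/thaw series of >= 2 cycles.
CRITERION_MIN_N = {
    "INTRA_ASSAY": 5,
    "INTER_ASSAY": 10,
    "PREP": 5,
    "AUTOSAMPLER": 7,
    "FREEZE_THAW_DIGESTED": 2,
    "FREEZE_THAW_PREDIGEST": 2,
}


@dataclass
class QCCriterionResult:
    criterion_id: str
    metric_name: str  # "R2" or "CV%"
    value: float
    threshold: float
    passed: bool
    details: dict = field(default_factory=dict)


@dataclass
class AssayValidationReport:
    results: dict  # peptide_id -> list[QCCriterionResult]
    excluded: list  # peptides failing LINEARITY (or with no usable signal)

    def overall_pass(self, peptide_id: str) -> bool:
        res = self.results.get(peptide_id, [])
        return bool(res) and all(r.passed for r in res)


def fit_linearity(series: pd.DataFrame, r2_min: float = 0.7,
                  strict: bool = False) -> QCCriterionResult:
    """OLS of area on concentration over all replicate points.

    ``series`` needs columns conc_fmol and area with >= 3 distinct
    concentrations. R-squared is the squared Pearson correlation; the fit
    passes at R-squared >= ``r2_min`` (strictly greater when ``strict``).
    """
    conc = np.asarray(series["conc_fmol"], dtype=float)
    area = np.asarray(series["area"], dtype=float)
    if np.unique(conc).size < 3:
        raise ValueError("need >= 3 distinct concentrations for a calibration fit")
    if np.unique(area).size == 1:
        # flat response: zero explained variance
        slope, intercept, r2 = 0.0, float(area[0]), 0.0
    else:
        fit = sps.linregress(conc, area)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    passed = r2 > r2_min if strict else r2 >= r2_min
    return QCCriterionResult("LINEARITY", "R2", r2, r2_min, passed,
                             details={"slope": slope, "intercept": intercept})


def compute_cv(values, population_sd: bool = False) -> float:
    """Coefficient of variation in percent: 100 * sd / mean.

    Uses the sample (n-1) standard deviation unless ``population_sd``.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("CV needs >= 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    sd = arr.std(ddof=0 if population_sd else 1)
    return float(100.0 * sd / mean)


def evaluate_criterion(values, criterion_id: str, cv_max: float = 20.0,
                       strict: bool = False,
                       population_sd: bool = False) -> QCCriterionResult:
    """CV across one validation criterion's replicate axis, pass at <= cv_max."""
    if criterion_id not in CRITERION_MIN_N:
        raise ValueError(f"unknown CV criterion {criterion_id!r}; "
                         f"expected one of {sorted(CRITERION_MIN_N)}")
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    need = CRITERION_MIN_N[criterion_id]
    if arr.size < need:
        raise ValueError(
            f"{criterion_id} expects >= {need} replicate values "
            f"(e.g. {need} same-day injections), got {arr.size}")
    cv = compute_cv(arr, population_sd=population_sd)
    passed = cv < cv_max if strict else cv <= cv_max
    return QCCriterionResult(criterion_id, "CV%", cv, cv_max, passed,
                             details={"n": int(arr.size)})


def validate_assay(bundle: dict, r2_min: float = 0.7, cv_max: float = 20.0,
                   strict: bool = False) -> AssayValidationReport:
    """Evaluate every supplied criterion per peptide.

    ``bundle`` maps peptide_id -> {criterion_id: data}, where LINEARITY data
    is a calibration DataFrame (conc_fmol, area) and CV criteria carry
    replicate value lists. Peptides failing LINEARITY — including those whose
    calibration shows no usable signal — are marked excluded; other peptides
    are unaffected.
    """
    if not bundle:
        raise ValueError("empty QC bundle")
    results: dict = {}
    excluded: list = []
    for pid, crits in bundle.items():
        if not crits:
            raise ValueError(f"peptide {pid!r} has no criterion data")
        res = []
        for cid, data in crits.items():
            if cid == "LINEARITY":
                r = fit_linearity(data, r2_min=r2_min, strict=strict)
            else:
                r = evaluate_criterion(data, cid, cv_max=cv_max, strict=strict)
            res.append(r)
        results[pid] = res
        lin = [r for r in res if r.criterion_id == "LINEARITY"]
        if lin and not lin[0].passed:
            excluded.append(pid)
    return AssayValidationReport(results=results, excluded=excluded)


def report_frame(report: AssayValidationReport) -> pd.DataFrame:
    rows = []
    for pid, res in report.results.items():
        for r in res:
            rows.append({"peptide_id": pid, "criterion": r.criterion_id,
                         "metric": r.metric_name, "value": r.value,
                         "threshold": r.threshold, "pass": r.passed})
        rows.append({"peptide_id": pid, "criterion": "OVERALL",
                     "metric": "all", "value": float(report.overall_pass(pid)),
                     "threshold": 1.0, "pass": report.overall_pass(pid)})
    return pd.DataFrame(rows)
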