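"""SRM relative quantification.

Turns a transition-level SRM report (Skyline-style export) into per-sample
peptide relative quantities: transition areas are summed per
(sample, peptide, label), the endogenous/heavy area ratio gives the relative
level against the spiked-in isotope-labelled internal standard, the ratio is
normalized for total CSF protein concentration, and pooled QC samples run in
every digestion batch are used to monitor (and optionally correct) batch
drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REASON_HEAVY_UNDETECTED = "HEAVY_UNDETECTED"

#: Accepted aliases for the transition-report columns (Skyline dialect).
COLUMN_ALIASES = {
    "sample_id": ("sample_id", "sample", "ReplicateName", "replicate"),
    "peptide_id": ("peptide_id", "peptide", "PeptideSequence"),
    "transition_id": ("transition_id", "transition", "FragmentIon"),
    "label": ("label", "IsotopeLabelType", "label_type"),
    "area": ("area", "Area", "peak_area"),
    "batch_id": ("batch_id", "batch"),
    "is_qc_pool": ("is_qc_pool", "qc_pool", "qc"),
    "retention_time": ("retention_time", "rt", "RetentionTime"),
}

#: Skyline exports call the endogenous channel "light".
LABEL_MAP = {"endogenous": "endogenous", "light": "endogenous", "heavy": "heavy"}


@dataclass
class BatchQCSummary:
    batch_means: pd.DataFrame  # peptides x batches, QC-pool mean ratio
    correction_factors: pd.DataFrame  # peptides x batches, multiplicative
    cv_across_batches: pd.Series  # percent per peptide
    mode: str = "monitor"


def normalize_report(report: pd.DataFrame) -> pd.DataFrame:
    """Rename aliased columns, map label vocabulary, validate basics."""
    colmap = {}
    for canon, aliases in COLUMN_ALIASES.items():
        for a in aliases:
            if a in report.columns:
                colmap[a] = canon
                break
    df = report.rename(columns=colmap).copy()
    required = ["sample_id", "peptide_id", "transition_id", "label", "area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"transition report lacks columns: {missing}")
    df["label"] = df["label"].astype(str).str.lower().map(LABEL_MAP)
    if df["label"].isna().any():
        raise ValueError("label column must be endogenous/light or heavy")
    if (df["area"] < 0).any():
        raise ValueError("negative transition areas")
    if "batch_id" not in df.columns:
        df["batch_id"] = "B1"
    if "is_qc_pool" not in df.columns:
        df["is_qc_pool"] = False
    df["is_qc_pool"] = df["is_qc_pool"].astype(bool)
    dup = df.duplicated(["sample_id", "peptide_id", "transition_id", "label"])
    if dup.any():
        raise ValueError(
            f"duplicate (sample, peptide, transition, label) rows: {int(dup.sum())}")
    return df


def aggregate_transitions(report: pd.DataFrame, min_transitions: int = 2
                          ) -> pd.DataFrame:
    """Sum transition areas per (sample, peptide, label).

    Returns a table with columns ``area`` (sum) and ``n_transitions``;
    ``low_evidence`` flags keys backed by fewer than ``min_transitions``
    transitions. Summation (not averaging) is the default aggregation; a mean
    is available via ``agg='mean'``-style post-processing by callers.
    """
    df = normalize_report(report)
    grouped = df.groupby(["sample_id", "peptide_id", "label"], sort=True).agg(
        area=("area", "sum"),
        n_transitions=("transition_id", "nunique"),
        batch_id=("batch_id", "first"),
        is_qc_pool=("is_qc_pool", "first"),
    ).reset_index()
    grouped["low_evidence"] = grouped["n_transitions"] < min_transitions
    return grouped


def compute_ratio(endo_area: float, heavy_area: float
                  ) -> tuple[float | None, str | None]:
    """Endogenous/heavy ratio; (None, reason) when the standard is absent."""
    if heavy_area < 0 or endo_area < 0:
        raise ValueError("areas must be non-negative")
    if heavy_area == 0:
        return None, REASON_HEAVY_UNDETECTED
    return endo_area / heavy_area, None


def normalize_ratio(ratio: float, total_protein_mg_l: float,
                    protein_scale: float = 1000.0) -> float:
    """Divide the ratio by total CSF protein expressed in g/L.

    ``protein_scale`` converts the metadata's mg/L to the normalization unit
    (1000 -> g/L); it is configurable because the correction's units are an
    assay-level convention.
    """
    if total_protein_mg_l <= 0:
        raise ValueError("total protein must be positive")
    return ratio / (total_protein_mg_l / protein_scale)


def quantify(report: pd.DataFrame, metadata: pd.DataFrame | None = None,
             min_transitions: int = 2, protein_scale: float = 1000.0,
             batch_correct: bool = False) -> tuple[pd.DataFrame, BatchQCSummary]:
    """Full transition-report -> per-sample peptide quantity table.

    Output columns: endo_area, heavy_area, ratio, normalized_ratio (when
    metadata with total_protein is given), corrected_ratio (batch QC
    correction of the normalized ratio when enabled, else a copy),
    missing_reason, low_evidence, batch_id, is_qc_pool.
    """
    agg = aggregate_transitions(report, min_transitions=min_transitions)
    wide = agg.pivot_table(index=["sample_id", "peptide_id", "batch_id",
                                  "is_qc_pool"],
                           columns="label", values="area", aggfunc="first")
    flags = agg.groupby(["sample_id", "peptide_id"])["low_evidence"].any()
    wide = wide.rename(columns={"endogenous": "endo_area", "heavy": "heavy_area"})
    for col in ("endo_area", "heavy_area"):
        if col not in wide.columns:
            wide[col] = np.nan
    out = wide.reset_index()
    ratios, reasons = [], []
    for e, h in zip(out["endo_area"], out["heavy_area"]):
        if np.isnan(h) or h == 0:
            ratios.append(np.nan)
            reasons.append(REASON_HEAVY_UNDETECTED)
        else:
            ratios.append((0.0 if np.isnan(e) else e) / h)
            reasons.append("")
    out["ratio"] = ratios
    out["missing_reason"] = reasons
    out["low_evidence"] = flags.reindex(
        pd.MultiIndex.from_frame(out[["sample_id", "peptide_id"]])).to_numpy()

    if metadata is not None and "total_protein" in metadata.columns:
        tp = metadata["total_protein"]
        out["normalized_ratio"] = [
            normalize_ratio(r, tp[s], protein_scale)
            if (s in tp.index and not np.isnan(r)) else np.nan
            for r, s in zip(out["ratio"], out["sample_id"])
        ]
        # QC pools are digests of a CSF pool, not cohort samples: carry the
        # un-normalized ratio so batch monitoring is protein-independent
        out.loc[out["is_qc_pool"], "normalized_ratio"] = \
            out.loc[out["is_qc_pool"], "ratio"]
    else:
        out["normalized_ratio"] = out["ratio"]

    corrected, summary = batch_qc_correct(
        out, mode="correct" if batch_correct else "monitor")
    return corrected, summary


def batch_qc_correct(quant: pd.DataFrame, mode: str = "monitor",
                     value_col: str = "normalized_ratio"
                     ) -> tuple[pd.DataFrame, BatchQCSummary]:
    """Monitor or correct per-batch drift with pooled QC samples.

    monitor: report per-batch QC-pool mean ratios and the across-batch CV per
    peptide; values pass through unchanged. correct: multiply every batch's
    values by (grand QC mean / batch QC mean) per peptide, which equalizes
    QC-pool means across batches.
    """
    if mode not in ("monitor", "correct"):
        raise ValueError(f"unknown mode {mode!r}")
    df = quant.copy()
    qc = df[df["is_qc_pool"] & ~df[value_col].isna()]
    batches = sorted(df["batch_id"].unique())
    peptides = sorted(df["peptide_id"].unique())
    means = qc.pivot_table(index="peptide_id", columns="batch_id",
                           values=value_col, aggfunc="mean")
    means = means.reindex(index=peptides, columns=batches)
    if mode == "correct":
        no_qc = [b for b in batches
                 if b not in means.columns or means[b].isna().all()]
        if no_qc:
            raise ValueError(f"batches without QC pools: {no_qc}")
    grand = means.mean(axis=1)
    factors = grand.to_numpy()[:, None] / means
    with np.errstate(invalid="ignore"):
        cv = 100.0 * means.std(axis=1, ddof=1) / means.mean(axis=1)
    summary = BatchQCSummary(batch_means=means, correction_factors=factors,
                             cv_across_batches=cv, mode=mode)
    df["corrected_ratio"] = df[value_col]
    if mode == "correct":
        f = factors.stack().rename("f").reset_index()
        f.columns = ["peptide_id", "batch_id", "f"]
        df = df.merge(f, on=["peptide_id", "batch_id"], how="left")
        df["corrected_ratio"] = df[value_col] * df.pop("f")
    return df, summary
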