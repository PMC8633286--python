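"""Shotgun-stage discovery screen and SRM candidate selection.

Implements the funnel that turns a discovery peptide intensity matrix into a
shortlist of SRM assay candidates: a detection-fraction filter (intensity
above the detection limit in at least a given fraction of samples), a
Mann-Whitney differential screen between two diagnostic groups, a
direction-agnostic fold ratio, and the 7-criterion candidate selection
(p < 0.05; fold ratio >= 1.5; detection >= 75% in both compared groups;
length <= 20 residues; protein uniqueness; knowledge-base presence; no
sequence liabilities).

Sequence liabilities are residues or motifs that destabilise targeted
quantification: methionine and cysteine (oxidation-prone), an NG dipeptide
(deamidation-prone asparagine), and an N-terminal Q or E (pyroglutamate
formation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import mann_whitney

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

LIABILITY_MET = "MET"
LIABILITY_CYS = "CYS"
LIABILITY_DEAMIDATION = "DEAMIDATION_MOTIF"
LIABILITY_NTERM = "NTERM_CYCLIZATION"


@dataclass
class PeptideAnnotation:
    sequence: str
    protein_name: str = ""
    is_unique: bool = True
    in_knowledge_base: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"invalid residues in sequence: {sorted(bad)}")


@dataclass
class DifferentialRecord:
    peptide_id: str
    means: dict  # group -> mean of non-missing intensities
    sds: dict
    p_value: float | None
    fold_ratio_value: float | None
    testable: bool = True


@dataclass
class CandidateDecision:
    peptide_id: str
    c1_pvalue: bool
    c2_ratio: bool
    c3_detection: bool
    c4_length: bool
    c5_unique: bool
    c6_knowledge_base: bool
    c7_liability: bool
    liability_reasons: list = field(default_factory=list)
    error: str | None = None

    @property
    def selected(self) -> bool:
        return all((self.c1_pvalue, self.c2_ratio, self.c3_detection,
                    self.c4_length, self.c5_unique, self.c6_knowledge_base,
                    self.c7_liability)) and self.error is None


def _detection_counts(matrix: pd.DataFrame, group_of: pd.Series,
                      zero_is_missing: bool = True):
    """Per-peptide observed counts and group sizes; zeros count as missing."""
    vals = matrix.to_numpy(dtype=float)
    observed = ~np.isnan(vals)
    if zero_is_missing:
        observed &= vals != 0
    groups = group_of.reindex(matrix.columns)
    if groups.isna().any():
        missing = list(matrix.columns[groups.isna()])
        raise ValueError(f"samples without group label: {missing}")
    return observed, groups


def filter_detection(matrix: pd.DataFrame, group_of: pd.Series,
                     min_fraction: float = 0.75, scope: str = "one_group",
                     groups: list | None = None) -> list:
    """Peptides detected in >= ``min_fraction`` of samples per group scope.

    ``scope='one_group'`` keeps a peptide if the detected fraction reaches the
    threshold in at least one of the listed groups; ``'both_groups'`` requires
    it in every listed group. Fractions are compared inclusively on exact
    counts.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in (0, 1]")
    if scope not in ("one_group", "both_groups"):
        raise ValueError(f"unknown scope {scope!r}")
    observed, grp = _detection_counts(matrix, group_of)
    if groups is None:
        groups = list(dict.fromkeys(grp.tolist()))
    fracs = []
    for g in groups:
        sel = (grp == g).to_numpy()
        if sel.sum() == 0:
            raise ValueError(f"group {g!r} has no samples in the matrix")
        fracs.append(observed[:, sel].sum(axis=1) / sel.sum())
    fracs = np.column_stack(fracs)
    keep = (fracs >= min_fraction).any(axis=1) if scope == "one_group" \
        else (fracs >= min_fraction).all(axis=1)
    return [pid for pid, k in zip(matrix.index, keep) if k]


def fold_ratio(mean_a: float, mean_b: float) -> float:
    """Direction-agnostic fold ratio: max(mean_a, mean_b) / min(...) >= 1."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("group means must be positive")
    return max(mean_a, mean_b) / min(mean_a, mean_b)


def differential_test(matrix: pd.DataFrame, group_of: pd.Series,
                      group_a: str = "PD", group_b: str = "MSA",
                      extra_groups: tuple = ("control",)) -> list[DifferentialRecord]:
    """Mann-Whitney screen of ``group_a`` vs ``group_b`` per peptide.

    Group means and SDs use non-missing values only; peptides with fewer than
    two non-missing values in either compared group are flagged untestable and
    carry no p value.
    """
    observed, grp = _detection_counts(matrix, group_of)
    vals = matrix.to_numpy(dtype=float)
    records = []
    report_groups = [g for g in (*extra_groups, group_a, group_b)
                     if (grp == g).any()]
    sel = {g: (grp == g).to_numpy() for g in report_groups}
    for i, pid in enumerate(matrix.index):
        means, sds = {}, {}
        for g in report_groups:
            v = vals[i, sel[g]]
            v = v[observed[i, sel[g]]]
            means[g] = float(np.mean(v)) if v.size else float("nan")
            sds[g] = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
        va = vals[i, sel[group_a]][observed[i, sel[group_a]]]
        vb = vals[i, sel[group_b]][observed[i, sel[group_b]]]
        if va.size < 2 or vb.size < 2:
            records.append(DifferentialRecord(pid, means, sds, None, None,
                                              testable=False))
            continue
        p = mann_whitney(va, vb).p_raw
        fr = fold_ratio(float(va.mean()), float(vb.mean()))
        records.append(DifferentialRecord(pid, means, sds, p, fr))
    return records


def sequence_liability_check(sequence: str) -> list[str]:
    """Liability codes for a tryptic peptide sequence (empty list = clean)."""
    bad = set(sequence) - AMINO_ACIDS
    if not sequence or bad:
        raise ValueError(f"invalid sequence {sequence!r}")
    codes = []
    if sequence[0] in ("Q", "E"):
        codes.append(LIABILITY_NTERM)
    if "M" in sequence:
        codes.append(LIABILITY_MET)
    if "C" in sequence:
        codes.append(LIABILITY_CYS)
    if "NG" in sequence:
        codes.append(LIABILITY_DEAMIDATION)
    return codes


def select_candidates(differentials: list[DifferentialRecord],
                      annotations: dict, matrix: pd.DataFrame,
                      group_of: pd.Series,
                      p_cutoff: float = 0.05, ratio_cutoff: float = 1.5,
                      detection_fraction: float = 0.75, max_length: int = 20,
                      group_a: str = "PD", group_b: str = "MSA",
                      ) -> list[CandidateDecision]:
    """Apply the 7 SRM selection criteria to every screened peptide.

    A peptide is selected iff all seven hold: (1) differential p below the
    cutoff, (2) fold ratio at least the cutoff, (3) detection at or above the
    fraction in *both* compared groups, (4) sequence length at most
    ``max_length``, (5) unique protein assignment, (6) knowledge-base
    presence, (7) no sequence liabilities. Peptides lacking an annotation get
    an error entry; the run continues.
    """
    detected_both = set(filter_detection(matrix, group_of,
                                         min_fraction=detection_fraction,
                                         scope="both_groups",
                                         groups=[group_a, group_b]))
    out = []
    for rec in differentials:
        ann = annotations.get(rec.peptide_id)
        if ann is None:
            out.append(CandidateDecision(rec.peptide_id, False, False, False,
                                         False, False, False, False,
                                         error="missing annotation"))
            continue
        liabilities = sequence_liability_check(ann.sequence)
        out.append(CandidateDecision(
            peptide_id=rec.peptide_id,
            c1_pvalue=rec.testable and rec.p_value is not None
            and rec.p_value < p_cutoff,
            c2_ratio=rec.fold_ratio_value is not None
            and rec.fold_ratio_value >= ratio_cutoff,
            c3_detection=rec.peptide_id in detected_both,
            c4_length=len(ann.sequence) <= max_length,
            c5_unique=bool(ann.is_unique),
            c6_knowledge_base=bool(ann.in_knowledge_base),
            c7_liability=not liabilities,
            liability_reasons=liabilities,
        ))
    return out


def decisions_frame(decisions: list[CandidateDecision]) -> pd.DataFrame:
    rows = [{
        "peptide_id": d.peptide_id, "c1_pvalue": d.c1_pvalue,
        "c2_ratio": d.c2_ratio, "c3_detection": d.c3_detection,
        "c4_length": d.c4_length, "c5_unique": d.c5_unique,
        "c6_knowledge_base": d.c6_knowledge_base, "c7_liability": d.c7_liability,
        "selected": d.selected,
        "liability_reasons": ";".join(d.liability_reasons),
        "error": d.error or "",
    } for d in decisions]
    return pd.DataFrame(rows).set_index("peptide_id")


def differentials_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"peptide_id": r.peptide_id, "p_value": r.p_value,
               "fold_ratio": r.fold_ratio_value, "testable": r.testable}
        for g, m in r.means.items():
            row[f"mean_{g}"] = m
        for g, s in r.sds.items():
            row[f"sd_{g}"] = s
        rows.append(row)
    return pd.DataFrame(rows).set_index("peptide_id")
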