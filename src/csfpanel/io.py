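"""Tabular readers/writers, schema validation and pipeline orchestration.

Conventions: TSV for matrices and result tables, CSV for metadata and
transition reports; UTF-8; decimal point "."; missing values accepted as
empty string, "NA" or "NaN" and written as "NA". Group labels are a
case-sensitive controlled vocabulary with a configurable alias map
(e.g. "HC" -> control).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discovery, models, srm, stats, synthetic, validation

NA_VALUES = ["", "NA", "NaN", "nan"]
GROUP_ALIASES = {"HC": "control", "CTRL": "control", "Control": "control"}

SCHEMAS = {
    "metadata": {"index": "sample_id", "sep": ",",
                 "required": ["group"], "numeric": ["age", "total_protein"]},
    "intensity_matrix": {"index": "peptide_id", "sep": "\t",
                         "required": [], "numeric": "all"},
    "srm_report": {"index": None, "sep": ",",
                   "required": ["sample_id", "peptide_id", "transition_id",
                                "label", "area"], "numeric": ["area"]},
    "annotations": {"index": "peptide_id", "sep": ",",
                    "required": ["sequence"], "numeric": []},
    "features": {"index": "sample_id", "sep": ",",
                 "required": ["label"], "numeric": []},
    "quant": {"index": None, "sep": "\t",
              "required": ["sample_id", "peptide_id", "ratio"], "numeric": []},
}


def read_table(path: str | Path, schema_id: str,
               group_aliases: dict | None = None) -> pd.DataFrame:
    """Read and validate one of the pipeline's tabular inputs.

    Unknown schema ids, absent required columns, duplicate keys and basic
    type violations (negative age or total protein) raise with coordinates.
    """
    if schema_id not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_id!r}")
    schema = SCHEMAS[schema_id]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=schema["sep"], na_values=NA_VALUES,
                     keep_default_na=False)
    if schema["index"]:
        if schema["index"] not in df.columns:
            # tolerate an unnamed first column holding the index
            df = df.rename(columns={df.columns[0]: schema["index"]})
        dup = df[schema["index"]].duplicated()
        if dup.any():
            rows = (np.where(dup)[0] + 2).tolist()
            raise ValueError(f"{path.name}: duplicate {schema['index']} "
                             f"at file rows {rows}")
        df = df.set_index(schema["index"])
    for col in schema["required"]:
        if col not in df.columns:
            raise ValueError(f"{path.name}: required column {col!r} missing")
    numeric = (list(df.columns) if schema["numeric"] == "all"
               else [c for c in schema["numeric"] if c in df.columns])
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path.name}: column {col!r} not numeric: {exc}")
    if schema_id == "metadata":
        aliases = {**GROUP_ALIASES, **(group_aliases or {})}
        df["group"] = df["group"].replace(aliases)
        if "age" in df.columns:
            bad = df.index[df["age"] <= 0].tolist()
            if bad:
                raise ValueError(f"{path.name}: non-positive age for rows {bad}")
        if "total_protein" in df.columns:
            bad = df.index[df["total_protein"].notna()
                           & (df["total_protein"] <= 0)].tolist()
            if bad:
                raise ValueError(
                    f"{path.name}: non-positive total_protein for rows {bad}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema_id: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = SCHEMAS[schema_id]["sep"] if schema_id in SCHEMAS else "\t"
    df.to_csv(path, sep=sep, na_rep="NA",
              index=SCHEMAS.get(schema_id, {}).get("index") is not None)
    return path


@dataclass
class PipelineConfig:
    outdir: str = "runs/run1"
    seed: int = 0
    p_cutoff: float = 0.05
    ratio_cutoff: float = 1.5
    detection_fraction: float = 0.75
    max_length: int = 20
    r2_min: float = 0.7
    cv_max: float = 20.0
    split_fraction: float = 0.7
    n_trees: int = 500
    protein_scale: float = 1000.0
    batch_correct: bool = False
    stages: tuple = ("simulate", "discover", "srm-qc", "srm-quant",
                     "stats", "model")
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides

    def validate(self) -> None:
        checks = [
            ("p_cutoff", 0 < self.p_cutoff <= 1),
            ("ratio_cutoff", self.ratio_cutoff >= 1),
            ("detection_fraction", 0 < self.detection_fraction <= 1),
            ("max_length", self.max_length >= 1),
            ("r2_min", 0 <= self.r2_min <= 1),
            ("cv_max", self.cv_max > 0),
            ("split_fraction", 0 < self.split_fraction < 1),
            ("n_trees", self.n_trees >= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"config field {name} out of range")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages in order; returns the manifest.

    Stage order: simulate -> discover -> srm-qc -> srm-quant -> stats ->
    model. Later stages read earlier stages' outputs from the run directory;
    requesting a stage whose prerequisite outputs are absent raises naming
    the missing stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {},
                      "thresholds": {
                          "p_cutoff": config.p_cutoff,
                          "ratio_cutoff": config.ratio_cutoff,
                          "detection_fraction": config.detection_fraction,
                          "max_length": config.max_length,
                          "r2_min": config.r2_min, "cv_max": config.cv_max,
                          "split_fraction": config.split_fraction}}

    def record(stage: str, **paths: Path) -> None:
        manifest["stages"].append(stage)
        for k, p in paths.items():
            manifest["outputs"][f"{stage}.{k}"] = {"path": str(p),
                                                   "sha256": _digest(Path(p))}

    def need(path: Path, stage: str, prerequisite: str) -> Path:
        if not Path(path).exists():
            raise FileNotFoundError(
                f"stage {stage!r} requires output of stage {prerequisite!r}: "
                f"{path} not found")
        return Path(path)

    if "simulate" in config.stages:
        sim_cfg = synthetic.SimulationConfig(seed=config.seed,
                                             **config.simulate)
        cohort = synthetic.generate_cohort(sim_cfg)
        paths = synthetic.write_cohort(cohort, outdir)
        record("simulate", **{k: Path(v) for k, v in paths.items()})

    if "discover" in config.stages:
        matrix = read_table(need(outdir / "intensity_matrix.tsv", "discover",
                                 "simulate"), "intensity_matrix")
        meta = read_table(outdir / "metadata.csv", "metadata")
        diffs = discovery.differential_test(matrix, meta["group"])
        dframe = discovery.differentials_frame(diffs)
        p1 = write_table(dframe, outdir / "differentials.tsv", "quant")
        ann_path = outdir / "annotations.csv"
        if ann_path.exists():
            ann_df = read_table(ann_path, "annotations")
            annotations = {pid: discovery.PeptideAnnotation(
                sequence=row["sequence"], protein_name=row.get("protein", ""),
                is_unique=bool(row.get("unique", 1)),
                in_knowledge_base=bool(row.get("knowledge_base", 1)))
                for pid, row in ann_df.iterrows()}
            decisions = discovery.select_candidates(
                diffs, annotations, matrix, meta["group"],
                p_cutoff=config.p_cutoff, ratio_cutoff=config.ratio_cutoff,
                detection_fraction=config.detection_fraction,
                max_length=config.max_length)
            p2 = write_table(discovery.decisions_frame(decisions),
                             outdir / "candidates.tsv", "quant")
            record("discover", differentials=p1, candidates=p2)
        else:
            record("discover", differentials=p1)

    if "srm-qc" in config.stages:
        cal = synthetic.generate_calibration_series(seed=config.seed)
        reps = {cid: synthetic.generate_replicate_set(
            1.0, validation.CRITERION_MIN_N[cid], 8.0,
            seed=config.seed + i + 1)
            for i, cid in enumerate(validation.CRITERION_MIN_N)}
        bundle = {"PEP001": {"LINEARITY": cal, **reps}}
        report = validation.validate_assay(bundle, r2_min=config.r2_min,
                                           cv_max=config.cv_max)
        p = write_table(validation.report_frame(report),
                        outdir / "assay_validation.tsv", "quant")
        (outdir / "assay_validation.json").write_text(json.dumps(
            {"excluded": report.excluded}, indent=2))
        record("srm-qc", report=p)

    if "srm-quant" in config.stages:
        rep = read_table(need(outdir / "srm_report.csv", "srm-quant",
                              "simulate"), "srm_report")
        meta = read_table(outdir / "metadata.csv", "metadata")
        quant, qc = srm.quantify(rep, meta, protein_scale=config.protein_scale,
                                 batch_correct=config.batch_correct)
        p = write_table(quant, outdir / "quantities.tsv", "quant")
        (outdir / "batch_qc.json").write_text(json.dumps({
            "mode": qc.mode,
            "cv_across_batches": {str(k): (None if np.isnan(v) else float(v))
                                  for k, v in qc.cv_across_batches.items()},
        }, indent=2))
        record("srm-quant", quantities=p)

    if "stats" in config.stages:
        quant = read_table(need(outdir / "quantities.tsv", "stats",
                                "srm-quant"), "quant")
        meta = read_table(outdir / "metadata.csv", "metadata")
        p = write_table(peptide_statistics(quant, meta),
                        outdir / "statistics.tsv", "quant")
        record("stats", statistics=p)

    if "model" in config.stages:
        table, labels = synthetic.generate_feature_table(seed=config.seed)
        specs = [models.ModelSpec(dataset_id=d, seed=config.seed,
                                  n_trees=config.n_trees,
                                  split_fraction=config.split_fraction)
                 for d in (1, 2, 3, 4)]
        _, comparison = models.run_model_suite(table, labels, specs)
        p = write_table(comparison.reset_index(),
                        outdir / "model_comparison.tsv", "quant")
        record("model", comparison=p)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def peptide_statistics(quant: pd.DataFrame, metadata: pd.DataFrame,
                       value_col: str = "corrected_ratio") -> pd.DataFrame:
    """Per-peptide group summary: means +- SD, age-adjusted omnibus p,
    pairwise PD-vs-AP p (rank ANCOVA, Bonferroni) and plain Mann-Whitney
    PD-vs-AP / PD-vs-MSA p, and the PD-vs-AP AUC (AP positive)."""
    df = quant[~quant["is_qc_pool"]].merge(
        metadata[["group", "age"]], left_on="sample_id", right_index=True)
    df["ap"] = df["group"].map(lambda g: "AP" if g in ("MSA", "PSP") else g)
    rows = []
    for pid, sub in df.groupby("peptide_id"):
        sub = sub[~sub[value_col].isna()]
        row: dict = {"peptide_id": pid}
        for g, gs in sub.groupby("group"):
            row[f"mean_{g}"] = gs[value_col].mean()
            row[f"sd_{g}"] = gs[value_col].std(ddof=1)
        three = sub[sub["ap"].isin(["control", "PD", "AP"])]
        try:
            anc = stats.rank_ancova(three[value_col], three["ap"], three["age"])
            row["p_omnibus_rank_ancova"] = anc.p_omnibus
            for pw in anc.pairwise:
                if set(pw.comparison.split(" vs ")) == {"PD", "AP"}:
                    row["p_pd_vs_ap_adj"] = pw.p_adjusted
        except ValueError:
            row["p_omnibus_rank_ancova"] = np.nan
        pd_v = sub.loc[sub["group"] == "PD", value_col]
        ap_v = sub.loc[sub["ap"] == "AP", value_col]
        msa_v = sub.loc[sub["group"] == "MSA", value_col]
        if len(pd_v) >= 2 and len(ap_v) >= 2:
            row["p_pd_vs_ap_mw"] = stats.mann_whitney(pd_v, ap_v).p_raw
            sel = sub[sub["ap"].isin(["PD", "AP"])]
            row["auc_pd_vs_ap"] = stats.roc_auc(
                sel[value_col].to_numpy(), sel["ap"].to_numpy(), "AP",
                auto_orient=True).auc
        if len(pd_v) >= 2 and len(msa_v) >= 2:
            row["p_pd_vs_msa_mw"] = stats.mann_whitney(pd_v, msa_v).p_raw
        rows.append(row)
    return pd.DataFrame(rows).set_index("peptide_id").reset_index()
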