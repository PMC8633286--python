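"""Synthetic CSF cohort generator.

Emulates the statistical structure of a two-stage CSF tryptic-peptide
biomarker study so the full pipeline (discovery screen, SRM quantification,
assay validation, statistics, multivariate models) runs without any raw
mass-spectrometry data:

* log-normal peptide intensities with planted group fold changes,
* peptide-age association induced through a Gaussian-copula latent factor
  calibrated to a target Spearman correlation,
* left-censored missingness (values below a per-peptide quantile of the
  pooled distribution become missing, never zero),
* per-group total CSF protein distributions,
* an SRM transition-level report with heavy-labelled internal standards,
  digestion batches and pooled QC samples,
* calibration dilution series and technical replicate sets for assay QC.

Defaults mirror the validation cohort of the study design this package
models: group sizes control/PD/MSA/PSP = 39/46/17/8, total protein means of
roughly 426/533/511/724 mg/L, and a heavy-peptide dilution series of
0-40 fmol in three replicates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("control", "PD", "MSA", "PSP")

#: Table-scale total protein (mg/L) per diagnostic group: (mean, sd).
DEFAULT_TOTAL_PROTEIN = {
    "control": (425.6, 211.2),
    "PD": (533.2, 164.7),
    "MSA": (510.7, 157.6),
    "PSP": (723.8, 366.1),
}

DEFAULT_N_PER_GROUP = {"control": 39, "PD": 46, "MSA": 17, "PSP": 8}

#: Heavy-peptide calibration dilution series in fmol.
CALIBRATION_LEVELS_FMOL = (0.0, 0.625, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0)


@dataclass(frozen=True)
class PlantedEffect:
    """A group-level fold change planted on one peptide.

    ``direction='up'`` multiplies the affected group's level by
    ``fold_change``; ``'down'`` divides it.
    """

    peptide_id: str
    affected_group: str
    fold_change: float
    direction: str = "down"


@dataclass
class SimulationConfig:
    n_per_group: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    n_peptides: int = 32
    age_mean: float = 60.0
    age_sd: float = 10.0
    planted_effects: list = field(default_factory=list)
    age_rho: dict = field(default_factory=dict)  # peptide_id -> target Spearman rho
    missing_censor_quantile: float = 0.1
    cv_technical: float = 10.0  # percent, replicate noise on SRM areas
    sigma_log: float = 0.8  # biological log-scale sd of discovery intensities
    srm_sigma_log: float = 0.4  # biological log-scale sd of SRM ratios
    total_protein: dict = field(default_factory=lambda: dict(DEFAULT_TOTAL_PROTEIN))
    n_batches: int = 5
    n_transitions: int = 3
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"n_per_group: unknown group {g!r}")
            if n < 2:
                raise ValueError(f"n_per_group: group {g!r} needs >= 2 samples, got {n}")
        for eff in self.planted_effects:
            if eff.fold_change < 1.0:
                raise ValueError(
                    f"planted_effects: fold_change must be >= 1, got {eff.fold_change}")
            if eff.direction not in ("up", "down"):
                raise ValueError(f"planted_effects: direction {eff.direction!r}")
            if eff.affected_group not in self.n_per_group:
                raise ValueError(
                    f"planted_effects: group {eff.affected_group!r} not simulated")
        if not (0.0 <= self.missing_censor_quantile < 1.0):
            raise ValueError("missing_censor_quantile must lie in [0, 1)")
        if self.cv_technical < 0:
            raise ValueError("cv_technical must be >= 0")
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        for pid, rho in self.age_rho.items():
            if not (-0.99 <= rho <= 0.99):
                raise ValueError(f"age_rho[{pid!r}] outside [-0.99, 0.99]")


@dataclass
class SyntheticCohort:
    metadata: pd.DataFrame
    discovery_matrix: pd.DataFrame  # peptides x samples, NaN = below detection
    srm_report: pd.DataFrame  # transition-level long table
    truth: dict

    def content_digest(self) -> str:
        h = hashlib.sha256()
        for df in (self.metadata, self.discovery_matrix, self.srm_report):
            h.update(df.to_csv().encode())
        h.update(json.dumps(self.truth, sort_keys=True).encode())
        return h.hexdigest()


def _copula_pearson(rho_spearman: float) -> float:
    # Bivariate-normal identity rho_S = (6/pi) asin(r/2); invert exactly.
    return 2.0 * np.sin(np.pi * rho_spearman / 6.0)


def _lognormal_cv_sigma(cv_percent: float) -> float:
    c = cv_percent / 100.0
    return float(np.sqrt(np.log1p(c * c)))


def _mult_noise(rng: np.random.Generator, cv_percent: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the stated CV."""
    if cv_percent == 0:
        return np.ones(size)
    s = _lognormal_cv_sigma(cv_percent)
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate metadata, a discovery intensity matrix and an SRM report.

    Per peptide p and sample i the pre-censoring discovery intensity is

        I_pi = exp(mu_p + sigma_log * z_pi) * m_p(group_i)

    where z_pi = r*z_age,i + sqrt(1-r^2)*eps shares a latent standard-normal
    factor with age (r chosen so the Spearman correlation with age hits the
    configured target) and m_p is the planted group multiplier. Values below
    the ``missing_censor_quantile`` quantile of the peptide's pooled
    distribution are replaced by NaN. The SRM report carries the same
    group structure as endogenous/heavy transition areas, with the endogenous
    signal scaled by the sample's total protein so that protein normalization
    recovers the underlying relative level.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # one RNG stream per logical block so adding peptides leaves earlier draws alone
    rng_meta, rng_int, rng_cens, rng_srm = (
        np.random.default_rng(s) for s in root.spawn(4))

    groups_order = [g for g in GROUPS if g in config.n_per_group]
    sample_ids, group_of = [], []
    for g in groups_order:
        for i in range(config.n_per_group[g]):
            sample_ids.append(f"{g}_{i + 1:03d}")
            group_of.append(g)
    n = len(sample_ids)

    z_age = rng_meta.standard_normal(n)
    ages = np.clip(config.age_mean + config.age_sd * z_age, 18.0, None)
    sexes = rng_meta.choice(["M", "F"], size=n)
    protein = np.empty(n)
    for g in groups_order:
        sel = np.array([gg == g for gg in group_of])
        mu, sd = config.total_protein[g]
        protein[sel] = np.clip(rng_meta.normal(mu, sd, sel.sum()), 50.0, None)
    batches = np.array([f"B{1 + i % config.n_batches}" for i in range(n)])
    rng_meta.shuffle(batches)

    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "group": group_of,
        "age": np.round(ages, 1),
        "sex": sexes,
        "total_protein": np.round(protein, 1),
        "batch_id": batches,
    }).set_index("sample_id")

    peptide_ids = [f"PEP{p + 1:03d}" for p in range(config.n_peptides)]
    effects = {e.peptide_id: e for e in config.planted_effects}
    for pid in effects:
        if pid not in peptide_ids:
            peptide_ids.append(pid)
    for pid in config.age_rho:
        if pid not in peptide_ids:
            peptide_ids.append(pid)

    grp_arr = np.array(group_of)
    values = np.empty((len(peptide_ids), n))
    mu_base = rng_int.uniform(np.log(1e5), np.log(1e7), size=len(peptide_ids))
    for pi, pid in enumerate(peptide_ids):
        rho_s = config.age_rho.get(pid, 0.0)
        r = _copula_pearson(rho_s)
        eps = rng_int.standard_normal(n)
        z = r * z_age + np.sqrt(max(0.0, 1.0 - r * r)) * eps
        level = np.exp(mu_base[pi] + config.sigma_log * z)
        eff = effects.get(pid)
        if eff is not None:
            mult = eff.fold_change if eff.direction == "up" else 1.0 / eff.fold_change
            level = np.where(grp_arr == eff.affected_group, level * mult, level)
        values[pi] = level

    pre_censor_means = values.mean(axis=1)
    observed = values.copy()
    if config.missing_censor_quantile > 0:
        cut = np.quantile(values, config.missing_censor_quantile, axis=1)
        observed[values < cut[:, None]] = np.nan
    _ = rng_cens  # stream reserved for stochastic censoring variants

    discovery = pd.DataFrame(observed, index=pd.Index(peptide_ids, name="peptide_id"),
                             columns=sample_ids)

    srm_report = _generate_srm_report(config, metadata, peptide_ids, effects,
                                      z_age, rng_srm)

    truth = {
        "planted_effects": [
            {"peptide_id": e.peptide_id, "affected_group": e.affected_group,
             "fold_change": e.fold_change, "direction": e.direction}
            for e in config.planted_effects
        ],
        "age_rho": dict(config.age_rho),
        "pre_censor_means": {pid: float(m) for pid, m in
                             zip(peptide_ids, pre_censor_means)},
    }
    return SyntheticCohort(metadata=metadata, discovery_matrix=discovery,
                           srm_report=srm_report, truth=truth)


def _generate_srm_report(config, metadata, peptide_ids, effects, z_age, rng):
    """Endogenous/heavy transition areas per sample, plus per-batch QC pools."""
    n = len(metadata)
    grp_arr = metadata["group"].to_numpy()
    protein_g_l = metadata["total_protein"].to_numpy() / 1000.0
    trans_resp = rng.uniform(0.3, 1.0, size=(len(peptide_ids), config.n_transitions))
    heavy_base = rng.uniform(5e4, 5e5, size=len(peptide_ids))
    base_ratio = rng.uniform(0.05, 3.0, size=len(peptide_ids))

    rows = []
    for pi, pid in enumerate(peptide_ids):
        eps = rng.standard_normal(n)
        rho_s = config.age_rho.get(pid, 0.0)
        r = _copula_pearson(rho_s)
        z = r * z_age + np.sqrt(max(0.0, 1.0 - r * r)) * eps
        s = config.srm_sigma_log
        rel = base_ratio[pi] * np.exp(s * z - 0.5 * s * s)
        eff = effects.get(pid)
        if eff is not None:
            mult = eff.fold_change if eff.direction == "up" else 1.0 / eff.fold_change
            rel = np.where(grp_arr == eff.affected_group, rel * mult, rel)
        # measured endogenous signal scales with total protein (g/L); the
        # pipeline's protein normalization divides it back out
        endo_level = rel * protein_g_l
        for t in range(config.n_transitions):
            noise_h = _mult_noise(rng, config.cv_technical, n)
            noise_e = _mult_noise(rng, config.cv_technical, n)
            h_area = heavy_base[pi] * trans_resp[pi, t] * noise_h
            e_area = heavy_base[pi] * trans_resp[pi, t] * endo_level * noise_e
            for i, sid in enumerate(metadata.index):
                rows.append((sid, pid, f"T{t + 1}", "heavy", h_area[i],
                             metadata["batch_id"].iloc[i], False))
                rows.append((sid, pid, f"T{t + 1}", "endogenous", e_area[i],
                             metadata["batch_id"].iloc[i], False))
        # two pooled QC samples per digestion batch, at the pooled mean level
        qc_level = float(np.mean(rel)) * float(np.mean(protein_g_l))
        for b in sorted(metadata["batch_id"].unique()):
            for q in (1, 2):
                for t in range(config.n_transitions):
                    nh = _mult_noise(rng, config.cv_technical, 1)[0]
                    ne = _mult_noise(rng, config.cv_technical, 1)[0]
                    rows.append((f"QCpool_{b}_{q}", pid, f"T{t + 1}", "heavy",
                                 heavy_base[pi] * trans_resp[pi, t] * nh, b, True))
                    rows.append((f"QCpool_{b}_{q}", pid, f"T{t + 1}", "endogenous",
                                 heavy_base[pi] * trans_resp[pi, t] * qc_level * ne,
                                 b, True))
    return pd.DataFrame(rows, columns=["sample_id", "peptide_id", "transition_id",
                                       "label", "area", "batch_id", "is_qc_pool"])


def generate_calibration_series(levels=CALIBRATION_LEVELS_FMOL, n_replicates: int = 3,
                                noise_cv: float = 5.0, seed: int = 0,
                                peptide_id: str = "PEP001",
                                response: float = 1e4) -> pd.DataFrame:
    """Simulated calibration dilution series (area ~ response * fmol).

    Returns a long table (peptide, conc_fmol, replicate, area) with
    multiplicative noise of the stated CV. Requires at least 3 distinct
    concentration levels so a line can be fitted downstream.
    """
    levels = [float(v) for v in levels]
    if any(v < 0 for v in levels):
        raise ValueError("levels must be non-negative")
    if len(set(levels)) < 3:
        raise ValueError("need >= 3 distinct concentration levels to assess linearity")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in levels:
        noise = _mult_noise(rng, noise_cv, n_replicates)
        for rep in range(1, n_replicates + 1):
            rows.append((peptide_id, conc, rep, response * conc * noise[rep - 1]))
    return pd.DataFrame(rows, columns=["peptide_id", "conc_fmol", "replicate", "area"])


def generate_replicate_set(true_value: float, n: int, cv_target: float,
                           seed: int = 0) -> np.ndarray:
    """Technical replicates of a peptide ratio with the stated expected CV."""
    if n < 2:
        raise ValueError("n must be >= 2 (a single value has no CV)")
    if cv_target < 0:
        raise ValueError("cv_target must be >= 0")
    rng = np.random.default_rng(seed)
    return true_value * _mult_noise(rng, cv_target, n)


def generate_feature_table(n_pd: int = 46, n_ap: int = 25, n_peptides: int = 14,
                           peptide_effects: dict | None = None,
                           marker_effects: dict | None = None,
                           missing_rate: float = 0.0,
                           sigma_log: float = 0.4,
                           seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Merged PD-vs-AP feature table for the multivariate models.

    Columns: ``pep_*`` peptide relative quantities (log-normal, optional
    per-peptide fold change applied to the AP group), biochemical markers
    (NfL, alpha_syn, abeta42, t_tau, p_tau; standard-normal z scores with an
    optional standardized AP shift from ``marker_effects``), binary rt_quic,
    clinical scores (UPDRS, ICARS, MMSE, hoehn_yahr) and age. Missing cells
    are introduced completely at random at ``missing_rate`` on the peptide and
    marker columns. Returns (features, labels) with labels in {PD, AP}.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = n_pd + n_ap
    labels = pd.Series(["PD"] * n_pd + ["AP"] * n_ap,
                       index=[f"S{i + 1:03d}" for i in range(n)], name="label")
    is_ap = (labels == "AP").to_numpy()
    data = {}
    peptide_effects = peptide_effects or {}
    for j in range(n_peptides):
        name = f"pep_{j + 1:02d}"
        base = rng.uniform(0.05, 3.0)
        vals = base * np.exp(sigma_log * rng.standard_normal(n)
                             - 0.5 * sigma_log**2)
        fold = peptide_effects.get(name, 1.0)
        if fold != 1.0:
            vals = np.where(is_ap, vals / fold, vals)  # AP lower, as observed
        data[name] = vals
    marker_effects = marker_effects or {}
    for mk in ("NfL", "alpha_syn", "abeta42", "t_tau", "p_tau"):
        shift = marker_effects.get(mk, 0.0)
        data[mk] = rng.standard_normal(n) + shift * is_ap
    q_prob = np.where(is_ap, 0.5, 0.5 + marker_effects.get("rt_quic", 0.0))
    data["rt_quic"] = (rng.uniform(size=n) < q_prob).astype(float)
    data["UPDRS"] = np.clip(rng.normal(28, 12, n)
                            + marker_effects.get("UPDRS", 0.0) * is_ap, 0, None)
    data["ICARS"] = np.clip(rng.normal(3, 3, n)
                            + marker_effects.get("ICARS", 0.0) * is_ap, 0, None)
    data["MMSE"] = np.clip(rng.normal(28, 2.2, n), 0, 30)
    data["hoehn_yahr"] = np.clip(np.round(rng.normal(2, 0.8, n)), 1, 5)
    data["age"] = np.clip(rng.normal(60, 10, n), 30, 90)
    table = pd.DataFrame(data, index=labels.index)
    if missing_rate > 0:
        cols = [c for c in table.columns if c.startswith("pep_")
                or c in ("NfL", "alpha_syn", "abeta42", "t_tau", "p_tau")]
        mask = rng.uniform(size=(n, len(cols))) < missing_rate
        # never blank out an entire column
        for j in range(len(cols)):
            if mask[:, j].all():
                mask[rng.integers(n), j] = False
        block = table[cols].to_numpy()
        block[mask] = np.nan
        table[cols] = block
    return table, labels


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write the three standard inputs plus a truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": outdir / "metadata.csv",
        "matrix": outdir / "intensity_matrix.tsv",
        "srm_report": outdir / "srm_report.csv",
        "truth": outdir / "truth.json",
    }
    cohort.metadata.to_csv(paths["metadata"], na_rep="NA")
    cohort.discovery_matrix.to_csv(paths["matrix"], sep="\t", na_rep="NA")
    cohort.srm_report.to_csv(paths["srm_report"], index=False, na_rep="NA")
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
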