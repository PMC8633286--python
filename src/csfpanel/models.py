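"""Random-forest discrimination models for PD vs atypical parkinsonism.

Four model datasets combine feature families: (1) the differential tryptic
peptides alone; (2) peptides plus established CSF biochemical markers (NfL,
alpha-synuclein, amyloid-beta 42, total tau, phosphorylated tau, RT-QuIC
status) and age; (3) peptides, markers and clinical assessments (UPDRS,
ICARS, MMSE, Hoehn-Yahr) with age; (4) markers plus clinical assessments with
age, without peptides. Each model imputes missing values with an
expectation-maximization fit of a multivariate-normal working model (with
optional bootstrap multiple imputation), splits the cohort 70/30 stratified
by diagnosis, fits a random forest on the training fold only, and reports the
held-out ROC AUC. Imputation and any importance-based feature retention are
fitted on the training fold and applied unchanged to the test fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .stats import roc_auc

PEPTIDE_PREFIX = "pep_"
MARKER_FEATURES = ("NfL", "alpha_syn", "abeta42", "t_tau", "p_tau", "rt_quic")
CLINICAL_FEATURES = ("UPDRS", "ICARS", "MMSE", "hoehn_yahr")

#: Feature families per model dataset.
DATASET_FAMILIES = {
    1: ("peptides",),
    2: ("peptides", "markers", "age"),
    3: ("peptides", "markers", "clinical", "age"),
    4: ("markers", "clinical", "age"),
}


@dataclass
class ModelSpec:
    dataset_id: int
    split_fraction: float = 0.7
    n_trees: int = 500
    seed: int = 0
    n_imputations: int = 1
    importance_selection: bool = False
    importance_quantile: float = 0.5

    @property
    def families(self) -> tuple:
        if self.dataset_id not in DATASET_FAMILIES:
            raise ValueError(f"unknown dataset_id {self.dataset_id}")
        return DATASET_FAMILIES[self.dataset_id]


@dataclass
class ModelResult:
    dataset_id: int
    train_ids: list
    test_ids: list
    held_out_auc: float
    feature_importances: dict
    retained_features: list
    n_imputed_cells: int
    error: str | None = None


class EMNormalImputer:
    """EM fit of a multivariate normal to data with missing entries.

    Fits the mean vector and covariance matrix by expectation-maximization
    (conditional means and covariances of the missing block given the
    observed block per row), then imputes either the conditional mean
    (``draw=False``) or a draw from the conditional normal. A ridge term
    keeps the covariance positive definite when features are few or highly
    collinear.
    """

    def __init__(self, max_iter: int = 60, tol: float = 1e-5,
                 ridge: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge
        self.mean_: np.ndarray | None = None
        self.cov_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "EMNormalImputer":
        x = np.asarray(x, dtype=float)
        n, p = x.shape
        if np.isnan(x).all(axis=0).any():
            j = int(np.where(np.isnan(x).all(axis=0))[0][0])
            raise ValueError(f"feature column {j} is fully missing")
        mu = np.nanmean(x, axis=0)
        var = np.nanvar(x, axis=0)
        var[var == 0] = 1.0
        sigma = np.diag(var)
        prev = -np.inf
        for _ in range(self.max_iter):
            ex = np.zeros((n, p))
            exx = np.zeros((p, p))
            for i in range(n):
                miss = np.isnan(x[i])
                xi = x[i].copy()
                ci = np.zeros((p, p))
                if miss.any():
                    obs = ~miss
                    soo = sigma[np.ix_(obs, obs)]
                    smo = sigma[np.ix_(miss, obs)]
                    smm = sigma[np.ix_(miss, miss)]
                    sol = np.linalg.solve(
                        soo + self.ridge * np.eye(obs.sum()),
                        (x[i, obs] - mu[obs]))
                    xi[miss] = mu[miss] + smo @ sol
                    cmm = smm - smo @ np.linalg.solve(
                        soo + self.ridge * np.eye(obs.sum()), smo.T)
                    ci[np.ix_(miss, miss)] = cmm
                ex[i] = xi
                exx += np.outer(xi, xi) + ci
            mu_new = ex.mean(axis=0)
            sigma_new = exx / n - np.outer(mu_new, mu_new)
            sigma_new += self.ridge * np.eye(p)
            delta = float(np.max(np.abs(mu_new - mu)))
            mu, sigma = mu_new, sigma_new
            if delta < self.tol and prev > -np.inf:
                break
            prev = delta
        self.mean_, self.cov_ = mu, sigma
        return self

    def transform(self, x: np.ndarray, rng: np.random.Generator | None = None,
                  draw: bool = False) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("imputer not fitted")
        x = np.asarray(x, dtype=float).copy()
        mu, sigma = self.mean_, self.cov_
        for i in range(x.shape[0]):
            miss = np.isnan(x[i])
            if not miss.any():
                continue
            obs = ~miss
            if obs.any():
                soo = sigma[np.ix_(obs, obs)] + self.ridge * np.eye(int(obs.sum()))
                smo = sigma[np.ix_(miss, obs)]
                cond_mean = mu[miss] + smo @ np.linalg.solve(soo, x[i, obs] - mu[obs])
                cond_cov = sigma[np.ix_(miss, miss)] - smo @ np.linalg.solve(soo, smo.T)
            else:
                cond_mean = mu[miss]
                cond_cov = sigma[np.ix_(miss, miss)]
            if draw and rng is not None:
                cond_cov = (cond_cov + cond_cov.T) / 2 + self.ridge * np.eye(int(miss.sum()))
                x[i, miss] = rng.multivariate_normal(cond_mean, cond_cov,
                                                     method="svd")
            else:
                x[i, miss] = cond_mean
        return x


def impute_missing(table: pd.DataFrame, n_imputations: int = 1, seed: int = 0,
                   bootstrap: bool = True) -> list[pd.DataFrame]:
    """EM/multivariate-normal multiple imputation of a numeric feature table.

    With ``n_imputations > 1`` each imputation refits the EM model on a
    bootstrap resample of the rows and fills missing cells with draws from
    the conditional normal; a single imputation uses conditional means from
    the full-data fit. Complete tables pass through unchanged.
    """
    if n_imputations < 1:
        raise ValueError("n_imputations must be >= 1")
    x = table.to_numpy(dtype=float)
    if not np.isnan(x).any():
        return [table.copy() for _ in range(n_imputations)]
    rng = np.random.default_rng(seed)
    out = []
    if n_imputations == 1:
        imp = EMNormalImputer().fit(x)
        out.append(pd.DataFrame(imp.transform(x), index=table.index,
                                columns=table.columns))
        return out
    n = x.shape[0]
    for _ in range(n_imputations):
        rows = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        imp = EMNormalImputer().fit(x[rows])
        out.append(pd.DataFrame(imp.transform(x, rng=rng, draw=True),
                                index=table.index, columns=table.columns))
    return out


def split_cohort(table: pd.DataFrame, labels: pd.Series, fraction: float = 0.7,
                 seed: int = 0, stratify: bool = True
                 ) -> tuple[pd.Index, pd.Index]:
    """Deterministic (per seed) stratified 70/30 split; returns index pairs."""
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples to split")
    train_idx, test_idx = train_test_split(
        table.index, train_size=fraction, random_state=seed,
        stratify=labels if stratify else None)
    return pd.Index(train_idx), pd.Index(test_idx)


def select_features(table: pd.DataFrame, families: tuple) -> list[str]:
    cols: list[str] = []
    if "peptides" in families:
        cols += [c for c in table.columns if c.startswith(PEPTIDE_PREFIX)]
    if "markers" in families:
        cols += [c for c in MARKER_FEATURES if c in table.columns]
    if "clinical" in families:
        cols += [c for c in CLINICAL_FEATURES if c in table.columns]
    if "age" in families and "age" in table.columns:
        cols.append("age")
    if not cols:
        raise ValueError(f"no feature columns found for families {families}")
    return cols


def fit_and_evaluate(spec: ModelSpec, table: pd.DataFrame, labels: pd.Series,
                     positive_label: str = "AP",
                     split: tuple | None = None) -> ModelResult:
    """Split, impute (train-fitted), fit the forest, report held-out AUC.

    With multiple imputations the held-out score of each sample is averaged
    over imputed completions before the AUC is computed. ``split`` accepts a
    precomputed (train_index, test_index) pair; otherwise a stratified
    70/30 split is drawn from the spec's seed.
    """
    cols = select_features(table, spec.families)
    x = table[cols]
    if split is not None:
        train_idx, test_idx = (pd.Index(split[0]), pd.Index(split[1]))
    else:
        train_idx, test_idx = split_cohort(x, labels,
                                           fraction=spec.split_fraction,
                                           seed=spec.seed)
    y_train = labels.loc[train_idx]
    y_test = labels.loc[test_idx]
    if y_test.nunique() < 2:
        raise ValueError("degenerate test set: one class only")
    rng = np.random.default_rng(spec.seed)
    xt = x.loc[train_idx].to_numpy(dtype=float)
    xs = x.loc[test_idx].to_numpy(dtype=float)
    n_missing = int(np.isnan(xt).sum() + np.isnan(xs).sum())

    scores = np.zeros(len(test_idx))
    importances = np.zeros(len(cols))
    retained = cols
    n_imp = spec.n_imputations if n_missing else 1
    for m in range(n_imp):
        if n_missing:
            rows = (rng.integers(0, len(xt), size=len(xt))
                    if n_imp > 1 else np.arange(len(xt)))
            imp = EMNormalImputer().fit(xt[rows])
            draw = n_imp > 1
            xt_c = imp.transform(xt, rng=rng, draw=draw)
            xs_c = imp.transform(xs, rng=rng, draw=draw)
        else:
            xt_c, xs_c = xt, xs
        clf = RandomForestClassifier(n_estimators=spec.n_trees,
                                     max_features="sqrt", max_depth=None,
                                     random_state=spec.seed + m)
        use_cols = list(range(len(cols)))
        if spec.importance_selection and len(cols) > 1:
            clf.fit(xt_c, y_train)
            pi = permutation_importance(clf, xt_c, y_train, n_repeats=10,
                                        random_state=spec.seed)
            cut = np.quantile(pi.importances_mean, spec.importance_quantile)
            use_cols = [i for i, v in enumerate(pi.importances_mean) if v >= cut]
            if not use_cols:
                use_cols = list(range(len(cols)))
            retained = [cols[i] for i in use_cols]
            clf = RandomForestClassifier(n_estimators=spec.n_trees,
                                         max_features="sqrt", max_depth=None,
                                         random_state=spec.seed + m)
        clf.fit(xt_c[:, use_cols], y_train)
        pos_col = list(clf.classes_).index(positive_label)
        scores += clf.predict_proba(xs_c[:, use_cols])[:, pos_col] / n_imp
        fi = np.zeros(len(cols))
        fi[use_cols] = clf.feature_importances_
        importances += fi / n_imp

    auc = roc_auc(scores, y_test.to_numpy(), positive_group=positive_label).auc
    return ModelResult(
        dataset_id=spec.dataset_id,
        train_ids=list(train_idx), test_ids=list(test_idx),
        held_out_auc=float(auc),
        feature_importances=dict(zip(cols, importances.tolist())),
        retained_features=list(retained),
        n_imputed_cells=n_missing)


def run_model_suite(table: pd.DataFrame, labels: pd.Series,
                    specs: list[ModelSpec] | None = None,
                    positive_label: str = "AP"
                    ) -> tuple[list[ModelResult], pd.DataFrame]:
    """One ModelResult per requested dataset plus an AUC comparison table."""
    if specs is None:
        specs = [ModelSpec(dataset_id=d) for d in (1, 2, 3, 4)]
    results: list[ModelResult] = []
    for spec in specs:
        try:
            results.append(fit_and_evaluate(spec, table, labels,
                                            positive_label=positive_label))
        except ValueError as exc:
            results.append(ModelResult(spec.dataset_id, [], [], float("nan"),
                                       {}, [], 0, error=str(exc)))
    columns = ["dataset_id", "held_out_auc", "n_retained",
               "retained_features", "error"]
    comparison = pd.DataFrame([{
        "dataset_id": r.dataset_id, "held_out_auc": r.held_out_auc,
        "n_retained": len(r.retained_features),
        "retained_features": ";".join(map(str, r.retained_features)),
        "error": r.error or "",
    } for r in results], columns=columns).set_index("dataset_id")
    return results, comparison
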