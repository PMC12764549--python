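"""Model suite for culture-response regression under grouped protocols.

The culture dataset has biological replicates nested inside blending
conditions, so every split — the train/test split, the cross-validation
folds used for hyperparameter tuning, and the test subsets used for the
baseline comparison — is performed at the condition level to prevent
replicate leakage. Hyperparameters are chosen by the conservative
(mean - SD) of the validation R² across folds, models are compared to a
predict-the-training-mean baseline with one-sided paired t-tests under
Holm correction, and "superior" models must additionally generalize:
their train/test metric ratios must stay inside a configured band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.compose import TransformedTargetRegressor
from sklearn.cross_decomposition import PLSRegression
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, DotProduct, WhiteKernel
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GroupKFold, ParameterGrid
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests
from xgboost import XGBRegressor


class RegressionError(ValueError):
    """Raised on ill-posed modeling requests."""


LINEAR_MODELS = ("plsr", "ridge", "lasso", "elasticnet", "svr_linear", "gpr_linear")
NONLINEAR_MODELS = ("rf", "gbdt", "xgboost", "svr_rbf", "gpr_rbf")
MODEL_NAMES = NONLINEAR_MODELS + LINEAR_MODELS
#: The four linear algorithms that came out of the case study as superior.
SUPERIOR_CANDIDATES = ("plsr", "ridge", "lasso", "elasticnet")


@dataclass(frozen=True)
class CultureDataset:
    """Per-sample culture data: condition/replicate ids, X and response y."""

    condition_id: np.ndarray
    replicate_id: np.ndarray
    X: np.ndarray
    y: np.ndarray
    component_ids: tuple[str, ...] = ()

    def __post_init__(self):
        cond = np.asarray(self.condition_id)
        rep = np.asarray(self.replicate_id)
        x = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        n = len(cond)
        if not (len(rep) == x.shape[0] == len(y) == n):
            raise RegressionError("condition_id, replicate_id, X and y disagree in length")
        if np.any(~np.isfinite(y)):
            raise RegressionError("missing or non-finite response values")
        if np.any(x < 0):
            raise RegressionError("component concentrations must be nonnegative")
        if not self.component_ids:
            object.__setattr__(
                self, "component_ids", tuple(f"c{j}" for j in range(x.shape[1]))
            )
        object.__setattr__(self, "condition_id", cond)
        object.__setattr__(self, "replicate_id", rep)
        object.__setattr__(self, "X", x)
        object.__setattr__(self, "y", y)

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def n_conditions(self) -> int:
        return len(np.unique(self.condition_id))

    def subset(self, mask: np.ndarray) -> "CultureDataset":
        return CultureDataset(
            condition_id=self.condition_id[mask],
            replicate_id=self.replicate_id[mask],
            X=self.X[mask],
            y=self.y[mask],
            component_ids=self.component_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.component_ids))
        df.insert(0, "response", self.y)
        df.insert(0, "replicate_id", self.replicate_id)
        df.insert(0, "condition_id", self.condition_id)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CultureDataset":
        required = {"condition_id", "replicate_id", "response"}
        missing = required - set(df.columns)
        if missing:
            raise RegressionError(f"culture CSV is missing columns: {sorted(missing)}")
        comps = [c for c in df.columns if c not in required]
        return cls(
            condition_id=df["condition_id"].to_numpy(),
            replicate_id=df["replicate_id"].to_numpy(),
            X=df[comps].to_numpy(dtype=float),
            y=df["response"].to_numpy(dtype=float),
            component_ids=tuple(comps),
        )


def load_culture_csv(path) -> CultureDataset:
    return CultureDataset.from_frame(pd.read_csv(path))


@dataclass
class ModelReport:
    model_name: str
    tuned_hyperparameters: dict
    r2_train: float
    r2_test: float
    mse_train: float
    mse_test: float
    mse_subsets: list[float]
    p_value_raw: float | None = None
    p_value_vs_baseline: float | None = None
    generalizability_ratios: dict[str, float] = field(default_factory=dict)
    superior: bool = False


def _default_grids(seed: int) -> dict[str, tuple[object, list[dict]]]:
    """Estimator + small hyperparameter grid per algorithm (<= 24 points)."""
    alphas = list(np.logspace(-2, 3, 8))
    return {
        "rf": (
            RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1),
            list(ParameterGrid({"max_features": [0.33, "sqrt", 1.0], "min_samples_leaf": [1, 3]})),
        ),
        "gbdt": (
            GradientBoostingRegressor(random_state=seed),
            list(ParameterGrid({"learning_rate": [0.05, 0.1], "n_estimators": [100, 300], "max_depth": [2, 3]})),
        ),
        "xgboost": (
            XGBRegressor(random_state=seed, n_jobs=1, verbosity=0),
            list(ParameterGrid({"learning_rate": [0.05, 0.1], "n_estimators": [100, 300], "max_depth": [2, 4]})),
        ),
        "svr_rbf": (
            SVR(kernel="rbf"),
            list(ParameterGrid({"C": [1.0, 10.0, 100.0], "gamma": ["scale", 0.01]})),
        ),
        "gpr_rbf": (
            GaussianProcessRegressor(
                kernel=ConstantKernel() * RBF() + WhiteKernel(),
                normalize_y=True,
                random_state=seed,
            ),
            list(ParameterGrid({"alpha": [1e-10, 1e-2]})),
        ),
        "plsr": (
            PLSRegression(),
            list(ParameterGrid({"n_components": [1, 2, 3, 4, 5, 6, 8, 10]})),
        ),
        "ridge": (Ridge(), list(ParameterGrid({"alpha": alphas}))),
        "lasso": (
            Lasso(max_iter=20000),
            list(ParameterGrid({"alpha": list(np.logspace(-3, 1, 8))})),
        ),
        "elasticnet": (
            ElasticNet(max_iter=20000),
            list(ParameterGrid({"alpha": list(np.logspace(-3, 1, 4)), "l1_ratio": [0.2, 0.5, 0.8]})),
        ),
        "svr_linear": (
            SVR(kernel="linear"),
            list(ParameterGrid({"C": [0.1, 1.0, 10.0]})),
        ),
        "gpr_linear": (
            GaussianProcessRegressor(
                kernel=DotProduct() + WhiteKernel(), normalize_y=True, random_state=seed
            ),
            list(ParameterGrid({"alpha": [1e-10, 1e-2]})),
        ),
    }


def _make_pipeline(estimator):
    """Standardize X and y around the estimator.

    The response (e.g. VCC in cells/mL) is orders of magnitude away from
    unit scale, so penalties and kernel hyperparameters are tuned against
    a standardized target; predictions are mapped back automatically.
    """
    return TransformedTargetRegressor(
        regressor=Pipeline([("scale", StandardScaler()), ("model", estimator)]),
        transformer=StandardScaler(),
    )


def grouped_split(
    ds: CultureDataset, train_fraction: float = 0.6, seed: int | None = None
) -> tuple[CultureDataset, CultureDataset]:
    """Condition-grouped train/test split; no condition appears in both."""
    conditions = np.unique(ds.condition_id)
    c = len(conditions)
    if c < 2:
        raise RegressionError("need at least 2 conditions to split")
    n_train = int(round(train_fraction * c))
    n_train = min(max(n_train, 1), c - 1)
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(conditions)
    train_conditions = set(shuffled[:n_train].tolist())
    mask = np.array([cid in train_conditions for cid in ds.condition_id])
    return ds.subset(mask), ds.subset(~mask)


def tune_and_fit(
    model_name: str,
    train: CultureDataset,
    folds: int = 5,
    seed: int = 0,
    grids: Mapping[str, tuple[object, list[dict]]] | None = None,
):
    """Grouped k-fold grid search with the (mean - SD) validation-R² criterion.

    Conditions are never split across folds. The grid point maximizing
    mean(R²) - SD(R²) over the validation folds is selected (first wins on
    ties) and the pipeline is refit on the full training set.

    Returns ``(fitted_pipeline, chosen_params, cv_table)``.
    """
    registry = grids if grids is not None else _default_grids(seed)
    if model_name not in registry:
        raise RegressionError(
            f"unknown model {model_name!r}; valid names: {sorted(registry)}"
        )
    if folds < 2:
        raise RegressionError("folds must be >= 2")
    estimator, grid = registry[model_name]
    groups = train.condition_id
    n_groups = len(np.unique(groups))
    folds = min(folds, n_groups)
    cv = GroupKFold(n_splits=folds)
    rows = []
    best_crit, best_params = -np.inf, None
    for params in grid:
        scores = []
        for tr_idx, va_idx in cv.split(train.X, train.y, groups):
            pipe = _make_pipeline(clone(estimator).set_params(**params))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pipe.fit(train.X[tr_idx], train.y[tr_idx])
            pred = np.ravel(pipe.predict(train.X[va_idx]))
            scores.append(r2_score(train.y[va_idx], pred))
        crit = float(np.mean(scores) - np.std(scores, ddof=0))
        rows.append({"params": params, "mean_r2": float(np.mean(scores)), "criterion": crit})
        if crit > best_crit:
            best_crit, best_params = crit, params
    final = _make_pipeline(clone(estimator).set_params(**best_params))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(train.X, train.y)
    return final, dict(best_params), pd.DataFrame(rows)


def evaluate(model, x, y) -> dict[str, float]:
    """R² and MSE of ``model`` on (x, y), per the usual definitions."""
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise RegressionError("cannot evaluate on an empty dataset")
    if np.var(y) == 0:
        raise RegressionError("R² is undefined for a zero-variance response")
    pred = np.ravel(model.predict(np.asarray(x, dtype=float)))
    return {"r2": float(r2_score(y, pred)), "mse": float(mean_squared_error(y, pred))}


def _grouped_partition(
    conditions: np.ndarray, n_subsets: int, rng: np.random.Generator
) -> list[np.ndarray]:
    shuffled = rng.permutation(conditions)
    return [np.asarray(part) for part in np.array_split(shuffled, n_subsets)]


def compare_to_baseline(
    models: Mapping[str, object],
    baseline,
    test: CultureDataset,
    n_subsets: int = 5,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Holm-corrected one-sided paired t-tests of model MSE vs baseline MSE.

    The test set is partitioned into ``n_subsets`` condition-grouped random
    subsets; per-subset MSEs are paired between each model and the
    predict-the-mean baseline, testing H1: model MSE < baseline MSE.
    """
    if n_subsets < 2:
        raise RegressionError("n_subsets must be >= 2")
    rng = np.random.default_rng(seed)
    parts = _grouped_partition(np.unique(test.condition_id), n_subsets, rng)
    masks = [np.isin(test.condition_id, part) for part in parts]
    base_pred = np.ravel(baseline.predict(test.X))
    base_mse = np.array(
        [mean_squared_error(test.y[m], base_pred[m]) for m in masks]
    )
    names = list(models)
    raw_p, subset_mses = [], {}
    for name in names:
        pred = np.ravel(models[name].predict(test.X))
        mses = np.array([mean_squared_error(test.y[m], pred[m]) for m in masks])
        subset_mses[name] = mses
        diffs = mses - base_mse
        if np.allclose(diffs, 0.0):
            p = 1.0
        else:
            p = float(stats.ttest_rel(mses, base_mse, alternative="less").pvalue)
            if math.isnan(p):
                p = 1.0
        raw_p.append(p)
    _, p_adj, _, _ = multipletests(raw_p, alpha=alpha, method="holm")
    return {
        name: {
            "p_raw": raw_p[i],
            "p_holm": float(p_adj[i]),
            "mse_subsets": subset_mses[name].tolist(),
            "baseline_mse_subsets": base_mse.tolist(),
        }
        for i, name in enumerate(names)
    }


def select_superior(
    reports: Iterable[ModelReport], band: float = 0.15, alpha: float = 0.05
) -> list[ModelReport]:
    """Flag superior models: significant vs baseline AND generalizable.

    Generalizability requires both the R² and the MSE train/test ratios to
    lie within [1/(1+band), 1+band].
    """
    lo, hi = 1.0 / (1.0 + band), 1.0 + band
    superior = []
    for rep in reports:
        ratios = {}
        for metric, tr, te in (
            ("r2", rep.r2_train, rep.r2_test),
            ("mse", rep.mse_train, rep.mse_test),
        ):
            ratios[metric] = tr / te if te != 0 else np.inf
        rep.generalizability_ratios = ratios
        ok_sig = rep.p_value_vs_baseline is not None and rep.p_value_vs_baseline < alpha
        ok_gen = all(lo <= r <= hi for r in ratios.values())
        rep.superior = bool(ok_sig and ok_gen)
        if rep.superior:
            superior.append(rep)
    return superior


@dataclass
class SuiteResult:
    reports: dict[str, ModelReport]
    models: dict[str, object]
    baseline: object
    train: CultureDataset
    test: CultureDataset

    @property
    def superior_models(self) -> dict[str, object]:
        return {n: self.models[n] for n, r in self.reports.items() if r.superior}


def run_model_suite(
    ds: CultureDataset,
    model_names: Sequence[str] | None = None,
    train_fraction: float = 0.6,
    folds: int = 5,
    n_subsets: int = 5,
    alpha: float = 0.05,
    band: float = 0.15,
    seed: int = 0,
    grids: Mapping[str, tuple[object, list[dict]]] | None = None,
) -> SuiteResult:
    """Full protocol: grouped split, tuning, evaluation, baseline tests."""
    names = list(model_names) if model_names is not None else list(MODEL_NAMES)
    train, test = grouped_split(ds, train_fraction, seed)
    baseline = DummyRegressor(strategy="mean").fit(train.X, train.y)
    models, reports = {}, {}
    for name in names:
        fitted, params, _ = tune_and_fit(name, train, folds=folds, seed=seed, grids=grids)
        tr = evaluate(fitted, train.X, train.y)
        te = evaluate(fitted, test.X, test.y)
        models[name] = fitted
        reports[name] = ModelReport(
            model_name=name,
            tuned_hyperparameters=params,
            r2_train=tr["r2"],
            r2_test=te["r2"],
            mse_train=tr["mse"],
            mse_test=te["mse"],
            mse_subsets=[],
        )
    comparison = compare_to_baseline(
        models, baseline, test, n_subsets=n_subsets, seed=seed, alpha=alpha
    )
    for name in names:
        reports[name].p_value_raw = comparison[name]["p_raw"]
        reports[name].p_value_vs_baseline = comparison[name]["p_holm"]
        reports[name].mse_subsets = comparison[name]["mse_subsets"]
    select_superior(reports.values(), band=band, alpha=alpha)
    return SuiteResult(reports=reports, models=models, baseline=baseline, train=train, test=test)
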