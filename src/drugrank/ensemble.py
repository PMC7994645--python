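"""Per-drug regression model roster: training, validation, persistence, prediction.

Each drug gets its own set of regressors fitted on normalized D features of
the training cell lines, tuned by repeated 10-fold cross-validation (3
repeats) on RMSE, except PLS and PCR which use leave-one-out. The roster
mirrors the eight-algorithm family used for drug-response modeling:
random forest, a boosted rule-committee stand-in, Bayesian ridge GLM, PLS,
PCR, RBF support-vector regression, and two multilayer perceptrons (deep
and single-hidden-layer). A consensus prediction averages random forest,
PCR and PLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import BayesianRidge, LinearRegression
from sklearn.model_selection import GridSearchCV, LeaveOneOut, RepeatedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.svm import SVR

from ._utils import derive_seed
from .distance import DistanceMatrix, apply_minmax

DEFAULT_ROSTER = (
    "random_forest",
    "rule_committee",
    "bayes_glm",
    "pls",
    "pcr",
    "svr",
    "mlp_deep",
    "mlp_single",
)

CONSENSUS_MEMBERS = ("random_forest", "pcr", "pls")

LOOCV_ALGORITHMS = {"pls", "pcr"}


def _algorithm_spec(name: str, n_features: int, n_train: int, seed: int):
    """Estimator + small hyperparameter grid for one roster entry."""
    max_comp = max(1, min(8, n_features, n_train - 1))
    comp_grid = sorted({1, 2, min(4, max_comp), max_comp})
    if name == "random_forest":
        est = RandomForestRegressor(n_estimators=100, random_state=seed)
        grid = {"max_features": [0.33, 1.0]}
    elif name == "rule_committee":
        # boosted-tree committee in place of a cubist-family learner
        est = GradientBoostingRegressor(n_estimators=100, random_state=seed)
        grid = {"learning_rate": [0.05, 0.1]}
    elif name == "bayes_glm":
        est = BayesianRidge()
        grid = {"alpha_init": [None, 1.0]}
    elif name == "pls":
        est = PLSRegression(scale=False)
        grid = {"n_components": comp_grid}
    elif name == "pcr":
        est = Pipeline([("pca", PCA(random_state=seed)), ("lm", LinearRegression())])
        grid = {"pca__n_components": comp_grid}
    elif name == "svr":
        est = SVR(kernel="rbf")
        grid = {"C": [0.1, 1.0, 10.0], "epsilon": [0.01, 0.1]}
    elif name == "mlp_deep":
        # lbfgs converges fast and stably on panels of tens of lines
        est = MLPRegressor(hidden_layer_sizes=(32, 16, 8), solver="lbfgs",
                           max_iter=2000, random_state=seed)
        grid = {"alpha": [1e-4, 1e-2]}
    elif name == "mlp_single":
        est = MLPRegressor(hidden_layer_sizes=(16,), solver="lbfgs",
                           max_iter=2000, random_state=seed)
        grid = {"alpha": [1e-4, 1e-2]}
    else:
        raise ValueError(f"unknown algorithm {name!r}")
    return est, grid


@dataclass
class DrugModel:
    """Fitted regressors and CV records for one drug."""

    drug: str
    predictor_ids: list[str]
    models: dict[str, object] = field(default_factory=dict)
    cv: dict[str, dict] = field(default_factory=dict)  # algo -> {best_params, cv_rmse, split_rmses}
    failures: dict[str, str] = field(default_factory=dict)
    seed: int = 0


@dataclass
class DrugModelEnsemble:
    models: dict[str, DrugModel] = field(default_factory=dict)
    predictor_sets: dict = field(default_factory=dict)
    norm_params: dict = field(default_factory=dict)
    train_lines: list[str] = field(default_factory=list)
    validation_lines: list[str] = field(default_factory=list)
    seed: int = 0
    roster: tuple = DEFAULT_ROSTER


def save_ensemble(ensemble: DrugModelEnsemble, out_dir) -> None:
    """Persist an ensemble: JSON manifest + one joblib file per drug."""
    import json
    from pathlib import Path

    import joblib

    out = Path(out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": ensemble.seed,
        "roster": list(ensemble.roster),
        "train_lines": ensemble.train_lines,
        "validation_lines": ensemble.validation_lines,
        "norm_params": {d: list(v) for d, v in ensemble.norm_params.items()},
        "predictor_sets": {d: [p["drug"] for p in s.predictors]
                           for d, s in ensemble.predictor_sets.items()},
        "drugs": {},
    }
    for drug, model in ensemble.models.items():
        fname = f"models/{len(manifest['drugs']):04d}.joblib"
        joblib.dump(model, out / fname)
        manifest["drugs"][drug] = {"file": fname, "cv": model.cv,
                                   "failures": model.failures}
    with open(out / "ensemble.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_ensemble(in_dir) -> DrugModelEnsemble:
    import json
    from pathlib import Path

    import joblib

    src = Path(in_dir)
    with open(src / "ensemble.json") as fh:
        manifest = json.load(fh)
    ens = DrugModelEnsemble(
        norm_params={d: tuple(v) for d, v in manifest["norm_params"].items()},
        train_lines=manifest["train_lines"],
        validation_lines=manifest["validation_lines"],
        seed=manifest["seed"], roster=tuple(manifest["roster"]))
    for drug, rec in manifest["drugs"].items():
        ens.models[drug] = joblib.load(src / rec["file"])
    return ens


def partition_cell_lines(cell_lines, responses, ratio: float = 0.8, seed: int = 0):
    """Stratified train/validation split of cell lines (default 80/20).

    Stratifies on quartile bins of each line's mean AAC so both partitions
    span the response range, mirroring stratified numeric partitioning.
    Deterministic given the seed.
    """
    cell_lines = [c for c in cell_lines if c in set(responses.aac.columns)]
    n = len(cell_lines)
    if n < 10:
        raise ValueError(f"need >= 10 cell lines to partition, got {n}")
    mean_aac = responses.aac[cell_lines].mean(axis=0, skipna=True)
    bins = pd.qcut(mean_aac.rank(method="first"), q=min(4, n), labels=False, duplicates="drop")
    rng = np.random.default_rng(seed)
    n_train_total = int(round(ratio * n))

    by_bin: dict[int, list[str]] = {}
    for line in cell_lines:
        by_bin.setdefault(int(bins[line]), []).append(line)
    # largest-remainder allocation of the train quota across bins
    quotas = {b: ratio * len(ls) for b, ls in by_bin.items()}
    base = {b: int(np.floor(q)) for b, q in quotas.items()}
    remaining = n_train_total - sum(base.values())
    order = sorted(by_bin, key=lambda b: -(quotas[b] - base[b]))
    for b in order[:remaining]:
        base[b] += 1
    train: list[str] = []
    for b, lines in sorted(by_bin.items()):
        lines = sorted(lines)
        picked = rng.choice(len(lines), size=min(base[b], len(lines)), replace=False)
        train.extend(lines[i] for i in sorted(picked))
    train_set = set(train)
    validation = [c for c in cell_lines if c not in train_set]
    return sorted(train_set), validation


def train_drug_models(X: pd.DataFrame, y: pd.Series, drug: str, roster=DEFAULT_ROSTER,
                      cv_folds: int = 10, cv_repeats: int = 3, seed: int = 0) -> DrugModel:
    """Grid-search every roster algorithm on one drug's (X, y) and refit the best.

    Tuning minimizes mean CV RMSE over RepeatedKFold(10, 3) resamples
    (leave-one-out for pls/pcr); the winning configuration is refitted on
    all training lines. Non-converging algorithms are recorded in
    ``failures`` without affecting the rest.
    """
    if X.isna().any().any():
        raise ValueError(f"{drug}: missing values in training features")
    n = len(y)
    if n < 10:
        raise ValueError(f"{drug}: need >= 10 training lines, got {n}")
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    model = DrugModel(drug=drug, predictor_ids=list(X.columns), seed=seed)
    for algo in roster:
        est, grid = _algorithm_spec(algo, X.shape[1], n, derive_seed(seed, drug, algo))
        if algo in LOOCV_ALGORITHMS:
            cv = LeaveOneOut()
        else:
            cv = RepeatedKFold(n_splits=min(cv_folds, n), n_repeats=cv_repeats,
                               random_state=derive_seed(seed, drug, algo, "cv"))
        search = GridSearchCV(est, grid, scoring="neg_root_mean_squared_error",
                              cv=cv, refit=True, error_score="raise")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                search.fit(Xv, yv)
        except Exception as exc:  # noqa: BLE001 - a failed learner must not sink the drug
            model.failures[algo] = f"{type(exc).__name__}: {exc}"
            continue
        idx = search.best_index_
        n_splits = search.n_splits_
        splits = [-search.cv_results_[f"split{i}_test_score"][idx] for i in range(n_splits)]
        model.models[algo] = search.best_estimator_
        model.cv[algo] = {
            "best_params": search.best_params_,
            "cv_rmse": float(-search.best_score_),
            "split_rmses": [float(s) for s in splits],
        }
    return model


def _predict_one(est, Xv: np.ndarray) -> np.ndarray:
    pred = np.asarray(est.predict(Xv), dtype=float).ravel()
    return np.clip(pred, 0.0, 1.0)


def predict_responses(ensemble: DrugModelEnsemble, new_distances: DistanceMatrix,
                      algorithm: str = "random_forest") -> pd.DataFrame:
    """Predicted AAC (drugs x samples), clipped to [0, 1].

    ``new_distances`` may be raw D values; they are normalized with the
    stored training min-max. A sample missing any predictor D for a drug
    gets a missing (NaN) prediction for that drug rather than a guess.
    """
    dm = new_distances if new_distances.normalized else apply_minmax(new_distances, ensemble.norm_params)
    samples = dm.sample_ids
    out = pd.DataFrame(np.nan, index=list(ensemble.models), columns=samples, dtype=float)
    for drug, model in ensemble.models.items():
        if algorithm == "consensus":
            preds = []
            for member in CONSENSUS_MEMBERS:
                if member in model.models:
                    preds.append(_row_prediction(model, member, dm, samples))
            if len(preds) < 2:
                continue
            stacked = np.vstack(preds)
            with np.errstate(all="ignore"):
                row = np.nanmean(stacked, axis=0)
            row[np.all(np.isnan(stacked), axis=0)] = np.nan
            out.loc[drug] = np.clip(row, 0.0, 1.0)
        else:
            if algorithm not in DEFAULT_ROSTER:
                raise ValueError(f"unknown algorithm {algorithm!r}")
            if algorithm not in model.models:
                continue
            out.loc[drug] = _row_prediction(model, algorithm, dm, samples)
    return out


def _row_prediction(model: DrugModel, algorithm: str, dm: DistanceMatrix, samples) -> np.ndarray:
    missing_predictors = [p for p in model.predictor_ids if p not in dm.d.index]
    if missing_predictors:
        return np.full(len(samples), np.nan)
    X = dm.d.loc[model.predictor_ids, samples].to_numpy(dtype=float).T
    ok = ~np.isnan(X).any(axis=1)
    row = np.full(len(samples), np.nan)
    if ok.any():
        row[ok] = _predict_one(model.models[algorithm], X[ok])
    return row


def consensus_prediction(ensemble: DrugModelEnsemble, new_distances: DistanceMatrix) -> pd.DataFrame:
    """Mean of the random forest, PCR and PLS predictions (>= 2 members required)."""
    return predict_responses(ensemble, new_distances, algorithm="consensus")


def stratify_by_mean_prediction(predictions: pd.Series) -> pd.Series:
    """Label samples 'high' (prediction > mean) or 'low' for one drug.

    The mean predicted response is the stratification cutoff (e.g. for
    splitting patients into predicted-responder groups).
    """
    obs = predictions.dropna()
    if len(obs) < 2:
        raise ValueError("need >= 2 predictions to stratify")
    cutoff = float(obs.mean())
    return pd.Series(np.where(predictions > cutoff, "high", "low"), index=predictions.index)
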