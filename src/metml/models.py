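"""Prediction-model registry and evaluation engine.

Models
------
``gbdt_pc_ec``    gradient-boosted trees (XGBoost) on marker PCs + ECs
                  (alias ``xgb_reg_1``);
``rf_pc_ec``      random forest on marker PCs + ECs (alias ``rf_reg``);
``mlp_pc_ec``     multilayer perceptron on marker PCs + ECs (alias ``DL_reg``);
``stacked_ensemble``  SVM-on-ECs + elastic-net-on-markers + XGBoost-on-
                  (40 marker PCs + ECs), combined by a Lasso meta-learner on
                  out-of-fold predictions (alias ``stacking_reg_3``);
``reaction_norm`` the linear kernel benchmark (see :mod:`metml.reaction_norm`).

Evaluation is nested cross-validation: an outer partition list from one of the
breeding CV schemes, and an inner k-fold on each outer training set that tunes
hyperparameters by seeded random search before the winning configuration is
refit on all outer-training data.  Pearson correlation between observed and
predicted values is always computed within environment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, LassoCV
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

from . import cv_schemes
from .data_model import METData
from .preprocess import Preprocessor, default_num_pcs

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def build_feature_table(
    met: METData,
    trait: str | None = None,
    include_env_predictors: bool = True,
    list_env_predictors: list[str] | None = None,
    lat_lon_included: bool = False,
    yr_included: bool = False,
) -> tuple[pd.DataFrame, pd.Series | None, dict[str, list[str]]]:
    """One row per phenotypic observation: marker dosages + ECs (+ soil/lat-lon/year).

    Returns the feature table, the trait vector (``None`` for test sets), and
    a block tag -> column names mapping.
    """
    pheno = met.pheno.reset_index(drop=True)
    if trait is not None:
        if trait not in pheno.columns:
            raise KeyError(f"trait {trait!r} not in phenotype table")
        keep = pheno[trait].notna()
        pheno = pheno[keep].reset_index(drop=True)
        y = pheno[trait].astype(float)
    else:
        y = None

    blocks: dict[str, list[str]] = {}
    parts = []

    markers = met.markers.loc[pheno["genotype_id"]].reset_index(drop=True).astype(float)
    blocks["markers"] = list(markers.columns)
    parts.append(markers)

    if include_env_predictors:
        if met.ecs is None or met.ecs.empty:
            raise ValueError("include_env_predictors=True but the MET data has no ECs")
        ecs = met.ecs
        if list_env_predictors:
            missing = [c for c in list_env_predictors if c not in ecs.columns]
            if missing:
                raise KeyError(f"unknown environmental predictor(s): {missing}")
            ecs = ecs[list_env_predictors]
        ec_rows = ecs.loc[pheno["env_id"]].reset_index(drop=True)
        blocks["ecs"] = list(ec_rows.columns)
        parts.append(ec_rows)
        if met.soil is not None and not met.soil.empty:
            soil_rows = met.soil.loc[pheno["env_id"]].reset_index(drop=True)
            soil_rows.columns = [f"soil_{c}" for c in soil_rows.columns]
            blocks["soil"] = list(soil_rows.columns)
            parts.append(soil_rows)

    if lat_lon_included:
        env_meta = met.env_info.set_index("env_id")
        ll = env_meta.loc[pheno["env_id"], ["latitude", "longitude"]].reset_index(drop=True)
        blocks["lat_lon"] = ["latitude", "longitude"]
        parts.append(ll)

    if yr_included:
        dummies = pd.get_dummies(pheno["year"].astype(int), prefix="year",
                                 drop_first=True, dtype=float)
        blocks["year"] = list(dummies.columns)
        parts.append(dummies)

    X = pd.concat(parts, axis=1)
    X.index = pheno.index
    return X, y, blocks


def observation_frame(met: METData, trait: str | None) -> pd.DataFrame:
    """Observation metadata aligned with :func:`build_feature_table` rows."""
    pheno = met.pheno.reset_index(drop=True)
    if trait is not None:
        pheno = pheno[pheno[trait].notna()].reset_index(drop=True)
    return pheno[["genotype_id", "env_id", "location", "year"]]


# ---------------------------------------------------------------------------
# registry and hyperparameter search
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    model_id: str
    factory: Callable  # (params, seed, blocks) -> estimator with fit/predict
    search_space: dict
    default_params: dict
    tree_based: bool = False
    uses_marker_pcs: bool = True  # preprocessor replaces markers by PCs


def _make_xgb(params, seed, blocks=None):
    return XGBRegressor(
        n_estimators=int(params.get("n_estimators", 300)),
        learning_rate=float(params.get("learning_rate", 0.05)),
        max_depth=int(params.get("max_depth", 4)),
        subsample=0.9,
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed) % (2**31),
        importance_type="gain",
        verbosity=0,
    )


def _make_rf(params, seed, blocks=None):
    from sklearn.ensemble import RandomForestRegressor

    return RandomForestRegressor(
        n_estimators=int(params.get("n_estimators", 300)),
        max_features=float(params.get("max_features", 0.5)),
        min_samples_leaf=int(params.get("min_samples_leaf", 2)),
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )


@dataclass
class MLPSpec:
    """Feed-forward network description: affine maps z = W'X + b with activation f(z)."""

    hidden_layers: tuple = (64, 32)
    activation: str = "relu"
    solver: str = "adam"
    alpha: float = 1e-4
    learning_rate_init: float = 1e-3
    max_iter: int = 500
    early_stopping: bool = True
    patience: int = 10
    validation_fraction: float = 0.1

    def __post_init__(self):
        if len(self.hidden_layers) < 1:
            raise ValueError("MLP needs at least one hidden layer")


def make_mlp(spec: MLPSpec, seed: int) -> MLPRegressor:
    return MLPRegressor(
        hidden_layer_sizes=tuple(spec.hidden_layers),
        activation=spec.activation,
        solver=spec.solver,
        alpha=spec.alpha,
        learning_rate_init=spec.learning_rate_init,
        max_iter=spec.max_iter,
        early_stopping=spec.early_stopping,
        n_iter_no_change=spec.patience,
        validation_fraction=spec.validation_fraction,
        random_state=int(seed) % (2**31),
    )


def fit_mlp(X, y, spec: MLPSpec | None = None, seed: int = 0) -> MLPRegressor:
    """Train a multilayer perceptron by backpropagation with early stopping."""
    spec = spec or MLPSpec()
    net = make_mlp(spec, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at small budgets
        net.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    if not np.isfinite(net.loss_):
        raise RuntimeError(
            "MLP training diverged (non-finite loss); lower learning_rate_init"
        )
    return net


def _make_mlp_estimator(params, seed, blocks=None):
    spec = MLPSpec(
        alpha=float(params.get("alpha", 1e-4)),
        learning_rate_init=float(params.get("learning_rate_init", 1e-3)),
    )
    return _MLPWrapper(spec, seed)


class _MLPWrapper:
    """Defers to :func:`fit_mlp` so divergence checks apply inside tuning too."""

    def __init__(self, spec, seed):
        self.spec, self.seed, self.net_ = spec, seed, None

    def fit(self, X, y):
        self.net_ = fit_mlp(X, y, self.spec, self.seed)
        return self

    def predict(self, X):
        return self.net_.predict(np.asarray(X, dtype=float))


def _make_stacked(params, seed, blocks=None):
    return StackedEnsembleRegressor(
        blocks=blocks or {},
        seed=seed,
        n_marker_pcs=int(params.get("n_marker_pcs", 40)),
    )


MODEL_REGISTRY: dict[str, ModelSpec] = {
    "gbdt_pc_ec": ModelSpec(
        "gbdt_pc_ec",
        _make_xgb,
        search_space={
            "n_estimators": ("int", 50, 1000),
            "learning_rate": ("log", 0.01, 0.3),
            "max_depth": ("int", 2, 10),
        },
        default_params={"n_estimators": 300, "learning_rate": 0.05, "max_depth": 4},
        tree_based=True,
    ),
    "rf_pc_ec": ModelSpec(
        "rf_pc_ec",
        _make_rf,
        search_space={
            "n_estimators": ("int", 100, 600),
            "max_features": ("uniform", 0.1, 1.0),
            "min_samples_leaf": ("int", 1, 10),
        },
        default_params={"n_estimators": 300, "max_features": 0.5, "min_samples_leaf": 2},
        tree_based=True,
    ),
    "mlp_pc_ec": ModelSpec(
        "mlp_pc_ec",
        _make_mlp_estimator,
        search_space={
            "alpha": ("log", 1e-5, 1e-1),
            "learning_rate_init": ("log", 1e-4, 1e-2),
        },
        default_params={"alpha": 1e-4, "learning_rate_init": 1e-3},
    ),
    "stacked_ensemble": ModelSpec(
        "stacked_ensemble",
        _make_stacked,
        search_space={},
        default_params={"n_marker_pcs": 40},
        uses_marker_pcs=False,  # the elastic-net base learner needs raw markers
    ),
}

_ALIASES = {
    "xgb_reg_1": "gbdt_pc_ec",
    "rf_reg": "rf_pc_ec",
    "dl_reg": "mlp_pc_ec",
    "stacking_reg_3": "stacked_ensemble",
}


def get_model_spec(model_id: str) -> ModelSpec:
    key = _ALIASES.get(model_id.lower(), model_id)
    if key == "reaction_norm":
        raise KeyError(
            "reaction_norm is a kernel benchmark; use metml.reaction_norm or "
            "nested_cv_evaluate(model_id='reaction_norm')"
        )
    if key not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {model_id!r}; known: {sorted(MODEL_REGISTRY)}")
    return MODEL_REGISTRY[key]


def sample_params(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "int":
            out[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "uniform":
            out[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "log":
            out[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "choice":
            out[name] = spec[1][rng.integers(len(spec[1]))]
        else:
            raise ValueError(f"unknown search-space kind {kind!r}")
    return out


def rmse(observed, predicted) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def tune_random_search(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    budget: int = 30,
    inner_folds: int = 5,
    seed: int = 0,
    blocks: dict | None = None,
) -> tuple[dict, list[dict]]:
    """Seeded random search over the model's space; inner-CV RMSE as objective."""
    if not spec.search_space or budget <= 0:
        return dict(spec.default_params), []
    rng = np.random.default_rng(seed)
    inner = KFold(n_splits=inner_folds, shuffle=True, random_state=int(seed) % (2**31))
    splits = list(inner.split(X))
    history = []
    best_params, best_score = None, np.inf
    Xv = X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    for _ in range(budget):
        params = sample_params(spec.search_space, rng)
        fold_rmse = []
        for tr, va in splits:
            est = spec.factory(params, seed, blocks)
            est.fit(Xv[tr], y[tr])
            fold_rmse.append(rmse(y[va], est.predict(Xv[va])))
        score = float(np.mean(fold_rmse))
        history.append({"params": params, "rmse": score})
        if score < best_score:
            best_params, best_score = params, score
    return best_params, history


# ---------------------------------------------------------------------------
# stacked ensemble
# ---------------------------------------------------------------------------

class StackedEnsembleRegressor:
    """Stacked ensemble with a Lasso meta-learner on out-of-fold predictions.

    Base learners (each restricted to its own feature block):

    * RBF support-vector regression on the environmental covariates;
    * elastic net on the (standardized) marker dosages;
    * XGBoost on ``n_marker_pcs`` marker principal components plus the ECs.

    The meta-learner is an L1-regularized linear combination fitted to the
    base learners' cross-validated predictions; base learners whose meta
    coefficient is exactly zero are dropped from the ensemble.
    """

    def __init__(self, blocks: dict, seed: int = 0, n_folds: int = 5,
                 n_marker_pcs: int = 40):
        self.blocks = blocks
        self.seed = int(seed) % (2**31)
        self.n_folds = n_folds
        self.n_marker_pcs = n_marker_pcs

    @staticmethod
    def fit_meta(meta_features: np.ndarray, y: np.ndarray, seed: int = 0):
        """L1-regularized combination of the base learners' CV predictions."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            meta = LassoCV(cv=5, random_state=int(seed) % (2**31), max_iter=50000)
            meta.fit(np.asarray(meta_features, dtype=float), np.asarray(y, dtype=float))
        return meta

    # -- feature views -------------------------------------------------------
    def _views(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        ec_cols = [c for c in self.blocks.get("ecs", []) if c in X.columns]
        snp_cols = [c for c in self.blocks.get("markers", []) if c in X.columns]
        if not ec_cols or not snp_cols:
            raise ValueError("stacked ensemble needs both a marker and an EC block")
        snps = X[snp_cols].to_numpy(dtype=float)
        pcs = snps @ self._pc_loadings
        return {
            "svr_ecs": X[ec_cols].to_numpy(dtype=float),
            "enet_snps": snps,
            "xgb_pc_ecs": np.hstack([pcs, X[ec_cols].to_numpy(dtype=float)]),
        }

    def _base_factories(self):
        return {
            "svr_ecs": lambda: SVR(kernel="rbf", C=1.0, epsilon=0.1),
            "enet_snps": lambda: ElasticNet(alpha=0.02, l1_ratio=0.5, max_iter=20000),
            "xgb_pc_ecs": lambda: _make_xgb(
                {"n_estimators": 200, "learning_rate": 0.05, "max_depth": 4}, self.seed
            ),
        }

    def fit(self, X: pd.DataFrame, y) -> "StackedEnsembleRegressor":
        y = np.asarray(y, dtype=float)
        snp_cols = [c for c in self.blocks.get("markers", []) if c in X.columns]
        snps = X[snp_cols].to_numpy(dtype=float)
        k = min(self.n_marker_pcs, len(X) - 1, snps.shape[1])
        centered = snps - snps.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        self._pc_loadings = vt[:k].T

        views = self._views(X)
        names = list(views)
        oof = np.full((len(X), len(names)), np.nan)
        cv = KFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        for tr, va in cv.split(X):
            for j, name in enumerate(names):
                est = self._base_factories()[name]()
                est.fit(views[name][tr], y[tr])
                oof[va, j] = est.predict(views[name][va])
        assert not np.isnan(oof).any()
        self.oof_predictions_ = pd.DataFrame(oof, columns=names, index=X.index)
        self.meta_ = self.fit_meta(oof, y, self.seed)
        self.meta_coef_ = dict(zip(names, self.meta_.coef_))
        self.survivors_ = [n for n, c in self.meta_coef_.items() if c != 0.0]
        if len(self.survivors_) < 2:
            warnings.warn(
                f"stacked ensemble: meta-learner kept {len(self.survivors_)} base "
                "learner(s); the ensemble reduces to the survivor(s)",
                stacklevel=2,
            )

        self.base_models_ = {}
        for name in names:
            est = self._base_factories()[name]()
            est.fit(views[name], y)
            self.base_models_[name] = est
        return self

    def base_predictions(self, X: pd.DataFrame) -> pd.DataFrame:
        views = self._views(X)
        return pd.DataFrame(
            {name: self.base_models_[name].predict(views[name])
             for name in self.base_models_},
            index=X.index,
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.meta_.predict(self.base_predictions(X).to_numpy())


def fit_stacked_ensemble(X: pd.DataFrame, y, blocks: dict, seed: int = 0,
                         n_folds: int = 5, n_marker_pcs: int = 40) -> StackedEnsembleRegressor:
    """Fit the stacked ensemble on a (preprocessed) feature table."""
    return StackedEnsembleRegressor(
        blocks=blocks, seed=seed, n_folds=n_folds, n_marker_pcs=n_marker_pcs
    ).fit(X, y)


# ---------------------------------------------------------------------------
# fitted pipeline and evaluation containers
# ---------------------------------------------------------------------------

@dataclass
class FittedPipeline:
    """Train-fitted preprocessor + tuned model, applied unchanged to new data."""

    preprocessor: Preprocessor
    model: object
    model_id: str
    params: dict
    seed: int
    train_index: np.ndarray
    feature_blocks: dict[str, list[str]] = field(default_factory=dict)
    X_train: pd.DataFrame | None = None
    y_train: np.ndarray | None = None
    X_test: pd.DataFrame | None = None
    y_test: np.ndarray | None = None

    def predict_processed(self, X_processed) -> np.ndarray:
        arr = X_processed.to_numpy(dtype=float) if hasattr(X_processed, "to_numpy") \
            else np.asarray(X_processed, dtype=float)
        if isinstance(self.model, StackedEnsembleRegressor):
            return self.model.predict(pd.DataFrame(arr, columns=self.feature_names))
        return np.asarray(self.model.predict(arr), dtype=float)

    def predict(self, X_raw: pd.DataFrame) -> np.ndarray:
        return self.predict_processed(self.preprocessor.transform(X_raw))

    @property
    def feature_names(self) -> list[str]:
        return list(self.preprocessor.feature_names_)

    def split_data(self, split: str):
        if split == "train":
            return self.X_train, self.y_train
        if split == "unseen":
            if self.X_test is None:
                raise ValueError("no unseen split stored with this pipeline")
            return self.X_test, self.y_test
        raise ValueError("split must be 'train' or 'unseen'")


def within_env_metrics(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-(partition, environment) Pearson r and RMSE from stored predictions.

    The correlation is always within environment; it is undefined (NaN) for
    environments with fewer than 3 test observations or zero variance.
    """
    rows = []
    for (part, env), grp in predictions.groupby(["partition", "env_id"], sort=True):
        obs = grp["observed"].to_numpy(dtype=float)
        pred = grp["predicted"].to_numpy(dtype=float)
        if len(grp) >= 3 and np.std(obs) > 0 and np.std(pred) > 0:
            r = float(stats.pearsonr(obs, pred)[0])
        else:
            r = float("nan")
            logger.info("partition %s env %s: r undefined (n=%d)", part, env, len(grp))
        rows.append(
            {"partition": part, "env_id": env, "n": len(grp),
             "pearson_r": r, "rmse": rmse(obs, pred)}
        )
    return pd.DataFrame(rows)


@dataclass
class EvaluationResult:
    """Predictions, metrics and tuning choices from one CV evaluation."""

    model_id: str
    trait: str
    cv_type: str
    predictions: pd.DataFrame
    metrics_by_env: pd.DataFrame
    hyperparameters: list[dict]
    seed: int | None
    partitions: list = field(default_factory=list)
    pipelines: list = field(default_factory=list)

    @property
    def mean_within_env_r(self) -> float:
        return float(self.metrics_by_env["pearson_r"].mean(skipna=True))

    @property
    def pooled_rmse(self) -> float:
        return rmse(self.predictions["observed"], self.predictions["predicted"])

    def summary(self) -> str:
        lines = [
            f"{self.model_id} / {self.trait} / {self.cv_type}: "
            f"{self.predictions['partition'].nunique()} partitions",
            f"  mean within-environment r: {self.mean_within_env_r:.3f}",
            f"  pooled RMSE:              {self.pooled_rmse:.3f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# nested CV evaluation
# ---------------------------------------------------------------------------

def nested_cv_evaluate(
    met: METData,
    trait: str,
    model_id: str = "gbdt_pc_ec",
    cv_type: str = "cv0",
    cv0_type: str = "leave-one-environment-out",
    nb_folds_cv1: int = 5,
    repeats_cv1: int = 1,
    nb_folds_cv2: int = 5,
    repeats_cv2: int = 1,
    seed: int | None = None,
    inner_folds: int = 5,
    tuning_budget: int = 30,
    num_pcs: int | None = None,
    include_env_predictors: bool = True,
    list_env_predictors: list[str] | None = None,
    lat_lon_included: bool = False,
    yr_included: bool = False,
    test_genotype_fraction: float = 0.5,
    min_train_years: int = 2,
    keep_pipelines: bool = True,
    mcmc_iterations: int = 2000,
    mcmc_burn_in: int = 200,
) -> EvaluationResult:
    """Nested-CV generalization estimate of one model under one CV scheme.

    For each outer partition the preprocessor is fitted on the outer training
    rows only, hyperparameters are tuned by inner CV on those rows, the winning
    configuration is refit on all outer-training data, and metrics are computed
    on the untouched outer test rows, per environment.
    """
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))

    if trait not in met.pheno.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    obs_mask = met.pheno[trait].notna()
    pheno_obs = met.pheno[obs_mask].reset_index(drop=True)
    partitions = cv_schemes.make_partitions(
        pheno_obs, met.env_info, cv_type=cv_type, cv0_type=cv0_type,
        nb_folds_cv1=nb_folds_cv1, repeats_cv1=repeats_cv1,
        nb_folds_cv2=nb_folds_cv2, repeats_cv2=repeats_cv2,
        seed=seed, test_genotype_fraction=test_genotype_fraction,
        min_train_years=min_train_years,
    )
    if not partitions:
        raise ValueError("CV configuration produced no partitions")

    if model_id == "reaction_norm":
        from . import reaction_norm as _rn

        return _rn.evaluate_partitions(
            met, trait, partitions, cv_type=cv_type, seed=seed,
            iterations=mcmc_iterations, burn_in=mcmc_burn_in,
        )

    spec = get_model_spec(model_id)
    X, y, blocks = build_feature_table(
        met, trait,
        include_env_predictors=include_env_predictors,
        list_env_predictors=list_env_predictors,
        lat_lon_included=lat_lon_included,
        yr_included=yr_included,
    )
    obs_meta = observation_frame(met, trait)
    y = y.to_numpy()

    pred_rows, all_params, pipelines = [], [], []
    for i, part in enumerate(partitions):
        part_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2**31))
        tr, te = part.train_index, part.test_index

        resolved_pcs = None
        if spec.uses_marker_pcs:
            resolved_pcs = num_pcs if num_pcs is not None else default_num_pcs(
                len(tr), len(blocks["markers"])
            )
        preproc = Preprocessor(num_pcs=resolved_pcs)
        Xtr = preproc.fit_transform(X.iloc[tr], marker_cols=blocks["markers"])
        Xte = preproc.transform(X.iloc[te])

        post_blocks = _post_transform_blocks(blocks, preproc)
        best_params, _ = tune_random_search(
            spec, Xtr, y[tr], budget=tuning_budget, inner_folds=inner_folds,
            seed=part_seed, blocks=post_blocks,
        )
        model = spec.factory(best_params, part_seed, post_blocks)
        if isinstance(model, StackedEnsembleRegressor):
            model.fit(Xtr, y[tr])
            pred = model.predict(Xte)
        else:
            model.fit(Xtr.to_numpy(dtype=float), y[tr])
            pred = np.asarray(model.predict(Xte.to_numpy(dtype=float)), dtype=float)

        meta = obs_meta.iloc[te]
        pred_rows.append(
            pd.DataFrame(
                {
                    "partition": i,
                    "obs_index": te,
                    "genotype_id": meta["genotype_id"].to_numpy(),
                    "env_id": meta["env_id"].to_numpy(),
                    "location": meta["location"].to_numpy(),
                    "year": meta["year"].to_numpy(),
                    "observed": y[te],
                    "predicted": pred,
                }
            )
        )
        all_params.append(best_params)
        if keep_pipelines:
            pipelines.append(
                FittedPipeline(
                    preprocessor=preproc, model=model, model_id=spec.model_id,
                    params=best_params, seed=part_seed, train_index=tr,
                    feature_blocks=post_blocks,
                    X_train=Xtr, y_train=y[tr], X_test=Xte, y_test=y[te],
                )
            )

    predictions = pd.concat(pred_rows, ignore_index=True)
    return EvaluationResult(
        model_id=spec.model_id,
        trait=trait,
        cv_type=cv_type,
        predictions=predictions,
        metrics_by_env=within_env_metrics(predictions),
        hyperparameters=all_params,
        seed=seed,
        partitions=partitions,
        pipelines=pipelines,
    )


def _post_transform_blocks(blocks: dict, preproc: Preprocessor) -> dict:
    """Map raw feature blocks to post-preprocessing column names."""
    out = {}
    for tag, cols in blocks.items():
        if tag == "markers" and preproc.num_pcs is not None:
            out[tag] = [f"PC{i + 1}" for i in range(preproc.num_pcs)]
        else:
            out[tag] = [c for c in cols if c not in preproc.dropped_]
    return out


# ---------------------------------------------------------------------------
# step 3: fit on all training data, predict a new test set
# ---------------------------------------------------------------------------

def predict_new(
    train_met: METData,
    test_met: METData,
    trait: str,
    model_id: str = "gbdt_pc_ec",
    seed: int | None = None,
    inner_folds: int = 5,
    tuning_budget: int = 30,
    num_pcs: int | None = None,
    include_env_predictors: bool = True,
    **feature_kwargs,
) -> tuple[pd.DataFrame, FittedPipeline]:
    """Tune on the full training set, fit once, predict every test observation.

    The test ECs must have been computed with the same aggregation method as
    the training ECs, and their column sets must match exactly.
    """
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    if include_env_predictors:
        train_cols = set(train_met.ecs.columns)
        test_cols = set(test_met.ecs.columns)
        if train_cols != test_cols:
            missing = sorted(train_cols - test_cols)
            extra = sorted(test_cols - train_cols)
            raise ValueError(
                f"EC columns differ between train and test (missing: {missing[:5]}, "
                f"extra: {extra[:5]})"
            )
        m_train = train_met.provenance.get("aggregation_method")
        m_test = test_met.provenance.get("aggregation_method")
        if m_train is not None and m_test is not None and m_train != m_test:
            raise ValueError(
                f"EC aggregation methods differ: train={m_train!r}, test={m_test!r}; "
                "recompute the test ECs with the training method"
            )

    spec = get_model_spec(model_id)
    X, y, blocks = build_feature_table(
        train_met, trait, include_env_predictors=include_env_predictors, **feature_kwargs
    )
    X_new, _, _ = build_feature_table(
        test_met, None, include_env_predictors=include_env_predictors, **feature_kwargs
    )
    resolved_pcs = None
    if spec.uses_marker_pcs:
        resolved_pcs = num_pcs if num_pcs is not None else default_num_pcs(
            len(X), len(blocks["markers"])
        )
    preproc = Preprocessor(num_pcs=resolved_pcs)
    Xtr = preproc.fit_transform(X, marker_cols=blocks["markers"])
    Xte = preproc.transform(X_new)
    post_blocks = _post_transform_blocks(blocks, preproc)

    best_params, _ = tune_random_search(
        spec, Xtr, y.to_numpy(), budget=tuning_budget, inner_folds=inner_folds,
        seed=seed, blocks=post_blocks,
    )
    model = spec.factory(best_params, seed, post_blocks)
    if isinstance(model, StackedEnsembleRegressor):
        model.fit(Xtr, y.to_numpy())
        pred = model.predict(Xte)
    else:
        model.fit(Xtr.to_numpy(dtype=float), y.to_numpy())
        pred = np.asarray(model.predict(Xte.to_numpy(dtype=float)), dtype=float)

    meta = observation_frame(test_met, None)
    out = meta.copy()
    out["predicted"] = pred
    pipeline = FittedPipeline(
        preprocessor=preproc, model=model, model_id=spec.model_id,
        params=best_params, seed=seed, train_index=np.arange(len(X)),
        feature_blocks=post_blocks, X_train=Xtr, y_train=y.to_numpy(),
    )
    return out, pipeline


def rank_predicted_genotypes(predictions: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Top-n genotypes per (location, year) by predicted value; ties by id."""
    required = {"location", "year", "genotype_id", "predicted"}
    if not required.issubset(predictions.columns):
        raise ValueError(f"predictions need columns {sorted(required)}")
    ranked = predictions.sort_values(
        ["location", "year", "predicted", "genotype_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    out = ranked.groupby(["location", "year"], sort=True).head(top_n).copy()
    out["rank"] = out.groupby(["location", "year"]).cumcount() + 1
    return out.reset_index(drop=True)
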