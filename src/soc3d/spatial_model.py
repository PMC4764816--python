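"""Random-forest models linking depth-function parameters to covariates.

Four models are trained on the calibration sites: a classifier for mattic
occurrence and regressors for log(mattic depth), log(C_a) and log(k). All
three regression targets are natural-log transformed (they are strictly
positive, right-skewed quantities) and back-transformed with a plain exp.
Model quality is summarized by out-of-bag (OOB) statistics over repeated
runs, and covariate relevance by permutation importance (mean decrease in
prediction accuracy).

The forests themselves (bootstrap sample per tree, ``mtry`` candidate
covariates per split, unpruned trees, OOB from rows absent from a tree's
bootstrap) come from scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from soc3d.depth_model import DepthFunctionParams

__all__ = [
    "RFConfig", "TrainedModelSet", "OOBSummary", "SUMMARY_COLUMNS",
    "train_mattic_classifier", "train_param_regressor", "train_model_set",
    "repeat_oob", "variable_importance", "predict_parameters",
]

SUMMARY_COLUMNS = [
    "minimum", "q1", "mean", "median", "q3", "maximum", "sd",
]


@dataclass(frozen=True)
class RFConfig:
    """Forest hyper-parameters: 1000 trees, mtry 4 (class) / 6 (regression)."""

    ntree: int = 1000
    mtry_class: int = 4
    mtry_reg: int = 6
    n_runs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")


def _check_table(table: pd.DataFrame, covariates: Sequence[str], target: str):
    X = table[list(covariates)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing covariate values in training table")
    y = table[target].to_numpy()
    return X, y


def train_mattic_classifier(
    table: pd.DataFrame,
    covariates: Sequence[str],
    cfg: RFConfig = RFConfig(),
    seed: int | None = None,
) -> tuple[RandomForestClassifier, float]:
    """Train the mattic-occurrence classifier; return (model, OOB error rate).

    OOB error is the misclassification rate of the out-of-bag majority vote.
    """
    X, y = _check_table(table, covariates, "has_mattic")
    y = y.astype(bool)
    if len(np.unique(y)) < 2:
        raise ValueError("need both mattic and non-mattic sites to train")
    clf = RandomForestClassifier(
        n_estimators=cfg.ntree,
        max_features=min(cfg.mtry_class, len(covariates)),
        oob_score=True,
        random_state=cfg.seed if seed is None else seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf, float(1.0 - clf.oob_score_)


def train_param_regressor(
    table: pd.DataFrame,
    covariates: Sequence[str],
    target: str,
    cfg: RFConfig = RFConfig(),
    seed: int | None = None,
    log_transform: bool = True,
) -> tuple[RandomForestRegressor, float]:
    """Train a regressor on the (log) target; return (model, OOB MSE).

    The target must be strictly positive when ``log_transform`` is set; OOB
    MSE is computed from OOB-averaged predictions on the model (log) scale,
    matching how forest packages report regression OOB error.
    """
    X, y = _check_table(table, covariates, target)
    y = y.astype(float)
    if log_transform:
        bad = np.nonzero(y <= 0)[0]
        if bad.size:
            sites = (table["site_id"].iloc[bad].tolist()
                     if "site_id" in table else bad.tolist())
            raise ValueError(f"non-positive {target!r} at sites {sites}")
        y = np.log(y)
    # small terminal leaves for regression (fully-grown trees overfit the
    # per-site noise and inflate OOB MSE; the R randomForest default is 5)
    reg = RandomForestRegressor(
        n_estimators=cfg.ntree,
        max_features=min(cfg.mtry_reg, len(covariates)),
        min_samples_leaf=3,
        oob_score=True,
        random_state=cfg.seed if seed is None else seed,
        n_jobs=1,
    )
    reg.fit(X, y)
    oob_pred = reg.oob_prediction_
    ok = np.isfinite(oob_pred)
    oob_mse = float(np.mean((oob_pred[ok] - y[ok]) ** 2))
    return reg, oob_mse


OOBSummary = pd.DataFrame  # one row per model/statistic, SUMMARY_COLUMNS


def summarize_runs(values: Sequence[float]) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    return {
        "minimum": float(v.min()),
        "q1": float(np.quantile(v, 0.25)),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "q3": float(np.quantile(v, 0.75)),
        "maximum": float(v.max()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
    }


def repeat_oob(
    trainer: Callable[[int], float],
    cfg: RFConfig = RFConfig(),
) -> dict[str, float]:
    """Repeat a training run with seeds seed+0 ... seed+n_runs-1.

    ``trainer(seed)`` returns one OOB statistic (error rate or MSE); the
    run-to-run distribution is summarized by the seven order statistics
    (min, quartiles, mean, median, max, SD).
    """
    if cfg.n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    values = [trainer(cfg.seed + i) for i in range(cfg.n_runs)]
    return summarize_runs(values)


def _in_bag_counts(tree_random_state: int, n_samples: int) -> np.ndarray:
    """Per-row bootstrap draw counts for one tree.

    Reconstructs the bootstrap sample from the tree's stored random state
    the same way the forest drew it (n uniform draws with replacement), so
    out-of-bag rows are exactly those with count zero.
    """
    rs = np.random.RandomState(tree_random_state)
    idx = rs.randint(0, n_samples, n_samples)
    return np.bincount(idx, minlength=n_samples)


def oob_predictions(model, X: np.ndarray) -> np.ndarray:
    """OOB-aggregated predictions, recomputed from the per-tree bootstraps.

    Regression: mean over trees for which the row is out-of-bag (NaN if a
    row was in-bag everywhere). Used to cross-check the bootstrap
    reconstruction against the fitted forest's own OOB output.
    """
    n = X.shape[0]
    total = np.zeros(n)
    count = np.zeros(n)
    for tree in model.estimators_:
        oob = _in_bag_counts(tree.random_state, n) == 0
        if oob.any():
            total[oob] += tree.predict(X[oob])
            count[oob] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def variable_importance(
    model,
    table: pd.DataFrame,
    covariates: Sequence[str],
    target: str,
    cfg: RFConfig = RFConfig(),
    n_repeats: int = 5,
    log_transform: bool | None = None,
) -> pd.DataFrame:
    """Out-of-bag permutation importance per covariate, ranked descending.

    The mean decrease in prediction accuracy: for every tree, each
    covariate is permuted among that tree's out-of-bag rows and the drop in
    OOB accuracy (classification) or the rise in OOB squared error
    (regression) is averaged over trees and permutation repeats.
    Deterministic given ``cfg.seed``.
    """
    X = table[list(covariates)].to_numpy(dtype=float)
    y = table[target].to_numpy()
    is_classifier = isinstance(model, RandomForestClassifier)
    if is_classifier:
        y = y.astype(model.classes_.dtype)
    else:
        y = y.astype(float)
        if log_transform is None or log_transform:
            y = np.log(y)
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    n_feat = len(covariates)
    drops = np.zeros((len(model.estimators_), n_feat))
    reps = np.zeros((len(model.estimators_), n_feat))
    for t_i, tree in enumerate(model.estimators_):
        oob = np.nonzero(_in_bag_counts(tree.random_state, n) == 0)[0]
        if oob.size < 2:
            continue
        Xo, yo = X[oob], y[oob]
        pred = tree.predict(Xo)
        if is_classifier:
            base = np.mean(pred == yo)
        else:
            base = -np.mean((pred - yo) ** 2)
        for j in range(n_feat):
            for _ in range(n_repeats):
                Xp = Xo.copy()
                Xp[:, j] = Xo[rng.permutation(oob.size), j]
                pp = tree.predict(Xp)
                if is_classifier:
                    score = np.mean(pp == yo)
                else:
                    score = -np.mean((pp - yo) ** 2)
                drops[t_i, j] += base - score
                reps[t_i, j] += 1
    used = reps[:, 0] > 0
    per_tree = drops[used] / reps[used]
    out = pd.DataFrame({
        "covariate": list(covariates),
        "importance": per_tree.mean(axis=0),
        "importance_sd": per_tree.std(axis=0, ddof=1),
    })
    return out.sort_values(
        "importance", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class TrainedModelSet:
    """The four fitted models plus the covariate/transform contract."""

    classifier: RandomForestClassifier
    reg_log_dmat: RandomForestRegressor
    reg_log_ca: RandomForestRegressor
    reg_log_k: RandomForestRegressor
    covariates: list[str]
    cfg: RFConfig
    oob: dict[str, float] = field(default_factory=dict)
    transforms: dict[str, str] = field(
        default_factory=lambda: {"d_mat": "log", "c_a": "log", "k": "log"}
    )

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "covariates": self.covariates,
            "transforms": self.transforms,
            "cfg": asdict(self.cfg),
            "oob": self.oob,
            "models": {
                "classifier": "classifier.joblib",
                "reg_log_dmat": "reg_log_dmat.joblib",
                "reg_log_ca": "reg_log_ca.joblib",
                "reg_log_k": "reg_log_k.joblib",
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for attr, fname in manifest["models"].items():
            joblib.dump(getattr(self, attr), out_dir / fname)

    @classmethod
    def load(cls, in_dir) -> "TrainedModelSet":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "manifest.json").read_text())
        models = {
            attr: joblib.load(in_dir / fname)
            for attr, fname in manifest["models"].items()
        }
        return cls(
            covariates=manifest["covariates"],
            cfg=RFConfig(**manifest["cfg"]),
            oob=manifest.get("oob", {}),
            transforms=manifest["transforms"],
            **models,
        )


def train_model_set(
    table: pd.DataFrame,
    covariates: Sequence[str],
    cfg: RFConfig = RFConfig(),
    seed: int | None = None,
) -> TrainedModelSet:
    """Train all four models from one site table.

    The table needs the covariate columns plus ``has_mattic``, ``d_mat``,
    ``c_a`` and ``k``. The mattic-depth regressor is trained only on
    mattic-bearing sites (d_mat is undefined elsewhere).
    """
    seed = cfg.seed if seed is None else seed
    clf, oob_err = train_mattic_classifier(table, covariates, cfg, seed=seed)
    mattic_rows = table[table["has_mattic"].astype(bool)]
    reg_d, mse_d = train_param_regressor(
        mattic_rows, covariates, "d_mat", cfg, seed=seed + 1
    )
    reg_c, mse_c = train_param_regressor(
        table, covariates, "c_a", cfg, seed=seed + 2
    )
    reg_k, mse_k = train_param_regressor(
        table, covariates, "k", cfg, seed=seed + 3
    )
    return TrainedModelSet(
        classifier=clf, reg_log_dmat=reg_d, reg_log_ca=reg_c, reg_log_k=reg_k,
        covariates=list(covariates), cfg=cfg,
        oob={
            "mattic_error_rate": oob_err,
            "log_dmat_mse": mse_d,
            "log_ca_mse": mse_c,
            "log_k_mse": mse_k,
        },
    )


def predict_parameters(
    models: TrainedModelSet, covariate_rows: pd.DataFrame
) -> list[DepthFunctionParams | None]:
    """Per-row depth-function parameters from the fitted model set.

    Mattic occurrence by majority vote (exact ties break toward "no
    mattic"); d_mat, c_a and k by exp of the regressor output, so they are
    strictly positive by construction; d_mat is forced to 0 where the
    classifier says no mattic. Rows flagged ``nodata`` (or with any NaN
    covariate) yield None.
    """
    missing = set(models.covariates) - set(covariate_rows.columns)
    if missing:
        raise ValueError(f"missing covariates: {sorted(missing)}")
    X = covariate_rows[models.covariates].to_numpy(dtype=float)
    bad = np.isnan(X).any(axis=1)
    if "nodata" in covariate_rows:
        bad |= covariate_rows["nodata"].to_numpy(dtype=bool)
    Xok = X[~bad]
    n = len(X)
    out: list[DepthFunctionParams | None] = [None] * n
    if Xok.shape[0] == 0:
        return out
    true_col = list(models.classifier.classes_).index(True)
    p_mattic = models.classifier.predict_proba(Xok)[:, true_col]
    has_mattic = p_mattic > 0.5  # exact 50/50 tie -> no mattic
    d_mat = np.exp(models.reg_log_dmat.predict(Xok))
    c_a = np.exp(models.reg_log_ca.predict(Xok))
    k = np.exp(models.reg_log_k.predict(Xok))
    ok_idx = np.nonzero(~bad)[0]
    for j, i in enumerate(ok_idx):
        out[i] = DepthFunctionParams(
            has_mattic=bool(has_mattic[j]),
            d_mat=float(d_mat[j]) if has_mattic[j] else 0.0,
            c_a=float(c_a[j]),
            k=float(k[j]),
        )
    return out
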