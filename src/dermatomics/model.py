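"""Random Forest skin-age modeling.

Two model variants mirror the intended analysis: a *full* model on every
available numeric predictor, and a *reduced polynomial* model that keeps the
top-8 predictors by impurity importance and expands them with degree-2
polynomial features (no bias: k linear + k squared + k(k-1)/2 pairwise
products; 44 columns for k=8). Both are evaluated with 5-fold shuffled
cross-validation (fixed seed) reporting MAE (years) and R^2 (per-fold,
averaged), then refit on the full dataset.

For xenograft scoring, slice-level predictions are averaged per
(sample, condition), pivoted wide, and differenced into the three
rejuvenation deltas (Pre-Young, Pre-Old, Young-Old); a positive
Pre-Young delta means the graft's predicted age dropped in a young host.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import PolynomialFeatures


@dataclass(frozen=True)
class ModelConfig:
    n_trees: int = 500
    cv_folds: int = 5
    shuffle: bool = True
    seed: int = 42
    top_k: int = 8
    poly_degree: int = 2
    include_bias: bool = False
    n_jobs: int = -1


@dataclass
class TrainedModel:
    forest: RandomForestRegressor
    predictors: list[str]  # ordered schema, incl. expanded-term names
    importances: pd.Series  # indexed by predictor, descending
    cv_mae: float
    cv_r2: float
    cv_fold_mae: list[float] = field(default_factory=list)
    cv_fold_r2: list[float] = field(default_factory=list)
    kind: str = "full"  # "full" | "reduced-polynomial"
    top_features: list[str] = field(default_factory=list)  # pre-expansion names

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.predictors if c not in X.columns]
        if missing:
            raise KeyError(f"feature table is missing model columns: {missing}")
        return self.forest.predict(X[self.predictors].to_numpy())


class JoinError(ValueError):
    pass


def assemble_features(
    he: pd.DataFrame,
    itgb4: pd.DataFrame,
    ki67: pd.DataFrame,
    metadata: pd.DataFrame,
    id_col: str = "ID",
    age_col: str = "age",
) -> pd.DataFrame:
    """Inner-join the three feature sources on the accession ID and attach age.

    Xenograft IDs concatenate the donor sample number with the graft
    condition (e.g. ``S3_Young``) upstream, so the same join works for both
    cohorts. Duplicate (ID, slice) keys raise; IDs missing from the metadata
    are dropped with a warning.
    """
    for name, df in (("he", he), ("itgb4", itgb4), ("ki67", ki67),
                     ("metadata", metadata)):
        if id_col not in df.columns:
            raise JoinError(f"{name} table lacks the {id_col!r} key column")
    key = [id_col] + (["slice_id"] if "slice_id" in he.columns else [])
    dup = he[he.duplicated(key, keep=False)]
    if len(dup):
        raise JoinError(
            f"duplicate {key} keys in H&E table: "
            f"{sorted(dup[id_col].unique().tolist())}"
        )
    merged = he.merge(itgb4, on=id_col, how="inner", suffixes=("", "_itgb4"))
    merged = merged.merge(ki67, on=id_col, how="inner", suffixes=("", "_ki67"))
    meta_cols = [id_col, age_col] + [
        c for c in metadata.columns if c not in (id_col, age_col)
    ]
    known = merged[id_col].isin(metadata[id_col])
    if not known.all():
        dropped = sorted(merged.loc[~known, id_col].unique().tolist())
        warnings.warn(f"IDs absent from metadata dropped: {dropped}")
        merged = merged[known]
    return merged.merge(metadata[meta_cols], on=id_col, how="inner")


def predictor_columns(
    table: pd.DataFrame,
    exclude: tuple[str, ...] = ("ID", "age", "slice_id", "sample", "condition"),
) -> list[str]:
    """Numeric columns of the table minus the target/key columns."""
    num = table.select_dtypes(include=[np.number]).columns
    return [c for c in num if c not in exclude]


def _cross_validate(
    X: np.ndarray, y: np.ndarray, cfg: ModelConfig
) -> tuple[list[float], list[float]]:
    kf = KFold(n_splits=cfg.cv_folds, shuffle=cfg.shuffle, random_state=cfg.seed)
    maes, r2s = [], []
    for train_idx, test_idx in kf.split(X):
        rf = RandomForestRegressor(
            n_estimators=cfg.n_trees, random_state=cfg.seed, n_jobs=cfg.n_jobs
        )
        rf.fit(X[train_idx], y[train_idx])
        pred = rf.predict(X[test_idx])
        maes.append(mean_absolute_error(y[test_idx], pred))
        r2s.append(r2_score(y[test_idx], pred))
    return maes, r2s


def train_full(
    table: pd.DataFrame,
    cfg: ModelConfig | None = None,
    predictors: list[str] | None = None,
    age_col: str = "age",
) -> TrainedModel:
    """Train and cross-validate the full-feature Random Forest."""
    cfg = cfg or ModelConfig()
    predictors = predictors or predictor_columns(table)
    sub = table[predictors + [age_col]].dropna()
    if len(sub) < cfg.cv_folds:
        raise ValueError(
            f"{len(sub)} complete rows < {cfg.cv_folds} CV folds"
        )
    X = sub[predictors].to_numpy(float)
    y = sub[age_col].to_numpy(float)
    if np.ptp(y) == 0:
        warnings.warn("constant age target: model is degenerate")
    maes, r2s = _cross_validate(X, y, cfg)
    rf = RandomForestRegressor(
        n_estimators=cfg.n_trees, random_state=cfg.seed, n_jobs=cfg.n_jobs
    )
    rf.fit(X, y)
    imp = pd.Series(rf.feature_importances_, index=predictors)
    # stable descending sort; ties keep column order
    imp = imp.iloc[np.argsort(-imp.to_numpy(), kind="stable")]
    return TrainedModel(
        forest=rf, predictors=predictors, importances=imp,
        cv_mae=float(np.mean(maes)), cv_r2=float(np.mean(r2s)),
        cv_fold_mae=maes, cv_fold_r2=r2s, kind="full",
    )


def polynomial_feature_names(features: list[str]) -> list[str]:
    """Deterministic names: linear terms, squares, then pairwise products
    in input-column order (``fA*fB`` with A before B)."""
    names = list(features)
    names += [f"{f}^2" for f in features]
    names += [f"{a}*{b}" for a, b in combinations(features, 2)]
    return names


def polynomial_expand(
    table: pd.DataFrame, features: list[str], degree: int = 2,
    include_bias: bool = False,
) -> pd.DataFrame:
    """Degree-2 polynomial expansion of the selected feature columns.

    Produces k linear + k squared + k(k-1)/2 pairwise-product columns
    (44 for k=8), named deterministically; other table columns pass through.
    """
    if degree != 2:
        raise NotImplementedError("only degree-2 expansion is supported")
    pf = PolynomialFeatures(degree=2, include_bias=include_bias)
    X = table[features].to_numpy(float)
    Xp = pf.fit_transform(X)
    sk_names = list(pf.get_feature_names_out(features))
    expanded = pd.DataFrame(Xp, columns=sk_names, index=table.index)
    rename = {f: f for f in features}
    rename.update({f"{f}^2": f"{f}^2" for f in features})
    out = pd.DataFrame(index=table.index)
    for name in polynomial_feature_names(features):
        if "*" in name:
            a, b = name.split("*")
            out[name] = expanded[f"{a} {b}"]
        else:
            out[name] = expanded[name]
    passthrough = [c for c in table.columns if c not in features]
    return pd.concat([out, table[passthrough]], axis=1)


def train_reduced(
    table: pd.DataFrame,
    full_model: TrainedModel,
    cfg: ModelConfig | None = None,
    age_col: str = "age",
) -> TrainedModel:
    """Top-k selection + polynomial expansion + retrain with the same folds."""
    cfg = cfg or ModelConfig()
    k = min(cfg.top_k, len(full_model.importances))
    if k < cfg.top_k:
        warnings.warn(
            f"only {k} predictors available; using all instead of top {cfg.top_k}"
        )
    top = list(full_model.importances.index[:k])
    expanded = polynomial_expand(table, top, degree=cfg.poly_degree,
                                 include_bias=cfg.include_bias)
    poly_cols = polynomial_feature_names(top)
    model = train_full(expanded, cfg, predictors=poly_cols, age_col=age_col)
    model.kind = "reduced-polynomial"
    model.top_features = top
    return model


@dataclass
class XenograftDelta:
    sample: str
    pre: float = np.nan
    young: float = np.nan
    old: float = np.nan
    delta_pre_young: float = np.nan
    delta_pre_old: float = np.nan
    delta_young_old: float = np.nan


def predict_and_delta(
    model: TrainedModel,
    graft_table: pd.DataFrame,
    sample_col: str = "sample",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Score graft slices and compute per-donor rejuvenation deltas.

    Slice predictions are averaged within each (sample, condition) pair and
    pivoted wide over conditions Pre/Young/Old. Deltas are differences of
    condition means: ``delta_pre_young = Pre - Young`` (positive = predicted
    age dropped after grafting into a young host), and likewise for
    Pre-Old and Young-Old. Donors missing a condition get missing deltas.
    """
    if model.top_features:  # reduced model: expand raw features first
        missing = [c for c in model.top_features if c not in graft_table.columns]
        if missing:
            raise KeyError(f"graft table is missing model columns: {missing}")
        scored = polynomial_expand(graft_table, model.top_features)
    else:
        scored = graft_table.copy()
    scored = scored.dropna(subset=model.predictors)
    preds = model.predict(scored)
    df = pd.DataFrame(
        {
            sample_col: scored[sample_col].to_numpy(),
            condition_col: scored[condition_col].to_numpy(),
            "predicted_age": preds,
        }
    )
    means = (
        df.groupby([sample_col, condition_col])["predicted_age"]
        .mean()
        .unstack(condition_col)
    )
    for cond in ("Pre", "Young", "Old"):
        if cond not in means.columns:
            means[cond] = np.nan
    wide = means[["Pre", "Young", "Old"]].copy()
    wide["delta_pre_young"] = wide["Pre"] - wide["Young"]
    wide["delta_pre_old"] = wide["Pre"] - wide["Old"]
    wide["delta_young_old"] = wide["Young"] - wide["Old"]
    return wide.reset_index()
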