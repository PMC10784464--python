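"""Tree-ensemble genomic prediction on SNP dosages plus environment factors.

Three regression-tree ensembles over a common feature encoding (marker
dosages followed by one-hot location and year indicators):

* bagging — D bootstrap resamples, one fully grown tree each, prediction
  is the plain average over the D trees;
* random forest — bagging with a random subset of m_try candidate
  predictors per split (default floor(p/3), the regression-tree rule);
* boosting — squared-error gradient boosting: each depth-limited tree is
  fit to the current residuals and accumulated with shrinkage lambda
  around the training-mean baseline.

The base tree learner is scikit-learn's DecisionTreeRegressor; the
bootstrap, subsampling and accumulation rules — and all default
hyperparameters (500 trees for bagging/RF; 250 trees, lambda = 0.1,
depth 3 for boosting) — are part of this module's contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .genotypes import GenotypeMatrix

__all__ = [
    "EnsembleSpec",
    "FeatureTable",
    "FittedEnsemble",
    "encode_features",
    "fit_ensemble",
    "predict_ensemble",
]

_DEFAULT_TREES = {"bagging": 500, "random_forest": 500, "boosting": 250}


@dataclass
class EnsembleSpec:
    """Hyperparameters for one ensemble method."""

    method: str                      # bagging | random_forest | boosting
    n_trees: int | None = None       # default 500 (bagging/RF) or 250 (boosting)
    m_try: int | None = None         # RF: floor(p/3), min 1; bagging: all p
    learning_rate: float = 0.1       # boosting shrinkage lambda
    depth: int = 3                   # boosting tree depth
    min_node_size: int = 5           # minimum leaf size for bagging/RF trees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _DEFAULT_TREES:
            raise ValueError(f"unknown ensemble method {self.method!r}")
        if self.n_trees is None:
            self.n_trees = _DEFAULT_TREES[self.method]
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class FeatureTable:
    """Design rows for (hybrid, environment) cells.

    ``X`` holds markers first, then location indicators, then year
    indicators, in a fixed column order; ``y`` is the eBLUE response (NaN
    for cells built purely for prediction); ``cells`` lists the (hybrid,
    environment) pair of each row.
    """

    X: pd.DataFrame
    y: pd.Series
    cells: list[tuple[str, str]] = field(repr=False, default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(self.X.iloc[idx].reset_index(drop=True),
                            self.y.iloc[idx].reset_index(drop=True),
                            [self.cells[i] for i in idx])


def encode_features(hybrids: GenotypeMatrix, eblues: pd.DataFrame,
                    env_info: pd.DataFrame,
                    cells: list[tuple[str, str]] | None = None,
                    trait: str | None = None) -> FeatureTable:
    """Build the SNP + environment-factor design for the given cells.

    ``env_info`` maps environment id -> location and year; both factors
    are one-hot encoded and appended after the marker columns. ``cells``
    defaults to the rows of ``eblues``; cells absent from the table get a
    NaN response and can serve as prediction rows.
    """
    df = eblues if trait is None else eblues[eblues["trait"] == trait]
    env_info = env_info.drop_duplicates("environment").set_index("environment")
    locations = sorted(env_info["location"].unique())
    years = sorted(env_info["year"].astype(str).unique())
    if cells is None:
        cells = list(zip(df["hybrid"], df["environment"]))
    lookup = df.set_index(["hybrid", "environment"])["eblue"]

    geno = hybrids.dosages
    rows, resp = [], []
    for h, e in cells:
        if e not in env_info.index:
            raise KeyError(f"unknown environment label {e!r}")
        if h not in geno.index:
            raise KeyError(f"hybrid {h!r} absent from genotype matrix")
        loc = env_info.loc[e, "location"]
        yr = str(env_info.loc[e, "year"])
        row = np.concatenate([
            geno.loc[h].to_numpy(dtype=float),
            [1.0 if loc == l else 0.0 for l in locations],
            [1.0 if yr == y else 0.0 for y in years],
        ])
        rows.append(row)
        resp.append(lookup.get((h, e), np.nan))
    columns = (list(geno.columns)
               + [f"loc_{l}" for l in locations]
               + [f"year_{y}" for y in years])
    X = pd.DataFrame(rows, columns=columns)
    return FeatureTable(X, pd.Series(resp, name="eblue"), list(cells))


@dataclass
class FittedEnsemble:
    spec: EnsembleSpec
    columns: list[str]
    trees: list
    baseline: float = 0.0  # training mean (boosting only)

    def predict(self, rows: FeatureTable | pd.DataFrame) -> np.ndarray:
        X = rows.X if isinstance(rows, FeatureTable) else rows
        if list(X.columns) != self.columns:
            raise ValueError("feature columns do not match the training order")
        Xv = X.to_numpy(dtype=float)
        preds = np.stack([t.predict(Xv) for t in self.trees])
        if self.spec.method == "boosting":
            return self.baseline + self.spec.learning_rate * preds.sum(axis=0)
        return preds.mean(axis=0)

    def staged_train_mse(self, train: FeatureTable) -> np.ndarray:
        """Boosting training MSE after 1..n_trees trees (diagnostic)."""
        if self.spec.method != "boosting":
            raise ValueError("staged MSE is a boosting diagnostic")
        Xv = train.X.to_numpy(dtype=float)
        y = train.y.to_numpy(dtype=float)
        f = np.full(len(y), self.baseline)
        out = []
        for t in self.trees:
            f = f + self.spec.learning_rate * t.predict(Xv)
            out.append(float(np.mean((y - f) ** 2)))
        return np.asarray(out)


def fit_ensemble(train: FeatureTable, spec: EnsembleSpec) -> FittedEnsemble:
    """Fit one of the three ensembles on the training rows."""
    if train.n_rows == 0:
        raise ValueError("empty training table")
    if train.y.isna().any():
        raise ValueError("training rows must all carry a response")
    p = train.n_predictors
    X = train.X.to_numpy(dtype=float)
    y = train.y.to_numpy(dtype=float)
    rng = np.random.default_rng(spec.seed)

    if spec.method in ("bagging", "random_forest"):
        if spec.method == "bagging":
            m_try = p  # bagging considers every predictor at every split
        else:
            m_try = spec.m_try if spec.m_try is not None else max(1, p // 3)
        if not 1 <= m_try <= p:
            raise ValueError(f"m_try={m_try} outside [1, {p}]")
        trees = []
        n = len(y)
        for _ in range(spec.n_trees):
            idx = rng.integers(0, n, size=n)  # bootstrap resample
            tree_seed = int(rng.integers(0, 2**31 - 1))
            tree = DecisionTreeRegressor(
                max_features=m_try, min_samples_leaf=spec.min_node_size,
                random_state=tree_seed)
            tree.fit(X[idx], y[idx])
            trees.append(tree)
        return FittedEnsemble(spec, list(train.X.columns), trees)

    # boosting: sequential fit to residuals around the training mean
    baseline = float(np.mean(y))
    resid = y - baseline
    trees = []
    for _ in range(spec.n_trees):
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = DecisionTreeRegressor(max_depth=spec.depth,
                                     min_samples_leaf=spec.min_node_size,
                                     random_state=tree_seed)
        tree.fit(X, resid)
        resid = resid - spec.learning_rate * tree.predict(X)
        trees.append(tree)
    return FittedEnsemble(spec, list(train.X.columns), trees, baseline=baseline)


def predict_ensemble(model: FittedEnsemble, rows: FeatureTable) -> pd.DataFrame:
    """Prediction table (hybrid, environment, method, value) for the given rows."""
    values = model.predict(rows)
    return pd.DataFrame({
        "hybrid": [c[0] for c in rows.cells],
        "environment": [c[1] for c in rows.cells],
        "method": model.spec.method,
        "value": values,
    })
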