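"""Instability-correlated expression signature and PLSR prediction model.

The model treats a tissue's instability index as a function of its gene
expression profile.  Probes are ranked by the p-value of their Pearson
correlation with the measured index across training samples; the correlation
is a *ranking metric only* — the regression itself is partial least squares
(PLSR) on the top-n probes, so the fitted model captures covariance
structure, not just the marginal linear association used for ranking.  The
signature size n is chosen by forward selection: leave-one-tissue-out
cross-validation (replicate arrays of a tissue held out together) computes a
root-mean-squared error of prediction (RMSEP) for each candidate n, probes
being re-ranked inside every fold so that selection never sees the held-out
tissue, and the n minimizing RMSEP wins.

:class:`SignatureRegressor` follows the scikit-learn estimator contract
(``fit``/``predict``, ``get_params``, trailing-underscore fitted attributes)
and composes with sklearn model-selection tooling; the module-level
functions are thin wrappers over it operating on :class:`ExpressionMatrix`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ExpressionMatrix",
    "SignatureRegressor",
    "PredictionScore",
    "rank_probes",
    "loo_rmsep_curve",
    "fit_final_model",
    "predict_index",
    "evaluate_rmsep",
]

DEFAULT_N_GRID = (5, 10, 25, 50, 75, 100, 150, 200, 300, 500)


@dataclass
class ExpressionMatrix:
    """Probes × samples log2 expression with per-sample phenotype.

    ``values`` has probe ids as index and sample ids as columns;
    ``phenotype`` (the measured instability index) may be None for
    prediction-only cohorts; ``tissue_of`` maps sample id → tissue label and
    defines the cross-validation blocks.
    """

    values: pd.DataFrame
    phenotype: pd.Series | None = None
    tissue_of: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.tissue_of is None:
            self.tissue_of = pd.Series(self.values.columns, index=self.values.columns)
        if self.phenotype is not None:
            missing = set(self.values.columns) - set(self.phenotype.index)
            if missing:
                raise ValueError(f"phenotype missing for samples {sorted(missing)}")
            self.phenotype = self.phenotype.loc[self.values.columns].astype(float)
        self.tissue_of = self.tissue_of.loc[self.values.columns]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def X(self) -> pd.DataFrame:
        """Samples × probes view (the estimator's orientation)."""
        return self.values.T

    def write(self, expression_tsv: str | Path, phenotype_csv: str | Path | None = None) -> None:
        self.values.to_csv(expression_tsv, sep="\t", index_label="probe_id")
        if phenotype_csv is not None:
            if self.phenotype is None:
                raise ValueError("no phenotype to write")
            pd.DataFrame({
                "sample_id": self.sample_ids,
                "tissue": self.tissue_of.values,
                "instability_index": self.phenotype.values,
            }).to_csv(phenotype_csv, index=False)

    @classmethod
    def read(
        cls, expression_tsv: str | Path, phenotype_csv: str | Path | None = None
    ) -> "ExpressionMatrix":
        values = pd.read_csv(expression_tsv, sep="\t", index_col=0)
        phenotype = tissue_of = None
        if phenotype_csv is not None:
            pheno = pd.read_csv(phenotype_csv).set_index("sample_id")
            phenotype = pheno["instability_index"]
            tissue_of = pheno["tissue"]
        return cls(values=values, phenotype=phenotype, tissue_of=tissue_of)


def _rank_array(X: np.ndarray, y: np.ndarray, probe_ids: pd.Index) -> pd.DataFrame:
    """Pearson r and two-sided p per probe, sorted by (p, probe id).

    Zero-variance probes have undefined correlation: they are flagged and
    ranked after every well-defined probe.
    """
    n = len(y)
    if n < 3:
        raise ValueError("probe ranking needs at least 3 samples")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    zero_var = sx == 0
    if sy == 0:
        raise ValueError("phenotype has zero variance")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    r[zero_var] = np.nan
    p[zero_var] = np.nan
    out = pd.DataFrame({"r": r, "p": p, "zero_variance": zero_var}, index=probe_ids)
    order = sorted(
        range(len(probe_ids)),
        key=lambda i: (bool(zero_var[i]), p[i] if not zero_var[i] else np.inf, probe_ids[i]),
    )
    return out.iloc[order]


def _pls_coef_path(X: np.ndarray, y: np.ndarray, max_components: int):
    """Coefficient path for 1..K PLS components from a single fit.

    PLS components are nested, so the k-component model's coefficients are
    recoverable by truncating the rotation/loading matrices of one
    K-component fit.  Predictors and response are mean-centered only.
    Returns (x_mean, y_mean, [coef_k for k in 1..K]).
    """
    n, m = X.shape
    K = int(min(max_components, m, max(1, n - 1)))
    pls = PLSRegression(n_components=K, scale=False).fit(X, y)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    coefs = [
        (pls.x_rotations_[:, :k] @ pls.y_loadings_[:, :k].T).ravel()
        for k in range(1, K + 1)
    ]
    return x_mean, y_mean, coefs


def _choose_components(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, max_components: int
) -> int:
    """Inner leave-one-group-out RMSEP minimizer over the component path."""
    uniq = np.unique(groups)
    if len(uniq) < 3:
        return 1
    sq_err: dict[int, list[float]] = {}
    k_common = max_components
    for g in uniq:
        held = groups == g
        x_mean, y_mean, coefs = _pls_coef_path(X[~held], y[~held], max_components)
        k_common = min(k_common, len(coefs))
        for k, coef in enumerate(coefs, start=1):
            pred = (X[held] - x_mean) @ coef + y_mean
            sq_err.setdefault(k, []).extend(((pred - y[held]) ** 2).tolist())
    rmseps = {k: float(np.sqrt(np.mean(v))) for k, v in sq_err.items() if k <= k_common}
    return min(sorted(rmseps), key=lambda k: rmseps[k])


class SignatureRegressor(RegressorMixin, BaseEstimator):
    """Correlation-ranked forward-selection PLSR for instability prediction.

    Parameters
    ----------
    n_grid : tuple of int
        Candidate signature sizes for forward selection.
    max_components : int
        Cap on PLS latent components; the count actually used is chosen per
        fit by an inner leave-one-group-out RMSEP criterion.
    cv_unit : {"tissue", "sample"}
        Cross-validation block: "tissue" holds out all replicate samples of
        a tissue together (the default, honest for replicated designs).
    rerank_in_fold : bool
        Re-rank probes within every CV fold (default).  False reuses the
        global ranking, which leaks selection information into the CV error
        and is provided only for comparison.
    n_selected, n_components : int, optional
        Fix the signature size and/or component count, skipping the
        corresponding selection step.

    Attributes
    ----------
    ranked_probes_ : DataFrame of per-probe r, p in rank order.
    cv_curve_ : dict mapping candidate n → leave-one-out RMSEP.
    cv_predictions_ : dict mapping candidate n → per-sample held-out predictions.
    n_selected_, n_components_ : chosen signature size and component count.
    selected_probes_ : list of probe ids in the signature.
    coef_, intercept_ : regression weights in original probe space.
    """

    def __init__(
        self,
        n_grid: tuple[int, ...] = DEFAULT_N_GRID,
        max_components: int = 10,
        cv_unit: str = "tissue",
        rerank_in_fold: bool = True,
        n_selected: int | None = None,
        n_components: int | None = None,
    ):
        self.n_grid = n_grid
        self.max_components = max_components
        self.cv_unit = cv_unit
        self.rerank_in_fold = rerank_in_fold
        self.n_selected = n_selected
        self.n_components = n_components

    def _coerce_X(self, X) -> tuple[np.ndarray, pd.Index]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), X.columns
        X = np.asarray(X, dtype=float)
        return X, pd.Index([f"f{i}" for i in range(X.shape[1])])

    def fit(self, X, y, groups=None):
        """Fit on samples × probes ``X`` and measured indices ``y``.

        ``groups`` assigns each sample its tissue; with ``cv_unit="tissue"``
        and no groups, each sample is its own block (plain LOO).
        """
        Xa, probe_ids = self._coerce_X(X)
        y = np.asarray(y, dtype=float)
        if Xa.shape[0] != len(y):
            raise ValueError("X and y disagree on sample count")
        if groups is None or self.cv_unit == "sample":
            groups = np.arange(len(y))
        groups = np.asarray(groups)

        self.feature_names_in_ = probe_ids
        self.n_features_in_ = Xa.shape[1]
        self.ranked_probes_ = _rank_array(Xa, y, probe_ids)
        usable = self.ranked_probes_.index[~self.ranked_probes_["zero_variance"]]
        col_of = {pid: i for i, pid in enumerate(probe_ids)}

        if self.n_selected is None:
            grid = sorted({n for n in self.n_grid if n <= len(usable)})
            if not grid:
                raise ValueError("n_grid has no feasible signature size")
            self.cv_curve_, self.cv_predictions_ = self._loo_curve(Xa, y, groups, grid, col_of)
            self.n_selected_ = min(grid, key=lambda n: (self.cv_curve_[n], n))
        else:
            self.cv_curve_, self.cv_predictions_ = {}, {}
            self.n_selected_ = int(self.n_selected)

        top = list(usable[: self.n_selected_])
        idx = np.array([col_of[pid] for pid in top])
        Xs = Xa[:, idx]
        if self.n_components is None:
            self.n_components_ = _choose_components(Xs, y, groups, self.max_components)
        else:
            self.n_components_ = int(min(self.n_components, Xs.shape[1], len(y) - 1))
        x_mean, y_mean, coefs = _pls_coef_path(Xs, y, self.n_components_)
        self.n_components_ = min(self.n_components_, len(coefs))
        self.selected_probes_ = top
        self.x_mean_ = x_mean
        self.coef_ = coefs[self.n_components_ - 1]
        self.intercept_ = y_mean - float(x_mean @ self.coef_)
        self.training_rmsep_ = float(
            np.sqrt(np.mean((Xs @ self.coef_ + self.intercept_ - y) ** 2))
        )
        return self

    def _loo_curve(self, Xa, y, groups, grid, col_of):
        global_usable = self.ranked_probes_.index[~self.ranked_probes_["zero_variance"]]
        curve: dict[int, list[float]] = {n: [] for n in grid}
        preds: dict[int, dict] = {n: {} for n in grid}
        for g in np.unique(groups):
            held = groups == g
            if self.rerank_in_fold:
                ranked = _rank_array(Xa[~held], y[~held], self.feature_names_in_)
                fold_usable = ranked.index[~ranked["zero_variance"]]
            else:
                fold_usable = global_usable
            for n in grid:
                top = list(fold_usable[:n])
                idx = np.array([col_of[pid] for pid in top])
                Xs_train, y_train = Xa[np.ix_(~held, idx)], y[~held]
                k = _choose_components(Xs_train, y_train, groups[~held], self.max_components)
                x_mean, y_mean, coefs = _pls_coef_path(Xs_train, y_train, k)
                coef = coefs[min(k, len(coefs)) - 1]
                pred = (Xa[np.ix_(held, idx)] - x_mean) @ coef + y_mean
                curve[n].extend(((pred - y[held]) ** 2).tolist())
                for i, s in zip(np.where(held)[0], pred):
                    preds[n][i] = float(s)
        rmsep = {n: float(np.sqrt(np.mean(v))) for n, v in curve.items()}
        return rmsep, preds

    def predict(self, X):
        """Predicted instability index per sample."""
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            missing = [p for p in self.selected_probes_ if p not in X.columns]
            if missing:
                raise KeyError(f"expression matrix lacks signature probes: {missing}")
            Xs = X[self.selected_probes_].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] == len(self.selected_probes_):
                Xs = X
            elif X.shape[1] == self.n_features_in_:
                col_of = {pid: i for i, pid in enumerate(self.feature_names_in_)}
                Xs = X[:, [col_of[p] for p in self.selected_probes_]]
            else:
                raise ValueError(
                    f"X has {X.shape[1]} features; expected {len(self.selected_probes_)} "
                    f"(signature) or {self.n_features_in_} (full training set)"
                )
        return Xs @ self.coef_ + self.intercept_

    def to_json(self, path: str | Path) -> None:
        """Serialize the fitted model (probes, coefficients, CV curve)."""
        check_is_fitted(self, "coef_")
        payload = {
            "selected_probes": list(self.selected_probes_),
            "coef": [float(c) for c in self.coef_],
            "intercept": float(self.intercept_),
            "n_selected": int(self.n_selected_),
            "n_components": int(self.n_components_),
            "cv_curve": {str(k): v for k, v in self.cv_curve_.items()},
            "training_rmsep": self.training_rmsep_,
            "params": {
                "n_grid": list(self.n_grid),
                "max_components": self.max_components,
                "cv_unit": self.cv_unit,
                "rerank_in_fold": self.rerank_in_fold,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureRegressor":
        payload = json.loads(Path(path).read_text())
        model = cls(
            n_grid=tuple(payload["params"]["n_grid"]),
            max_components=payload["params"]["max_components"],
            cv_unit=payload["params"]["cv_unit"],
            rerank_in_fold=payload["params"]["rerank_in_fold"],
        )
        model.selected_probes_ = payload["selected_probes"]
        model.coef_ = np.asarray(payload["coef"])
        model.intercept_ = payload["intercept"]
        model.n_selected_ = payload["n_selected"]
        model.n_components_ = payload["n_components"]
        model.cv_curve_ = {int(k): v for k, v in payload["cv_curve"].items()}
        model.training_rmsep_ = payload["training_rmsep"]
        model.n_features_in_ = len(payload["selected_probes"])
        model.feature_names_in_ = pd.Index(payload["selected_probes"])
        return model


@dataclass(frozen=True)
class PredictionScore:
    """RMSEP plus the Pearson correlation of predicted vs measured."""

    rmsep: float
    pearson_r: float
    p_value: float


def rank_probes(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-probe Pearson r/p against the phenotype, in rank order."""
    if expr.phenotype is None:
        raise ValueError("ranking requires a phenotype")
    return _rank_array(expr.X().to_numpy(dtype=float), expr.phenotype.to_numpy(), expr.probe_ids)


def loo_rmsep_curve(
    expr: ExpressionMatrix,
    n_grid: tuple[int, ...] = DEFAULT_N_GRID,
    max_components: int = 10,
    rerank_in_fold: bool = True,
    cv_unit: str = "tissue",
) -> dict[int, float]:
    """Forward-selection RMSEP curve by leave-one-tissue-out CV."""
    if not n_grid:
        raise ValueError("n_grid must not be empty")
    model = SignatureRegressor(
        n_grid=tuple(n_grid), max_components=max_components,
        rerank_in_fold=rerank_in_fold, cv_unit=cv_unit,
    ).fit(expr.X(), expr.phenotype, groups=expr.tissue_of.to_numpy())
    return model.cv_curve_


def fit_final_model(
    expr: ExpressionMatrix,
    n_selected: int,
    n_components: int | None = None,
    max_components: int = 10,
) -> SignatureRegressor:
    """Fit the final PLSR on all training samples with a fixed signature size."""
    return SignatureRegressor(
        n_selected=n_selected, n_components=n_components, max_components=max_components,
    ).fit(expr.X(), expr.phenotype, groups=expr.tissue_of.to_numpy())


def predict_index(
    model: SignatureRegressor, expr: ExpressionMatrix, average_replicates: bool = False
) -> pd.Series:
    """Predicted instability index per sample (or per tissue, averaged)."""
    pred = pd.Series(model.predict(expr.X()), index=expr.sample_ids, name="predicted_index")
    if average_replicates:
        return pred.groupby(expr.tissue_of).mean()
    return pred


def evaluate_rmsep(predicted, measured) -> PredictionScore:
    """RMSEP between prediction and measurement, with Pearson r and p."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    rmsep = float(np.sqrt(np.mean((predicted - measured) ** 2)))
    if len(predicted) >= 3 and np.std(predicted) > 0 and np.std(measured) > 0:
        r, p = stats.pearsonr(predicted, measured)
    else:
        r, p = float("nan"), float("nan")
    return PredictionScore(rmsep=rmsep, pearson_r=float(r), p_value=float(p))
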