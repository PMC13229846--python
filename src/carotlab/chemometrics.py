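"""Regression models linking colour parameters to pigment content.

The predictor matrix holds the five colour parameters (L*, a*, b*, C*,
h deg) in fixed order.  Because C* and h are derived from a* and b*, the
predictors are strongly multicollinear; partial least squares (PLS) with
latent variables is the reference method, with single and multiple linear
regressions retained for comparison.

PLS is the univariate NIPALS sequence on z-scored predictors and response:
each component's weight vector maximises covariance between the X-scores
and the current y-residual, X is deflated after every component, and the
final model is back-transformed to original units so the fitted model can
be written as an explicit coefficient vector over (L*, a*, b*, C*, h deg).

Model quality is reported as explained variance (both the squared Pearson
correlation of fitted vs observed and 1 - SSE/SST are stored), calibration
RMSE, and cross-validated RMSEP from ten random segments: the data are
randomly split into near-equal segments, each segment is predicted by a
model calibrated on the other nine (standardisation re-estimated inside
every training fold), predictions are reverted to original scale, and
RMSEP is the root mean squared error over all held-out predictions.
Relative errors are expressed against the mean of the observed contents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PREDICTOR_COLUMNS",
    "PLSColourRegressor",
    "ModelReport",
    "fit_single_linear",
    "fit_multiple_linear",
    "fit_pls",
    "cross_validate",
    "compare_to_reference",
    "load_reference_models",
    "build_report_tables",
]

#: Canonical predictor order for every model in this package.
PREDICTOR_COLUMNS = ("L_star", "a_star", "b_star", "C_star", "h_deg")


def predictor_matrix(df: pd.DataFrame) -> np.ndarray:
    """Extract the (n, 5) colour predictor matrix in canonical order."""
    missing = [c for c in PREDICTOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    X = df.loc[:, list(PREDICTOR_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("predictor matrix contains missing values")
    return X


def _standardise(M: np.ndarray):
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    return mean, sd


class PLSColourRegressor(RegressorMixin, BaseEstimator):
    """Univariate PLS regression (NIPALS) with z-score standardisation.

    Parameters
    ----------
    n_components : int, default 5
        Number of latent variables; must not exceed the number of
        predictors (five for the colour parameter matrix).

    Attributes
    ----------
    x_mean_, x_sd_, y_mean_, y_sd_ : standardisation parameters.
    x_weights_ : ndarray (p, k) — weight vectors w (unit norm).
    x_loadings_ : ndarray (p, k) — loadings p.
    y_loadings_ : ndarray (k,) — loadings q.
    coef_ : ndarray (p,) — coefficients in original units.
    intercept_ : float — intercept in original units.

    The latent-variable path and the back-transformed coefficient form give
    identical predictions (to numerical precision); both are exposed.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if self.n_components > p:
            raise ValueError(
                f"n_components={self.n_components} exceeds the {p} available predictors"
            )
        if n <= self.n_components:
            raise ValueError("need more samples than components")
        self.x_mean_, self.x_sd_ = _standardise(X)
        self.y_mean_, self.y_sd_ = float(y.mean()), float(y.std(ddof=1))
        if np.any(self.x_sd_ == 0.0):
            const = [i for i, s in enumerate(self.x_sd_) if s == 0.0]
            raise ValueError(f"constant predictor column(s) at index {const}")
        if self.y_sd_ == 0.0:
            raise ValueError("response is constant")
        Xs = (X - self.x_mean_) / self.x_sd_
        ys = (y - self.y_mean_) / self.y_sd_

        W = np.zeros((p, self.n_components))
        P = np.zeros((p, self.n_components))
        q = np.zeros(self.n_components)
        Xd, yd = Xs.copy(), ys.copy()
        k_eff = 0
        for k in range(self.n_components):
            w = Xd.T @ yd
            norm = np.linalg.norm(w)
            if norm < 1e-12:  # X residual carries no covariance with y
                break
            w /= norm
            t = Xd @ w
            tt = float(t @ t)
            if tt < 1e-12:
                break
            P[:, k] = Xd.T @ t / tt
            q[k] = float(yd @ t) / tt
            W[:, k] = w
            Xd -= np.outer(t, P[:, k])
            yd = yd - q[k] * t
            k_eff += 1
        self.n_components_ = k_eff
        W, P, q = W[:, :k_eff], P[:, :k_eff], q[:k_eff]
        self.x_weights_, self.x_loadings_, self.y_loadings_ = W, P, q
        # standardised-space coefficients: B = W (P'W)^{-1} q
        beta_std = W @ np.linalg.solve(P.T @ W, q)
        self.coef_ = beta_std * self.y_sd_ / self.x_sd_
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        return self

    def predict(self, X) -> np.ndarray:
        """Predict via the back-transformed coefficient vector."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_via_scores(self, X) -> np.ndarray:
        """Predict through the latent-variable path (scores then loadings).

        Provided as an internal consistency check: agrees with
        :meth:`predict` to numerical precision.
        """
        check_is_fitted(self, "coef_")
        Xd = (np.asarray(X, dtype=float) - self.x_mean_) / self.x_sd_
        Xd = Xd.copy()
        ys = np.zeros(Xd.shape[0])
        for k in range(self.n_components_):
            t = Xd @ self.x_weights_[:, k]
            ys += self.y_loadings_[k] * t
            Xd -= np.outer(t, self.x_loadings_[:, k])
        return ys * self.y_sd_ + self.y_mean_

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "n_components": self.n_components,
            "n_components_effective": self.n_components_,
            "x_mean": self.x_mean_.tolist(),
            "x_sd": self.x_sd_.tolist(),
            "y_mean": self.y_mean_,
            "y_sd": self.y_sd_,
            "weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "coefficients_original_scale": self.coef_.tolist(),
            "intercept": self.intercept_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSColourRegressor":
        m = cls(n_components=d["n_components"])
        m.n_components_ = d["n_components_effective"]
        m.x_mean_ = np.asarray(d["x_mean"], dtype=float)
        m.x_sd_ = np.asarray(d["x_sd"], dtype=float)
        m.y_mean_, m.y_sd_ = float(d["y_mean"]), float(d["y_sd"])
        m.x_weights_ = np.asarray(d["weights"], dtype=float)
        m.x_loadings_ = np.asarray(d["x_loadings"], dtype=float)
        m.y_loadings_ = np.asarray(d["y_loadings"], dtype=float)
        m.coef_ = np.asarray(d["coefficients_original_scale"], dtype=float)
        m.intercept_ = float(d["intercept"])
        return m


@dataclass
class ModelReport:
    """Fit-quality summary for one (pigment, light condition, model) cell."""

    pigment: str
    light_condition: str
    model_type: str  # single_linear | multiple_linear | pls
    r2: float  # squared Pearson correlation, fitted vs observed
    r2_ss: float  # 1 - SSE/SST
    rmse_cal: float
    rmse_cal_pct: float
    rmsep: float | None = None
    rmsep_pct: float | None = None
    p_value: float | None = None
    coefficients: dict = field(default_factory=dict)
    coef_significance: dict = field(default_factory=dict)
    n_samples: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _fit_stats(y: np.ndarray, fitted: np.ndarray):
    resid = y - fitted
    rmse = float(np.sqrt(np.mean(resid**2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_ss = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    if np.std(fitted) == 0.0 or np.std(y) == 0.0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    denom = abs(float(y.mean()))
    rmse_pct = 100.0 * rmse / denom if denom > 0 else float("nan")
    return r2, r2_ss, rmse, rmse_pct


def fit_single_linear(x, y, pigment="", light_condition="", predictor="") -> ModelReport:
    """Ordinary least squares of one pigment on one colour parameter."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0.0:
        raise ValueError("predictor has zero variance")
    if np.std(y) == 0.0:
        slope, intercept, r2, p = 0.0, float(y.mean()), 0.0, 1.0
        fitted = np.full_like(y, y.mean())
    else:
        res = scipy.stats.linregress(x, y)
        slope, intercept, p = res.slope, res.intercept, res.pvalue
        r2 = res.rvalue**2
        fitted = slope * x + intercept
    _, r2_ss, rmse, rmse_pct = _fit_stats(y, fitted)
    return ModelReport(
        pigment=pigment,
        light_condition=light_condition,
        model_type="single_linear",
        r2=float(r2),
        r2_ss=r2_ss,
        rmse_cal=rmse,
        rmse_cal_pct=rmse_pct,
        p_value=float(p),
        coefficients={predictor or "x": float(slope), "intercept": float(intercept)},
        n_samples=x.size,
    )


def _name_collinear_columns(Xz: np.ndarray, names) -> list:
    """Identify columns involved in an exact linear dependency."""
    full_rank = np.linalg.matrix_rank(Xz)
    culprits = []
    for j in range(Xz.shape[1]):
        reduced = np.delete(Xz, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            culprits.append(names[j])
    return culprits or list(names)


def fit_multiple_linear(X, y, pigment="", light_condition="", names=PREDICTOR_COLUMNS) -> ModelReport:
    """OLS of a pigment on all five colour parameters, z-scored predictors.

    Predictors are standardised so coefficient magnitudes are comparable
    across light conditions; significance stars follow the 0.05 / 0.01 /
    0.001 convention.  Exact collinearity raises an error naming the
    dependent columns — the designed failure mode that motivates PLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more than n_predictors + 1 observations")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        raise ValueError(f"constant predictor column(s): "
                         f"{[names[i] for i in np.where(sd == 0)[0]]}")
    Xz = (X - X.mean(axis=0)) / sd
    if np.linalg.matrix_rank(Xz) < p:
        raise np.linalg.LinAlgError(
            "exactly collinear predictors: " + ", ".join(_name_collinear_columns(Xz, names))
        )
    model = sm.OLS(y, sm.add_constant(Xz)).fit()
    fitted = np.asarray(model.fittedvalues)
    r2, r2_ss, rmse, rmse_pct = _fit_stats(y, fitted)
    coef = {"intercept": float(model.params[0])}
    stars = {}
    for i, name in enumerate(names):
        coef[name] = float(model.params[i + 1])
        stars[name] = _stars(float(model.pvalues[i + 1]))
    return ModelReport(
        pigment=pigment,
        light_condition=light_condition,
        model_type="multiple_linear",
        r2=r2,
        r2_ss=r2_ss,
        rmse_cal=rmse,
        rmse_cal_pct=rmse_pct,
        p_value=float(model.f_pvalue),
        coefficients=coef,
        coef_significance=stars,
        n_samples=n,
    )


def fit_pls(X, y, n_components: int = 5) -> PLSColourRegressor:
    """Fit a :class:`PLSColourRegressor` (deterministic; no randomness)."""
    return PLSColourRegressor(n_components=n_components).fit(X, y)


@dataclass
class CVResult:
    rmsep: float
    rmsep_pct: float
    predictions: np.ndarray  # held-out predictions, original sample order
    fold_assignments: np.ndarray


def cross_validate(
    X, y, estimator=None, n_segments: int = 10, seed: int = 0, relative_to: str = "mean"
) -> CVResult:
    """Random-segment cross-validation with per-fold refitting.

    The samples are split by a seeded random permutation into
    ``n_segments`` near-equal segments; each segment is predicted from a
    model calibrated on the remaining segments (standardisation parameters
    re-estimated inside every training fold), predictions are reverted to
    the original scale, and RMSEP is computed over all held-out
    predictions.  ``rmsep_pct`` is relative to the mean observed content
    by default (``relative_to="range"`` uses the observed range instead).
    """
    from sklearn.base import clone

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < n_segments:
        raise ValueError(f"cannot split {n} samples into {n_segments} segments")
    if estimator is None:
        estimator = PLSColourRegressor()
    preds = np.empty(n)
    folds = np.empty(n, dtype=int)
    kf = KFold(n_splits=n_segments, shuffle=True, random_state=seed)
    for k, (tr, te) in enumerate(kf.split(X)):
        model = clone(estimator).fit(X[tr], y[tr])
        preds[te] = model.predict(X[te])
        folds[te] = k
    rmsep = float(np.sqrt(np.mean((preds - y) ** 2)))
    if relative_to == "mean":
        denom = abs(float(y.mean()))
    elif relative_to == "range":
        denom = float(y.max() - y.min())
    else:
        raise ValueError(f"unknown relative_to {relative_to!r}")
    return CVResult(
        rmsep=rmsep,
        rmsep_pct=100.0 * rmsep / denom if denom > 0 else float("nan"),
        predictions=preds,
        fold_assignments=folds,
    )


def report_pls(
    X, y, pigment="", light_condition="", n_components=5, n_segments=10, seed=0
) -> "tuple[ModelReport, PLSColourRegressor]":
    """Fit PLS, cross-validate, and assemble a :class:`ModelReport`."""
    model = fit_pls(X, y, n_components=n_components)
    fitted = model.predict(X)
    r2, r2_ss, rmse, rmse_pct = _fit_stats(np.asarray(y, dtype=float), fitted)
    cv = cross_validate(
        X, y, PLSColourRegressor(n_components=n_components), n_segments=n_segments, seed=seed
    )
    coef = {name: float(c) for name, c in zip(PREDICTOR_COLUMNS, model.coef_)}
    coef["intercept"] = float(model.intercept_)
    report = ModelReport(
        pigment=pigment,
        light_condition=light_condition,
        model_type="pls",
        r2=r2,
        r2_ss=r2_ss,
        rmse_cal=rmse,
        rmse_cal_pct=rmse_pct,
        rmsep=cv.rmsep,
        rmsep_pct=cv.rmsep_pct,
        coefficients=coef,
        n_samples=len(np.asarray(y).ravel()),
    )
    return report, model


def load_reference_models() -> dict:
    """Published coefficient vectors keyed 'eq8'..'eq11', 'table3:<pigment>'."""
    from importlib.resources import files

    return json.loads(files("carotlab.data").joinpath("reference_models.json").read_text())


def compare_to_reference(coefficients, key: str, reference: dict | None = None) -> dict:
    """Signed coefficient deltas, cosine similarity and sign agreement.

    ``coefficients`` may be a 5-vector over the canonical predictor order,
    a dict of per-predictor coefficients, or a fitted
    :class:`PLSColourRegressor`.
    """
    if reference is None:
        reference = load_reference_models()
    try:
        ref = np.asarray(reference["models"][key]["coefficients"], dtype=float)
    except KeyError:
        raise KeyError(
            f"unknown reference model key {key!r}; "
            f"known: {sorted(reference['models'])}"
        ) from None
    if isinstance(coefficients, PLSColourRegressor):
        vec = np.asarray(coefficients.coef_, dtype=float)
    elif isinstance(coefficients, dict):
        vec = np.array([coefficients[c] for c in PREDICTOR_COLUMNS], dtype=float)
    else:
        vec = np.asarray(coefficients, dtype=float)
    if vec.shape != ref.shape:
        raise ValueError("coefficient vector must have 5 entries")
    deltas = vec - ref
    denom = np.linalg.norm(vec) * np.linalg.norm(ref)
    cosine = float(vec @ ref / denom) if denom > 0 else float("nan")
    sign_agreement = float(np.mean(np.sign(vec) == np.sign(ref)))
    return {
        "key": key,
        "deltas": dict(zip(PREDICTOR_COLUMNS, deltas.tolist())),
        "cosine_similarity": cosine,
        "sign_agreement": sign_agreement,
    }


def build_report_tables(reports) -> dict:
    """Assemble grid tables from a list of :class:`ModelReport`.

    Returns a dict of DataFrames:

    * ``"multiple_linear"`` — per-pigment coefficient/significance grid
      across light conditions (one block per pigment).
    * ``"pls_by_condition"`` — R2 / calibration RMSE(%) / RMSEP(%) per
      pigment x light condition.
    * ``"pls_models"`` — coefficient vectors of the PLS models.

    Missing grid cells remain absent; an empty input yields header-only
    tables.
    """
    ml_rows, pls_rows, model_rows = [], [], []
    for r in reports:
        if r.model_type == "multiple_linear":
            row = {"pigment": r.pigment, "light_condition": r.light_condition}
            for name in PREDICTOR_COLUMNS:
                row[name] = r.coefficients.get(name)
                row[name + "_sig"] = r.coef_significance.get(name, "")
            row["r2"] = r.r2_ss
            row["p_value"] = r.p_value
            ml_rows.append(row)
        elif r.model_type == "pls":
            pls_rows.append(
                {
                    "pigment": r.pigment,
                    "light_condition": r.light_condition,
                    "r2": r.r2,
                    "rmse_cal": r.rmse_cal,
                    "rmse_cal_pct": r.rmse_cal_pct,
                    "rmsep": r.rmsep,
                    "rmsep_pct": r.rmsep_pct,
                    "n": r.n_samples,
                }
            )
            model_rows.append(
                {
                    "pigment": r.pigment,
                    "light_condition": r.light_condition,
                    **{c: r.coefficients.get(c) for c in PREDICTOR_COLUMNS},
                    "intercept": r.coefficients.get("intercept"),
                }
            )
    ml_cols = ["pigment", "light_condition"]
    for name in PREDICTOR_COLUMNS:
        ml_cols += [name, name + "_sig"]
    ml_cols += ["r2", "p_value"]
    return {
        "multiple_linear": pd.DataFrame(ml_rows, columns=ml_cols),
        "pls_by_condition": pd.DataFrame(
            pls_rows,
            columns=["pigment", "light_condition", "r2", "rmse_cal",
                     "rmse_cal_pct", "rmsep", "rmsep_pct", "n"],
        ),
        "pls_models": pd.DataFrame(
            model_rows,
            columns=["pigment", "light_condition", *PREDICTOR_COLUMNS, "intercept"],
        ),
    }


def tables_to_markdown(tables: dict) -> str:
    """Render the report tables as simple GitHub-flavoured markdown."""
    chunks = []
    for name, df in tables.items():
        chunks.append(f"## {name}\n")
        if df.empty:
            chunks.append("| " + " | ".join(df.columns) + " |")
            chunks.append("|" + "---|" * len(df.columns))
        else:
            chunks.append("| " + " | ".join(df.columns) + " |")
            chunks.append("|" + "---|" * len(df.columns))
            for _, row in df.iterrows():
                cells = [
                    f"{v:.4g}" if isinstance(v, float) else str(v) for v in row.to_list()
                ]
                chunks.append("| " + " | ".join(cells) + " |")
        chunks.append("")
    return "\n".join(chunks)
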