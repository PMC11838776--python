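"""The p_TSPO logistic model.

The model assigns each (subject, ROI) row a probability of TSPO
overexpression,

    logit(p_TSPO) = beta0 + sum_j beta_j X_j  [+ u_dataset],

with the X_j the normalized design features. The fixed-effects fit is
maximum likelihood via iteratively reweighted least squares (IRLS) with an
optional ridge penalty to rescue separated designs. The hierarchical variant
adds a Gaussian random intercept per dataset (acquisition batch effect) and
is fitted by Laplace-approximate maximum likelihood; with a single dataset it
degenerates exactly to the plain fit.

API follows the Model -> fit() -> Results convention: build
:class:`TSPOLogit` from a design frame, call :meth:`TSPOLogit.fit`, work
with the returned :class:`TSPOLogitResults` (params, bse, summary(),
predict(), wald_screen()).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .errors import (CollinearityError, FitError, InsufficientDataError,
                     PredictionError, SeparationError)
from .features import META_COLUMNS, FeatureSpec

__all__ = ["TSPOLogit", "TSPOLogitResults", "ModelBundle", "wald_screen",
           "predict_ptspo"]

_MIN_SIGMA = 1e-3
_MAX_SIGMA = 10.0


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # -2 log-likelihood for 0/1 outcomes, numerically safe in eta
    return float(2 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def _irls(X: np.ndarray, y: np.ndarray, ridge: float, offset: np.ndarray,
          maxiter: int, tol: float, feature_names: list[str]):
    """IRLS for logistic regression. Column 0 of X is the intercept and is
    never penalized. Returns (beta, deviance, n_iter, converged)."""
    n, p = X.shape
    pen = np.zeros(p)
    pen[1:] = ridge
    beta = np.zeros(p)
    dev = _deviance(y, X @ beta + offset)
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        eta = X @ beta + offset
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta - offset + (y - mu) / w
        A = X.T @ (w[:, None] * X) + 2 * np.diag(pen)
        b = X.T @ (w * z)
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError("singular weighted normal equations") from exc
        dev_new = _deviance(y, X @ beta_new + offset) + float(np.sum(pen * beta_new ** 2))
        if not np.isfinite(dev_new):
            raise FitError("deviance diverged during IRLS")
        beta = beta_new
        if abs(dev - dev_new) < tol * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new
        if ridge == 0 and np.max(np.abs(beta)) > 1e6:
            break
    if ridge == 0 and X.shape[1] > 1:
        scales = X.std(axis=0)
        scales[0] = 1.0
        scaled = np.abs(beta) * scales
        # a (near-)zero deviance is only reachable by driving |beta| to
        # infinity, i.e. the classes are (quasi-)completely separated
        if (dev < 1e-6 * n or np.max(scaled[1:], initial=0.0) > 5e2
                or (not converged and np.max(np.abs(beta)) > 1e4)):
            j = int(np.argmax(scaled[1:])) + 1
            raise SeparationError(
                f"(quasi-)complete separation; diverging feature: {feature_names[j - 1]!r}."
                " Refit with a small ridge penalty.")
    return beta, _deviance(y, X @ beta + offset), it, converged


class TSPOLogit:
    """Logistic model for the probability of regional TSPO overexpression.

    Parameters
    ----------
    endog : 0/1 outcome vector (training labels: low-expression ROI -> 0,
        high-expression ROI -> 1).
    exog : feature matrix, one column per named feature (no constant column;
        the intercept is handled internally).
    feature_names : column names of ``exog``.
    groups : optional dataset/batch label per row; with >= 2 distinct values
        ``fit()`` uses the hierarchical random-intercept likelihood.
    """

    def __init__(self, endog, exog, feature_names=None, groups=None,
                 feature_spec: FeatureSpec | None = None):
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise FitError("endog/exog shape mismatch")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise FitError("endog must be 0/1")
        if y.min() == y.max():
            raise InsufficientDataError("training outcomes contain a single class")
        if np.any(X.std(axis=0) == 0):
            j = int(np.flatnonzero(X.std(axis=0) == 0)[0])
            name = feature_names[j] if feature_names else f"column {j}"
            raise CollinearityError(f"constant feature {name!r}")
        self.endog = y
        self.exog = X
        self.feature_names = list(feature_names) if feature_names is not None \
            else [f"x{j}" for j in range(X.shape[1])]
        self.groups = None if groups is None else np.asarray(groups)
        self.feature_spec = feature_spec

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_design(cls, design: pd.DataFrame, features: list[str] | None = None,
                    feature_spec: FeatureSpec | None = None,
                    use_groups: bool = True) -> "TSPOLogit":
        """Build from a design frame produced by
        :func:`ptspo.features.build_design`; only rows with a 0/1 outcome
        (training-labelled ROIs) are used."""
        if features is None:
            features = (feature_spec.active_features if feature_spec is not None
                        else [c for c in design.columns if c not in META_COLUMNS])
        rows = design[design["outcome"].notna()]
        groups = None
        if use_groups and "dataset_id" in rows.columns:
            groups = rows["dataset_id"].to_numpy()
        return cls(rows["outcome"].to_numpy(), rows[features].to_numpy(),
                   feature_names=features, groups=groups, feature_spec=feature_spec)

    # -- fitting ------------------------------------------------------------
    def fit(self, ridge: float = 0.0, maxiter: int = 100, tol: float = 1e-10,
            hierarchical: bool | None = None) -> "TSPOLogitResults":
        """Maximum-likelihood fit.

        ``hierarchical=None`` (default) uses the random-intercept likelihood
        whenever >= 2 distinct groups are present; with one group it falls
        back to the plain fit with a notice.
        """
        if hierarchical is None:
            hierarchical = self.groups is not None and len(np.unique(self.groups)) > 1
        if hierarchical:
            if self.groups is None:
                raise FitError("hierarchical fit requires group labels")
            if len(np.unique(self.groups)) < 2:
                warnings.warn("single dataset: falling back to the plain logistic fit",
                              stacklevel=2)
                return self._fit_plain(ridge, maxiter, tol)
            return self._fit_laplace(ridge, maxiter, tol)
        return self._fit_plain(ridge, maxiter, tol)

    def _Xc(self) -> np.ndarray:
        return np.column_stack([np.ones(self.exog.shape[0]), self.exog])

    def _fit_plain(self, ridge, maxiter, tol) -> "TSPOLogitResults":
        X = self._Xc()
        if ridge == 0 and np.linalg.matrix_rank(X) < X.shape[1]:
            raise CollinearityError("rank-deficient design matrix")
        beta, dev, it, conv = _irls(X, self.endog, ridge, np.zeros(len(self.endog)),
                                    maxiter, tol, self.feature_names)
        mu = expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        A = X.T @ (w[:, None] * X)
        if ridge:
            pen = np.zeros(X.shape[1])
            pen[1:] = ridge
            A = A + 2 * np.diag(pen)
        cov = np.linalg.pinv(A)
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        return TSPOLogitResults(self, beta, bse, deviance=dev, n_iter=it,
                                converged=conv, method="irls", ridge=ridge)

    # -- hierarchical (Laplace) --------------------------------------------
    def _fit_laplace(self, ridge, maxiter, tol) -> "TSPOLogitResults":
        X = self._Xc()
        y = self.endog
        labels, gidx = np.unique(self.groups, return_inverse=True)
        G = len(labels)
        idx_per_group = [np.flatnonzero(gidx == g) for g in range(G)]
        pen = np.zeros(X.shape[1])
        pen[1:] = ridge

        def group_modes(beta, sigma):
            """Per-group posterior mode of the random intercept (1-D Newton)."""
            us, hs, lls = np.zeros(G), np.zeros(G), np.zeros(G)
            for g, idx in enumerate(idx_per_group):
                eta0 = X[idx] @ beta
                yg = y[idx]
                u = 0.0
                for _ in range(50):
                    mu = expit(eta0 + u)
                    grad = np.sum(yg - mu) - u / sigma ** 2
                    hess = -np.sum(mu * (1 - mu)) - 1 / sigma ** 2
                    step = -grad / hess
                    u += step
                    if abs(step) < 1e-12:
                        break
                mu = expit(eta0 + u)
                us[g] = u
                hs[g] = np.sum(np.clip(mu * (1 - mu), 1e-12, None)) + 1 / sigma ** 2
                lls[g] = -(_deviance(yg, eta0 + u) / 2) - u ** 2 / (2 * sigma ** 2)
            return us, hs, lls

        def neg_marginal(theta):
            beta, logsig = theta[:-1], theta[-1]
            sigma = float(np.exp(logsig))
            us, hs, lls = group_modes(beta, sigma)
            logL = float(np.sum(lls) - 0.5 * np.sum(np.log(sigma ** 2 * hs)))
            return -(logL - float(np.sum(pen * beta ** 2)))

        start = self._fit_plain(max(ridge, 1e-8), maxiter, tol).params_array
        x0 = np.concatenate([start, [np.log(0.5)]])
        bounds = [(None, None)] * X.shape[1] + [(np.log(_MIN_SIGMA), np.log(_MAX_SIGMA))]
        opt = minimize(neg_marginal, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
        if not opt.success and not np.isfinite(opt.fun):
            raise FitError(f"hierarchical fit failed: {opt.message}")
        beta = opt.x[:-1]
        sigma = float(np.exp(opt.x[-1]))
        us, _, _ = group_modes(beta, sigma)
        # centre the intercept offsets: their mean belongs to beta0
        shift = float(us.mean())
        beta = beta.copy()
        beta[0] += shift
        us = us - shift
        # fixed-effect covariance from the numerical Hessian of the marginal
        hess = _numerical_hessian(neg_marginal, np.concatenate([beta, [opt.x[-1]]]))
        try:
            cov = np.linalg.pinv(hess)[:X.shape[1], :X.shape[1]]
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            bse = np.full(X.shape[1], np.nan)
        eta = X @ beta + us[gidx]
        return TSPOLogitResults(
            self, beta, bse, deviance=_deviance(y, eta), n_iter=int(opt.nit),
            converged=bool(opt.success), method="laplace", ridge=ridge,
            random_effects=pd.Series(us, index=[str(l) for l in labels]),
            random_sd=sigma)


def _numerical_hessian(f, x, step: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    h = step * (1 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej); fpm = f(x + ei - ej)
            fmp = f(x - ei + ej); fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


class TSPOLogitResults:
    """Fitted p_TSPO model: coefficient estimates, their uncertainties,
    optional per-dataset intercepts, and prediction."""

    def __init__(self, model: TSPOLogit, beta: np.ndarray, bse: np.ndarray, *,
                 deviance: float, n_iter: int, converged: bool, method: str,
                 ridge: float = 0.0, random_effects: pd.Series | None = None,
                 random_sd: float | None = None):
        self.model = model
        names = ["intercept"] + model.feature_names
        self.params = pd.Series(beta, index=names)
        self.bse = pd.Series(bse, index=names)
        self.deviance = deviance
        self.n_iter = n_iter
        self.converged = converged
        self.method = method
        self.ridge = ridge
        self.random_effects = random_effects
        self.random_sd = random_sd

    # -- basic statistics ---------------------------------------------------
    @property
    def params_array(self) -> np.ndarray:
        return self.params.to_numpy()

    @property
    def llf(self) -> float:
        return -self.deviance / 2

    @property
    def zvalues(self) -> pd.Series:
        """Wald z statistics (coefficient / SE)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * norm.sf(np.abs(self.zvalues.to_numpy())),
                         index=self.params.index)

    def wald_screen(self, z_threshold: float = 1.96) -> list[str]:
        """Features with |Wald z| above the threshold (intercept excluded)."""
        z = self.zvalues.drop("intercept")
        if not np.all(np.isfinite(self.bse.drop("intercept"))):
            raise FitError("standard errors unavailable for Wald screening")
        return [name for name, v in z.items() if abs(v) > z_threshold]

    # -- prediction ---------------------------------------------------------
    def linear_predictor(self, exog, dataset=None,
                         dataset_policy: str = "population") -> np.ndarray:
        """eta = beta0 + X beta (+ dataset intercept). Datasets unseen in
        training get offset 0 (population level)."""
        if isinstance(exog, pd.DataFrame):
            missing = [f for f in self.model.feature_names if f not in exog.columns]
            if missing:
                raise PredictionError(f"missing features: {missing}")
            X = exog[self.model.feature_names].to_numpy(float)
            if dataset is None and dataset_policy == "match" and "dataset_id" in exog:
                dataset = exog["dataset_id"].to_numpy()
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.model.feature_names):
                raise PredictionError(
                    f"expected {len(self.model.feature_names)} features, got {X.shape[1]}")
        if np.any(~np.isfinite(X)):
            raise PredictionError("non-finite feature values")
        eta = self.params_array[0] + X @ self.params_array[1:]
        if dataset is not None and self.random_effects is not None:
            offs = np.asarray([self.random_effects.get(str(d), 0.0)
                               for d in np.atleast_1d(dataset)])
            eta = eta + (offs if offs.size == eta.size else offs[0])
        return eta

    def predict(self, exog, dataset=None, dataset_policy: str = "population"
                ) -> np.ndarray:
        """Probability of TSPO overexpression for each row."""
        return expit(self.linear_predictor(exog, dataset, dataset_policy))

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "p_TSPO logistic model" + (" (hierarchical, Laplace)" if self.method == "laplace" else ""),
            "=" * 64,
            f"{'coef':<18}{'estimate':>12}{'std err':>12}{'Wald z':>11}{'P>|z|':>10}",
            "-" * 64,
        ]
        z, p = self.zvalues, self.pvalues
        for name in self.params.index:
            lines.append(f"{name:<18}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                         f"{z[name]:>11.2f}{p[name]:>10.3g}")
        lines.append("-" * 64)
        lines.append(f"deviance {self.deviance:.4f}   iterations {self.n_iter}"
                     f"   converged {self.converged}")
        if self.random_sd is not None:
            lines.append(f"between-dataset intercept SD {self.random_sd:.4f}")
            offs = ", ".join(f"{k}: {v:+.3f}" for k, v in self.random_effects.items())
            lines.append(f"dataset offsets  {offs}")
        lines.append("Wald z statistics reported (not t); dispersion fixed at 1.")
        return "\n".join(lines)

    def to_bundle(self, feature_spec: FeatureSpec | None = None,
                  seed: int | None = None) -> "ModelBundle":
        spec = feature_spec or self.model.feature_spec
        if spec is None:
            raise FitError("a FeatureSpec is required to bundle the model")
        return ModelBundle(
            feature_spec=spec, params=dict(self.params.items()),
            bse=dict(self.bse.items()), feature_names=list(self.model.feature_names),
            method=self.method, deviance=self.deviance,
            random_effects=(dict(self.random_effects.items())
                            if self.random_effects is not None else None),
            random_sd=self.random_sd, seed=seed)


def wald_screen(results: TSPOLogitResults, z_threshold: float = 1.96) -> list[str]:
    """Module-level alias of :meth:`TSPOLogitResults.wald_screen`."""
    return results.wald_screen(z_threshold)


def predict_ptspo(results_or_bundle, design: pd.DataFrame,
                  dataset_policy: str = "population") -> pd.DataFrame:
    """p_TSPO table (subject_id, roi_id, linear_predictor, p_tspo) for every
    row of a design frame."""
    eta = results_or_bundle.linear_predictor(design, dataset_policy=dataset_policy)
    out = design[[c for c in ("subject_id", "roi_id", "dataset_id") if c in design]].copy()
    out["linear_predictor"] = eta
    out["p_tspo"] = expit(eta)
    return out


@dataclass
class ModelBundle:
    """Serializable trained model: coefficients + normalization + metadata.

    The bundle is what the CLI persists after training and loads for
    prediction; it is independent of the in-memory fit objects.
    """

    feature_spec: FeatureSpec
    params: dict[str, float]
    bse: dict[str, float]
    feature_names: list[str]
    method: str
    deviance: float
    random_effects: dict[str, float] | None = None
    random_sd: float | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def linear_predictor(self, design: pd.DataFrame,
                         dataset_policy: str = "population") -> np.ndarray:
        missing = [f for f in self.feature_names if f not in design.columns]
        if missing:
            raise PredictionError(f"missing features: {missing}")
        X = design[self.feature_names].to_numpy(float)
        beta = np.array([self.params[f] for f in self.feature_names])
        eta = self.params["intercept"] + X @ beta
        if dataset_policy == "match" and self.random_effects and "dataset_id" in design:
            eta = eta + np.asarray([self.random_effects.get(str(d), 0.0)
                                    for d in design["dataset_id"]])
        return eta

    def predict(self, design: pd.DataFrame,
                dataset_policy: str = "population") -> pd.DataFrame:
        return predict_ptspo_bundle(self, design, dataset_policy)

    def save(self, path: str | Path) -> None:
        payload = {
            "feature_spec": self.feature_spec.to_dict(), "params": self.params,
            "bse": self.bse, "feature_names": self.feature_names,
            "method": self.method, "deviance": self.deviance,
            "random_effects": self.random_effects, "random_sd": self.random_sd,
            "seed": self.seed, "extras": self.extras,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        d = json.loads(Path(path).read_text())
        return cls(feature_spec=FeatureSpec.from_dict(d["feature_spec"]),
                   params=d["params"], bse=d["bse"],
                   feature_names=d["feature_names"], method=d["method"],
                   deviance=d["deviance"], random_effects=d.get("random_effects"),
                   random_sd=d.get("random_sd"), seed=d.get("seed"),
                   extras=d.get("extras", {}))


def predict_ptspo_bundle(bundle: ModelBundle, design: pd.DataFrame,
                         dataset_policy: str = "population") -> pd.DataFrame:
    eta = bundle.linear_predictor(design, dataset_policy)
    out = design[[c for c in ("subject_id", "roi_id", "dataset_id") if c in design]].copy()
    out["linear_predictor"] = eta
    out["p_tspo"] = expit(eta)
    return out
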