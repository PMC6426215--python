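"""From-scratch learners for genomic / phenomic prediction.

Four methods, the standard toolkit of genomic selection studies:

* :func:`fit_ridge` — ridge regression with an unpenalized intercept;
  ``lam="reml"`` estimates the penalty as sigma_e^2 / sigma_beta^2 of the
  equivalent random-effects model via the spectral decomposition of X X'.
* :func:`fit_plsr` — partial least squares regression (NIPALS deflation);
  ``ncomp="cv"`` picks the component count by inner 5-fold CV.
* :func:`fit_random_forest` — bagged unpruned CART regression trees with
  per-split feature subsampling (numba kernels).
* :func:`fit_bayesb` — Bayesian marker regression with a point mass at
  zero and a t-slab (normal slab with marker-specific scaled-inv-chi2
  variance), fit by Gibbs sampling (numba kernel).

All learners standardize columns internally (zero-variance columns are
excluded from standardization and get zero coefficients) so marker and
reflectance features are commensurate when concatenated.  Hyperparameter
defaults follow the community conventions of the corresponding R
packages: RF ntree=500, mtry=floor(p/3), min_node=5; BayesB pi=0.9,
nu=5, n_iter=6000, burnin=1000 with the slab scale solved from an
expected 50% of phenotypic variance; PLSR ncomp="cv"; ridge lam="reml".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import _kernels


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardizer:
    """Per-column centering/scaling record fit on the training partition."""

    mean: np.ndarray
    scale: np.ndarray
    constant: np.ndarray  # zero-variance flags

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        constant = sd <= 1e-12
        scale = np.where(constant, 1.0, sd)
        return cls(mean=mean, scale=scale, constant=constant)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mean) / self.scale
        if self.constant.any():
            Xs[:, self.constant] = 0.0
        return Xs


def _check_features(model_features, new_features) -> None:
    if model_features is None or new_features is None:
        return
    if list(model_features) != list(new_features):
        extra = set(new_features) - set(model_features)
        missing = set(model_features) - set(new_features)
        raise ValueError(
            f"feature mismatch: missing {sorted(missing)[:5]}, "
            f"unexpected {sorted(extra)[:5]}"
        )


# ---------------------------------------------------------------------------
# models


@dataclass
class LinearModel:
    """Shared predict/serialization for coefficient-based learners."""

    method: str
    intercept: float
    coef: np.ndarray  # on the standardized X scale
    std: Standardizer
    hyper: dict = field(default_factory=dict)
    features: list | None = None
    extra: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray, features=None) -> np.ndarray:
        _check_features(self.features, features)
        return self.intercept + self.std.transform(X) @ self.coef

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "intercept": float(self.intercept),
            "coef": self.coef.tolist(),
            "std": {"mean": self.std.mean.tolist(),
                    "scale": self.std.scale.tolist(),
                    "constant": self.std.constant.tolist()},
            "hyper": self.hyper,
            "features": self.features,
            "extra": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                      for k, v in self.extra.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        std = Standardizer(
            mean=np.asarray(d["std"]["mean"], dtype=float),
            scale=np.asarray(d["std"]["scale"], dtype=float),
            constant=np.asarray(d["std"]["constant"], dtype=bool),
        )
        return cls(method=d["method"], intercept=d["intercept"],
                   coef=np.asarray(d["coef"], dtype=float), std=std,
                   hyper=d.get("hyper", {}), features=d.get("features"),
                   extra=d.get("extra", {}))


@dataclass
class ForestModel:
    """Random-forest ensemble state (node arrays per tree)."""

    feat: np.ndarray
    thr: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    oob_prediction: np.ndarray
    hyper: dict
    features: list | None = None
    method: str = "rf"

    def predict(self, X: np.ndarray, features=None) -> np.ndarray:
        _check_features(self.features, features)
        X = np.ascontiguousarray(np.asarray(X, dtype=float))
        return _kernels.forest_predict(X, self.feat, self.thr, self.left,
                                       self.right, self.value)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "feat": self.feat.tolist(), "thr": self.thr.tolist(),
            "left": self.left.tolist(), "right": self.right.tolist(),
            "value": self.value.tolist(),
            "oob_prediction": self.oob_prediction.tolist(),
            "hyper": self.hyper, "features": self.features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForestModel":
        return cls(
            feat=np.asarray(d["feat"], dtype=np.int32),
            thr=np.asarray(d["thr"], dtype=float),
            left=np.asarray(d["left"], dtype=np.int32),
            right=np.asarray(d["right"], dtype=np.int32),
            value=np.asarray(d["value"], dtype=float),
            oob_prediction=np.asarray(d["oob_prediction"], dtype=float),
            hyper=d.get("hyper", {}), features=d.get("features"),
        )


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    return (ForestModel if d["method"] == "rf" else LinearModel).from_dict(d)


# ---------------------------------------------------------------------------
# ridge


def _reml_lambda(Xs: np.ndarray, yc: np.ndarray) -> float:
    """Penalty lambda = sigma_e^2 / sigma_beta^2 by REML on the equivalent
    random-effects model, via the eigendecomposition of Xs Xs'."""
    n = Xs.shape[0]
    K = Xs @ Xs.T
    theta, U = np.linalg.eigh(K)
    theta = np.clip(theta, 0.0, None)
    omega2 = (U.T @ yc) ** 2
    # centering makes the intercept direction a null eigenvector with
    # omega ~ 0; REML uses the n-1 remaining contrasts
    keep = np.argsort(theta)[1:]
    th = theta[keep]
    om2 = omega2[keep]
    m = len(th)

    def neg2(loglam):
        # profiled restricted -2 loglik of V = sigma_b^2 (K + lam I) on the
        # n-1 contrasts orthogonal to the intercept
        lam = np.exp(loglam)
        d = th + lam
        return m * np.log(np.sum(om2 / d) / m) + np.sum(np.log(d))

    res = minimize_scalar(neg2, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(np.exp(res.x))


def fit_ridge(X: np.ndarray, y: np.ndarray, lam="reml",
              features=None) -> LinearModel:
    """Ridge regression on standardized X with an unpenalized intercept.

    ``lam=0`` gives (minimum-norm) OLS; ``lam="reml"`` estimates the
    penalty from the data.  Solved in the primal or dual form, whichever
    is smaller.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n != len(y) or n < 3:
        raise ValueError("need rows(X) == len(y) >= 3")
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    ybar = float(y.mean())
    yc = y - ybar
    if lam == "reml":
        lam_val = _reml_lambda(Xs, yc)
    else:
        lam_val = float(lam)
        if lam_val < 0:
            raise ValueError("lambda must be >= 0")
    if lam_val == 0.0:
        coef = np.linalg.pinv(Xs) @ yc
    elif p <= n:
        A = Xs.T @ Xs + lam_val * np.eye(p)
        coef = np.linalg.solve(A, Xs.T @ yc)
    else:
        A = Xs @ Xs.T + lam_val * np.eye(n)
        coef = Xs.T @ np.linalg.solve(A, yc)
    return LinearModel(method="rr", intercept=ybar, coef=coef, std=std,
                       hyper={"lambda": lam_val,
                              "lambda_mode": "reml" if lam == "reml" else "fixed"},
                       features=list(features) if features is not None else None)


# ---------------------------------------------------------------------------
# PLSR


def _nipals(Xs: np.ndarray, yc: np.ndarray, ncomp: int):
    """NIPALS for univariate y; returns (W, P, q) loadings."""
    n, p = Xs.shape
    Xd = Xs.copy()
    yd = yc.copy()
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    used = 0
    for a in range(ncomp):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-12:
            break
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pa)
        yd = yd - qa * t
        W[:, a] = w
        P[:, a] = pa
        q[a] = qa
        used += 1
    return W[:, :used], P[:, :used], q[:used]


def _pls_coef(W, P, q) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    R = np.linalg.solve(P.T @ W, np.eye(W.shape[1]))
    return W @ R @ q


def fit_plsr(X: np.ndarray, y: np.ndarray, ncomp="cv", cv_folds: int = 5,
             cv_max_comp: int = 15, seed: int = 0,
             features=None) -> LinearModel:
    """Partial least squares regression by NIPALS on standardized X.

    ``ncomp="cv"`` selects the number of components on a 1..15 grid by
    inner 5-fold cross-validation (smallest MSE, ties to fewer
    components).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    max_valid = max(min(n - 1, p), 1)
    if ncomp == "cv":
        grid_top = min(cv_max_comp, max_valid)
        ncomp_val = _plsr_cv(X, y, grid_top, cv_folds, seed)
    else:
        ncomp_val = int(ncomp)
        if not 1 <= ncomp_val <= max_valid:
            raise ValueError(f"ncomp must be in [1, {max_valid}]")
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    ybar = float(y.mean())
    W, P, q = _nipals(Xs, y - ybar, ncomp_val)
    coef = _pls_coef(W, P, q)
    return LinearModel(method="plsr", intercept=ybar, coef=coef, std=std,
                       hyper={"ncomp": ncomp_val,
                              "ncomp_mode": "cv" if ncomp == "cv" else "fixed"},
                       features=list(features) if features is not None else None,
                       extra={"n_components_used": W.shape[1]})


def _plsr_cv(X, y, grid_top, folds, seed) -> int:
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = min(folds, n)
    sse = np.zeros(grid_top)
    for f in range(folds):
        test = perm[f::folds]
        train = np.setdiff1d(perm, test)
        if len(train) < 2:
            continue
        std = Standardizer.fit(X[train])
        Xs = std.transform(X[train])
        ybar = y[train].mean()
        top = min(grid_top, max(min(len(train) - 1, X.shape[1]), 1))
        W, P, q = _nipals(Xs, y[train] - ybar, top)
        Xt = std.transform(X[test])
        for a in range(grid_top):
            k = min(a + 1, W.shape[1])
            pred = ybar + Xt @ _pls_coef(W[:, :k], P[:, :k], q[:k])
            sse[a] += float(np.sum((y[test] - pred) ** 2))
    return int(np.argmin(sse)) + 1


# ---------------------------------------------------------------------------
# random forest


def fit_random_forest(X: np.ndarray, y: np.ndarray, ntree: int = 500,
                      mtry: int | None = None, min_node: int = 5,
                      seed: int = 0, features=None) -> ForestModel:
    """Bagged unpruned CART regression trees (variance-reduction splits
    over ``mtry`` randomly drawn features; default mtry = floor(p/3))."""
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    if mtry is None:
        mtry = max(p // 3, 1)
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must be in [1, {p}]")
    feat, thr, left, right, value, inbag = _kernels.grow_forest(
        X, y, ntree, mtry, min_node, seed % (2 ** 31)
    )
    oob = _kernels.forest_oob_predict(X, feat, thr, left, right, value, inbag)
    return ForestModel(feat=feat, thr=thr, left=left, right=right,
                       value=value, oob_prediction=oob,
                       hyper={"ntree": ntree, "mtry": mtry,
                              "min_node": min_node, "seed": seed},
                       features=list(features) if features is not None else None)


# ---------------------------------------------------------------------------
# BayesB


def fit_bayesb(X: np.ndarray, y: np.ndarray, pi: float = 0.9,
               nu: float = 5.0, s2: float | None = None,
               n_iter: int = 6000, burnin: int = 1000, thin: int = 1,
               r2: float = 0.5, seed: int = 0,
               features=None) -> LinearModel:
    """BayesB by Gibbs sampling: point mass at zero (prior prob ``pi``)
    plus a t-slab (normal with marker-specific scaled-inv-chi2 variance,
    ``nu`` degrees of freedom).

    When ``s2`` is None the slab scale is solved so the prior expectation
    of the marker variance explains a fraction ``r2`` of var(y) on
    standardized markers.  Returns posterior-mean effects; posterior
    inclusion probabilities are in ``model.extra["pip"]``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must be in [0, 1]")
    if nu <= 0 or n_iter <= burnin:
        raise ValueError("need nu > 0 and n_iter > burnin")
    std = Standardizer.fit(X)
    Xs = np.ascontiguousarray(std.transform(X))
    ybar = float(y.mean())
    yc = y - ybar
    vy = float(np.var(yc)) or 1.0
    if s2 is None:
        p_in = max((1.0 - pi) * p, 1.0)
        s2 = r2 * vy * max(nu - 2.0, 0.5) / (nu * p_in)
    nu_e, S_e = 5.0, (1.0 - r2) * vy * 3.0 / 5.0  # prior mean (1-r2)*vy
    mu, beta, pip, sig_e_chain = _kernels.bayesb_gibbs(
        Xs, yc, float(pi), float(nu), float(s2), int(n_iter), int(burnin),
        int(thin), int(seed) % (2 ** 31), nu_e, S_e
    )
    if pi >= 1.0:
        import warnings
        warnings.warn("BayesB with pi=1 is the all-null model")
    return LinearModel(
        method="bayesb", intercept=ybar + mu, coef=beta, std=std,
        hyper={"pi": pi, "nu": nu, "s2": s2, "n_iter": n_iter,
               "burnin": burnin, "thin": thin, "seed": seed},
        features=list(features) if features is not None else None,
        extra={"pip": pip, "sigma_e2_mean": float(sig_e_chain[burnin:].mean()),
               "sigma_e2_chain_tail": sig_e_chain[-50:]},
    )


# ---------------------------------------------------------------------------
# dispatch


_FITTERS = {
    "rr": fit_ridge,
    "plsr": fit_plsr,
    "rf": fit_random_forest,
    "bayesb": fit_bayesb,
}


def fit(method: str, X: np.ndarray, y: np.ndarray, seed: int = 0,
        features=None, **params):
    """Fit any of the four learners by name ('plsr', 'rf', 'rr', 'bayesb')."""
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; choose from "
                         f"{sorted(_FITTERS)}")
    if method in ("rf", "plsr", "bayesb"):
        params.setdefault("seed", seed)
    return _FITTERS[method](X, y, features=features, **params)


def predict(model, X: np.ndarray, features=None) -> np.ndarray:
    """Predict from a fitted model; feature names checked when present."""
    return model.predict(X, features=features)
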