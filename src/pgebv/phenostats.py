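"""REML mixed models for alpha-lattice trials: BLUEs, variance components
and entry-mean repeatability.

The trial model is

    y = mean + genotype + environment + GxE + rep(env) + block(rep) + error

fit two ways, mirroring standard multi-environment practice:

* per environment with genotype *fixed* (rep and block-within-rep random)
  to obtain best linear unbiased estimators (BLUEs) of genotype means;
* across environments with everything random to estimate the variance
  components that enter entry-mean repeatability

      h^2 = sigma_G^2 / (sigma_G^2 + sigma_GxE^2 / l + sigma_e^2 / (r l))

  with l environments and r replicates.

REML is computed by EM on Henderson's mixed-model equations with a
safeguarded Aitken acceleration step (the accelerated iterate is accepted
only if the restricted likelihood does not decrease).  Components are
floored during iteration and truncated to zero on output when they hit the
boundary.  The datasets here are small (hundreds of plots), so robustness
is preferred over speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

log = logging.getLogger(__name__)

BAND_PREFIX = "B"  # band x flight BLUE columns look like B392_F1


def band_columns(plots: pd.DataFrame) -> list:
    """Columns named like ``B<wavelength>_F<flight>``."""
    out = []
    for c in plots.columns:
        if c.startswith(BAND_PREFIX) and "_F" in c:
            head, _, tail = c.partition("_F")
            if head[1:].isdigit() and tail.isdigit():
                out.append(c)
    return out


# ---------------------------------------------------------------------------
# core REML machinery


@dataclass
class RemlFit:
    """Result of one EM-REML fit."""

    beta: np.ndarray
    beta_se: np.ndarray
    u: dict
    sigma2: dict  # per random term plus "e"
    loglik: float  # restricted log-likelihood (up to an additive constant)
    n_iter: int
    converged: bool
    truncated: list = field(default_factory=list)
    history: np.ndarray | None = None  # -2 loglik per iteration, if tracked


def _indicator(labels) -> tuple[np.ndarray, list]:
    codes, cats = pd.factorize(np.asarray(labels), sort=True)
    Z = np.zeros((len(codes), len(cats)))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z, list(cats)


def reml_em(y: np.ndarray, X: np.ndarray, Zs: dict, tol: float = 1e-8,
            max_iter: int = 500, start: dict | None = None,
            accelerate: bool = True, track: bool = False,
            method: str = "hybrid") -> RemlFit:
    """REML for ``y = X beta + sum_i Z_i u_i + e`` with i.i.d. blocks.

    ``Zs`` maps term name -> design matrix.  ``X`` must be full column
    rank.  ``method='em'`` uses pure (monotone) EM updates on the mixed
    model equations; ``'hybrid'`` (default) runs a short EM warm-up and
    then average-information (AI) steps, each accepted only if the
    restricted likelihood does not decrease (EM fallback otherwise).
    Convergence: max change of any component relative to var(y) below
    ``tol``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = X.shape[1]
    names = list(Zs)
    qs = {k: Zs[k].shape[1] for k in names}
    W = np.hstack([X] + [Zs[k] for k in names])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    vy = float(np.var(y)) or 1.0
    floor = 1e-10 * vy

    slices = {}
    off = p
    for k in names:
        slices[k] = slice(off, off + qs[k])
        off += qs[k]
    q_tot = off - p

    sig = {k: vy / (len(names) + 1) for k in names}
    sig["e"] = vy / (len(names) + 1)
    if start:
        for k, v in start.items():
            if k in sig and np.isfinite(v):
                sig[k] = max(float(v), floor)

    def assemble(sigmas):
        C = WtW.copy()
        for k in names:
            sl = slices[k]
            C[np.arange(sl.start, sl.stop), np.arange(sl.start, sl.stop)] += \
                sigmas["e"] / max(sigmas[k], floor)
        return C

    def neg2_restricted_ll(sigmas, chol=None, s=None):
        if chol is None:
            C = assemble(sigmas)
            chol = cho_factor(C, lower=True)
            s = cho_solve(chol, Wty)
        logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
        quad = (yty - float(s @ Wty)) / sigmas["e"]
        val = ((n - p - q_tot) * np.log(sigmas["e"])
               + sum(qs[k] * np.log(max(sigmas[k], floor)) for k in names)
               + logdet + quad)
        return val

    frozen = set()  # components pinned at the zero boundary

    def em_step(sigmas):
        C = assemble(sigmas)
        chol = cho_factor(C, lower=True)
        s = cho_solve(chol, Wty)
        Cinv = cho_solve(chol, np.eye(C.shape[0]))
        new = {}
        for k in names:
            if k in frozen:
                new[k] = floor
                continue
            sl = slices[k]
            uk = s[sl]
            tr = np.trace(Cinv[sl, sl])
            new[k] = max((float(uk @ uk) + sigmas["e"] * tr) / qs[k], floor)
        new["e"] = max((yty - float(s @ Wty)) / (n - p), floor)
        return new, chol, s

    def ai_step(sigmas):
        """One average-information update over the non-frozen components;
        returns an accepted proposal or None."""
        active = [k for k in names if k not in frozen]
        C = assemble(sigmas)
        chol = cho_factor(C, lower=True)
        s = cho_solve(chol, Wty)
        Cinv = cho_solve(chol, np.eye(C.shape[0]))
        w = (y - W @ s) / sigmas["e"]  # P y
        tr_pv = {}
        ypvp = {}
        for k in active:
            sl = slices[k]
            tr_c = np.trace(Cinv[sl, sl])
            sk = max(sigmas[k], floor)
            tr_pv[k] = (qs[k] * sk - sigmas["e"] * tr_c) / sk ** 2
            ypvp[k] = float(s[sl] @ s[sl]) / sk ** 2
        # frozen blocks contribute ~0 to tr(P V); V still holds them at the floor
        tr_p = (n - p - sum(sigmas[k] * tr_pv[k] for k in active)) / sigmas["e"]
        fs = [Zs[k] @ (s[slices[k]] / max(sigmas[k], floor)) for k in active]
        F = np.column_stack(fs + [w])
        T = cho_solve(chol, W.T @ F)
        PF = (F - W @ T) / sigmas["e"]
        AI = 0.5 * (F.T @ PF)
        score = np.array([0.5 * (ypvp[k] - tr_pv[k]) for k in active]
                         + [0.5 * (float(w @ w) - tr_p)])
        try:
            step = np.linalg.solve(AI + 1e-10 * np.eye(len(score)), score)
        except np.linalg.LinAlgError:
            return None
        keys = active + ["e"]
        cur = np.array([sigmas[k] for k in keys])
        base = neg2_restricted_ll(sigmas, chol, s)
        for half in range(8):
            cand_vec = cur + step / (2 ** half)
            cand = dict(sigmas)
            cand.update({k: max(float(v), floor)
                         for k, v in zip(keys, cand_vec)})
            if cand["e"] <= floor:
                continue
            try:
                if neg2_restricted_ll(cand) <= base + 1e-10:
                    return cand
            except (np.linalg.LinAlgError, FloatingPointError):
                continue
        return None

    hist = []
    prev2 = prev1 = None
    converged = False
    it = 0
    n_warmup = 5 if method == "hybrid" else max_iter
    for it in range(1, max_iter + 1):
        new, chol, s = em_step(sig)
        if track:
            hist.append(neg2_restricted_ll(sig, chol, s))
        # a component shrinking through ~0 converges at an EM rate -> 1;
        # pin it at the boundary once it is negligible and still falling
        for k in names:
            if k not in frozen and new[k] < 1e-7 * vy and new[k] <= sig[k]:
                frozen.add(k)
                new[k] = floor
        delta = max(abs(new[k] - sig[k]) / vy for k in new)
        prev2, prev1 = prev1, dict(sig)
        sig = new
        if delta < tol:
            converged = True
            break
        if method == "hybrid" and it >= n_warmup:
            cand = ai_step(sig)
            if cand is not None:
                delta = max(abs(cand[k] - sig[k]) / vy for k in cand)
                for k in names:
                    if k not in frozen and cand[k] < 1e-7 * vy \
                            and cand[k] <= sig[k]:
                        frozen.add(k)
                        cand[k] = floor
                sig = cand
                if delta < tol:
                    converged = True
                    break
        elif accelerate and method == "em" and prev2 is not None and it % 3 == 0:
            acc = {}
            ok = True
            for k in sig:
                if k in frozen:
                    acc[k] = sig[k]
                    continue
                t0 = np.log(max(prev2[k], floor))
                t1 = np.log(max(prev1[k], floor))
                t2 = np.log(max(sig[k], floor))
                d1, d2 = t1 - t0, t2 - t1
                if abs(d1) < 1e-14 or abs(d2) < 1e-14:
                    acc[k] = sig[k]
                    continue
                r = d2 / d1
                if not (-0.5 < r < 0.995):
                    ok = False
                    break
                acc[k] = float(np.exp(t2 + d2 * r / (1.0 - r)))
            if ok:
                try:
                    if neg2_restricted_ll(acc) <= neg2_restricted_ll(sig):
                        sig = acc
                except np.linalg.LinAlgError:
                    pass

    C = assemble(sig)
    chol = cho_factor(C, lower=True)
    s = cho_solve(chol, Wty)
    Cinv = cho_solve(chol, np.eye(C.shape[0]))
    beta = s[:p]
    beta_se = np.sqrt(np.clip(sig["e"] * np.diag(Cinv)[:p], 0, None))
    u = {k: s[slices[k]] for k in names}
    neg2 = neg2_restricted_ll(sig, chol, s)

    truncated = []
    out_sig = {}
    for k, v in sig.items():
        if v <= 10 * floor or v < 1e-8 * vy:
            out_sig[k] = 0.0
            if k != "e":
                truncated.append(k)
        else:
            out_sig[k] = float(v)
    if not converged:
        log.warning("REML did not converge in %d iterations (last delta at "
                    "tol %g)", max_iter, tol)
    return RemlFit(beta=beta, beta_se=beta_se, u=u, sigma2=out_sig,
                   loglik=-0.5 * neg2, n_iter=it, converged=converged,
                   truncated=truncated,
                   history=np.asarray(hist) if track else None)


def gls_solve(y: np.ndarray, X: np.ndarray, Zs: dict, sigma2: dict
              ) -> np.ndarray:
    """Generalized least squares fixed effects at *given* variance
    components (mixed-model-equations solve; no REML iteration)."""
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    names = list(Zs)
    W = np.hstack([X] + [Zs[k] for k in names])
    C = W.T @ W
    off = p
    for k in names:
        q = Zs[k].shape[1]
        ratio = sigma2["e"] / max(sigma2[k], 1e-12)
        C[np.arange(off, off + q), np.arange(off, off + q)] += ratio
        off += q
    s = cho_solve(cho_factor(C, lower=True), W.T @ y)
    return s[:p]


# ---------------------------------------------------------------------------
# trial models


@dataclass
class VarianceComponents:
    """Variance components on the plot scale (trait units squared)."""

    sigma_g2: float = np.nan
    sigma_gxe2: float = np.nan
    sigma_env2: float = np.nan
    sigma_rep2: float = np.nan
    sigma_block2: float = np.nan
    sigma_e2: float = np.nan
    n_envs: int = 1
    n_reps: int = 1
    truncated: list = field(default_factory=list)
    converged: bool = True

    def as_dict(self) -> dict:
        return {
            "sigma_g2": self.sigma_g2, "sigma_gxe2": self.sigma_gxe2,
            "sigma_env2": self.sigma_env2, "sigma_rep2": self.sigma_rep2,
            "sigma_block2": self.sigma_block2, "sigma_e2": self.sigma_e2,
            "n_envs": self.n_envs, "n_reps": self.n_reps,
            "truncated": list(self.truncated), "converged": self.converged,
        }


@dataclass
class Repeatability:
    h2: float
    trait: str
    environments: list
    variant: str  # "across" (entry-mean over envs) or "within" (single env)


def fit_env_model(plots: pd.DataFrame, environment, trait: str,
                  tol: float = 1e-8, max_iter: int = 500,
                  start: dict | None = None):
    """Per-environment model: genotype fixed, rep and block(rep) random.

    Returns (blues, vc, fit) where ``blues`` is a Series of genotype BLUEs
    (NaN for genotypes absent from every plot of the environment) with the
    GLS standard errors in ``blues.attrs['se']``.
    """
    sub = plots.loc[(plots["env"] == environment) & plots[trait].notna()]
    if sub.empty:
        raise ValueError(f"no data for environment {environment!r}")
    genos_all = sorted(plots.loc[plots["env"] == environment, "genotype"].unique())
    y = sub[trait].to_numpy(float)
    X, genos = _indicator(sub["genotype"])  # cell-means: one column per genotype
    if len(genos) < 2:
        raise ValueError("need >= 2 genotypes with data")
    Z_rep, _ = _indicator(sub["rep"])
    Z_block, _ = _indicator(sub["block"])
    fit = reml_em(y, X, {"rep": Z_rep, "block": Z_block}, tol=tol,
                  max_iter=max_iter, start=start)
    blues = pd.Series(np.nan, index=pd.Index(genos_all, name="genotype"),
                      name=trait)
    se = pd.Series(np.nan, index=blues.index, name="se")
    blues.loc[genos] = fit.beta
    se.loc[genos] = fit.beta_se
    blues.attrs["se"] = se
    missing = [g for g in genos_all if g not in genos]
    if missing:
        log.warning("environment %s trait %s: %d genotypes without plots",
                    environment, trait, len(missing))
    vc = VarianceComponents(
        sigma_rep2=fit.sigma2["rep"], sigma_block2=fit.sigma2["block"],
        sigma_e2=fit.sigma2["e"], n_envs=1,
        n_reps=int(sub["rep"].nunique()), truncated=fit.truncated,
        converged=fit.converged,
    )
    return blues, vc, fit


def fit_combined_model(plots: pd.DataFrame, trait: str, tol: float = 1e-8,
                       max_iter: int = 500) -> VarianceComponents:
    """Across-environment model with genotype, environment, GxE, rep(env)
    and block(rep) all random; returns REML variance components."""
    sub = plots.loc[plots[trait].notna()]
    if sub["env"].nunique() < 2:
        raise ValueError("combined model needs >= 2 environments")
    y = sub[trait].to_numpy(float)
    X = np.ones((len(sub), 1))
    Zg, _ = _indicator(sub["genotype"])
    Ze, _ = _indicator(sub["env"])
    Zge, _ = _indicator(sub["env"].astype(str) + ":" + sub["genotype"].astype(str))
    Zr, _ = _indicator(sub["env"].astype(str) + "_R" + sub["rep"].astype(str))
    Zb, _ = _indicator(sub["block"])
    start = _moment_start(sub, trait)
    fit = reml_em(y, X, {"geno": Zg, "env": Ze, "gxe": Zge, "rep": Zr,
                         "block": Zb}, tol=tol, max_iter=max_iter, start=start)
    return VarianceComponents(
        sigma_g2=fit.sigma2["geno"], sigma_gxe2=fit.sigma2["gxe"],
        sigma_env2=fit.sigma2["env"], sigma_rep2=fit.sigma2["rep"],
        sigma_block2=fit.sigma2["block"], sigma_e2=fit.sigma2["e"],
        n_envs=int(sub["env"].nunique()), n_reps=int(sub["rep"].nunique()),
        truncated=fit.truncated, converged=fit.converged,
    )


def _moment_start(sub: pd.DataFrame, trait: str) -> dict:
    """Cheap method-of-moments warm start for the combined model (exact for
    balanced data without block effects; only used as an initial point)."""
    try:
        cell = sub.pivot_table(index="genotype", columns="env", values=trait,
                               aggfunc="mean")
        within = sub.groupby(["genotype", "env"])[trait].var(ddof=1)
        r = max(float(sub.groupby(["genotype", "env"])[trait].size().mean()), 1.0)
        s_e = float(np.nanmean(within)) if np.isfinite(np.nanmean(within)) else 1.0
        m = cell.to_numpy()
        gm = np.nanmean(m)
        ge = np.nanmean(m, axis=0)
        gg = np.nanmean(m, axis=1)
        resid = m - gg[:, None] - ge[None, :] + gm
        l = m.shape[1]
        ms_g = l * np.nanvar(gg, ddof=1)
        ms_ge = np.nansum(resid ** 2) / ((m.shape[0] - 1) * (l - 1))
        s_ge = max(ms_ge - s_e / r, 0.01 * s_e)
        s_g = max((ms_g - ms_ge) / l, 0.01 * s_e)
        vy = float(sub[trait].var())
        return {"geno": s_g, "gxe": s_ge, "e": max(s_e * 0.9, 0.05 * vy),
                "env": max(float(np.nanvar(ge, ddof=1)), 0.05 * vy),
                "rep": 0.05 * vy, "block": 0.05 * vy}
    except Exception:  # pragma: no cover - fall back to flat start
        return {}


def repeatability(vc: VarianceComponents, trait: str = "GY",
                  variant: str = "across") -> Repeatability:
    """Entry-mean repeatability.

    ``across``: h2 = sG2 / (sG2 + sGxE2/l + se2/(r l)) with l environments
    and r replicates.  ``within``: h2 = sG2 / (sG2 + se2/r) for a single
    environment's components.
    """
    l, r = vc.n_envs, vc.n_reps
    if l < 1 or r < 1:
        raise ValueError("need l >= 1 environments and r >= 1 replicates")
    if variant == "across":
        denom = vc.sigma_g2 + vc.sigma_gxe2 / l + vc.sigma_e2 / (r * l)
    elif variant == "within":
        denom = vc.sigma_g2 + vc.sigma_e2 / r
    else:
        raise ValueError(f"unknown variant {variant!r}")
    h2 = np.nan if denom <= 0 else vc.sigma_g2 / denom
    if denom <= 0:
        log.warning("repeatability undefined: zero phenotypic variance")
    return Repeatability(h2=float(h2), trait=trait, environments=[], variant=variant)


def within_env_repeatability(plots: pd.DataFrame, environment, trait: str,
                             **kwargs) -> Repeatability:
    """Single-environment repeatability: refit with genotype random."""
    sub = plots.loc[(plots["env"] == environment) & plots[trait].notna()]
    y = sub[trait].to_numpy(float)
    X = np.ones((len(sub), 1))
    Zg, _ = _indicator(sub["genotype"])
    Zr, _ = _indicator(sub["rep"])
    Zb, _ = _indicator(sub["block"])
    fit = reml_em(y, X, {"geno": Zg, "rep": Zr, "block": Zb}, **kwargs)
    r = int(sub["rep"].nunique())
    denom = fit.sigma2["geno"] + fit.sigma2["e"] / r
    h2 = np.nan if denom <= 0 else fit.sigma2["geno"] / denom
    return Repeatability(h2=float(h2), trait=trait,
                         environments=[environment], variant="within")


# ---------------------------------------------------------------------------
# BLUE table


def build_blue_table(plots: pd.DataFrame, traits: list | None = None,
                     tol: float = 1e-8, max_iter: int = 500) -> pd.DataFrame:
    """Genotype x environment BLUEs for grain yield and every band x flight.

    Returns a frame indexed by (genotype, env) with one column per trait;
    per-environment variance components are stored in
    ``result.attrs['variance_components']`` and the count of missing BLUEs
    in ``result.attrs['n_missing']``.
    """
    if traits is None:
        traits = ["GY"] + band_columns(plots)
    envs = list(dict.fromkeys(plots["env"]))
    pieces = {}
    vcs = {}
    n_missing = 0
    for env in envs:
        cols = {}
        warm = None
        for trait in traits:
            if plots.loc[plots["env"] == env, trait].notna().sum() == 0:
                cols[trait] = None
                continue
            blues, vc, fit = fit_env_model(plots, env, trait, tol=tol,
                                           max_iter=max_iter, start=warm)
            warm = dict(fit.sigma2)
            blues = blues.copy()
            blues.attrs = {}  # the SE sidecar confuses pd.concat attr checks
            cols[trait] = blues
            vcs[(env, trait)] = vc
            n_missing += int(blues.isna().sum())
        genos = sorted(plots.loc[plots["env"] == env, "genotype"].unique())
        idx = pd.Index(genos, name="genotype")
        frame = pd.concat(
            {t: (cols[t] if cols[t] is not None
                 else pd.Series(np.nan, index=idx)) for t in traits},
            axis=1,
        ).reindex(idx)
        frame["env"] = env
        pieces[env] = frame
    out = pd.concat(pieces.values())
    out = out.reset_index().set_index(["genotype", "env"]).sort_index()
    out.attrs["variance_components"] = vcs
    out.attrs["n_missing"] = n_missing
    if n_missing:
        log.warning("build_blue_table: %d missing BLUEs propagated", n_missing)
    return out


def repeatability_table(plots: pd.DataFrame, traits: list | None = None,
                        **kwargs) -> pd.DataFrame:
    """Across-environment repeatability per trait (entry-mean basis)."""
    if traits is None:
        traits = ["GY", "AD", "SD", "PH"] + band_columns(plots)
    rows = []
    for trait in traits:
        vc = fit_combined_model(plots, trait, **kwargs)
        h2 = repeatability(vc, trait=trait)
        rows.append({"trait": trait, "h2": h2.h2, "sigma_g2": vc.sigma_g2,
                     "sigma_gxe2": vc.sigma_gxe2, "sigma_e2": vc.sigma_e2})
    return pd.DataFrame(rows)
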