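"""Cross-validation schemes for marker / hyperspectral yield prediction.

Builds genotype-by-environment datasets from the BLUE table and the bin
map, then scores prediction accuracy r_GP (Pearson correlation between
predicted and observed grain-yield BLUEs) under two schemes:

* ``within_2fold`` — per environment, genotypes are split at random into
  halves; each half predicts the other (both directions scored), repeated
  ``n_reps`` times;
* ``across_LOEO`` — leave-one-environment-out: all records of three
  environments train a model that predicts the held-out environment,
  whose own reflectance features (measured pre-harvest) are available at
  test time.

Input sets: M = bin markers (identical across a genotype's environments),
H = band x flight reflectance BLUEs (environment-specific), HM = both
blocks concatenated.  Standardization and any inner hyperparameter CV are
fit strictly on the training partition (the learners do this internally).

Bootstrap standard errors resample (predicted, observed) pairs with
replacement; degenerate resamples are skipped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import learners
from .core import BinMap, MISSING

log = logging.getLogger(__name__)

INPUT_SETS = ("M", "H", "HM")
SCHEMES = ("within_2fold", "across_LOEO")
LEARNERS = ("plsr", "rf", "rr", "bayesb")

#: replication counts used by the study, per learner
PAPER_REPS = {"plsr": 1000, "rf": 2000, "rr": 3000, "bayesb": 1000}


@dataclass
class LearnerSpec:
    """A learner plus its hyperparameters, as used inside CV."""

    method: str
    params: dict = field(default_factory=dict)

    def fit(self, X, y, seed):
        return learners.fit(self.method, X, y, seed=seed, **self.params)


#: desk-scale presets (smaller chains / forests than the learner defaults,
#: chosen so the full 24-cell grid runs on one core in minutes)
DESK_PRESETS = {
    "plsr": LearnerSpec("plsr", {"ncomp": "cv"}),
    "rf": LearnerSpec("rf", {"ntree": 300}),
    "rr": LearnerSpec("rr", {"lam": "reml"}),
    "bayesb": LearnerSpec("bayesb", {"n_iter": 1500, "burnin": 300}),
}


@dataclass
class Dataset:
    """Records keyed (genotype, env) with y = grain-yield BLUE and M/H
    feature blocks."""

    records: pd.DataFrame  # columns genotype, env
    y: np.ndarray
    M: np.ndarray | None
    H: np.ndarray | None
    input_set: str
    feature_names_m: list = field(default_factory=list)
    feature_names_h: list = field(default_factory=list)
    excluded_genotypes: list = field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        if self.input_set == "M":
            return self.M
        if self.input_set == "H":
            return self.H
        return np.hstack([self.M, self.H])

    @property
    def feature_names(self) -> list:
        if self.input_set == "M":
            return list(self.feature_names_m)
        if self.input_set == "H":
            return list(self.feature_names_h)
        return list(self.feature_names_m) + list(self.feature_names_h)

    @property
    def environments(self) -> list:
        return list(dict.fromkeys(self.records["env"]))


def coded_bin_matrix(binmap: BinMap) -> pd.DataFrame:
    """Bin calls in -1/+1 coding, het as 0, missing mean-imputed per bin.

    Bin calls are genotype attributes (no phenotype enters), so the
    imputation is computed once on all lines.
    """
    calls = binmap.bin_calls.astype(float)
    arr = np.where(calls == MISSING, np.nan, calls)
    col_mean = np.nanmean(arr, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    arr = np.where(np.isnan(arr), col_mean[None, :], arr)
    return pd.DataFrame(arr, index=binmap.line_ids,
                        columns=binmap.bins["bin"].tolist())


def build_dataset(blues: pd.DataFrame, binmap: BinMap | pd.DataFrame | None,
                  input_set: str = "HM", target: str = "GY") -> Dataset:
    """Assemble the (genotype, env) dataset for one input set.

    ``blues`` is the genotype x environment BLUE table (index
    (genotype, env), columns GY + band features).  ``binmap`` may be a
    BinMap or a precomputed coded marker frame; it is required for M/HM.
    """
    if input_set not in INPUT_SETS:
        raise ValueError(f"input_set must be one of {INPUT_SETS}")
    tab = blues.reset_index()
    h_cols = [c for c in blues.columns if c != target]
    excluded: list = []

    marker_frame = None
    if input_set in ("M", "HM"):
        if binmap is None:
            raise ValueError("bin map required for marker input sets")
        marker_frame = (coded_bin_matrix(binmap)
                        if isinstance(binmap, BinMap) else binmap)
        known = set(marker_frame.index)
        excluded = sorted(set(tab["genotype"]) - known)
        if excluded:
            log.warning("build_dataset: %d genotypes without marker data "
                        "excluded: %s", len(excluded), excluded[:5])
            tab = tab[tab["genotype"].isin(known)]

    tab = tab[tab[target].notna()].reset_index(drop=True)
    y = tab[target].to_numpy(float)
    M = H = None
    names_m: list = []
    names_h: list = []
    if input_set in ("M", "HM"):
        M = marker_frame.loc[tab["genotype"]].to_numpy(float)
        names_m = list(marker_frame.columns)
    if input_set in ("H", "HM"):
        H = tab[h_cols].to_numpy(float)
        names_h = list(h_cols)
        keep = ~np.isnan(H).all(axis=1)
        if not keep.all():
            log.warning("build_dataset: %d records without H features dropped",
                        int((~keep).sum()))
            tab, y = tab[keep].reset_index(drop=True), y[keep]
            H = H[keep]
            if M is not None:
                M = M[keep]
        # per-feature missing BLUEs: impute with the column mean (features
        # only; standardization is still training-fold-local)
        col_mean = np.nanmean(H, axis=0)
        nan_at = np.isnan(H)
        if nan_at.any():
            H[nan_at] = np.take(col_mean, np.nonzero(nan_at)[1])
    return Dataset(records=tab[["genotype", "env"]], y=y, M=M, H=H,
                   input_set=input_set, feature_names_m=names_m,
                   feature_names_h=names_h, excluded_genotypes=excluded)


# ---------------------------------------------------------------------------
# accuracy measures


def pearson_rgp(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Sample Pearson correlation; NaN (flagged upstream) when either
    vector is constant."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("length mismatch")
    if len(predicted) < 2:
        raise ValueError("need at least 2 pairs")
    if predicted.std() <= 1e-14 or observed.std() <= 1e-14:
        return float("nan")
    return float(np.corrcoef(predicted, observed)[0, 1])


def bootstrap_se(predicted: np.ndarray, observed: np.ndarray,
                 n_boot: int = 10000, seed: int = 0) -> float:
    """Bootstrap SE of the correlation: resample index pairs with
    replacement; SD of the resampled correlations.  Degenerate resamples
    (constant vectors) are skipped; more than 50% degenerate is an error."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = len(predicted)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    a = predicted[idx]
    b = observed[idx]
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((am ** 2).sum(axis=1))
    sb = np.sqrt((bm ** 2).sum(axis=1))
    ok = (sa > 1e-12) & (sb > 1e-12)
    if ok.sum() < 0.5 * n_boot:
        raise ValueError(f"{n_boot - int(ok.sum())} of {n_boot} bootstrap "
                         "resamples degenerate")
    r = (am * bm).sum(axis=1)[ok] / (sa[ok] * sb[ok])
    return float(r.std(ddof=1))


# ---------------------------------------------------------------------------
# schemes


@dataclass
class SchemeResult:
    scheme: str
    learner: str
    input_set: str
    r_gp: float
    se_boot: float
    per_env: dict
    n_reps: int
    n_degenerate: int = 0
    n_skipped: int = 0
    seed: int = 0

    def as_row(self) -> dict:
        d = asdict(self)
        d.pop("per_env")
        for env, r in self.per_env.items():
            d[f"r_{env}"] = r
        return d


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def twofold_cv(data: Dataset, spec: LearnerSpec, n_reps: int = 50,
               seed: int = 0, n_boot: int = 1000, min_test: int = 4,
               pooled: bool = False) -> SchemeResult:
    """Within-environment two-fold CV, both split directions scored.

    ``pooled=True`` draws one split over all records (environments mixed
    in training) instead of the default per-environment splits; accuracy
    is still scored per environment.
    """
    if pooled:
        return _twofold_pooled(data, spec, n_reps, seed, n_boot, min_test)
    envs = data.environments
    per_env = {}
    per_env_se = []
    n_degenerate = 0
    n_skipped = 0
    X_all = data.X
    names = data.feature_names
    for ej, env in enumerate(envs):
        rows = np.flatnonzero((data.records["env"] == env).to_numpy())
        if len(rows) < 2 * min_test:
            n_skipped += n_reps
            continue
        rs = []
        first_pairs = None
        for rep in range(n_reps):
            rng = np.random.default_rng(_child_seed(seed, ej, rep))
            perm = rng.permutation(rows)
            half = len(rows) // 2
            folds = (perm[:half], perm[half:])
            rep_pairs = []
            for d, (test, train) in enumerate(((folds[0], folds[1]),
                                               (folds[1], folds[0]))):
                if len(test) < min_test:
                    n_skipped += 1
                    continue
                model = spec.fit(X_all[train], data.y[train],
                                 seed=_child_seed(seed, ej, rep, d))
                pred = learners.predict(model, X_all[test], features=None)
                r = pearson_rgp(pred, data.y[test])
                if np.isnan(r):
                    n_degenerate += 1
                    r = 0.0
                rs.append(r)
                rep_pairs.append((pred, data.y[test]))
            if rep == 0 and rep_pairs:
                first_pairs = (np.concatenate([p for p, _ in rep_pairs]),
                               np.concatenate([o for _, o in rep_pairs]))
        if rs:
            per_env[env] = float(np.mean(rs))
            if first_pairs is not None and len(first_pairs[0]) >= 4:
                try:
                    per_env_se.append(bootstrap_se(*first_pairs,
                                                   n_boot=n_boot,
                                                   seed=_child_seed(seed, ej, 9999)))
                except ValueError:
                    pass
        _ = names  # feature bookkeeping retained for API parity
    r_gp = float(np.mean(list(per_env.values()))) if per_env else float("nan")
    se = float(np.mean(per_env_se)) if per_env_se else float("nan")
    return SchemeResult(scheme="within_2fold", learner=spec.method,
                        input_set=data.input_set, r_gp=r_gp, se_boot=se,
                        per_env=per_env, n_reps=n_reps,
                        n_degenerate=n_degenerate, n_skipped=n_skipped,
                        seed=seed)


def _twofold_pooled(data: Dataset, spec: LearnerSpec, n_reps, seed, n_boot,
                    min_test) -> SchemeResult:
    """Pooled-split variant: one random half of all records trains, the
    other is predicted; r_GP still scored within each environment."""
    n = len(data.y)
    X_all = data.X
    env_arr = data.records["env"].to_numpy()
    envs = data.environments
    rs = {env: [] for env in envs}
    n_degenerate = 0
    n_skipped = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(_child_seed(seed, 500, rep))
        perm = rng.permutation(n)
        half = n // 2
        folds = (perm[:half], perm[half:])
        for d, (test, train) in enumerate(((folds[0], folds[1]),
                                           (folds[1], folds[0]))):
            model = spec.fit(X_all[train], data.y[train],
                             seed=_child_seed(seed, 500, rep, d))
            pred = learners.predict(model, X_all[test])
            for env in envs:
                at = env_arr[test] == env
                if at.sum() < min_test:
                    n_skipped += 1
                    continue
                r = pearson_rgp(pred[at], data.y[test][at])
                if np.isnan(r):
                    n_degenerate += 1
                    r = 0.0
                rs[env].append(r)
    per_env = {env: float(np.mean(v)) for env, v in rs.items() if v}
    return SchemeResult(scheme="within_2fold_pooled", learner=spec.method,
                        input_set=data.input_set,
                        r_gp=float(np.mean(list(per_env.values()))),
                        se_boot=float("nan"), per_env=per_env,
                        n_reps=n_reps, n_degenerate=n_degenerate,
                        n_skipped=n_skipped, seed=seed)


def leave_one_env_out(data: Dataset, spec: LearnerSpec, seed: int = 0,
                      n_boot: int = 1000,
                      use_target_h: bool = True) -> SchemeResult:
    """Across-environment leave-one-environment-out CV.

    Each environment is predicted from a model trained on every record of
    the other environments; by default the held-out environment
    contributes its own (pre-harvest) H features at test time.  With
    ``use_target_h=False`` the test records instead carry their
    genotype's H features averaged over the training environments.
    """
    envs = data.environments
    if len(envs) < 2:
        raise ValueError("LOEO needs at least 2 environments")
    per_env = {}
    ses = []
    n_degenerate = 0
    X_all = data.X
    for ej, env in enumerate(envs):
        test = np.flatnonzero((data.records["env"] == env).to_numpy())
        train = np.flatnonzero((data.records["env"] != env).to_numpy())
        model = spec.fit(X_all[train], data.y[train],
                         seed=_child_seed(seed, 7000 + ej))
        X_test = X_all[test]
        if not use_target_h and data.input_set in ("H", "HM") \
                and data.H is not None:
            X_test = X_test.copy()
            h_train = pd.DataFrame(data.H[train])
            h_train["genotype"] = data.records["genotype"].to_numpy()[train]
            h_mean = h_train.groupby("genotype").mean()
            genos = data.records["genotype"].to_numpy()[test]
            h_sub = h_mean.reindex(genos).to_numpy()
            fallback = np.nanmean(data.H[train], axis=0)
            nan_rows = np.isnan(h_sub).any(axis=1)
            h_sub[nan_rows] = fallback
            offset = 0 if data.input_set == "H" else data.M.shape[1]
            X_test[:, offset:offset + data.H.shape[1]] = h_sub
        pred = learners.predict(model, X_test)
        r = pearson_rgp(pred, data.y[test])
        if np.isnan(r):
            n_degenerate += 1
            r = 0.0
        per_env[env] = float(r)
        if len(test) >= 4:
            try:
                ses.append(bootstrap_se(pred, data.y[test], n_boot=n_boot,
                                        seed=_child_seed(seed, 8000 + ej)))
            except ValueError:
                pass
    return SchemeResult(scheme="across_LOEO", learner=spec.method,
                        input_set=data.input_set,
                        r_gp=float(np.mean(list(per_env.values()))),
                        se_boot=float(np.mean(ses)) if ses else float("nan"),
                        per_env=per_env, n_reps=1,
                        n_degenerate=n_degenerate, seed=seed)


# ---------------------------------------------------------------------------
# grid


@dataclass
class GridConfig:
    schemes: tuple = SCHEMES
    learner_names: tuple = LEARNERS
    input_sets: tuple = INPUT_SETS
    n_reps: int | str = 50  # int, or "paper" for the per-learner study counts
    n_boot: int = 1000
    seed: int = 1
    learner_specs: dict = field(default_factory=lambda: dict(DESK_PRESETS))

    def reps_for(self, learner: str) -> int:
        if self.n_reps == "paper":
            return PAPER_REPS[learner]
        return int(self.n_reps)


def run_experiment_grid(blues: pd.DataFrame, binmap, config: GridConfig,
                        target: str = "GY") -> pd.DataFrame:
    """Full factorial schemes x learners x input sets; failed cells are
    recorded with their error and the grid continues."""
    datasets = {s: build_dataset(blues, binmap, input_set=s, target=target)
                for s in config.input_sets}
    rows = []
    for input_set in config.input_sets:
        data = datasets[input_set]
        for learner in config.learner_names:
            spec = config.learner_specs[learner]
            for scheme in config.schemes:
                try:
                    if scheme == "within_2fold":
                        res = twofold_cv(data, spec,
                                         n_reps=config.reps_for(learner),
                                         seed=config.seed,
                                         n_boot=config.n_boot)
                    else:
                        res = leave_one_env_out(data, spec, seed=config.seed,
                                                n_boot=config.n_boot)
                    row = res.as_row()
                    row["error"] = ""
                except Exception as exc:  # record and continue
                    log.error("grid cell (%s, %s, %s) failed: %s", scheme,
                              learner, input_set, exc)
                    row = {"scheme": scheme, "learner": learner,
                           "input_set": input_set, "r_gp": np.nan,
                           "se_boot": np.nan, "n_reps": 0, "n_degenerate": 0,
                           "n_skipped": 0, "seed": config.seed,
                           "error": str(exc)}
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_grid(results: pd.DataFrame) -> dict:
    """Fig-4-style summary: means by scheme, learner and input set."""
    ok = results[results["error"] == ""] if "error" in results else results
    return {
        "overall_mean_r_gp": float(ok["r_gp"].mean()),
        "by_scheme": ok.groupby("scheme")["r_gp"].mean().to_dict(),
        "by_learner": ok.groupby("learner")["r_gp"].mean().to_dict(),
        "by_input_set": ok.groupby("input_set")["r_gp"].mean().to_dict(),
        "by_cell": {
            f"{r.scheme}|{r.learner}|{r.input_set}": float(r.r_gp)
            for r in ok.itertuples()
        },
        "n_cells": int(len(results)),
        "n_failed": int((results.get("error", "") != "").sum()),
    }
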