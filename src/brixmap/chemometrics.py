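"""PLSR calibration between mean ROI spectra and Brix reference values.

Contains the modelling core of the pipeline:

* PLS1 regression (SIMPLS by default, NIPALS as an alternative; for a single
  response the two produce identical coefficient paths up to round-off);
* latent-variable selection by k-fold cross-validation with the
  "global minimum + 1 SD" parsimony rule, LV count capped at 20;
* CARS (competitive adaptive reweighted sampling) wavelength selection:
  per Monte-Carlo run, bands are ranked by |PLS regression coefficient|,
  an exponentially decreasing schedule enforces the retained count, and
  adaptive reweighted sampling (draws proportional to |coefficient|) picks
  which bands survive; the run whose subset yields the lowest RMSECV wins;
* a paired train/test splitter that sends one measured side of each fruit to
  the training set and the other to the test set (1:1 ratio);
* the 2 x 2 x 2 x 3 model-search grid (SNV or raw, second derivative or not,
  CARS or not, fruit/flesh/achene ROI) reported like a calibration table,
  sorted ascending by R2 of prediction.

Coefficients are reported on autoscaled predictors, so CARS's
coefficient-magnitude ranking is scale-fair.  All randomness flows through an
explicit seed; results are bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Pretreatment, ScalingParams, SpectrumTable

__all__ = [
    "PLSRModel",
    "CVResult",
    "CARSResult",
    "pls1_coefficient_path",
    "plsr_fit",
    "plsr_predict",
    "cross_validate",
    "rmse",
    "r2",
    "cars_select",
    "split_train_test",
    "run_model_grid",
]

MAX_LV_DEFAULT = 20


# ---------------------------------------------------------------------------
# PLS1 core

def _simpls_path(Xc: np.ndarray, yc: np.ndarray, n_lv: int) -> np.ndarray:
    """SIMPLS coefficient path on centered data: rows a=1..n_lv.

    Stops early (returning a shorter path) once the deflated covariance is
    numerically exhausted; extra requested components carry no information.
    """
    n, p = Xc.shape
    S = Xc.T @ yc
    V = np.zeros((p, n_lv))
    R = np.zeros((p, n_lv))
    Q = np.zeros(n_lv)
    path = np.zeros((n_lv, p))
    t_ref = 0.0
    for a in range(n_lv):
        r = S.copy()
        t = Xc @ r
        nt = np.linalg.norm(t)
        if a == 0:
            t_ref = nt
        if nt <= 1e-10 * max(t_ref, 1e-300):
            return path[:a]
        t /= nt
        r /= nt
        pl = Xc.T @ t
        q = float(yc @ t)
        v = pl - V[:, :a] @ (V[:, :a].T @ pl) if a else pl.copy()
        v /= np.linalg.norm(v)
        S = S - v * (v @ S)
        V[:, a] = v
        R[:, a] = r
        Q[a] = q
        path[a] = R[:, :a + 1] @ Q[:a + 1]
    return path


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, n_lv: int) -> np.ndarray:
    """NIPALS PLS1 coefficient path on centered data."""
    n, p = Xc.shape
    Xa = Xc.copy()
    ya = yc.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros(n_lv)
    path = np.zeros((n_lv, p))
    w_ref = 0.0
    for a in range(n_lv):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if a == 0:
            w_ref = nw
        if nw <= 1e-10 * max(w_ref, 1e-300):
            return path[:a]
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        pl = Xa.T @ t / tt
        q = float(ya @ t) / tt
        Xa = Xa - np.outer(t, pl)
        ya = ya - q * t
        W[:, a] = w
        P[:, a] = pl
        Q[a] = q
        k = a + 1
        path[a] = W[:, :k] @ np.linalg.solve(P[:, :k].T @ W[:, :k], Q[:k])
    return path


def pls1_coefficient_path(X: np.ndarray, y: np.ndarray, n_lv: int,
                          algorithm: str = "simpls",
                          strict: bool = True) -> tuple[np.ndarray, np.ndarray, float]:
    """Coefficient path for 1..n_lv latent variables.

    Returns ``(path, x_means, y_mean)``; predictions with ``a`` LVs are
    ``(X - x_means) @ path[a-1] + y_mean``.  If the data's effective rank is
    exhausted before ``n_lv`` components, ``strict=True`` raises; otherwise a
    truncated path is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be 2-D with one y value per row")
    if n_lv < 1 or n_lv > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(
            f"n_lv must be in [1, min(n_samples-1, n_bands)] = "
            f"[1, {min(X.shape[0] - 1, X.shape[1])}]"
        )
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    if algorithm == "simpls":
        path = _simpls_path(Xc, yc, n_lv)
    elif algorithm == "nipals":
        path = _nipals_path(Xc, yc, n_lv)
    else:
        raise ValueError("algorithm must be 'simpls' or 'nipals'")
    if strict and path.shape[0] < n_lv:
        raise ValueError(
            f"n_lv={n_lv} exceeds the effective rank ({path.shape[0]})"
        )
    return path, xm, ym


# ---------------------------------------------------------------------------
# Metrics

def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-square error sqrt(sum (yhat - y)^2 / n), in Brix%."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must be equal-length vectors, n >= 2")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must be equal-length vectors, n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y has zero variance; R2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# Model container

@dataclass
class PLSRModel:
    """A fitted Brix calibration: pretreatment chain, autoscaling parameters,
    retained bands, regression coefficients on scaled predictors, LV count."""

    pretreatment: Pretreatment
    scaling: ScalingParams
    band_indices: np.ndarray          # into the pretreated band axis
    coef: np.ndarray                  # per retained band, scaled-X units
    intercept: float                  # training-set mean Brix
    n_lv: int
    algorithm: str = "simpls"
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.band_indices = np.asarray(self.band_indices, dtype=int)
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != self.band_indices.shape:
            raise ValueError("one coefficient per retained band required")
        if not 1 <= self.n_lv <= MAX_LV_DEFAULT:
            raise ValueError(f"n_lv must lie in [1, {MAX_LV_DEFAULT}]")

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "pretreatment": self.pretreatment.to_dict(),
            "means": self.scaling.means.tolist(),
            "stds": self.scaling.stds.tolist(),
            "band_indices": self.band_indices.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "n_lv": self.n_lv,
            "algorithm": self.algorithm,
            "wavelengths": (None if self.wavelengths is None
                            else np.asarray(self.wavelengths).tolist()),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PLSRModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(
            pretreatment=Pretreatment.from_dict(doc["pretreatment"]),
            scaling=ScalingParams(np.array(doc["means"]), np.array(doc["stds"])),
            band_indices=np.array(doc["band_indices"], dtype=int),
            coef=np.array(doc["coef"]),
            intercept=float(doc["intercept"]),
            n_lv=int(doc["n_lv"]),
            algorithm=doc["algorithm"],
            wavelengths=(None if doc["wavelengths"] is None
                         else np.array(doc["wavelengths"])),
        )

    def predict_matrix(self, X_pretreated: np.ndarray) -> np.ndarray:
        """Predict from an already-pretreated samples x bands matrix."""
        X = np.atleast_2d(np.asarray(X_pretreated, float))
        if X.shape[1] <= self.band_indices.max():
            raise ValueError("band count does not cover the model's band indices")
        Xs = (X[:, self.band_indices] - self.scaling.means) / self.scaling.stds
        return Xs @ self.coef + self.intercept


def plsr_fit(table: SpectrumTable, n_lv: int | None = None,
             pretreatment: Pretreatment = Pretreatment(),
             band_indices: np.ndarray | None = None,
             algorithm: str = "simpls", max_lv: int = MAX_LV_DEFAULT,
             cv_k: int = 10, seed: int = 0) -> PLSRModel:
    """Fit a Brix calibration on a training table of raw mean spectra.

    Applies the pretreatment chain, restricts to ``band_indices`` (all bands
    by default), autoscales, and fits PLS1.  If ``n_lv`` is None it is chosen
    by k-fold cross-validation with the min+1SD rule.
    """
    if table.y is None:
        raise ValueError("training table has no Brix values")
    pre = pretreatment.apply(table)
    if band_indices is None:
        band_indices = np.arange(pre.n_bands)
    band_indices = np.asarray(band_indices, dtype=int)
    sub = pre.replace(pre.X[:, band_indices],
                      _subaxis(pre, band_indices))
    if n_lv is None:
        cv = cross_validate(sub, max_lv=max_lv, k=cv_k, seed=seed)
        n_lv = cv.selected_lv
    scaling = _fit_scaling(sub.X)
    Xs = (sub.X - scaling.means) / scaling.stds
    path, xm, ym = pls1_coefficient_path(Xs, sub.y, n_lv, algorithm)
    # Xs columns have mean 0, so xm is ~0; fold it in exactly regardless.
    coef = path[n_lv - 1]
    intercept = ym - float(xm @ coef)
    return PLSRModel(pretreatment=pretreatment, scaling=scaling,
                     band_indices=band_indices, coef=coef,
                     intercept=intercept, n_lv=n_lv, algorithm=algorithm,
                     wavelengths=sub.axis.centers.copy())


def plsr_predict(model: PLSRModel, table: SpectrumTable) -> np.ndarray:
    """Predict Brix for a table of raw mean spectra."""
    pre = model.pretreatment.apply(table)
    return model.predict_matrix(pre.X)


def _subaxis(table: SpectrumTable, idx: np.ndarray):
    from .hypercube import WavelengthAxis
    centers = table.axis.centers[np.sort(idx)]
    if np.array_equal(np.sort(idx), idx):
        return WavelengthAxis(table.axis.centers[idx])
    raise ValueError("band_indices must be sorted ascending")


# ---------------------------------------------------------------------------
# Cross-validation with the min + 1 SD rule

@dataclass
class CVResult:
    rmsecv: np.ndarray        # per candidate LV (1-based: rmsecv[a-1])
    sd: np.ndarray            # per-LV SD of fold RMSEs
    selected_lv: int
    fold_rmse: np.ndarray     # (k, max_lv) per-fold RMSE matrix


def _fit_scaling(X: np.ndarray) -> ScalingParams:
    """Autoscaling parameters tolerant of (near-)constant bands.

    A band whose variance is zero, or negligible next to the most informative
    band's (below 1e-9 of the largest SD, i.e. round-off), gets unit scale:
    after centering it contributes essentially nothing, whereas dividing by a
    round-off SD would blow float noise up to full-variance pseudo-signal.
    """
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=1)
    cutoff = stds.max() * 1e-9
    stds = np.where(stds <= cutoff, 1.0, stds)
    return ScalingParams(means, stds)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels stratified by y rank: consecutive rank blocks of size k get
    a random permutation of fold labels, so each fold spans the Brix range."""
    n = y.size
    folds = np.empty(n, dtype=int)
    order = np.argsort(y, kind="stable")
    for start in range(0, n, k):
        block = order[start:start + k]
        folds[block] = rng.permutation(k)[:block.size]
    return folds


def cross_validate(table: SpectrumTable, max_lv: int = MAX_LV_DEFAULT,
                   k: int = 10, seed: int = 0,
                   algorithm: str = "simpls",
                   folds: np.ndarray | None = None) -> CVResult:
    """k-fold CV over candidate LV counts; picks the smallest LV whose RMSECV
    is within one SD (taken at the global minimiser, across folds) of the
    global minimum.

    Autoscaling is refit inside every training fold so no test-fold
    information leaks into the scaling.
    """
    if table.y is None:
        raise ValueError("cross-validation needs Brix values")
    n = table.n_samples
    if k > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    if folds is None:
        folds = _stratified_folds(table.y, k, rng)
    counts = np.bincount(folds, minlength=k)
    if np.any(counts < 2):
        raise ValueError("every fold needs at least 2 samples")
    max_lv = min(max_lv, table.n_bands, int(n - counts.max() - 1))
    if max_lv < 1:
        raise ValueError("not enough samples for even one latent variable")
    preds = np.full((max_lv, n), np.nan)
    fold_rmse = np.full((k, max_lv), np.nan)
    for f in range(k):
        val = folds == f
        tr = ~val
        scaling = _fit_scaling(table.X[tr])
        Xtr = (table.X[tr] - scaling.means) / scaling.stds
        Xval = (table.X[val] - scaling.means) / scaling.stds
        path, xm, ym = pls1_coefficient_path(Xtr, table.y[tr], max_lv,
                                             algorithm, strict=False)
        a_max = path.shape[0]                  # may truncate on low rank
        p_val = (Xval - xm) @ path.T + ym      # (n_val, a_max)
        preds[:a_max, val] = p_val.T
        err = p_val - table.y[val][:, None]
        fold_rmse[f, :a_max] = np.sqrt(np.mean(err ** 2, axis=0))
    valid = ~np.isnan(preds).any(axis=1)
    preds = preds[valid]
    fold_rmse = fold_rmse[:, valid]
    rmsecv = np.sqrt(np.mean((preds - table.y) ** 2, axis=1))
    sd = np.std(fold_rmse, axis=0, ddof=1)
    a_min = int(np.argmin(rmsecv))
    bound = rmsecv[a_min] + sd[a_min]
    selected = int(np.flatnonzero(rmsecv <= bound)[0]) + 1
    return CVResult(rmsecv=rmsecv, sd=sd, selected_lv=selected,
                    fold_rmse=fold_rmse)


# ---------------------------------------------------------------------------
# CARS wavelength selection

@dataclass
class CARSResult:
    selected_bands: np.ndarray
    per_run_subsets: list[np.ndarray]
    per_run_rmsecv: np.ndarray
    retention_schedule: np.ndarray
    best_run: int


def cars_select(table: SpectrumTable, n_runs: int = 50, mc_ratio: float = 0.8,
                k: int = 10, seed: int = 0, max_lv: int = MAX_LV_DEFAULT,
                algorithm: str = "simpls") -> CARSResult:
    """Competitive adaptive reweighted sampling over the table's bands.

    Run ``i`` (1-based) fits PLS1 on a Monte-Carlo subset of the samples using
    the currently retained bands, ranks bands by |coefficient| (on autoscaled
    predictors), enforces the exponentially decaying retention fraction
    r_i = a*exp(-c*i) pinned to r_1 = 1 and r_{n_runs} = 2/n_bands, then keeps
    the unique outcome of |coefficient|-weighted draws within that count.
    Every run's subset is scored by RMSECV on the full table with one fixed
    fold assignment, so subset comparisons are paired; the subset with the
    lowest RMSECV wins.
    """
    if table.y is None:
        raise ValueError("CARS needs Brix values")
    p = table.n_bands
    n = table.n_samples
    if p < 3:
        raise ValueError("CARS needs at least 3 bands")
    if n_runs < 2:
        raise ValueError("CARS needs at least 2 runs")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(table.y, k, np.random.default_rng(seed))

    c = np.log(p / 2.0) / (n_runs - 1)
    schedule = np.exp(c) * np.exp(-c * np.arange(1, n_runs + 1))
    n_mc = max(2, int(round(mc_ratio * n)))
    # reference LV count chosen once on the full table
    base_lv = cross_validate(table, max_lv=max_lv, k=k, seed=seed,
                             algorithm=algorithm, folds=folds).selected_lv

    retained = np.arange(p)
    subsets: list[np.ndarray] = []
    scores: list[float] = []
    for i in range(n_runs):
        rows = rng.choice(n, size=n_mc, replace=False)
        sub = table.subset_rows(rows)
        Xsub = sub.X[:, retained]
        scal = _fit_scaling(Xsub)   # constant bands get ~0 coefficients
        Xs = (Xsub - scal.means) / scal.stds
        a = min(base_lv, retained.size, n_mc - 1)
        path, _, _ = pls1_coefficient_path(Xs, sub.y, a, algorithm,
                                           strict=False)
        w = np.abs(path[-1])
        n_keep = max(2, int(round(schedule[i] * p)))
        n_keep = min(n_keep, retained.size)
        # enforced (exponentially decaying) cut: top bands by |coef|,
        # ties broken toward the lower band index
        order = np.lexsort((retained, -w))
        forced = order[:n_keep]
        wf = w[forced]
        if wf.sum() == 0:
            probs = np.full(forced.size, 1.0 / forced.size)
        else:
            probs = wf / wf.sum()
        # adaptive reweighted sampling within the enforced count
        draws = rng.choice(forced.size, size=n_keep, replace=True, p=probs)
        keep_local = np.unique(draws)
        new_retained = np.sort(retained[forced[keep_local]])
        if new_retained.size < 2:
            break      # schedule exhausted early; stop with what we have
        retained = new_retained
        cv = cross_validate(table.subset_rows(np.arange(n)).replace(
            table.X[:, retained], _axis_subset(table, retained)),
            max_lv=max_lv, k=k, seed=seed, algorithm=algorithm, folds=folds)
        subsets.append(retained.copy())
        scores.append(float(np.min(cv.rmsecv)))
    if not subsets:
        raise ValueError("CARS could not complete a single run")
    scores_arr = np.asarray(scores)
    best = int(np.argmin(scores_arr))
    return CARSResult(selected_bands=subsets[best],
                      per_run_subsets=subsets,
                      per_run_rmsecv=scores_arr,
                      retention_schedule=schedule[:len(subsets)],
                      best_run=best)


def _axis_subset(table: SpectrumTable, idx: np.ndarray):
    from .hypercube import WavelengthAxis
    return WavelengthAxis(table.axis.centers[idx])


# ---------------------------------------------------------------------------
# Train/test split and the model-search grid

def split_train_test(table: SpectrumTable, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-fruit paired split: one measured side to train, the other to test.

    ``table.meta`` must carry ``fruit`` and ``side`` columns; every fruit must
    appear with exactly two sides.  Returns boolean row masks (train, test).
    """
    if table.meta is None or not {"fruit", "side"} <= set(table.meta.columns):
        raise ValueError("split needs meta columns 'fruit' and 'side'")
    meta = table.meta
    rng = np.random.default_rng(seed)
    train = np.zeros(table.n_samples, dtype=bool)
    for fruit, grp in meta.groupby("fruit", sort=True):
        sides = sorted(grp["side"].unique())
        if len(sides) != 2:
            raise ValueError(f"fruit {fruit!r} does not have exactly two sides")
        train_side = sides[int(rng.integers(2))]
        train[grp.index[grp["side"] == train_side]] = True
    return train, ~train


_GRID_PRETREATMENTS = [
    ("Raw", Pretreatment()),
    ("SNV", Pretreatment(snv=True)),
    ("2nd derivative", Pretreatment(deriv2=True)),
    ("SNV + 2nd derivative", Pretreatment(snv=True, deriv2=True)),
]


def run_model_grid(tables: dict[str, SpectrumTable], seed: int = 0,
                   max_lv: int = MAX_LV_DEFAULT, cv_k: int = 10,
                   cars_runs: int = 50, mc_ratio: float = 0.8,
                   algorithm: str = "simpls") -> pd.DataFrame:
    """Run the 24-pattern model search (2 pretreatments x 2 derivative
    choices x CARS-or-not x 3 ROIs) and report a calibration table sorted
    ascending by R2p.

    All patterns share one per-fruit train/test split so rows are comparable.
    """
    expected = {"fruit", "flesh", "achene"}
    if set(tables) != expected:
        raise ValueError(f"tables must be keyed by {sorted(expected)}")
    ref = tables["fruit"]
    tr_mask, te_mask = split_train_test(ref, seed=seed)
    rows = []
    for roi in ("fruit", "flesh", "achene"):
        table = tables[roi]
        if table.n_samples != ref.n_samples:
            raise ValueError("ROI tables must be sample-aligned")
        tr_idx = np.flatnonzero(tr_mask)
        te_idx = np.flatnonzero(te_mask)
        for label, pretreat in _GRID_PRETREATMENTS:
            pre_all = pretreat.apply(table)
            train = pre_all.subset_rows(tr_idx)
            test = pre_all.subset_rows(te_idx)
            for use_cars in (False, True):
                if use_cars:
                    cars = cars_select(train, n_runs=cars_runs,
                                       mc_ratio=mc_ratio, k=cv_k, seed=seed,
                                       max_lv=max_lv, algorithm=algorithm)
                    bands = cars.selected_bands
                else:
                    bands = np.arange(train.n_bands)
                sub_train = train.replace(train.X[:, bands],
                                          _axis_subset(train, bands))
                cv = cross_validate(sub_train, max_lv=max_lv, k=cv_k,
                                    seed=seed, algorithm=algorithm)
                model = plsr_fit(train, n_lv=cv.selected_lv,
                                 band_indices=bands, algorithm=algorithm)
                yhat_c = model.predict_matrix(train.X)
                yhat_p = model.predict_matrix(test.X)
                rows.append({
                    "pretreatment": label,
                    "selection": "CARS + CV" if use_cars else "CV",
                    "roi": roi,
                    "n_variables": int(bands.size),
                    "n_lv": int(cv.selected_lv),
                    "rmsecv": float(cv.rmsecv[cv.selected_lv - 1]),
                    "rmsec": rmse(train.y, yhat_c),
                    "rmsep": rmse(test.y, yhat_p),
                    "r2c": r2(train.y, yhat_c),
                    "r2p": r2(test.y, yhat_p),
                })
    report = pd.DataFrame(rows).sort_values("r2p", ascending=True,
                                            kind="stable")
    return report.reset_index(drop=True)
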