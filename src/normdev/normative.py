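"""Vertexwise normative modeling with cross-validated reference predictions.

The reference (TD) cohort is scored strictly out-of-fold: each TD subject's
predicted thickness and predictive uncertainty come from a model that never
saw that subject. Clinical (ASD) subjects are scored by the model refit on
the full TD cohort. Provenance is recorded per row so the two prediction
routes can never be confused downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .deviations import bh_fdr
from .gp import GPFitError, VertexGPRegressor, _Workspace

logger = logging.getLogger(__name__)


@dataclass
class PredictionSet:
    """Per subject-vertex predictive means and variances with provenance."""

    yhat: np.ndarray          # subjects x vertices
    var_latent: np.ndarray    # subjects x vertices
    noise_var: np.ndarray     # subjects x vertices
    provenance: np.ndarray    # per subject: "cv-fold-k" or "full-model"
    fold_assignment: np.ndarray | None = None   # per TD subject
    failed_vertices: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))

    @property
    def total_var(self) -> np.ndarray:
        return self.var_latent + self.noise_var

    @property
    def is_out_of_fold(self) -> np.ndarray:
        return np.char.startswith(self.provenance.astype(str), "cv-fold")


def _standardized(X: np.ndarray) -> np.ndarray:
    """Replicate the estimator's covariate standardization for workspace
    sharing across vertices (dummies untouched, continuous z-scored)."""
    X = np.asarray(X, dtype=float)
    is_dummy = np.array([np.isin(np.unique(col), [0.0, 1.0]).all()
                         for col in X.T])
    mean = np.where(is_dummy, 0.0, X.mean(axis=0))
    scale = np.where(is_dummy, 1.0, X.std(axis=0))
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale


class NormativeModel(BaseEstimator):
    """Per-vertex GP normative models fit on a reference cohort.

    ``fit(X, Y)`` runs empirical Bayes independently at every vertex
    (column of ``Y``); ``predict(X)`` returns predictive means, latent
    variances and noise variances as subjects x vertices arrays.
    Vertices whose optimization fails are flagged in
    ``failed_vertices_`` and excluded downstream.
    """

    def __init__(self, n_restarts: int = 5, max_iter: int = 200,
                 tol: float = 1e-6, min_train: int = 20,
                 random_state=None):
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.min_train = min_train
        self.random_state = random_state

    def fit(self, X, Y, initial_thetas=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and Y have inconsistent row counts")
        ws = _Workspace(_standardized(X))
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            Y.shape[1])
        models: list[VertexGPRegressor | None] = []
        failed = []
        for v in range(Y.shape[1]):
            theta0 = None if initial_thetas is None else initial_thetas[v]
            reg = VertexGPRegressor(
                n_restarts=self.n_restarts if theta0 is None else 0,
                max_iter=self.max_iter, tol=self.tol,
                min_train=self.min_train, initial_theta=theta0,
                random_state=int(seeds[v]),
            )
            try:
                reg.fit(X, Y[:, v], workspace=ws)
                models.append(reg)
            except GPFitError:
                logger.warning("vertex %d: all restarts failed; flagged", v)
                models.append(None)
                failed.append(v)
        self.models_ = models
        self.failed_vertices_ = np.asarray(failed, dtype=int)
        self.n_vertices_ = Y.shape[1]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        yhat = np.full((n, self.n_vertices_), np.nan)
        var_latent = np.full((n, self.n_vertices_), np.nan)
        noise_var = np.full((n, self.n_vertices_), np.nan)
        for v, model in enumerate(self.models_):
            if model is None:
                continue
            m, s2, n2 = model.predict(X, return_var=True)
            yhat[:, v] = m
            var_latent[:, v] = s2
            noise_var[:, v] = n2
        return yhat, var_latent, noise_var

    @property
    def thetas_(self) -> list:
        return [None if m is None else m.kernel_params_.to_vector()
                for m in self.models_]


def make_folds(n: int, folds: int, seed=None) -> np.ndarray:
    """Seeded uniform-random fold assignment (0..folds-1) per subject."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("fewer subjects than folds")
    rng = np.random.default_rng(seed)
    assignment = np.arange(n) % folds
    return rng.permutation(assignment)


def run_normative(td_X, td_Y, asd_X=None, folds: int = 10,
                  n_restarts: int = 5, min_train: int = 20,
                  seed=None, max_iter: int = 200, tol: float = 1e-6):
    """Full normative run: CV out-of-fold predictions for the reference
    cohort and full-model predictions for the clinical cohort.

    The full-cohort model is fit first (multi-restart empirical Bayes);
    each fold's refit is then warm-started from the full-model optimum,
    but re-optimizes its own marginal likelihood on the fold's training
    subjects only. Returns ``(td_pred, asd_pred, full_model)``;
    ``asd_pred`` is None when ``asd_X`` is None.
    """
    td_X = np.atleast_2d(np.asarray(td_X, dtype=float))
    td_Y = np.asarray(td_Y, dtype=float)
    n_td, n_vert = td_Y.shape
    if n_td == 0:
        raise ValueError("reference cohort is empty; cannot fit")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n_td < folds:
        raise ValueError("reference cohort smaller than fold count")

    ss = np.random.SeedSequence(seed)
    fold_seed, fit_seed = ss.generate_state(2)
    assignment = make_folds(n_td, folds, seed=fold_seed)

    full = NormativeModel(n_restarts=n_restarts, max_iter=max_iter, tol=tol,
                          min_train=min_train, random_state=int(fit_seed))
    full.fit(td_X, td_Y)
    warm = full.thetas_

    yhat = np.full((n_td, n_vert), np.nan)
    var_latent = np.full((n_td, n_vert), np.nan)
    noise_var = np.full((n_td, n_vert), np.nan)
    provenance = np.empty(n_td, dtype=object)
    failed = set(full.failed_vertices_.tolist())

    for k in range(folds):
        test = assignment == k
        train = ~test
        if train.sum() == 0:
            raise ValueError(f"fold {k} emptied of training data")
        fold_model = NormativeModel(
            n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            min_train=min_train, random_state=int(fit_seed) + k + 1)
        fold_model.fit(td_X[train], td_Y[train], initial_thetas=warm)
        failed.update(fold_model.failed_vertices_.tolist())
        m, s2, n2 = fold_model.predict(td_X[test])
        yhat[test] = m
        var_latent[test] = s2
        noise_var[test] = n2
        provenance[test] = f"cv-fold-{k}"

    failed_arr = np.asarray(sorted(failed), dtype=int)
    td_pred = PredictionSet(yhat=yhat, var_latent=var_latent,
                            noise_var=noise_var, provenance=provenance,
                            fold_assignment=assignment,
                            failed_vertices=failed_arr)

    asd_pred = None
    if asd_X is not None:
        asd_X = np.atleast_2d(np.asarray(asd_X, dtype=float))
        m, s2, n2 = full.predict(asd_X)
        asd_pred = PredictionSet(
            yhat=m, var_latent=s2, noise_var=n2,
            provenance=np.full(asd_X.shape[0], "full-model", dtype=object),
            failed_vertices=failed_arr)
    return td_pred, asd_pred, full


def evaluate_fit(pred: PredictionSet, Y_true, q: float = 0.05) -> pd.DataFrame:
    """Per-vertex fit quality of the out-of-fold reference predictions.

    Pearson correlation between observed and predicted values across
    subjects, its two-sided p-value, RMSE (mm), and a BH-FDR significance
    flag at level ``q`` across vertices. Zero-variance prediction vectors
    yield an undefined correlation and are flagged non-significant.
    """
    if not bool(np.all(pred.is_out_of_fold)):
        raise ValueError("fit evaluation requires out-of-fold predictions")
    Y_true = np.asarray(Y_true, dtype=float)
    yhat = pred.yhat
    n, n_vert = Y_true.shape
    r = np.full(n_vert, np.nan)
    p = np.ones(n_vert)
    rmse = np.sqrt(np.mean((Y_true - yhat) ** 2, axis=0))
    valid = ~np.isin(np.arange(n_vert), pred.failed_vertices)
    for v in np.flatnonzero(valid):
        # constant vectors (ptp == 0) have undefined correlation
        if np.ptp(Y_true[:, v]) == 0 or np.ptp(yhat[:, v]) == 0:
            continue
        rv = float(np.corrcoef(Y_true[:, v], yhat[:, v])[0, 1])
        r[v] = rv
        t = rv * np.sqrt(max(n - 2, 1) / max(1.0 - rv ** 2, 1e-300))
        p[v] = max(2.0 * stats.t.sf(abs(t), df=n - 2),
                   np.finfo(float).tiny)
    significant = np.zeros(n_vert, dtype=bool)
    testable = valid & ~np.isnan(r)
    if testable.any() and q > 0:
        significant[testable] = bh_fdr(p[testable], q)
    return pd.DataFrame({
        "vertex": np.arange(n_vert), "pearson_r": r, "p": p,
        "rmse": rmse, "significant": significant,
    })
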