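"""Latent-variable chemometrics: NIPALS PCA, PLS-DA and OPLS-DA.

All latent models are fitted with the NIPALS algorithm (missing entries are
handled by skipping them in the inner products), the convention used by
chemometrics packages for spectroscopic and metabolomic matrices:

* **PCA** for overview and Hotelling's T2 outlier screening, with the
  F-distribution closed form for the (1 - alpha) T2 limit;
* **PLS-DA** (PLS2 on a dummy-coded class matrix) for multi-class
  discrimination, with Q2 = 1 - PRESS/SSY from 7-fold venetian-blind
  cross-validation and CV-ANOVA significance;
* **OPLS-DA** for binary contrasts: a single class-predictive component
  plus orthogonal (class-uncorrelated) components, so that variable
  selection can read importance off one predictive direction.

Variable selection combines the variable importance on projection
(VIP > 1, squared values averaging 1 across variables) with the loading
on the correlation scale p(corr) (|p(corr)| > 0.5), the Pearson
correlation between a variable and the predictive score vector.

Per-sample class predictions YpredPS (cross-validated) feed a
classification list: a sample belongs to a class when YpredPS > 0.65,
does not belong below 0.35, and is borderline in between (with a
sub-flag above 0.6).  Classification percentages count only the
confidently called samples: 100 * belongs / (belongs + not).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

log = logging.getLogger(__name__)

NIPALS_TOL = 1e-10
NIPALS_LOOSE_TOL = 1e-3   # accepted with a warning at the iteration cap
NIPALS_MAX_ITER = 1000
DEFAULT_CV_FOLDS = 7
BELONGS_THRESHOLD = 0.65
NOT_THRESHOLD = 0.35
BORDERLINE_FLAG = 0.60
VIP_CUT = 1.0
PCORR_CUT = 0.5


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


@dataclass
class PreprocessSpec:
    """log2 + autoscaling for features; median-0 / sd-1 for covariates.

    Features are log2-transformed (zeros offset by half the smallest
    positive value of the feature) and autoscaled to mean 0 / sd 1.
    Clinical covariates (standardized age ``age_stand``, standardized fecal
    Hb ``fit_stand``) are standardized to median 0 and sd 1 -- the
    asymmetry with respect to the features is intentional.
    """

    log_transform: bool = True
    autoscale: bool = True
    covariate_standardize: bool = True
    include_covariates: tuple = ()


@dataclass
class PreprocessFit:
    spec: PreprocessSpec
    half_min: pd.Series
    col_mean: pd.Series
    col_sd: pd.Series
    cov_median: pd.Series
    cov_sd: pd.Series

    def transform(self, abundance: pd.DataFrame, cohort: CohortTable | None = None) -> pd.DataFrame:
        X = abundance[self.col_mean.index.difference(self.cov_median.index, sort=False)
                      .intersection(abundance.columns)]
        X = abundance[[c for c in abundance.columns if c in self.half_min.index]].astype(float)
        if self.spec.log_transform:
            X = X.mask(X <= 0, self.half_min, axis=1)
            X = np.log2(X)
        if self.spec.autoscale:
            X = (X - self.col_mean[X.columns]) / self.col_sd[X.columns]
        cols = [X]
        for cov in self.spec.include_covariates:
            raw = _covariate_values(cov, cohort, X.index)
            cols.append(((raw - self.cov_median[cov]) / self.cov_sd[cov]).rename(cov))
        return pd.concat(cols, axis=1)


def _covariate_values(name: str, cohort: CohortTable, index: pd.Index) -> pd.Series:
    if cohort is None:
        raise ValueError("covariates requested but no cohort given")
    src = {"age_stand": "age", "fit_stand": "fecal_hb"}.get(name)
    if src is None:
        raise ValueError(f"unknown covariate {name!r}")
    return cohort.data.loc[index, src].astype(float)


def preprocess(
    abundance: pd.DataFrame,
    cohort: CohortTable | None = None,
    spec: PreprocessSpec | None = None,
) -> tuple[pd.DataFrame, PreprocessFit]:
    """Build the model matrix: log2 + autoscale features, append covariates."""
    spec = spec or PreprocessSpec()
    X = abundance.astype(float)
    pos = X.where(X > 0)
    half_min = pos.min() / 2.0
    if spec.log_transform:
        X = np.log2(X.mask(X <= 0, half_min, axis=1))
    mean = X.mean()
    sd = X.std(ddof=1)
    const = sd.isna() | (sd <= 1e-12 * (1.0 + mean.abs()))
    if const.any():
        log.warning("preprocess: %d constant feature columns scaled by 1", int(const.sum()))
        sd = sd.mask(const, 1.0)
    if spec.autoscale:
        X = (X - mean) / sd
    cov_median, cov_sd = {}, {}
    cols = [X]
    for cov in spec.include_covariates:
        raw = _covariate_values(cov, cohort, X.index)
        m, s = float(raw.median()), float(raw.std(ddof=1))
        s = s if s > 0 else 1.0
        cov_median[cov], cov_sd[cov] = m, s
        cols.append(((raw - m) / s).rename(cov))
    fit = PreprocessFit(spec, half_min, mean, sd, pd.Series(cov_median), pd.Series(cov_sd))
    return pd.concat(cols, axis=1), fit


# ---------------------------------------------------------------------------
# masked linear algebra helpers (NIPALS skip-missing inner products)
# ---------------------------------------------------------------------------


def _masked_score(X: np.ndarray, mask: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row scores t_i = sum_obs(x_ij w_j) / sum_obs(w_j^2)."""
    num = np.where(mask, X, 0.0) @ w
    den = mask @ (w**2)
    return num / np.where(den == 0, 1.0, den)


def _masked_loading(X: np.ndarray, mask: np.ndarray, t: np.ndarray) -> np.ndarray:
    num = np.where(mask, X, 0.0).T @ t
    den = mask.T @ (t**2)
    return num / np.where(den == 0, 1.0, den)


def _ss(X: np.ndarray, mask: np.ndarray | None = None) -> float:
    if mask is None:
        return float(np.nansum(X**2))
    return float(np.sum(np.where(mask, X, 0.0) ** 2))


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class LatentModel:
    """Fitted latent-variable model (PCA / PLS-DA / OPLS-DA)."""

    kind: str
    scores: pd.DataFrame                      # predictive scores (samples x A)
    loadings: pd.DataFrame                    # X loadings (features x A)
    r2x: float
    n_components: int
    sample_ids: pd.Index
    feature_names: pd.Index
    weights: pd.DataFrame | None = None       # X weights (PLS family)
    y_loadings: np.ndarray | None = None
    ortho_scores: pd.DataFrame | None = None  # OPLS orthogonal scores
    ortho_loadings: pd.DataFrame | None = None
    ortho_weights: pd.DataFrame | None = None
    r2x_per_component: tuple = ()
    r2x_pred: float | None = None
    r2x_ortho: tuple = ()
    r2y: float | None = None
    q2: float | None = None
    press: float | None = None
    ssy: float | None = None
    ssy_explained: np.ndarray | None = None   # Y sum of squares per predictive comp.
    classes: tuple = ()
    y_mean: np.ndarray | None = None
    y_pred_cv: pd.DataFrame | None = None     # cross-validated YpredPS per class
    cv_folds: int | None = None
    cv_seed: int | None = None
    cv_anova_p: float | None = None
    cv_anova_df: tuple | None = None          # (df_model, df_residual) convention used
    vip: pd.Series | None = None
    p_corr: pd.Series | None = None
    hotelling_t2: pd.Series | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "n_components": self.n_components,
            "r2x": None if self.r2x is None else round(self.r2x, 4),
            "r2y": None if self.r2y is None else round(self.r2y, 4),
            "q2": None if self.q2 is None else round(self.q2, 4),
            "cv_anova_p": self.cv_anova_p,
            "cv_anova_df": self.cv_anova_df,
            "classes": list(self.classes),
            "cv_folds": self.cv_folds,
            "cv_seed": self.cv_seed,
        }


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def _nipals_pca_component(X, mask, tol=NIPALS_TOL, max_iter=NIPALS_MAX_ITER):
    col_var = np.nanvar(np.where(mask, X, np.nan), axis=0)
    t = np.where(mask, X, 0.0)[:, int(np.nanargmax(col_var))].astype(float).copy()
    if not t.any():
        t = np.ones(X.shape[0])
    for _ in range(max_iter):
        p = _masked_loading(X, mask, t)
        p /= np.linalg.norm(p)
        t_new = _masked_score(X, mask, p)
        change = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
        if change <= tol:
            return t_new, p
        t = t_new
    if change <= NIPALS_LOOSE_TOL:  # close eigenvalues: slow but essentially converged
        log.warning("NIPALS PCA stopped at max_iter with relative change %.2e", change)
        return t, p
    raise ConvergenceError


def fit_pca(X: pd.DataFrame, n_components: int = 2) -> LatentModel:
    """NIPALS principal component analysis with Hotelling's T2 per sample.

    Missing entries are skipped in the inner products.  Columns are centred
    on their observed means; scaling is the caller's responsibility (see
    :func:`preprocess`).  Raises :class:`ConvergenceError` naming the
    component if NIPALS does not converge.
    """
    Xv = X.to_numpy(float)
    mask = np.isfinite(Xv)
    if (~mask).all(axis=0).any():
        raise ValueError("all-missing columns are not allowed")
    Xc = Xv - np.nanmean(np.where(mask, Xv, np.nan), axis=0)
    Xc = np.where(mask, Xc, np.nan)
    ss_total = _ss(Xc, mask)
    E = Xc.copy()
    scores, loadings, r2 = [], [], []
    for a in range(n_components):
        try:
            t, p = _nipals_pca_component(np.where(mask, E, 0.0), mask)
        except ConvergenceError:
            raise ConvergenceError(f"NIPALS PCA failed to converge on component {a + 1}")
        E = E - np.outer(t, p)
        scores.append(t)
        loadings.append(p)
        r2.append(1.0 - _ss(E, mask) / ss_total - sum(r2))
    T = np.column_stack(scores)
    model = LatentModel(
        kind="PCA",
        scores=pd.DataFrame(T, index=X.index, columns=[f"t{i+1}" for i in range(n_components)]),
        loadings=pd.DataFrame(
            np.column_stack(loadings), index=X.columns,
            columns=[f"p{i+1}" for i in range(n_components)],
        ),
        r2x=float(sum(r2)),
        r2x_per_component=tuple(r2),
        n_components=n_components,
        sample_ids=X.index,
        feature_names=X.columns,
    )
    model.hotelling_t2 = hotelling_t2(model)
    return model


def hotelling_t2(model: LatentModel) -> pd.Series:
    """Per-sample T2 from the normalized score vectors."""
    T = model.scores.to_numpy(float)
    var = T.var(axis=0, ddof=1)
    t2 = (T**2 / var[None, :]).sum(axis=1)
    return pd.Series(t2, index=model.sample_ids, name="hotelling_t2")


def t2_limit(n: int, n_components: int, alpha: float = 0.05) -> float:
    """F-distribution closed form of the (1 - alpha) Hotelling T2 limit:
    ``A (n-1)(n+1) / (n (n-A)) * F_{1-alpha}(A, n-A)``."""
    a = n_components
    return a * (n - 1) * (n + 1) / (n * (n - a)) * float(stats.f.ppf(1 - alpha, a, n - a))


def detect_outliers(model: LatentModel, alpha: float = 0.05) -> list:
    """Samples outside the (1 - alpha) Hotelling T2 ellipse.

    Removal is a separate, explicit step for the caller; the flagged ids
    are logged.  ``alpha >= 1`` means the ellipse covers everything.
    """
    if alpha >= 1.0:
        return []
    t2 = model.hotelling_t2 if model.hotelling_t2 is not None else hotelling_t2(model)
    limit = t2_limit(model.n_samples, model.n_components, alpha)
    flagged = list(t2.index[t2 > limit])
    if flagged:
        log.info("detect_outliers: %d samples above T2 limit %.3f", len(flagged), limit)
    return flagged


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


def _dummy_y(classes: Sequence, order: Sequence | None = None) -> tuple[np.ndarray, tuple]:
    labels = tuple(order) if order is not None else tuple(pd.unique(pd.Series(list(classes))))
    Y = np.column_stack([(np.asarray(classes) == c).astype(float) for c in labels])
    return Y, labels


def _nipals_pls_component(X, mask, Y, tol=NIPALS_TOL, max_iter=NIPALS_MAX_ITER):
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    t = np.zeros(X.shape[0])
    for _ in range(max_iter):
        w = _masked_loading(X, mask, u)
        w /= np.linalg.norm(w)
        t_new = _masked_score(X, mask, w)
        q = Y.T @ t_new / (t_new @ t_new)
        if np.linalg.norm(q) > 0:
            u = Y @ q / (q @ q)
        change = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
        t = t_new
        if change <= tol:
            break
    else:
        if change > NIPALS_LOOSE_TOL:
            raise ConvergenceError("NIPALS PLS failed to converge")
        log.warning("NIPALS PLS stopped at max_iter with relative change %.2e", change)
    p = _masked_loading(X, mask, t)
    return t, w, p, q


def _fit_pls_core(Xc, mask, Yc, n_components):
    E, F = Xc.copy(), Yc.copy()
    T, W, P, Q = [], [], [], []
    for _ in range(n_components):
        t, w, p, q = _nipals_pls_component(np.where(mask, E, 0.0), mask, F)
        E = E - np.outer(t, p)
        F = F - np.outer(t, q)
        T.append(t), W.append(w), P.append(p), Q.append(q)
    return (np.column_stack(T), np.column_stack(W), np.column_stack(P),
            np.column_stack(Q), E, F)


def _pls_predict(Xnew, W, P, Q):
    mask = np.isfinite(Xnew)
    E = np.where(mask, Xnew, np.nan)
    Yhat = np.zeros((Xnew.shape[0], Q.shape[0]))
    for a in range(W.shape[1]):
        t = _masked_score(np.where(mask, E, 0.0), mask, W[:, a])
        E = E - np.outer(t, P[:, a])
        Yhat += np.outer(t, Q[:, a])
    return Yhat


def _venetian_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Fold labels: venetian-blind assignment by order after a seeded shuffle."""
    if folds > n:
        log.warning("cross-validation folds reduced from %d to %d", folds, n)
        folds = n
    order = np.random.default_rng(seed).permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    return fold_of


def fit_plsda(
    X: pd.DataFrame,
    classes: Sequence,
    n_components: int = 2,
    cv_folds: int = DEFAULT_CV_FOLDS,
    cv_seed: int = 0,
    class_order: Sequence | None = None,
) -> LatentModel:
    """PLS2 discriminant analysis on a dummy-coded class matrix.

    Q2 comes from venetian-blind cross-validation in which each training
    fold is re-centred before fitting; YpredPS are the cross-model
    predictions of the held-out samples.
    """
    Y, labels = _dummy_y(classes, class_order)
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    Xv = X.to_numpy(float)
    mask = np.isfinite(Xv)
    xm = np.nanmean(np.where(mask, Xv, np.nan), axis=0)
    ym = Y.mean(axis=0)
    Xc = np.where(mask, Xv - xm, np.nan)
    Yc = Y - ym
    ssx = _ss(Xc, mask)
    ssy = float((Yc**2).sum())

    T, W, P, Q, E, F = _fit_pls_core(Xc, mask, Yc, n_components)
    r2x = 1.0 - _ss(E, mask) / ssx
    r2y = 1.0 - float((F**2).sum()) / ssy
    ssy_explained = (Q**2).sum(axis=0) * (T**2).sum(axis=0)

    # cross-validation
    n = len(X)
    fold_of = _venetian_folds(n, cv_folds, cv_seed)
    press = 0.0
    ypred = np.empty_like(Y)
    for f in np.unique(fold_of):
        tr, te = fold_of != f, fold_of == f
        xm_f = np.nanmean(np.where(mask[tr], Xv[tr], np.nan), axis=0)
        ym_f = Y[tr].mean(axis=0)
        Tf, Wf, Pf, Qf, _, _ = _fit_pls_core(
            np.where(mask[tr], Xv[tr] - xm_f, np.nan), mask[tr], Y[tr] - ym_f, n_components
        )
        yh = _pls_predict(Xv[te] - xm_f, Wf, Pf, Qf) + ym_f
        ypred[te] = yh
        press += float(((Y[te] - yh) ** 2).sum())
    q2 = 1.0 - press / ssy

    model = LatentModel(
        kind="PLSDA",
        scores=pd.DataFrame(T, index=X.index, columns=[f"t{i+1}" for i in range(n_components)]),
        loadings=pd.DataFrame(P, index=X.columns, columns=[f"p{i+1}" for i in range(n_components)]),
        weights=pd.DataFrame(W, index=X.columns, columns=[f"w{i+1}" for i in range(n_components)]),
        y_loadings=Q,
        r2x=float(r2x),
        r2y=float(r2y),
        q2=float(q2),
        press=press,
        ssy=ssy,
        ssy_explained=ssy_explained,
        n_components=n_components,
        sample_ids=X.index,
        feature_names=X.columns,
        classes=labels,
        y_mean=ym,
        y_pred_cv=pd.DataFrame(ypred, index=X.index, columns=list(labels)),
        cv_folds=int(len(np.unique(fold_of))),
        cv_seed=cv_seed,
    )
    model.hotelling_t2 = hotelling_t2(model)
    model.cv_anova_p = cv_anova(model)
    model.vip = vip_scores(model)
    model.p_corr = p_corr(model, X)
    return model


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _fit_opls_core(Xc, mask, yc, n_ortho):
    w = _masked_loading(Xc, mask, yc)  # X'y direction
    w /= np.linalg.norm(w)
    E = Xc.copy()
    To, Wo, Po = [], [], []
    for _ in range(n_ortho):
        t = _masked_score(np.where(mask, E, 0.0), mask, w)
        p = _masked_loading(np.where(mask, E, 0.0), mask, t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:   # no Y-orthogonal structure left
            break
        w_o /= norm
        t_o = _masked_score(np.where(mask, E, 0.0), mask, w_o)
        p_o = _masked_loading(np.where(mask, E, 0.0), mask, t_o)
        E = E - np.outer(t_o, p_o)
        To.append(t_o), Wo.append(w_o), Po.append(p_o)
    t = _masked_score(np.where(mask, E, 0.0), mask, w)
    p = _masked_loading(np.where(mask, E, 0.0), mask, t)
    q = float(yc @ t / (t @ t))
    return w, t, p, q, To, Wo, Po, E


def _opls_predict(Xnew, w, p, q, Wo, Po):
    mask = np.isfinite(Xnew)
    E = np.where(mask, Xnew, np.nan)
    for w_o, p_o in zip(Wo, Po):
        t_o = _masked_score(np.where(mask, E, 0.0), mask, w_o)
        E = E - np.outer(t_o, p_o)
    t = _masked_score(np.where(mask, E, 0.0), mask, w)
    return t * q, t


def fit_oplsda(
    X: pd.DataFrame,
    classes: Sequence,
    n_components: int = 2,
    cv_folds: int = DEFAULT_CV_FOLDS,
    cv_seed: int = 0,
    positive_class=None,
) -> LatentModel:
    """Orthogonal PLS-DA for a binary contrast.

    ``n_components`` counts one predictive plus ``n_components - 1``
    orthogonal components.  The modeled R2X is partitioned into a
    predictive and an orthogonal part that sum to the total.  Exactly two
    classes are required; use :func:`fit_plsda` otherwise.
    """
    labels = tuple(pd.unique(pd.Series(list(classes))))
    if len(labels) != 2:
        raise ValueError("OPLS-DA requires exactly two classes; use fit_plsda for more")
    if positive_class is None:
        positive_class = labels[0]
    negative_class = labels[0] if positive_class == labels[1] else labels[1]
    y = (np.asarray(classes) == positive_class).astype(float)

    Xv = X.to_numpy(float)
    mask = np.isfinite(Xv)
    xm = np.nanmean(np.where(mask, Xv, np.nan), axis=0)
    ym = float(y.mean())
    Xc = np.where(mask, Xv - xm, np.nan)
    yc = y - ym
    ssx = _ss(Xc, mask)
    ssy = float((yc**2).sum())
    n_ortho = max(0, n_components - 1)

    w, t, p, q, To, Wo, Po, E = _fit_opls_core(np.where(mask, Xc, np.nan), mask, yc, n_ortho)
    r2x_pred = _ss(np.outer(t, p)) / ssx
    r2x_ortho = tuple(_ss(np.outer(t_o, p_o)) / ssx for t_o, p_o in zip(To, Po))
    r2y = 1.0 - float(((yc - t * q) ** 2).sum()) / ssy
    n_fitted = 1 + len(To)

    n = len(X)
    fold_of = _venetian_folds(n, cv_folds, cv_seed)
    press = 0.0
    yhat_all = np.empty(n)
    for f in np.unique(fold_of):
        tr, te = fold_of != f, fold_of == f
        xm_f = np.nanmean(np.where(mask[tr], Xv[tr], np.nan), axis=0)
        ym_f = float(y[tr].mean())
        wf, tf, pf, qf, Tof, Wof, Pof, _ = _fit_opls_core(
            np.where(mask[tr], Xv[tr] - xm_f, np.nan), mask[tr], y[tr] - ym_f, n_ortho
        )
        yh, _ = _opls_predict(Xv[te] - xm_f, wf, pf, qf, Wof, Pof)
        yh = yh + ym_f
        yhat_all[te] = yh
        press += float(((y[te] - yh) ** 2).sum())
    q2 = 1.0 - press / ssy

    model = LatentModel(
        kind="OPLSDA",
        scores=pd.DataFrame({"t1": t}, index=X.index),
        loadings=pd.DataFrame({"p1": p}, index=X.columns),
        weights=pd.DataFrame({"w1": w}, index=X.columns),
        y_loadings=np.array([[q]]),
        ortho_scores=pd.DataFrame(
            np.column_stack(To) if To else np.empty((n, 0)),
            index=X.index, columns=[f"to{i+1}" for i in range(len(To))],
        ),
        ortho_loadings=pd.DataFrame(
            np.column_stack(Po) if Po else np.empty((len(X.columns), 0)),
            index=X.columns, columns=[f"po{i+1}" for i in range(len(Po))],
        ),
        ortho_weights=pd.DataFrame(
            np.column_stack(Wo) if Wo else np.empty((len(X.columns), 0)),
            index=X.columns, columns=[f"wo{i+1}" for i in range(len(Wo))],
        ),
        r2x=float(r2x_pred + sum(r2x_ortho)),
        r2x_pred=float(r2x_pred),
        r2x_ortho=r2x_ortho,
        r2y=float(r2y),
        q2=float(q2),
        press=press,
        ssy=ssy,
        ssy_explained=np.array([q**2 * float(t @ t)]),
        n_components=n_fitted,
        sample_ids=X.index,
        feature_names=X.columns,
        classes=(positive_class, negative_class),
        y_mean=np.array([ym]),
        y_pred_cv=pd.DataFrame(
            {positive_class: yhat_all, negative_class: 1.0 - yhat_all}, index=X.index
        ),
        cv_folds=int(len(np.unique(fold_of))),
        cv_seed=cv_seed,
    )
    model.hotelling_t2 = hotelling_t2(model)
    model.cv_anova_p = cv_anova(model)
    model.vip = vip_scores(model)
    model.p_corr = p_corr(model, X)
    return model


# ---------------------------------------------------------------------------
# model diagnostics and variable selection
# ---------------------------------------------------------------------------


def cv_anova(model: LatentModel) -> float:
    """Cross-validated ANOVA significance of a PLS-family model.

    F compares the Y sum of squares explained under cross-validation
    (SSY - PRESS) against the cross-validated residual sum of squares
    (PRESS), with df_model = number of fitted components A and
    df_residual = N - 1 - A (recorded on the model for audit).  PRESS >=
    SSY (no predictive power) yields p = 1.
    """
    if model.press is None or model.ssy is None:
        raise ValueError("model has no cross-validated predictions")
    n, a = model.n_samples, model.n_components
    df1, df2 = a, max(1, n - 1 - a)
    model.cv_anova_df = (df1, df2)
    if model.press >= model.ssy:
        return 1.0
    F = ((model.ssy - model.press) / df1) / (model.press / df2)
    return float(stats.f.sf(F, df1, df2))


def vip_scores(model: LatentModel) -> pd.Series:
    """Variable importance on projection over the predictive components.

    ``VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a)`` with normalized
    weight vectors, so the mean squared VIP across the p variables is 1.
    """
    if model.weights is None:
        raise ValueError("VIP requires a PLS-family model")
    W = model.weights.to_numpy(float)
    ssy = np.asarray(model.ssy_explained, float)
    p = W.shape[0]
    vip = np.sqrt(p * (W**2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.feature_names, name="vip")


def p_corr(model: LatentModel, X: pd.DataFrame) -> pd.Series:
    """Loading on the correlation scale: Pearson r between each preprocessed
    variable and the (first) predictive score vector.  Constant variables
    get p(corr) = 0 and a warning."""
    t = model.scores.iloc[:, 0].to_numpy(float)
    Xv = X.loc[model.sample_ids].to_numpy(float)
    out = np.zeros(Xv.shape[1])
    tc = t - t.mean()
    for j in range(Xv.shape[1]):
        x = Xv[:, j]
        ok = np.isfinite(x)
        xc = x[ok] - x[ok].mean()
        tcc = tc[ok] - tc[ok].mean()
        denom = np.linalg.norm(xc) * np.linalg.norm(tcc)
        if denom == 0:
            log.warning("p_corr: constant variable %s set to 0", X.columns[j])
            out[j] = 0.0
        else:
            out[j] = float(xc @ tcc / denom)
    return pd.Series(out, index=X.columns, name="p_corr")


def select_variables(
    vip: pd.Series,
    p_corr: pd.Series,
    vip_cut: float = VIP_CUT,
    pcorr_cut: float = PCORR_CUT,
) -> pd.DataFrame:
    """Variables with VIP > cut AND |p(corr)| > cut, sorted by VIP descending."""
    joined = pd.DataFrame({"vip": vip, "p_corr": p_corr}).dropna()
    keep = joined[(joined["vip"] > vip_cut) & (joined["p_corr"].abs() > pcorr_cut)]
    return keep.sort_values("vip", ascending=False)


# ---------------------------------------------------------------------------
# classification list
# ---------------------------------------------------------------------------


@dataclass
class ClassificationList:
    """Per-sample, per-class YvarPS / YpredPS with threshold categories."""

    table: pd.DataFrame  # sample_id, class_label, y_var, y_pred, category, borderline_gt_06

    def counts(self, true_classes: pd.Series) -> pd.DataFrame:
        """BELONGS / BORDERLINE / NOT counts of each class among its own
        members (the Yvar = 1 samples of that class column)."""
        t = self.table
        own = t[t["y_var"] == 1.0]
        out = (
            own.groupby("class_label")["category"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["BELONGS", "BORDERLINE", "NOT"], fill_value=0)
        )
        flagged = own[own["borderline_gt_06"]].groupby("class_label").size()
        out["borderline_gt_06"] = flagged.reindex(out.index, fill_value=0)
        return out


def classification_list(
    model: LatentModel,
    true_classes: pd.Series | None = None,
    lower: float = NOT_THRESHOLD,
    upper: float = BELONGS_THRESHOLD,
    flag: float = BORDERLINE_FLAG,
) -> ClassificationList:
    """Categorize cross-validated YpredPS per class column.

    ``> upper`` belongs to the class, ``< lower`` does not, in between is
    borderline (sub-flagged when above ``flag``).
    """
    if model.y_pred_cv is None:
        raise ValueError("model has no per-sample class predictions")
    if true_classes is None:
        raise ValueError("true class labels are required to fill YvarPS")
    rows = []
    for cls in model.y_pred_cv.columns:
        for sid, yp in model.y_pred_cv[cls].items():
            cat = "BELONGS" if yp > upper else ("NOT" if yp < lower else "BORDERLINE")
            rows.append(
                {
                    "sample_id": sid,
                    "class_label": cls,
                    "y_var": float(true_classes.loc[sid] == cls),
                    "y_pred": float(yp),
                    "category": cat,
                    "borderline_gt_06": cat == "BORDERLINE" and yp > flag,
                }
            )
    return ClassificationList(pd.DataFrame(rows))


def classification_percentages(n_belongs: int, n_borderline: int, n_not: int) -> float:
    """Percent correctly classified among confidently called samples:
    ``100 * belongs / (belongs + not)``; borderline samples are excluded
    from numerator and denominator.  Undefined (NaN) when no sample was
    confidently called."""
    called = n_belongs + n_not
    if called == 0:
        log.warning("classification_percentages: no confidently called samples")
        return float("nan")
    return 100.0 * n_belongs / called


def classification_percentage_table(clist: ClassificationList, true_classes: pd.Series) -> pd.DataFrame:
    """Per-class counts plus the correctly-classified percentage."""
    counts = clist.counts(true_classes)
    counts["pct_correct"] = [
        classification_percentages(r["BELONGS"], r["BORDERLINE"], r["NOT"])
        for _, r in counts.iterrows()
    ]
    return counts
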