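"""AIC multimodel inference linking land-use composition to water chemistry.

Every first-order predictor subset (2^k models, intercept-only included)
is fitted as a Gaussian GLM (ordinary least squares); models are
compared through Akaike weights, predictor importance is the summed
weight of the models containing each predictor, and coefficients are
model-averaged. Hierarchical partitioning supplies each predictor's
independent contribution to the full-model R^2.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


class ModelSetError(ValueError):
    pass


@dataclass(frozen=True)
class ModelFit:
    """One fitted Gaussian GLM over a predictor subset.

    AIC counts the residual-variance parameter: AIC = -2 logLik + 2(p+1)
    with p regression coefficients (intercept included).
    """

    predictors: tuple[str, ...]
    params: pd.Series          # intercept + coefficients
    bse: pd.Series
    loglik: float
    aic: float
    aicc: float
    r2: float
    n: int


@dataclass(frozen=True)
class EnsembleResult:
    response: str
    models: list[ModelFit]
    weights: np.ndarray
    importance: pd.Series              # predictor -> [0,1]
    averaged_coef: pd.Series           # shrinkage model-averaged coefficients
    best_model: ModelFit
    full_model_r2: float
    independent: pd.Series             # hierarchical-partitioning independent R^2
    joint: pd.Series
    criterion: str


def enumerate_models(predictors) -> list[tuple[str, ...]]:
    """All 2^k predictor subsets, ordered by size then lexicographically."""
    preds = list(predictors)
    if not 1 <= len(preds) <= 20:
        raise ModelSetError("need between 1 and 20 predictors")
    if len(set(preds)) != len(preds):
        raise ModelSetError("duplicate predictor names")
    out: list[tuple[str, ...]] = []
    for size in range(len(preds) + 1):
        out.extend(sorted(itertools.combinations(sorted(preds), size)))
    return out


def fit_gaussian_glm(y, X: pd.DataFrame,
                     predictors: tuple[str, ...] | None = None) -> ModelFit:
    """OLS fit of y on a predictor subset (Gaussian likelihood)."""
    if predictors is None:
        predictors = tuple(X.columns)
    y = np.asarray(y, dtype=float)
    sub = X[list(predictors)] if predictors else X[[]]
    n = len(y)
    k = len(predictors)
    if n <= k + 2:
        raise ModelSetError(f"n={n} too small for {k} predictors")
    if not np.isfinite(y).all() or not np.isfinite(sub.to_numpy(dtype=float)).all():
        raise ModelSetError("non-finite values in response or predictors")
    design = sm.add_constant(sub.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ModelSetError(f"collinear predictors in subset {predictors}")
    res = sm.OLS(y, design).fit()
    p = k + 1                       # regression coefficients
    kk = p + 1                      # + residual variance
    aic = -2.0 * res.llf + 2.0 * kk
    aicc = aic + (2.0 * kk * (kk + 1)) / (n - kk - 1) if n - kk - 1 > 0 else math.inf
    return ModelFit(
        predictors=tuple(predictors),
        params=res.params,
        bse=res.bse,
        loglik=float(res.llf),
        aic=float(aic),
        aicc=float(aicc),
        r2=float(res.rsquared) if k else 0.0,
        n=n,
    )


def akaike_weights(aics) -> np.ndarray:
    """Normalized exp(-dAIC/2) model weights."""
    aics = np.asarray(aics, dtype=float)
    if aics.size < 2:
        raise ModelSetError("need at least two models")
    if not np.isfinite(aics).all():
        raise ModelSetError("non-finite AIC values")
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def importance_and_average(fits: list[ModelFit], weights,
                           response: str = "y",
                           averaging: str = "shrinkage",
                           criterion: str = "aic") -> EnsembleResult:
    """Predictor importance and model-averaged coefficients.

    importance(j) = sum of the weights of models containing j;
    shrinkage averaging substitutes 0 for a coefficient in models that
    omit it (``averaging='conditional'`` renormalizes over containing
    models instead).
    """
    weights = np.asarray(weights, dtype=float)
    if len(fits) != len(weights):
        raise ModelSetError("one weight per fitted model required")
    all_preds = sorted({p for f in fits for p in f.predictors})
    importance = pd.Series(0.0, index=all_preds)
    avg = pd.Series(0.0, index=["const"] + all_preds)
    cond_norm = pd.Series(0.0, index=all_preds)
    for f, w in zip(fits, weights):
        avg["const"] += w * f.params["const"]
        for p in f.predictors:
            importance[p] += w
            avg[p] += w * f.params[p]
            cond_norm[p] += w
    if averaging == "conditional":
        for p in all_preds:
            if cond_norm[p] > 0:
                avg[p] /= cond_norm[p]
    elif averaging != "shrinkage":
        raise ModelSetError(f"unknown averaging mode {averaging!r}")
    best = fits[int(np.argmin([f.aic for f in fits]))]
    full = max(fits, key=lambda f: len(f.predictors))
    return EnsembleResult(
        response=response, models=fits, weights=weights,
        importance=importance, averaged_coef=avg, best_model=best,
        full_model_r2=full.r2,
        independent=pd.Series(dtype=float), joint=pd.Series(dtype=float),
        criterion=criterion,
    )


def projection_r2(y, X: pd.DataFrame, predictors) -> float:
    """R^2 of the least-squares projection of y onto [1, X[predictors]].

    Uses the column space only (SVD with a rank tolerance), so it is
    well defined even for exactly collinear subsets such as a full
    compositional design.
    """
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    ss = float(yc @ yc)
    if ss == 0:
        raise ModelSetError("response has zero variance")
    if not predictors:
        return 0.0
    Xc = X[list(predictors)].to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > 1e-10 * s[0]).sum()) if s.size else 0
    if rank == 0:
        return 0.0
    u = u[:, :rank]
    fitted = u @ (u.T @ yc)
    return float(fitted @ fitted) / ss


def _subset_r2(y, X: pd.DataFrame, predictors) -> dict[tuple[str, ...], float]:
    return {sub: projection_r2(y, X, sub) for sub in enumerate_models(predictors)}


def independent_contribution(y, X: pd.DataFrame,
                             predictors=None) -> tuple[pd.Series, pd.Series]:
    """Hierarchical partitioning of the full-model R^2.

    A predictor's independent contribution is the average, over
    hierarchy levels h = 0..k-1, of the mean R^2 gain from adding it to
    the size-h subsets that omit it (equivalently its Shapley value over
    orderings). The joint contribution is its marginal R^2 minus the
    independent part; independents sum to the full-model R^2.
    """
    if predictors is None:
        predictors = list(X.columns)
    k = len(predictors)
    if k > 12:
        raise ModelSetError("hierarchical partitioning enumerates 2^k subsets; "
                            "restrict to <= 12 predictors")
    r2 = _subset_r2(y, X, predictors)
    indep = {}
    for j in sorted(predictors):
        level_means = []
        for h in range(k):
            gains = [
                r2[tuple(sorted(set(sub) | {j}))] - r2[sub]
                for sub in itertools.combinations(sorted(set(predictors) - {j}), h)
            ]
            level_means.append(float(np.mean(gains)))
        indep[j] = float(np.mean(level_means))
    independent = pd.Series(indep).sort_index()
    joint = pd.Series(
        {j: r2[(j,)] - independent[j] for j in sorted(predictors)}
    ).sort_index()
    return independent, joint


def model_ensemble(y, X: pd.DataFrame, predictors=None, response: str = "y",
                   criterion: str = "aic", averaging: str = "shrinkage",
                   log10_response: bool = False) -> EnsembleResult:
    """Full multimodel-inference pipeline for one chemistry response.

    Rows with a missing response or predictor are dropped (listwise).
    """
    if predictors is None:
        predictors = list(X.columns)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    ok = y.notna() & X[list(predictors)].notna().all(axis=1)
    if (~ok).any():
        logger.info("model_ensemble[%s]: dropping %d sample(s) with missing values",
                    response, int((~ok).sum()))
    y, X = y[ok], X.loc[ok]
    if log10_response:
        if (y <= 0).any():
            raise ModelSetError("log10 response transform requires positive values")
        y = np.log10(y)
    fits = []
    skipped = []
    for sub in enumerate_models(predictors):
        try:
            fits.append(fit_gaussian_glm(y, X, sub))
        except ModelSetError:
            # exactly aliased subset (e.g. a full compositional design):
            # its column space equals a smaller subset's, which is already
            # in the model set, so the model carries no extra information
            skipped.append(sub)
    if skipped:
        logger.info("model_ensemble[%s]: skipped %d aliased subset(s), e.g. %s",
                    response, len(skipped), skipped[0])
    crit = [f.aicc if criterion == "aicc" else f.aic for f in fits]
    weights = akaike_weights(crit)
    ens = importance_and_average(fits, weights, response=response,
                                 averaging=averaging, criterion=criterion)
    indep, joint = independent_contribution(y, X, predictors)
    return EnsembleResult(
        response=ens.response, models=ens.models, weights=ens.weights,
        importance=ens.importance, averaged_coef=ens.averaged_coef,
        best_model=ens.best_model,
        full_model_r2=projection_r2(y, X, tuple(predictors)),
        independent=indep, joint=joint, criterion=criterion,
    )
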