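"""Constrained ordination and variation partitioning.

Canonical correspondence analysis (CCA) is implemented through the
chi-square-standardized residual matrix: with P the relative-frequency
table, r and c its row/column sums, the analysis decomposes

    Q = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

after projecting its rows onto the row-weighted column space of the
constraints. Eigenvalues are squared singular values of the fitted
matrix; total inertia is ||Q||_F^2 (the Pearson chi-square statistic of
the table divided by its grand total). Redundancy-analysis (RDA) R^2
with the Ezekiel adjustment underpins three-way variation partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_RANK_TOL = 1e-10


class OrdinationError(ValueError):
    pass


@dataclass(frozen=True)
class OrdinationResult:
    """CCA/CA decomposition: inertias, axes and the three score sets.

    ``site_scores`` are linear-combination (LC) scores in standard
    coordinates; ``otu_scores`` are in scaling-2 principal coordinates
    (standard coordinates multiplied by the axis singular value, i.e. the
    square root of the eigenvalue); ``biplot_scores`` are row-weighted
    correlations of each constraint with the LC site scores.
    """

    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    site_scores: pd.DataFrame     # n x axes
    otu_scores: pd.DataFrame      # m x axes
    biplot_scores: pd.DataFrame   # q x axes (empty for unconstrained CA)
    axis_labels: tuple[str, ...]
    scaling: int = 2

    @property
    def residual_inertia(self) -> float:
        return self.total_inertia - self.constrained_inertia

    @property
    def proportion_explained(self) -> float:
        return self.constrained_inertia / self.total_inertia


@dataclass(frozen=True)
class PermutationAnovaResult:
    pseudo_f: float
    p_value: float
    n_perm: int
    term: str
    seed: int | None


@dataclass(frozen=True)
class VarpartResult:
    """Three-set variation partitioning (adjusted R^2 decomposition)."""

    subset_r2: dict[tuple[str, ...], float]   # 7 non-empty subsets
    unique: dict[str, float]                  # per-set unique fraction
    shared_pairwise: dict[tuple[str, str], float]
    shared_all: float
    residual: float
    set_names: tuple[str, str, str]


def _chi_square_matrix(Y: np.ndarray):
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise OrdinationError("Y must be a 2-D site-by-OTU matrix")
    if (Y < 0).any():
        raise OrdinationError("Y must be non-negative")
    rs, cs = Y.sum(axis=1), Y.sum(axis=0)
    if (rs == 0).any():
        raise OrdinationError("zero-sum row(s) in the community matrix")
    if (cs == 0).any():
        raise OrdinationError("zero-sum column(s) in the community matrix")
    P = Y / Y.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return Q, r, c


def _weighted_standardize(X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Zero weighted mean, unit weighted variance per column (weights r)."""
    mean = r @ X
    Xc = X - mean
    var = r @ (Xc ** 2)
    if (var <= 0).any():
        bad = np.flatnonzero(var <= 0)
        raise OrdinationError(f"constant constraint column(s) at index {bad.tolist()}")
    return Xc / np.sqrt(var)


def _project_weighted(Q: np.ndarray, X: np.ndarray, r: np.ndarray):
    """Fitted values of Q regressed on X with row weights r; returns (fitted, rank)."""
    Xs = _weighted_standardize(np.asarray(X, dtype=float), r)
    Xw = Xs * np.sqrt(r)[:, None]
    u, s, vt = np.linalg.svd(Xw, full_matrices=False)
    rank = int((s > _RANK_TOL * s[0]).sum()) if s.size else 0
    u = u[:, :rank]
    fitted = u @ (u.T @ Q)
    return fitted, rank


def cca(Y, X=None, otu_ids=None, site_ids=None,
        constraint_names=None, n_axes: int | None = None) -> OrdinationResult:
    """Canonical correspondence analysis of Y constrained by X.

    With ``X=None`` an unconstrained correspondence analysis is returned.
    Accepts DataFrames (ids taken from the index/columns) or arrays.
    """
    if isinstance(Y, pd.DataFrame):
        site_ids = site_ids or list(Y.index.astype(str))
        otu_ids = otu_ids or list(Y.columns.astype(str))
        Y = Y.to_numpy()
    if isinstance(X, pd.DataFrame):
        constraint_names = constraint_names or list(X.columns.astype(str))
        X = X.to_numpy()
    Q, r, c = _chi_square_matrix(Y)
    n, m = Q.shape
    total_inertia = float((Q ** 2).sum())
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != n:
            raise OrdinationError("X and Y must have the same number of sites")
        if X.shape[1] >= n:
            raise OrdinationError("need fewer constraints than sites")
    if X is None or X.shape[1] == 0:
        fitted, q_rank = Q, None
        max_axes = min(n - 1, m - 1)
        label = "CA"
    else:
        fitted, q_rank = _project_weighted(Q, X, r)
        if q_rank < X.shape[1]:
            raise OrdinationError(
                f"constraint matrix is rank deficient (rank {q_rank} < "
                f"{X.shape[1]} columns); drop collinear columns"
            )
        max_axes = min(q_rank, n - 1, m - 1)
        label = "CCA"
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s > _RANK_TOL * (s[0] if s.size else 1.0)
    k = min(int(keep.sum()), max_axes)
    if n_axes is not None:
        k = min(k, n_axes)
    U, s, Vt = U[:, :k], s[:k], Vt[:k, :]
    eig = s ** 2
    constrained = float((fitted ** 2).sum())
    labels = tuple(f"{label}{i + 1}" for i in range(k))
    site_std = U / np.sqrt(r)[:, None]               # LC scores, standard coords
    otu_prin = (Vt.T / np.sqrt(c)[:, None]) * s      # scaling-2 principal coords
    site_ids = list(site_ids) if site_ids is not None else [str(i) for i in range(n)]
    otu_ids = list(otu_ids) if otu_ids is not None else [str(j) for j in range(m)]
    site_df = pd.DataFrame(site_std, index=site_ids, columns=list(labels))
    otu_df = pd.DataFrame(otu_prin, index=otu_ids, columns=list(labels))
    if X is not None and X.shape[1] > 0:
        names = (list(constraint_names) if constraint_names is not None
                 else [f"X{j}" for j in range(X.shape[1])])
        bip = np.zeros((X.shape[1], k))
        for j in range(X.shape[1]):
            xj = X[:, j] - r @ X[:, j]
            sx = np.sqrt(r @ xj ** 2)
            for a in range(k):
                za = site_std[:, a] - r @ site_std[:, a]
                sz = np.sqrt(r @ za ** 2)
                bip[j, a] = (r * xj) @ za / (sx * sz)
        biplot = pd.DataFrame(bip, index=names, columns=list(labels))
    else:
        biplot = pd.DataFrame(index=[], columns=list(labels))
    return OrdinationResult(
        eigenvalues=eig,
        total_inertia=total_inertia,
        constrained_inertia=constrained if X is not None else total_inertia,
        site_scores=site_df,
        otu_scores=otu_df,
        biplot_scores=biplot,
        axis_labels=labels,
    )


def _constrained_inertia(Q: np.ndarray, X: np.ndarray, r: np.ndarray) -> float:
    fitted, _ = _project_weighted(Q, X, r)
    return float((fitted ** 2).sum())


def permutation_anova(Y, X, term: str = "model", n_perm: int = 999,
                      seed: int | None = None,
                      constraint_names=None) -> PermutationAnovaResult:
    """Permutation significance test of a CCA model or of one constraint.

    ``term='model'`` permutes whole rows of X and uses the pseudo-F of
    the full model. ``term='margin:<name>'`` tests a single constraint
    with the remaining columns as covariates: its marginal inertia is the
    full-model constrained inertia minus the reduced model's, and only
    the tested column is permuted.
    """
    if isinstance(X, pd.DataFrame):
        constraint_names = constraint_names or list(X.columns.astype(str))
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if constraint_names is None:
            constraint_names = [f"X{j}" for j in range(X.shape[1])]
    if isinstance(Y, pd.DataFrame):
        Y = Y.to_numpy()
    if n_perm < 99:
        raise OrdinationError("n_perm must be at least 99")
    Q, r, _ = _chi_square_matrix(Y)
    n, q = X.shape
    if n <= q + 1:
        raise OrdinationError("need more sites than constraints plus one")
    total = float((Q ** 2).sum())
    rng = np.random.default_rng(seed)

    full = _constrained_inertia(Q, X, r)
    resid = total - full

    if term == "model":
        f_obs = (full / q) / (resid / (n - 1 - q))
        hits = 0
        for _ in range(n_perm):
            Xp = X[rng.permutation(n)]
            fp = _constrained_inertia(Q, Xp, r)
            f_perm = (fp / q) / ((total - fp) / (n - 1 - q))
            if f_perm >= f_obs - 1e-12:
                hits += 1
    elif term.startswith("margin:"):
        name = term.split(":", 1)[1]
        if name not in constraint_names:
            raise OrdinationError(f"margin term {name!r} not among constraints "
                                  f"{list(constraint_names)}")
        j = list(constraint_names).index(name)
        others = np.delete(X, j, axis=1)
        reduced = _constrained_inertia(Q, others, r) if others.shape[1] else 0.0
        marg = full - reduced
        f_obs = (marg / 1) / (resid / (n - 1 - q))
        hits = 0
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = X[rng.permutation(n), j]
            fp_full = _constrained_inertia(Q, Xp, r)
            fp_marg = fp_full - reduced
            f_perm = fp_marg / ((total - fp_full) / (n - 1 - q))
            if f_perm >= f_obs - 1e-12:
                hits += 1
    else:
        raise OrdinationError(f"unknown term {term!r}; use 'model' or 'margin:<name>'")
    p = (hits + 1) / (n_perm + 1)
    return PermutationAnovaResult(pseudo_f=float(f_obs), p_value=float(p),
                                  n_perm=n_perm, term=term, seed=seed)


def rda_adjusted_r2(Y_transformed, X) -> float:
    """Ezekiel-adjusted redundancy-analysis R^2 of Y on X.

    R^2 is the fraction of the total (centered) sum of squares of Y
    captured by its least-squares projection on [1, X];
    R^2_adj = 1 - (1 - R^2)(n - 1)/(n - q - 1) and may be negative.
    """
    Y = np.asarray(Y_transformed, dtype=float)
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    q = int((s > _RANK_TOL * s[0]).sum()) if s.size else 0
    if q >= n - 1:
        raise OrdinationError("too many constraints for the sample size")
    ss_tot = float((Yc ** 2).sum())
    if ss_tot == 0:
        raise OrdinationError("Y has zero total variance")
    if q == 0:
        return 0.0
    u = u[:, :q]
    fitted = u @ (u.T @ Yc)
    r2 = float((fitted ** 2).sum()) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)


def varpart3(Y_transformed, X1, X2, X3,
             names: tuple[str, str, str] = ("X1", "X2", "X3")) -> VarpartResult:
    """Partition the variance of Y over three explanatory matrices.

    Adjusted R^2 is computed for each of the 7 non-empty subsets of
    {X1, X2, X3}; unique and shared fractions follow by solving the
    inclusion–exclusion system, and residual = 1 - R^2_adj(X1 X2 X3).
    """
    mats = [np.asarray(x.to_numpy() if isinstance(x, pd.DataFrame) else x,
                       dtype=float) for x in (X1, X2, X3)]
    mats = [m[:, None] if m.ndim == 1 else m for m in mats]
    subsets = [(0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]
    r2 = {}
    for sub in subsets:
        Xcat = np.hstack([mats[i] for i in sub])
        r2[sub] = rda_adjusted_r2(Y_transformed, Xcat)
    # fractions: u1,u2,u3 (unique), s12,s13,s23 (pairwise-only), g (three-way)
    frac_parts = [
        frozenset({0}), frozenset({1}), frozenset({2}),
        frozenset({0, 1}), frozenset({0, 2}), frozenset({1, 2}),
        frozenset({0, 1, 2}),
    ]
    A = np.zeros((7, 7))
    b = np.zeros(7)
    for i, sub in enumerate(subsets):
        covered = set(sub)
        for jf, part in enumerate(frac_parts):
            # a fraction is explained by subset `sub` iff any of its member
            # sets is in the subset
            if part & covered:
                A[i, jf] = 1.0
        b[i] = r2[sub]
    sol = np.linalg.solve(A, b)
    key = lambda sub: tuple(names[i] for i in sub)
    return VarpartResult(
        subset_r2={key(sub): float(r2[sub]) for sub in subsets},
        unique={names[i]: float(sol[i]) for i in range(3)},
        shared_pairwise={
            (names[0], names[1]): float(sol[3]),
            (names[0], names[2]): float(sol[4]),
            (names[1], names[2]): float(sol[5]),
        },
        shared_all=float(sol[6]),
        residual=float(1.0 - r2[(0, 1, 2)]),
        set_names=names,
    )
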