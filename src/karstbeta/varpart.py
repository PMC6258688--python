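"""Variation partitioning of community dissimilarity via distance-based RDA.

The response is the principal-coordinate representation of a square-root
transformed dissimilarity matrix (square-rooted Bray-Curtis matrices are
Euclidean-embeddable, so the PCoA has no meaningful negative eigenvalues).
Explained variation of a predictor set X is the redundancy statistic
R^2 = ||P_X Y||^2_F / ||Y||^2_F, adjusted with Ezekiel's formula
adjR^2 = 1 - (1 - R^2)(n - 1)/(n - m - 1).  With environmental predictors E
and spatial (dbMEM) predictors S, the classic four fractions are

    a = adjR2(E+S) - adjR2(S)     (pure habitat)
    b = adjR2(E) + adjR2(S) - adjR2(E+S)   (spatially structured habitat)
    c = adjR2(E+S) - adjR2(E)     (pure space)
    d = 1 - adjR2(E+S)            (undetermined)

which sum to one by construction.  Predictors are chosen beforehand by
forward selection with a residual-permutation test and Blanchet's double
stopping rule (candidate p-value above alpha, or cumulative adjR^2
exceeding the global model's adjR^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distmat import DistMatrix
from .errors import ComputationError, ValidationError

EIGEN_TOL = 1e-9  # PCoA axes with lambda <= EIGEN_TOL * lambda_max are numerical zeros


def sqrt_transform(d: DistMatrix) -> DistMatrix:
    """Element-wise square root of a dissimilarity matrix with entries in [0, 1]."""
    vals = d.condensed
    finite = vals[np.isfinite(vals)]
    if finite.size and finite.min() < 0:
        raise ValidationError("negative dissimilarity entry")
    return DistMatrix(d.ids, np.sqrt(vals), metric=f"sqrt({d.metric})")


@dataclass
class ResponseMatrix:
    """Principal coordinates of a dissimilarity matrix, scaled to sqrt(lambda)."""

    ids: list
    coords: np.ndarray  # (n sites, k axes)
    eigenvalues: np.ndarray

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def pcoa_response(d: DistMatrix, negative_tol: float = 1e-8) -> ResponseMatrix:
    """PCoA of a distance matrix, retaining positive axes.

    Warns if eigenvalues below ``-negative_tol * lambda_max`` occur (the
    input was not Euclidean-embeddable); such axes are discarded.
    """
    sq = d.square()
    if not np.all(np.isfinite(sq)):
        raise ValidationError("distance matrix contains undefined entries")
    a = -0.5 * sq**2
    row = a.mean(axis=1, keepdims=True)
    g = a - row - row.T + a.mean()
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam_max = evals[0]
    if lam_max <= 0:
        raise ComputationError("degenerate response: all PCoA eigenvalues ~ 0")
    if evals[-1] < -negative_tol * lam_max:
        warnings.warn(
            f"negative PCoA eigenvalue {evals[-1]:.3e} (non-Euclidean input); discarded",
            stacklevel=2,
        )
    keep = evals > EIGEN_TOL * lam_max
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    return ResponseMatrix(list(d.ids), coords, evals[keep])


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if X is None:
        return np.empty((0, 0)), []
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, list(range(X.shape[1]))


def _r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Redundancy R^2 of centred response Y on predictors X (intercept implied).

    Uses the least-squares projection onto the column space of the centred
    predictors, which stays correct for rank-deficient predictor sets.
    """
    if X.size == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    fitted = Xc @ coef
    tot = (Y**2).sum()
    if tot == 0:
        raise ComputationError("response has zero variance")
    return float((fitted**2).sum() / tot)


def ezekiel_adjust(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjusted R^2 for n sites and m predictors."""
    if m == 0:
        return 0.0
    if n - m - 1 <= 0:
        raise ComputationError(f"over-parameterised model: n={n}, m={m}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


@dataclass
class SelectionResult:
    """Forward-selection outcome: chosen columns with their step statistics."""

    selected: list
    added_r2: list
    p_values: list
    cumulative_adj_r2: list
    global_adj_r2: float
    stop_reason: str

    def matrix(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected]


def forward_select(
    Y: ResponseMatrix | np.ndarray,
    X: pd.DataFrame,
    n_perm: int = 9999,
    alpha: float = 0.05,
    seed: int | None = None,
    max_select: int | None = None,
) -> SelectionResult:
    """Forward selection of predictor columns for a multivariate response.

    Follows the double-stopping forward-selection protocol: the global
    (all-candidate) model is permutation-tested first and nothing is selected
    unless it is significant (this is what keeps the null selection rate at
    the alpha level); then at each step the candidate adding the most R^2
    enters if its residual-permutation p-value is <= alpha and the cumulative
    adjusted R^2 has not exceeded the global model's adjusted R^2.
    Candidates collinear with the current model are skipped.  A saturated
    global model (R^2 ~ 1 because there are as many candidates as sites)
    carries no information, so the global gate is bypassed with a warning.
    """
    Ymat = Y.coords if isinstance(Y, ResponseMatrix) else np.asarray(Y, dtype=float)
    Ymat = Ymat - Ymat.mean(axis=0)
    n = Ymat.shape[0]
    Xmat, names = _as_matrix(X)
    if Xmat.shape[0] != n:
        raise ValidationError("response and predictors have different site counts")
    if Xmat.shape[1] >= n - 1:
        warnings.warn(
            f"{Xmat.shape[1]} candidates for {n} sites: global model is saturated",
            stacklevel=2,
        )
    tot = (Ymat**2).sum()
    rng = np.random.default_rng(seed)

    m_global = min(Xmat.shape[1], n - 2)
    global_r2 = _r2(Ymat, Xmat)
    global_adj = ezekiel_adjust(global_r2, n, m_global)

    if global_r2 < 1.0 - 1e-10 and Xmat.shape[1] > 0:
        Xc = Xmat - Xmat.mean(axis=0)
        U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
        Qg = U[:, sv > sv[0] * 1e-10]  # orthonormal basis of the column space
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            count += ((Qg.T @ Ymat[perm]) ** 2).sum() / tot >= global_r2 - 1e-12
        p_global = (count + 1) / (n_perm + 1)
        if p_global > alpha:
            warnings.warn(
                f"global model not significant (p={p_global:.4g}); nothing selected",
                stacklevel=2,
            )
            return SelectionResult([], [], [], [], float(global_adj), "global test failed")
    elif Xmat.shape[1] >= n - 1:
        warnings.warn("saturated global model: global significance gate bypassed", stacklevel=2)

    selected: list[int] = []
    added_r2: list[float] = []
    p_values: list[float] = []
    cum_adj: list[float] = []
    Q = np.empty((n, 0))
    Yres = Ymat.copy()
    stop = "exhausted candidates"
    max_m = n - 2  # keep the Ezekiel denominator positive
    if max_select is not None:
        max_m = min(max_m, max_select)
    while len(selected) < Xmat.shape[1]:
        if len(selected) >= max_m:
            stop = f"reached n - 2 = {max_m} predictors"
            break
        best_j, best_ss, best_u = -1, 0.0, None
        for j in range(Xmat.shape[1]):
            if j in selected:
                continue
            x = Xmat[:, j] - Xmat[:, j].mean()
            r = x - Q @ (Q.T @ x)
            nrm = np.linalg.norm(r)
            if nrm**2 <= 1e-12 * max((x**2).sum(), 1e-300):
                continue  # collinear with current model
            u = r / nrm
            ss = ((u @ Yres) ** 2).sum()
            if ss > best_ss:
                best_j, best_ss, best_u = j, ss, u
        if best_j < 0:
            stop = "no non-collinear candidate left"
            break
        if best_ss <= 1e-12 * tot:
            stop = "no candidate adds variance"
            break
        # residual-permutation test of the best candidate
        count = 0
        obs = best_ss
        for _ in range(n_perm):
            perm = rng.permutation(n)
            count += ((best_u @ Yres[perm]) ** 2).sum() >= obs - 1e-15
        p = (count + 1) / (n_perm + 1)
        if p > alpha:
            stop = f"candidate p={p:.4g} > alpha={alpha}"
            break
        new_adj = ezekiel_adjust(
            _r2(Ymat, Xmat[:, selected + [best_j]]), n, len(selected) + 1
        )
        if new_adj > global_adj + 1e-10:
            stop = "cumulative adjR2 exceeded global model adjR2"
            break
        selected.append(best_j)
        added_r2.append(best_ss / tot)
        p_values.append(float(p))
        cum_adj.append(new_adj)
        Q = np.hstack([Q, best_u[:, None]])
        Yres = Yres - best_u[:, None] * (best_u @ Yres)[None, :]
    else:
        stop = "all candidates selected"
    if not selected:
        warnings.warn("forward selection kept no predictor", stacklevel=2)
    return SelectionResult(
        selected=[names[j] for j in selected],
        added_r2=added_r2,
        p_values=p_values,
        cumulative_adj_r2=cum_adj,
        global_adj_r2=float(global_adj),
        stop_reason=stop,
    )


@dataclass(frozen=True)
class VarpartFractions:
    """Adjusted-R^2 fractions a/b/c/d and the raw model R^2s behind them."""

    a: float
    b: float
    c: float
    d: float
    r2_env: float
    r2_space: float
    r2_both: float
    n: int
    m_env: int
    m_space: int

    def __post_init__(self) -> None:
        total = self.a + self.b + self.c + self.d
        assert abs(total - 1.0) < 1e-9, "fractions must sum to 1"


def varpart(Y: ResponseMatrix | np.ndarray, E, S) -> VarpartFractions:
    """Partition response variation between predictor sets E (habitat) and S (space)."""
    Ymat = Y.coords if isinstance(Y, ResponseMatrix) else np.asarray(Y, dtype=float)
    Ymat = Ymat - Ymat.mean(axis=0)
    n = Ymat.shape[0]
    Emat, _ = _as_matrix(E)
    Smat, _ = _as_matrix(S)
    for X, label in ((Emat, "E"), (Smat, "S")):
        if X.size and X.shape[0] != n:
            raise ValidationError(f"predictor set {label} has wrong site count")
    m_e = Emat.shape[1] if Emat.size else 0
    m_s = Smat.shape[1] if Smat.size else 0

    r2_e = _r2(Ymat, Emat) if m_e else 0.0
    r2_s = _r2(Ymat, Smat) if m_s else 0.0
    if m_e and m_s:
        both = np.hstack([Emat, Smat])
    elif m_e:
        both = Emat
    elif m_s:
        both = Smat
    else:
        both = np.empty((n, 0))
    r2_es = _r2(Ymat, both) if both.size else 0.0

    adj_e = ezekiel_adjust(r2_e, n, m_e)
    adj_s = ezekiel_adjust(r2_s, n, m_s)
    adj_es = ezekiel_adjust(r2_es, n, m_e + m_s)

    a = adj_es - adj_s
    c = adj_es - adj_e
    b = adj_e + adj_s - adj_es
    d = 1.0 - adj_es
    if min(a, b, c, d) < -0.1:
        warnings.warn(
            f"strongly negative fraction (a={a:.3f}, b={b:.3f}, c={c:.3f}); "
            "check predictor selection",
            stacklevel=2,
        )
    return VarpartFractions(a, b, c, d, r2_e, r2_s, r2_es, n, m_e, m_s)
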