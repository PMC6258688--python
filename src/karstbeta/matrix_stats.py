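"""Mantel permutation tests (Spearman) and the grain-trend Spearman test.

The Mantel statistic is the Spearman correlation between the condensed
upper triangles of two distance matrices over the same sites; the null
distribution is built by simultaneously permuting rows and columns of the
second matrix.  Because relabelling sites only permutes the multiset of
off-diagonal entries, average ranks are permutation-equivariant: both
condensed vectors are ranked once and each permutation just re-gathers the
rank matrix, making 9,999 permutations cheap even for hundreds of sites.

p-values: for random permutations, p = (#{r_perm >= r_obs} + 1)/(n_perm + 1)
(one-sided "greater"; two-sided compares |r|), never below 1/(n_perm + 1).
With ``exhaustive=True`` all n! relabellings are enumerated (identity
included) and p is the exact tail fraction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr

from .distmat import DistMatrix
from .errors import ComputationError, ValidationError

_ALTERNATIVES = ("greater", "two-sided")


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    alternative: str
    seed: int | None = None
    method: str = "spearman"


def _condensed_ranks(d: DistMatrix) -> np.ndarray:
    return rankdata(d.condensed)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ComputationError("constant distance matrix: correlation undefined")
    return float((xc @ yc) / denom)


def mantel(
    dx: DistMatrix,
    dy: DistMatrix,
    n_perm: int = 9999,
    alternative: str = "greater",
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test between two distance matrices over identical site sets."""
    if alternative not in _ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {_ALTERNATIVES}")
    if not dx.same_sites(dy):
        raise ValidationError("distance matrices are over different site sets/orders")
    n = dx.n
    if n < 3:
        raise ValidationError("need at least 3 sites for a Mantel test")

    rx = _condensed_ranks(dx)
    ry = _condensed_ranks(dy)
    r_obs = _pearson(rx, ry)

    ry_sq = squareform(ry, checks=False)
    iu = np.triu_indices(n, k=1)

    def r_for(perm: np.ndarray) -> float:
        permuted = ry_sq[np.ix_(perm, perm)][iu]
        return _pearson(rx, permuted)

    if exhaustive:
        if n > 8:
            raise ComputationError("exhaustive enumeration limited to n <= 8 sites")
        stats = np.array([r_for(np.array(p)) for p in itertools.permutations(range(n))])
        n_perm = len(stats)
        if alternative == "greater":
            p = float(np.mean(stats >= r_obs - 1e-12))
        else:
            p = float(np.mean(np.abs(stats) >= abs(r_obs) - 1e-12))
        return MantelResult(r_obs, p, n_perm, alternative, seed)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        stat = r_for(rng.permutation(n))
        if alternative == "greater":
            count += stat >= r_obs - 1e-12
        else:
            count += abs(stat) >= abs(r_obs) - 1e-12
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r_obs, float(p), n_perm, alternative, seed)


@dataclass(frozen=True)
class TrendResult:
    grains: tuple
    means: tuple
    rho: float
    p: float
    exact: bool


def _exact_spearman_p(rho_obs: float, n: int) -> float:
    """Exact two-sided p from the full n! permutation distribution (no ties)."""
    ranks = np.arange(1, n + 1, dtype=float)
    base = ranks - ranks.mean()
    denom = base @ base
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = (base @ base[list(perm)]) / denom
        count += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


def grain_trend(grains, means) -> TrendResult:
    """Spearman correlation between grain size and a per-grain component mean.

    For n <= 9 grains without ties the two-sided p-value is exact (full
    permutation distribution of rho); otherwise scipy's large-sample
    approximation with average ranks is used.
    """
    grains = np.asarray(grains, dtype=float)
    means = np.asarray(means, dtype=float)
    if grains.ndim != 1 or grains.shape != means.shape or len(grains) < 3:
        raise ValidationError("need >= 3 (grain, mean) pairs of equal length")
    if len(np.unique(grains)) != len(grains):
        raise ValidationError("tied grain sizes")
    if np.allclose(means, means[0]):
        raise ComputationError("constant means: Spearman rho undefined")

    rho, p_approx = spearmanr(grains, means)
    no_ties = len(np.unique(means)) == len(means)
    if len(grains) <= 9 and no_ties:
        return TrendResult(
            tuple(grains), tuple(means), float(rho), _exact_spearman_p(rho, len(grains)), True
        )
    return TrendResult(tuple(grains), tuple(means), float(rho), float(p_approx), False)
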