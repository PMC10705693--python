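"""Independent reference implementations used to check the package.

Everything here is written directly from first principles (definitional
double loops, literal subset enumeration, dense eigensolvers) and must not
import from :mod:`stemcortex`, so agreement between the two codebases is
meaningful evidence of correctness.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# -- partitions ------------------------------------------------------------

def all_partitions(n: int):
    """Every set partition of ``range(n)`` as a label vector, via restricted
    growth strings (Bell-number enumeration)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_used: int):
        if i == n:
            yield labels.copy()
            return
        for v in range(max_used + 2):
            labels[i] = v
            yield from rec(i + 1, max(max_used, v))

    yield from rec(1, 0) if n > 1 else iter([labels.copy()])


def modularity_naive(W: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Signed modularity, definitional double loop over ordered pairs.

    Positive and negative parts are scored separately: within-community
    positive weight against a configuration null scaled by gamma, minus the
    corresponding negative-weight term, with the positive term normalized by
    the total positive weight and the negative term by the total weight.
    """
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    n = len(W)
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    vp = Wp.sum()   # ordered-pair sum
    vn = Wn.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            if vp > 0:
                q += (Wp[i, j] - gamma * Wp[i].sum() * Wp[:, j].sum() / vp) / vp
            if vn > 0:
                q -= (Wn[i, j] - gamma * Wn[i].sum() * Wn[:, j].sum() / vn) / (vp + vn)
    return q


def exhaustive_best_q(W: np.ndarray, gamma: float) -> float:
    """Maximum modularity over every partition (feasible for n <= 8)."""
    best = -np.inf
    for labels in all_partitions(len(W)):
        best = max(best, modularity_naive(W, labels, gamma))
    return best


# -- regression / dominance ------------------------------------------------

def r2_adjusted_naive(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted R^2 of OLS with intercept, via lstsq on the raw design."""
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def dominance_naive_p3(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Dominance (Shapley over adjusted R^2) for exactly 3 predictors,
    with every submodel written out literally."""
    assert X.shape[1] == 3
    r = {s: r2_adjusted_naive(y, X[:, list(s)])
         for k in (1, 2, 3) for s in combinations(range(3), k)}
    out = np.empty(3)
    for i in range(3):
        j, k = [v for v in range(3) if v != i]
        size0 = r[(i,)]                                   # adding i to {}
        size1 = np.mean([r[tuple(sorted((i, j)))] - r[(j,)],
                         r[tuple(sorted((i, k)))] - r[(k,)]])
        size2 = r[(0, 1, 2)] - r[tuple(sorted((j, k)))]
        out[i] = np.mean([size0, size1, size2])
    return out


# -- diffusion embedding ---------------------------------------------------

def diffusion_embedding_naive(A: np.ndarray, n_components: int,
                              alpha: float = 0.5):
    """Diffusion-map coordinates via a dense nonsymmetric eigensolver.

    Anisotropic normalization with exponent alpha, then the row-stochastic
    Markov matrix, then `scipy.linalg.eig` on the nonsymmetric operator
    directly (no symmetric conjugation). Components are unit-normalized,
    centered, and scaled by lambda / (1 - lambda); each component's sign is
    arbitrary, so comparisons must be up to sign.
    """
    from scipy.linalg import eig

    d = A.sum(axis=1)
    if alpha != 0:
        A = A / np.outer(d ** alpha, d ** alpha)
        d = A.sum(axis=1)
    M = A / d[:, None]
    w, v = eig(M)
    w = np.real(w)
    v = np.real(v)
    order = np.argsort(-w)
    w, v = w[order], v[:, order]
    v = v / np.linalg.norm(v, axis=0)
    lam = np.clip(w[1:n_components + 1], 0.0, 1.0)
    comps = v[:, 1:n_components + 1]
    comps = comps - comps.mean(axis=0)
    coords = comps * (lam / np.clip(1.0 - lam, 1e-12, None))
    return coords, lam


# -- misc ------------------------------------------------------------------

def pearson_naive(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def smooth_sphere_map(coords: np.ndarray, rng: np.random.Generator,
                      n_bumps: int = 20, kappa: float = 10.0) -> np.ndarray:
    """A spatially autocorrelated map: a random mixture of von Mises-Fisher
    bumps on unit-sphere coordinates."""
    v = np.zeros(len(coords))
    for _ in range(n_bumps):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        v += rng.standard_normal() * np.exp(kappa * (coords @ u - 1.0))
    return (v - v.mean()) / v.std()
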