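"""Diffusion map embedding of similarity matrices.

The first non-trivial component of the embedding ("principal gradient")
orders regions so that nearby scores mean similar connectivity profiles.
The affinity is built by row-wise sparsification of the similarity matrix
followed by a normalized-angle (cosine-similarity) kernel; the embedding
uses anisotropic diffusion normalization (exponent ``alpha``, default 0.5)
and a dense symmetric eigendecomposition -- deterministic, no randomized
approximation, appropriate for the few-hundred-region matrices here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ParameterError, ShapeError


@dataclass
class GradientSet:
    """Embedding coordinates (region x component) and their eigenvalues."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    affinity_spec: dict

    @property
    def first(self) -> np.ndarray:
        return self.coordinates[:, 0]


def build_affinity(S: np.ndarray, sparsity: float = 0.9) -> np.ndarray:
    """Row-sparsified normalized-angle affinity of a similarity matrix.

    Per row the top ``(1 - sparsity)`` fraction of entries is retained
    (ties included by threshold value), the rest zeroed; the matrix is then
    symmetrized by averaging and passed through the normalized-angle kernel
    ``1 - arccos(cos(x_i, x_j)) / pi``, yielding entries in [0, 1].
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ShapeError("similarity matrix must be square")
    if not 0 <= sparsity < 1:
        raise ParameterError("sparsity must lie in [0, 1)")
    n = S.shape[0]
    keep = max(1, int(np.ceil((1 - sparsity) * n)))
    sparse = np.zeros_like(S)
    for i in range(n):
        row = S[i]
        thresh = np.sort(row)[::-1][keep - 1]
        mask = row >= thresh
        sparse[i, mask] = row[mask]
    sparse = (sparse + sparse.T) / 2.0
    norms = np.linalg.norm(sparse, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise ParameterError(
            f"rows all-zero after sparsification (regions {dead.tolist()})")
    cos = sparse @ sparse.T / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    return aff


def diffusion_embed(affinity: np.ndarray, n_components: int = 5,
                    alpha: float = 0.5, seed: int | None = None) -> GradientSet:
    """Diffusion map embedding at diffusion time 0.

    Steps: anisotropic normalization ``W / (d_i^alpha d_j^alpha)``;
    symmetric conjugation of the row-stochastic operator; dense
    eigendecomposition; the trivial constant component is dropped and each
    remaining component is scaled by ``lambda / (1 - lambda)`` (the
    multi-scale, diffusion-time-0 weighting). ``seed`` is accepted for
    interface uniformity; the dense solver is deterministic.
    """
    W = np.asarray(affinity, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ShapeError("affinity must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ShapeError("affinity must be symmetric")
    if (W < -1e-12).any():
        raise ParameterError("affinity must be nonnegative")
    n = W.shape[0]
    _check_connected(W)
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ParameterError("affinity has an isolated region")
    if alpha != 0:
        W = W / np.outer(d ** alpha, d ** alpha)
        d = W.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(d)
    M = W * np.outer(d_isqrt, d_isqrt)
    M = (M + M.T) / 2.0
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the Markov operator
    psi = evecs * d_isqrt[:, None]
    # drop the trivial stationary component
    psi = psi / np.linalg.norm(psi, axis=0)
    # negative spectrum is uninformative for diffusion distance; clip to [0, 1]
    lambdas = np.clip(evals[1:n_components + 1], 0.0, 1.0)
    comps = psi[:, 1:n_components + 1]
    comps = comps - comps.mean(axis=0)
    scale = lambdas / np.clip(1.0 - lambdas, 1e-12, None)
    coords = comps * scale
    return GradientSet(coords, lambdas,
                       {"alpha": alpha, "n_components": n_components})


def _check_connected(W: np.ndarray) -> None:
    n = W.shape[0]
    adj = W > 0
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        nxt = np.flatnonzero(adj[i] & ~seen)
        seen[nxt] = True
        stack.extend(nxt.tolist())
    if not seen.all():
        raise ParameterError(
            "affinity graph is disconnected; embedding undefined across components")


def align_sign(g: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip an eigenvector's (arbitrary) sign iff it anticorrelates with a
    reference map; orthogonal references leave it unchanged."""
    g = np.asarray(g, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if g.shape != reference.shape:
        raise ShapeError("gradient and reference must have equal length")
    if np.ptp(g) == 0 or np.ptp(reference) == 0:
        warnings.warn("zero-variance input; sign left unchanged", stacklevel=2)
        return g
    r = np.corrcoef(g, reference)[0, 1]
    return -g if r < 0 else g


def compare_gradients(g1: np.ndarray, g2: np.ndarray, null=None,
                      seed: int = 0) -> tuple[float, float]:
    """Pearson correlation of two cortical gradients with a spin p-value.

    ``null`` is a :class:`~stemcortex.nulls.SpinNull`; when omitted only the
    correlation is returned (p = NaN).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ShapeError("gradients must share the cortical scheme")
    r = float(stats.pearsonr(g1, g2)[0])
    if null is None:
        return r, np.nan
    from .nulls import spin_pvalue
    _, p = spin_pvalue(g1, g2, null)
    return r, p
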