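"""Signed community detection on similarity matrices.

Quality function (signed, asymmetric weighting of the negative term):

    Q(gamma) = (1/v+) sum_ij [w+_ij - gamma p+_ij] delta(s_i, s_j)
             - (1/(v+ + v-)) sum_ij [w-_ij - gamma p-_ij] delta(s_i, s_j)

where ``w+``/``w-`` are the positive and negative parts of the (zero-
diagonal) matrix, ``s±_i`` are node strengths, ``v± = sum_ij w±_ij`` are
the total weights over ordered pairs, and ``p±_ij = s±_i s±_j / v±`` is the
configuration-model expectation. At gamma = 1 on a nonnegative matrix this
reduces to Newman-Girvan modularity. Positive correlations are thus
concentrated within communities while negative correlations are pushed
between them; the resolution ``gamma`` scales the null term, with larger
values favouring finer partitions.

Optimization uses the Louvain heuristic (greedy node moves + graph
aggregation), repeated from random node orders. Partition stability is
scored by the z-score of the pair-counting Rand index under the
hypergeometric permutation null, and a consensus partition is obtained by
re-clustering the ensemble agreement matrix (minus its analytic
permutation-null expectation) until every run returns the same partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import DegreeMap, FunctionalConnectome
from .exceptions import ConvergenceError, ParameterError, ShapeError


@dataclass
class Partition:
    """Community labels (canonical: contiguous ints in first-occurrence
    order) with the resolution and quality at which they were found."""

    labels: np.ndarray
    gamma: float
    quality: float

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class PartitionEnsemble:
    partitions: list[Partition]
    gamma: float
    seeds: list[int] = field(default_factory=list)


@dataclass
class ConsensusResult:
    consensus: Partition
    zrand_mean: float
    zrand_var: float
    n_communities: int
    gamma: float


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities as contiguous integers in first-occurrence order."""
    _, first, inverse = np.unique(labels, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first))
    return order[inverse].astype(labels.dtype)


def _split(W: np.ndarray):
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ShapeError("similarity matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ShapeError("similarity matrix must be symmetric")
    W = (W + W.T) / 2.0
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    Wp = np.clip(W, 0.0, None)
    Wn = np.clip(-W, 0.0, None)
    if Wp.sum() == 0 and Wn.sum() == 0:
        raise ParameterError("all-zero matrix: modularity undefined")
    return Wp, Wn


def modularity_q(W: np.ndarray, labels, gamma: float = 1.0) -> float:
    """Evaluate the signed quality function for one partition."""
    Wp, Wn = _split(W)
    labels = _canonical(np.asarray(labels, dtype=int))
    n_comm = labels.max() + 1
    H = np.zeros((len(labels), n_comm))
    H[np.arange(len(labels)), labels] = 1.0
    q = 0.0
    for Wx, sign in ((Wp, +1), (Wn, -1)):
        v = Wx.sum()
        if v == 0:
            continue
        norm = Wp.sum() if sign > 0 else Wp.sum() + Wn.sum()
        s = Wx.sum(axis=1)
        e_within = float(np.einsum("ic,ij,jc->", H, Wx, H))
        s_comm = H.T @ s
        null = float((s_comm ** 2).sum()) / v
        q += sign * (e_within - gamma * null) / norm
    return q


def _local_move(Wp, Wn, sp, sn, vp, vn, labels, gamma, rng):
    """One Louvain level: greedy node moves until no gain.

    Matrices may carry self-loops (from aggregation); self-loop weight
    moves with the node so it cancels in move gains. One empty-community
    slot is always offered so a node can split off into a fresh singleton.
    """
    n = Wp.shape[0]
    n_comm = int(labels.max()) + 1
    Sp = np.bincount(labels, weights=sp, minlength=n_comm + 1)
    Sn = np.bincount(labels, weights=sn, minlength=n_comm + 1)
    denom_n = vp + vn
    improved_any = False
    while True:
        moved = False
        for i in rng.permutation(n):
            a = labels[i]
            width = Sp.size
            kp = np.bincount(labels, weights=Wp[i], minlength=width)
            kn = np.bincount(labels, weights=Wn[i], minlength=width)
            kp[a] -= Wp[i, i]
            kn[a] -= Wn[i, i]
            Sp_a = Sp[a] - sp[i]
            Sn_a = Sn[a] - sn[i]
            gain = np.zeros(width)
            if vp > 0:
                gain += (2.0 / vp) * ((kp - kp[a])
                                      - gamma * sp[i] * (Sp - Sp_a) / vp)
            if vn > 0:
                gain -= (2.0 / denom_n) * ((kn - kn[a])
                                           - gamma * sn[i] * (Sn - Sn_a) / vn)
            gain[a] = 0.0
            b = int(np.argmax(gain))
            if gain[b] > 1e-12 and b != a:
                labels[i] = b
                Sp[a] -= sp[i]; Sn[a] -= sn[i]
                Sp[b] += sp[i]; Sn[b] += sn[i]
                moved = True
                improved_any = True
                if b == width - 1:  # occupied the empty slot; open a new one
                    Sp = np.append(Sp, 0.0)
                    Sn = np.append(Sn, 0.0)
        if not moved:
            break
    return labels, improved_any


def _one_pass(Wp0, Wn0, vp, vn, labels, gamma, rng):
    """Multi-level Louvain pass (local moves + aggregation) starting from
    an initial partition of the original graph."""
    labels = _canonical(np.asarray(labels, dtype=int))
    # node_to_super maps original nodes to rows of the current (possibly
    # aggregated) graph; the first local move is initialized from `labels`,
    # subsequent levels start from singleton super-nodes.
    node_to_super = np.arange(Wp0.shape[0])
    Wp, Wn = Wp0, Wn0
    start = labels
    improved_total = False
    first = True
    while True:
        sp, sn = Wp.sum(axis=1), Wn.sum(axis=1)
        new_labels, improved = _local_move(Wp, Wn, sp, sn, vp, vn,
                                           start.copy(), gamma, rng)
        new_labels = _canonical(new_labels)
        node_to_super = new_labels[node_to_super]
        improved_total |= improved
        n_comm = int(new_labels.max()) + 1
        if n_comm == Wp.shape[0] and not first:
            break
        if not improved and not first:
            break
        if n_comm == Wp.shape[0] and first and not improved and \
                np.array_equal(new_labels, np.arange(n_comm)):
            break  # singleton start, nothing moved
        H = np.zeros((Wp.shape[0], n_comm))
        H[np.arange(Wp.shape[0]), new_labels] = 1.0
        Wp, Wn = H.T @ Wp @ H, H.T @ Wn @ H
        start = np.arange(n_comm)
        first = False
    return _canonical(node_to_super), improved_total


def louvain(W: np.ndarray, gamma: float = 1.0,
            seed: int | np.random.Generator = 0,
            n_starts: int = 5) -> Partition:
    """Louvain optimization of the signed quality function.

    Node visiting order is shuffled by ``seed``. Levels of node moves and
    graph aggregation repeat until stable, followed by node-level
    refinement sweeps on the original graph; the whole cycle iterates
    until no move improves Q. The best of ``n_starts`` independent starts
    is returned (ensemble drivers pass ``n_starts=1`` so that run-to-run
    variability remains available for stability scoring).
    """
    if n_starts < 1:
        raise ParameterError("n_starts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    Wp0, Wn0 = _split(W)
    n = Wp0.shape[0]
    vp, vn = Wp0.sum(), Wn0.sum()
    best: Partition | None = None
    for _ in range(n_starts):
        labels = np.arange(n)
        for _ in range(100):  # refinement cycles; converges long before this
            labels, improved = _one_pass(Wp0, Wn0, vp, vn, labels, gamma, rng)
            if not improved:
                break
        part = Partition(labels, gamma, modularity_q(W, labels, gamma))
        if best is None or part.quality > best.quality + 1e-12:
            best = part
    return best


# -- partition similarity --------------------------------------------------

def _pair_count(labels: np.ndarray) -> float:
    sizes = np.bincount(labels)
    return float((sizes * (sizes - 1) // 2).sum())


def _zrand_stats(labels: np.ndarray) -> tuple[float, float, int]:
    """Per-partition quantities reused across z-Rand pairs: (M1, C1, k)."""
    n = labels.size
    M1 = _pair_count(labels)
    sizes = np.bincount(labels).astype(float)
    C1 = n * (n * n - 3 * n - 2) - 8 * (n + 1) * M1 + 4 * (sizes ** 3).sum()
    return M1, C1, int(labels.max()) + 1


def _zrand_pair(l1, l2, stats1, stats2) -> float:
    n = l1.size
    M = n * (n - 1) / 2
    M1, C1, k1 = stats1
    M2, C2, k2 = stats2
    cont = np.bincount(l1 * k2 + l2, minlength=k1 * k2).astype(float)
    w = float((cont * (cont - 1) / 2).sum())
    a = M / 16
    b = (4 * M1 - 2 * M) ** 2 * (4 * M2 - 2 * M) ** 2 / (256 * M * M)
    c = C1 * C2 / (16 * n * (n - 1) * (n - 2))
    d = ((4 * M1 - 2 * M) ** 2 - 4 * C1 - 4 * M) \
        * ((4 * M2 - 2 * M) ** 2 - 4 * C2 - 4 * M) \
        / (64 * n * (n - 1) * (n - 2) * (n - 3))
    sigma2 = a - b + c + d
    if sigma2 <= 0:
        return np.nan
    return float((w - M1 * M2 / M) / np.sqrt(sigma2))


def zrand(p1, p2) -> float:
    """z-score of the pair-counting Rand coefficient under the
    hypergeometric permutation null (Traud et al. formulation)."""
    l1 = p1.labels if isinstance(p1, Partition) else np.asarray(p1, dtype=int)
    l2 = p2.labels if isinstance(p2, Partition) else np.asarray(p2, dtype=int)
    if l1.shape != l2.shape:
        raise ShapeError("partitions must share a node set")
    l1, l2 = _canonical(l1), _canonical(l2)
    if l1.size < 4:
        raise ParameterError("z-Rand needs at least 4 nodes")
    z = _zrand_pair(l1, l2, _zrand_stats(l1), _zrand_stats(l2))
    if np.isnan(z):
        warnings.warn("degenerate z-Rand null variance", stacklevel=2)
    return z


def adjusted_rand_index(p1, p2) -> float:
    """Adjusted Rand index (permutation-expected chance corrected)."""
    l1 = p1.labels if isinstance(p1, Partition) else np.asarray(p1, dtype=int)
    l2 = p2.labels if isinstance(p2, Partition) else np.asarray(p2, dtype=int)
    if l1.shape != l2.shape:
        raise ShapeError("partitions must share a node set")
    l1, l2 = _canonical(l1), _canonical(l2)
    n = l1.size
    k1, k2 = l1.max() + 1, l2.max() + 1
    cont = np.bincount(l1 * k2 + l2, minlength=k1 * k2).reshape(k1, k2)
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)
    comb = lambda x: x * (x - 1) / 2.0  # noqa: E731
    sum_ij = comb(cont).sum()
    sum_a, sum_b = comb(a).sum(), comb(b).sum()
    total = comb(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


# -- ensembles and consensus ----------------------------------------------

def run_ensemble(W: np.ndarray, gamma: float, n_runs: int = 250,
                 seed: int = 0) -> PartitionEnsemble:
    """``n_runs`` Louvain runs at one resolution, seeds derived from a
    master seed by a counter."""
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    seeds = list(range(n_runs))
    parts = []
    for k in seeds:
        rng = np.random.default_rng(np.random.SeedSequence([seed, int(gamma * 1e6), k]))
        parts.append(louvain(W, gamma, rng, n_starts=1))
    return PartitionEnsemble(parts, gamma, seeds)


def _agreement(label_stack: np.ndarray) -> np.ndarray:
    """Fraction of partitions assigning each node pair together."""
    R, n = label_stack.shape
    A = np.zeros((n, n))
    for r in range(R):
        lab = label_stack[r]
        A += (lab[:, None] == lab[None, :])
    A /= R
    np.fill_diagonal(A, 0.0)
    return A


def _null_agreement(label_stack: np.ndarray) -> float:
    """Analytic permutation-null expected co-assignment probability,
    averaged over the ensemble."""
    n = label_stack.shape[1]
    probs = []
    for lab in label_stack:
        sizes = np.bincount(lab)
        probs.append((sizes * (sizes - 1)).sum() / (n * (n - 1)))
    return float(np.mean(probs))


def ensemble_zrand(ensemble: PartitionEnsemble) -> tuple[float, float]:
    """Mean and variance of z-Rand over all partition pairs in the ensemble.

    Identical partitions are grouped first, so only distinct pairs are
    scored; each score is weighted by its pair multiplicity.
    """
    stack = np.stack([_canonical(p.labels) for p in ensemble.partitions])
    uniq, counts = np.unique(stack, axis=0, return_counts=True)
    stats = [_zrand_stats(u) for u in uniq]
    values, weights = [], []
    for i in range(len(uniq)):
        if counts[i] > 1:
            values.append(_zrand_pair(uniq[i], uniq[i], stats[i], stats[i]))
            weights.append(counts[i] * (counts[i] - 1) / 2)
        for j in range(i + 1, len(uniq)):
            values.append(_zrand_pair(uniq[i], uniq[j], stats[i], stats[j]))
            weights.append(counts[i] * counts[j])
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ok = np.isfinite(values)
    if not ok.any():
        return np.nan, np.nan
    values, weights = values[ok], weights[ok]
    mean = float(np.average(values, weights=weights))
    var = float(np.average((values - mean) ** 2, weights=weights))
    return mean, var


def consensus(ensemble: PartitionEnsemble, seed: int = 0,
              max_iter: int = 25) -> ConsensusResult:
    """Agreement-matrix consensus clustering.

    The co-assignment matrix, minus its analytic permutation-null
    expectation (negatives clipped to zero), is re-clustered with Louvain
    (gamma = 1) until every run returns an identical partition.
    """
    if len(ensemble.partitions) < 2:
        if len(ensemble.partitions) == 1:
            p = ensemble.partitions[0]
            return ConsensusResult(p, np.nan, np.nan, p.n_communities,
                                   ensemble.gamma)
        raise ParameterError("consensus needs at least one partition")
    zmean, zvar = ensemble_zrand(ensemble)
    stack = np.stack([p.labels for p in ensemble.partitions])
    qualities = [p.quality for p in ensemble.partitions]
    n_runs = min(len(ensemble.partitions), 100)
    for it in range(max_iter):
        uniq = np.unique(stack, axis=0)
        if uniq.shape[0] == 1:
            labels = _canonical(uniq[0])
            part = Partition(labels, ensemble.gamma, float(qualities[0]))
            return ConsensusResult(part, zmean, zvar, part.n_communities,
                                   ensemble.gamma)
        A = _agreement(stack)
        B = np.clip(A - _null_agreement(stack), 0.0, None)
        if B.sum() == 0:
            raise ConvergenceError("agreement matrix vanished under the null")
        runs = []
        for k in range(n_runs):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 7, it, k]))
            runs.append(louvain(B, 1.0, rng, n_starts=1))
        stack = np.stack([r.labels for r in runs])
        qualities = [r.quality for r in runs]
    raise ConvergenceError(f"consensus did not stabilize in {max_iter} iterations")


def gamma_sweep(W: np.ndarray, gammas, n_runs: int = 250,
                seed: int = 0) -> list[ConsensusResult]:
    """Consensus clustering across a strictly increasing resolution grid."""
    gammas = np.asarray(list(gammas), dtype=float)
    if gammas.size == 0 or np.any(np.diff(gammas) <= 0):
        raise ParameterError("gamma grid must be strictly increasing")
    out = []
    for g in gammas:
        ens = run_ensemble(W, float(g), n_runs=n_runs, seed=seed)
        if n_runs == 1:
            p = ens.partitions[0]
            out.append(ConsensusResult(p, np.nan, np.nan, p.n_communities,
                                       float(g)))
        else:
            out.append(consensus(ens, seed=seed))
    return out


@dataclass
class Plateau:
    """A maximal contiguous resolution range with a constant community count."""

    n_communities: int
    gamma_min: float
    gamma_max: float
    length: int
    representative: ConsensusResult  # result at the plateau's middle gamma


def stable_plateaus(sweep: list[ConsensusResult]) -> list[Plateau]:
    """Summarize a resolution sweep as contiguous constant-k plateaus.

    Plateaus are returned sorted by decreasing length (ties broken by lower
    mean z-Rand variance, i.e. higher run-to-run stability). The length of a
    plateau measures how robust a partition is to the resolution parameter;
    the longest plateau is the natural candidate when a sweep must be
    condensed to a single partition for a downstream recovery experiment.
    """
    if not sweep:
        raise ParameterError("empty resolution sweep")
    plateaus = []
    start = 0
    for i in range(1, len(sweep) + 1):
        if i == len(sweep) or sweep[i].n_communities != sweep[start].n_communities:
            block = sweep[start:i]
            rep = block[(len(block) - 1) // 2]
            finite = [c.zrand_var for c in block if np.isfinite(c.zrand_var)]
            zv = float(np.mean(finite)) if finite else np.inf
            plateaus.append((len(block), zv,
                             Plateau(block[0].n_communities, block[0].gamma,
                                     block[-1].gamma, len(block), rep)))
            start = i
    plateaus.sort(key=lambda t: (-t[0], t[1]))
    return [p for _, _, p in plateaus]


def default_gamma_grid() -> np.ndarray:
    """Resolution grid 0.1..6.0 in steps of 0.1 (60 values)."""
    return np.round(np.arange(1, 61) * 0.1, 10)


def community_degree_maps(fc: FunctionalConnectome,
                          partition: Partition) -> list[DegreeMap]:
    """Per-community cortical degree maps: for each community, the sum of a
    cortical region's (raw) FC with all brainstem nuclei in that community."""
    bst = fc.scheme.indices("brainstem")
    ctx = fc.scheme.indices("cortex")
    if partition.labels.size != bst.size:
        raise ShapeError("partition must cover the brainstem axis")
    maps = []
    for c in range(partition.n_communities):
        members = bst[partition.labels == c]
        if members.size == 0:
            warnings.warn(f"community {c} is empty; skipped", stacklevel=2)
            continue
        vals = np.nansum(fc.matrix[np.ix_(ctx, members)], axis=1)
        maps.append(DegreeMap(vals, "cortex", f"brainstem_community_{c}"))
    return maps
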