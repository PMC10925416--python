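"""Affinity tensor construction and non-negative CP decomposition (HALS).

The pairwise affinities of all animals are arranged in a 3-way tensor
with modes TIME x ANIMALS x PAIRS, where the pair mode is the vectorized
upper triangle of the symmetric affinity matrix (n(n-1)/2 entries,
lexicographic (i, j) with i < j).  A rank-R canonical polyadic (CP)
decomposition approximates the tensor by a sum of R rank-1 outer
products

    T  ~=  sum_r  lambda_r  f_t^(r) o f_w^(r) o f_a^(r)

with all factors elementwise non-negative.  Each component is directly
interpretable: f_t says *when* an affinity pattern is expressed, f_w in
*which animals*, and f_a *between which neuron pairs* -- a soft
multi-clustering of transient functional circuits.

Fitting minimizes half the squared reconstruction error over observed
entries by hierarchical alternating least squares (HALS): cyclic
closed-form updates of one factor column at a time, projected to the
non-negative orthant.  Missing entries (unobserved neurons) are handled
EM-style by imputing them with the current reconstruction before each
sweep, which keeps the observed-entry objective monotonically
non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

from ._util import derive_seed


@dataclass(frozen=True)
class PairMap:
    """Bijection between unordered pairs (i, j), i < j, and [0, n(n-1)/2)."""

    n: int
    i_idx: np.ndarray
    j_idx: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    def index(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("no diagonal pairs")
        if i > j:
            i, j = j, i
        if not (0 <= i < j < self.n):
            raise IndexError(f"pair ({i},{j}) out of range for n={self.n}")
        # lexicographic offset: pairs starting below i, plus (j - i - 1)
        return i * (2 * self.n - i - 1) // 2 + (j - i - 1)

    def inverse(self, p: int) -> tuple:
        if not (0 <= p < self.n_pairs):
            raise IndexError(f"pair index {p} out of range")
        return int(self.i_idx[p]), int(self.j_idx[p])


def pair_index(n: int) -> PairMap:
    """Lexicographic pair map for ``n`` nodes (matches ``np.triu_indices``)."""
    if n < 2:
        raise ValueError("need n >= 2")
    i_idx, j_idx = np.triu_indices(n, k=1)
    return PairMap(n=n, i_idx=i_idx, j_idx=j_idx)


def vectorize_matrix(A: np.ndarray, pm: PairMap) -> np.ndarray:
    """Upper-triangular vectorization; inverse of :func:`factor_to_matrix`."""
    return A[pm.i_idx, pm.j_idx]


def factor_to_matrix(f_a: np.ndarray, pm: PairMap) -> np.ndarray:
    """Reorganize a pair-vector as a symmetric zero-diagonal n x n matrix."""
    f_a = np.asarray(f_a)
    if f_a.shape != (pm.n_pairs,):
        raise ValueError(f"expected length {pm.n_pairs}, got {f_a.shape}")
    A = np.zeros((pm.n, pm.n), dtype=f_a.dtype)
    A[pm.i_idx, pm.j_idx] = f_a
    return A + A.T


@dataclass
class AffinityTensor:
    """TIME x ANIMALS x PAIRS tensor with an observation mask."""

    data: np.ndarray
    mask: np.ndarray
    pair_map: PairMap
    neuron_ids: list = field(default_factory=list)
    dt: float = 1.0

    @property
    def shape(self) -> tuple:
        return self.data.shape


def build_tensor(a) -> AffinityTensor:
    """Arrange an AffinitySeries (animal x pair x time) as T x W x P."""
    data = np.ascontiguousarray(np.transpose(a.a, (2, 0, 1)))
    mask = np.broadcast_to(a.pair_observed[None, :, :], data.shape).copy()
    return AffinityTensor(
        data=data, mask=mask, pair_map=a.pair_map, neuron_ids=a.neuron_ids, dt=a.dt
    )


@dataclass
class CPModel:
    """Rank-R non-negative CP model.

    ``factors`` are (T x R, W x R, P x R); each affinity-factor column
    has unit Euclidean norm with its scale folded into ``lambdas``;
    components are sorted by lambda descending.
    """

    rank: int
    factors: tuple
    lambdas: np.ndarray
    objective: float
    objective_history: np.ndarray
    n_iter: int
    converged: bool
    seed: int | None = None

    @property
    def temporal(self) -> np.ndarray:
        return self.factors[0]

    @property
    def animal(self) -> np.ndarray:
        return self.factors[1]

    @property
    def affinity(self) -> np.ndarray:
        return self.factors[2]


def cp_reconstruct(model: CPModel) -> np.ndarray:
    """Dense reconstruction sum_r lambda_r v_r^(1) o v_r^(2) o v_r^(3)."""
    X1, X2, X3 = model.factors
    return np.einsum("r,tr,wr,pr->twp", model.lambdas, X1, X2, X3, optimize=True)


def _reconstruct_raw(factors) -> np.ndarray:
    X1, X2, X3 = factors
    return np.einsum("tr,wr,pr->twp", X1, X2, X3, optimize=True)


def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _khatri_rao(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    # column-wise Kronecker, rows ordered to match _unfold's C-order flatten
    r = A.shape[1]
    return (A[:, None, :] * B[None, :, :]).reshape(-1, r)


def _hals_single(data, mask, R, rng, max_iter, tol):
    """One HALS run from a random non-negative init.

    Returns (factors, history).  ``mask`` is None for fully observed data.
    """
    dims = data.shape
    scale = data[mask].mean() if mask is not None else data.mean()
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0 if np.any(data > 0) else 0.0
    if scale == 0.0:
        factors = [np.zeros((d, R)) for d in dims]
        return factors, np.array([0.0])
    init_scale = (scale / max(R, 1)) ** (1.0 / 3.0)
    factors = [rng.uniform(0.1, 1.0, size=(d, R)) * init_scale for d in dims]

    observed = None if mask is None else mask
    norm_obs = 0.5 * np.sum(data[observed] ** 2) if observed is not None else 0.5 * np.sum(data**2)

    X = data.copy()
    history = []
    prev = None
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        if observed is not None:
            recon = _reconstruct_raw(factors)
            X = np.where(observed, data, recon)
        grams = [f.T @ f for f in factors]
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            # C-order flatten of moveaxis puts the *earlier* remaining mode first
            kr = _khatri_rao(others[0], others[1])
            G = np.ones((R, R))
            for m in range(3):
                if m != mode:
                    G = G * grams[m]
            M = _unfold(X, mode) @ kr
            A = factors[mode]
            for r in range(R):
                g = G[r, r]
                if g <= 1e-30:
                    A[:, r] = 0.0
                    continue
                v = A[:, r] + (M[:, r] - A @ G[:, r]) / g
                A[:, r] = np.maximum(v, 0.0)
            grams[mode] = A.T @ A

        recon = _reconstruct_raw(factors)
        if observed is not None:
            obj = 0.5 * np.sum((data[observed] - recon[observed]) ** 2)
        else:
            obj = 0.5 * np.sum((data - recon) ** 2)
        history.append(obj)
        if prev is not None:
            denom = max(prev, 1e-30)
            if (prev - obj) / denom < tol:
                break
        prev = obj
    return factors, np.asarray(history)


def _canonicalize(factors) -> tuple:
    """Unit-norm affinity columns, scale in lambda, sorted descending."""
    X1, X2, X3 = (np.asarray(f, dtype=float).copy() for f in factors)
    lam = np.linalg.norm(X3, axis=0)
    nz = lam > 0
    X3[:, nz] /= lam[nz]
    order = np.argsort(-lam, kind="stable")
    return (X1[:, order], X2[:, order], X3[:, order]), lam[order]


def hals_fit(
    tensor: AffinityTensor,
    rank: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> CPModel:
    """Fit one non-negative CP model by HALS from a seeded random init.

    The recorded objective history (half squared error over observed
    entries) is monotonically non-increasing.  Masked entries never
    influence the fit.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    data = np.asarray(tensor.data, dtype=float)
    mask = None if tensor.mask is None or tensor.mask.all() else np.asarray(tensor.mask, bool)
    if mask is not None and not mask.any():
        raise ValueError("tensor has no observed entries")
    if np.any((data < 0) & (mask if mask is not None else True)):
        raise ValueError("tensor must be non-negative where observed")
    if rank > max(data.shape):
        import warnings

        warnings.warn(f"rank {rank} exceeds every tensor dimension {data.shape}")
    rng = np.random.default_rng(seed)
    factors, history = _hals_single(data, mask, rank, rng, max_iter, tol)
    factors, lam = _canonicalize(factors)
    return CPModel(
        rank=rank,
        factors=factors,
        lambdas=lam,
        objective=float(history[-1]),
        objective_history=history,
        n_iter=len(history),
        converged=len(history) < max_iter,
        seed=seed,
    )


def factor_congruence(model_a: CPModel, model_b: CPModel) -> float:
    """Similarity of two CP models in [0(ish), 1].

    For every component pair, the product over the three modes of the
    cosine similarity between factor columns; components are matched by
    the Hungarian algorithm and the matched scores averaged.
    """
    R = min(model_a.rank, model_b.rank)
    C = np.ones((model_a.rank, model_b.rank))
    for Xa, Xb in zip(model_a.factors, model_b.factors):
        na = np.linalg.norm(Xa, axis=0)
        nb = np.linalg.norm(Xb, axis=0)
        na = np.where(na > 0, na, 1.0)
        nb = np.where(nb > 0, nb, 1.0)
        C = C * ((Xa / na).T @ (Xb / nb))
    row, col = linear_sum_assignment(-C)
    return float(np.mean(C[row, col][:R]))


class NonnegativeCP(BaseEstimator):
    """Non-negative CP decomposition fitted by multi-restart HALS.

    Parameters
    ----------
    rank : int
        Number of components R.
    n_restarts : int, default 10
        Seeded random restarts; the best objective wins.
    max_iter, tol : stopping rule per restart.
    random_state : int, default 0
        Master seed; restart seeds are derived from it.

    Attributes (after fit)
    ----------
    factors_ : (T x R, W x R, P x R) non-negative factor matrices
    lambdas_ : per-component scales (affinity columns unit-norm)
    objective_ : best half-squared-error over observed entries
    objective_history_ : history of the winning restart
    model_ : the winning :class:`CPModel`
    """

    def __init__(self, rank=3, n_restarts=10, max_iter=500, tol=1e-7, random_state=0):
        self.rank = rank
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, tensor: AffinityTensor, y=None):
        best = None
        self.restart_models_ = []
        for k in range(self.n_restarts):
            seed = derive_seed(self.random_state, f"hals-restart-{k}")
            m = hals_fit(tensor, self.rank, seed=seed, max_iter=self.max_iter, tol=self.tol)
            self.restart_models_.append(m)
            if best is None or m.objective < best.objective:
                best = m
        self.model_ = best
        self.factors_ = best.factors
        self.lambdas_ = best.lambdas
        self.objective_ = best.objective
        self.objective_history_ = best.objective_history
        self.n_iter_ = best.n_iter
        return self

    def reconstruct(self) -> np.ndarray:
        return cp_reconstruct(self.model_)


def select_rank(
    tensor: AffinityTensor,
    ranks,
    n_restarts: int = 10,
    seed: int = 0,
):
    """Rank-selection diagnostics: best objective and restart stability per R.

    Stability is the mean pairwise factor congruence between the restart
    solutions at a given rank; a planted rank tends to be markedly more
    stable than an overfit one.  Returns a pandas DataFrame; no automatic
    choice is imposed.
    """
    import pandas as pd

    ranks = list(ranks)
    if not ranks:
        raise ValueError("empty rank grid")
    rows = []
    for R in ranks:
        est = NonnegativeCP(
            rank=R, n_restarts=n_restarts, random_state=derive_seed(seed, f"rank-{R}")
        ).fit(tensor)
        models = est.restart_models_
        sims = [
            factor_congruence(models[i], models[j])
            for i in range(len(models))
            for j in range(i + 1, len(models))
        ]
        rows.append(
            {
                "rank": R,
                "best_objective": est.objective_,
                "stability": float(np.mean(sims)) if sims else 1.0,
                "n_restarts": n_restarts,
            }
        )
    return pd.DataFrame(rows)
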