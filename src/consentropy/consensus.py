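"""Consensus clustering of categorical base clusterings.

Three algorithms synthesize a single labeling from an N×M matrix of base
cluster labels (N observations, M base clusterings), exposed as
scikit-learn-style estimators:

* :class:`KModesConsensus` — the categorical analogue of k-means: rows are
  partitioned into K groups minimizing the total Hamming distance to each
  group's column-wise mode vector.  Base clusterings contribute equally and
  their labels are nominal categories.
* :class:`LCAConsensus` — latent class analysis: a categorical mixture model
  in which an unobserved latent class (the consensus clustering) explains
  the observed base labels, assumed conditionally independent given the
  class.  Fitted by EM; disagreement between methods is absorbed by
  method-specific conditional probabilities.
* :class:`WeightedJSDConsensus` — co-association optimization: each base
  clustering m contributes a binary similarity matrix S^(m) (1 where two
  observations share a label); a consensus similarity matrix S and
  per-method weights ω are found by minimizing

      sum_m ω_m JSD(S || S^(m)) + λ sum_m ω_m log ω_m,   sum ω_m = 1, ω ≥ 0

  where JSD is applied entrywise to the Bernoulli-valued matrices.  The
  entropy regularizer (strength λ) prevents the consensus from collapsing
  onto any single base clustering.  S is then partitioned with the Leiden
  community-detection algorithm; the weights report each method's relative
  contribution.  Dense N×N storage limits this method to moderate N.

Labels are permutation-equivariant inputs: recoding labels inside any base
clustering leaves the consensus partition unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp, xlogy
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .labelings import LabelingCollection

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "LcaModel",
    "KModesConsensus",
    "LCAConsensus",
    "WeightedJSDConsensus",
    "bernoulli_jsd",
    "resolution_search",
    "ResolutionSearchResult",
    "kmodes_consensus",
    "lca_consensus",
    "weighted_consensus",
]


# --------------------------------------------------------------------------
# result containers


@dataclass
class ConsensusResult:
    """A consensus labeling plus the run record that produced it."""

    labels: np.ndarray
    n_clusters: int
    algorithm: str
    seed: int
    objective_trace: list[float]
    converged: bool
    weights: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "n_clusters": int(self.n_clusters),
            "seed": int(self.seed),
            "converged": bool(self.converged),
            "objective_trace": [float(v) for v in self.objective_trace],
            "weights": None if self.weights is None else [float(w) for w in self.weights],
        }


@dataclass
class LcaModel:
    """Fitted latent-class model: priors π_k and per-column conditionals
    θ_{mkj} = P(column m shows label j | latent class k)."""

    class_priors: np.ndarray
    conditionals: list[np.ndarray]
    log_likelihood: float


# --------------------------------------------------------------------------
# shared helpers


def _validate_label_matrix(X) -> np.ndarray:
    X = check_array(X, dtype=None, ensure_2d=True)
    X = np.asarray(X)
    if X.dtype.kind not in "iu":
        Xi = np.empty(X.shape, dtype=np.int64)
        for j in range(X.shape[1]):
            _, Xi[:, j] = np.unique(X[:, j], return_inverse=True)
        return Xi
    out = np.empty(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        _, out[:, j] = np.unique(X[:, j], return_inverse=True)
    return out


def _as_int_seed(random_state) -> int:
    if random_state is None:
        return 0
    return int(random_state)


# --------------------------------------------------------------------------
# K-modes


class KModesConsensus(ClusterMixin, BaseEstimator):
    """K-modes consensus over an N×M categorical label matrix.

    Minimizes the total Hamming distance of rows to their cluster's mode
    vector (column-wise modal label).  Initialization samples K distinct
    rows; the best of ``n_starts`` restarts (lowest final objective) is
    kept.

    Parameters
    ----------
    n_clusters : int
        Number K of consensus clusters.
    n_starts : int, default 10
        Random restarts.
    max_iter : int, default 100
        Iteration cap per restart.
    random_state : int, default 0
        Seed; identical seeds give bit-identical results.

    Attributes
    ----------
    labels_ : (N,) consensus cluster codes
    modes_ : (K, M) mode vectors of the best run
    objective_ : final Hamming objective of the best run
    objective_trace_ : per-iteration objective of the best run (non-increasing)
    n_iter_ : iterations used by the best run
    converged_ : whether the best run reached a fixed point
    """

    def __init__(self, n_clusters: int = 2, n_starts: int = 10, max_iter: int = 100,
                 random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _validate_label_matrix(X)
        n, _ = X.shape
        k = self.n_clusters
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters={k} must be in [1, {n}]")
        rng = np.random.default_rng(_as_int_seed(self.random_state))
        best = None
        for _ in range(max(1, self.n_starts)):
            run = self._single_run(X, k, rng)
            if best is None or run[1] < best[1]:
                best = run
        labels, objective, modes, trace, n_iter, converged = best
        self.labels_ = labels
        self.objective_ = float(objective)
        self.modes_ = modes
        self.objective_trace_ = trace
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    @staticmethod
    def _modes_of(X: np.ndarray, labels: np.ndarray, k: int,
                  prev: np.ndarray | None) -> np.ndarray:
        n, m = X.shape
        modes = np.zeros((k, m), dtype=np.int64)
        for c in range(k):
            rows = X[labels == c]
            if rows.shape[0] == 0:
                if prev is not None:
                    modes[c] = prev[c]
                continue
            for j in range(m):
                counts = np.bincount(rows[:, j])
                modes[c, j] = int(np.argmax(counts))  # tie -> smallest code
        return modes

    def _single_run(self, X, k, rng):
        n, m = X.shape
        distinct = np.unique(X, axis=0)
        if distinct.shape[0] >= k:
            pick = rng.choice(distinct.shape[0], size=k, replace=False)
            modes = distinct[pick].copy()
        else:
            pick = rng.choice(n, size=k, replace=True)
            modes = X[pick].copy()

        labels = np.zeros(n, dtype=np.int64)
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            dist = (X[:, None, :] != modes[None, :, :]).sum(axis=2)
            new_labels = np.argmin(dist, axis=1)
            # repair empty clusters: reseed from the row farthest from its mode
            for c in range(k):
                if not (new_labels == c).any():
                    row_dist = dist[np.arange(n), new_labels]
                    far = int(np.argmax(row_dist))
                    modes[c] = X[far]
                    new_labels[far] = c
                    logger.debug("reseeded empty k-modes cluster %d from row %d", c, far)
            objective = float(
                (X != modes[new_labels]).sum()
            )
            trace.append(objective)
            if np.array_equal(new_labels, labels) and it > 1:
                converged = True
                labels = new_labels
                break
            labels = new_labels
            modes = self._modes_of(X, labels, k, prev=modes)
        objective = float((X != modes[labels]).sum())
        if not trace or objective < trace[-1]:
            trace.append(objective)
        return labels, objective, modes, trace, it, converged

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# --------------------------------------------------------------------------
# latent class analysis


class LCAConsensus(ClusterMixin, BaseEstimator):
    """Latent class analysis consensus, fitted by EM.

    Model: P(x_i) = sum_k π_k prod_m θ_{mk, x_im}.  The M-step applies a
    Dirichlet pseudocount (``pseudocount``) to the conditional updates, so
    the monotone objective is the penalized log-posterior; the reported
    ``log_likelihood_`` is the observed-data log-likelihood of the best
    restart.  Consensus labels are maximum-a-posteriori latent classes.

    Attributes
    ----------
    labels_, class_priors_, conditionals_, log_likelihood_,
    objective_trace_ (non-decreasing penalized objective), converged_
    """

    def __init__(self, n_clusters: int = 2, n_starts: int = 10, tol: float = 1e-6,
                 max_iter: int = 200, pseudocount: float = 0.1,
                 random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.pseudocount = pseudocount
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _validate_label_matrix(X)
        n, m = X.shape
        k = self.n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        n_patterns = np.unique(X, axis=0).shape[0]
        if k > n_patterns:
            logger.warning(
                "n_clusters=%d exceeds the %d distinct row patterns; some "
                "latent classes may stay empty", k, n_patterns,
            )
        rng = np.random.default_rng(_as_int_seed(self.random_state))
        alphabets = [int(X[:, j].max()) + 1 for j in range(m)]
        # a single base clustering: the latent-class model is unidentifiable
        # from one categorical observation (any mixture reproducing the
        # marginal is optimal), so the labeling is returned unchanged
        if m == 1 and k >= alphabets[0]:
            return self._fit_degenerate_single_column(X, k, alphabets[0])
        best = None
        for _ in range(max(1, self.n_starts)):
            run = self._em_run(X, k, alphabets, rng)
            if best is None or run["objective"] > best["objective"]:
                best = run
        self.labels_ = best["labels"]
        self.class_priors_ = best["pi"]
        self.conditionals_ = best["theta"]
        self.log_likelihood_ = best["loglik"]
        self.objective_trace_ = best["trace"]
        self.converged_ = best["converged"]
        self.n_iter_ = best["n_iter"]
        return self

    def _fit_degenerate_single_column(self, X, k, a):
        n = X.shape[0]
        labels = X[:, 0]
        counts = np.bincount(labels, minlength=k).astype(float)
        pi = counts / n
        theta = np.full((k, a), self.pseudocount / (self.pseudocount * a))
        occupied = np.flatnonzero(counts)
        theta[:] = self.pseudocount
        theta[occupied, occupied] += counts[occupied]
        theta /= theta.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            loglik = float(np.sum(xlogy(counts, np.maximum(pi, 1e-300))))
        self.labels_ = labels
        self.class_priors_ = pi
        self.conditionals_ = [theta]
        self.log_likelihood_ = loglik
        self.objective_trace_ = [loglik + self.pseudocount * float(np.log(theta).sum())]
        self.converged_ = True
        self.n_iter_ = 0
        return self

    def _em_run(self, X, k, alphabets, rng):
        n, m = X.shape
        alpha = self.pseudocount
        resp = rng.dirichlet(np.ones(k), size=n)

        pi = np.full(k, 1.0 / k)
        theta = [np.full((k, a), 1.0 / a) for a in alphabets]
        prev_obj = -np.inf
        trace: list[float] = []
        converged = False
        loglik = -np.inf
        it = 0
        for it in range(1, self.max_iter + 1):
            # M-step from current responsibilities
            nk = resp.sum(axis=0)
            pi = nk / n
            for j in range(m):
                counts = np.zeros((k, alphabets[j]))
                np.add.at(counts.T, X[:, j], resp)  # counts.T[label, :] += resp[i, :]
                theta[j] = (counts + alpha) / (nk[:, None] + alpha * alphabets[j])
            # E-step
            log_l = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), -np.inf)[None, :].repeat(n, axis=0)
            for j in range(m):
                log_l += np.log(theta[j])[:, X[:, j]].T
            row_ll = logsumexp(log_l, axis=1)
            loglik = float(row_ll.sum())
            if not np.isfinite(loglik):
                raise FloatingPointError("non-finite log-likelihood in LCA EM")
            penalty = alpha * float(sum(np.log(t).sum() for t in theta))
            objective = loglik + penalty
            trace.append(objective)
            resp = np.exp(log_l - row_ll[:, None])
            if objective - prev_obj < self.tol and it > 1:
                converged = True
                break
            prev_obj = objective
        labels = np.argmax(resp, axis=1)
        return {
            "labels": labels,
            "pi": pi,
            "theta": theta,
            "loglik": loglik,
            "objective": trace[-1],
            "trace": trace,
            "converged": converged,
            "n_iter": it,
        }

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# --------------------------------------------------------------------------
# weighted Jensen-Shannon-divergence consensus


def bernoulli_jsd(p, q):
    """Jensen–Shannon divergence between Bernoulli(p) and Bernoulli(q).

    ``JSD = 0.5 KL(p||m) + 0.5 KL(q||m)`` with ``m = (p+q)/2``, natural
    log, ``0 log 0 = 0``.  Symmetric, zero iff p == q, maximum ln 2 at
    (0, 1).  Accepts scalars or arrays in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if (p < 0).any() or (p > 1).any() or (q < 0).any() or (q > 1).any():
        raise ValueError("bernoulli_jsd arguments must lie in [0, 1]")
    mid = 0.5 * (p + q)

    def kl(a, b):
        return (xlogy(a, a) - xlogy(a, b)) + (xlogy(1 - a, 1 - a) - xlogy(1 - a, 1 - b))

    out = 0.5 * kl(p, mid) + 0.5 * kl(q, mid)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class ResolutionSearchResult:
    resolution: float
    labels: np.ndarray
    n_clusters: int
    achieved_k: bool


def resolution_search(
    partitioner,
    target_k: int,
    bounds: tuple[float, float] = (0.01, 10.0),
    max_iter: int = 40,
    seed: int = 0,
) -> ResolutionSearchResult:
    """Binary search for a resolution yielding exactly *target_k* clusters.

    Assumes the cluster count of ``partitioner(resolution, seed)`` is
    non-decreasing in the resolution.  If the upper bound yields too few
    clusters it is doubled up to 3 times; if the target remains
    unreachable, the labels whose cluster count is nearest to the target
    are returned (ties favor fewer clusters) with ``achieved_k=False``.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")

    best: ResolutionSearchResult | None = None

    def record(res: float, labels: np.ndarray) -> int:
        nonlocal best
        labels = np.asarray(labels)
        kc = len(np.unique(labels))
        cand = ResolutionSearchResult(res, labels, kc, kc == target_k)
        if best is None:
            best = cand
        else:
            d_new, d_old = abs(kc - target_k), abs(best.n_clusters - target_k)
            if d_new < d_old or (d_new == d_old and kc < best.n_clusters):
                best = cand
        return kc

    k_lo = record(lo, partitioner(lo, seed))
    if k_lo == target_k:
        return best
    k_hi = record(hi, partitioner(hi, seed))
    if k_hi == target_k:
        return best
    doublings = 0
    while k_hi < target_k and doublings < 3:
        hi *= 2
        doublings += 1
        k_hi = record(hi, partitioner(hi, seed))
        if k_hi == target_k:
            return best
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        k_mid = record(mid, partitioner(mid, seed))
        if k_mid == target_k:
            return best
        if k_mid < target_k:
            lo = mid
        else:
            hi = mid
    logger.warning(
        "resolution search did not reach exactly %d clusters; returning "
        "nearest (%d clusters at resolution %.4g)", target_k, best.n_clusters,
        best.resolution,
    )
    return best


def _leiden_partitioner(similarity: np.ndarray, sparsify: float):
    """Build a (resolution, seed) -> labels partitioner on a similarity
    matrix, dropping edges below the sparsification threshold."""
    import igraph as ig
    import leidenalg

    n = similarity.shape[0]
    iu = np.triu_indices(n, k=1)
    w = similarity[iu]
    keep = w >= sparsify
    edges = list(zip(iu[0][keep].tolist(), iu[1][keep].tolist()))
    weights = w[keep].tolist()
    graph = ig.Graph(n=n, edges=edges)

    def partition(resolution: float, seed: int) -> np.ndarray:
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=resolution,
            seed=int(seed),
            n_iterations=2,
        )
        return np.asarray(part.membership, dtype=np.int64)

    return partition


class WeightedJSDConsensus(ClusterMixin, BaseEstimator):
    """Weighted co-association consensus with a Jensen–Shannon loss.

    Alternating minimization of
    ``sum_m ω_m JSD(S||S^(m)) + λ sum_m ω_m log ω_m`` over the consensus
    similarity matrix S (entries in [0, 1], unit diagonal excluded from the
    loss) and the method weights ω on the simplex:

    * S-step: with ω fixed, every off-diagonal entry s_ij independently
      minimizes ``sum_m ω_m JSD(s, s^(m)_ij)`` — a 1-D convex problem
      depending only on the ω-weighted vote ``a = sum_m ω_m s^(m)_ij``,
      solved once per distinct vote by bounded scalar minimization.
    * ω-step: with S fixed, the entropy-regularized Lagrangian gives the
      closed form ``ω_m ∝ exp(−D_m/λ)`` with ``D_m = JSD(S||S^(m))``.

    ``JSD(S||S^(m))`` is the mean entrywise Bernoulli JSD over off-diagonal
    pairs, keeping D_m in [0, ln 2] regardless of N so that λ is
    scale-free.  Both steps solve their subproblem exactly, so the
    objective trace is non-increasing.  The converged S is partitioned with
    Leiden community detection; if ``n_clusters`` is given, the resolution
    is binary-searched to hit that count.

    Attributes
    ----------
    labels_, weights_, similarity_, objective_trace_, converged_,
    resolution_, achieved_k_
    """

    def __init__(self, n_clusters: int | None = None, lam: float = 0.1,
                 tol: float = 1e-8, max_iter: int = 100, sparsify: float = 0.01,
                 resolution: float = 1.0, max_n: int = 20000,
                 random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter
        self.sparsify = sparsify
        self.resolution = resolution
        self.max_n = max_n
        self.random_state = random_state

    # -- objective pieces ---------------------------------------------------

    @staticmethod
    def coassociation_matrices(X: np.ndarray) -> np.ndarray:
        """Stack of binary co-association matrices, one per column:
        ``S^(m)_ij = 1`` iff observations i and j share a label in column m."""
        n, m = X.shape
        out = np.empty((m, n, n), dtype=bool)
        for j in range(m):
            col = X[:, j]
            out[j] = col[:, None] == col[None, :]
        return out

    @staticmethod
    def _divergences(s_flat: np.ndarray, b_flat: np.ndarray) -> np.ndarray:
        """Mean off-diagonal Bernoulli JSD of S against each S^(m)."""
        j1 = bernoulli_jsd(s_flat, np.ones_like(s_flat))
        j0 = bernoulli_jsd(s_flat, np.zeros_like(s_flat))
        return np.where(b_flat, j1[None, :], j0[None, :]).mean(axis=1)

    def _objective(self, s_flat, b_flat, w):
        d = self._divergences(s_flat, b_flat)
        return float(w @ d + self.lam * np.sum(xlogy(w, w))), d

    @staticmethod
    def _optimal_entry(a: float) -> float:
        """Minimizer over s of ``a·JSD(s,1) + (1−a)·JSD(s,0)``."""
        if a <= 0.0:
            return 0.0
        if a >= 1.0:
            return 1.0
        f = lambda s: a * bernoulli_jsd(s, 1.0) + (1 - a) * bernoulli_jsd(s, 0.0)  # noqa: E731
        res = minimize_scalar(f, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-12})
        return float(res.x)

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        X = _validate_label_matrix(X)
        n, m = X.shape
        if n > self.max_n:
            raise ValueError(
                f"N={n} exceeds max_n={self.max_n}: the dense N×N similarity "
                "matrices require quadratic memory"
            )
        coassoc = self.coassociation_matrices(X)
        iu = np.triu_indices(n, k=1)
        b_flat = coassoc[:, iu[0], iu[1]]  # (M, n_pairs) binary

        w = np.full(m, 1.0 / m)
        s_flat = b_flat.mean(axis=0).astype(float)
        trace: list[float] = []
        converged = False
        prev = np.inf
        for _ in range(self.max_iter):
            # S-step: solve once per distinct weighted vote
            votes = w @ b_flat
            votes = np.round(votes, 12)
            uniq, inv = np.unique(votes, return_inverse=True)
            s_flat = np.asarray([self._optimal_entry(a) for a in uniq])[inv]
            # ω-step: softmax of negative divergences
            d = self._divergences(s_flat, b_flat)
            z = -d / self.lam
            z -= z.max()
            w = np.exp(z)
            w /= w.sum()
            obj, d = self._objective(s_flat, b_flat, w)
            trace.append(obj)
            if prev - obj < self.tol and len(trace) > 1:
                converged = True
                break
            prev = obj

        similarity = np.eye(n)
        similarity[iu] = s_flat
        similarity.T[iu] = s_flat

        partitioner = _leiden_partitioner(similarity, self.sparsify)
        seed = _as_int_seed(self.random_state)
        if self.n_clusters is None:
            labels = partitioner(self.resolution, seed)
            self.resolution_ = float(self.resolution)
            self.achieved_k_ = True
        else:
            found = resolution_search(partitioner, self.n_clusters, seed=seed)
            labels = found.labels
            self.resolution_ = found.resolution
            self.achieved_k_ = found.achieved_k

        self.labels_ = labels
        self.weights_ = w
        self.similarity_ = similarity
        self.objective_trace_ = trace
        self.converged_ = converged
        self.divergences_ = d
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# --------------------------------------------------------------------------
# collection-level wrappers


def kmodes_consensus(collection: LabelingCollection, k: int, n_starts: int = 10,
                     seed: int = 0, max_iter: int = 100) -> ConsensusResult:
    """K-modes consensus of a labeling collection."""
    est = KModesConsensus(n_clusters=k, n_starts=n_starts, max_iter=max_iter,
                          random_state=seed).fit(collection.label_matrix)
    return ConsensusResult(
        labels=est.labels_,
        n_clusters=len(np.unique(est.labels_)),
        algorithm="kmodes",
        seed=seed,
        objective_trace=est.objective_trace_,
        converged=est.converged_,
    )


def lca_consensus(collection: LabelingCollection, k: int, n_starts: int = 10,
                  seed: int = 0, tol: float = 1e-6, max_iter: int = 200
                  ) -> tuple[ConsensusResult, LcaModel]:
    """Latent-class-analysis consensus of a labeling collection."""
    est = LCAConsensus(n_clusters=k, n_starts=n_starts, tol=tol,
                       max_iter=max_iter, random_state=seed).fit(collection.label_matrix)
    result = ConsensusResult(
        labels=est.labels_,
        n_clusters=len(np.unique(est.labels_)),
        algorithm="lca",
        seed=seed,
        objective_trace=est.objective_trace_,
        converged=est.converged_,
    )
    model = LcaModel(
        class_priors=est.class_priors_,
        conditionals=est.conditionals_,
        log_likelihood=est.log_likelihood_,
    )
    return result, model


def weighted_consensus(collection: LabelingCollection, lam: float = 0.1,
                       k: int | None = None, tol: float = 1e-8,
                       max_iter: int = 100, seed: int = 0) -> ConsensusResult:
    """Weighted-JSD co-association consensus of a labeling collection."""
    est = WeightedJSDConsensus(n_clusters=k, lam=lam, tol=tol, max_iter=max_iter,
                               random_state=seed).fit(collection.label_matrix)
    return ConsensusResult(
        labels=est.labels_,
        n_clusters=len(np.unique(est.labels_)),
        algorithm="weighted",
        seed=seed,
        objective_trace=est.objective_trace_,
        converged=est.converged_,
        weights=est.weights_,
    )
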