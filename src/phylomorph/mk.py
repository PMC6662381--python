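"""Mk models of discrete character evolution on a phylogeny.

Implements the K-state continuous-time Markov model (Mk) with the three
standard rate-matrix constraints — ER (one rate), SYM (symmetric pairs),
ARD (all rates different) — maximum-likelihood fitting via Felsenstein's
pruning algorithm, AIC model selection, and marginal ancestral-state
estimation by a down-pass/up-pass message combination.

The likelihood is evaluated with per-node scaling so it stays finite on
hundreds of tips; transition matrices for all edges are obtained from one
eigendecomposition of Q per evaluation (with a scipy ``expm`` fallback when
the eigenbasis is ill-conditioned).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
from sklearn.base import BaseEstimator

from .tree import Phylogeny

__all__ = [
    "QMatrix",
    "MkFit",
    "ModelComparison",
    "MkModel",
    "transition_probability",
    "transition_matrices",
    "mk_log_likelihood",
    "fit_mk",
    "select_model",
    "marginal_ancestral_states",
]

RATE_LOWER = 1e-9
RATE_UPPER = 1e3
MODELS = ("ER", "SYM", "ARD")


@dataclass(frozen=True)
class QMatrix:
    """Instantaneous transition-rate matrix; rows sum to zero."""

    states: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        K = len(self.states)
        if m.shape != (K, K):
            raise ValueError(f"matrix shape {m.shape} does not match {K} states")
        off = m.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        fixed = off - np.diag(off.sum(axis=1))
        object.__setattr__(self, "matrix", fixed)

    @property
    def k(self) -> int:
        return len(self.states)

    def stationary_distribution(self) -> np.ndarray:
        """Left null vector of Q, normalized to a probability vector."""
        w, v = scipy.linalg.eig(self.matrix.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    @classmethod
    def from_rates(cls, states, rates, model: str) -> "QMatrix":
        """Build a Q-matrix from the free-parameter vector of *model*."""
        K = len(states)
        idx = _rate_index(K, model)
        m = np.zeros((K, K))
        rates = np.asarray(rates, dtype=float)
        for (i, j), r in idx.items():
            m[i, j] = rates[r]
        return cls(tuple(states), m)


def _rate_index(K: int, model: str) -> dict:
    """Map off-diagonal position (i, j) -> free-parameter index."""
    if model == "ER":
        return {(i, j): 0 for i in range(K) for j in range(K) if i != j}
    if model == "SYM":
        idx, r = {}, 0
        for i in range(K):
            for j in range(i + 1, K):
                idx[(i, j)] = idx[(j, i)] = r
                r += 1
        return idx
    if model == "ARD":
        idx, r = {}, 0
        for i in range(K):
            for j in range(K):
                if i != j:
                    idx[(i, j)] = r
                    r += 1
        return idx
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def n_free_rates(K: int, model: str) -> int:
    return {"ER": 1, "SYM": K * (K - 1) // 2, "ARD": K * (K - 1)}[model]


@dataclass
class MkFit:
    model: str
    q: QMatrix
    lnl: float
    k: int
    root_prior: np.ndarray
    converged: bool = True
    n_restarts: int = 0
    data_hash: int | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.lnl + 2.0 * self.k


@dataclass
class ModelComparison:
    fits: list
    best: MkFit = field(init=False)
    delta_aic: np.ndarray = field(init=False)

    def __post_init__(self):
        if len(self.fits) < 2:
            raise ValueError("need at least 2 fits to compare")
        hashes = {f.data_hash for f in self.fits}
        if len(hashes) > 1:
            raise ValueError("fits were computed on different data")
        aics = np.array([f.aic for f in self.fits])
        # argmin with ties broken toward fewer parameters
        best_aic = aics.min()
        tied = [f for f, a in zip(self.fits, aics) if np.isclose(a, best_aic)]
        self.best = min(tied, key=lambda f: f.k)
        self.delta_aic = aics - best_aic


# ---------------------------------------------------------------------------
# transition probabilities
# ---------------------------------------------------------------------------


def transition_probability(q: QMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Q t), a row-stochastic matrix."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    P = scipy.linalg.expm(q.matrix * t)
    return np.clip(P, 0.0, 1.0)


def transition_matrices(q: QMatrix, ts: np.ndarray) -> np.ndarray:
    """P(t) for a vector of durations, shape (len(ts), K, K).

    Uses one eigendecomposition of Q; falls back to per-duration ``expm``
    when the eigenbasis is ill-conditioned (near-defective Q).
    """
    ts = np.asarray(ts, dtype=float)
    K = q.k
    try:
        w, V = scipy.linalg.eig(q.matrix)
        Vinv = scipy.linalg.inv(V)
        cond = np.linalg.norm(V, 2) * np.linalg.norm(Vinv, 2)
        if not np.isfinite(cond) or cond > 1e8:
            raise np.linalg.LinAlgError
        E = np.exp(np.multiply.outer(ts, w))  # (n, K)
        P = np.einsum("ij,nj,jk->nik", V, E, Vinv)
        P = np.real(P)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        P = np.stack([scipy.linalg.expm(q.matrix * t) for t in ts])
    P = np.clip(P, 0.0, 1.0)
    # renormalize tiny numerical drift
    P /= P.sum(axis=2, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


def _tip_state_vector(tree: Phylogeny, states, state_labels) -> np.ndarray:
    """Integer state per tip, raising if any tip is missing."""
    mapping = states.states if hasattr(states, "states") else dict(states)
    missing = [t for t in tree.tip_labels if t not in mapping]
    if missing:
        raise KeyError(f"tips without a state: {missing}")
    lut = {s: i for i, s in enumerate(state_labels)}
    bad = sorted({mapping[t] for t in tree.tip_labels} - set(state_labels))
    if bad:
        raise KeyError(f"tip states not in state set {list(state_labels)}: {bad}")
    return np.asarray([lut[mapping[t]] for t in tree.tip_labels], dtype=np.int64)


def _partials(tree: Phylogeny, tip_idx: np.ndarray, P: np.ndarray, K: int):
    """Down-pass conditional likelihoods with per-node scaling.

    Returns (F, logscale) where F[node] is the scaled conditional likelihood
    of the data below *node* given its state, and logscale the summed log
    scaling factors.
    """
    F = np.zeros((tree.n_nodes, K))
    F[np.arange(tree.n_tips), tip_idx] = 1.0
    logscale = 0.0
    for node in tree.postorder:
        if node < tree.n_tips:
            continue
        f = np.ones(K)
        for c in tree.children[node]:
            f = f * (P[c] @ F[c])
        s = f.max()
        if s <= 0:
            raise FloatingPointError("zero likelihood at internal node")
        F[node] = f / s
        logscale += np.log(s)
    return F, logscale


def _edge_P(tree: Phylogeny, q: QMatrix) -> np.ndarray:
    P = transition_matrices(q, tree.edge_length)
    # zero-length edges (incl. the root's dummy entry) get the identity
    zero = tree.edge_length <= 0
    if zero.any():
        P[zero] = np.eye(q.k)
    return P


def mk_log_likelihood(tree: Phylogeny, states, q: QMatrix, root_prior=None) -> float:
    """Log-probability of the tip states under Q (Felsenstein pruning)."""
    K = q.k
    prior = _resolve_prior(root_prior, q)
    tip_idx = _tip_state_vector(tree, states, q.states)
    P = _edge_P(tree, q)
    F, logscale = _partials(tree, tip_idx, P, K)
    like = float(prior @ F[tree.root])
    if like <= 0:
        return -np.inf
    return np.log(like) + logscale


def _resolve_prior(root_prior, q: QMatrix) -> np.ndarray:
    if root_prior is None or (isinstance(root_prior, str) and root_prior == "flat"):
        return np.full(q.k, 1.0 / q.k)
    if isinstance(root_prior, str):
        if root_prior == "stationary":
            return q.stationary_distribution()
        raise ValueError(f"unknown root prior policy {root_prior!r}")
    p = np.asarray(root_prior, dtype=float)
    if p.shape != (q.k,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("root prior must be a probability vector over the states")
    return p


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_mk(
    tree: Phylogeny,
    states,
    model: str = "ARD",
    root_prior="flat",
    n_starts: int = 10,
    seed: int = 0,
    state_labels=None,
    tol: float = 1e-8,
) -> MkFit:
    """Maximum-likelihood Mk fit under the ER/SYM/ARD constraint.

    Optimizes log-rates with L-BFGS-B from ``n_starts`` log-uniform random
    start points (plus one data-informed start at the parsimony-rate
    heuristic), keeping the best optimum.
    """
    mapping = states.states if hasattr(states, "states") else dict(states)
    if state_labels is None:
        state_labels = tuple(sorted({mapping[t] for t in tree.tip_labels}))
    if len(state_labels) < 2:
        raise ValueError("need at least 2 observed states to fit a rate matrix")
    K = len(state_labels)
    tip_idx = _tip_state_vector(tree, mapping, state_labels)
    n_par = n_free_rates(K, model)
    rng = np.random.default_rng(seed)

    def neg_lnl(log_rates):
        q = QMatrix.from_rates(state_labels, np.exp(log_rates), model)
        prior = _resolve_prior(root_prior, q)
        P = _edge_P(tree, q)
        try:
            F, logscale = _partials(tree, tip_idx, P, K)
        except FloatingPointError:
            return 1e10
        like = float(prior @ F[tree.root])
        if like <= 0 or not np.isfinite(like):
            return 1e10
        return -(np.log(like) + logscale)

    # data-informed central rate: minimum state changes per unit tree length
    n_changes = max(1, len(set(tip_idx)) - 1)
    base = n_changes / max(tree.total_length, 1e-12)
    starts = [np.full(n_par, np.log(base))]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.log(base) + rng.uniform(-3.0, 3.0, size=n_par))

    bounds = [(np.log(RATE_LOWER), np.log(RATE_UPPER))] * n_par
    best = None
    n_ok = 0
    for x0 in starts:
        res = scipy.optimize.minimize(
            neg_lnl, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "maxiter": 2000},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    if best is None:
        raise RuntimeError(f"Mk optimization failed from all {len(starts)} starts")
    q = QMatrix.from_rates(state_labels, np.exp(best.x), model)
    prior = _resolve_prior(root_prior, q)
    data_hash = hash((tuple(tree.tip_labels), tuple(tip_idx), tuple(state_labels)))
    return MkFit(
        model=model, q=q, lnl=-float(best.fun), k=n_par, root_prior=prior,
        converged=bool(best.success), n_restarts=n_ok, data_hash=data_hash,
    )


def select_model(fits) -> ModelComparison:
    """AIC model choice among Mk fits of the same data."""
    return ModelComparison(fits=list(fits))


# ---------------------------------------------------------------------------
# marginal ancestral states
# ---------------------------------------------------------------------------


def marginal_ancestral_states(tree: Phylogeny, states, q: QMatrix, root_prior=None):
    """Marginal posterior state probabilities at every node given all tips.

    Down pass computes subtree conditionals F; up pass propagates the
    complementary ("rest of tree") message A; the node marginal is the
    normalized elementwise product A*F.

    Returns an (n_nodes, K) array indexed like the tree's nodes.
    """
    K = q.k
    prior = _resolve_prior(root_prior, q)
    tip_idx = _tip_state_vector(tree, states, q.states)
    P = _edge_P(tree, q)
    F, _ = _partials(tree, tip_idx, P, K)

    # messages from each child into its parent, cached for sibling products
    up_msg = np.zeros((tree.n_nodes, K))
    for node in tree.postorder:
        if tree.parent[node] >= 0:
            up_msg[node] = P[node] @ F[node]

    A = np.zeros((tree.n_nodes, K))
    A[tree.root] = prior
    for node in tree.preorder:
        kids = tree.children[node]
        for c in kids:
            m = A[node].copy()
            for s in kids:
                if s != c:
                    m = m * up_msg[s]
            ac = P[c].T @ m
            tot = ac.sum()
            if tot <= 0:
                raise FloatingPointError("zero marginal message")
            A[c] = ac / tot

    post = A * F
    post /= post.sum(axis=1, keepdims=True)
    return post


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class MkModel(BaseEstimator):
    """Mk discrete-character model as a fit/predict estimator.

    Parameters
    ----------
    model : {"ER", "SYM", "ARD", "auto"}
        Rate-matrix constraint; ``"auto"`` fits all three and keeps the one
        with minimal AIC.
    root_prior : "flat", "stationary" or probability vector
    n_starts, seed, tol : optimizer controls (multi-start L-BFGS-B on
        log-rates).

    Attributes
    ----------
    q_ : QMatrix                  fitted rate matrix
    lnl_, aic_ : float            log-likelihood and AIC of the kept fit
    fit_ : MkFit                  full fit record
    comparison_ : ModelComparison (only when ``model="auto"``)
    """

    def __init__(self, model="ARD", root_prior="flat", n_starts=10, seed=0, tol=1e-8):
        self.model = model
        self.root_prior = root_prior
        self.n_starts = n_starts
        self.seed = seed
        self.tol = tol

    def fit(self, tree: Phylogeny, states, state_labels=None):
        if self.model == "auto":
            fits = [
                fit_mk(tree, states, m, self.root_prior, self.n_starts, self.seed,
                       state_labels, self.tol)
                for m in MODELS
            ]
            self.comparison_ = select_model(fits)
            self.fit_ = self.comparison_.best
        else:
            self.fit_ = fit_mk(tree, states, self.model, self.root_prior,
                               self.n_starts, self.seed, state_labels, self.tol)
        self.q_ = self.fit_.q
        self.lnl_ = self.fit_.lnl
        self.aic_ = self.fit_.aic
        self._tree = tree
        self._states = states
        return self

    def predict_ancestral(self, tree=None, states=None):
        """Marginal ancestral state probabilities under the fitted Q."""
        tree = tree if tree is not None else self._tree
        states = states if states is not None else self._states
        return marginal_ancestral_states(tree, states, self.q_, self.fit_.root_prior)

    def score(self, tree: Phylogeny, states) -> float:
        return mk_log_likelihood(tree, states, self.q_, self.fit_.root_prior)
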