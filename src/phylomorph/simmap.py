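"""Bayesian stochastic character mapping.

Samples complete character histories (a piecewise-constant state path on
every branch) conditioned on observed tip states and a Q-matrix: node states
are drawn root-to-tips from their joint conditional distribution, then each
branch path is filled in by endpoint-conditioned sampling via uniformization.
Summaries deliver per-node state frequencies, mean realized transition
counts, and counts of independent origins of a focal state.

A naive rejection sampler (forward simulation until the endpoint matches) is
provided as an independent oracle for the uniformization path sampler; it is
never used in the pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mk import QMatrix, _edge_P, _partials, _resolve_prior, _tip_state_vector
from .tree import Phylogeny

__all__ = [
    "CharacterHistory",
    "MapSummary",
    "sample_history",
    "sample_histories",
    "count_transitions",
    "count_origins",
    "summarize_maps",
    "rejection_sample_path",
]

_MAX_UNIFORMIZATION_JUMPS = 100_000


@dataclass
class CharacterHistory:
    """One realized history: state segments per edge plus node states.

    ``paths[node]`` lists ``(state_index, dwell_time)`` segments on the edge
    above *node*, ordered parent-to-child; the root has an empty path.
    """

    tree: Phylogeny
    states: tuple
    node_states: np.ndarray  # int state index per node
    paths: list  # list of [(state, dwell), ...] per node

    def validate(self, atol: float = 1e-9):
        for node in range(self.tree.n_nodes):
            if node == self.tree.root:
                continue
            path = self.paths[node]
            total = sum(d for _, d in path)
            blen = self.tree.edge_length[node]
            if abs(total - blen) > max(atol, atol * max(blen, 1.0)):
                raise ValueError(f"edge {node}: dwell times sum to {total}, branch {blen}")
            if path:
                if path[0][0] != self.node_states[self.tree.parent[node]]:
                    raise ValueError(f"edge {node}: first segment disagrees with parent state")
                if path[-1][0] != self.node_states[node]:
                    raise ValueError(f"edge {node}: last segment disagrees with child state")

    def dwell_times(self) -> np.ndarray:
        """Total time spent in each state across the whole tree."""
        out = np.zeros(len(self.states))
        for path in self.paths:
            for s, d in path:
                out[s] += d
        return out


@dataclass
class MapSummary:
    n_maps: int
    states: tuple
    node_state_freq: np.ndarray  # (n_nodes, K)
    mean_transition_counts: np.ndarray  # (K, K)
    mean_origins: np.ndarray  # per-state mean number of gains
    origin_locations: pd.DataFrame  # edge (child node id) -> gain frequency per state

    def node_frequencies_frame(self, tree: Phylogeny) -> pd.DataFrame:
        df = pd.DataFrame(self.node_state_freq, columns=list(self.states))
        df.insert(0, "node", np.arange(tree.n_nodes))
        df.insert(1, "is_tip", df["node"] < tree.n_tips)
        return df


def _sample_node_states(tree, tip_idx, P, F, prior, rng) -> np.ndarray:
    """Joint draw of all node states given tips (root-to-tips)."""
    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    node_states[: tree.n_tips] = tip_idx
    for node in tree.preorder:
        if node < tree.n_tips:
            continue
        if node == tree.root:
            w = prior * F[node]
        else:
            i = node_states[tree.parent[node]]
            w = P[node][i] * F[node]
        tot = w.sum()
        if tot <= 0:
            raise FloatingPointError(f"zero conditional at node {node}")
        node_states[node] = rng.choice(len(w), p=w / tot)
    return node_states


def _uniformized_path(Q, P_t, a, b, t, rng):
    """Endpoint-conditioned CTMC path on one branch via uniformization.

    Returns [(state, dwell), ...] from *a* (at the parent) to *b* (at the
    child), dwell times summing to *t*.
    """
    K = Q.shape[0]
    omega = float(-Q.diagonal().min())
    if omega <= 0 or t <= 0:
        if a != b:
            raise ValueError("state change required on a zero-rate or zero-length branch")
        return [(int(a), float(t))]
    R = np.eye(K) + Q / omega
    p_ab = P_t[a, b]
    if p_ab <= 0:
        raise ValueError(f"impossible endpoint pair {a}->{b} on branch of length {t}")

    # sample number of dominated-chain jumps N | a, b
    u = rng.random()
    cum = 0.0
    Rn = np.eye(K)  # R^n
    R_powers = [Rn]
    n = 0
    log_pois = -omega * t  # log Poisson(omega t) pmf at n=0, built incrementally
    while True:
        term = np.exp(log_pois) * Rn[a, b] / p_ab
        cum += term
        if u <= cum:
            break
        n += 1
        if n > _MAX_UNIFORMIZATION_JUMPS:
            raise RuntimeError("uniformization failed to converge")
        log_pois += np.log(omega * t) - np.log(n)
        Rn = Rn @ R
        R_powers.append(Rn)

    if n == 0:
        return [(int(a), float(t))]
    # jump times: order statistics of n uniforms on (0, t)
    times = np.sort(rng.random(n)) * t
    # chain states at jumps, forward draw weighted by remaining steps to b
    chain = [a]
    for k in range(1, n):
        w = R[chain[-1], :] * R_powers[n - k][:, b]
        tot = w.sum()
        chain.append(int(rng.choice(K, p=w / tot)))
    chain.append(b)
    # collapse virtual (self) transitions into dwell segments
    segs = []
    seg_state, seg_start = chain[0], 0.0
    for k in range(1, n + 1):
        if chain[k] != seg_state:
            segs.append((int(seg_state), float(times[k - 1] - seg_start)))
            seg_state, seg_start = chain[k], times[k - 1]
    segs.append((int(seg_state), float(t - seg_start)))
    return segs


def sample_history(tree: Phylogeny, states, q: QMatrix, root_prior=None, seed=0,
                   rng=None) -> CharacterHistory:
    """Draw one character history from P(history | tips, Q)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    prior = _resolve_prior(root_prior, q)
    tip_idx = _tip_state_vector(tree, states, q.states)
    P = _edge_P(tree, q)
    F, _ = _partials(tree, tip_idx, P, q.k)
    node_states = _sample_node_states(tree, tip_idx, P, F, prior, rng)
    paths: list = [[] for _ in range(tree.n_nodes)]
    for node in range(tree.n_nodes):
        if node == tree.root:
            continue
        a = node_states[tree.parent[node]]
        b = node_states[node]
        t = float(tree.edge_length[node])
        if t <= 0:
            if a != b:
                raise ValueError(f"zero-length edge {node} with differing endpoints")
            paths[node] = [(int(a), 0.0)]
        else:
            paths[node] = _uniformized_path(q.matrix, P[node], int(a), int(b), t, rng)
    return CharacterHistory(tree=tree, states=q.states, node_states=node_states, paths=paths)


def sample_histories(tree, states, q, n_maps=1000, root_prior=None, seed=0) -> list:
    """Draw *n_maps* independent histories (one RNG stream, seeded)."""
    rng = np.random.default_rng(seed)
    return [sample_history(tree, states, q, root_prior, rng=rng) for _ in range(n_maps)]


def count_transitions(history: CharacterHistory) -> np.ndarray:
    """Realized i->j change counts across all edges (diagonal zero)."""
    K = len(history.states)
    counts = np.zeros((K, K), dtype=np.int64)
    for path in history.paths:
        for k in range(1, len(path)):
            counts[path[k - 1][0], path[k][0]] += 1
    return counts


def count_origins(history: CharacterHistory, focal) -> int:
    """Number of independent gains of the focal state (one per entry event)."""
    f = history.states.index(focal) if not isinstance(focal, (int, np.integer)) else int(focal)
    n = 0
    for path in history.paths:
        for k in range(1, len(path)):
            if path[k][0] == f and path[k - 1][0] != f:
                n += 1
    return n


def _edge_gains(history: CharacterHistory) -> np.ndarray:
    """(n_nodes, K) indicator: does the edge above each node gain state k?"""
    K = len(history.states)
    out = np.zeros((history.tree.n_nodes, K), dtype=bool)
    for node, path in enumerate(history.paths):
        for k in range(1, len(path)):
            if path[k][0] != path[k - 1][0]:
                out[node, path[k][0]] = True
    return out


def summarize_maps(histories, origin_report_threshold: float = 0.5) -> MapSummary:
    """Frequencies and means over a set of histories on one tree."""
    if not histories:
        raise ValueError("need at least one history")
    tree = histories[0].tree
    states = histories[0].states
    for h in histories[1:]:
        if h.tree.n_nodes != tree.n_nodes or h.tree.tip_labels != tree.tip_labels:
            raise ValueError("histories were sampled on different trees")
        if h.states != states:
            raise ValueError("histories use different state sets")
    K = len(states)
    n = len(histories)
    freq = np.zeros((tree.n_nodes, K))
    trans = np.zeros((K, K))
    origins = np.zeros(K)
    gains = np.zeros((tree.n_nodes, K))
    for h in histories:
        freq[np.arange(tree.n_nodes), h.node_states] += 1.0
        c = count_transitions(h)
        trans += c
        origins += c.sum(axis=0)  # gain events into each state
        gains += _edge_gains(h)
    freq /= n
    gains /= n
    rows = []
    for node in range(tree.n_nodes):
        for k in range(K):
            if gains[node, k] >= origin_report_threshold:
                rows.append({"edge": node, "state": states[k], "gain_frequency": gains[node, k]})
    return MapSummary(
        n_maps=n,
        states=states,
        node_state_freq=freq,
        mean_transition_counts=trans / n,
        mean_origins=origins / n,
        origin_locations=pd.DataFrame(rows, columns=["edge", "state", "gain_frequency"]),
    )


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------


def rejection_sample_path(Q, a, b, t, rng, max_tries=1_000_000):
    """Endpoint-conditioned path by forward simulation with rejection.

    Independent oracle for :func:`sample_history`'s uniformization sampler:
    simulates the unconditioned chain from state *a* for time *t* and rejects
    until it lands in *b*.
    """
    Q = np.asarray(Q, dtype=float)
    K = Q.shape[0]
    for _ in range(max_tries):
        segs = []
        s, elapsed = int(a), 0.0
        while True:
            rate = -Q[s, s]
            wait = np.inf if rate <= 0 else rng.exponential(1.0 / rate)
            if elapsed + wait >= t:
                segs.append((s, t - elapsed))
                break
            segs.append((s, wait))
            elapsed += wait
            p = Q[s].copy()
            p[s] = 0.0
            s = int(rng.choice(K, p=p / p.sum()))
        if segs[-1][0] == b:
            return segs
    raise RuntimeError("rejection sampler exceeded max_tries")
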