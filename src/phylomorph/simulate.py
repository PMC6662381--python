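"""Synthetic data generators emulating the study's data structure.

Every analysis stage in this package can be exercised without museum or
repository downloads: pure-birth (Yule) chronograms, discrete characters
evolved under an arbitrary Q-matrix (with the true history retained for
recovery tests), multivariate Brownian traits with state-dependent rates, a
convergent-attraction regime for focal tips, foot-like landmark datasets,
and linear measurement tables with allometry and missing entries.

All generators are pure functions of their seed: identical seeds give
bit-identical output.

Default scales mirror the study system: chronogram heights of ~200 Myr
(the order of the salamander root age), six microhabitat states, trait
dimensionality 6 (log shape ratios) or 42 (21 landmarks x 2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .morpho import MEASUREMENT_VARS, LandmarkConfiguration
from .simmap import CharacterHistory
from .tree import Phylogeny

__all__ = [
    "simulate_yule_tree",
    "simulate_discrete_character",
    "paint_clade_history",
    "simulate_multivariate_bm",
    "simulate_convergent_traits",
    "foot_template",
    "generate_landmark_dataset",
    "generate_measurement_table",
]

DEFAULT_TREE_HEIGHT = 200.0  # Myr; order of the salamander chronogram root age


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0,
                       height: float | None = 1.0) -> Phylogeny:
    """Ultrametric pure-birth tree with *n_tips*, optionally rescaled.

    ``height=None`` keeps the raw coalescent-of-births depth; the default
    rescales the tree to unit height (pass e.g. ``height=200.0`` for a
    chronogram-like time scale).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    # grow forward in time; each open lineage splits at rate birth_rate
    n_nodes = 2 * n_tips - 1
    t = 0.0
    all_lineages = [{"start": 0.0, "parent": None}]
    open_lineages = [0]
    while len(open_lineages) < n_tips:
        k = len(open_lineages)
        t += rng.exponential(1.0 / (birth_rate * k))
        which = open_lineages[rng.integers(k)]
        all_lineages[which]["end"] = t
        for _ in range(2):
            all_lineages.append({"start": t, "parent": which})
            open_lineages.append(len(all_lineages) - 1)
        open_lineages.remove(which)
    # run the n surviving lineages for one more waiting time so the newest
    # split does not sit exactly at the present
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for i in open_lineages:
        all_lineages[i]["end"] = t_end
    open_set = set(open_lineages)
    tips = sorted(open_set)
    internals = [i for i in range(len(all_lineages)) if i not in open_set]
    node_of = {lin_id: node_id for node_id, lin_id in enumerate(tips)}
    # reverse creation order puts lineage 0 (the root) at the last node index
    for offset, lin_id in enumerate(sorted(internals, reverse=True)):
        node_of[lin_id] = n_tips + offset
    parent = np.full(n_nodes, -1, dtype=np.int64)
    elen = np.zeros(n_nodes)
    for lin_id, lin in enumerate(all_lineages):
        node = node_of[lin_id]
        if lin["parent"] is not None:
            parent[node] = node_of[lin["parent"]]
            elen[node] = lin["end"] - lin["start"]
    labels = [f"t{i+1}" for i in range(n_tips)]
    tree = Phylogeny(parent, elen, labels)
    if height is not None:
        tree = tree.rescale(height)
    return tree


def simulate_discrete_character(tree: Phylogeny, q, root=None, seed: int = 0,
                                rng=None):
    """Forward CTMC simulation of a discrete character along the tree.

    *root* may be a state label, a state index, or None (drawn uniformly).
    Returns ``(tip_states, history)`` where *tip_states* maps tip label to
    state label and *history* is the full true :class:`CharacterHistory`.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    Q = q.matrix
    K = q.k
    if root is None:
        root_state = int(rng.integers(K))
    elif isinstance(root, (int, np.integer)):
        root_state = int(root)
    else:
        root_state = q.states.index(root)
    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    node_states[tree.root] = root_state
    paths: list = [[] for _ in range(tree.n_nodes)]
    for node in tree.preorder:
        if node == tree.root:
            continue
        s = int(node_states[tree.parent[node]])
        t_total = float(tree.edge_length[node])
        segs = []
        elapsed = 0.0
        while True:
            rate = -Q[s, s]
            wait = np.inf if rate <= 0 else rng.exponential(1.0 / rate)
            if elapsed + wait >= t_total:
                segs.append((s, t_total - elapsed))
                break
            segs.append((s, wait))
            elapsed += wait
            w = Q[s].copy()
            w[s] = 0.0
            s = int(rng.choice(K, p=w / w.sum()))
        paths[node] = segs
        node_states[node] = s
    history = CharacterHistory(tree=tree, states=q.states, node_states=node_states,
                               paths=paths)
    tip_states = {tree.tip_labels[i]: q.states[node_states[i]] for i in range(tree.n_tips)}
    return tip_states, history


def paint_clade_history(tree: Phylogeny, states=("bg", "fg"), min_fraction: float = 0.25,
                        max_fraction: float = 0.5, seed: int = 0):
    """Two-state history with one monophyletic foreground regime.

    Picks (uniformly) an internal node whose clade holds between
    *min_fraction* and *max_fraction* of the tips; every branch inside the
    clade carries the foreground state, all others the background state.
    Because tip membership matches branch history exactly, this is the clean
    construction for state-dependent-rate simulations.

    Returns ``(history, tip_states)``.
    """
    rng = np.random.default_rng(seed)
    desc = tree.descendant_tips()
    cands = [n for n in range(tree.n_tips, tree.n_nodes)
             if min_fraction <= len(desc[n]) / tree.n_tips <= max_fraction]
    if not cands:
        raise ValueError("no clade in the requested size range")
    node = cands[rng.integers(len(cands))]
    inside_tips = set(desc[node].tolist())
    in_clade = np.zeros(tree.n_nodes, dtype=bool)
    in_clade[node] = True
    for m in tree.preorder:
        p = tree.parent[m]
        if p >= 0 and in_clade[p]:
            in_clade[m] = True
    node_states = in_clade.astype(np.int64)
    paths: list = [[] for _ in range(tree.n_nodes)]
    for m in range(tree.n_nodes):
        if m == tree.root:
            continue
        s = int(node_states[m])
        ps = int(node_states[tree.parent[m]])
        blen = float(tree.edge_length[m])
        if ps == s:
            paths[m] = [(s, blen)]
        else:
            # the regime switch sits at the top of the clade's stem branch
            paths[m] = [(ps, 0.0), (s, blen)]
    history = CharacterHistory(tree=tree, states=tuple(states),
                               node_states=node_states, paths=paths)
    tip_states = {tree.tip_labels[i]: states[1 if i in inside_tips else 0]
                  for i in range(tree.n_tips)}
    return history, tip_states


def _edge_state_durations(tree: Phylogeny, history, states) -> np.ndarray:
    """(n_nodes, K) time spent in each state on the edge above each node."""
    K = len(states)
    out = np.zeros((tree.n_nodes, K))
    for node, path in enumerate(history.paths):
        for s, d in path:
            out[node, s] += d
    return out


def simulate_multivariate_bm(tree: Phylogeny, p: int = 6, rate=1.0, seed: int = 0,
                             history=None, rate_by_state=None, rng=None,
                             root_value=None) -> pd.DataFrame:
    """Multivariate Brownian traits, optionally with state-dependent rates.

    With *history* and *rate_by_state* given, each branch segment
    contributes Gaussian increments with variance (segment duration x rate
    of the segment's state); otherwise a single *rate* applies everywhere.
    Returns a species-indexed (n_tips, p) DataFrame.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if history is not None:
        if rate_by_state is None:
            raise ValueError("rate_by_state required with a history")
        if history.tree.n_nodes != tree.n_nodes or history.tree.tip_labels != tree.tip_labels:
            raise ValueError("history was simulated on a different tree")
        rates = np.asarray([rate_by_state[s] for s in history.states], dtype=float)
        if np.any(rates < 0):
            raise ValueError("rates must be nonnegative")
        dur = _edge_state_durations(tree, history, history.states)
        edge_var = dur @ rates
    else:
        edge_var = tree.edge_length * float(rate)
    values = np.zeros((tree.n_nodes, p))
    if root_value is not None:
        values[tree.root] = np.asarray(root_value, dtype=float)
    for node in tree.preorder:
        if node == tree.root:
            continue
        sd = np.sqrt(edge_var[node])
        values[node] = values[tree.parent[node]] + sd * rng.standard_normal(p)
    return pd.DataFrame(values[: tree.n_tips], index=tree.tip_labels,
                        columns=[f"x{i+1}" for i in range(p)])


def simulate_convergent_traits(tree: Phylogeny, focal, attractor, strength: float,
                               base_rate: float = 1.0, p: int | None = None,
                               seed: int = 0, n_steps_per_height: int = 100) -> pd.DataFrame:
    """Brownian traits with attraction toward a point on focal-only branches.

    Branches whose descendant tips are all focal follow an Euler-discretized
    OU pull toward *attractor* with the given *strength* (per Myr); all
    other branches evolve by pure BM. ``strength=0`` reduces exactly to
    :func:`simulate_multivariate_bm`.
    """
    if strength < 0:
        raise ValueError("strength must be nonnegative")
    attractor = np.atleast_1d(np.asarray(attractor, dtype=float))
    if p is None:
        p = attractor.size
    rng = np.random.default_rng(seed)
    focal_idx = set(tree.tip_index(focal).tolist())
    desc = tree.descendant_tips()
    focal_edge = np.zeros(tree.n_nodes, dtype=bool)
    for node in range(tree.n_nodes):
        if node != tree.root:
            focal_edge[node] = set(desc[node].tolist()) <= focal_idx
    dt_max = tree.height / n_steps_per_height
    values = np.zeros((tree.n_nodes, p))
    for node in tree.preorder:
        if node == tree.root:
            continue
        x = values[tree.parent[node]].copy()
        t = float(tree.edge_length[node])
        if not focal_edge[node] or strength == 0.0:
            x = x + np.sqrt(base_rate * t) * rng.standard_normal(p)
        else:
            # exact OU-toward-point transition per step (stable for any
            # strength; reduces to BM increments as strength -> 0)
            n_steps = max(1, int(np.ceil(t / dt_max)))
            dt = t / n_steps
            decay = np.exp(-strength * dt)
            sd = np.sqrt(base_rate * (1.0 - decay**2) / (2.0 * strength))
            for _ in range(n_steps):
                x = attractor + (x - attractor) * decay + sd * rng.standard_normal(p)
        values[node] = x
    return pd.DataFrame(values[: tree.n_tips], index=tree.tip_labels,
                        columns=[f"x{i+1}" for i in range(p)])


# ---------------------------------------------------------------------------
# landmark and measurement data
# ---------------------------------------------------------------------------


def foot_template() -> LandmarkConfiguration:
    """A synthetic five-toed foot: 11 landmarks + 10 semilandmarks.

    Landmarks 0-4 are toe tips, 5-8 the webbing minima between adjacent
    toes, 9-10 the ankle corners. Semilandmarks 11-20 flank each toe tip in
    anterior/posterior pairs; each slides along the chord between its toe's
    webbing (or ankle) brackets. This stand-in is generated, not digitized
    from specimens.
    """
    toe_x = np.linspace(-1.0, 1.0, 5)
    toe_len = np.array([0.8, 1.1, 1.3, 1.1, 0.8])
    tips = np.column_stack([toe_x, toe_len])
    web_x = (toe_x[:-1] + toe_x[1:]) / 2
    webs = np.column_stack([web_x, 0.25 * np.ones(4)])
    ankle = np.array([[-1.1, -0.5], [1.1, -0.5]])
    landmarks = np.vstack([tips, webs, ankle])
    semis = []
    neighbors = {}
    brackets = [(9, 5), (5, 6), (6, 7), (7, 8), (8, 10)]  # flanks of each toe
    for toe in range(5):
        left, right = brackets[toe]
        tip = tips[toe]
        offs = np.array([[-0.12, -0.15], [0.12, -0.15]])
        for side, off in enumerate(offs):
            idx = 11 + 2 * toe + side
            semis.append(tip + off)
            neighbors[idx] = (left, toe) if side == 0 else (toe, right)
    coords = np.vstack([landmarks, np.asarray(semis)])
    return LandmarkConfiguration(
        specimen="template", species="template", coords=coords,
        semilandmarks=tuple(range(11, 21)), neighbors=neighbors,
    )


def generate_landmark_dataset(template: LandmarkConfiguration | None = None,
                              n_species: int = 20, n_per_species: int = 5,
                              species_sd: float = 0.05, noise: float = 0.02,
                              missing_fraction: float = 0.0, seed: int = 0,
                              tree: Phylogeny | None = None,
                              bm_rate: float = 0.0025) -> list:
    """Specimens as similarity-transformed, noisy copies of species shapes.

    Species mean shapes deviate from the template by independent Gaussian
    perturbations (or by BM on *tree* when given); each specimen adds
    isotropic digitizing noise and a random rotation/translation/scale; a
    *missing_fraction* of points is masked (NaN), never more than 6 per
    specimen.
    """
    if template is None:
        template = foot_template()
    rng = np.random.default_rng(seed)
    n_pts = template.coords.shape[0]
    if tree is not None:
        n_species = tree.n_tips
        dev = simulate_multivariate_bm(tree, p=2 * n_pts, rate=bm_rate,
                                       rng=rng).to_numpy().reshape(n_species, n_pts, 2)
        names = list(tree.tip_labels)
    else:
        dev = species_sd * rng.standard_normal((n_species, n_pts, 2))
        names = [f"sp{i+1}" for i in range(n_species)]
    out = []
    for si, name in enumerate(names):
        mean_shape = template.coords + dev[si]
        for k in range(n_per_species):
            pts = mean_shape + noise * rng.standard_normal((n_pts, 2))
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            scale = np.exp(rng.normal(0, 0.2))
            shift = rng.normal(0, 2.0, size=2)
            pts = scale * pts @ R.T + shift
            if missing_fraction > 0:
                mask = rng.random(n_pts) < missing_fraction
                if mask.sum() > 6:
                    mask[np.flatnonzero(mask)[6:]] = False
                pts[mask] = np.nan
            out.append(LandmarkConfiguration(
                specimen=f"{name}_{k+1}", species=name, coords=pts,
                semilandmarks=template.semilandmarks, neighbors=template.neighbors,
            ))
    return out


DEFAULT_ALLOMETRY = {
    # coefficient, exponent on SVL; chosen to look like salamander proportions
    "TL": (0.9, 1.05), "HL": (0.25, 0.95), "BW": (0.15, 1.0),
    "SE": (0.08, 0.9), "FLL": (0.28, 1.0), "HLL": (0.3, 1.0),
}


def generate_measurement_table(n_species: int = 50, n_per_species: int = 10,
                               allometry: dict | None = None, noise: float = 0.05,
                               missing_fraction: float = 0.02, seed: int = 0,
                               svl_mean_log: float = np.log(45.0),
                               svl_sd_log: float = 0.4) -> pd.DataFrame:
    """Specimen linear-measurement table with allometry and missing cells.

    SVL is lognormal across species; every other variable is
    ``coefficient * SVL^exponent`` times lognormal noise. A
    *missing_fraction* of non-SVL cells is masked at random (SVL is never
    fully removed from a specimen).
    """
    if allometry is None:
        allometry = DEFAULT_ALLOMETRY
    for v, (c, e) in allometry.items():
        if c <= 0:
            raise ValueError(f"allometry coefficient for {v} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_species):
        sp = f"sp{si+1}"
        sp_svl = np.exp(rng.normal(svl_mean_log, svl_sd_log))
        for k in range(n_per_species):
            svl = sp_svl * np.exp(rng.normal(0, noise))
            row = {"specimen": f"{sp}_{k+1}", "species": sp, "SVL": svl}
            for v in MEASUREMENT_VARS[1:]:
                c, e = allometry[v]
                row[v] = c * svl**e * np.exp(rng.normal(0, noise))
            rows.append(row)
    df = pd.DataFrame(rows)
    if missing_fraction > 0:
        maskable = [v for v in MEASUREMENT_VARS if v != "SVL"]
        vals = df[maskable].to_numpy()
        mask = rng.random(vals.shape) < missing_fraction
        vals[mask] = np.nan
        df[maskable] = vals
    return df
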