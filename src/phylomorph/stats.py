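"""Group-structured phylogenetic comparative statistics.

All tests share one GLS backbone: under Brownian motion the tip values have
covariance proportional to the shared-path-length matrix C, so data are
analyzed after transformation by C^{-1/2} (equivalently, weighted by the
tree). On a star tree every statistic here reduces to its ordinary
non-phylogenetic counterpart.

Implemented tests:

* phylogenetic ANOVA with residual-randomization permutation (RRPP) and
  pairwise distances between GLS group means;
* the multivariate Brownian rate sigma^2_mult and its between-group
  comparison by BM simulation;
* the convergence measures C1 (proportional reduction of current distance
  between focal taxa relative to their maximal ancestral distance) and C5
  (number of lineages whose path through morphospace enters the convex hull
  of the focal taxa), both with BM-simulation p-values;
* the allometric-convergence permutation test (do two groups' predicted
  shapes approach each other along a shared size axis?).

Permutation and simulation p-values all use the (1 + exceedances) /
(1 + draws) convention and are reproducible given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial import ConvexHull, QhullError

from .tree import Phylogeny, phylo_covariance, prune_to_taxa

__all__ = [
    "GroupedTraitMatrix",
    "AnovaResult",
    "PairwiseResult",
    "RateComparisonResult",
    "ConvergenceResult",
    "AllometryConvergenceResult",
    "ancestral_states_bm",
    "node_covariance",
    "phylogenetic_anova",
    "pairwise_group_distances",
    "sigma_mult",
    "compare_rates_by_group",
    "convergence_c1",
    "convergence_c5",
    "allometric_convergence",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GroupedTraitMatrix:
    """Species-by-trait matrix with a group label (and optional size) per species."""

    species: list
    Y: np.ndarray
    group: np.ndarray
    size: np.ndarray | None = None

    def __post_init__(self):
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.group = np.asarray(self.group)
        if len(self.species) != self.Y.shape[0] or len(self.group) != self.Y.shape[0]:
            raise ValueError("species, Y and group must agree in length")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("trait matrix contains non-finite values")
        if self.size is not None:
            self.size = np.asarray(self.size, dtype=float)

    @classmethod
    def from_frames(cls, traits: pd.DataFrame, groups, size=None):
        groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
        common = [s for s in traits.index if s in groups.index]
        Y = traits.loc[common].to_numpy(dtype=float)
        g = groups.loc[common].to_numpy()
        sz = None
        if size is not None:
            size = pd.Series(size) if not isinstance(size, pd.Series) else size
            sz = size.loc[common].to_numpy(dtype=float)
        return cls(species=list(common), Y=Y, group=g, size=sz)

    def subset(self, mask) -> "GroupedTraitMatrix":
        mask = np.asarray(mask)
        return GroupedTraitMatrix(
            species=[s for s, m in zip(self.species, mask) if m],
            Y=self.Y[mask], group=self.group[mask],
            size=None if self.size is None else self.size[mask],
        )


@dataclass
class AnovaResult:
    R2: float
    F: float
    Z: float
    p: float
    n_perm: int
    df_model: int
    df_resid: int


@dataclass
class PairwiseResult:
    groups: list
    distances: pd.DataFrame
    p_values: pd.DataFrame
    n_perm: int


@dataclass
class RateComparisonResult:
    sigma2_by_group: dict
    ratio: float
    p: float
    pairwise_ratios: pd.DataFrame
    pairwise_p: pd.DataFrame
    n_sim: int


@dataclass
class ConvergenceResult:
    C1: float | None = None
    p_C1: float | None = None
    C5: int | None = None
    p_C5: float | None = None
    n_sim: int = 0
    details: dict = field(default_factory=dict)


@dataclass
class AllometryConvergenceResult:
    D_small: float
    D_large: float
    statistic: float
    p: float
    n_perm: int


# ---------------------------------------------------------------------------
# GLS backbone
# ---------------------------------------------------------------------------


def _inv_sqrt(C: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    if w.min() <= tol * w.max():
        raise np.linalg.LinAlgError("phylogenetic covariance is singular")
    return V @ np.diag(1.0 / np.sqrt(w)) @ V.T


class _TreeContext:
    """Cached per-(tree, taxa) GLS machinery."""

    def __init__(self, tree: Phylogeny, taxa):
        taxa = list(taxa)
        if set(taxa) - set(tree.tip_labels):
            missing = sorted(set(taxa) - set(tree.tip_labels))
            raise KeyError(f"species not in tree: {missing}")
        if set(taxa) != set(tree.tip_labels):
            tree = prune_to_taxa(tree, taxa)
        self.tree = tree
        C, order = phylo_covariance(tree, taxa)
        self.taxa = order
        self.C = C
        self.T = _inv_sqrt(C)
        Cinv = self.T @ self.T
        one = np.ones(len(order))
        self.w = Cinv @ one / (one @ Cinv @ one)  # GLS mean weights
        self.L = np.linalg.cholesky(C)


def _align(tree: Phylogeny, data: GroupedTraitMatrix):
    ctx = _TreeContext(tree, data.species)
    order = {s: i for i, s in enumerate(data.species)}
    idx = np.asarray([order[s] for s in ctx.taxa])
    aligned = GroupedTraitMatrix(
        species=list(ctx.taxa), Y=data.Y[idx], group=data.group[idx],
        size=None if data.size is None else data.size[idx],
    )
    return ctx, aligned


def node_covariance(tree: Phylogeny) -> np.ndarray:
    """Shared-path-length (MRCA depth) matrix over *all* nodes of the tree."""
    n = tree.n_nodes
    depth = tree.node_depths()
    desc: list = [None] * n
    for node in tree.postorder:
        if node < tree.n_tips:
            desc[node] = np.asarray([node], dtype=np.int64)
        else:
            desc[node] = np.concatenate([[node]] + [desc[c] for c in tree.children[node]])
    C = np.zeros((n, n))
    for node in tree.postorder:
        if node < tree.n_tips:
            continue
        kids = tree.children[node]
        sets = [desc[c] for c in kids]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                C[np.ix_(sets[a], sets[b])] = depth[node]
                C[np.ix_(sets[b], sets[a])] = depth[node]
        C[node, desc[node]] = depth[node]
        C[desc[node], node] = depth[node]
    np.fill_diagonal(C, depth)
    return C


def _ancestral_operator(tree: Phylogeny):
    """Matrix W (n_internal, n_tips) with anc = W @ Y (ML/GLS states under BM)."""
    n, nt = tree.n_nodes, tree.n_tips
    Call = node_covariance(tree)
    Ctt = Call[:nt, :nt]
    Cit = Call[nt:, :nt]
    Cinv = np.linalg.inv(Ctt)
    one = np.ones(nt)
    w = Cinv @ one / (one @ Cinv @ one)
    # anc = a + Cit Ctt^-1 (Y - 1 a),  a = w' Y
    W = np.outer(np.ones(n - nt), w) + Cit @ Cinv @ (np.eye(nt) - np.outer(one, w))
    return W


def ancestral_states_bm(tree: Phylogeny, Y: np.ndarray) -> np.ndarray:
    """GLS (ML under BM) ancestral trait values for every internal node.

    Rows are ordered by node index ``n_tips .. n_nodes-1``; *Y* rows must
    follow ``tree.tip_labels``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != tree.n_tips:
        raise ValueError("Y must have one row per tip, in tip_labels order")
    return _ancestral_operator(tree) @ Y


# ---------------------------------------------------------------------------
# phylogenetic ANOVA (RRPP)
# ---------------------------------------------------------------------------


def _design(groups: np.ndarray):
    levels = sorted(set(groups.tolist()))
    X = np.zeros((len(groups), len(levels)))
    for j, g in enumerate(levels):
        X[groups == g, j] = 1.0
    return X, levels


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _anova_stats(M_model, M_resid, M_total, Y):
    ss_model = float(np.sum((M_model @ Y) ** 2))
    ss_resid = float(np.sum((M_resid @ Y) ** 2))
    ss_total = float(np.sum((M_total @ Y) ** 2))
    return ss_model, ss_resid, ss_total


def phylogenetic_anova(tree: Phylogeny, data: GroupedTraitMatrix,
                       n_perm: int = 999, seed: int = 0) -> AnovaResult:
    """Multivariate phylogenetic ANOVA of traits on group, with RRPP p-value.

    Data are GLS-transformed by C^{-1/2}; the null distribution permutes
    the reduced-model (intercept-only) residual rows; the effect size Z is
    the standard deviate of log F against that distribution.
    """
    ctx, data = _align(tree, data)
    groups = data.group
    if len(set(groups.tolist())) < 2:
        raise ValueError("need at least 2 groups")
    X, _ = _design(groups)
    N, p = data.Y.shape
    g = X.shape[1]
    T = ctx.T
    Yt = T @ data.Y
    Xt = T @ X
    X0t = T @ np.ones((N, 1))
    H = _hat(Xt)
    H0 = _hat(X0t)
    M_model = H - H0
    M_resid = np.eye(N) - H
    M_total = np.eye(N) - H0

    ss_m, ss_r, ss_t = _anova_stats(M_model, M_resid, M_total, Yt)
    df1, df2 = g - 1, N - g
    F_obs = (ss_m / df1) / (ss_r / df2)
    R2 = ss_m / ss_t if ss_t > 0 else 0.0

    rng = np.random.default_rng(seed)
    fitted0 = H0 @ Yt
    R0 = Yt - fitted0
    logF = [np.log(F_obs)]
    n_ge = 0
    for _ in range(n_perm):
        Ys = fitted0 + R0[rng.permutation(N)]
        sm, sr, _ = _anova_stats(M_model, M_resid, M_total, Ys)
        Fs = (sm / df1) / (sr / df2)
        if Fs >= F_obs:
            n_ge += 1
        logF.append(np.log(max(Fs, 1e-300)))
    logF = np.asarray(logF)
    sd = logF.std()
    Z = (np.log(F_obs) - logF.mean()) / sd if sd > 0 else 0.0
    p = (1 + n_ge) / (1 + n_perm)
    return AnovaResult(R2=R2, F=F_obs, Z=float(Z), p=float(p), n_perm=n_perm,
                       df_model=df1, df_resid=df2)


def pairwise_group_distances(tree: Phylogeny, data: GroupedTraitMatrix,
                             n_perm: int = 999, seed: int = 0) -> PairwiseResult:
    """Euclidean distances between GLS group means with RRPP p-values."""
    ctx, data = _align(tree, data)
    X, levels = _design(data.group)
    N = len(data.species)
    T = ctx.T
    Yt = T @ data.Y
    Xt = T @ X
    X0t = T @ np.ones((N, 1))
    H0 = _hat(X0t)
    fitted0 = H0 @ Yt
    R0 = Yt - fitted0

    def group_means(Y):
        beta, *_ = np.linalg.lstsq(Xt, Y, rcond=None)
        return beta  # (g, p): GLS group means in trait space

    def dists(beta):
        return np.sqrt(((beta[:, None, :] - beta[None, :, :]) ** 2).sum(axis=2))

    D_obs = dists(group_means(Yt))
    rng = np.random.default_rng(seed)
    n_ge = np.zeros_like(D_obs)
    for _ in range(n_perm):
        Ys = fitted0 + R0[rng.permutation(N)]
        n_ge += dists(group_means(Ys)) >= D_obs - 1e-15
    P = (1 + n_ge) / (1 + n_perm)
    np.fill_diagonal(P, 1.0)
    return PairwiseResult(
        groups=levels,
        distances=pd.DataFrame(D_obs, index=levels, columns=levels),
        p_values=pd.DataFrame(P, index=levels, columns=levels),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# evolutionary rates
# ---------------------------------------------------------------------------


def sigma_mult(tree: Phylogeny, Y, species=None) -> float:
    """Multivariate Brownian rate: squared GLS-transformed deviation from the
    phylogenetic mean, summed over species and dimensions, over (N * p)."""
    if isinstance(Y, pd.DataFrame):
        species = list(Y.index)
        Y = Y.to_numpy(dtype=float)
    if species is None:
        species = list(tree.tip_labels)
    ctx = _TreeContext(tree, species)
    idx = {s: i for i, s in enumerate(species)}
    Y = np.atleast_2d(np.asarray(Y, dtype=float))[[idx[s] for s in ctx.taxa]]
    return _rates_from_transformed(_transformed_residuals(ctx, Y))


def _transformed_residuals(ctx: _TreeContext, Y: np.ndarray) -> np.ndarray:
    a = ctx.w @ Y
    return ctx.T @ (Y - a)


def _rates_from_transformed(R: np.ndarray) -> float:
    N, p = R.shape
    return float(np.sum(R**2) / (N * p))


def _group_rates(R: np.ndarray, groups: np.ndarray, levels) -> np.ndarray:
    p = R.shape[1]
    out = np.empty(len(levels))
    for j, g in enumerate(levels):
        mask = groups == g
        out[j] = np.sum(R[mask] ** 2) / (mask.sum() * p)
    return out


def compare_rates_by_group(tree: Phylogeny, data: GroupedTraitMatrix,
                           n_sim: int = 999, seed: int = 0) -> RateComparisonResult:
    """Per-group sigma^2_mult and a simulation test of rate heterogeneity.

    Group rates partition the full-tree transformed residuals (common
    phylogenetic mean) by group. The null distribution of the max/min rate
    ratio comes from BM simulation on the whole tree at the pooled rate,
    preserving the empirical trait covariance.
    """
    counts = pd.Series(data.group).value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"groups with fewer than 2 species excluded: {small}")
        data = data.subset(~np.isin(data.group, small))
    ctx, data = _align(tree, data)
    levels = sorted(set(data.group.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups of size >= 2")
    N, p = data.Y.shape
    R = _transformed_residuals(ctx, data.Y)
    rates = _group_rates(R, data.group, levels)
    ratio_obs = rates.max() / rates.min()
    pw_obs = rates[:, None] / rates[None, :]

    # null: BM at the pooled rate with the empirical evolutionary trait
    # covariance (R'R / N), simulated on the full tree
    Vcv = R.T @ R / N
    S = np.linalg.cholesky(Vcv + 1e-12 * np.trace(Vcv) / p * np.eye(p))
    rng = np.random.default_rng(seed)
    n_ge = 0
    pw_ge = np.zeros((len(levels), len(levels)))
    pw_obs_sym = np.maximum(pw_obs, pw_obs.T)
    for _ in range(n_sim):
        Ysim = ctx.L @ rng.standard_normal((N, p)) @ S.T
        Rs = _transformed_residuals(ctx, Ysim)
        rs = _group_rates(Rs, data.group, levels)
        if rs.max() / rs.min() >= ratio_obs:
            n_ge += 1
        pw_sim = rs[:, None] / rs[None, :]
        pw_ge += np.maximum(pw_sim, pw_sim.T) >= pw_obs_sym - 1e-15
    p_val = (1 + n_ge) / (1 + n_sim)
    Ppw = (1 + pw_ge) / (1 + n_sim)
    np.fill_diagonal(Ppw, 1.0)
    return RateComparisonResult(
        sigma2_by_group=dict(zip(levels, rates)),
        ratio=float(ratio_obs), p=float(p_val),
        pairwise_ratios=pd.DataFrame(pw_obs, index=levels, columns=levels),
        pairwise_p=pd.DataFrame(Ppw, index=levels, columns=levels),
        n_sim=n_sim,
    )


# ---------------------------------------------------------------------------
# convergence: C1 and C5
# ---------------------------------------------------------------------------


def _as_tip_matrix(tree: Phylogeny, Y):
    if isinstance(Y, pd.DataFrame):
        Y = Y.loc[tree.tip_labels].to_numpy(dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != tree.n_tips:
        raise ValueError("Y must have one row per tip, ordered like tip_labels")
    return Y


def _c1_paths(tree: Phylogeny, focal_idx):
    """Per focal pair: node-index lists of the two tip-to-MRCA paths."""
    paths = {}
    for ii in range(len(focal_idx)):
        for jj in range(ii + 1, len(focal_idx)):
            i, j = focal_idx[ii], focal_idx[jj]
            m = tree.mrca(i, j)
            pi = []
            a = i
            while True:
                pi.append(a)
                if a == m:
                    break
                a = int(tree.parent[a])
            pj = []
            a = j
            while True:
                pj.append(a)
                if a == m:
                    break
                a = int(tree.parent[a])
            paths[(i, j)] = (np.asarray(pi), np.asarray(pj))
    return paths


def _c1_statistic(values: np.ndarray, paths) -> float:
    """values: (n_nodes, p) node trait values; mean C1 over focal pairs."""
    c1 = []
    for (i, j), (pi, pj) in paths.items():
        d_tip = np.linalg.norm(values[i] - values[j])
        diff = values[pi][:, None, :] - values[pj][None, :, :]
        d_max = np.sqrt((diff**2).sum(axis=2)).max()
        if d_max <= 0:
            warnings.warn("identical values along both lineages; C1 pair set to 0")
            c1.append(0.0)
        else:
            c1.append(1.0 - d_tip / d_max)
    return float(np.mean(c1))


def _node_values(tree: Phylogeny, Y: np.ndarray, W_anc: np.ndarray) -> np.ndarray:
    return np.vstack([Y, W_anc @ Y])


def convergence_c1(tree: Phylogeny, Y, focal, n_sim: int = 999, seed: int = 0) -> ConvergenceResult:
    """Stayton's C1 for a focal tip set, with a BM-simulation p-value.

    For each focal pair, C1 = 1 - (tip distance) / (maximum distance between
    any two ancestral values along the two tip-to-MRCA paths, tips
    included); ancestral values are GLS estimates under BM. The p-value is
    the fraction of BM simulations (at the empirical rate matrix) whose C1
    meets or exceeds the observed.
    """
    Y = _as_tip_matrix(tree, Y)
    focal_idx = tree.tip_index(focal)
    if len(focal_idx) < 2:
        raise ValueError("need at least 2 focal taxa")
    W_anc = _ancestral_operator(tree)
    paths = _c1_paths(tree, focal_idx)
    obs = _c1_statistic(_node_values(tree, Y, W_anc), paths)

    ctx = _TreeContext(tree, tree.tip_labels)
    R = _transformed_residuals(ctx, Y)
    N, p = Y.shape
    Vcv = R.T @ R / N
    S = np.linalg.cholesky(Vcv + 1e-12 * max(np.trace(Vcv) / p, 1e-30) * np.eye(p))
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_sim):
        Ysim = ctx.L @ rng.standard_normal((N, p)) @ S.T
        if _c1_statistic(_node_values(tree, Ysim, W_anc), paths) >= obs - 1e-15:
            n_ge += 1
    return ConvergenceResult(C1=obs, p_C1=(1 + n_ge) / (1 + n_sim), n_sim=n_sim)


def _hull_equations(points: np.ndarray):
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValueError(
            "degenerate focal hull; reduce dims or supply more spread focal taxa"
        ) from exc
    return hull.equations  # rows (a, b): a . x + b <= 0 inside


def _lineage_enters(path_pts: np.ndarray, eqs: np.ndarray, tol: float = 1e-9) -> bool:
    """Does the root-to-tip polyline enter the convex region?"""
    A, b = eqs[:, :-1], eqs[:, -1]
    f = path_pts @ A.T + b  # (n_pts, m); inside iff all <= tol
    inside = (f <= tol).all(axis=1)
    for k in range(1, len(path_pts)):
        if inside[k - 1]:
            continue  # already in the region; not an entry from outside
        # clip segment k-1 -> k against the halfplanes (Liang-Barsky)
        fp, fq = f[k - 1], f[k]
        tmin, tmax = 0.0, 1.0
        feasible = True
        for c in range(len(b)):
            d = fq[c] - fp[c]
            if abs(d) < 1e-300:
                if fp[c] > tol:
                    feasible = False
                    break
                continue
            t_cross = (tol - fp[c]) / d
            if d > 0:
                tmax = min(tmax, t_cross)
            else:
                tmin = max(tmin, t_cross)
            if tmin > tmax:
                feasible = False
                break
        if feasible:
            return True
    return False


def _c5_statistic(tree: Phylogeny, values: np.ndarray, focal_idx, dims: int):
    """Count lineages entering the focal convex hull in the first *dims* PCs."""
    tipY = values[: tree.n_tips]
    mean = tipY.mean(axis=0)
    Yc = tipY - mean
    _, _, Vt = np.linalg.svd(Yc, full_matrices=False)
    proj = (values - mean) @ Vt[:dims].T
    eqs = _hull_equations(proj[focal_idx])
    count = 0
    for tip in range(tree.n_tips):
        path = tree.path_to_root(tip)[::-1]  # root -> tip
        if _lineage_enters(proj[path], eqs):
            count += 1
    return count


def convergence_c5(tree: Phylogeny, Y, focal, dims: int = 2,
                   n_sim: int = 999, seed: int = 0) -> ConvergenceResult:
    """Stayton's C5: lineages crossing into the focal region of morphospace.

    Tips and GLS ancestral estimates are ordinated on the first *dims*
    principal axes; the focal region is the convex hull of the focal tips;
    C5 counts root-to-tip lineages whose path enters the hull from outside
    (each lineage once). The p-value is from BM simulations re-ordinated
    the same way.
    """
    Y = _as_tip_matrix(tree, Y)
    focal_idx = tree.tip_index(focal)
    if len(focal_idx) < dims + 1:
        raise ValueError("need at least dims+1 focal taxa for a non-degenerate hull")
    W_anc = _ancestral_operator(tree)
    obs = _c5_statistic(tree, _node_values(tree, Y, W_anc), focal_idx, dims)

    ctx = _TreeContext(tree, tree.tip_labels)
    R = _transformed_residuals(ctx, Y)
    N, p = Y.shape
    Vcv = R.T @ R / N
    S = np.linalg.cholesky(Vcv + 1e-12 * max(np.trace(Vcv) / p, 1e-30) * np.eye(p))
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_sim):
        Ysim = ctx.L @ rng.standard_normal((N, p)) @ S.T
        try:
            c5s = _c5_statistic(tree, _node_values(tree, Ysim, W_anc), focal_idx, dims)
        except ValueError:
            continue
        if c5s >= obs:
            n_ge += 1
    return ConvergenceResult(C5=int(obs), p_C5=(1 + n_ge) / (1 + n_sim), n_sim=n_sim)


# ---------------------------------------------------------------------------
# allometric convergence
# ---------------------------------------------------------------------------


def allometric_convergence(data: GroupedTraitMatrix, n_perm: int = 999,
                           seed: int = 0) -> AllometryConvergenceResult:
    """Do two groups' shapes converge as size increases?

    Each group's shape is regressed on log size; predicted shapes for both
    groups are compared at the shared smallest and largest observed sizes.
    The statistic D_small - D_large is positive when the groups are farther
    apart at small size than at large size (allometric convergence); its
    null distribution permutes species between groups, sizes kept with
    their species.
    """
    if data.size is None:
        raise ValueError("size values required")
    levels = sorted(set(data.group.tolist()))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    for g in levels:
        if (data.group == g).sum() < 3:
            raise ValueError(f"group {g} has fewer than 3 species")
    s = np.asarray(data.size, dtype=float)
    Y = data.Y
    lo_all, hi_all = float(s.min()), float(s.max())
    g1 = data.group == levels[0]
    if max(s[g1].min(), s[~g1].min()) > min(s[g1].max(), s[~g1].max()):
        warnings.warn("group size ranges do not overlap; predictions are extrapolated")

    def stat(groups):
        preds = {}
        for g in levels:
            mask = groups == g
            A = np.column_stack([np.ones(mask.sum()), s[mask]])
            beta, *_ = np.linalg.lstsq(A, Y[mask], rcond=None)
            preds[g] = (np.array([1.0, lo_all]) @ beta, np.array([1.0, hi_all]) @ beta)
        d_small = float(np.linalg.norm(preds[levels[0]][0] - preds[levels[1]][0]))
        d_large = float(np.linalg.norm(preds[levels[0]][1] - preds[levels[1]][1]))
        return d_small, d_large

    d_small, d_large = stat(data.group)
    obs = d_small - d_large
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = data.group[rng.permutation(len(data.group))]
        if len(set(perm[: (data.group == levels[0]).sum()])) == 0:  # pragma: no cover
            continue
        ds, dl = stat(perm)
        if ds - dl >= obs - 1e-15:
            n_ge += 1
    return AllometryConvergenceResult(
        D_small=d_small, D_large=d_large, statistic=obs,
        p=(1 + n_ge) / (1 + n_perm), n_perm=n_perm,
    )
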