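"""Geometric and linear morphometrics.

Turns raw specimen data into species-level trait matrices:

* linear measurements -> regression-imputed values -> log Mosimann shape
  ratios (each variable divided by snout-vent length, then ln-transformed);
* 2D landmark configurations (11 fixed landmarks + 10 semilandmarks on the
  hind foot) -> thin-plate-spline completion of missing points ->
  generalized Procrustes alignment with bending-energy semilandmark
  sliding -> species mean shapes;
* PCA/phylomorphospace projection of any species trait matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .tps import bending_energy_matrix, tps_coefficients, tps_warp
from .tree import Phylogeny

__all__ = [
    "MEASUREMENT_VARS",
    "RATIO_VARS",
    "LandmarkConfiguration",
    "ProcrustesResult",
    "impute_missing_measurements",
    "shape_ratios",
    "interpolate_missing_landmarks",
    "GeneralizedProcrustes",
    "gpa",
    "species_mean_shapes",
    "phylomorphospace",
    "centroid_size",
]

MEASUREMENT_VARS = ("SVL", "TL", "HL", "BW", "SE", "FLL", "HLL")
RATIO_VARS = ("TL", "HL", "BW", "SE", "FLL", "HLL")


# ---------------------------------------------------------------------------
# linear measurements
# ---------------------------------------------------------------------------


def _genus(species: str) -> str:
    return str(species).split("_")[0]


def impute_missing_measurements(df: pd.DataFrame, min_complete: int = 3):
    """Fill missing linear measurements by multivariate regression.

    For each specimen with missing entries, the missing variables are
    predicted (on the log scale) from the observed ones by least squares fit
    on complete cases drawn from the narrowest taxonomic pool that has
    enough of them: conspecifics, else congeners, else all specimens.
    Observed values are untouched.

    Returns ``(completed_df, n_imputed)``.
    """
    df = df.copy()
    vars_ = [v for v in MEASUREMENT_VARS if v in df.columns]
    if not vars_:
        raise ValueError("no measurement columns found")
    X = df[vars_].to_numpy(dtype=float)
    if np.any(X[~np.isnan(X)] <= 0):
        raise ValueError("measurements must be positive")
    obs = ~np.isnan(X)
    if np.any(~obs.any(axis=1)):
        bad = df.index[~obs.any(axis=1)].tolist()
        raise ValueError(f"specimens with all measurements missing: {bad}")

    complete_mask = obs.all(axis=1)
    logX = np.log(X)
    species = df["species"].astype(str).to_numpy()
    genus = np.array([_genus(s) for s in species])

    n_imputed = 0
    for i in np.flatnonzero(~complete_mask):
        miss = np.flatnonzero(~obs[i])
        have = np.flatnonzero(obs[i])
        needed = len(have) + 2  # intercept + slack beyond exact fit
        pools = [
            complete_mask & (species == species[i]),
            complete_mask & (genus == genus[i]),
            complete_mask,
        ]
        pool = next((p for p in pools if p.sum() >= max(min_complete, needed)), pools[-1])
        if pool.sum() < 2:
            raise ValueError("no complete cases available for imputation")
        A = np.column_stack([np.ones(pool.sum()), logX[pool][:, have]])
        B = logX[pool][:, miss]
        coef, *_ = np.linalg.lstsq(A, B, rcond=None)
        pred = np.concatenate([[1.0], logX[i, have]]) @ coef
        X[i, miss] = np.exp(pred)
        n_imputed += len(miss)
    df[vars_] = X
    return df, n_imputed


def shape_ratios(df: pd.DataFrame) -> pd.DataFrame:
    """Species-level log Mosimann shape ratios.

    Species means of each measurement are divided by the species mean SVL and
    natural-log transformed. Returns a species-indexed frame with columns
    ``ln_TL_SVL`` ... ``ln_HLL_SVL`` plus ``mean_SVL``.
    """
    vars_ = [v for v in MEASUREMENT_VARS if v in df.columns]
    if "SVL" not in vars_:
        raise ValueError("SVL column required")
    if df[vars_].isna().any().any():
        raise ValueError("measurements contain missing values; impute first")
    means = df.groupby("species")[vars_].mean()
    if (means <= 0).any().any():
        raise ValueError("nonpositive species mean measurement")
    out = pd.DataFrame(index=means.index)
    for v in RATIO_VARS:
        if v in means.columns:
            out[f"ln_{v}_SVL"] = np.log(means[v] / means["SVL"])
    out["mean_SVL"] = means["SVL"]
    return out


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

N_LANDMARKS = 11
N_SEMILANDMARKS = 10
N_POINTS = N_LANDMARKS + N_SEMILANDMARKS


@dataclass
class LandmarkConfiguration:
    """One specimen's digitized 2D points (NaN rows mark missing points)."""

    specimen: str
    species: str
    coords: np.ndarray  # (n_points, 2)
    semilandmarks: tuple = ()
    neighbors: dict = field(default_factory=dict)  # semilandmark -> (anterior, posterior)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n_points, 2)")
        for sl, (a, p) in self.neighbors.items():
            if sl not in self.semilandmarks:
                raise ValueError(f"neighbor map keys must be semilandmarks: {sl}")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.coords).any(axis=1)

    @property
    def is_complete(self) -> bool:
        return not self.missing.any()


def centroid_size(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(c**2)))


def interpolate_missing_landmarks(config: LandmarkConfiguration,
                                  reference: LandmarkConfiguration | np.ndarray,
                                  max_missing: int = 6) -> LandmarkConfiguration:
    """Estimate missing points by a thin-plate spline from a complete reference.

    The spline mapping reference -> config is fit on the shared (present)
    points; missing points are the spline image of the corresponding
    reference points. Present points are returned untouched.
    """
    ref = reference.coords if isinstance(reference, LandmarkConfiguration) else np.asarray(reference)
    if np.isnan(ref).any():
        raise ValueError("reference configuration must be complete")
    miss = config.missing
    if not miss.any():
        return config
    if miss.sum() > max_missing:
        raise ValueError(f"{config.specimen}: {miss.sum()} missing points exceeds {max_missing}")
    shared = ~miss
    if shared.sum() < 3:
        raise ValueError("need at least 3 shared points for interpolation")
    W, A = tps_coefficients(ref[shared], config.coords[shared])
    filled = config.coords.copy()
    filled[miss] = tps_warp(ref[shared], W, A, ref[miss])
    return LandmarkConfiguration(config.specimen, config.species, filled,
                                 config.semilandmarks, config.neighbors)


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------


@dataclass
class ProcrustesResult:
    aligned: np.ndarray          # (n, p, 2), centered, unit centroid size
    centroid_sizes: np.ndarray   # (n,)
    consensus: np.ndarray        # (p, 2)
    n_iterations: int
    bending_energy_trace: list   # per sliding iteration: (before, after)
    reflected: np.ndarray        # which inputs were mirror-corrected

    def procrustes_distances(self) -> np.ndarray:
        n = self.aligned.shape[0]
        flat = self.aligned.reshape(n, -1)
        d = np.sqrt(((flat[:, None, :] - flat[None, :, :]) ** 2).sum(axis=2))
        return d


def _center_scale(X: np.ndarray):
    c = X - X.mean(axis=0)
    s = np.sqrt(np.sum(c**2))
    if s <= 0:
        raise ValueError("degenerate configuration (zero centroid size)")
    return c / s, s


def _rotate_onto(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (no reflection) of X onto target."""
    U, _, Vt = np.linalg.svd(X.T @ target)
    d = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, d])
    return X @ (U @ S @ Vt)


class GeneralizedProcrustes(BaseEstimator):
    """Generalized Procrustes superimposition with semilandmark sliding.

    Iteratively centers, scales to unit centroid size, and rotates each
    configuration onto the running consensus; when ``slide=True``, each
    iteration additionally slides the semilandmarks along their local
    tangent (the chord between bracketing neighbors) to minimize thin-plate
    bending energy against the consensus, accepting a slide only when it
    lowers that energy.

    Parameters
    ----------
    slide : bool
        Enable bending-energy semilandmark sliding.
    semilandmarks : sequence of int
        Indices of sliding points.
    neighbors : dict
        ``semilandmark -> (anterior, posterior)`` bracketing indices.
    fix_reflections : bool
        Mirror-correct configurations whose orthogonal fit to the consensus
        requires a reflection (digitizing-orientation errors).
    tol, max_iter : convergence controls on the consensus update.

    Attributes
    ----------
    aligned_, centroid_sizes_, consensus_, n_iterations_,
    bending_energy_trace_, reflected_ : see :class:`ProcrustesResult`.
    """

    def __init__(self, slide=False, semilandmarks=(), neighbors=None,
                 fix_reflections=True, tol=1e-8, max_iter=100,
                 max_slide_iter=10, slide_tol=1e-4):
        self.slide = slide
        self.semilandmarks = semilandmarks
        self.neighbors = neighbors
        self.fix_reflections = fix_reflections
        self.tol = tol
        self.max_iter = max_iter
        self.max_slide_iter = max_slide_iter
        self.slide_tol = slide_tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 2:
            raise ValueError("X must be (n_configs, n_points, 2)")
        n = X.shape[0]
        if n < 2:
            raise ValueError("need at least 2 configurations")
        if np.isnan(X).any():
            raise ValueError("configurations contain missing points; complete them first")
        if self.slide and (not self.semilandmarks or not self.neighbors):
            raise ValueError("sliding requires semilandmarks and a neighbor map")

        aligned = np.empty_like(X)
        sizes = np.empty(n)
        for i in range(n):
            aligned[i], sizes[i] = _center_scale(X[i])

        reflected = np.zeros(n, dtype=bool)
        consensus, _ = _center_scale(aligned[0])
        trace = []
        n_iter = 0
        # sliding switches itself off once a pass stops lowering bending
        # energy (relative improvement below slide_tol) or after
        # max_slide_iter passes; plain alignment then converges the consensus
        sliding_active = bool(self.slide)
        for n_iter in range(1, self.max_iter + 1):
            if self.fix_reflections:
                for i in range(n):
                    M = aligned[i].T @ consensus
                    if np.linalg.det(M) < 0:
                        aligned[i] = aligned[i] * np.array([1.0, -1.0])
                        reflected[i] = ~reflected[i]
            for i in range(n):
                aligned[i] = _rotate_onto(aligned[i], consensus)
            if sliding_active:
                before, after = self._slide_all(aligned, consensus)
                trace.append((before, after))
                for i in range(n):
                    aligned[i], _ = _center_scale(aligned[i])
                    aligned[i] = _rotate_onto(aligned[i], consensus)
                if (before - after <= self.slide_tol * max(before, 1e-12)
                        or len(trace) >= self.max_slide_iter):
                    sliding_active = False
            new_consensus, _ = _center_scale(aligned.mean(axis=0))
            delta = np.sqrt(np.sum((new_consensus - consensus) ** 2))
            consensus = new_consensus
            if delta < self.tol and not sliding_active:
                break
        else:
            raise RuntimeError(
                f"GPA did not converge in {self.max_iter} iterations (last delta {delta:.3g})")

        self.aligned_ = aligned
        self.centroid_sizes_ = sizes
        self.consensus_ = consensus
        self.n_iterations_ = n_iter
        self.bending_energy_trace_ = trace
        self.reflected_ = reflected
        return self

    def transform(self, X):
        """Align new configurations to the fitted consensus (no sliding)."""
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            c, _ = _center_scale(X[i])
            out[i] = _rotate_onto(c, self.consensus_)
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).aligned_

    # -- sliding ---------------------------------------------------------

    def _slide_all(self, aligned: np.ndarray, consensus: np.ndarray):
        """One bending-energy sliding pass; returns (energy_before, energy_after)."""
        p = consensus.shape[0]
        B = bending_energy_matrix(consensus)
        B2 = np.kron(np.eye(2), B)  # acts on stacked [x; y] vectors
        sl = list(self.semilandmarks)
        cvec = consensus.T.reshape(-1)

        def energy(conf):
            v = conf.T.reshape(-1) - cvec
            return float(v @ B2 @ v)

        before = after = 0.0
        for i in range(aligned.shape[0]):
            conf = aligned[i]
            e0 = energy(conf)
            before += e0
            # tangent directions from the specimen's own bracketing points
            U = np.zeros((2 * p, len(sl)))
            limits = np.empty(len(sl))
            for k, j in enumerate(sl):
                a, b = self.neighbors[j]
                chord = conf[b] - conf[a]
                norm = np.linalg.norm(chord)
                if norm <= 0:
                    limits[k] = 0.0
                    continue
                t = chord / norm
                U[j, k] = t[0]
                U[p + j, k] = t[1]
                limits[k] = norm / 2.0
            v = conf.T.reshape(-1) - cvec
            H = U.T @ B2 @ U
            g = U.T @ B2 @ v
            step = -np.linalg.pinv(H, rcond=1e-10) @ g
            # shrink uniformly to keep semilandmarks between their brackets;
            # a convex quadratic decreases along the whole Newton segment
            with np.errstate(divide="ignore", invalid="ignore"):
                over = np.abs(step) / limits
            over = over[np.isfinite(over)]
            alpha = min(1.0, 1.0 / over.max()) if over.size and over.max() > 1 else 1.0
            cand_vec = conf.T.reshape(-1) + U @ (alpha * step)
            cand = cand_vec.reshape(2, p).T
            e1 = energy(cand)
            if e1 < e0:
                aligned[i] = cand
                after += e1
            else:
                after += e0
        return before, after


def gpa(configs, slide=False, semilandmarks=(), neighbors=None, **kwargs) -> ProcrustesResult:
    """Functional wrapper over :class:`GeneralizedProcrustes`.

    *configs* may be an (n, p, 2) array or a list of
    :class:`LandmarkConfiguration` (whose semilandmark metadata is used when
    ``slide=True`` and none is given explicitly).
    """
    if len(configs) and isinstance(configs[0], LandmarkConfiguration):
        if slide and not semilandmarks:
            semilandmarks = configs[0].semilandmarks
            neighbors = configs[0].neighbors
        X = np.stack([c.coords for c in configs])
    else:
        X = np.asarray(configs, dtype=float)
    est = GeneralizedProcrustes(slide=slide, semilandmarks=semilandmarks,
                                neighbors=neighbors, **kwargs).fit(X)
    return ProcrustesResult(
        aligned=est.aligned_, centroid_sizes=est.centroid_sizes_,
        consensus=est.consensus_, n_iterations=est.n_iterations_,
        bending_energy_trace=est.bending_energy_trace_, reflected=est.reflected_,
    )


def species_mean_shapes(configs, slide=False, **kwargs):
    """Two-stage species mean shapes.

    Specimens are aligned within each species (GPA) and averaged; the
    species consensuses are then aligned together. Returns
    ``(mean_coords, species_order, mean_centroid_sizes, result)`` where
    *mean_coords* is (n_species, p, 2) aligned and *mean_centroid_sizes*
    holds each species' mean specimen centroid size (for allometry).
    """
    by_species: dict[str, list] = {}
    for c in configs:
        by_species.setdefault(c.species, []).append(c)
    species = sorted(by_species)
    sem = configs[0].semilandmarks
    nb = configs[0].neighbors
    means, csizes = [], []
    for sp in species:
        group = by_species[sp]
        if not group:
            warnings.warn(f"species {sp} has no specimens; dropped")
            continue
        if len(group) == 1:
            c, s = _center_scale(group[0].coords)
            means.append(c)
            csizes.append(s)
        else:
            res = gpa(group, slide=slide, semilandmarks=sem, neighbors=nb, **kwargs)
            means.append(res.consensus)
            csizes.append(float(res.centroid_sizes.mean()))
    mean_cfgs = [LandmarkConfiguration(sp, sp, m, sem, nb) for sp, m in zip(species, means)]
    result = gpa(mean_cfgs, slide=slide, semilandmarks=sem, neighbors=nb, **kwargs)
    return result.aligned, species, np.asarray(csizes), result


# ---------------------------------------------------------------------------
# phylomorphospace
# ---------------------------------------------------------------------------


def phylomorphospace(tree: Phylogeny, traits: pd.DataFrame):
    """Centered PCA of species traits with BM ancestral states projected in.

    Returns a dict with ``scores`` (species frame), ``ancestor_scores``
    (internal-node array, tree node indexing), ``variance_fractions`` and
    ``components``.
    """
    from .stats import ancestral_states_bm

    common = [t for t in tree.tip_labels if t in traits.index]
    if len(common) < 2:
        raise ValueError("fewer than 2 species shared between tree and traits")
    sub = prune_if_needed(tree, common)
    Y = traits.loc[sub.tip_labels].to_numpy(dtype=float)
    mean = Y.mean(axis=0)
    Yc = Y - mean
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    scores = Yc @ Vt.T
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    anc = ancestral_states_bm(sub, Y)
    anc_scores = (anc - mean) @ Vt.T
    return {
        "tree": sub,
        "scores": pd.DataFrame(scores, index=sub.tip_labels,
                               columns=[f"PC{i+1}" for i in range(scores.shape[1])]),
        "ancestor_scores": anc_scores,
        "variance_fractions": frac,
        "components": Vt,
    }


def prune_if_needed(tree: Phylogeny, taxa) -> Phylogeny:
    from .tree import prune_to_taxa

    if set(taxa) == set(tree.tip_labels):
        return tree
    return prune_to_taxa(tree, taxa)
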