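"""Self-contained validation experiments on fully synthetic data.

Each function runs one calibration or recovery experiment end to end —
generate data under known conditions, run the package's estimator, measure
the outcome — and returns plain numbers. They back both the test suite and
``scripts/acceptance.py``.

Oracles used here (state enumeration for the pruning likelihood, rejection
sampling for endpoint-conditioned paths, closed-form two-shape alignment)
are written independently of the implementation paths they check.

Problem sizes follow the study's scale where the experiment calls for it
(hundreds of tips, 6 trait dimensions, 200-Myr tree heights) and are
otherwise chosen to finish in minutes on one CPU.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy.linalg import expm
from scipy.stats import chi2_contingency

from . import mk, morpho, simmap, simulate, stats

__all__ = [
    "likelihood_enumeration_check",
    "mapping_oracle_check",
    "q_recovery",
    "rate_ratio_recovery",
    "rate_ratio_type1",
    "anova_type1",
    "anova_star_tree_check",
    "c1_controls",
    "c5_worked_example",
    "gpa_contract",
    "pipeline_recovery",
]


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# 1. pruning likelihood vs enumeration
# ---------------------------------------------------------------------------


def _enumeration_lnl(tree, states, q, prior):
    K = q.k
    tips = [q.states.index(states[l]) for l in tree.tip_labels]
    interior = list(range(tree.n_tips, tree.n_nodes))
    P = {n: expm(q.matrix * tree.edge_length[n]) for n in range(tree.n_nodes)}
    total = 0.0
    for combo in itertools.product(range(K), repeat=len(interior)):
        assign = dict(zip(interior, combo))
        for i, s in enumerate(tips):
            assign[i] = s
        pr = prior[assign[tree.root]]
        for n in range(tree.n_nodes):
            if n != tree.root:
                pr *= P[n][assign[tree.parent[n]], assign[n]]
        total += pr
    return np.log(total)


def likelihood_enumeration_check(seed: int = 0, n_cases: int = 20) -> float:
    """Max |pruning lnL - enumeration lnL| over random trees with <= 5 tips
    and <= 3 states."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for case_seed in _seeds(seed, n_cases):
        n = int(rng.integers(3, 6))
        K = int(rng.integers(2, 4))
        tree = simulate.simulate_yule_tree(n, seed=case_seed, height=1.0)
        m = rng.uniform(0.05, 1.5, (K, K))
        np.fill_diagonal(m, 0)
        q = mk.QMatrix(tuple("abc"[:K]), m)
        states = {l: q.states[rng.integers(K)] for l in tree.tip_labels}
        prior = np.full(K, 1.0 / K)
        dev = abs(mk.mk_log_likelihood(tree, states, q, prior)
                  - _enumeration_lnl(tree, states, q, prior))
        worst = max(worst, dev)
    return worst


# ---------------------------------------------------------------------------
# 2. uniformization path sampler vs rejection oracle
# ---------------------------------------------------------------------------


def mapping_oracle_check(seed: int = 0, n_draws: int = 10_000) -> float:
    """Chi-square p-value comparing change-count distributions of the
    uniformization sampler and the rejection oracle on a single branch."""
    q = mk.QMatrix(("a", "b"), np.array([[0, 0.8], [0.5, 0]]))
    t_len = 1.5
    P = expm(q.matrix * t_len)
    rng = np.random.default_rng(seed)
    uni = [len(simmap._uniformized_path(q.matrix, P, 0, 1, t_len, rng)) - 1
           for _ in range(n_draws)]
    rej = [len(simmap.rejection_sample_path(q.matrix, 0, 1, t_len, rng)) - 1
           for _ in range(n_draws)]
    cats = sorted(set(uni) | set(rej))
    table = np.array([[uni.count(c) for c in cats], [rej.count(c) for c in cats]])
    while table.shape[1] > 2 and table[:, -1].sum() < 10:
        table[:, -2] += table[:, -1]
        table = table[:, :-1]
    _, p, *_ = chi2_contingency(table)
    return float(p)


# ---------------------------------------------------------------------------
# 3. ARD rate recovery under ~20x asymmetry
# ---------------------------------------------------------------------------


def q_recovery(seed: int = 0, n_synth: int = 50, n_tips: int = 400,
               rates=(0.002, 0.04), height: float = 200.0) -> dict:
    """Fraction of syntheses whose fitted ARD rates are both within a factor
    2 of the generating values."""
    ok = 0
    used = 0
    for s in _seeds(seed, n_synth):
        tree = simulate.simulate_yule_tree(n_tips, seed=s, height=height)
        q_true = mk.QMatrix(("t", "a"), np.array([[0, rates[0]], [rates[1], 0]]))
        tips, _ = simulate.simulate_discrete_character(tree, q_true, root=0, seed=s + 1)
        if len(set(tips.values())) < 2:
            continue
        used += 1
        fit = mk.fit_mk(tree, tips, model="ARD", n_starts=4, seed=s + 2,
                        state_labels=("t", "a"))
        r01, r10 = fit.q.matrix[0, 1], fit.q.matrix[1, 0]
        if rates[0] / 2 <= r01 <= rates[0] * 2 and rates[1] / 2 <= r10 <= rates[1] * 2:
            ok += 1
    return {"fraction_within_factor2": ok / used if used else float("nan"),
            "n_used": used}


# ---------------------------------------------------------------------------
# 4. state-dependent rate-ratio recovery and test calibration
# ---------------------------------------------------------------------------


def rate_ratio_recovery(seed: int = 0, n_synth: int = 100, n_tips: int = 300,
                        p: int = 6, rates=(1.0, 4.0)) -> dict:
    """Foreground/background BM rate ratio estimation with a clade regime."""
    in_band = 0
    est = []
    for s in _seeds(seed, n_synth):
        tree = simulate.simulate_yule_tree(n_tips, seed=s, height=1.0)
        hist, tips = simulate.paint_clade_history(tree, seed=s + 1)
        Y = simulate.simulate_multivariate_bm(
            tree, p=p, history=hist, rate_by_state={"bg": rates[0], "fg": rates[1]},
            seed=s + 2)
        g = np.array([tips[l] for l in tree.tip_labels])
        ctx = stats._TreeContext(tree, list(tree.tip_labels))
        R = stats._transformed_residuals(ctx, Y.to_numpy())
        r_bg, r_fg = stats._group_rates(R, g, ["bg", "fg"])
        ratio = r_fg / r_bg
        est.append(ratio)
        if 3.0 <= ratio <= 5.0:
            in_band += 1
    return {"fraction_in_band": in_band / n_synth, "median_ratio": float(np.median(est))}


def rate_ratio_type1(seed: int = 0, n_rep: int = 400, n_sim: int = 99,
                     n_tips: int = 300, p: int = 6, alpha: float = 0.05) -> float:
    """Rejection rate of the rate-heterogeneity test under equal rates."""
    rej = 0
    for s in _seeds(seed, n_rep):
        tree = simulate.simulate_yule_tree(n_tips, seed=s, height=1.0)
        _, tips = simulate.paint_clade_history(tree, seed=s + 1)
        Y = simulate.simulate_multivariate_bm(tree, p=p, rate=1.0, seed=s + 2)
        g = np.array([tips[l] for l in tree.tip_labels])
        data = stats.GroupedTraitMatrix(species=list(tree.tip_labels),
                                        Y=Y.to_numpy(), group=g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.compare_rates_by_group(tree, data, n_sim=n_sim, seed=s + 3)
        if res.p <= alpha:
            rej += 1
    return rej / n_rep


# ---------------------------------------------------------------------------
# 5. RRPP ANOVA calibration
# ---------------------------------------------------------------------------


def anova_type1(seed: int = 0, n_synth: int = 1000, n_tips: int = 100, p: int = 6,
                n_perm: int = 199, n_groups: int = 4, alpha: float = 0.05,
                n_trees: int = 10) -> float:
    """Rejection rate of the phylogenetic ANOVA under randomized labels on
    BM data (its null)."""
    rej = 0
    tree_seeds = _seeds(seed, n_trees)
    per_tree = n_synth // n_trees
    labels = np.array([f"g{i}" for i in range(n_groups)])
    for ts in tree_seeds:
        tree = simulate.simulate_yule_tree(n_tips, seed=ts, height=1.0)
        ctx = stats._TreeContext(tree, list(tree.tip_labels))
        rng = np.random.default_rng(ts + 1)
        for _ in range(per_tree):
            Y = ctx.L @ rng.standard_normal((n_tips, p))
            g = labels[rng.integers(n_groups, size=n_tips)]
            data = stats.GroupedTraitMatrix(species=list(tree.tip_labels),
                                            Y=Y, group=g)
            res = stats.phylogenetic_anova(tree, data, n_perm=n_perm,
                                           seed=int(rng.integers(2**31)))
            if res.p <= alpha:
                rej += 1
    return rej / (per_tree * n_trees)


def anova_star_tree_check(seed: int = 0, n_tips: int = 30, p: int = 4) -> float:
    """Max |phylogenetic - ordinary| deviation of (R2, F) on a star tree."""
    from .tree import read_newick

    tree = read_newick("(" + ",".join(f"s{i}:1" for i in range(n_tips)) + "):0;")
    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((n_tips, p))
    g = np.array(["a", "b", "c"])[rng.integers(3, size=n_tips)]
    data = stats.GroupedTraitMatrix(species=list(tree.tip_labels), Y=Y, group=g)
    res = stats.phylogenetic_anova(tree, data, n_perm=19, seed=seed)

    levels = sorted(set(g.tolist()))
    X = np.zeros((n_tips, len(levels)))
    for j, lv in enumerate(levels):
        X[g == lv, j] = 1.0
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    one = np.ones((n_tips, 1))
    H0 = one @ np.linalg.pinv(one.T @ one) @ one.T
    ssm = np.sum(((H - H0) @ Y) ** 2)
    ssr = np.sum(((np.eye(n_tips) - H) @ Y) ** 2)
    sst = np.sum(((np.eye(n_tips) - H0) @ Y) ** 2)
    F = (ssm / (len(levels) - 1)) / (ssr / (n_tips - len(levels)))
    return float(max(abs(res.F - F), abs(res.R2 - ssm / sst)))


# ---------------------------------------------------------------------------
# 6. convergence controls
# ---------------------------------------------------------------------------


def c1_controls(seed: int = 0, n_synth: int = 100, n_tips: int = 100,
                n_focal: int = 8, strength: float = 6.0, n_sim: int = 99) -> dict:
    """C1 on constructed identical focal tips, and detection power under the
    convergent-attraction regime.

    The default attraction strength (6 per tree height) makes the pull's
    half-life, ln(2)/6 of the tree height, comparable to a typical pendant
    branch on a 100-tip Yule tree: focal terminal branches are drawn most of
    the way to the attractor while the deeper history stays Brownian.
    """
    tree = simulate.simulate_yule_tree(n_tips, seed=seed, height=1.0)
    Y = simulate.simulate_multivariate_bm(tree, p=4, rate=1.0, seed=seed + 1)
    focal = list(tree.tip_labels[:n_focal])
    Y.loc[focal] = Y.loc[focal].iloc[0].to_numpy()
    c1_identical = stats.convergence_c1(tree, Y, focal, n_sim=9, seed=seed + 2).C1

    hits = 0
    for s in _seeds(seed + 1, n_synth):
        t = simulate.simulate_yule_tree(n_tips, seed=s, height=1.0)
        rng = np.random.default_rng(s + 1)
        foc = list(rng.choice(t.tip_labels, size=n_focal, replace=False))
        Yc = simulate.simulate_convergent_traits(
            t, foc, attractor=np.full(4, 1.5), strength=strength, base_rate=1.0,
            seed=s + 2)
        res = stats.convergence_c1(t, Yc, foc, n_sim=n_sim, seed=s + 3)
        if res.p_C1 <= 0.05:
            hits += 1
    return {"c1_identical_focal": float(c1_identical), "power": hits / n_synth}


def c5_worked_example(seed: int = 0) -> int:
    """C5 on a 10-tip example whose crossing count (3) is countable by hand:
    three focal tips cluster far from every other species, so exactly their
    three lineages enter the focal hull."""
    import pandas as pd

    from .tree import read_newick

    nwk = ("(((f1:1,f2:1):1,(f3:1,o1:1):1):2,"
           "((o2:1,o3:1):1,((o4:0.5,o7:0.5):0.5,(o5:0.5,o6:0.5):0.5):1):2):0;")
    tree = read_newick(nwk)
    rng = np.random.default_rng(seed)
    Y = pd.DataFrame(rng.normal(0, 0.3, (10, 2)), index=tree.tip_labels,
                     columns=["x", "y"])
    Y.loc["f1"] = [10.0, 10.0]
    Y.loc["f2"] = [11.0, 10.0]
    Y.loc["f3"] = [10.5, 11.0]
    res = stats.convergence_c5(tree, Y, ["f1", "f2", "f3"], dims=2, n_sim=9,
                               seed=seed + 1)
    return int(res.C5)


# ---------------------------------------------------------------------------
# 7. GPA contract
# ---------------------------------------------------------------------------


def gpa_contract(seed: int = 0) -> dict:
    """Alignment of similarity-transformed copies and bending-energy
    monotonicity of semilandmark sliding."""
    template = simulate.foot_template()
    rng = np.random.default_rng(seed)
    X = []
    for _ in range(8):
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        X.append(np.exp(rng.normal(0, 0.4)) * template.coords @ R.T
                 + rng.normal(0, 4, 2))
    res = morpho.gpa(np.stack(X))
    max_dist = float(res.procrustes_distances().max())

    specs = simulate.generate_landmark_dataset(n_species=10, n_per_species=3,
                                               seed=seed + 1)
    res2 = morpho.gpa(specs, slide=True)
    worst_increase = max((after - before for before, after in
                          res2.bending_energy_trace), default=0.0)
    return {"max_pairwise_distance": max_dist,
            "max_bending_energy_increase": float(worst_increase)}


# ---------------------------------------------------------------------------
# 8. end-to-end pipeline on a synthetic bundle
# ---------------------------------------------------------------------------


def pipeline_recovery(seed: int = 0, n_tips: int = 400) -> dict:
    """Full pipeline on a synthetic bundle built with a 20x loss/gain
    asymmetry; returns the recovered asymmetry ratio and section presence."""
    from . import microhabitat
    from .pipeline import PipelineConfig, run_full_analysis

    tree = simulate.simulate_yule_tree(n_tips, seed=seed, height=200.0)
    q = mk.QMatrix(("T", "A"), np.array([[0, 0.002], [0.04, 0]]))
    tips, _ = simulate.simulate_discrete_character(tree, q, root=0, seed=seed + 1)
    records = [microhabitat.MicrohabitatRecord(species=s, primary=st)
               for s, st in tips.items()]
    traits = simulate.simulate_multivariate_bm(tree, p=6, rate=0.001, seed=seed + 2)
    cfg = PipelineConfig(tree=tree, microhabitat_records=records, schemes=("6-M",),
                         traits=traits, n_maps=100, n_perm=99, n_sim=49,
                         mk_n_starts=4, seed=seed + 3, run_convergence=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = run_full_analysis(cfg)
    sch = rep["schemes"]["6-M"]
    states = sch["q_states"]
    Q = np.asarray(sch["q_matrix"])
    i, j = states.index("T"), states.index("A")
    return {
        "asymmetry_ratio": float(Q[j, i] / Q[i, j]),
        "best_model": sch["best_model"],
        "sections_complete": int(
            {"model_comparison", "mapping", "root_state_probs"} <= set(sch)
            and "anova" in rep["morphology"]),
        "mean_loss_transitions": float(
            sch["mapping"]["mean_transition_counts"]["T"]["A"]),
    }
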