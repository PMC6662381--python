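"""End-to-end analysis orchestration.

``run_full_analysis`` executes, per classification scheme: state assignment
-> ER/SYM/ARD Mk fits and AIC choice -> marginal ancestral states ->
stochastic maps and their summaries; and, when morphology inputs are given:
imputation -> log shape ratios (and/or TPS completion -> GPA -> species
means) -> phylogenetic ANOVA, pairwise distances, rate comparison, C1/C5
convergence and the allometric-convergence test. ``sensitivity_analysis``
repeats configured analyses over a posterior set of chronograms and reports
95% intervals.

All outputs are plain CSV/JSON under the configured output directory; every
seed and draw count is logged into the summary JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import microhabitat, mk, morpho, simmap, stats
from .tree import Phylogeny, prune_to_taxa, read_newick_trees

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_analysis", "sensitivity_analysis"]


@dataclass
class PipelineConfig:
    tree: object  # Phylogeny or path
    microhabitat_records: object = None  # list[MicrohabitatRecord] or path
    schemes: tuple = ("6-M",)
    traits: object = None  # species x traits DataFrame (e.g. log shape ratios)
    measurements: object = None  # specimen measurement DataFrame or path
    landmarks: object = None  # list[LandmarkConfiguration]
    focal_state: str = "A"
    n_maps: int = 1000
    n_perm: int = 999
    n_sim: int = 999
    mk_n_starts: int = 10
    seed: int = 0
    out_dir: object = None
    run_mk: bool = True
    run_mapping: bool = True
    run_morphology: bool = True
    run_convergence: bool = True
    run_rates: bool = True

    def __post_init__(self):
        if not self.schemes:
            raise ValueError("at least one classification scheme required")


def _load_tree(tree) -> Phylogeny:
    if isinstance(tree, Phylogeny):
        return tree
    return read_newick_trees(tree)[0]


def _load_records(records):
    if records is None:
        return None
    if isinstance(records, (str, Path)):
        return microhabitat.read_records(records)
    return records


def _q_to_frame(q: mk.QMatrix) -> pd.DataFrame:
    return pd.DataFrame(q.matrix, index=list(q.states), columns=list(q.states))


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run the configured stages; returns (and optionally writes) a report bundle."""
    report: dict = {"seeds": {"master": config.seed}, "schemes": {}, "morphology": {}}
    tree = _load_tree(config.tree)
    records = _load_records(config.microhabitat_records)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "setup"
    try:
        if records is not None and config.run_mk:
            for scheme in config.schemes:
                stage = f"classification[{scheme}]"
                assignment = microhabitat.apply_scheme(records, scheme)
                species = [s for s in assignment.states if s in set(tree.tip_labels)]
                sub = prune_to_taxa(tree, species) if set(species) != set(tree.tip_labels) else tree
                labels = tuple(sorted({assignment.states[s] for s in sub.tip_labels}))
                sch_rep: dict = {"n_species": sub.n_tips, "states": list(labels)}

                stage = f"mk[{scheme}]"
                fits = [
                    mk.fit_mk(sub, assignment, model=m, n_starts=config.mk_n_starts,
                              seed=config.seed, state_labels=labels)
                    for m in mk.MODELS
                ]
                comparison = mk.select_model(fits)
                sch_rep["model_comparison"] = {
                    f.model: {"lnL": f.lnl, "k": f.k, "AIC": f.aic, "dAIC": float(d)}
                    for f, d in zip(comparison.fits, comparison.delta_aic)
                }
                sch_rep["best_model"] = comparison.best.model
                best = comparison.best
                sch_rep["q_states"] = list(best.q.states)
                sch_rep["q_matrix"] = best.q.matrix.tolist()
                if out_dir:
                    _q_to_frame(best.q).to_csv(out_dir / f"qmatrix_{scheme}.csv")

                stage = f"ancestral[{scheme}]"
                marg = mk.marginal_ancestral_states(sub, assignment, best.q, best.root_prior)
                sch_rep["root_state_probs"] = {
                    s: float(marg[sub.root, i]) for i, s in enumerate(best.q.states)
                }
                if out_dir:
                    pd.DataFrame(marg, columns=list(best.q.states)).to_csv(
                        out_dir / f"ancestral_{scheme}.csv", index_label="node")

                if config.run_mapping:
                    stage = f"simmap[{scheme}]"
                    hists = simmap.sample_histories(
                        sub, assignment, best.q, n_maps=config.n_maps,
                        root_prior=best.root_prior, seed=config.seed + 1)
                    summary = simmap.summarize_maps(hists)
                    sch_rep["mapping"] = {
                        "n_maps": summary.n_maps,
                        "mean_transition_counts": pd.DataFrame(
                            summary.mean_transition_counts,
                            index=list(best.q.states), columns=list(best.q.states),
                        ).to_dict(),
                        "mean_origins": dict(zip(best.q.states, summary.mean_origins.tolist())),
                        "root_state_freq": {
                            s: float(summary.node_state_freq[sub.root, i])
                            for i, s in enumerate(best.q.states)
                        },
                    }
                    if config.focal_state in best.q.states:
                        origin_counts = [simmap.count_origins(h, config.focal_state)
                                         for h in hists]
                        vals, cts = np.unique(origin_counts, return_counts=True)
                        sch_rep["mapping"]["focal_origins"] = {
                            "state": config.focal_state,
                            "mean": float(np.mean(origin_counts)),
                            "mode": int(vals[np.argmax(cts)]),
                        }
                    if out_dir:
                        summary.node_frequencies_frame(sub).to_csv(
                            out_dir / f"node_state_freq_{scheme}.csv", index=False)
                report["schemes"][scheme] = sch_rep

        if config.run_morphology and (
            config.traits is not None or config.measurements is not None
        ):
            stage = "morphology"
            traits = config.traits
            if traits is None:
                meas = config.measurements
                if isinstance(meas, (str, Path)):
                    meas = pd.read_csv(meas)
                completed, n_imp = morpho.impute_missing_measurements(meas)
                ratios = morpho.shape_ratios(completed)
                traits = ratios.drop(columns=["mean_SVL"])
                report["morphology"]["n_imputed"] = n_imp
                if out_dir:
                    ratios.to_csv(out_dir / "shape_ratios.csv")
            scheme = config.schemes[0]
            if records is not None:
                assignment = microhabitat.apply_scheme(records, scheme)
                groups = pd.Series(assignment.states)
            else:
                raise ValueError("morphological statistics require microhabitat records")
            common = [s for s in traits.index if s in set(tree.tip_labels)
                      and s in set(groups.index)]
            sub = prune_to_taxa(tree, common)
            data = stats.GroupedTraitMatrix.from_frames(traits.loc[common], groups)
            report["morphology"]["n_species"] = len(common)

            stage = "anova"
            an = stats.phylogenetic_anova(sub, data, n_perm=config.n_perm,
                                          seed=config.seed + 2)
            report["morphology"]["anova"] = {
                "R2": an.R2, "F": an.F, "Z": an.Z, "p": an.p, "n_perm": an.n_perm}
            pw = stats.pairwise_group_distances(sub, data, n_perm=config.n_perm,
                                                seed=config.seed + 3)
            if out_dir:
                pw.distances.to_csv(out_dir / "pairwise_distances.csv")
                pw.p_values.to_csv(out_dir / "pairwise_p.csv")

            if config.run_rates:
                stage = "rates"
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rates = stats.compare_rates_by_group(
                        sub, data, n_sim=config.n_sim, seed=config.seed + 4)
                report["morphology"]["rates"] = {
                    "sigma2_by_group": rates.sigma2_by_group,
                    "ratio": rates.ratio, "p": rates.p, "n_sim": rates.n_sim}

            if config.run_convergence:
                stage = "convergence"
                aligned_groups = pd.Series(data.group, index=data.species)
                focal = [s for s in data.species
                         if aligned_groups[s] == config.focal_state]
                if len(focal) >= 3:
                    c1 = stats.convergence_c1(sub, traits.loc[sub.tip_labels], focal,
                                              n_sim=config.n_sim, seed=config.seed + 5)
                    c5 = stats.convergence_c5(sub, traits.loc[sub.tip_labels], focal,
                                              n_sim=config.n_sim, seed=config.seed + 6)
                    report["morphology"]["convergence"] = {
                        "C1": c1.C1, "p_C1": c1.p_C1,
                        "C5": c5.C5, "p_C5": c5.p_C5, "n_sim": config.n_sim}

            stage = "phylomorphospace"
            pms = morpho.phylomorphospace(sub, traits.loc[sub.tip_labels])
            report["morphology"]["pc_variance_fractions"] = (
                pms["variance_fractions"][:5].tolist())
            if out_dir:
                pms["scores"].to_csv(out_dir / "phylomorphospace_scores.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    if out_dir:
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _collect_numeric(report: dict, prefix="") -> dict:
    out = {}
    for k, v in report.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_collect_numeric(v, key + "."))
        elif isinstance(v, (int, float, np.integer, np.floating)) and not isinstance(v, bool):
            out[key] = float(v)
    return out


def sensitivity_analysis(config: PipelineConfig, trees, quantiles=(0.025, 0.975)) -> dict:
    """Repeat the configured analyses over a set of chronograms.

    *trees* may be a multi-tree Newick path or a list of Phylogeny. Returns
    per-statistic quantile intervals across trees, plus the per-tree tables.
    """
    if isinstance(trees, (str, Path)):
        trees = read_newick_trees(trees)
    if len(trees) < 2:
        raise ValueError("need at least 2 trees for a sensitivity analysis")
    rows = []
    n_skipped = 0
    for i, t in enumerate(trees):
        cfg = PipelineConfig(**{**asdict_shallow(config), "tree": t, "out_dir": None})
        try:
            rep = run_full_analysis(cfg)
        except (RuntimeError, KeyError) as exc:
            warnings.warn(f"tree {i} skipped: {exc}")
            n_skipped += 1
            continue
        rows.append(_collect_numeric(rep))
    table = pd.DataFrame(rows)
    intervals = {
        col: [float(table[col].quantile(quantiles[0])),
              float(table[col].quantile(quantiles[1]))]
        for col in table.columns
    }
    return {"per_tree": table, "intervals": intervals, "n_trees": len(rows),
            "n_skipped": n_skipped}


def asdict_shallow(config: PipelineConfig) -> dict:
    return {f: getattr(config, f) for f in config.__dataclass_fields__}
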