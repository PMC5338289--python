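"""Recovery benchmarks: run the pipeline on planted-truth simulations.

Each sweep regenerates data under the study's stated conditions across a
range of RNG seeds, runs the relevant pipeline stages, and reports how
well the planted structure is recovered. Used by the test suite and the
reproduction script; the condition defaults are the simulation defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import compute_diff, intersect_hits, select_hits
from .network import (
    build_seed_subnetworks,
    filter_by_annotation,
    merge_subnetworks,
    nominate_central_node,
    rank_central_nodes,
    select_containing,
)
from .preprocess import call_matrix, filter_probesets, summarize_experiment
from .simulate import (
    ArraySimConfig,
    CohortSimConfig,
    GraphSimConfig,
    annotation_for,
    generate_interaction_graph,
    generate_microarray_experiment,
    generate_tma_cohort,
)
from .survival import cox_fit, log_rank, spearman


def run_recovery_once(cfg: ArraySimConfig) -> dict:
    """One simulate -> preprocess -> diffexpr run against planted truth."""
    exp, truth = generate_microarray_experiment(cfg)
    calls = call_matrix(exp)
    expr = summarize_experiment(exp)
    filtered, _ = filter_probesets(expr, calls)
    ann = annotation_for(sorted(exp.probes["probeset_id"].unique()))
    lines = filtered.cell_lines
    hits = {ln: select_hits(compute_diff(filtered, ln), ann) for ln in lines}
    common = intersect_hits(hits[lines[0]], hits[lines[1]])
    planted = {truth.gene_of_probeset[pid] for pid in truth.shared_responders}
    found = common.gene_names
    return {
        "seed": cfg.seed,
        "n_planted": len(planted),
        "n_recovered": len(planted & found),
        "n_false": len(found - planted),
        "n_common": len(common),
        "recovery_frac": len(planted & found) / len(planted) if planted else float("nan"),
    }


def responder_recovery_sweep(
    n_seeds: int = 20, base_seed: int = 0, **overrides
) -> pd.DataFrame:
    """Shared-responder recovery across a seed sweep of the generator."""
    rows = [
        run_recovery_once(ArraySimConfig(seed=base_seed + i, **overrides))
        for i in range(n_seeds)
    ]
    return pd.DataFrame(rows)


def hub_recovery_sweep(
    n_runs: int = 100,
    base_seed: int = 0,
    n_seed_genes: int = 30,
    **overrides,
) -> pd.DataFrame:
    """Planted-hub nomination rate over repeated graph generations.

    Each run builds seed subnetworks, selects those containing a
    hub-adjacent seed gene as anchor, merges, filters to bone/neoplasm
    tags and asks whether the composite centrality ranks the planted
    hub first.
    """
    seeds = {f"G{i:03d}" for i in range(n_seed_genes)}
    rows = []
    for i in range(n_runs):
        cfg = GraphSimConfig(seed=base_seed + i, **overrides)
        g, truth = generate_interaction_graph(cfg, seeds)
        anchor = truth.hub_adjacent_seeds[0]
        subnets = build_seed_subnetworks(g, seeds)
        chosen = select_containing(subnets, anchor)
        merged = merge_subnetworks(chosen, g, all_seeds=seeds)
        final = filter_by_annotation(merged, {"bone", "neoplasm"}, {anchor})
        central = nominate_central_node(rank_central_nodes(final))
        rows.append({"seed": cfg.seed, "central": central, "hub": truth.hub_gene,
                     "hub_is_central": central == truth.hub_gene})
    return pd.DataFrame(rows)


def cohort_statistics_sweep(
    n_seeds: int = 20, base_seed: int = 0, **overrides
) -> pd.DataFrame:
    """Spearman, log-rank and Cox HR across simulated cohorts."""
    rows = []
    for i in range(n_seeds):
        cfg = CohortSimConfig(seed=base_seed + i, **overrides)
        cohort, _ = generate_tma_cohort(cfg)
        grp = np.where(cohort["ar_category"] > cfg.high_cutoff, "high", "low")
        rho, _ = spearman(cohort["ar_category"], cohort["cdk11_category"])
        _, _, lr_p = log_rank(grp, cohort["followup_months"], cohort["event"].astype(bool))
        hr = cox_fit(
            pd.DataFrame({"ar_high": (grp == "high").astype(float)}),
            cohort["followup_months"],
            cohort["event"].astype(bool),
        ).hazard_ratio("ar_high")
        rows.append({"seed": cfg.seed, "spearman_rho": rho, "log_rank_p": lr_p,
                     "cox_hr": hr})
    return pd.DataFrame(rows)
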