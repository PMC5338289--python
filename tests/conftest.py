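"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately avoid the code paths they check: the
signed-rank oracle enumerates sign patterns with itertools, the
hypergeometric oracle counts combinations, the betweenness oracle
enumerates shortest paths explicitly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cdk11net.containers import ExpressionMatrix, ProbeLevelExperiment


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_signed_rank_p(diffs) -> float:
    """Exact one-sided signed-rank p by explicit sign enumeration."""
    d = [x for x in np.asarray(diffs, dtype=float) if x != 0.0]
    if not d:
        return 0.5
    ranks = stats.rankdata([abs(x) for x in d])
    w = sum(r for r, x in zip(ranks, d) if x > 0)
    hits = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        ws = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if ws >= w - 1e-9:
            hits += 1
    return hits / total


def brute_force_hypergeom_tail(population: int, successes: int, draws: int, k: int) -> float:
    """P(X >= k) by counting combinations."""
    total = math.comb(population, draws)
    acc = 0
    for j in range(k, min(successes, draws) + 1):
        acc += math.comb(successes, j) * math.comb(population - successes, draws - j)
    return acc / total


def brute_force_betweenness(g) -> dict:
    """Normalized betweenness by explicit shortest-path enumeration."""
    import networkx as nx

    nodes = sorted(g.nodes)
    score = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: s / norm for v, s in score.items()}


def breslow_partial_loglik(beta: float, x, times, events) -> float:
    """Scalar-covariate Breslow partial log-likelihood, direct sum."""
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
    return ll


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def tiny_experiment() -> ProbeLevelExperiment:
    """4 arrays x 3 probe sets x 8 probes of noiseless intensities."""
    rng = np.random.default_rng(42)
    rows = []
    arrays = [
        ("lineA_knockdown", "lineA", "knockdown"),
        ("lineA_control", "lineA", "control"),
        ("lineB_knockdown", "lineB", "knockdown"),
        ("lineB_control", "lineB", "control"),
    ]
    for pid in ["PS001", "PS002", "PS003"]:
        base = rng.uniform(200, 2000)
        for arr, _, _ in arrays:
            for idx in range(8):
                pm = base * (1 + 0.1 * idx)
                rows.append((arr, pid, idx, pm, 0.4 * pm))
    probes = pd.DataFrame(rows, columns=["array_id", "probeset_id", "probe_idx", "pm", "mm"])
    samples = pd.DataFrame(arrays, columns=["array_id", "cell_line", "condition"])
    return ProbeLevelExperiment(probes=probes, samples=samples).validate()


def expression_from_values(values: dict[str, list[float]], probesets: list[str]) -> ExpressionMatrix:
    """ExpressionMatrix from a {array_id: column} mapping over 2 lines."""
    samples = pd.DataFrame(
        [
            ("lineA_knockdown", "lineA", "knockdown"),
            ("lineA_control", "lineA", "control"),
            ("lineB_knockdown", "lineB", "knockdown"),
            ("lineB_control", "lineB", "control"),
        ],
        columns=["array_id", "cell_line", "condition"],
    )
    frame = pd.DataFrame(values, index=probesets)
    return ExpressionMatrix(values=frame, samples=samples[samples["array_id"].isin(frame.columns)])
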