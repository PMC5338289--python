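"""Synthetic inputs with planted ground truth.

Three generators emulate the three kinds of data the pipeline consumes:

* a four-array knockdown experiment (two osteosarcoma-like cell lines,
  siRNA knockdown vs non-specific-siRNA control) at the probe-pair level
  of an Affymetrix-style expression chip, with planted shared and
  line-specific responder probe sets;
* a gene-interaction graph with a planted well-connected hub wired to a
  chosen fraction of the seed genes, standing in for a curated
  interaction database;
* an immunohistochemistry cohort with correlated ordinal staining scores
  for two markers and a staining-dependent event hazard.

Every generator is a pure function of its config (including the RNG
seed): the same config yields byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import GroundTruth, ProbeLevelExperiment
from .errors import ConfigurationError

CELL_LINES = ("lineA", "lineB")

# Marginal staining-category frequencies observed on a published
# osteosarcoma tissue microarray (categories 0..5+ over 87 evaluable
# cores); the default latent cutpoints reproduce them in expectation.
DEFAULT_CATEGORY_FREQS = (5 / 87, 24 / 87, 22 / 87, 19 / 87, 15 / 87, 2 / 87)


def _default_thresholds() -> tuple[float, ...]:
    cum = np.cumsum(DEFAULT_CATEGORY_FREQS)[:-1]
    return tuple(float(t) for t in stats.norm.ppf(cum))


# ---------------------------------------------------------------------------
# microarray experiment
# ---------------------------------------------------------------------------


@dataclass
class ArraySimConfig:
    """Generative settings for the two-line knockdown experiment.

    ``effect_log2`` is the magnitude of the log2 shift a responder probe
    set undergoes in the knockdown array of a line where it responds;
    each responder is assigned a random direction (up or down in
    knockdown). ``mm_fraction`` is the expected mismatch/perfect-match
    intensity ratio for expressed probe sets. Absent probe sets are
    drawn at a fixed low background (``background_log2``) on every
    array, with PM and MM at the same level so they draw Absent calls.
    """

    n_probesets: int = 500
    probes_per_set: int = 11
    n_shared_responders: int = 20
    n_specific_responders_per_line: int = 10
    effect_log2: float = 1.5
    baseline_log2_range: tuple[float, float] = (7.0, 12.0)
    probe_affinity_sd: float = 0.5
    noise_sd: float = 0.15
    mm_fraction: float = 0.5
    n_absent_probesets: int = 50
    background_log2: float = 4.0
    n_replicates: int = 1
    seed: int = 0

    def validate(self) -> "ArraySimConfig":
        if self.n_probesets < 1:
            raise ConfigurationError("n_probesets must be >= 1")
        if self.probes_per_set < 3:
            raise ConfigurationError("probes_per_set must be >= 3 for detection calls")
        planted = (
            self.n_shared_responders
            + 2 * self.n_specific_responders_per_line
            + self.n_absent_probesets
        )
        if planted > self.n_probesets:
            raise ConfigurationError(
                "n_shared_responders + 2*n_specific_responders_per_line + "
                f"n_absent_probesets = {planted} exceeds n_probesets = {self.n_probesets}"
            )
        if not (0.0 < self.mm_fraction < 1.0):
            raise ConfigurationError("mm_fraction must lie in the open interval (0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.probe_affinity_sd < 0:
            raise ConfigurationError("probe_affinity_sd must be >= 0")
        lo, hi = self.baseline_log2_range
        if not lo <= hi:
            raise ConfigurationError("baseline_log2_range must be (low, high) with low <= high")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        return self


def _probeset_ids(n: int) -> list[str]:
    return [f"PS{i:05d}" for i in range(1, n + 1)]


def annotation_for(probeset_ids: list[str]) -> pd.DataFrame:
    """One-gene-per-probe-set annotation table (probeset_id, gene_symbol)."""
    return pd.DataFrame(
        {
            "probeset_id": probeset_ids,
            "gene_symbol": [pid.replace("PS", "GENE") for pid in probeset_ids],
        }
    )


def generate_microarray_experiment(
    cfg: ArraySimConfig,
) -> tuple[ProbeLevelExperiment, GroundTruth]:
    """Simulate PM/MM intensities for 2 cell lines x {knockdown, control}.

    The probe model is log-normal with additive per-probe affinities:

        PM_ij = 2 ** (baseline_s + affinity_j + dir * effect_log2 * I[responder]
                      + eps),            eps  ~ N(0, noise_sd)
        MM_ij = mm_fraction * PM_ij * 2 ** eps',   eps' ~ N(0, noise_sd)

    so with zero noise a responder's knockdown/control PM ratio equals
    exactly ``2 ** (dir * effect_log2)`` in its responding line, and
    median-polish summarization recovers the planted effect exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    probesets = _probeset_ids(cfg.n_probesets)
    perm = rng.permutation(cfg.n_probesets)
    k = cfg.n_shared_responders
    m = cfg.n_specific_responders_per_line
    shared_idx = perm[:k]
    specific_idx = {
        "lineA": perm[k : k + m],
        "lineB": perm[k + m : k + 2 * m],
    }
    absent_idx = perm[k + 2 * m : k + 2 * m + cfg.n_absent_probesets]
    absent = [probesets[i] for i in absent_idx]

    shared_dirs = {
        probesets[i]: int(d) for i, d in zip(shared_idx, rng.choice([-1, 1], size=k))
    }
    responder_sets: dict[str, dict[str, int]] = {}
    for line in CELL_LINES:
        dirs = dict(shared_dirs)
        for i, d in zip(specific_idx[line], rng.choice([-1, 1], size=m)):
            dirs[probesets[i]] = int(d)
        responder_sets[line] = dirs

    baselines = rng.uniform(*cfg.baseline_log2_range, size=cfg.n_probesets)
    affinities = rng.normal(0.0, cfg.probe_affinity_sd, size=(cfg.n_probesets, cfg.probes_per_set))

    sample_rows = []
    for line in CELL_LINES:
        for cond in ("knockdown", "control"):
            for rep in range(1, cfg.n_replicates + 1):
                suffix = f"_r{rep}" if cfg.n_replicates > 1 else ""
                sample_rows.append((f"{line}_{cond}{suffix}", line, cond))
    samples = pd.DataFrame(sample_rows, columns=["array_id", "cell_line", "condition"])

    is_absent = np.zeros(cfg.n_probesets, dtype=bool)
    is_absent[absent_idx] = True

    ps_index = {pid: i for i, pid in enumerate(probesets)}
    line_effect = {}
    for line in CELL_LINES:
        vec = np.zeros(cfg.n_probesets)
        for pid, d in responder_sets[line].items():
            vec[ps_index[pid]] = d * cfg.effect_log2
        line_effect[line] = vec

    frames = []
    for array_id, line, cond in sample_rows:
        effect = line_effect[line] if cond == "knockdown" else np.zeros(cfg.n_probesets)
        mean_log2 = baselines[:, None] + affinities + effect[:, None]
        mean_log2[is_absent] = cfg.background_log2
        eps = rng.normal(0.0, cfg.noise_sd, size=mean_log2.shape) if cfg.noise_sd > 0 else 0.0
        eps2 = rng.normal(0.0, cfg.noise_sd, size=mean_log2.shape) if cfg.noise_sd > 0 else 0.0
        pm = np.exp2(mean_log2 + eps)
        mm = np.where(
            is_absent[:, None],
            np.exp2(mean_log2 + eps2),  # background: no PM/MM discrimination
            cfg.mm_fraction * pm * np.exp2(eps2),
        )
        frames.append(
            pd.DataFrame(
                {
                    "array_id": array_id,
                    "probeset_id": np.repeat(probesets, cfg.probes_per_set),
                    "probe_idx": np.tile(np.arange(cfg.probes_per_set), cfg.n_probesets),
                    "pm": pm.ravel(),
                    "mm": mm.ravel(),
                }
            )
        )
    probes = pd.concat(frames, ignore_index=True)

    ann = annotation_for(probesets)
    truth = GroundTruth(
        responder_sets=responder_sets,
        shared_responders=shared_dirs,
        absent_probesets=absent,
        gene_of_probeset=dict(zip(ann["probeset_id"], ann["gene_symbol"])),
    )
    return ProbeLevelExperiment(probes=probes, samples=samples).validate(), truth


# ---------------------------------------------------------------------------
# interaction graph
# ---------------------------------------------------------------------------


@dataclass
class GraphSimConfig:
    """Settings for the synthetic gene-interaction graph.

    The base topology is a preferential-attachment (Barabasi-Albert)
    graph; one designated non-seed hub node is additionally wired to
    ``ceil(hub_seed_fraction * n_seeds)`` of the seed genes and tagged
    {bone, neoplasm}. Remaining nodes draw a single tissue/disease tag
    from ``tag_probs``.
    """

    n_nodes: int = 200
    edges_per_new_node: int = 2
    hub_seed_fraction: float = 0.7
    tag_probs: dict[str, float] = field(
        default_factory=lambda: {"bone": 0.3, "neoplasm": 0.3, "other": 0.4}
    )
    hub_name: str = "HUB"
    seed: int = 0

    def validate(self) -> "GraphSimConfig":
        if not (0.0 < self.hub_seed_fraction <= 1.0):
            raise ConfigurationError("hub_seed_fraction must lie in (0, 1]")
        if self.edges_per_new_node < 1:
            raise ConfigurationError("edges_per_new_node must be >= 1")
        if self.n_nodes < self.edges_per_new_node + 1:
            raise ConfigurationError("n_nodes must exceed edges_per_new_node")
        if abs(sum(self.tag_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("tag_probs frequencies must sum to 1")
        return self


def generate_interaction_graph(
    cfg: GraphSimConfig, seeds: set[str]
) -> tuple[nx.Graph, GroundTruth]:
    """Build a connected undirected gene graph containing every seed.

    Returns the graph (node attribute ``tags`` holds the tag set) and a
    ground truth recording the planted hub and the seeds it touches.
    """
    cfg.validate()
    seeds = sorted(seeds)
    n_wired = math.ceil(cfg.hub_seed_fraction * len(seeds))
    if n_wired < 2:
        raise ConfigurationError(
            "hub_seed_fraction * n_seeds must be >= 2 so the hub touches at least two seeds"
        )
    if len(seeds) + 1 > cfg.n_nodes:
        raise ConfigurationError("n_nodes too small to host all seeds plus the hub")

    rng = np.random.default_rng(cfg.seed)
    base = nx.barabasi_albert_graph(
        cfg.n_nodes, cfg.edges_per_new_node, seed=int(rng.integers(2**31))
    )

    # assign seed genes and the hub to random distinct base nodes
    slots = rng.permutation(cfg.n_nodes)
    labels: dict[int, str] = {}
    for slot, gene in zip(slots, seeds):
        labels[int(slot)] = gene
    hub_slot = int(slots[len(seeds)])
    labels[hub_slot] = cfg.hub_name
    filler = (i for i in range(cfg.n_nodes))
    for node in base.nodes:
        if node not in labels:
            labels[node] = f"N{next(filler):04d}"
    g = nx.relabel_nodes(base, labels)

    wired = [seeds[i] for i in sorted(rng.choice(len(seeds), size=n_wired, replace=False))]
    g.add_edges_from((cfg.hub_name, s) for s in wired)
    g.remove_edges_from(nx.selfloop_edges(g))

    tag_names = sorted(cfg.tag_probs)
    probs = np.array([cfg.tag_probs[t] for t in tag_names])
    for node in sorted(g.nodes):
        g.nodes[node]["tags"] = {tag_names[rng.choice(len(tag_names), p=probs)]}
    g.nodes[cfg.hub_name]["tags"] = {"bone", "neoplasm"}

    truth = GroundTruth(hub_gene=cfg.hub_name, hub_adjacent_seeds=wired)
    return g, truth


# ---------------------------------------------------------------------------
# TMA cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortSimConfig:
    """Settings for the synthetic immunohistochemistry cohort.

    Two latent standard-normal marker scores with correlation
    ``rho_latent`` are thresholded at ``category_thresholds`` (5 ordered
    cutpoints) into ordinal staining categories 0-5 for AR and CDK11.
    Event times are exponential with hazard ``baseline_hazard``
    multiplied by ``hazard_ratio_high`` for AR-high patients (category
    >= 3); censoring times are exponential with rate ``censor_rate``.
    """

    n_patients: int = 87
    rho_latent: float = 0.8
    category_thresholds: tuple[float, ...] = field(default_factory=_default_thresholds)
    hazard_ratio_high: float = 2.5
    baseline_hazard: float = 0.015  # events per month
    censor_rate: float = 0.008
    high_cutoff: int = 2  # category <= cutoff is "low"
    covariate_mixes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "gender": {"male": 0.6, "female": 0.4},
            "grade": {"1": 0.13, "2": 0.46, "3": 0.41},
            "metastasis": {"absent": 0.33, "present": 0.67},
            "recurrence": {"absent": 0.7, "present": 0.3},
            "chemo_response": {"good": 0.13, "poor": 0.55, "NA": 0.32},
        }
    )
    seed: int = 0

    def validate(self) -> "CohortSimConfig":
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not -1.0 <= self.rho_latent <= 1.0:
            raise ConfigurationError("rho_latent must lie in [-1, 1]")
        t = self.category_thresholds
        if len(t) != 5 or any(a >= b for a, b in zip(t, t[1:])):
            raise ConfigurationError(
                "category_thresholds must be 5 strictly increasing cutpoints"
            )
        if self.hazard_ratio_high <= 0:
            raise ConfigurationError("hazard_ratio_high must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ConfigurationError("censor_rate must be >= 0")
        for cov, mix in self.covariate_mixes.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"covariate_mixes[{cov!r}] frequencies must sum to 1")
        return self


def generate_tma_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a TMA cohort table with correlated AR/CDK11 staining.

    Columns: patient_id, ar_category, cdk11_category, age_years, gender,
    grade, metastasis, recurrence, chemo_response, followup_months,
    event.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    z_ar = rng.normal(size=n)
    noise = rng.normal(size=n)
    rho = cfg.rho_latent
    z_cdk = rho * z_ar + math.sqrt(max(0.0, 1.0 - rho * rho)) * noise

    cuts = np.asarray(cfg.category_thresholds)
    ar_cat = np.searchsorted(cuts, z_ar).astype(int)
    cdk_cat = np.searchsorted(cuts, z_cdk).astype(int)

    ar_high = ar_cat > cfg.high_cutoff
    hazard = cfg.baseline_hazard * np.where(ar_high, cfg.hazard_ratio_high, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        censor_time = rng.exponential(1.0 / cfg.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    followup = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    age = np.clip(np.round(rng.lognormal(math.log(28.0), 0.45, size=n)), 6, 75).astype(int)

    covs = {}
    for cov, mix in cfg.covariate_mixes.items():
        levels = sorted(mix)
        probs = np.array([mix[lv] for lv in levels])
        covs[cov] = np.array(levels)[rng.choice(len(levels), size=n, p=probs / probs.sum())]

    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "ar_category": ar_cat,
            "cdk11_category": cdk_cat,
            "age_years": age,
            "gender": covs["gender"],
            "grade": covs["grade"].astype(int),
            "metastasis": covs["metastasis"],
            "recurrence": covs["recurrence"],
            "chemo_response": covs["chemo_response"],
            "followup_months": followup,
            "event": event.astype(int),
        }
    )
    truth = GroundTruth(
        cohort_params={
            "rho_latent": cfg.rho_latent,
            "hazard_ratio_high": cfg.hazard_ratio_high,
            "baseline_hazard": cfg.baseline_hazard,
            "high_cutoff": cfg.high_cutoff,
        }
    )
    return cohort, truth
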