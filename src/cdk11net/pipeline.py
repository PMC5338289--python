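"""Pipeline orchestration: simulate -> preprocess -> diffexpr -> network -> tma.

Stage boundaries are files on disk, so any stage can be re-run alone or
fed externally produced data of the same shape (e.g. probe tables
extracted from real arrays). ``run_pipeline`` executes the stages in
order from a single config mapping and writes a JSON manifest with the
config hash and a checksum of every output, so a re-run with the same
config and seed can be verified byte-identical.
"""

from __future__ import annotations

import datetime
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .diffexpr import (
    DEFAULT_Z_THRESHOLD,
    cluster_and_order,
    compute_diff,
    intersect_hits,
    select_hits,
)
from .errors import Cdk11NetError
from .network import (
    build_seed_subnetworks,
    filter_by_annotation,
    merge_subnetworks,
    nominate_central_node,
    rank_central_nodes,
    select_containing,
)
from .preprocess import (
    MIN_MAX_LOG2,
    DetectionParams,
    call_matrix,
    filter_probesets,
    summarize_experiment,
)
from .simulate import (
    ArraySimConfig,
    CohortSimConfig,
    GraphSimConfig,
    annotation_for,
    generate_interaction_graph,
    generate_microarray_experiment,
    generate_tma_cohort,
)
from .survival import (
    chi_square,
    cohort_summary,
    cox_fit,
    dichotomize,
    kaplan_meier,
    log_rank,
    spearman,
    staining_distribution,
    stepwise_cox,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "diffexpr", "network", "tma")


class StageError(Cdk11NetError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_jsonable(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
            "started": self.started,
            "finished": self.finished,
        }


def default_config(seed: int = 0) -> dict:
    """A complete demo config; every block can be overridden from YAML."""
    return {
        "seed": seed,
        "array": {},
        "detection": {},
        "diffexpr": {"threshold": DEFAULT_Z_THRESHOLD, "min_max_log2": MIN_MAX_LOG2},
        "network": {
            "n_nodes": 200,
            "edges_per_new_node": 2,
            "hub_seed_fraction": 0.7,
            "allowed_tags": ["bone", "neoplasm"],
            "anchor": None,
        },
        "cohort": {},
    }


def _merged(config: dict | None, seed: int | None) -> dict:
    cfg = default_config()
    for key, block in (config or {}).items():
        if isinstance(block, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(block)
        else:
            cfg[key] = block
    if seed is not None:
        cfg["seed"] = seed
    return cfg


class PipelineRun:
    """Executes stages against an output directory, tracking the manifest."""

    def __init__(self, config: dict | None = None, outdir: str | Path = "out",
                 seed: int | None = None):
        self.config = _merged(config, seed)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(self.config.get("seed", 0))
        self.meta = {"seed": self.seed, "config_hash": io.config_hash(self.config)}
        self.manifest = RunManifest(config_hash=self.meta["config_hash"], seed=self.seed)

    def path(self, name: str) -> Path:
        return self.outdir / name

    def _run_stage(self, name: str, fn) -> None:
        t0 = time.time()
        written: list[Path] = []
        try:
            outputs = fn(written)
        except Exception as err:  # noqa: BLE001 - rename partials, then re-raise
            for p in written:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise StageError(name, err) from err
        self.manifest.stages[name] = {
            "outputs": {p.name: io.file_checksum(p) for p in written},
            "elapsed_s": round(time.time() - t0, 3),
            **(outputs or {}),
        }

    # -- stages -------------------------------------------------------------

    def simulate(self) -> None:
        def fn(written):
            acfg = ArraySimConfig(**{"seed": self.seed, **self.config["array"]})
            exp, truth = generate_microarray_experiment(acfg)
            ccfg = CohortSimConfig(**{"seed": self.seed + 2, **self.config["cohort"]})
            cohort, ctruth = generate_tma_cohort(ccfg)
            truth.cohort_params = ctruth.cohort_params
            ann = annotation_for(sorted(exp.probes["probeset_id"].unique()))
            io.write_experiment(exp, self.path("probes.tsv"), self.path("samples.tsv"),
                                meta=self.meta)
            io.write_table(ann, self.path("annotation.tsv"), meta=self.meta)
            io.write_cohort(cohort, self.path("cohort.csv"), meta=self.meta)
            io.write_json(truth.to_jsonable(), self.path("ground_truth.json"))
            written.extend(
                self.path(n)
                for n in ["probes.tsv", "samples.tsv", "annotation.tsv",
                          "cohort.csv", "ground_truth.json"]
            )
            return {"n_probesets": acfg.n_probesets, "n_patients": ccfg.n_patients}

        self._run_stage("simulate", fn)

    def preprocess(self) -> None:
        def fn(written):
            exp = io.read_experiment(self.path("probes.tsv"), self.path("samples.tsv"))
            params = DetectionParams(**self.config["detection"])
            calls = call_matrix(exp, params)
            expr = summarize_experiment(exp)
            filtered, report = filter_probesets(
                expr, calls, self.config["diffexpr"]["min_max_log2"]
            )
            io.write_calls(calls, self.path("calls.tsv"), self.path("call_pvalues.tsv"),
                           meta=self.meta)
            io.write_expression(filtered, self.path("expression.tsv"),
                                self.path("expr_samples.tsv"), meta=self.meta)
            written.extend(
                self.path(n)
                for n in ["calls.tsv", "call_pvalues.tsv", "expression.tsv",
                          "expr_samples.tsv"]
            )
            return {
                "n_input": report.n_input,
                "n_dropped_all_absent": report.n_dropped_all_absent,
                "n_dropped_low_max": report.n_dropped_low_max,
                "n_kept": report.n_kept,
            }

        self._run_stage("preprocess", fn)

    def diffexpr(self) -> None:
        def fn(written):
            expr = io.read_expression(self.path("expression.tsv"),
                                      self.path("expr_samples.tsv"))
            ann = io.read_table(self.path("annotation.tsv"))
            threshold = float(self.config["diffexpr"]["threshold"])
            hits = {}
            for line in expr.cell_lines:
                diff = compute_diff(expr, line)
                hits[line] = select_hits(diff, ann, threshold)
                io.write_table(hits[line].entries, self.path(f"hits_{line}.tsv"),
                               meta=self.meta)
                written.append(self.path(f"hits_{line}.tsv"))
            lines = expr.cell_lines
            common = intersect_hits(hits[lines[0]], hits[lines[1]])
            io.write_table(common.genes.reset_index(), self.path("common_hits.tsv"),
                           meta=self.meta)
            written.append(self.path("common_hits.tsv"))
            if len(common) >= 2:
                order, _ = cluster_and_order(
                    common.genes[[f"d_{lines[0]}", f"d_{lines[1]}"]]
                )
                ordered = common.genes.loc[order]
                io.write_table(ordered.reset_index(), self.path("heatmap_matrix.tsv"),
                               meta=self.meta)
                written.append(self.path("heatmap_matrix.tsv"))
                self._heatmap(ordered[[f"d_{lines[0]}", f"d_{lines[1]}"]], written)
            return {
                "hit_probes": {ln: len(hits[ln]) for ln in lines},
                "hit_genes": {ln: len(hits[ln].genes) for ln in lines},
                "n_common_genes": len(common),
            }

        self._run_stage("diffexpr", fn)

    def _heatmap(self, matrix: pd.DataFrame, written: list[Path]) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, max(2, 0.18 * len(matrix))))
        vmax = float(np.abs(matrix.to_numpy()).max()) or 1.0
        im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(matrix.shape[1]), matrix.columns, fontsize=7)
        ax.set_yticks(range(len(matrix)), matrix.index, fontsize=5)
        fig.colorbar(im, ax=ax, label="control - knockdown (log2)")
        fig.tight_layout()
        path = self.path("heatmap.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    def network(self) -> None:
        def fn(written):
            ncfg = dict(self.config["network"])
            allowed = set(ncfg.pop("allowed_tags"))
            anchor = ncfg.pop("anchor")
            common = io.read_table(self.path("common_hits.tsv"))
            seeds = set(common["gene_symbol"])
            if len(seeds) < 3:
                raise Cdk11NetError(
                    f"only {len(seeds)} common genes; too few seeds for network reconstruction"
                )
            gcfg = GraphSimConfig(**{"seed": self.seed + 1, **ncfg})
            g, truth = generate_interaction_graph(gcfg, seeds)
            io.write_graph(g, self.path("edges.tsv"), self.path("node_tags.tsv"),
                           meta=self.meta)
            written.extend([self.path("edges.tsv"), self.path("node_tags.tsv")])
            if anchor is None:
                # the anchor plays the knocked-down gene's part: a gene known
                # to sit next to the network's driver; default to the first
                # hub-adjacent seed recorded by the generator
                anchor = truth.hub_adjacent_seeds[0]
            subnets = build_seed_subnetworks(g, seeds)
            chosen = select_containing(subnets, anchor)
            if not chosen:
                raise Cdk11NetError(f"anchor {anchor!r} not in any candidate subnetwork")
            merged = merge_subnetworks(chosen, g, all_seeds=seeds)
            final = filter_by_annotation(merged, allowed, {anchor})
            report = rank_central_nodes(final)
            io.write_table(report.reset_index(), self.path("centrality.tsv"),
                           meta=self.meta)
            io.write_graph(final.graph, self.path("final_network_edges.tsv"),
                           meta=self.meta)
            written.extend([self.path("centrality.tsv"),
                            self.path("final_network_edges.tsv")])
            central = nominate_central_node(report)
            io.write_json(
                {
                    "anchor": anchor,
                    "central_node": central,
                    "planted_hub": truth.hub_gene,
                    "n_candidate_subnetworks": len(subnets),
                    "n_containing_anchor": len(chosen),
                    "merged_size": len(merged),
                    "final_size": len(final),
                    "enrichment_p": merged.enrichment_p,
                },
                self.path("network_summary.json"),
            )
            written.append(self.path("network_summary.json"))
            return {"central_node": central, "planted_hub": truth.hub_gene}

        self._run_stage("network", fn)

    def tma(self) -> None:
        def fn(written):
            cohort = io.read_cohort(self.path("cohort.csv"))
            cutoff = int(self.config.get("tma", {}).get("cutoff", 2))
            cohort["ar_group"] = [dichotomize(int(c), cutoff) for c in cohort["ar_category"]]
            cohort["cdk11_group"] = [
                dichotomize(int(c), cutoff) for c in cohort["cdk11_category"]
            ]
            summary = cohort_summary(cohort, cutoff)
            io.write_table(summary, self.path("cohort_summary.csv"), sep=",",
                           meta=self.meta)
            written.append(self.path("cohort_summary.csv"))
            dist = staining_distribution(
                np.bincount(cohort["ar_category"], minlength=6)[:6], cutoff
            )
            io.write_table(dist, self.path("ar_staining_distribution.csv"), sep=",",
                           meta=self.meta)
            written.append(self.path("ar_staining_distribution.csv"))

            ct = pd.crosstab(cohort["ar_group"], cohort["cdk11_group"])
            chi2_stat, chi2_df, chi2_p = chi_square(ct.to_numpy())
            rho, rho_p = spearman(cohort["ar_category"], cohort["cdk11_category"])
            times = cohort["followup_months"].to_numpy(float)
            events = cohort["event"].to_numpy(bool)
            groups = cohort["ar_group"].to_numpy()
            lr_stat, lr_df, lr_p = log_rank(groups, times, events)

            curves = {}
            for label in ("low", "high"):
                mask = groups == label
                curve = kaplan_meier(times[mask], events[mask])
                frame = pd.DataFrame(
                    {"time": curve.times, "at_risk": curve.at_risk,
                     "survival": curve.survival}
                )
                p = self.path(f"km_ar_{label}.tsv")
                io.write_table(frame, p, meta=self.meta)
                written.append(p)
                curves[label] = curve

            x = pd.DataFrame({"ar_high": (groups == "high").astype(float)})
            cox = cox_fit(x, times, events)
            candidates = pd.DataFrame(
                {
                    "ar_high": (groups == "high").astype(float),
                    "age": cohort["age_years"].astype(float),
                    "male": (cohort["gender"] == "male").astype(float),
                    "grade": cohort["grade"].astype(float),
                    "metastasis": (cohort["metastasis"] == "present").astype(float),
                    "recurrence": (cohort["recurrence"] == "present").astype(float),
                }
            )
            step = stepwise_cox(candidates, times, events)
            stats_out = {
                "chi_square": {"statistic": chi2_stat, "df": chi2_df, "p": chi2_p},
                "spearman": {"rho": rho, "p": rho_p},
                "log_rank": {"statistic": lr_stat, "df": lr_df, "p": lr_p},
                "cox_ar_high": cox.summary.reset_index().to_dict(orient="records"),
                "stepwise_selected": step.covariates,
                "stepwise_summary": step.summary.reset_index().to_dict(orient="records"),
            }
            io.write_json(stats_out, self.path("tma_stats.json"))
            written.append(self.path("tma_stats.json"))
            self._km_plot(curves, written)
            return {
                "spearman_rho": rho,
                "log_rank_p": lr_p,
                "cox_hr_ar_high": cox.hazard_ratio("ar_high"),
            }

        self._run_stage("tma", fn)

    def _km_plot(self, curves, written: list[Path]) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for label, curve in curves.items():
            ax.step(np.concatenate([[0], curve.times]),
                    np.concatenate([[1.0], curve.survival]),
                    where="post", label=f"AR {label}")
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        fig.tight_layout()
        path = self.path("km_ar.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    # -- driver -------------------------------------------------------------

    def run(self, stages: tuple[str, ...] = STAGES) -> RunManifest:
        self.manifest.started = datetime.datetime.now().isoformat(timespec="seconds")
        for stage in stages:
            logger.info("running stage %s", stage)
            getattr(self, stage)()
        self.manifest.finished = datetime.datetime.now().isoformat(timespec="seconds")
        io.write_json(self.manifest.to_jsonable(), self.path("manifest.json"))
        return self.manifest


def run_pipeline(config: dict | None = None, outdir: str | Path = "out",
                 seed: int | None = None,
                 stages: tuple[str, ...] = STAGES) -> RunManifest:
    """Execute the pipeline end to end and return its manifest."""
    return PipelineRun(config, outdir, seed).run(stages)


def make_report(outdir: str | Path) -> Path:
    """Collate a run's outputs into a single markdown report.

    Sections whose stage outputs are missing are flagged rather than
    failing, so partial runs still produce a readable document.
    """
    outdir = Path(outdir)
    manifest = io.read_json(outdir / "manifest.json")
    lines = ["# cdk11net run report", "",
             f"config hash: `{manifest['config_hash']}`  seed: {manifest['seed']}", ""]

    stages = manifest.get("stages", {})
    pre = stages.get("preprocess")
    lines.append("## Preprocessing")
    if pre:
        lines += [
            f"- probe sets in: {pre['n_input']}",
            f"- dropped (absent on all arrays): {pre['n_dropped_all_absent']}",
            f"- dropped (max log2 <= threshold): {pre['n_dropped_low_max']}",
            f"- retained: {pre['n_kept']}", "",
        ]
    else:
        lines += ["- MISSING: preprocess stage did not complete", ""]

    de = stages.get("diffexpr")
    lines.append("## Differential expression")
    if de:
        for ln, n in de["hit_probes"].items():
            lines.append(f"- {ln}: {n} hit probes ({de['hit_genes'][ln]} genes)")
        lines += [f"- common genes in both lines: {de['n_common_genes']}", ""]
        truth_path = outdir / "ground_truth.json"
        common_path = outdir / "common_hits.tsv"
        if truth_path.exists() and common_path.exists():
            truth = io.read_json(truth_path)
            planted = {
                truth["gene_of_probeset"][pid] for pid in truth["shared_responders"]
            }
            found = set(io.read_table(common_path)["gene_symbol"])
            tp = len(planted & found)
            lines += [
                "### Recovery of planted shared responders",
                f"- planted: {len(planted)}, recovered: {tp}, "
                f"missed: {len(planted - found)}, spurious: {len(found - planted)}", "",
            ]
    else:
        lines += ["- MISSING: diffexpr stage did not complete", ""]

    net = stages.get("network")
    lines.append("## Network")
    if net:
        lines += [
            f"- nominated central node: **{net['central_node']}**",
            f"- planted hub: {net['planted_hub']}", "",
        ]
    else:
        lines += ["- MISSING: network stage did not complete", ""]

    tma = stages.get("tma")
    lines.append("## TMA cohort")
    if tma:
        lines += [
            f"- Spearman rho (AR vs CDK11 staining): {tma['spearman_rho']:.3f}",
            f"- log-rank p (AR high vs low): {tma['log_rank_p']:.3g}",
            f"- Cox HR for AR-high: {tma['cox_hr_ar_high']:.2f}", "",
        ]
    else:
        lines += ["- MISSING: tma stage did not complete", ""]

    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
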