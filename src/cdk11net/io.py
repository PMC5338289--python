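"""Reading and writing the pipeline's plain-text interchange files.

Stage boundaries are files: tab-delimited tables for expression data,
CSV for the cohort, TSV edge lists for the graph, JSON for ground truth
and manifests. Every numeric table is written with a comment header
recording the seed and config hash of the run that produced it; readers
skip '#' comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import (
    DetectionCallMatrix,
    ExpressionMatrix,
    ProbeLevelExperiment,
)
from .errors import InputError


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _header(meta: dict | None) -> str:
    if not meta:
        return ""
    pairs = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# {pairs}\n"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    sep: str = "\t",
    index: bool = False,
    meta: dict | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, sep=sep, index=index)
    return path


def read_table(path: str | Path, sep: str = "\t", index_col=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


# -- probe-level experiment -------------------------------------------------


def write_experiment(
    exp: ProbeLevelExperiment, probes_path, samples_path, meta: dict | None = None
) -> None:
    write_table(exp.probes, probes_path, meta=meta)
    write_table(exp.samples, samples_path, meta=meta)


def read_experiment(probes_path, samples_path) -> ProbeLevelExperiment:
    return ProbeLevelExperiment(
        probes=read_table(probes_path), samples=read_table(samples_path)
    ).validate()


# -- expression / call matrices ---------------------------------------------


def write_expression(
    expr: ExpressionMatrix, values_path, samples_path=None, meta: dict | None = None
) -> None:
    write_table(expr.values, values_path, index=True, meta=meta)
    if samples_path is not None:
        write_table(expr.samples, samples_path, meta=meta)


def read_expression(values_path, samples_path) -> ExpressionMatrix:
    values = read_table(values_path, index_col=0)
    samples = read_table(samples_path)
    return ExpressionMatrix(values=values, samples=samples).validate()


def write_calls(calls: DetectionCallMatrix, calls_path, pvalues_path=None, meta=None) -> None:
    write_table(calls.calls, calls_path, index=True, meta=meta)
    if pvalues_path is not None:
        write_table(calls.pvalues, pvalues_path, index=True, meta=meta)


def read_calls(calls_path, pvalues_path=None) -> DetectionCallMatrix:
    calls = read_table(calls_path, index_col=0)
    if pvalues_path is not None:
        pvalues = read_table(pvalues_path, index_col=0)
    else:
        pvalues = pd.DataFrame(float("nan"), index=calls.index, columns=calls.columns)
    return DetectionCallMatrix(calls=calls, pvalues=pvalues).validate()


# -- interaction graph ------------------------------------------------------


def write_graph(g: nx.Graph, edges_path, tags_path=None, meta: dict | None = None) -> None:
    edges = pd.DataFrame(
        sorted((min(a, b), max(a, b)) for a, b in g.edges), columns=["node_a", "node_b"]
    )
    write_table(edges, edges_path, meta=meta)
    if tags_path is not None:
        tags = pd.DataFrame(
            {
                "node": sorted(g.nodes),
                "tags": [
                    ",".join(sorted(g.nodes[n].get("tags", ()))) for n in sorted(g.nodes)
                ],
            }
        )
        write_table(tags, tags_path, meta=meta)


def read_graph(edges_path, tags_path=None) -> nx.Graph:
    edges = read_table(edges_path)
    g = nx.Graph()
    g.add_edges_from(zip(edges["node_a"], edges["node_b"]))
    if tags_path is not None:
        tags = read_table(tags_path)
        for _, row in tags.iterrows():
            node = row["node"]
            if node not in g:
                g.add_node(node)
            raw = row["tags"]
            g.nodes[node]["tags"] = (
                set(str(raw).split(",")) if isinstance(raw, str) and raw else set()
            )
    return g


# -- cohort & JSON ----------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(cohort, path, sep=",", meta=meta)


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    # "NA" is a real stratum (chemo response not assessed), not missing data
    cohort = pd.read_csv(path, comment="#", keep_default_na=False, na_values=[""])
    required = {"ar_category", "cdk11_category", "followup_months", "event"}
    missing = required - set(cohort.columns)
    if missing:
        raise InputError(f"cohort table missing columns {sorted(missing)}")
    return cohort


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
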