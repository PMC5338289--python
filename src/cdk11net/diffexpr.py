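"""Paired-difference z-score differential expression and hit intersection.

For each cell line a single knockdown array is compared against its
control by subtracting knockdown from control expression probe set by
probe set ("Diff_Data"); the differences are standardized by their own
mean and standard deviation, and probe sets with |z| at or beyond a
threshold (default 3) form the line's hit list. The hit lists of the
two lines are intersected at the gene level; genes hit by multiple
probes carry the average difference, and genes whose direction differs
between the lines are kept but flagged discordant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix
from .errors import AnalysisError, InputError

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 3.0


@dataclass
class DiffData:
    """Control-minus-knockdown differences and their z-scores for one line.

    A positive difference means expression fell upon knockdown.
    """

    cell_line: str
    d: pd.Series  # probeset -> difference (log2 units)
    mu: float
    sigma: float
    z: pd.Series  # probeset -> (d - mu) / sigma


@dataclass
class HitList:
    """Probe sets whose |z| meets the threshold, most extreme first."""

    cell_line: str
    threshold: float
    entries: pd.DataFrame  # columns: probeset_id, gene_symbol, d, z, direction

    @property
    def genes(self) -> set[str]:
        return set(self.entries["gene_symbol"].dropna())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CommonHitSet:
    """Genes hit in both cell lines, with per-line averaged differences."""

    genes: pd.DataFrame  # index gene, columns: d_<lineA>, d_<lineB>, concordant
    provenance: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    @property
    def gene_names(self) -> set[str]:
        return set(self.genes.index)

    def __len__(self) -> int:
        return len(self.genes)


def compute_diff(expr: ExpressionMatrix, line: str) -> DiffData:
    """Diff_Data for one cell line: control minus knockdown, z-scored.

    The z-scores use the sample standard deviation (n-1 denominator)
    over all retained probe sets, so by construction mean(z) = 0 and
    sd(z) = 1.
    """
    expr.validate()
    control = expr.sample_for(line, "control")
    knockdown = expr.sample_for(line, "knockdown")
    d = expr.values[control] - expr.values[knockdown]
    mu = float(d.mean())
    sigma = float(d.std(ddof=1))
    if not np.isfinite(sigma) or sigma <= 0:
        raise AnalysisError(
            f"differences for line {line!r} have zero variance; z-scores undefined"
        )
    return DiffData(cell_line=line, d=d, mu=mu, sigma=sigma, z=(d - mu) / sigma)


def select_hits(
    diff: DiffData,
    annotation: pd.DataFrame | dict[str, str],
    threshold: float = DEFAULT_Z_THRESHOLD,
    strict_gt: bool = False,
) -> HitList:
    """Probe sets with z at or beyond +/-threshold, annotated and sorted.

    ``annotation`` maps probeset_id -> gene_symbol (a dict or a frame
    with those two columns). Probe sets missing from the annotation are
    kept with a null symbol and a logged warning; they cannot enter a
    gene-level intersection.
    """
    if threshold <= 0:
        raise InputError("threshold must be > 0")
    if isinstance(annotation, pd.DataFrame):
        ann = dict(zip(annotation["probeset_id"], annotation["gene_symbol"]))
    else:
        ann = dict(annotation)
    mask = np.abs(diff.z) > threshold if strict_gt else np.abs(diff.z) >= threshold
    hits = pd.DataFrame(
        {
            "probeset_id": diff.z.index[mask],
            "d": diff.d[mask].to_numpy(),
            "z": diff.z[mask].to_numpy(),
        }
    )
    hits["gene_symbol"] = [ann.get(pid) for pid in hits["probeset_id"]]
    unannotated = hits["gene_symbol"].isna()
    if unannotated.any():
        logger.warning(
            "%d hit probe sets lack a gene symbol and cannot enter the intersection",
            int(unannotated.sum()),
        )
    hits["direction"] = np.where(hits["d"] > 0, "down_in_knockdown", "up_in_knockdown")
    hits = hits.sort_values(
        ["z", "probeset_id"], key=lambda s: -s.abs() if s.name == "z" else s
    ).reset_index(drop=True)
    return HitList(
        cell_line=diff.cell_line,
        threshold=threshold,
        entries=hits[["probeset_id", "gene_symbol", "d", "z", "direction"]],
    )


def _gene_means(hits: HitList) -> pd.DataFrame:
    e = hits.entries.dropna(subset=["gene_symbol"])
    return e.groupby("gene_symbol").agg(
        d=("d", "mean"), probesets=("probeset_id", list)
    )


def intersect_hits(a: HitList, b: HitList) -> CommonHitSet:
    """Gene-level intersection of two per-line hit lists.

    Genes present in both lists are retained regardless of direction;
    multi-probe genes carry the mean difference of their hit probes in
    each line. ``concordant`` records whether the sign of the averaged
    difference agrees between the lines.
    """
    ga, gb = _gene_means(a), _gene_means(b)
    common = sorted(set(ga.index) & set(gb.index))
    da = ga.loc[common, "d"]
    db = gb.loc[common, "d"]
    frame = pd.DataFrame(
        {
            f"d_{a.cell_line}": da,
            f"d_{b.cell_line}": db,
            "concordant": np.sign(da) == np.sign(db),
        },
        index=pd.Index(common, name="gene_symbol"),
    )
    prov = {
        g: {a.cell_line: ga.loc[g, "probesets"], b.cell_line: gb.loc[g, "probesets"]}
        for g in common
    }
    return CommonHitSet(genes=frame, provenance=prov)


def cluster_and_order(values: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Agglomerative ordering of genes for heatmap display.

    Average linkage on Euclidean row distances; rows are pre-sorted
    lexicographically so equal-distance merges resolve identically
    regardless of input row order. Returns (leaf order, linkage matrix).
    """
    if len(values) < 2:
        raise InputError("clustering needs at least 2 rows")
    x = values.sort_index()
    arr = x.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise InputError("clustering requires finite values")
    link = hierarchy.linkage(pdist(arr, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(link)
    return [x.index[i] for i in order], link
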