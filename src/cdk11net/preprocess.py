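"""Probe-level preprocessing: detection calls, normalization, summarization.

The Present/Marginal/Absent detection call follows the classic
Wilcoxon-signed-rank presence/absence algorithm used for PM/MM
expression chips: per probe pair a discrimination score
``R_i = (PM_i - MM_i) / (PM_i + MM_i)`` is tested one-sided against a
small offset ``tau``; the resulting p-value is thresholded at
``alpha1``/``alpha2`` into P, M or A. The exact null distribution is
enumerated over all sign assignments for small probe counts; larger
counts fall back to the tie-corrected normal approximation.

Between-array normalization is quantile normalization of log2(PM), and
probe sets are summarized to one value per array by Tukey median
polish. Probe sets absent on every array, or never exceeding a minimum
intensity, are filtered before differential analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DetectionCallMatrix, ExpressionMatrix, ProbeLevelExperiment
from .errors import InputError

#: minimum max-intensity filter threshold, log2(100)
MIN_MAX_LOG2 = float(np.log2(100.0))


@dataclass
class DetectionParams:
    """Thresholds of the presence/absence call.

    Defaults are the published chip-vendor defaults: ``tau`` offsets the
    discrimination scores before ranking; p < ``alpha1`` is Present,
    ``alpha1`` <= p < ``alpha2`` is Marginal, otherwise Absent.
    """

    tau: float = 0.015
    alpha1: float = 0.04
    alpha2: float = 0.06

    def validate(self) -> "DetectionParams":
        if not (0.0 < self.alpha1 < self.alpha2 < 0.5):
            raise InputError("require 0 < alpha1 < alpha2 < 0.5")
        if self.tau < 0:
            raise InputError("tau must be >= 0")
        return self


@lru_cache(maxsize=16)
def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign patterns as a (2^n, n) 0/1 matrix."""
    bits = np.arange(2**n, dtype=np.uint32)
    return ((bits[:, None] >> np.arange(n)) & 1).astype(np.float64)


@lru_cache(maxsize=16)
def _untied_dist(n: int) -> np.ndarray:
    """Sorted exact null distribution of W for untied ranks 1..n."""
    return np.sort(_sign_matrix(n) @ np.arange(1.0, n + 1.0))


def signed_rank_p(diffs: np.ndarray, exact_max_n: int = 12) -> float:
    """One-sided signed-rank p-value for median(diffs) > 0.

    Zero differences are dropped; tied absolute values share mid-ranks.
    For n <= ``exact_max_n`` the p-value is exact, computed from the
    full 2^n enumeration of sign assignments on the observed ranks;
    above that a normal approximation with tie correction and a 0.5
    continuity correction is used.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.5
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        if np.unique(ranks).size == n:
            # untied ranks are a permutation of 1..n: the cached null
            # distribution applies, no per-call enumeration needed
            dist = _untied_dist(n)
            idx = np.searchsorted(dist, w - 1e-9, side="left")
            return float((dist.size - idx) / dist.size)
        dist = _sign_matrix(n) @ ranks
        return float(np.mean(dist >= w - 1e-9))
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 0.5
    z = (w - mu - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


def detection_call(
    pm: np.ndarray, mm: np.ndarray, params: DetectionParams | None = None
) -> tuple[str, float]:
    """Present/Marginal/Absent call for one probe set on one array."""
    params = (params or DetectionParams()).validate()
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape or pm.ndim != 1:
        raise InputError("pm and mm must be 1-D vectors of equal length")
    if pm.size < 3:
        raise InputError("detection call needs at least 3 probe pairs")
    if (pm <= 0).any() or (mm <= 0).any():
        raise InputError("intensities must be strictly positive")
    r = (pm - mm) / (pm + mm)
    p = signed_rank_p(r - params.tau)
    if p < params.alpha1:
        call = "P"
    elif p < params.alpha2:
        call = "M"
    else:
        call = "A"
    return call, p


def call_matrix(
    exp: ProbeLevelExperiment, params: DetectionParams | None = None
) -> DetectionCallMatrix:
    """One detection call per probe set per array."""
    params = (params or DetectionParams()).validate()
    exp.validate()
    arrays = exp.array_ids
    probesets = exp.probeset_ids
    wide = exp.probes.pivot(
        index=["probeset_id", "probe_idx"], columns="array_id", values=["pm", "mm"]
    )
    pm_wide = wide["pm"][arrays]
    mm_wide = wide["mm"][arrays]
    call_rows = {}
    pval_rows = {}
    for pid in probesets:
        pm = pm_wide.xs(pid, level="probeset_id").to_numpy()
        mm = mm_wide.xs(pid, level="probeset_id").to_numpy()
        crow, prow = [], []
        for k, arr in enumerate(arrays):
            try:
                c, p = detection_call(pm[:, k], mm[:, k], params)
            except InputError as err:
                raise InputError(f"probe set {pid!r}, array {arr!r}: {err}") from err
            crow.append(c)
            prow.append(p)
        call_rows[pid] = crow
        pval_rows[pid] = prow
    calls = pd.DataFrame.from_dict(call_rows, orient="index", columns=arrays)
    pvals = pd.DataFrame.from_dict(pval_rows, orient="index", columns=arrays)
    return DetectionCallMatrix(calls=calls, pvalues=pvals).validate()


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common (mean-of-sorted) distribution.

    Ties within a column receive the mean of the reference values their
    positions span, so the transform is rank-preserving and idempotent.
    """
    if values.size == 0:
        raise InputError("cannot quantile-normalize an empty matrix")
    x = values.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise InputError("quantile normalization requires finite values")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        col = np.empty(x.shape[0])
        col[order] = ref
        # ties share the mean of the reference values they would occupy
        s = pd.Series(col).groupby(x[:, j]).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def median_polish(
    x: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a probe x sample matrix.

    Returns (overall, row_effects, col_effects, residuals) of the
    additive decomposition ``x = overall + row + col + resid``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise InputError("median polish expects a non-empty 2-D matrix")
    if not np.isfinite(x).all():
        raise InputError("median polish requires finite values")
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    resid = x.copy()
    for _ in range(max_iter):
        rm = np.median(resid, axis=1)
        resid -= rm[:, None]
        row += rm
        cm = np.median(resid, axis=0)
        resid -= cm[None, :]
        col += cm
        mr = np.median(row)
        row -= mr
        mc = np.median(col)
        col -= mc
        overall += mr + mc
        if max(np.abs(rm).max(), np.abs(cm).max()) < tol:
            break
    return overall, row, col, resid


def summarize_probeset(log2_probe_values: pd.DataFrame) -> pd.Series:
    """One expression value per sample from a probe x sample log2 matrix.

    The value is overall + per-sample effect of the median-polish fit,
    i.e. the probe-set expression with probe affinities removed.
    """
    overall, _, col, _ = median_polish(log2_probe_values.to_numpy())
    return pd.Series(overall + col, index=log2_probe_values.columns)


def summarize_experiment(
    exp: ProbeLevelExperiment, normalize: bool = True
) -> ExpressionMatrix:
    """log2(PM) -> optional quantile normalization -> median polish."""
    exp.validate()
    arrays = exp.array_ids
    pm = exp.probes.pivot(
        index=["probeset_id", "probe_idx"], columns="array_id", values="pm"
    )[arrays]
    log2 = np.log2(pm)
    if normalize:
        log2 = quantile_normalize(log2)
    rows = {}
    for pid, sub in log2.groupby(level="probeset_id", sort=True):
        rows[pid] = summarize_probeset(sub.droplevel("probeset_id"))
    values = pd.DataFrame.from_dict(rows, orient="index")[arrays]
    values.index.name = "probeset_id"
    return ExpressionMatrix(values=values, samples=exp.samples.copy()).validate()


@dataclass
class FilterReport:
    n_input: int
    n_dropped_all_absent: int
    n_dropped_low_max: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_dropped_all_absent - self.n_dropped_low_max


def filter_probesets(
    expr: ExpressionMatrix,
    calls: DetectionCallMatrix,
    min_max_log2: float = MIN_MAX_LOG2,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop probe sets absent everywhere or never rising above background.

    A probe set survives if it is called non-Absent on at least one
    array AND its maximum normalized log2 value is strictly greater
    than ``min_max_log2`` (default log2(100)).
    """
    expr.validate()
    calls.validate()
    if not expr.values.index.equals(calls.calls.index) or set(expr.values.columns) != set(
        calls.calls.columns
    ):
        raise InputError("expression matrix and call matrix are not aligned")
    all_absent = (calls.calls[expr.values.columns] == "A").all(axis=1)
    low_max = expr.values.max(axis=1) <= min_max_log2
    keep = ~all_absent & ~low_max
    report = FilterReport(
        n_input=len(expr.values),
        n_dropped_all_absent=int(all_absent.sum()),
        n_dropped_low_max=int((low_max & ~all_absent).sum()),
    )
    kept = ExpressionMatrix(values=expr.values.loc[keep].copy(), samples=expr.samples.copy())
    return kept.validate(), report
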