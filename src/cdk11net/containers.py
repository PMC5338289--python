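"""In-memory containers passed between pipeline stages.

The pipeline's canonical tabular container is the pandas DataFrame;
these thin dataclasses bundle the frames with the metadata each stage
needs (sample sheet, detection parameters, provenance), and perform the
structural validation the stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

#: canonical column order of a probe-level intensity table
PROBE_COLUMNS = ["array_id", "probeset_id", "probe_idx", "pm", "mm"]

#: canonical column order of a sample sheet
SAMPLE_COLUMNS = ["array_id", "cell_line", "condition"]

CONDITIONS = ("knockdown", "control")


@dataclass
class ProbeLevelExperiment:
    """Raw probe-pair intensities for a set of hybridized arrays.

    Attributes
    ----------
    probes : DataFrame
        One row per (array, probe set, probe pair) with positive
        perfect-match (``pm``) and mismatch (``mm``) intensities.
    samples : DataFrame
        One row per array with ``cell_line`` and ``condition``
        (``knockdown`` or ``control``).
    """

    probes: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> "ProbeLevelExperiment":
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise InputError(f"probe table missing columns {missing}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise InputError(f"sample sheet missing columns {missing}")
        if (self.probes["pm"] <= 0).any() or (self.probes["mm"] <= 0).any():
            raise InputError("probe intensities must be strictly positive")
        unknown = set(self.probes["array_id"]) - set(self.samples["array_id"])
        if unknown:
            raise InputError(f"probe table references unknown arrays {sorted(unknown)}")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise InputError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        return self

    @property
    def array_ids(self) -> list[str]:
        return list(self.samples["array_id"])

    @property
    def probeset_ids(self) -> list[str]:
        return sorted(self.probes["probeset_id"].unique())

    def pm_mm_matrices(self, probeset_id: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Probe x array PM and MM matrices for one probe set."""
        sub = self.probes[self.probes["probeset_id"] == probeset_id]
        pm = sub.pivot(index="probe_idx", columns="array_id", values="pm")
        mm = sub.pivot(index="probe_idx", columns="array_id", values="mm")
        return pm[self.array_ids], mm[self.array_ids]


@dataclass
class ExpressionMatrix:
    """Probe-set x sample log2 expression values plus the sample sheet."""

    values: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> "ExpressionMatrix":
        if not np.isfinite(self.values.to_numpy()).all():
            raise InputError("expression matrix contains non-finite values")
        if set(self.values.columns) != set(self.samples["array_id"]):
            raise InputError("expression columns do not match the sample sheet")
        return self

    def sample_for(self, cell_line: str, condition: str) -> str:
        """Array id of the unique sample for a line/condition pair."""
        sel = self.samples[
            (self.samples["cell_line"] == cell_line)
            & (self.samples["condition"] == condition)
        ]
        if len(sel) != 1:
            raise InputError(
                f"expected exactly one {condition} sample for line {cell_line!r}, "
                f"found {len(sel)}"
            )
        return sel["array_id"].iloc[0]

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.samples["cell_line"].unique())


@dataclass
class DetectionCallMatrix:
    """Present/Marginal/Absent calls and their signed-rank p-values."""

    calls: pd.DataFrame  # probeset x array, values in {"P", "M", "A"}
    pvalues: pd.DataFrame  # same shape, one-sided signed-rank p

    def validate(self) -> "DetectionCallMatrix":
        if not self.calls.index.equals(self.pvalues.index) or not self.calls.columns.equals(
            self.pvalues.columns
        ):
            raise InputError("call and p-value matrices are not aligned")
        bad = set(np.unique(self.calls.to_numpy())) - {"P", "M", "A"}
        if bad:
            raise InputError(f"unknown detection calls {sorted(bad)}")
        return self


@dataclass
class GroundTruth:
    """Planted truth recorded by the synthetic generators.

    ``responder_sets`` maps cell line -> {probeset_id: direction}, where
    direction is +1 for up-in-knockdown and -1 for down-in-knockdown.
    """

    responder_sets: dict[str, dict[str, int]] = field(default_factory=dict)
    shared_responders: dict[str, int] = field(default_factory=dict)
    absent_probesets: list[str] = field(default_factory=list)
    gene_of_probeset: dict[str, str] = field(default_factory=dict)
    hub_gene: str | None = None
    hub_adjacent_seeds: list[str] = field(default_factory=list)
    cohort_params: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "responder_sets": self.responder_sets,
            "shared_responders": self.shared_responders,
            "absent_probesets": self.absent_probesets,
            "gene_of_probeset": self.gene_of_probeset,
            "hub_gene": self.hub_gene,
            "hub_adjacent_seeds": self.hub_adjacent_seeds,
            "cohort_params": self.cohort_params,
        }
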