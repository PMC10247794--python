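"""Core containers shared across the epiLiver pipeline.

The pipeline moves between two data modalities:

* array-style methylation *beta values* (fraction methylated, in [0, 1]) held
  probe x sample in a :class:`BetaMatrix`;
* targeted-bisulfite amplicon read counts held long-form in an
  :class:`AmpliconCallTable` (one row per sample x amplicon x CpG).

Marker panels and linear score models are small typed records so that the
published coefficients and refit coefficients flow through the same code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The four amplicons whose region medians feed the HCC-detect M score.
DETECT_REGIONS: tuple[str, ...] = ("CHFR", "VASH2", "CCNJ", "GRID2IP")

#: The single amplicon behind the HCC-spec (liver tissue-of-origin) score.
SPEC_REGION: str = "F12"

#: All five targeted amplicons, in canonical order.
AMPLICONS: tuple[str, ...] = DETECT_REGIONS + (SPEC_REGION,)

#: Recognised sample-sheet groups (``tissue:<name>`` is also accepted).
GROUPS: tuple[str, ...] = ("healthy", "CHB", "nonHCC_cancer", "HCC", "blood")

#: HCC clinical stages; ``none`` for samples without a stage.
STAGES: tuple[str, ...] = ("none", "0", "A", "B", "C", "D")

SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "stage", "afp_ng_per_ml")


class BetaMatrix:
    """Probe x sample matrix of methylation beta values.

    Parameters
    ----------
    data
        DataFrame with probe IDs as the index and sample IDs as columns.
        All entries must be finite and lie in [0, 1].
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValueError("duplicate probe IDs in beta matrix")
        if data.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in beta matrix")
        values = data.to_numpy(dtype=float)
        if values.size and (not np.isfinite(values).all() or values.min() < 0 or values.max() > 1):
            raise ValueError("beta values must be finite and within [0, 1]")
        self.data = data

    @property
    def probes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return BetaMatrix(self.data.loc[:, list(samples)])

    def subset_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        probes = list(probes)
        missing = [p for p in probes if p not in self.data.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing}")
        return BetaMatrix(self.data.loc[probes])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BetaMatrix({self.shape[0]} probes x {self.shape[1]} samples)"


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet and return it with canonical column order.

    A sample sheet has one row per sample with columns ``sample_id``,
    ``group``, ``stage`` and ``afp_ng_per_ml`` (NaN = not measured).  Stages
    other than ``none`` are only allowed for HCC samples.
    """
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    sheet = sheet.copy()
    if "stage" not in sheet.columns:
        sheet["stage"] = "none"
    if "afp_ng_per_ml" not in sheet.columns:
        sheet["afp_ng_per_ml"] = np.nan
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in sample sheet")
    bad_group = ~(
        sheet["group"].isin(GROUPS) | sheet["group"].astype(str).str.startswith("tissue:")
    )
    if bad_group.any():
        raise ValueError(f"unknown groups: {sorted(sheet.loc[bad_group, 'group'].unique())}")
    if not sheet["stage"].isin(STAGES).all():
        raise ValueError("unknown stage label in sample sheet")
    staged_non_hcc = (sheet["stage"] != "none") & (sheet["group"] != "HCC")
    if staged_non_hcc.any():
        raise ValueError("stage may only be set for HCC samples")
    afp = sheet["afp_ng_per_ml"].to_numpy(dtype=float)
    if np.nanmin(afp, initial=0.0) < 0:
        raise ValueError("AFP values must be nonnegative")
    return sheet.loc[:, list(SAMPLE_SHEET_COLUMNS)]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth recorded by the synthetic-cohort generator."""

    planted_detect_markers: tuple[str, ...]
    planted_spec_marker: str | None
    tumor_fraction: dict[str, float] = field(default_factory=dict)
    background_error: float = 0.0
    low_coverage_samples: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "planted_detect_markers": list(self.planted_detect_markers),
            "planted_spec_marker": self.planted_spec_marker,
            "tumor_fraction": dict(self.tumor_fraction),
            "background_error": self.background_error,
            "low_coverage_samples": list(self.low_coverage_samples),
        }


AMPLICON_CALL_COLUMNS = ("sample_id", "amplicon", "cpg_offset", "n_meth", "n_unmeth")


def validate_amplicon_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Validate an amplicon call table (long form per-CpG read counts)."""
    missing = [c for c in AMPLICON_CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table missing columns {missing}")
    calls = calls.loc[:, list(AMPLICON_CALL_COLUMNS)].copy()
    for col in ("cpg_offset", "n_meth", "n_unmeth"):
        values = calls[col].to_numpy()
        if not np.issubdtype(np.asarray(values).dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError(f"column {col!r} must hold integers")
            calls[col] = np.asarray(values).astype(np.int64)
    if (calls[["n_meth", "n_unmeth"]].to_numpy() < 0).any():
        raise ValueError("read counts must be nonnegative")
    if (calls["cpg_offset"].to_numpy() < 1).any():
        raise ValueError("CpG offsets are 1-based and must be >= 1")
    if calls.duplicated(subset=["sample_id", "amplicon", "cpg_offset"]).any():
        raise ValueError("duplicate (sample, amplicon, offset) rows")
    return calls


@dataclass(frozen=True)
class MarkerPanel:
    """Selected marker CpGs: an ordered detect set plus one spec CpG."""

    detect_cpgs: tuple[str, ...]
    spec_cpg: str | None = None

    def __post_init__(self):
        if not self.detect_cpgs and self.spec_cpg is None:
            raise ValueError("marker panel must not be empty")
        if self.spec_cpg is not None and self.spec_cpg in self.detect_cpgs:
            raise ValueError("spec CpG must be disjoint from detect CpGs")
        if len(set(self.detect_cpgs)) != len(self.detect_cpgs):
            raise ValueError("duplicate detect CpGs")


@dataclass(frozen=True)
class ScoreModel:
    """Linear methylation score: intercept + sum(weight * beta)."""

    weights: Mapping[str, float]
    intercept: float

    def __post_init__(self):
        w = np.asarray(list(self.weights.values()), dtype=float)
        if w.size == 0:
            raise ValueError("score model needs at least one weight")
        if not np.isfinite(w).all() or not np.isfinite(self.intercept):
            raise ValueError("score model parameters must be finite")

    def evaluate(self, betas: Mapping[str, float]) -> float:
        total = self.intercept
        for probe, weight in self.weights.items():
            if probe not in betas:
                raise KeyError(f"missing beta value for probe {probe!r}")
            total += weight * float(betas[probe])
        return total
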