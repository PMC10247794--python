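"""Readers and writers for the pipeline's plain-text interchange formats.

* beta matrix: TSV, probes as rows, first column ``probe_id``, header row of
  sample IDs;
* sample sheet: CSV with columns sample_id, group, stage, afp_ng_per_ml;
* amplicon calls: one coverage file per sample in the Bismark ``.cov``
  dialect — ``<amplicon> <start> <end> <meth_pct> <count_meth>
  <count_unmeth>`` with 1-based inclusive coordinates (start == end for a
  single CpG);
* simulation truth: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, SimTruth, validate_amplicon_calls, validate_sample_sheet


def write_beta_tsv(matrix: BetaMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="probe_id")


def read_beta_tsv(path: str | Path) -> BetaMatrix:
    data = pd.read_csv(path, sep="\t", index_col="probe_id")
    return BetaMatrix(data)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet).to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "group": str, "stage": str})
    return validate_sample_sheet(sheet)


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")


def read_truth_json(path: str | Path) -> SimTruth:
    raw = json.loads(Path(path).read_text())
    return SimTruth(
        planted_detect_markers=tuple(raw["planted_detect_markers"]),
        planted_spec_marker=raw["planted_spec_marker"],
        tumor_fraction=dict(raw["tumor_fraction"]),
        background_error=float(raw["background_error"]),
        low_coverage_samples=tuple(raw.get("low_coverage_samples", ())),
    )


def write_coverage_dir(calls: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write one coverage file per sample; returns sample_id -> file path."""
    calls = validate_amplicon_calls(calls)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample_id, sub in calls.groupby("sample_id", sort=True):
        path = out_dir / f"{sample_id}.cov"
        sub = sub.sort_values(["amplicon", "cpg_offset"])
        with open(path, "w") as fh:
            for row in sub.itertuples(index=False):
                total = row.n_meth + row.n_unmeth
                pct = 100.0 * row.n_meth / total if total else 0.0
                fh.write(
                    f"{row.amplicon}\t{row.cpg_offset}\t{row.cpg_offset}"
                    f"\t{pct:.6f}\t{row.n_meth}\t{row.n_unmeth}\n"
                )
        paths[str(sample_id)] = path
    return paths


def coverage_manifest(out_dir: str | Path) -> dict[str, Path]:
    """Map sample IDs to ``<sample_id>.cov`` files found in a directory."""
    out_dir = Path(out_dir)
    return {p.stem: p for p in sorted(out_dir.glob("*.cov"))}


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
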