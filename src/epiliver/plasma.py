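"""Targeted-bisulfite amplicon processing: coverage files -> M scores.

A plasma sample is sequenced over five short amplicons (CHFR, VASH2, CCNJ,
GRID2IP detect regions plus the F12 spec region).  Per-CpG methylation
percentages are recomputed from read counts, summarized per region by the
median (robust to a single spuriously methylated CpG), QC'd against a
100-read depth floor, and log2-normalized into M scores:

    m_detect = sum over detect regions of log2(median% + pseudocount)
    m_spec   = log2(median%(F12) + pseudocount)
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AMPLICONS, DETECT_REGIONS, SPEC_REGION, validate_amplicon_calls

logger = logging.getLogger(__name__)


class CoverageFormatError(ValueError):
    """A malformed line in a coverage file."""


def read_coverage_file(
    path: str | Path, sample_id: str | None = None, pct_tolerance: float = 0.1
) -> pd.DataFrame:
    """Parse one Bismark-dialect coverage file into an amplicon call table.

    Lines are ``<amplicon> <start> <end> <meth_pct> <count_meth>
    <count_unmeth>`` (tab- or space-separated, 1-based inclusive
    coordinates).  The percent column is recomputed from the counts and
    only validated (warning when it disagrees by more than
    ``pct_tolerance`` percentage points).
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise CoverageFormatError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            amplicon, start_s, end_s, pct_s, meth_s, unmeth_s = fields
            try:
                start, end = int(start_s), int(end_s)
                pct = float(pct_s)
                n_meth, n_unmeth = int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise CoverageFormatError(f"{path}:{lineno}: {exc}") from None
            if start < 1 or end < start:
                raise CoverageFormatError(
                    f"{path}:{lineno}: bad 1-based coordinates {start}-{end}"
                )
            if n_meth < 0 or n_unmeth < 0:
                raise CoverageFormatError(f"{path}:{lineno}: negative read count")
            if not 0 <= pct <= 100:
                raise CoverageFormatError(f"{path}:{lineno}: percent outside [0, 100]")
            total = n_meth + n_unmeth
            recomputed = 100.0 * n_meth / total if total else 0.0
            if abs(recomputed - pct) > pct_tolerance:
                warnings.warn(
                    f"{path}:{lineno}: percent column {pct:.3f} disagrees with "
                    f"counts ({recomputed:.3f})",
                    stacklevel=2,
                )
            rows.append((sample_id, amplicon, start, n_meth, n_unmeth))
    if not rows:
        warnings.warn(f"{path}: empty coverage file", stacklevel=2)
        return pd.DataFrame(
            columns=["sample_id", "amplicon", "cpg_offset", "n_meth", "n_unmeth"]
        )
    calls = pd.DataFrame(
        rows, columns=["sample_id", "amplicon", "cpg_offset", "n_meth", "n_unmeth"]
    )
    return validate_amplicon_calls(calls)


def read_coverage_dir(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Concatenate per-sample coverage files (sample_id -> path)."""
    tables = [read_coverage_file(p, sample_id=s) for s, p in sorted(paths.items())]
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame(
            columns=["sample_id", "amplicon", "cpg_offset", "n_meth", "n_unmeth"]
        )
    return validate_amplicon_calls(pd.concat(tables, ignore_index=True))


def region_medians(
    calls: pd.DataFrame,
    min_reads: int = 100,
    amplicons: tuple[str, ...] = AMPLICONS,
    depth_rule: str = "min",
) -> pd.DataFrame:
    """Per-sample region medians with coverage QC.

    Per CpG, methylation% = 100 * n_meth / (n_meth + n_unmeth); the region
    summary is the median over its CpGs.  A region's QC depth is the
    minimum per-CpG depth within the amplicon (``depth_rule='mean'``
    switches to the mean).  ``qc_pass`` requires every amplicon present
    with QC depth >= ``min_reads``.

    Returns a DataFrame indexed by sample with columns ``median_<amp>``,
    ``reads_<amp>`` and ``qc_pass``.
    """
    if depth_rule not in ("min", "mean"):
        raise ValueError("depth_rule must be 'min' or 'mean'")
    calls = validate_amplicon_calls(calls)
    records = {}
    for sample_id, sub in calls.groupby("sample_id", sort=True):
        rec: dict[str, float | bool] = {}
        qc = True
        for amp in amplicons:
            region = sub[sub["amplicon"] == amp]
            if region.empty:
                logger.warning("sample %s: amplicon %s has no CpGs; QC fail", sample_id, amp)
                rec[f"median_{amp}"] = np.nan
                rec[f"reads_{amp}"] = 0.0
                qc = False
                continue
            depth = (region["n_meth"] + region["n_unmeth"]).to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = np.where(depth > 0, 100.0 * region["n_meth"].to_numpy() / depth, 0.0)
            region_depth = depth.min() if depth_rule == "min" else depth.mean()
            rec[f"median_{amp}"] = float(np.median(pct))
            rec[f"reads_{amp}"] = float(region_depth)
            if region_depth < min_reads:
                qc = False
        rec["qc_pass"] = qc
        records[sample_id] = rec
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "sample_id"
    return out


def m_scores(medians: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Log2-normalized M scores from region medians.

    ``m_detect`` sums log2(median% + pseudocount) over the four detect
    regions (equal weight per region); ``m_spec`` is the normalized F12
    median.  QC-failing samples are emitted with NaN scores.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    norm = {
        amp: np.log2(medians[f"median_{amp}"].to_numpy(dtype=float) + pseudocount)
        for amp in AMPLICONS
    }
    m_detect = sum(norm[amp] for amp in DETECT_REGIONS)
    m_spec = norm[SPEC_REGION]
    out = pd.DataFrame(
        {"m_detect": m_detect, "m_spec": m_spec, "qc_pass": medians["qc_pass"]},
        index=medians.index,
    )
    out.loc[~out["qc_pass"], ["m_detect", "m_spec"]] = np.nan
    return out
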