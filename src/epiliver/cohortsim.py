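"""Synthetic methylation cohorts with planted ground truth.

Two generators mirror the two data modalities of the study design:

``simulate_tissue_betas``
    An array-style probe x sample beta matrix over HCC, non-HCC liver
    disease, blood, other somatic tissues and non-HCC cancers.  Most probes
    are "methylation-resistant" background (near zero in every sample); a
    planted set of detect markers is hypermethylated in a configured
    fraction of HCC samples only, and one planted spec marker is methylated
    in liver-lineage samples (HCC and non-HCC liver) only.

``simulate_plasma_reads``
    Targeted-bisulfite read counts over five amplicons.  Each HCC plasma
    sample carries a latent tumor fraction ``tf``; per-CpG methylated reads
    are Binomial(depth, tf * m_tumor + (1 - tf) * eps), so case methylation
    is the tumor signal diluted into an almost-unmethylated cell-free DNA
    background with a flat error rate ``eps``.

All randomness flows from an explicit integer seed through
``numpy.random.default_rng``; identical config + seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AMPLICONS,
    BetaMatrix,
    SimTruth,
    validate_amplicon_calls,
    validate_sample_sheet,
)

# ---------------------------------------------------------------------------
# beta-distribution helpers (mean/concentration parameterization)
# ---------------------------------------------------------------------------


def _beta_ab(mean: float, concentration: float) -> tuple[float, float]:
    if not 0 < mean < 1:
        raise ValueError("beta mean must be in (0, 1)")
    if concentration <= 0:
        raise ValueError("beta concentration must be positive")
    return mean * concentration, (1 - mean) * concentration


def _truncated_beta(
    rng: np.random.Generator,
    mean: float,
    concentration: float,
    low: float,
    high: float,
    size,
) -> np.ndarray:
    """Sample Beta(mean, concentration) truncated to (low, high) via the CDF."""
    a, b = _beta_ab(mean, concentration)
    lo, hi = stats.beta.cdf([low, high], a, b)
    u = rng.uniform(lo, hi, size=size)
    return stats.beta.ppf(u, a, b)


# ---------------------------------------------------------------------------
# tissue / array cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueSimConfig:
    """Configuration for the array-style tissue cohort.

    ``group_sizes`` maps group name to sample count.  ``liver`` here means
    non-HCC liver disease (fibrosis/cirrhosis), the control arm of the
    detect-marker comparison; ``blood`` and ``tissue`` are the normal panels
    used to call methylation-resistant sites; ``nonHCC_cancer`` stands in
    for tumors of other origins used in the tissue-of-origin search.
    """

    n_probes: int = 2000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "HCC": 50,
            "tissue:liver": 50,
            "blood": 50,
            "tissue:other": 50,
            "nonHCC_cancer": 50,
        }
    )
    n_detect_markers: int = 4
    n_spec_markers: int = 1
    n_spec_decoys: int = 3
    #: fraction of HCC samples methylated at each planted detect marker;
    #: cycled if fewer entries than markers.  All >= 0.5 so every planted
    #: marker shows the categorical case/control split.
    detect_meth_fractions: tuple[float, ...] = (0.59, 0.57, 0.52, 0.50)
    #: methylated-case beta distribution (mean, concentration), truncated
    #: below at ``detect_min_beta`` so planted positives clear the 0.2 rule.
    case_mean: float = 0.5
    case_concentration: float = 20.0
    detect_min_beta: float = 0.25
    #: liver-lineage (spec) marker beta distribution in HCC + liver samples.
    spec_mean: float = 0.7
    spec_concentration: float = 20.0
    spec_min_beta: float = 0.3
    decoy_mean: float = 0.3
    decoy_concentration: float = 20.0
    #: methylation-resistant background: Beta(mean 0.01, concentration 50)
    #: truncated below 0.1 so resistant sites are resistant by construction.
    background_mean: float = 0.01
    background_concentration: float = 50.0
    background_max_beta: float = 0.1
    #: fraction of probes that are *not* methylation-resistant (variably
    #: methylated in every tissue) and so fall out of the resistant filter.
    nonresistant_fraction: float = 0.3
    nonresistant_mean: float = 0.4
    nonresistant_concentration: float = 4.0
    #: HCC stage mix (A includes the rare stage-0 cases).
    stage_probs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.113, "B": 0.285, "C": 0.351, "D": 0.251}
    )

    def validate(self) -> None:
        if self.n_probes <= 0 or any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("probe count and group sizes must be positive")
        n_special = self.n_detect_markers + self.n_spec_markers + self.n_spec_decoys
        if self.n_probes < n_special:
            raise ValueError("probe count smaller than number of planted markers")
        if "HCC" not in self.group_sizes:
            raise ValueError("tissue cohort requires an HCC group")
        if any(not 0 < f <= 1 for f in self.detect_meth_fractions):
            raise ValueError("detect methylated fractions must be in (0, 1]")


def _assign_stages(rng: np.random.Generator, n: int, stage_probs: dict[str, float]) -> np.ndarray:
    stages = list(stage_probs)
    p = np.asarray([stage_probs[s] for s in stages], dtype=float)
    p = p / p.sum()
    return rng.choice(stages, size=n, p=p)


def simulate_tissue_betas(
    cfg: TissueSimConfig | None = None, seed: int = 0
) -> tuple[BetaMatrix, pd.DataFrame, SimTruth]:
    """Generate an array-style beta matrix with planted HCC markers.

    Returns ``(matrix, sample_sheet, truth)``.  Planted detect markers are
    below 0.1 in every non-HCC sample and above 0.2 in the configured
    fraction of HCC samples (the methylated count is fixed at
    ``round(fraction * n_HCC)``, so the planted prevalence is exact); the
    spec marker is methylated in HCC and liver samples only.
    """
    cfg = cfg or TissueSimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    probes = np.array([f"cg{i:08d}" for i in range(cfg.n_probes)])
    sample_ids: list[str] = []
    groups: list[str] = []
    for group, n in cfg.group_sizes.items():
        tag = group.replace("tissue:", "t_")
        sample_ids.extend(f"{tag}_{i:03d}" for i in range(n))
        groups.extend([group] * n)
    samples = np.array(sample_ids)
    group_arr = np.array(groups)
    n_samples = len(samples)

    # probe roles: planted markers first, then a non-resistant block, rest background
    n_special = cfg.n_detect_markers + cfg.n_spec_markers + cfg.n_spec_decoys
    detect_idx = np.arange(cfg.n_detect_markers)
    spec_idx = np.arange(cfg.n_detect_markers, cfg.n_detect_markers + cfg.n_spec_markers)
    decoy_idx = np.arange(cfg.n_detect_markers + cfg.n_spec_markers, n_special)
    n_nonres = int(round(cfg.nonresistant_fraction * (cfg.n_probes - n_special)))
    nonres_idx = np.arange(n_special, n_special + n_nonres)

    values = _truncated_beta(
        rng,
        cfg.background_mean,
        cfg.background_concentration,
        0.0,
        cfg.background_max_beta,
        (cfg.n_probes, n_samples),
    )
    if n_nonres:
        a, b = _beta_ab(cfg.nonresistant_mean, cfg.nonresistant_concentration)
        values[nonres_idx, :] = rng.beta(a, b, size=(n_nonres, n_samples))

    is_hcc = group_arr == "HCC"
    is_liver = np.isin(group_arr, ["tissue:liver"])
    hcc_cols = np.flatnonzero(is_hcc)
    liver_like_cols = np.flatnonzero(is_hcc | is_liver)
    n_hcc = hcc_cols.size

    # planted detect markers: exact methylated count per marker among HCC
    fracs = cfg.detect_meth_fractions
    for k, row in enumerate(detect_idx):
        frac = fracs[k % len(fracs)]
        n_meth = int(round(frac * n_hcc))
        meth_cols = rng.permutation(hcc_cols)[:n_meth]
        values[row, meth_cols] = _truncated_beta(
            rng, cfg.case_mean, cfg.case_concentration, cfg.detect_min_beta, 1.0, n_meth
        )

    # planted spec marker(s): methylated in all liver-lineage samples
    for row in spec_idx:
        values[row, liver_like_cols] = _truncated_beta(
            rng, cfg.spec_mean, cfg.spec_concentration, cfg.spec_min_beta, 1.0,
            liver_like_cols.size,
        )
    # decoys: liver-lineage methylation at sub-threshold effect size
    a, b = _beta_ab(cfg.decoy_mean, cfg.decoy_concentration)
    for row in decoy_idx:
        values[row, liver_like_cols] = rng.beta(a, b, size=liver_like_cols.size)

    matrix = BetaMatrix(pd.DataFrame(np.clip(values, 0.0, 1.0), index=probes, columns=samples))

    stage = np.array(["none"] * n_samples, dtype=object)
    stage[hcc_cols] = _assign_stages(rng, n_hcc, cfg.stage_probs)
    sheet = validate_sample_sheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": group_arr,
                "stage": stage,
                "afp_ng_per_ml": np.nan,
            }
        )
    )

    truth = SimTruth(
        planted_detect_markers=tuple(probes[detect_idx]),
        planted_spec_marker=str(probes[spec_idx[0]]) if cfg.n_spec_markers else None,
        tumor_fraction={s: 1.0 for s in samples[hcc_cols]},
        background_error=0.0,
    )
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# plasma / targeted amplicon cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlasmaSimConfig:
    """Configuration for the targeted-bisulfite plasma cohort.

    Depth per region follows a negative binomial with mean
    ``coverage_mean`` and dispersion ``coverage_dispersion``; every CpG in
    an amplicon shares the region depth (amplicon reads span the region).
    Tumor fraction per HCC sample is Beta(2, 2) scaled by a stage
    multiplier, so late stages shed more tumor DNA.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"healthy": 50, "CHB": 50, "HCC": 100}
    )
    stage_probs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.113, "B": 0.285, "C": 0.351, "D": 0.251}
    )
    stage_tf_multiplier: dict[str, float] = field(
        default_factory=lambda: {"A": 0.3, "B": 0.5, "C": 0.7, "D": 0.8}
    )
    tf_beta_a: float = 2.0
    tf_beta_b: float = 2.0
    tf_max: float = 1.0
    #: when set, every HCC sample gets exactly this tumor fraction
    tf_fixed: float | None = None
    #: per-amplicon methylation level of pure tumor DNA
    tumor_methylation: dict[str, float] = field(
        default_factory=lambda: {
            "CHFR": 0.80,
            "VASH2": 0.85,
            "CCNJ": 0.60,
            "GRID2IP": 0.70,
            "F12": 0.90,
        }
    )
    #: flat background error (bisulfite conversion failure / sequencing error)
    background_error: float = 0.005
    coverage_mean: float = 4000.0
    coverage_dispersion: float = 5.0
    #: CpGs per amplicon (all within the 5-15 per-region range of 100-200 bp
    #: CpG-dense amplicons)
    cpgs_per_amplicon: dict[str, int] = field(
        default_factory=lambda: {"CHFR": 8, "VASH2": 12, "CCNJ": 6, "GRID2IP": 9, "F12": 10}
    )
    #: fraction of samples planted with one region below the 100-read QC bar
    low_coverage_fraction: float = 0.0125
    low_coverage_depth_max: int = 99

    def validate(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if not 0 <= self.background_error <= 1:
            raise ValueError("background error rate must be in [0, 1]")
        if not self.tumor_methylation or not self.cpgs_per_amplicon:
            raise ValueError("amplicon set must not be empty")
        if set(self.tumor_methylation) != set(self.cpgs_per_amplicon):
            raise ValueError("tumor methylation and CpG counts must cover the same amplicons")
        if not 0 <= self.tf_max <= 1:
            raise ValueError("tf_max must be in [0, 1]")


def simulate_plasma_reads(
    cfg: PlasmaSimConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate per-CpG amplicon read counts under tumor-fraction dilution.

    Returns ``(calls, sample_sheet, truth)`` where ``calls`` is a long-form
    AmpliconCallTable DataFrame.  Non-HCC samples have tumor fraction 0, so
    their methylated reads arise from the background error rate alone.
    """
    cfg = cfg or PlasmaSimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    sample_ids: list[str] = []
    groups: list[str] = []
    for group, n in cfg.group_sizes.items():
        sample_ids.extend(f"{group}_{i:03d}" for i in range(n))
        groups.extend([group] * n)
    samples = np.array(sample_ids)
    group_arr = np.array(groups)
    n_samples = len(samples)
    amplicons = list(cfg.cpgs_per_amplicon)

    hcc_mask = group_arr == "HCC"
    stage = np.array(["none"] * n_samples, dtype=object)
    stage[hcc_mask] = _assign_stages(rng, int(hcc_mask.sum()), cfg.stage_probs)

    tf = np.zeros(n_samples)
    hcc_idx = np.flatnonzero(hcc_mask)
    if cfg.tf_fixed is not None:
        tf[hcc_idx] = cfg.tf_fixed
    else:
        raw = rng.beta(cfg.tf_beta_a, cfg.tf_beta_b, size=hcc_idx.size)
        mult = np.array([cfg.stage_tf_multiplier[stage[i]] for i in hcc_idx])
        tf[hcc_idx] = np.clip(raw * mult * cfg.tf_max, 0.0, 1.0)

    # region depths: NB(mean, dispersion) shared by all CpGs of the region
    r = cfg.coverage_dispersion
    p = r / (r + cfg.coverage_mean)
    depth = rng.negative_binomial(r, p, size=(n_samples, len(amplicons)))
    depth = np.maximum(depth, 1)

    # plant low-coverage QC failures: one random region per chosen sample
    n_low = int(round(cfg.low_coverage_fraction * n_samples))
    low_samples = rng.permutation(n_samples)[:n_low]
    for si in low_samples:
        ai = rng.integers(len(amplicons))
        depth[si, ai] = rng.integers(10, cfg.low_coverage_depth_max + 1)

    rows = []
    for ai, amp in enumerate(amplicons):
        n_cpg = cfg.cpgs_per_amplicon[amp]
        m_tumor = cfg.tumor_methylation[amp]
        prob = np.clip(tf * m_tumor + (1.0 - tf) * cfg.background_error, 0.0, 1.0)
        for offset in range(1, n_cpg + 1):
            n_meth = rng.binomial(depth[:, ai], prob)
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": samples,
                        "amplicon": amp,
                        "cpg_offset": offset,
                        "n_meth": n_meth,
                        "n_unmeth": depth[:, ai] - n_meth,
                    }
                )
            )
    calls = validate_amplicon_calls(pd.concat(rows, ignore_index=True))
    calls = calls.sort_values(["sample_id", "amplicon", "cpg_offset"], ignore_index=True)

    sheet = validate_sample_sheet(
        pd.DataFrame(
            {"sample_id": samples, "group": group_arr, "stage": stage, "afp_ng_per_ml": np.nan}
        )
    )
    truth = SimTruth(
        planted_detect_markers=(),
        planted_spec_marker=None,
        tumor_fraction={samples[i]: float(tf[i]) for i in hcc_idx},
        background_error=cfg.background_error,
        low_coverage_samples=tuple(sorted(samples[low_samples])),
    )
    return calls, sheet, truth


# ---------------------------------------------------------------------------
# AFP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AfpSimConfig:
    """Log-normal serum AFP per group (ng/mL), with per-group missingness.

    Medians rise with HCC stage; healthy and CHB medians sit far below the
    400 ng/mL positivity threshold.  Missingness reflects that AFP is only
    assayed opportunistically outside the HCC group.
    """

    group_median: dict[str, float] = field(
        default_factory=lambda: {"healthy": 4.0, "CHB": 12.0, "nonHCC_cancer": 8.0}
    )
    stage_median: dict[str, float] = field(
        default_factory=lambda: {"0": 100.0, "A": 150.0, "B": 600.0, "C": 1500.0, "D": 4000.0}
    )
    group_sigma: dict[str, float] = field(
        default_factory=lambda: {"healthy": 1.0, "CHB": 1.2, "nonHCC_cancer": 1.2}
    )
    hcc_sigma: float = 1.5
    missingness: dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.6, "CHB": 0.55, "nonHCC_cancer": 0.5, "HCC": 0.07}
    )

    def validate(self) -> None:
        if any(v <= 0 for v in self.group_median.values()) or any(
            v <= 0 for v in self.stage_median.values()
        ):
            raise ValueError("AFP medians must be positive")
        if any(v <= 0 for v in self.group_sigma.values()) or self.hcc_sigma <= 0:
            raise ValueError("AFP log-scale sigmas must be positive")
        if any(not 0 <= v <= 1 for v in self.missingness.values()):
            raise ValueError("missingness must be in [0, 1]")


def simulate_afp(
    sheet: pd.DataFrame, cfg: AfpSimConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Fill the ``afp_ng_per_ml`` column of a sample sheet.

    HCC samples draw from a stage-specific log-normal; other groups from a
    group-specific one.  A per-group fraction of values is set missing.
    """
    cfg = cfg or AfpSimConfig()
    cfg.validate()
    sheet = validate_sample_sheet(sheet)
    rng = np.random.default_rng(seed)

    afp = np.full(len(sheet), np.nan)
    for i, row in enumerate(sheet.itertuples(index=False)):
        if row.group == "HCC":
            median = cfg.stage_median.get(row.stage, cfg.stage_median["B"])
            sigma = cfg.hcc_sigma
        else:
            key = row.group if row.group in cfg.group_median else "healthy"
            median = cfg.group_median[key]
            sigma = cfg.group_sigma.get(key, 1.0)
        afp[i] = rng.lognormal(mean=np.log(median), sigma=sigma)
    for group, frac in cfg.missingness.items():
        mask = (sheet["group"] == group).to_numpy()
        drop = rng.random(int(mask.sum())) < frac
        idx = np.flatnonzero(mask)[drop]
        afp[idx] = np.nan
    out = sheet.copy()
    out["afp_ng_per_ml"] = afp
    return out
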