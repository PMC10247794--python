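"""Published HCC-detect / HCC-spec array scores and ROC utilities.

The published weighted polygenic scores over Illumina 450K betas are

    HCC-detect = 0.75*b(VASH2) + 0.43*b(GRID2IP) + 0.64*b(CHFR)
                 + 0.8*b(CCNJ) + 0.064
    HCC-spec   = 1.35*b(F12) + 0.18

where b(.) is the beta value at the marker CpG of each gene region
(cg03768777, cg24804544, cg02012576, cg05739190, cg14126493).  The combined
score is their sum; a tissue sample is called HCC when the combined score
strictly exceeds the chosen threshold (0.87 against all tissues, 1.1
against other liver disease).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .datatypes import ScoreModel

#: marker CpG of each gene region
MARKER_CPGS: dict[str, str] = {
    "CHFR": "cg02012576",
    "VASH2": "cg03768777",
    "CCNJ": "cg05739190",
    "GRID2IP": "cg24804544",
    "F12": "cg14126493",
}

#: published HCC-detect model (weights keyed by marker CpG)
DETECT_MODEL = ScoreModel(
    weights={
        MARKER_CPGS["VASH2"]: 0.75,
        MARKER_CPGS["GRID2IP"]: 0.43,
        MARKER_CPGS["CHFR"]: 0.64,
        MARKER_CPGS["CCNJ"]: 0.8,
    },
    intercept=0.064,
)

#: published HCC-spec model (single F12 CpG)
SPEC_MODEL = ScoreModel(weights={MARKER_CPGS["F12"]: 1.35}, intercept=0.18)

#: combined-score call thresholds: HCC vs all tissues, HCC vs liver disease
COMBINED_THRESHOLDS = (0.87, 1.1)


def _check_beta(name: str, value: float) -> float:
    value = float(value)
    if not 0 <= value <= 1:
        raise ValueError(f"{name} beta value {value} outside [0, 1]")
    return value


def detect_score(betas: Mapping[str, float], model: ScoreModel = DETECT_MODEL) -> float:
    """HCC-detect weighted score.  ``betas`` may be keyed by CpG ID or gene name."""
    resolved = dict(betas)
    for gene, cpg in MARKER_CPGS.items():
        if gene in resolved and cpg not in resolved:
            resolved[cpg] = resolved[gene]
    for probe in model.weights:
        if probe not in resolved:
            raise KeyError(f"missing beta value for probe {probe!r}")
        _check_beta(probe, resolved[probe])
    return model.evaluate(resolved)


def spec_score(beta_f12: float, model: ScoreModel = SPEC_MODEL) -> float:
    """HCC-spec score from the F12 marker CpG beta."""
    _check_beta("F12", beta_f12)
    (weight,) = model.weights.values()
    return model.intercept + weight * float(beta_f12)


def combined_score(detect: float, spec: float) -> float:
    """Sum of the detect and spec scores."""
    if not (np.isfinite(detect) and np.isfinite(spec)):
        raise ValueError("scores must be finite")
    return float(detect) + float(spec)


def classify_tissue(score: float, threshold: float = COMBINED_THRESHOLDS[0]) -> str:
    """Call ``HCC`` iff the combined score strictly exceeds the threshold."""
    return "HCC" if score > threshold else "nonHCC"


def equal_weight_detect(betas: Mapping[str, float] | Sequence[float]) -> float:
    """Unweighted detect score: the mean of the four marker betas."""
    if isinstance(betas, Mapping):
        values = [
            betas[key]
            for key in (
                gene if gene in betas else MARKER_CPGS[gene]
                for gene in ("VASH2", "GRID2IP", "CHFR", "CCNJ")
            )
        ]
    else:
        values = list(betas)
    if len(values) != 4:
        raise ValueError("equal-weight detect score needs exactly four betas")
    values = [_check_beta(f"beta[{i}]", v) for i, v in enumerate(values)]
    return float(np.mean(values))


@dataclass(frozen=True)
class RocResult:
    """ROC summary: rank-based AUC, curve points, sensitivity at specificity."""

    auc: float
    points: list[tuple[float, float, float]]  # (fpr, tpr, threshold)
    sens_at_spec: dict[float, float]


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    specificities: Sequence[float] = (0.95,),
) -> RocResult:
    """ROC with a Mann-Whitney AUC (ties count one half).

    ``sens_at_spec[s]`` is the largest sensitivity attainable by any
    threshold whose specificity is at least ``s``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    sens = {}
    for s in specificities:
        ok = fpr <= 1 - s + 1e-12
        sens[float(s)] = float(tpr[ok].max()) if ok.any() else 0.0
    return RocResult(
        auc=float(auc),
        points=list(zip(fpr.tolist(), tpr.tolist(), thr.tolist())),
        sens_at_spec=sens,
    )


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1."""
    labels = np.asarray(labels).astype(int)
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=float))
    return float(thr[np.argmax(tpr - fpr)])
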