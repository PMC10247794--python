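"""The epiLiver classifier and its evaluation statistics.

Each M score (detect and spec) is turned into a probability of HCC by a
univariable logistic regression; the *epiLiver* statistic is the sum of the
two probabilities, in [0, 2], called HCC when it strictly exceeds 1.62.
AFP (alpha-fetoprotein, ng/mL) gives an orthogonal serum call at the
conventional 400 ng/mL threshold; the combined rule calls HCC when either
test is positive, with missing AFP deferring to epiLiver.

Supporting statistics: confusion-matrix evaluation with per-stage
sensitivity, percentile-bootstrap group differences (B = 1000) and
validation-set cross-validation (random 50% splits, three repeats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .scores import RocResult, roc_auc

#: epiLiver sum-of-probabilities call threshold
EPILIVER_THRESHOLD = 1.62

#: serum AFP positivity threshold, ng/mL
AFP_THRESHOLD = 400.0


@dataclass(frozen=True)
class LogisticModel:
    """Univariable logistic model: P(HCC|m) = expit(intercept + slope*m)."""

    slope: float
    intercept: float
    trained_on: dict = field(default_factory=dict)


def fit_logistic(
    m: Sequence[float], labels: Sequence[int], ridge: float = 1e-6, tol: float = 1e-8
) -> LogisticModel:
    """Maximum-likelihood logistic fit with a tiny ridge stabilizer.

    The ridge penalty (``ridge/2 * ||params||^2`` added to the negative
    log-likelihood) keeps the parameters finite under perfect separation,
    which near-categorical methylation markers routinely produce.
    """
    m = np.asarray(m, dtype=float)
    labels = np.asarray(labels).astype(float)
    if m.ndim != 1 or m.shape != labels.shape:
        raise ValueError("m and labels must be aligned 1-D vectors")
    classes = np.unique(labels)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("labels must contain both classes (0 and 1)")

    def objective(theta):
        intercept, slope = theta
        eta = intercept + slope * m
        # log(1 + e^eta) - y*eta, numerically stable
        nll = np.sum(np.logaddexp(0.0, eta) - labels * eta)
        nll += 0.5 * ridge * (intercept**2 + slope**2)
        p = special.expit(eta)
        grad = np.array(
            [np.sum(p - labels) + ridge * intercept, np.sum((p - labels) * m) + ridge * slope]
        )
        return nll, grad

    res = optimize.minimize(objective, x0=np.zeros(2), jac=True, method="BFGS", tol=tol)
    if not res.success and np.linalg.norm(res.jac) > 1e-4 * (1 + abs(res.fun)):
        raise RuntimeError(f"logistic fit did not converge: {res.message}")
    n1 = int(labels.sum())
    return LogisticModel(
        slope=float(res.x[1]),
        intercept=float(res.x[0]),
        trained_on={"n_case": n1, "n_control": int(len(labels) - n1), "ridge": ridge},
    )


def probability(model: LogisticModel, m) -> np.ndarray | float:
    """Predicted probability of HCC at M score ``m``."""
    m = np.asarray(m, dtype=float)
    out = special.expit(model.intercept + model.slope * m)
    return float(out) if out.ndim == 0 else out


def epiliver_call(
    p_detect: float, p_spec: float, threshold: float = EPILIVER_THRESHOLD
) -> tuple[float, str]:
    """Sum-of-probabilities statistic and its binary call (strict >)."""
    for name, p in (("p_detect", p_detect), ("p_spec", p_spec)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name}={p} outside [0, 1]")
    total = float(p_detect) + float(p_spec)
    return total, ("HCC" if total > threshold else "nonHCC")


def afp_call(afp_ng_per_ml: float | None, threshold: float = AFP_THRESHOLD) -> str:
    """AFP serum call: positive iff AFP strictly exceeds the threshold."""
    if afp_ng_per_ml is None or (isinstance(afp_ng_per_ml, float) and np.isnan(afp_ng_per_ml)):
        return "missing"
    if afp_ng_per_ml < 0:
        raise ValueError("AFP must be nonnegative")
    return "positive" if afp_ng_per_ml > threshold else "negative"


def combined_call(epiliver: str, afp: str) -> str:
    """OR rule: HCC iff epiLiver calls HCC or AFP is positive."""
    if epiliver not in ("HCC", "nonHCC"):
        raise ValueError(f"bad epiLiver call {epiliver!r}")
    if afp not in ("positive", "negative", "missing"):
        raise ValueError(f"bad AFP call {afp!r}")
    return "HCC" if (epiliver == "HCC" or afp == "positive") else "nonHCC"


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix plus overall and stage-stratified rates."""

    confusion: dict[str, int]  # tp, fp, tn, fn
    sensitivity: float
    specificity: float
    sensitivity_by_stage: dict[str, float]
    auc: float | None
    roc: RocResult | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": dict(self.confusion),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_by_stage": dict(self.sensitivity_by_stage),
            "auc": self.auc,
        }


def evaluate(
    calls: Sequence[str],
    labels: Sequence[int],
    stages: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> EvalReport:
    """Confusion matrix, specificity, per-stage sensitivity and (when
    continuous scores are supplied) the ROC AUC."""
    calls = np.asarray(calls)
    labels = np.asarray(labels).astype(int)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels length mismatch")
    pred = calls == "HCC"
    truth = labels == 1
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    tn = int((~pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    by_stage: dict[str, float] = {}
    if stages is not None:
        stages = np.asarray(stages)
        if stages.shape != labels.shape:
            raise ValueError("stages and labels length mismatch")
        for stage in sorted(set(stages[truth])):
            mask = truth & (stages == stage)
            by_stage[str(stage)] = float(pred[mask].mean())
    roc = None
    auc = None
    if scores is not None:
        roc = roc_auc(scores, labels)
        auc = roc.auc
    return EvalReport(
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        sensitivity=float(sens),
        specificity=float(spec),
        sensitivity_by_stage=by_stage,
        auc=auc,
        roc=roc,
    )


def bootstrap_diff(
    a: Sequence[float], b: Sequence[float], B: int = 1000, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile-bootstrap CI and p-value for mean(a) - mean(b).

    Resamples each group with replacement ``B`` times; the 95% CI is the
    2.5/97.5 percentile of the resampled differences and the two-sided p
    is ``2 * min(P(diff <= 0), P(diff >= 0))``, floored at ``1/B`` and
    capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if B < 100:
        import warnings

        warnings.warn(f"B={B} bootstrap replicates is small", stacklevel=2)
    rng = np.random.default_rng(seed)
    diffs = np.empty(B)
    for i in range(B):
        diffs[i] = rng.choice(a, a.size).mean() - rng.choice(b, b.size).mean()
    ci_low, ci_high = np.percentile(diffs, [2.5, 97.5])
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    p = float(np.clip(p, 1.0 / B, 1.0))
    return float(ci_low), float(ci_high), p


def cross_validate(
    mscores: pd.DataFrame,
    labels: Sequence[int],
    train_frac: float = 0.5,
    reps: int = 3,
    seed: int = 0,
    threshold: float = EPILIVER_THRESHOLD,
) -> list[dict]:
    """Validation-set cross-validation of the epiLiver classifier.

    Each repetition draws a random ``train_frac`` split (resplit up to 100
    times until both classes appear in train and test), fits the detect
    and spec logistic models on the training half, and evaluates the
    sum-of-probabilities classifier on the held-out half.
    """
    labels = np.asarray(labels).astype(int)
    if len(mscores) != len(labels):
        raise ValueError("mscores and labels length mismatch")
    n = len(labels)
    n_train = int(round(train_frac * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("dataset too small to split")
    rng = np.random.default_rng(seed)
    md = mscores["m_detect"].to_numpy(dtype=float)
    ms = mscores["m_spec"].to_numpy(dtype=float)
    results = []
    for rep in range(reps):
        for _ in range(100):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            if len(np.unique(labels[train])) == 2 and len(np.unique(labels[test])) == 2:
                break
        else:
            raise ValueError("could not find a split with both classes on each side")
        model_d = fit_logistic(md[train], labels[train])
        model_s = fit_logistic(ms[train], labels[train])
        sum_prob = probability(model_d, md[test]) + probability(model_s, ms[test])
        calls = np.where(sum_prob > threshold, "HCC", "nonHCC")
        report = evaluate(calls, labels[test], scores=sum_prob)
        results.append(
            {
                "rep": rep,
                "auc": report.auc,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "model_detect": model_d,
                "model_spec": model_s,
                "n_train": int(n_train),
                "n_test": int(n - n_train),
            }
        )
    return results
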