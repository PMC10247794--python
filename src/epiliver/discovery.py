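"""Marker discovery from beta matrices.

The discovery chain mirrors how the HCC marker panel was built:

1. :func:`resistant_sites` — CpGs unmethylated in every normal sample
   (every beta < 0.1 and per-probe median < 0.02), intersected across
   normal tissue and blood panels with :func:`intersect_sets`;
2. :func:`categorical_filter` — sites methylated (>20%) in at least half
   the HCC samples but in no control sample;
3. :func:`differential_shortlist` — Welch t-test with a Bonferroni factor
   of 450,000 (the array's test count), keeping the top sites by |delta|;
4. :func:`reduce_panel` — an L1-penalized logistic path shrinks the
   shortlist to a minimal panel (four CpGs by default);
5. :func:`spec_site` — tissue-of-origin search: shortlist by delta > 0.5
   and Q < 1e-20, then a multivariable linear regression picks the single
   CpG with the largest effect;
6. :func:`fit_weights` — OLS of the binary label on panel betas gives the
   weighted polygenic score;
7. :func:`enrichment` — hypergeometric genomic-feature enrichment of a
   panel against an annotated universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .datatypes import BetaMatrix, MarkerPanel, ScoreModel

__all__ = [
    "resistant_sites",
    "intersect_sets",
    "differential_shortlist",
    "categorical_filter",
    "reduce_panel",
    "spec_site",
    "fit_weights",
    "enrichment",
    "RankedCpGs",
]


# ---------------------------------------------------------------------------
# methylation-resistant sites
# ---------------------------------------------------------------------------


def resistant_sites(m: BetaMatrix, max_beta: float = 0.1, max_median: float = 0.02) -> set[str]:
    """CpGs hypomethylated in *every* sample of the matrix.

    A probe qualifies when every beta is strictly below ``max_beta`` and the
    across-sample median is strictly below ``max_median``.  Adding samples
    can only shrink the returned set.
    """
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("beta matrix must be nonempty")
    for name, thr in (("max_beta", max_beta), ("max_median", max_median)):
        if not 0 < thr <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    values = m.data.to_numpy()
    keep = (values.max(axis=1) < max_beta) & (np.median(values, axis=1) < max_median)
    return set(m.probes[keep])


def intersect_sets(sets: list[set[str]]) -> set[str]:
    """Intersection of one or more CpG sets."""
    if not sets:
        raise ValueError("need at least one CpG set")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


# ---------------------------------------------------------------------------
# differential + categorical shortlisting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedCpGs:
    """Ranked differential CpGs: |delta| descending, ties by adjusted p then ID."""

    table: pd.DataFrame  # columns: probe, delta, p_raw, p_adjusted

    @property
    def probes(self) -> list[str]:
        return list(self.table["probe"])

    def __len__(self) -> int:
        return len(self.table)


def _check_two_groups(case: BetaMatrix, ctrl: BetaMatrix, candidates: set[str]) -> list[str]:
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    probes = sorted(candidates)
    for m in (case, ctrl):
        missing = [p for p in probes if p not in m.probes]
        if missing:
            raise KeyError(f"candidate probes absent from matrix: {missing[:5]}")
    return probes


def _welch_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values; degenerate zero-variance rows get
    p = 0 when the means differ and p = 1 when they are equal."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(x, y, axis=1, equal_var=False).pvalue
    both_const = (x.std(axis=1) == 0) & (y.std(axis=1) == 0)
    means_differ = x.mean(axis=1) != y.mean(axis=1)
    p = np.where(both_const & means_differ, 0.0, p)
    p = np.where(both_const & ~means_differ, 1.0, p)
    return np.nan_to_num(p, nan=1.0)


def differential_shortlist(
    case: BetaMatrix,
    ctrl: BetaMatrix,
    candidates: set[str],
    min_abs_delta: float = 0.2,
    alpha: float = 0.05,
    n_tests: int = 450_000,
    top_k: int = 20,
) -> RankedCpGs:
    """Welch t-test shortlist with a fixed Bonferroni factor.

    Keeps candidates with ``p * n_tests < alpha`` and ``|delta| >
    min_abs_delta`` where ``delta = mean(case) - mean(ctrl)``, and returns
    the ``top_k`` by |delta| (ties by adjusted p, then probe ID).
    """
    probes = _check_two_groups(case, ctrl, candidates)
    if not probes:
        return RankedCpGs(pd.DataFrame(columns=["probe", "delta", "p_raw", "p_adjusted"]))
    x = case.data.loc[probes].to_numpy()
    y = ctrl.data.loc[probes].to_numpy()
    delta = x.mean(axis=1) - y.mean(axis=1)
    p_raw = _welch_p(x, y)
    p_adj = np.minimum(p_raw * n_tests, 1.0)
    keep = (p_raw * n_tests < alpha) & (np.abs(delta) > min_abs_delta)
    table = pd.DataFrame(
        {"probe": probes, "delta": delta, "p_raw": p_raw, "p_adjusted": p_adj}
    )[keep]
    table = table.assign(_absd=table["delta"].abs()).sort_values(
        ["_absd", "p_adjusted", "probe"], ascending=[False, True, True]
    )
    return RankedCpGs(table.drop(columns="_absd").head(top_k).reset_index(drop=True))


def categorical_filter(
    case: BetaMatrix,
    ctrl: BetaMatrix,
    candidates: set[str],
    meth_thresh: float = 0.2,
    case_frac: float = 0.5,
    ctrl_max: float = 0.2,
) -> set[str]:
    """Sites methylated above ``meth_thresh`` in at least ``case_frac`` of
    cases while no control exceeds ``ctrl_max`` — the categorical
    case/control split behind the detect markers."""
    probes = _check_two_groups(case, ctrl, candidates)
    if not probes:
        return set()
    x = case.data.loc[probes].to_numpy()
    y = ctrl.data.loc[probes].to_numpy()
    frac_meth = (x > meth_thresh).mean(axis=1)
    ctrl_ok = (y <= ctrl_max).all(axis=1)
    keep = (frac_meth >= case_frac) & ctrl_ok
    return {p for p, k in zip(probes, keep) if k}


# ---------------------------------------------------------------------------
# panel reduction
# ---------------------------------------------------------------------------


def _dedupe_columns(X: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate (identical) probe columns, keeping the
    lexicographically smallest probe ID of each duplicate class."""
    X = X.loc[:, sorted(X.columns)]
    return X.T.drop_duplicates().T


def reduce_panel(
    m: BetaMatrix,
    labels: np.ndarray,
    candidates: RankedCpGs | list[str],
    target_size: int = 4,
) -> MarkerPanel:
    """Shrink a candidate shortlist to a compact panel via an L1 logistic path.

    The penalty grid runs from strong to weak; the panel is the support at
    the strongest penalty whose support size is between 1 and
    ``target_size`` with training AUC >= 0.99.  If no point on the path
    qualifies, the ``target_size`` probes with the largest |coefficient| at
    the weakest penalty are returned.  Duplicate probe columns are
    collapsed to the lexicographically smallest ID, making the selection
    deterministic.
    """
    probes = candidates.probes if isinstance(candidates, RankedCpGs) else list(candidates)
    if not probes:
        raise ValueError("candidate list is empty")
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    X = _dedupe_columns(m.data.loc[probes].T)
    probes = list(X.columns)
    if len(probes) <= target_size and len(probes) == 1:
        return MarkerPanel(detect_cpgs=tuple(probes))

    Xv = X.to_numpy(dtype=float)
    Cs = np.logspace(-2, 3, 40)  # ascending C == descending penalty strength
    coef_last = None
    for C in Cs:
        clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", random_state=0, max_iter=5000
        )
        clf.fit(Xv, labels)
        coef = clf.coef_.ravel()
        support = np.flatnonzero(coef != 0)
        coef_last = coef
        if 1 <= support.size <= target_size:
            auc = roc_auc_score(labels, clf.decision_function(Xv))
            if auc >= 0.99:
                return MarkerPanel(detect_cpgs=tuple(sorted(np.array(probes)[support])))
    order = np.argsort(-np.abs(coef_last), kind="stable")[:target_size]
    return MarkerPanel(detect_cpgs=tuple(sorted(np.array(probes)[order])))


# ---------------------------------------------------------------------------
# tissue-of-origin single CpG
# ---------------------------------------------------------------------------


def spec_site(
    m: BetaMatrix,
    labels: np.ndarray,
    min_delta: float = 0.5,
    q_max: float = 1e-20,
    n_tests: int = 450_000,
    shortlist_size: int = 7,
) -> tuple[RankedCpGs, str]:
    """Find the single CpG that marks the target tissue.

    Shortlists probes hypermethylated in the target class (``delta >
    min_delta`` and Bonferroni-adjusted ``Q < q_max``, capped at
    ``shortlist_size`` by the usual ranking), then fits a multivariable
    linear regression of the label on the shortlisted betas and returns the
    probe with the largest |coefficient|.
    """
    labels = np.asarray(labels).astype(int)
    if min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("need at least 2 samples per class")
    target = m.data.loc[:, labels == 1].to_numpy()
    rest = m.data.loc[:, labels == 0].to_numpy()
    delta = target.mean(axis=1) - rest.mean(axis=1)
    p_raw = _welch_p(target, rest)
    q = np.minimum(p_raw * n_tests, 1.0)
    keep = (delta > min_delta) & (p_raw * n_tests < q_max)
    if not keep.any():
        raise ValueError("no site meets thresholds")
    table = pd.DataFrame(
        {"probe": m.probes, "delta": delta, "p_raw": p_raw, "p_adjusted": q}
    )[keep]
    table = table.assign(_absd=table["delta"].abs()).sort_values(
        ["_absd", "p_adjusted", "probe"], ascending=[False, True, True]
    )
    shortlist = RankedCpGs(
        table.drop(columns="_absd").head(shortlist_size).reset_index(drop=True)
    )
    X = sm.add_constant(m.data.loc[shortlist.probes].T.to_numpy(), has_constant="add")
    fit = sm.OLS(labels.astype(float), X).fit()
    best = int(np.argmax(np.abs(fit.params[1:])))
    return shortlist, shortlist.probes[best]


# ---------------------------------------------------------------------------
# coefficient fitting
# ---------------------------------------------------------------------------


def _dependent_probes(X: pd.DataFrame) -> list[str]:
    """Probes whose columns are linearly dependent on earlier ones."""
    dependent = []
    kept = np.ones((len(X), 0))
    for probe in X.columns:
        col = X[probe].to_numpy(dtype=float)[:, None]
        trial = np.hstack([np.ones((len(X), 1)), kept, col])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            dependent.append(probe)
        else:
            kept = np.hstack([kept, col])
    return dependent


def fit_weights(m: BetaMatrix, labels: np.ndarray, panel: MarkerPanel) -> ScoreModel:
    """OLS of the 0/1 label on panel betas: the weighted polygenic score."""
    labels = np.asarray(labels).astype(float)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    probes = list(panel.detect_cpgs)
    X = m.data.loc[probes].T
    dependent = _dependent_probes(X)
    if dependent:
        raise ValueError(f"collinear panel design; dependent probes: {dependent}")
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    fit = sm.OLS(labels, design).fit()
    return ScoreModel(
        weights={p: float(w) for p, w in zip(probes, fit.params[1:])},
        intercept=float(fit.params[0]),
    )


# ---------------------------------------------------------------------------
# genomic-feature enrichment
# ---------------------------------------------------------------------------


def enrichment(
    panel: set[str], annotations: pd.Series | dict, universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric enrichment/depletion of a CpG panel per feature.

    ``annotations`` maps probe -> iterable of feature labels.  For each
    feature with K universe probes, N universe probes total and a panel of
    n probes with k in the feature: ``p_enrich = P(X >= k)``, ``p_deplete =
    P(X <= k)`` and ``fold = (k/n)/(K/N)`` (NaN when K = 0).
    """
    if not set(panel) <= set(universe):
        raise ValueError("panel must be a subset of the universe")
    ann = dict(annotations)
    feature_members: dict[str, set[str]] = {}
    for probe in universe:
        for feat in ann.get(probe, ()):
            feature_members.setdefault(feat, set()).add(probe)
    N, n = len(universe), len(panel)
    rows = []
    for feat in sorted(feature_members):
        members = feature_members[feat]
        K = len(members)
        k = len(members & set(panel))
        rows.append(
            {
                "feature": feat,
                "overlap": k,
                "panel_size": n,
                "feature_size": K,
                "universe_size": N,
                "fold": (k / n) / (K / N) if K and n else np.nan,
                "p_enrich": float(stats.hypergeom.sf(k - 1, N, K, n)),
                "p_deplete": float(stats.hypergeom.cdf(k, N, K, n)),
            }
        )
    return pd.DataFrame(rows)
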