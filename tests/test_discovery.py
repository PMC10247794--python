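"""Marker discovery: thresholds, rankings, panel reduction, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from epiliver import cohortsim, discovery
from epiliver.datatypes import BetaMatrix, MarkerPanel

from conftest import make_beta_matrix


class TestResistantSites:
    @pytest.mark.parametrize(
        "betas, included",
        [
            ([0.01, 0.015, 0.05], True),   # max 0.05 < 0.1, median 0.015 < 0.02
            ([0.05, 0.12, 0.01], False),   # one beta >= 0.1
            ([0.03, 0.04, 0.05], False),   # median 0.04 >= 0.02
        ],
    )
    def test_threshold_rules(self, betas, included):
        m = make_beta_matrix({"cgA": betas})
        assert ("cgA" in discovery.resistant_sites(m)) is included

    def test_strict_inequalities_at_boundary(self):
        m = make_beta_matrix({"cgA": [0.1, 0.0, 0.0], "cgB": [0.02, 0.02, 0.02]})
        assert discovery.resistant_sites(m) == set()

    def test_adding_methylated_samples_only_shrinks_the_set(self):
        # appending samples at or above each probe's current maximum can
        # only raise the per-probe max and median, so the set cannot grow
        rng = np.random.default_rng(11)
        data = pd.DataFrame(
            rng.beta(0.5, 20, size=(200, 12)),
            index=[f"cg{i:03d}" for i in range(200)],
            columns=[f"s{i}" for i in range(12)],
        )
        base = discovery.resistant_sites(BetaMatrix(data))
        extended = data.copy()
        extended["s_new"] = data.max(axis=1)
        assert discovery.resistant_sites(BetaMatrix(extended)) <= base

    def test_empty_matrix_and_bad_thresholds(self):
        m = make_beta_matrix({"cgA": [0.0, 0.0]})
        with pytest.raises(ValueError):
            discovery.resistant_sites(BetaMatrix(pd.DataFrame()))
        with pytest.raises(ValueError):
            discovery.resistant_sites(m, max_beta=0.0)


class TestIntersect:
    @pytest.mark.parametrize(
        "sets, expected",
        [
            ([{"a", "b", "c"}, {"b", "c", "d"}], {"b", "c"}),
            ([{"a", "b"}], {"a", "b"}),
            ([{"a"}, {"b"}], set()),
        ],
    )
    def test_intersection(self, sets, expected):
        assert discovery.intersect_sets(sets) == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            discovery.intersect_sets([])


class TestDifferentialShortlist:
    def test_degenerate_variance_probe_ranks_first(self):
        case = make_beta_matrix({"cgX": [0.8] * 5, "cgN": [0.1, 0.12, 0.11, 0.09, 0.1]})
        ctrl = make_beta_matrix({"cgX": [0.0] * 5, "cgN": [0.1, 0.11, 0.12, 0.1, 0.09]})
        ranked = discovery.differential_shortlist(case, ctrl, {"cgX", "cgN"})
        assert ranked.probes == ["cgX"]
        assert ranked.table.loc[0, "delta"] == pytest.approx(0.8)
        assert ranked.table.loc[0, "p_raw"] == 0.0

    def test_small_delta_excluded_regardless_of_p(self):
        case = make_beta_matrix({"cgX": [0.1] * 10})
        ctrl = make_beta_matrix({"cgX": [0.0] * 10})
        ranked = discovery.differential_shortlist(case, ctrl, {"cgX"})
        assert len(ranked) == 0

    def test_null_simulation_yields_no_survivors(self):
        rng = np.random.default_rng(42)
        probes = [f"cg{i:04d}" for i in range(1000)]
        case = BetaMatrix(pd.DataFrame(rng.beta(2, 2, (1000, 20)), index=probes,
                                       columns=[f"c{i}" for i in range(20)]))
        ctrl = BetaMatrix(pd.DataFrame(rng.beta(2, 2, (1000, 20)), index=probes,
                                       columns=[f"k{i}" for i in range(20)]))
        ranked = discovery.differential_shortlist(case, ctrl, set(probes))
        assert len(ranked) == 0  # expected false positives = 1000 * 0.05/450000

    def test_invariant_to_sample_and_probe_order(self, tissue_cohort):
        matrix, sheet, _ = tissue_cohort
        hcc = sheet.loc[sheet["group"] == "HCC", "sample_id"].tolist()
        liver = sheet.loc[sheet["group"] == "tissue:liver", "sample_id"].tolist()
        case = matrix.subset_samples(hcc)
        ctrl = matrix.subset_samples(liver)
        candidates = set(matrix.probes[:50]) | {matrix.probes[0]}
        base = discovery.differential_shortlist(case, ctrl, candidates)
        shuffled_case = BetaMatrix(case.data.iloc[::-1, ::-1])
        shuffled_ctrl = BetaMatrix(ctrl.data.iloc[::-1, ::-1])
        perm = discovery.differential_shortlist(shuffled_case, shuffled_ctrl, candidates)
        assert base.probes == perm.probes

    def test_too_few_samples_rejected(self):
        case = make_beta_matrix({"cgX": [0.5]})
        ctrl = make_beta_matrix({"cgX": [0.1, 0.2]})
        with pytest.raises(ValueError):
            discovery.differential_shortlist(case, ctrl, {"cgX"})


class TestCategoricalFilter:
    @pytest.mark.parametrize(
        "case_betas, ctrl_betas, included",
        [
            ([0.25, 0.3, 0.05, 0.01], [0.01] * 4, True),   # 2/4 = 50% >= 50%
            ([0.25, 0.05, 0.05, 0.01], [0.01] * 4, False),  # 25% < 50%
            ([0.25, 0.3, 0.05, 0.01], [0.01, 0.5, 0.01, 0.01], False),  # ctrl violation
        ],
    )
    def test_categorical_rule(self, case_betas, ctrl_betas, included):
        case = make_beta_matrix({"cgA": case_betas})
        ctrl = make_beta_matrix({"cgA": ctrl_betas})
        out = discovery.categorical_filter(case, ctrl, {"cgA"})
        assert ("cgA" in out) is included


class TestReducePanel:
    def test_recovers_planted_separating_probes(self):
        matrix, sheet, truth = cohortsim.simulate_tissue_betas(seed=7)
        hcc = sheet.loc[sheet["group"] == "HCC", "sample_id"].tolist()
        liver = sheet.loc[sheet["group"] == "tissue:liver", "sample_id"].tolist()
        sub = matrix.subset_samples(hcc + liver)
        labels = np.array([1] * len(hcc) + [0] * len(liver))
        # candidates: planted markers among background decoys
        candidates = list(truth.planted_detect_markers) + list(matrix.probes[-16:])
        panel = discovery.reduce_panel(sub, labels, candidates)
        assert set(panel.detect_cpgs) == set(truth.planted_detect_markers)

    def test_single_candidate_returned(self):
        m = make_beta_matrix({"cgA": [0.9, 0.8, 0.1, 0.0]})
        panel = discovery.reduce_panel(m, [1, 1, 0, 0], ["cgA"])
        assert panel.detect_cpgs == ("cgA",)

    def test_duplicate_columns_deduplicated_lexicographically(self):
        col = [0.9, 0.85, 0.8, 0.05, 0.1, 0.0]
        m = make_beta_matrix({"cgB": col, "cgA": col})
        panel = discovery.reduce_panel(m, [1, 1, 1, 0, 0, 0], ["cgB", "cgA"])
        assert panel.detect_cpgs == ("cgA",)

    def test_single_class_rejected(self):
        m = make_beta_matrix({"cgA": [0.9, 0.8]})
        with pytest.raises(ValueError):
            discovery.reduce_panel(m, [1, 1], ["cgA"])


class TestSpecSite:
    def test_recovers_planted_spec_marker(self, tissue_cohort):
        matrix, sheet, truth = tissue_cohort
        keep = sheet["group"] != "tissue:liver"
        samples = sheet.loc[keep, "sample_id"].tolist()
        labels = (sheet.loc[keep, "group"] == "HCC").astype(int).to_numpy()
        shortlist, probe = discovery.spec_site(matrix.subset_samples(samples), labels)
        assert probe == truth.planted_spec_marker
        assert len(shortlist) <= 7

    def test_largest_effect_wins_in_orthogonal_design(self):
        # cgBig is an exact predictor of the label; cgSmall carries a
        # weaker differential signal, so both pass the shortlist but the
        # regression attributes the effect to cgBig
        big = [0.0, 0.0, 0.6, 0.6, 0.0, 0.0, 0.6, 0.6]
        small = [0.0, 0.1, 0.3, 0.4, 0.0, 0.1, 0.3, 0.4]
        labels = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        m = make_beta_matrix({"cgBig": big, "cgSmall": small})
        _, probe = discovery.spec_site(m, labels, min_delta=0.2, q_max=1.0, n_tests=1)
        assert probe == "cgBig"

    def test_no_site_meeting_thresholds_raises(self):
        m = make_beta_matrix({"cgA": [0.1, 0.12, 0.09, 0.11]})
        with pytest.raises(ValueError, match="no site meets thresholds"):
            discovery.spec_site(m, np.array([1, 1, 0, 0]))


class TestFitWeights:
    def test_exact_fit_single_probe(self):
        m = make_beta_matrix({"cgA": [1.0, 1.0, 0.0, 0.0]})
        model = discovery.fit_weights(m, [1, 1, 0, 0], MarkerPanel(("cgA",)))
        assert model.weights["cgA"] == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)

    def test_null_labels_give_prevalence_intercept(self):
        rng = np.random.default_rng(8)
        probes = {f"cg{i}": rng.beta(2, 2, 200).tolist() for i in range(4)}
        m = make_beta_matrix(probes)
        labels = rng.permutation([1] * 60 + [0] * 140)
        model = discovery.fit_weights(m, labels, MarkerPanel(tuple(sorted(probes))))
        assert model.intercept == pytest.approx(0.3, abs=0.15)
        for w in model.weights.values():
            assert abs(w) < 0.3

    def test_planted_panel_refit_has_positive_weights(self, tissue_cohort):
        matrix, sheet, truth = tissue_cohort
        hcc = sheet.loc[sheet["group"] == "HCC", "sample_id"].tolist()
        liver = sheet.loc[sheet["group"] == "tissue:liver", "sample_id"].tolist()
        sub = matrix.subset_samples(hcc + liver)
        labels = np.array([1] * len(hcc) + [0] * len(liver))
        model = discovery.fit_weights(sub, labels, MarkerPanel(truth.planted_detect_markers))
        assert all(w > 0 for w in model.weights.values())

    def test_collinear_design_names_dependent_probe(self):
        m = make_beta_matrix({"cgA": [0.1, 0.2, 0.3, 0.4], "cgB": [0.2, 0.4, 0.6, 0.8]})
        with pytest.raises(ValueError, match="cgB"):
            discovery.fit_weights(m, [0, 0, 1, 1], MarkerPanel(("cgA", "cgB")))


def enrichment_oracle(N, K, n, k):
    """Exhaustive enumeration over all C(N, n) panel draws."""
    universe = list(range(N))
    feature = set(range(K))
    ge = le = total = 0
    for draw in itertools.combinations(universe, n):
        overlap = len(feature & set(draw))
        total += 1
        ge += overlap >= k
        le += overlap <= k
    return ge / total, le / total


class TestEnrichment:
    def _run(self, N, K, n, k):
        universe = {f"p{i}" for i in range(N)}
        ann = {f"p{i}": ["feat"] for i in range(K)}
        panel = {f"p{i}" for i in range(k)} | {f"p{K + i}" for i in range(n - k)}
        assert len(panel) == n
        table = discovery.enrichment(panel, ann, universe)
        return table[table["feature"] == "feat"].iloc[0]

    def test_full_overlap_example(self):
        row = self._run(N=10, K=5, n=4, k=4)
        assert row["p_enrich"] == pytest.approx(5 / 210)

    def test_zero_overlap_depletion_example(self):
        row = self._run(N=10, K=5, n=4, k=0)
        assert row["p_deplete"] == pytest.approx(5 / 210)

    def test_fold_is_one_at_expected_overlap(self):
        row = self._run(N=10, K=5, n=4, k=2)  # expected overlap n*K/N = 2
        assert row["fold"] == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 4), (12, 6, 5)])
    def test_matches_enumeration_oracle(self, N, K, n):
        for k in range(0, min(K, n) + 1):
            row = self._run(N, K, n, k)
            p_ge, p_le = enrichment_oracle(N, K, n, k)
            assert row["p_enrich"] == pytest.approx(p_ge)
            assert row["p_deplete"] == pytest.approx(p_le)
            assert row["p_enrich"] + row["p_deplete"] >= 1.0 - 1e-12

    def test_panel_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            discovery.enrichment({"x"}, {}, {"a", "b"})

    def test_empty_feature_fold_missing(self):
        table = discovery.enrichment({"a"}, {"a": []}, {"a", "b"})
        assert table.empty or table["fold"].isna().all()
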