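import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from oncopath.markers import (
    DEFAULT_FDR_GRID,
    OneVsRestMarkerSelector,
    anova_screen,
    bh_adjust,
    biotype_composition,
    gini_purity,
    one_vs_rest_ttest,
    select_proteins,
    select_transcripts,
    top_biotype_percent,
)
from oncopath import SimConfig, generate_study

from conftest import make_matrix


def two_class_matrix(rows):
    """6-sample matrix: s0-s2 labelled A, s3-s5 labelled B."""
    m = make_matrix(rows, scale="log2")
    labels = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
    return m, labels


class TestAnovaScreen:
    def test_constant_feature_dropped(self):
        m, labels = two_class_matrix([[2.0] * 6, [1, 2, 3, 7, 8, 9]])
        out = anova_screen(m, labels)
        assert out.loc["f0", "anova_p"] == 1.0
        assert not out.loc["f0", "retained"]
        assert out.loc["f1", "retained"]

    def test_strong_shift_retained(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.1, size=(1, 10))
        shifted = base.copy()
        shifted[0, :5] += 5.0
        m = make_matrix(shifted, scale="log2")
        m.values.columns = [f"s{i}" for i in range(10)]
        labels = {f"s{i}": ("A" if i < 5 else "B") for i in range(10)}
        out = anova_screen(m, labels)
        assert out.loc["f0", "anova_p"] < 1e-6
        assert out.loc["f0", "retained"]

    def test_sample_order_irrelevant(self):
        m, labels = two_class_matrix([[1, 5, 2, 8, 7, 9], [0, 1, 0, 1, 0, 1]])
        out1 = anova_screen(m, labels)
        perm = ["s4", "s0", "s5", "s2", "s1", "s3"]
        m2 = m.subset_samples(perm)
        out2 = anova_screen(m2, labels)
        np.testing.assert_allclose(out1["anova_p"], out2["anova_p"])

    def test_small_class_named_in_error(self):
        m, _ = two_class_matrix([[1, 2, 3, 4, 5, 6]])
        labels = {"s0": "A", "s1": "A", "s2": "A", "s3": "A", "s4": "A", "s5": "tiny"}
        with pytest.raises(ValueError, match="tiny"):
            anova_screen(m, labels)


class TestOneVsRestTtest:
    def test_equal_groups_null(self):
        m, labels = two_class_matrix([[1, 2, 3, 1, 2, 3]])
        out = one_vs_rest_ttest(m, labels, "A")
        assert out.loc["f0", "t_stat"] == pytest.approx(0.0)
        assert out.loc["f0", "p_raw"] == pytest.approx(1.0)

    def test_pooled_t_closed_form(self):
        # {1,2,3} vs {4,5,6}: pooled sd 1, se = sqrt(2/3), |t| = 3/se = 3.674, df=4
        m, labels = two_class_matrix([[1, 2, 3, 4, 5, 6]])
        out = one_vs_rest_ttest(m, labels, "A")
        assert abs(out.loc["f0", "t_stat"]) == pytest.approx(3.674, abs=1e-3)
        assert out.loc["f0", "p_raw"] == pytest.approx(0.0213, abs=1e-3)
        assert out.loc["f0", "direction"] == "down"

    def test_scaling_one_group_changes_p(self):
        m, labels = two_class_matrix([[1, 2, 3, 4, 5, 6]])
        base = one_vs_rest_ttest(m, labels, "A").loc["f0", "p_raw"]
        both = make_matrix([[2, 4, 6, 8, 10, 12]], scale="log2")
        p_both = one_vs_rest_ttest(both, labels, "A").loc["f0", "p_raw"]
        one = make_matrix([[2, 4, 6, 4, 5, 6]], scale="log2")
        p_one = one_vs_rest_ttest(one, labels, "A").loc["f0", "p_raw"]
        assert p_both == pytest.approx(base)
        assert p_one != pytest.approx(base)

    def test_too_few_values_marked_missing(self):
        rows = np.array([[1.0, np.nan, np.nan, 4.0, 5.0, 6.0]])
        m, labels = two_class_matrix(rows)
        out = one_vs_rest_ttest(m, labels, "A")
        assert np.isnan(out.loc["f0", "p_raw"])


class TestBhAdjust:
    def test_known_values(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_step_up_oracle(self, p):
        # independent brute-force step-up: sort, apply p(i)*n/i, running min
        p = np.asarray(p)
        order = np.argsort(p)
        n = len(p)
        adjusted = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adjusted[i] = running
        np.testing.assert_allclose(bh_adjust(p), adjusted, atol=1e-12)


class TestGiniPurity:
    def test_reference_values(self):
        assert gini_purity([1, 1, 2, 2], ["a", "a", "b", "b"]) == pytest.approx(1.0)
        assert gini_purity([1, 1, 1, 1], ["a", "a", "b", "b"]) == pytest.approx(0.5)
        assert gini_purity([1, 1, 1, 1], ["t", "t", "t", "r"]) == pytest.approx(0.625)

    def test_relabelling_and_order_invariance(self):
        rng = np.random.default_rng(5)
        clusters = rng.integers(0, 3, size=30)
        labels = rng.choice(["t", "r"], size=30)
        base = gini_purity(clusters, labels)
        remap = np.array([7, 2, 9])[clusters]
        assert gini_purity(remap, labels) == pytest.approx(base)
        perm = rng.permutation(30)
        assert gini_purity(clusters[perm], labels[perm]) == pytest.approx(base)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gini_purity([], [])


class TestSelectTranscripts:
    def test_grid_has_nine_cutoffs(self):
        assert len(DEFAULT_FDR_GRID) == 9
        np.testing.assert_allclose(DEFAULT_FDR_GRID, 10.0 ** np.arange(-10, -1))

    def test_recovers_planted_markers(self, bundle, study_result):
        for cls in bundle.truth["classes"]:
            sel = study_result.marker_sets[(cls, "transcript")]
            planted = set(bundle.truth["markers"][cls])
            got = set(sel.feature_ids)
            sensitivity = len(planted & got) / len(planted)
            precision = len(planted & got) / len(got)
            assert sensitivity >= 0.90
            assert precision >= 0.90

    def test_subset_size_monotone_in_cutoff(self, study_result):
        for (cls, layer), sel in study_result.marker_sets.items():
            if layer != "transcript":
                continue
            sizes = [e.subset_size for e in sorted(sel.evaluations, key=lambda e: e.fdr_cutoff)]
            assert sizes == sorted(sizes)

    def test_no_signal_yields_empty_set(self):
        bundle = generate_study(
            SimConfig(
                n_classes=2, n_samples_per_class=8, n_features=120,
                n_markers_per_class=5, effect_size_log2=0.0,
                n_pathways=5, planted_pathways_per_class=1, n_drugs=4, seed=0,
            )
        )
        from oncopath.preprocess import cap_outliers, log2_transform

        log2m = log2_transform(cap_outliers(bundle.transcript_matrix)[0])
        with pytest.warns(UserWarning, match="no transcript"):
            sel = select_transcripts(log2m, bundle.labels, "type_1")
        assert sel.feature_ids == []
        assert sel.chosen_cutoff is None

    def test_permuted_labels_lower_purity(self, bundle):
        from oncopath.preprocess import cap_outliers, log2_transform

        log2m = log2_transform(cap_outliers(bundle.transcript_matrix)[0])
        intact = select_transcripts(log2m, bundle.labels, "type_1")
        best_intact = max(e.gini_purity for e in intact.evaluations if e.gini_purity is not None)
        rng = np.random.default_rng(0)
        samples = list(bundle.labels)
        permuted_purities = []
        for _ in range(3):
            shuffled = rng.permutation([bundle.labels[s] for s in samples])
            permuted = dict(zip(samples, shuffled))
            sel = select_transcripts(log2m, permuted, "type_1")
            scored = [e.gini_purity for e in sel.evaluations if e.gini_purity is not None]
            permuted_purities.append(max(scored) if scored else 0.0)
        assert np.median(permuted_purities) < best_intact


class TestSelectProteins:
    def test_selection_matches_raw_p_rule(self, bundle, study_result):
        for cls in bundle.truth["classes"]:
            sel = study_result.marker_sets[(cls, "protein")]
            expected = sel.stats.index[sel.stats["p_raw"] < 0.05]
            assert list(sel.feature_ids) == list(expected)
            assert sel.chosen_cutoff == 0.05

    def test_empty_after_screen(self):
        m, labels = two_class_matrix([[2.0] * 6])
        sel = select_proteins(m, labels, "A")
        assert sel.feature_ids == []


class TestBiotypeSummary:
    def test_composition_counts(self):
        counts = biotype_composition(["lincRNA", "protein_coding", "protein_coding", None])
        assert counts.tolist() == [2, 1]
        assert counts.index.tolist() == ["protein_coding", "lincRNA"]

    def test_top_fraction_with_external_total(self):
        counts = pd.Series({"a": 50, "b": 30, "c": 15})
        assert top_biotype_percent(counts, n_top=2, total=100) == pytest.approx(80.0)


class TestSelectorEstimator:
    def test_clone_and_fit_transform(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 0.3, size=(24, 40))
        y = np.repeat(["A", "B", "C"], 8)
        X[y == "A", :4] += 3.0  # 4 markers for class A
        sel = OneVsRestMarkerSelector(target="A", layer="transcript")
        assert clone(sel).get_params()["target"] == "A"
        sel.fit(X, y)
        assert sel.get_support().sum() == 4
        assert set(np.flatnonzero(sel.get_support())) == {0, 1, 2, 3}
        assert sel.transform(X).shape == (24, 4)

    def test_protein_layer_threshold(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, size=(30, 50))
        y = np.repeat(["A", "B"], 15)
        sel = OneVsRestMarkerSelector(target="A", layer="protein").fit(X, y)
        stats = sel.stats_
        assert sel.get_support().sum() == int((stats["p_raw"] < 0.05).sum())
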