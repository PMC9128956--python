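"""Normalization, specificity scoring, DE and classification."""

import numpy as np
import pandas as pd
import pytest

from ervregnet.expression import (
    ExpressionMatrix,
    GERMLINE_CELL_TYPES,
    PGCLC_MODEL,
    SpecificityModel,
    aggregate_te_subfamilies,
    classify_features,
    compare_species,
    de_from_table,
    differential_upregulation,
    normalize_cp10k,
    specificity_score,
    top_score_set,
)

from conftest import matrix_from_blocks


def brute_force_scores(matrix, model):
    """Independent per-feature reimplementation with explicit loops."""
    keep = [
        c
        for c in matrix.cells
        if matrix.cell_meta.loc[c, "cell_type"] in model.cell_types
    ]
    totals = {c: matrix.counts[c].sum() for c in keep}
    logx = {
        (f, c): np.log2(matrix.counts.loc[f, c] / totals[c] * 1e4 + 1.0)
        for f in matrix.features
        for c in keep
    }
    out = {}
    for f in matrix.features:
        vals = [logx[(f, c)] for c in keep]
        mu, sd = np.mean(vals), np.std(vals)
        if sd == 0:
            out[f] = None
            continue
        z = {c: (logx[(f, c)] - mu) / sd for c in keep}
        means = []
        for ct in model.cell_types:
            cells_ct = [c for c in keep if matrix.cell_meta.loc[c, "cell_type"] == ct]
            means.append(np.mean([z[c] for c in cells_ct]))
        lo, hi = min(means), max(means)
        if hi == lo:
            out[f] = None
            continue
        rescaled = [(m - lo) / (hi - lo) for m in means]
        ssr = sum((d - w) ** 2 for d, w in zip(rescaled, model.weights))
        out[f] = -np.log10(max(ssr, 1e-12))
    return out


class TestNormalization:
    def test_cp10k_proportions(self):
        m = matrix_from_blocks(
            {"a": dict.fromkeys(GERMLINE_CELL_TYPES, 1),
             "b": dict.fromkeys(GERMLINE_CELL_TYPES, 3),
             "c": dict.fromkeys(GERMLINE_CELL_TYPES, 6)},
            n_cells=1,
        )
        cp10k, logx = normalize_cp10k(m)
        assert np.allclose(cp10k.iloc[:, 0], [1000, 3000, 6000])
        # log2 of a zero count is log2(0+1) = 0
        m.counts.iloc[0, 0] = 0
        _, logx = normalize_cp10k(m)
        assert logx.iloc[0, 0] == 0.0

    def test_cp10k_columns_sum_to_10k(self, random_matrix):
        cp10k, _ = normalize_cp10k(random_matrix)
        assert np.allclose(cp10k.sum(axis=0), 1e4, atol=1e-6)

    def test_empty_matrix_errors(self):
        m = matrix_from_blocks({"a": dict.fromkeys(GERMLINE_CELL_TYPES, 1)})
        m.counts = m.counts.iloc[:0, :0]
        with pytest.raises(ValueError):
            normalize_cp10k(m)


class TestAggregation:
    def test_sums_and_conservation(self, random_matrix):
        mapping = {f: f"sub{int(f[1:]) % 5}" for f in random_matrix.features}
        agg = aggregate_te_subfamilies(random_matrix, mapping)
        assert agg.counts.to_numpy().sum() == random_matrix.counts.to_numpy().sum()
        assert agg.counts.shape[0] == 5
        # explicit small case: loci [2, 3, 0] in one subfamily sum to 5
        one = random_matrix.counts.iloc[:3].copy()
        one.iloc[0, 0], one.iloc[1, 0], one.iloc[2, 0] = 2, 3, 0
        m = ExpressionMatrix(one, random_matrix.cell_meta)
        agg1 = aggregate_te_subfamilies(m, dict.fromkeys(one.index, "s"))
        assert agg1.counts.iloc[0, 0] == 5

    def test_single_locus_subfamily_is_identity(self, random_matrix):
        mapping = {f: f for f in random_matrix.features}
        agg = aggregate_te_subfamilies(random_matrix, mapping)
        assert np.array_equal(
            agg.counts.sort_index().to_numpy(),
            random_matrix.counts.sort_index().to_numpy(),
        )

    def test_missing_locus_errors(self, random_matrix):
        mapping = {f: "s" for f in list(random_matrix.features)[:-1]}
        with pytest.raises(ValueError, match="missing from annotation"):
            aggregate_te_subfamilies(random_matrix, mapping)


class TestSpecificityScore:
    def test_matches_brute_force(self, random_matrix):
        scores = specificity_score(random_matrix)
        oracle = brute_force_scores(random_matrix, PGCLC_MODEL)
        for f, expected in oracle.items():
            if expected is None:
                assert scores.loc[f, "flag"] != ""
            else:
                assert scores.loc[f, "score"] == pytest.approx(expected, abs=1e-9)

    def test_perfect_model_match_scores_12(self):
        # counts chosen so log2[CP10k+1] per-type means rescale exactly to
        # the model vector (0, 0, 1, 0.5, 0, 0): with per-cell totals of
        # 10,000 the CP10k value equals the count, and
        # log2(100) = log2(10000) / 2.
        target = dict(zip(GERMLINE_CELL_TYPES, [0, 0, 9999, 99, 0, 0]))
        filler = dict(zip(GERMLINE_CELL_TYPES, [10000, 10000, 1, 9901, 10000, 10000]))
        m = matrix_from_blocks({"t": target, "fill": filler})
        scores = specificity_score(m)
        assert scores.loc["t", "ssr"] == pytest.approx(0.0, abs=1e-12)
        assert scores.loc["t", "score"] == pytest.approx(12.0)

    def test_hand_computed_ssr(self):
        # per-type profile rescaling to (0,0,0,0,0,1) against the model
        # (0,0,1,0.5,0,0): SSR = 1 + 0.25 + 1 = 2.25
        target = dict(zip(GERMLINE_CELL_TYPES, [1, 1, 1, 1, 1, 9]))
        filler = dict(zip(GERMLINE_CELL_TYPES, [9, 9, 9, 9, 9, 1]))
        m = matrix_from_blocks({"t": target, "fill": filler})
        scores = specificity_score(m)
        assert scores.loc["t", "ssr"] == pytest.approx(2.25, abs=1e-12)
        assert scores.loc["t", "score"] == pytest.approx(-np.log10(2.25), abs=1e-9)
        assert scores.loc["t", "score"] == pytest.approx(-0.3522, abs=1e-4)

    def test_model_vector_weights(self):
        assert PGCLC_MODEL.cell_types == GERMLINE_CELL_TYPES
        assert PGCLC_MODEL.weights == (0.0, 0.0, 1.0, 0.5, 0.0, 0.0)

    def test_invariant_to_library_size(self, random_matrix):
        scores = specificity_score(random_matrix)
        scaled = ExpressionMatrix(
            random_matrix.counts * np.arange(1, 61), random_matrix.cell_meta
        )
        rescored = specificity_score(scaled)
        ok = scores["flag"] == ""
        assert np.allclose(
            scores.loc[ok, "score"], rescored.loc[ok, "score"], atol=1e-9
        )

    def test_ranking_is_monotone_in_ssr(self, random_matrix):
        scores = specificity_score(random_matrix)
        ok = scores[scores["flag"] == ""]
        by_score = ok.sort_values("score", ascending=False).index
        by_neg_ssr = ok.sort_values("ssr", ascending=True).index
        assert list(by_score) == list(by_neg_ssr)

    def test_zero_variance_flagged_not_errored(self, random_matrix):
        m = random_matrix
        m.counts.iloc[0] = 0  # all-zero feature: constant after CP10k too
        scores = specificity_score(m)
        assert scores.iloc[0]["flag"] == "zero_variance"
        assert np.isnan(scores.iloc[0]["score"])

    def test_missing_model_cell_type_errors(self, random_matrix):
        sub = random_matrix.subset_cells(
            [c for c in random_matrix.cells if not c.startswith("PGCLC")]
        )
        with pytest.raises(ValueError, match="PGCLC"):
            specificity_score(sub)

    def test_model_validation(self):
        with pytest.raises(ValueError, match="equal 1"):
            SpecificityModel(("a", "b"), (0.5, 0.5))
        with pytest.raises(ValueError):
            SpecificityModel(("a", "b"), (1.0, 1.5))


class TestDifferentialUpregulation:
    @pytest.fixture
    def two_group_matrix(self):
        rng = np.random.default_rng(3)
        n = 40
        cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        counts = pd.DataFrame(
            rng.poisson(20, size=(30, 2 * n)),
            index=[f"f{i}" for i in range(30)],
            columns=cols,
        )
        counts.iloc[0, :n] *= 8  # strongly up in group A
        counts.iloc[1] = 0  # constant zero, must be filtered
        meta = pd.DataFrame({"cell_type": "x"}, index=pd.Index(cols, name="cell_id"))
        return ExpressionMatrix(counts, meta), cols[:n], cols[n:]

    def test_planted_signal_detected(self, two_group_matrix):
        m, a, b = two_group_matrix
        de = differential_upregulation(m, a, b)
        assert de.loc["f0", "log2fc"] > 1
        assert de.loc["f0", "fdr"] < 0.05

    def test_zero_feature_removed_by_filter(self, two_group_matrix):
        m, a, b = two_group_matrix
        de = differential_upregulation(m, a, b)
        assert "f1" not in de.index

    def test_identical_groups_give_zero_fc(self, two_group_matrix):
        m, a, b = two_group_matrix
        # same cells duplicated under new names
        dup = ExpressionMatrix(
            pd.concat(
                [m.counts[a], m.counts[a].rename(columns=lambda c: c + "_dup")], axis=1
            ),
            pd.DataFrame(
                {"cell_type": "x"},
                index=pd.Index([*a, *(c + "_dup" for c in a)], name="cell_id"),
            ),
        )
        de = differential_upregulation(dup, a, [c + "_dup" for c in a])
        assert np.allclose(de["log2fc"], 0.0)
        assert (de["p"] == 1.0).all()

    def test_group_overlap_errors(self, two_group_matrix):
        m, a, b = two_group_matrix
        with pytest.raises(ValueError, match="overlap"):
            differential_upregulation(m, a, a[:5] + b)

    def test_fdr_dominates_p(self, two_group_matrix):
        m, a, b = two_group_matrix
        de = differential_upregulation(m, a, b)
        assert (de["fdr"] >= de["p"] - 1e-12).all()

    def test_adapter_mode_validates(self):
        good = pd.DataFrame(
            {"feature": ["g1"], "log2fc": [2.0], "fdr": [0.01]}
        )
        assert de_from_table(good).loc["g1", "log2fc"] == 2.0
        with pytest.raises(ValueError, match="missing columns"):
            de_from_table(pd.DataFrame({"feature": ["g1"], "log2fc": [1.0]}))


class TestClassification:
    @pytest.fixture
    def score_de_tables(self):
        n = 100
        feats = [f"g{i:03d}" for i in range(n)]
        scores = pd.DataFrame(
            {"ssr": np.linspace(0.1, 5, n), "score": -np.log10(np.linspace(0.1, 5, n)),
             "flag": ""},
            index=pd.Index(feats, name="feature"),
        )
        de = pd.DataFrame(
            {"log2fc": [2.0] * 50 + [0.0] * 50, "fdr": [0.001] * 50 + [0.9] * 50},
            index=pd.Index(feats, name="feature"),
        )
        return scores, de

    def test_top_fraction_exact_count(self, score_de_tables):
        scores, de = score_de_tables
        top, realized = top_score_set(scores, 0.10)
        assert len(top) == 10
        assert realized == pytest.approx(0.10)

    def test_tie_rule_is_inclusive(self, score_de_tables):
        scores, de = score_de_tables
        scores = scores.copy()
        scores.iloc[:15, scores.columns.get_loc("score")] = 3.0  # 15-way tie at the top
        top, realized = top_score_set(scores, 0.10)
        assert len(top) == 15
        assert realized == pytest.approx(0.15)

    def test_rule_application(self, score_de_tables):
        scores, de = score_de_tables
        labels = classify_features(scores, de)
        # rank 1..10 are top-score; first 50 are naive-up
        assert labels.loc["g000", "label"] == "both"
        assert labels.loc["g010", "label"] == "naive_only"  # rank 11, DE-up
        assert labels.loc["g060", "label"] == "other"

    def test_partition(self, score_de_tables):
        scores, de = score_de_tables
        labels = classify_features(scores, de)
        assert labels["label"].isin(["both", "pgclc_only", "naive_only", "other"]).all()
        assert len(labels) == 100

    def test_manual_override(self, score_de_tables):
        scores, de = score_de_tables
        labels = classify_features(scores, de, overrides={"g000": "pgclc_only"})
        assert labels.loc["g000", "label"] == "pgclc_only"
        assert bool(labels.loc["g000", "override"])

    def test_empty_universe_errors(self, score_de_tables):
        scores, de = score_de_tables
        with pytest.raises(ValueError, match="empty"):
            classify_features(scores, de.iloc[:0])


class TestCompareSpecies:
    def _labels(self, mapping):
        return pd.DataFrame(
            {"label": pd.Series(mapping)}, index=pd.Index(mapping, name="feature")
        )

    def test_rule_and_counts(self):
        human = self._labels({"g1": "both", "g2": "both", "g3": "other"})
        other = self._labels({"o1": "other", "o2": "both", "o3": "both"})
        res = compare_species(
            human, other, {"g1": "o1", "g2": "o2", "g3": "o3"},
            {"g1": True, "g2": True, "g3": True},
        )
        assert res["likely_regulated"] == {"g1"}  # both-in-human, not in other, adjacent
        assert res["n_shared_both"] == 1

    def test_all_conserved_gives_empty_set(self):
        human = self._labels({"g1": "both"})
        other = self._labels({"o1": "both"})
        res = compare_species(human, other, {"g1": "o1"}, {"g1": True})
        assert res["likely_regulated"] == set()

    def test_adjacency_required(self):
        human = self._labels({"g1": "both"})
        other = self._labels({"o1": "other"})
        res = compare_species(human, other, {"g1": "o1"}, {"g1": False})
        assert res["likely_regulated"] == set()

    def test_duplicate_orthologs_error(self):
        human = self._labels({"g1": "both", "g2": "both"})
        other = self._labels({"o1": "other"})
        with pytest.raises(ValueError, match="one-to-one"):
            compare_species(human, other, {"g1": "o1", "g2": "o1"}, {})
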