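import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_model
from prscape.enrichment import (
    ContingencyTable2x2,
    EnrichmentMatrix,
    build_contingency,
    build_enrichment_matrix,
    cluster_order,
    divergence_filter,
    fisher_two_sided_p,
    signed_score,
)
from prscape.errors import UntestableTableError
from prscape.frequencies import PopulationAlleleCounts


def fisher_oracle(a, b, c, d):
    """Independent enumeration: sum hypergeometric probabilities of all
    same-margin tables no more probable than the observed one (integer
    weights; same 1e-7 relative tie rule as R's fisher.test)."""
    r1, r2, c1 = a + b, c + d, a + c
    weights = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    obs = weights[a]
    num = sum(w for w in weights.values() if w <= obs * (1 + 1e-7))
    return num / math.comb(r1 + r2, c1)


def counts_of(pop, data):
    frame = pd.DataFrame(
        [{"rsid": r, "eac": e, "tac": t} for r, (e, t) in data.items()]
    ).set_index("rsid")
    return PopulationAlleleCounts(pop, frame)


class TestContingency:
    def test_cells_from_counts(self):
        t = build_contingency(
            counts_of("A", {"rs1": (8, 10)}), counts_of("rest", {"rs1": (10, 40)}), "rs1"
        )
        assert (t.a, t.b, t.c, t.d) == (8, 2, 10, 30)

    def test_degenerate_all_zero_column_has_p_one(self):
        t = build_contingency(
            counts_of("A", {"rs1": (0, 10)}), counts_of("rest", {"rs1": (0, 40)}), "rs1"
        )
        assert (t.a, t.b, t.c, t.d) == (0, 10, 0, 40)
        assert fisher_two_sided_p(t) == 1.0

    def test_zero_total_untestable(self):
        with pytest.raises(UntestableTableError):
            build_contingency(
                counts_of("A", {"rs1": (0, 0)}), counts_of("rest", {"rs1": (5, 10)}), "rs1"
            )


class TestFisher:
    @pytest.mark.parametrize(
        "table",
        [(8, 2, 10, 30), (0, 10, 40, 0), (5, 5, 50, 50), (1, 9, 9, 1), (3, 0, 0, 3)],
    )
    def test_matches_enumeration_oracle(self, table):
        p = fisher_two_sided_p(ContingencyTable2x2(*table))
        assert p == pytest.approx(fisher_oracle(*table), rel=1e-10)

    def test_modal_table_gives_p_one(self):
        assert fisher_two_sided_p(ContingencyTable2x2(5, 5, 50, 50)) == 1.0

    def test_stable_for_large_counts(self):
        # 1000GP-scale haplotype counts must not under/overflow
        p = fisher_two_sided_p(ContingencyTable2x2(900, 422, 1500, 3500))
        assert 0.0 < p <= 1.0
        sp = scipy.stats.fisher_exact([[900, 422], [1500, 3500]]).pvalue
        assert p == pytest.approx(sp, rel=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.integers(0, 40),
        b=st.integers(0, 40),
        c=st.integers(0, 40),
        d=st.integers(0, 40),
    )
    def test_agrees_with_scipy_cross_check(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        p = fisher_two_sided_p(ContingencyTable2x2(a, b, c, d))
        sp = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert p == pytest.approx(min(sp, 1.0), rel=1e-6)

    def test_p_decreases_toward_separation_at_fixed_margins(self):
        # margins (20, 20; 20, 20): shift a from balanced 10 toward 20
        last = 1.1
        for a in range(10, 21):
            p = fisher_two_sided_p(ContingencyTable2x2(a, 20 - a, 20 - a, a))
            assert p < last
            last = p


class TestSignedScore:
    def test_equal_proportions_score_zero(self):
        assert signed_score(ContingencyTable2x2(5, 5, 50, 50)) == 0.0

    def test_enriched_positive_depleted_negative_same_magnitude(self):
        enriched = ContingencyTable2x2(9, 1, 10, 30)
        depleted = ContingencyTable2x2(1, 9, 30, 10)  # allele columns swapped
        s_plus = signed_score(enriched)
        s_minus = signed_score(depleted)
        assert s_plus > 0 > s_minus
        assert s_plus == pytest.approx(-s_minus, rel=1e-12)
        assert s_plus == pytest.approx(-math.log10(fisher_oracle(9, 1, 10, 30)))

    def test_magnitude_is_neg_log10_p(self):
        t = ContingencyTable2x2(8, 2, 10, 30)
        assert abs(signed_score(t)) == pytest.approx(
            -math.log10(fisher_two_sided_p(t))
        )

    def test_underflow_floored_at_300(self):
        t = ContingencyTable2x2(40000, 0, 0, 40000)
        assert signed_score(t) == pytest.approx(300.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.integers(0, 30),
        b=st.integers(0, 30),
        c=st.integers(0, 30),
        d=st.integers(0, 30),
    )
    def test_antisymmetric_under_row_swap(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        s = signed_score(ContingencyTable2x2(a, b, c, d))
        swapped = signed_score(ContingencyTable2x2(c, d, a, b))
        assert s == pytest.approx(-swapped, abs=1e-12)


class TestMatrix:
    def model_and_counts(self):
        model = make_model([1.0, 1.0], rsids=["rs1", "rs2"])
        counts = {
            "A": counts_of("A", {"rs1": (90, 100), "rs2": (10, 100)}),
            "B": counts_of("B", {"rs1": (10, 100), "rs2": (50, 100)}),
            "C": counts_of("C", {"rs1": (50, 100), "rs2": (50, 100)}),
        }
        return model, counts

    def test_pool_excludes_focal_population(self):
        model, counts = self.model_and_counts()
        m = build_enrichment_matrix(model, counts)
        # focal A vs pool(B, C) at rs1: 90/100 vs 60/200
        expected = signed_score(ContingencyTable2x2(90, 10, 60, 140))
        assert m.scores.loc["rs1", "A"] == pytest.approx(expected)

    def test_identical_populations_give_zero_matrix(self):
        model = make_model([1.0], rsids=["rs1"])
        counts = {p: counts_of(p, {"rs1": (30, 100)}) for p in ("A", "B", "C")}
        m = build_enrichment_matrix(model, counts)
        assert (m.scores.to_numpy() == 0).all()

    def test_untestable_cells_recorded_missing(self):
        model = make_model([1.0, 1.0], rsids=["rs1", "rs2"])
        counts = {
            "A": counts_of("A", {"rs1": (5, 10)}),
            "B": counts_of("B", {"rs1": (5, 10), "rs2": (1, 10)}),
        }
        m = build_enrichment_matrix(model, counts)
        assert np.isnan(m.scores.loc["rs2", "A"])
        assert np.isnan(m.scores.loc["rs2", "B"])  # pool lacks rs2

    def test_requires_two_populations(self):
        model, counts = self.model_and_counts()
        with pytest.raises(ValueError):
            build_enrichment_matrix(model, {"A": counts["A"]})

    def test_bonferroni_column_emitted_not_used(self):
        model, counts = self.model_and_counts()
        m = build_enrichment_matrix(model, counts)
        long = m.to_long()
        n_tests = long["p_value"].notna().sum()
        assert long["p_bonferroni"].to_numpy() == pytest.approx(
            np.minimum(long["p_value"] * n_tests, 1.0).to_numpy()
        )


class TestDivergenceFilter:
    def matrix(self, scores):
        df = pd.DataFrame(scores, columns=["AFR", "EAS"])
        df.index = [f"rs{i}" for i in range(len(df))]
        return EnrichmentMatrix(df, 10.0 ** (-df.abs()))

    def test_sum_above_cutoff_retained(self):
        m = self.matrix([[40.0, -25.0]])
        assert divergence_filter(m, "AFR", "EAS", 60) == ["rs0"]

    def test_boundary_is_strict(self):
        m = self.matrix([[30.0, -30.0]])
        assert divergence_filter(m, "AFR", "EAS", 60) == []

    def test_cutoff_zero_retains_all_nonzero(self):
        m = self.matrix([[1.0, -2.0], [0.5, 3.0]])
        assert divergence_filter(m, "AFR", "EAS", 0) == ["rs0", "rs1"]

    def test_unknown_population_raises(self):
        m = self.matrix([[1.0, 2.0]])
        with pytest.raises(KeyError):
            divergence_filter(m, "AFR", "KOR", 10)


class TestClusterOrder:
    def test_identical_rows_adjacent(self):
        scores = pd.DataFrame(
            [[5.0, -5.0], [-4.0, 4.0], [5.0, -5.0]],
            index=["rs1", "rs2", "rs3"],
            columns=["A", "B"],
        )
        rows, _ = cluster_order(EnrichmentMatrix(scores, scores * 0 + 0.5))
        pos = {scores.index[i]: rank for rank, i in enumerate(rows)}
        assert abs(pos["rs1"] - pos["rs3"]) == 1

    def test_opposite_sign_blocks_separate_at_top_split(self):
        rng = np.random.default_rng(0)
        up = rng.normal(10, 0.5, size=(4, 3))
        down = rng.normal(-10, 0.5, size=(4, 3))
        scores = pd.DataFrame(np.vstack([up, down]))
        scores.index = [f"rs{i}" for i in range(8)]
        rows, _ = cluster_order(EnrichmentMatrix(scores, scores * 0 + 0.5))
        leaf_blocks = [i // 4 for i in rows]
        assert leaf_blocks in ([0] * 4 + [1] * 4, [1] * 4 + [0] * 4)

    def test_single_row_identity_order(self):
        scores = pd.DataFrame([[1.0, 2.0]], index=["rs1"], columns=["A", "B"])
        rows, cols = cluster_order(EnrichmentMatrix(scores, scores * 0 + 0.5))
        assert rows == [0]

    def test_permutation_invariance_of_merge_heights(self):
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        perm = rng.permutation(10)
        h1 = np.sort(linkage(X, "complete", "euclidean")[:, 2])
        h2 = np.sort(linkage(X[perm], "complete", "euclidean")[:, 2])
        assert h1 == pytest.approx(h2)
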