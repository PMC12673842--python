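"""GMT handling, set expansion, and the preranked permutation statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_es
from isoscope import enrichment
from isoscope.annotation import TranscriptRecord, make_tx_to_gene
from isoscope.enrichment import (
    EnrichmentParams,
    RankedList,
    enrichment_score,
    expand_gene_sets,
    permutation_pvalue,
    rank_transcripts,
    read_gmt,
    run_enrichment,
    write_gmt,
    _score_from_mask,
)
from isoscope.errors import EnrichmentError, ParseError


class TestReadGmt:
    def test_members_deduplicated(self):
        sets = read_gmt("SETA\tdesc\tG1\tG2\tG2\n")
        assert sets["SETA"].members == {"G1", "G2"}

    def test_line_without_members_is_an_error(self):
        with pytest.raises(ParseError, match="line 1"):
            read_gmt("SETA\tdesc\n")

    def test_duplicate_set_name_is_an_error(self):
        with pytest.raises(ParseError, match="duplicate"):
            read_gmt("SETA\td\tG1\nSETA\td\tG2\n")

    def test_empty_file_is_an_empty_collection(self):
        assert read_gmt("") == {}

    def test_round_trip_preserves_membership(self, sim_gmt):
        sets = read_gmt(sim_gmt.gmt_text)
        text = write_gmt(sets)
        assert read_gmt(text) == sets
        assert write_gmt(read_gmt(text)) == text


class TestExpandGeneSets:
    @pytest.fixture()
    def small_dict(self):
        return make_tx_to_gene(
            [
                TranscriptRecord("TX1.1", "G1.1", "A-201", "A", 100, "protein_coding"),
                TranscriptRecord("TX2.1", "G1.1", "A-202", "A", 90, "retained_intron"),
                TranscriptRecord("TX3.1", "G2.1", "B-201", "B", 80, "lncRNA"),
            ]
        )

    def test_stratum_selects_matching_transcripts_only(self, small_dict):
        sets = {"S": enrichment.GeneSet("S", "", frozenset({"A"}))}
        out = expand_gene_sets(sets, small_dict, "protein_coding", min_size=1)
        assert out.sets == {"S": frozenset({"TX1.1"})}

    def test_non_coding_group_pools_alternative_processing_types(self, small_dict):
        sets = {"S": enrichment.GeneSet("S", "", frozenset({"A"}))}
        out = expand_gene_sets(sets, small_dict, "non_coding_group", min_size=1)
        assert out.sets == {"S": frozenset({"TX2.1"})}

    def test_set_without_stratum_transcripts_dropped(self, small_dict):
        sets = {"S": enrichment.GeneSet("S", "", frozenset({"A"}))}
        out = expand_gene_sets(sets, small_dict, "lncRNA", min_size=1)
        assert out.sets == {}

    def test_unmatched_gene_symbols_counted(self, small_dict):
        sets = {"S": enrichment.GeneSet("S", "", frozenset({"A", "GHOST1", "GHOST2"}))}
        out = expand_gene_sets(sets, small_dict, "protein_coding", min_size=1)
        assert out.n_unmatched_genes == 2

    def test_gene_ids_match_version_insensitively(self, small_dict):
        sets = {"S": enrichment.GeneSet("S", "", frozenset({"G2.9"}))}
        out = expand_gene_sets(sets, small_dict, "lncRNA", min_size=1)
        assert out.sets == {"S": frozenset({"TX3.1"})}


class TestRankTranscripts:
    def _rows(self, triples):
        return pd.DataFrame(
            [
                {"transcript_id": t, "category": "protein_coding", "log2fc": fc, "qvalue": q}
                for t, fc, q in triples
            ]
        )

    def test_sorted_by_stat_descending(self):
        ranked = rank_transcripts(
            self._rows([("a", 2.0, 0.1), ("b", -1.0, 0.1), ("c", 0.5, 0.1)]),
            "protein_coding",
        )
        assert ranked.ids == ("a", "c", "b")
        assert list(ranked.stats) == [2.0, 0.5, -1.0]

    def test_ties_broken_by_qvalue_then_id(self):
        ranked = rank_transcripts(
            self._rows([("z", 1.0, 0.04), ("a", 1.0, 0.01), ("m", 1.0, 0.04)]),
            "protein_coding",
        )
        assert ranked.ids == ("a", "m", "z")

    def test_empty_stratum_yields_empty_list(self):
        ranked = rank_transcripts(self._rows([("a", 1.0, 0.1)]), "lncRNA")
        assert len(ranked) == 0


class TestEnrichmentScore:
    def test_single_hit_at_top_unweighted(self):
        ranked = RankedList(("a", "b", "c"), np.array([2.0, 1.0, 0.5]))
        es, profile = enrichment_score(ranked, {"a"}, weight_exponent=0)
        assert es == 1.0
        assert profile == pytest.approx([1.0, 0.5, 0.0])

    def test_single_hit_at_bottom_unweighted(self):
        # hand-enumerated walk: two misses of -1/2, then the hit back to 0
        ranked = RankedList(("a", "b", "c"), np.array([2.0, 1.0, 0.5]))
        es, profile = enrichment_score(ranked, {"c"}, weight_exponent=0)
        assert es == -1.0
        assert profile == pytest.approx([-0.5, -1.0, 0.0])

    def test_degenerate_sets_rejected(self):
        ranked = RankedList(("a", "b", "c"), np.array([2.0, 1.0, 0.5]))
        with pytest.raises(EnrichmentError, match="empty intersection"):
            enrichment_score(ranked, {"zz"})
        with pytest.raises(EnrichmentError, match="covers"):
            enrichment_score(ranked, {"a", "b", "c"})

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            k = int(rng.integers(1, n))
            p = float(rng.integers(0, 2))
            stats = np.sort(rng.normal(0, 1.5, n))[::-1].copy()
            hit = np.zeros(n, bool)
            hit[rng.choice(n, k, replace=False)] = True
            es, _ = _score_from_mask(stats, hit, p)
            assert es == brute_force_es(stats, hit, p)

    def test_complement_mirrors_sign_when_unweighted(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            k = int(rng.integers(1, n))
            stats = np.sort(rng.normal(0, 1, n))[::-1].copy()
            hit = np.zeros(n, bool)
            hit[rng.choice(n, k, replace=False)] = True
            es_set, prof = _score_from_mask(stats, hit, 0.0)
            es_comp, prof_c = _score_from_mask(stats, ~hit, 0.0)
            # the two running sums are exact negatives of each other
            np.testing.assert_allclose(prof_c, -prof, atol=1e-12)
            assert es_set * es_comp <= 0


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    stats=st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=40),
    data=st.data(),
)
def test_running_sum_is_bounded_and_returns_to_zero(stats, data):
    """|ES| never exceeds 1 and the completed walk ends back at ~0."""
    stats = np.sort(np.asarray(stats, float))[::-1].copy()
    n = len(stats)
    k = data.draw(st.integers(1, n - 1))
    positions = data.draw(st.permutations(range(n)))
    hit = np.zeros(n, bool)
    hit[list(positions[:k])] = True
    p = data.draw(st.sampled_from([0.0, 1.0]))
    es, profile = _score_from_mask(stats, hit, p)
    assert abs(es) <= 1 + 1e-12
    assert abs(profile[-1]) < 1e-9


class TestPermutationPvalue:
    def _ranked(self, n, seed=7):
        rng = np.random.default_rng(seed)
        stats = np.sort(rng.normal(0, 1, n))[::-1].copy()
        return RankedList(tuple(f"t{i}" for i in range(n)), stats)

    def test_same_seed_is_bit_identical(self):
        ranked = self._ranked(40)
        members = {"t0", "t3", "t11", "t20"}
        a = permutation_pvalue(ranked, members, 1.0, 500, seed=9)
        b = permutation_pvalue(ranked, members, 1.0, 500, seed=9)
        assert (a.pvalue, a.nes, a.es) == (b.pvalue, b.nes, b.es)

    def test_monte_carlo_agrees_with_exhaustive_null(self):
        # N=6, set size 2: the null has exactly 15 distinct member sets
        stats = np.array([3.0, 2.0, 1.0, 0.5, -1.0, -2.0])
        ids = tuple("abcdef")
        ranked = RankedList(ids, stats)
        for p in (0.0, 1.0):
            null = []
            for combo in itertools.combinations(range(6), 2):
                hit = np.zeros(6, bool)
                hit[list(combo)] = True
                null.append(_score_from_mask(stats, hit, p)[0])
            null = np.array(null)
            for combo in itertools.combinations(range(6), 2):
                hit = np.zeros(6, bool)
                hit[list(combo)] = True
                es = _score_from_mask(stats, hit, p)[0]
                matching = null > 0 if es > 0 else null < 0
                if matching.sum() == 0:
                    continue
                exhaustive = (matching & (np.abs(null) >= abs(es))).sum() / matching.sum()
                res = permutation_pvalue(
                    ranked, [ids[i] for i in combo], p, n_perm=50_000, seed=42
                )
                assert res.pvalue == pytest.approx(exhaustive, abs=0.01)

    def test_null_pvalues_are_calibrated(self):
        # random sets on a null ranked list: type-I error at 0.05 and a
        # Kolmogorov-Smirnov check of overall uniformity
        from scipy import stats as sps

        ranked = self._ranked(300)
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(2000):
            members = [f"t{j}" for j in rng.choice(300, 10, replace=False)]
            pvals.append(permutation_pvalue(ranked, members, 1.0, 200, seed=rng).pvalue)
        pvals = np.asarray(pvals)
        type1 = float(np.mean(pvals <= 0.05))
        assert 0.03 <= type1 <= 0.07
        ks = sps.kstest(pvals, "uniform").statistic
        # critical value of the one-sample KS statistic at alpha=0.01, n=2000
        assert ks < 1.63 / np.sqrt(len(pvals))


class TestRunEnrichment:
    def _params(self):
        return EnrichmentParams(min_size=5, weight_exponent=1.0, n_perm=500, seed=3)

    def test_planted_set_has_minimum_padj_in_its_stratum(
        self, annotated_tx, sim_gmt, tx2gene
    ):
        sets = read_gmt(sim_gmt.gmt_text)
        result = run_enrichment(
            annotated_tx, sets, tx2gene, ["protein_coding"], self._params()
        )
        stratum = result.loc[result["stratum"] == "protein_coding"]
        best = stratum.loc[stratum["padj"] == stratum["padj"].min(), "pathway"]
        assert list(best) == ["PLANTED_SWITCH_SET"]

    def test_empty_gmt_gives_empty_result(self, annotated_tx, tx2gene):
        out = run_enrichment(annotated_tx, {}, tx2gene, ["protein_coding"], self._params())
        assert out.empty
        assert list(out.columns) == enrichment.RESULT_COLUMNS

    def test_identical_seed_identical_table(self, annotated_tx, sim_gmt, tx2gene):
        sets = read_gmt(sim_gmt.gmt_text)
        a = run_enrichment(annotated_tx, sets, tx2gene, ["protein_coding", "lncRNA"], self._params())
        b = run_enrichment(annotated_tx, sets, tx2gene, ["protein_coding", "lncRNA"], self._params())
        pd.testing.assert_frame_equal(a, b)

    def test_padj_is_bh_monotone_within_stratum(self, annotated_tx, sim_gmt, tx2gene):
        sets = read_gmt(sim_gmt.gmt_text)
        result = run_enrichment(
            annotated_tx, sets, tx2gene, ["protein_coding", "non_coding_group"], self._params()
        )
        assert (result["padj"] <= 1).all()
        assert (result["padj"] >= result["pvalue"]).all()
        for _, sub in result.groupby("stratum"):
            ordered = sub.sort_values("pvalue")
            assert ordered["padj"].is_monotonic_increasing

    def test_leading_edge_is_subset_of_present_members(self, annotated_tx, sim_gmt, tx2gene):
        sets = read_gmt(sim_gmt.gmt_text)
        result = run_enrichment(annotated_tx, sets, tx2gene, ["protein_coding"], self._params())
        expanded = expand_gene_sets(sets, tx2gene, "protein_coding", 5)
        for row in result.itertuples():
            ledge = set(row.leading_edge.split(",")) if row.leading_edge else set()
            assert ledge <= expanded.sets[row.pathway]
            assert abs(row.es) <= 1
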