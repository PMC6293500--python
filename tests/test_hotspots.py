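import pytest

from rlda.corpus_io import SynonymLexicon
from rlda.hotspots import (HotspotRecord, YearHotspots, central_word,
                           count_across_years, export_wordcloud_data,
                           merge_year, read_wordcloud_data, relation_edges,
                           tier_for_count)

# Cross-year central-word memberships used as the worked example for trend
# counting (appearance years of recurring hotspot words).
TND_YEARS = {
    "tnf": [2007, 2008, 2010, 2011, 2013, 2016],
    "tumor": [2007, 2010, 2016],
    "inflammation": [2007, 2013, 2014],
    "hypertension": [2008, 2011, 2015],
    "adolescent": [2007, 2009, 2014],
    "cell": [2007, 2014, 2015],
    "cataract": [2008],
    "retina": [2009],
    "stroke": [2008, 2015],
    "periodontitis": [2009, 2011],
    "interleukin": [2007, 2010],
}


def yearly_from_membership(membership):
    years = sorted({y for ys in membership.values() for y in ys})
    return [
        YearHotspots(year=y, central_words=[
            (w, 0.1) for w, ys in membership.items() if y in ys])
        for y in years
    ]


class TestCentralWord:
    def test_rank_one_word(self):
        row = [("depression", 0.10), ("mental", 0.04), ("anxiety", 0.03)]
        assert central_word(row) == "depression"

    def test_single_word_row(self):
        assert central_word([("cell", 0.2)]) == "cell"

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            central_word([])


class TestMergeYear:
    def test_disjoint_rows_union(self):
        r1 = [(f"a{i}", 0.1 - i * 0.001) for i in range(20)]
        r2 = [(f"b{i}", 0.1 - i * 0.001) for i in range(20)]
        yh = merge_year(2007, [r1, r2])
        assert len(yh.central_words) == 40

    def test_duplicate_word_keeps_max_weight(self):
        yh = merge_year(2007, [[("tnf", 0.05)], [("tnf", 0.03)]])
        assert yh.central_words == [("tnf", 0.05)]

    def test_sorted_descending(self):
        yh = merge_year(2007, [[("a", 0.01), ("b", 0.5)], [("c", 0.1)]])
        weights = [w for _, w in yh.central_words]
        assert weights == sorted(weights, reverse=True)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_year(2007, [])


class TestTierRule:
    @pytest.mark.parametrize("count,tier", [
        (1, "once"), (2, "twice"), (3, "thrice"),
        (4, "more-than-thrice"), (6, "more-than-thrice"),
    ])
    def test_mapping_total(self, count, tier):
        assert tier_for_count(count) == tier


class TestCountAcrossYears:
    def test_tnf_counts_six_years(self):
        records = count_across_years(yearly_from_membership(TND_YEARS))
        tnf = next(r for r in records if r.word == "tnf")
        assert tnf.count == 6
        assert tnf.tier == "more-than-thrice"
        assert tnf.appearance_years == [2007, 2008, 2010, 2011, 2013, 2016]
        assert records[0].word == "tnf"  # sorted by count descending

    def test_synonym_group_counts_any_member(self):
        yearly = yearly_from_membership(
            {"cataract": [2008], "retinopathy": [2009], "tnf": [2008, 2009]})
        groups = {"cataract/retina/retinopathy":
                  ["cataract", "retina", "retinopathy"]}
        records = count_across_years(yearly, word_groups=groups)
        grp = next(r for r in records if r.word == "cataract/retina/retinopathy")
        assert grp.count == 2
        assert grp.appearance_years == [2008, 2009]

    def test_empty_input(self):
        assert count_across_years([]) == []

    def test_duplicate_years_rejected(self):
        yh = YearHotspots(2007, [("a", 0.1)])
        with pytest.raises(ValueError):
            count_across_years([yh, yh])

    def test_permutation_invariant_in_year_order(self):
        yearly = yearly_from_membership(TND_YEARS)
        fwd = count_across_years(yearly)
        rev = count_across_years(list(reversed(yearly)))
        assert [(r.word, r.count, r.appearance_years) for r in fwd] == \
               [(r.word, r.count, r.appearance_years) for r in rev]

    def test_every_record_tiered(self):
        for r in count_across_years(yearly_from_membership(TND_YEARS)):
            assert r.tier == tier_for_count(r.count)


class TestWordcloudExport:
    def test_round_trip_preserves_words_and_weights(self, tmp_path):
        yh = YearHotspots(2007, [("tumor", 0.123456), ("cell", 0.05)])
        p = tmp_path / "wc.tsv"
        export_wordcloud_data(yh, p)
        back = read_wordcloud_data(2007, p)
        assert [w for w, _ in back.central_words] == ["tumor", "cell"]
        for (_, w1), (_, w2) in zip(yh.central_words, back.central_words):
            assert w2 == pytest.approx(w1, abs=1e-6)

    def test_empty_hotspots_write_header_only(self, tmp_path):
        p = tmp_path / "wc.tsv"
        export_wordcloud_data(YearHotspots(2007, []), p)
        assert p.read_text() == "word\tweight\n"
        assert read_wordcloud_data(2007, p).central_words == []


class TestRelationEdges:
    lexicon = SynonymLexicon({
        "depression": ["depression", "mental", "anxiety"],
        "stroke": ["stroke"],
    })

    def exemplars(self, *word_probs):
        return [list(word_probs)]

    def test_shared_disease_yields_edges_to_both_seeds(self):
        rows = {
            "diabetes": self.exemplars(("depression", 0.2), ("bafo", 0.1)),
            "obesity": self.exemplars(("mental", 0.15), ("kura", 0.1)),
        }
        edges = relation_edges(rows, self.lexicon, min_weight=0.05)
        pairs = {(s, d) for s, d, _ in edges}
        assert ("diabetes", "depression") in pairs
        assert ("obesity", "depression") in pairs

    def test_min_weight_above_all_probabilities_gives_no_edges(self):
        rows = {"diabetes": self.exemplars(("depression", 0.2))}
        assert relation_edges(rows, self.lexicon, min_weight=0.5) == []

    def test_absent_disease_gets_no_edge(self):
        rows = {"diabetes": self.exemplars(("depression", 0.2))}
        edges = relation_edges(rows, self.lexicon, min_weight=0.0)
        assert all(d != "stroke" for _, d, _ in edges)

    def test_self_edge_skipped(self):
        lex = SynonymLexicon({"diabetes": ["diabetes"], "stroke": ["stroke"]})
        rows = {"diabetes": self.exemplars(("diabetes", 0.5))}
        assert relation_edges(rows, lex) == []

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            relation_edges({"diabetes": []}, SynonymLexicon({}))

    def test_edge_weight_is_max_probability(self):
        rows = {"diabetes": [
            [("depression", 0.1)], [("anxiety", 0.3)],
        ]}
        edges = relation_edges(rows, self.lexicon)
        assert edges == [("diabetes", "depression", pytest.approx(0.3))]


def test_hotspot_record_shape():
    r = HotspotRecord(word="tnf", appearance_years=[2007, 2008], count=2,
                      tier="twice")
    assert r.count == len(r.appearance_years)
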