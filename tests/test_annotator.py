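import pytest

from conftest import brute_force_direct
from enzner.annotator import (
    RuleConfig,
    Sentence,
    annotate_document,
    direct_match,
    find_enzyme_abbreviations,
    flat_direct_match,
    keyword_match,
    split_sentences,
)
from enzner.bioc_io import BioCDoc, BioCValidationError, Passage, article_text
from enzner.dictionary import EnzymeEntry, build_hierarchy, default_greek_table
from enzner.synth import SynthSpec, generate_corpus

GREEK = default_greek_table()


class TestSplitSentences:
    def test_offsets_are_global(self):
        sents = split_sentences("Kinases act. Phosphatases too.", 100)
        assert [s.text for s in sents] == ["Kinases act.", "Phosphatases too."]
        assert [s.start_offset for s in sents] == [100, 113]

    def test_empty_paragraph(self):
        assert split_sentences("", 0) == []

    def test_single_sentence_without_terminal_period(self):
        sents = split_sentences("enzyme activity was high", 5)
        assert len(sents) == 1
        assert sents[0].text == "enzyme activity was high"
        assert sents[0].start_offset == 5

    def test_species_initial_does_not_split(self):
        sents = split_sentences("Levels rose in E. coli cultures. A second point.", 0)
        assert len(sents) == 2
        assert sents[0].text.endswith("cultures.")

    def test_token_offsets_inside_sentence_span(self):
        (s,) = split_sentences("alcohol dehydrogenase rose.", 50)
        for tok, off in s.tokens:
            assert s.text[off - 50 : off - 50 + len(tok)] == tok


class TestDirectMatch:
    def test_greedy_keeps_only_the_longest_nested_form(self, tree):
        s = Sentence.from_text(
            "The aliphatic alcohol dehydrogenase activity was measured.", 0
        )
        matches = direct_match(s, tree)
        assert [m.surface for m in matches] == ["aliphatic alcohol dehydrogenase"]
        assert matches[0].identifier == "1.1.1.1"

    def test_no_candidates_no_matches(self, tree):
        s = Sentence.from_text("The cohort was recruited in two cities.", 0)
        assert direct_match(s, tree) == []

    def test_repeated_mention_gives_two_matches(self, tree):
        s = Sentence.from_text(
            "alcohol dehydrogenase and alcohol dehydrogenase", 0
        )
        matches = direct_match(s, tree)
        assert len(matches) == 2
        assert {m.start for m in matches} == {0, 26}

    def test_case_insensitive_but_surface_preserved(self, tree):
        s = Sentence.from_text("Alkaline Phosphatase rose twofold.", 0)
        (m,) = direct_match(s, tree)
        assert m.surface == "Alkaline Phosphatase"
        assert m.identifier == "3.1.3.1"

    def test_no_match_inside_hyphenated_token(self, tree):
        s = Sentence.from_text("catalase-positive colonies were counted.", 0)
        assert direct_match(s, tree) == []

    def test_agrees_with_brute_force_on_tricky_sentences(self, tree):
        texts = [
            "The aliphatic alcohol dehydrogenase and alcohol dehydrogenase.",
            "β-galactosidase and beta galactosidase were assayed.",
            "Na+/K+-ATPase activity fell while catalase rose.",
            "glucose-6-phosphate dehydrogenase (NADP+) was stable.",
            "no enzymes appear in this control sentence.",
        ]
        for text in texts:
            s = Sentence.from_text(text, 0)
            got = {(m.start, m.length, m.identifier) for m in direct_match(s, tree)}
            assert got == brute_force_direct(s, tree), text

    def test_flat_scan_equals_branch_scan(self, tree):
        s = Sentence.from_text(
            "Serum glutathione peroxidase and trypsin levels fell.", 7
        )
        assert direct_match(s, tree) == flat_direct_match(s, tree)


class TestKeywordMatch:
    def test_unseen_modifier_plus_root(self, tree, cfg):
        s = Sentence.from_text("Levels of deoxycytidine kinase were high.", 0)
        assert direct_match(s, tree) == []
        (m,) = keyword_match(s, tree, cfg)
        assert m.surface == "deoxycytidine kinase"
        assert m.identifier == "kinase"
        assert m.method == "keyword"

    def test_stoplist_words_never_fire(self, tree, cfg):
        s = Sentence.from_text("the database was queried", 0)
        assert keyword_match(s, tree, cfg) == []

    def test_single_number_forward_rule(self, cfg):
        # "carboxylesterase" here is a branch root but not a standalone form
        local = build_hierarchy(
            [EnzymeEntry("3.1.1.1", ("liver carboxylesterase",))], GREEK
        )
        s = Sentence.from_text("carboxylesterase 2 is expressed in gut.", 0)
        (m,) = keyword_match(s, local, cfg)
        assert m.surface == "carboxylesterase 2"

    def test_bracket_group_forward_rule(self, tree, cfg):
        s = Sentence.from_text("A novel transpeptidase (type II) was found.", 0)
        (m,) = keyword_match(s, tree, cfg)
        assert m.surface == "novel transpeptidase (type II)"

    def test_greek_letter_forward_rule(self, tree, cfg):
        s = Sentence.from_text("We purified the secretase γ from tissue.", 0)
        (m,) = keyword_match(s, tree, cfg)
        assert m.surface == "secretase γ"

    def test_function_words_block_backward_extension(self, tree, cfg):
        s = Sentence.from_text("We assayed the transpeptidase in serum.", 0)
        (m,) = keyword_match(s, tree, cfg)
        assert m.surface == "transpeptidase"

    def test_descriptive_modifiers_excluded(self, tree, cfg):
        s = Sentence.from_text("Levels of serum transpeptidase were high.", 0)
        (m,) = keyword_match(s, tree, cfg)
        assert m.surface == "transpeptidase"

    def test_backward_extension_capped_at_four_words(self, tree, cfg):
        s = Sentence.from_text(
            "one two three four five six transaminase", 0
        )
        (m,) = keyword_match(s, tree, cfg)
        assert m.surface == "three four five six transaminase"

    def test_tokens_inside_direct_matches_do_not_fire(self, tree, cfg):
        s = Sentence.from_text("Total alkaline phosphatase was measured.", 0)
        d = direct_match(s, tree)
        assert [m.surface for m in d] == ["alkaline phosphatase"]
        assert keyword_match(s, tree, cfg, direct=d) == []

    def test_punctuation_blocks_backward_extension(self, tree, cfg):
        s = Sentence.from_text("In plasma, transpeptidase rose.", 0)
        (m,) = keyword_match(s, tree, cfg)
        assert m.surface == "transpeptidase"


class TestAbbreviations:
    def test_greek_abbreviated_enzyme_definition(self, tree, cfg):
        found = find_enzyme_abbreviations(
            {"γGT": "gamma-glutamyl transpeptidase"}, tree, cfg
        )
        assert "γGT" in found
        assert found["γGT"].identifier == "2.3.2.2"

    def test_non_enzyme_definition_rejected(self, tree, cfg):
        found = find_enzyme_abbreviations(
            {"CSF": "cerebrospinal fluid"}, tree, cfg
        )
        assert found == {}

    def test_identifier_comes_from_definition_match(self, tree, cfg):
        found = find_enzyme_abbreviations(
            {"ADH": "alcohol dehydrogenase"}, tree, cfg
        )
        assert found["ADH"].identifier == "1.1.1.1"
        assert found["ADH"].method == "direct"

    def test_enzyme_must_cover_definition_head(self, tree, cfg):
        # enzyme present but the definition's head noun is not the enzyme
        found = find_enzyme_abbreviations(
            {"ADA": "alcohol dehydrogenase activity"}, tree, cfg
        )
        assert found == {}


def _doc(paragraphs, labels=None, pmcid="PMC1"):
    passages = []
    offset = 0
    labels = labels or ["results"] * len(paragraphs)
    for text, label in zip(paragraphs, labels):
        passages.append(Passage(text=text, offset=offset, section_label=label,
                                infons={"section_type": label}))
        offset += len(text) + 1
    return BioCDoc(pmcid=pmcid, passages=passages, infons={"domain": "other"})


class TestAnnotateDocument:
    def test_planted_enzymes_slice_back_to_their_annotations(self, tree, cfg):
        doc = _doc([
            "Serum catalase was elevated. We also measured trypsin.",
            "Finally, alkaline phosphatase decreased.",
        ])
        out = annotate_document(doc, tree, {}, cfg)
        anns = out.all_annotations()
        assert [a.text for a in anns] == [
            "catalase", "trypsin", "alkaline phosphatase"
        ]
        full = article_text(out)
        for a in anns:
            assert full[a.offset : a.end] == a.text
        assert [a.id for a in anns] == ["1", "2", "3"]

    def test_document_without_enzymes_round_trips_unchanged(self, tree, cfg):
        doc = _doc(["Participants signed consent forms.",
                    "Weights were recorded weekly."])
        out = annotate_document(doc, tree, {}, cfg)
        assert out.all_annotations() == []
        assert [p.text for p in out.passages] == [p.text for p in doc.passages]
        assert [p.offset for p in out.passages] == [p.offset for p in doc.passages]

    def test_abbreviation_occurrences_all_annotated(self, tree, cfg):
        doc = _doc([
            "Alcohol dehydrogenase (ADH) is abundant. ADH rose. ADH fell.",
            "Baseline ADH and final ADH values differed.",
        ])
        out = annotate_document(doc, tree, {"ADH": "alcohol dehydrogenase"}, cfg)
        anns = out.all_annotations()
        by_method = {}
        for a in anns:
            by_method.setdefault(a.infons["method"], []).append(a)
        assert len(by_method["direct"]) == 1  # the definition site
        assert len(by_method["abbreviation"]) == 5
        assert all(a.infons["identifier"] == "1.1.1.1" for a in anns)

    def test_unconfigured_sections_are_skipped(self, tree, cfg):
        doc = _doc(["catalase was high.", "catalase was low."],
                   labels=["results", "acknowledgements"])
        out = annotate_document(doc, tree, {}, cfg)
        assert len(out.all_annotations()) == 1

    def test_inconsistent_passage_offsets_rejected(self, tree, cfg):
        doc = BioCDoc(pmcid="PMC2", passages=[
            Passage(text="first paragraph here", offset=0),
            Passage(text="overlapping", offset=5),
        ])
        with pytest.raises(BioCValidationError, match="/passages/1"):
            annotate_document(doc, tree, {}, cfg)

    def test_determinism_and_input_untouched(self, tree, cfg):
        doc = _doc(["Serum catalase and the database were reviewed."])
        out1 = annotate_document(doc, tree, {}, cfg)
        out2 = annotate_document(doc, tree, {}, cfg)
        assert out1 == out2
        assert doc.all_annotations() == []  # input not mutated

    def test_annotations_never_overlap(self, tree, cfg):
        corpus = generate_corpus(
            SynthSpec(n_docs=6, seed=5, abbreviation_rate=0.3), tree
        )
        for doc in corpus.docs:
            out = annotate_document(doc, tree, corpus.abbrevs[doc.pmcid], cfg)
            spans = sorted((a.offset, a.end) for a in out.all_annotations())
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
            full = article_text(out)
            for a in out.all_annotations():
                assert full[a.offset : a.end] == a.text
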