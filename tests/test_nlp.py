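import re

import pytest

import consort_check as cc
from consort_check.ingest import Sentence, split_sentences
from consort_check.nlp import (
    ConfigurationError,
    CuePattern,
    annotate_sentence,
    lemmatize_word,
    match_cues,
    tag_entities,
    _ENTITY_PATTERNS,
)


def sent(text, label="METHODS"):
    return Sentence(text=text, section_label=label, index=0, start=0,
                    end=len(text))


class TestLemmatization:
    @pytest.mark.parametrize("surface,lemma", [
        ("randomised", "randomize"),
        ("randomized", "randomize"),
        ("randomization", "randomization"),  # lemmatization, not stemming
        ("randomisation", "randomization"),
        ("hospitalisation", "hospitalization"),
        ("criteria", "criterion"),
        ("analyses", "analysis"),
        ("stratified", "stratify"),
        ("enrolled", "enrol"),
        ("blinding", "blind"),
        ("concealed", "conceal"),
        ("generalisability", "generalizability"),
        ("stopped", "stop"),
        ("lost", "lose"),
        ("withdrew", "withdraw"),
        ("otherwise", "otherwise"),  # not a British -ise verb
    ])
    def test_spelling_normalized_lemmas(self, surface, lemma):
        assert lemmatize_word(surface) == lemma

    def test_annotation_is_aligned_and_deterministic(self):
        s = sent("Patients were randomised to receive 40 mg daily.")
        a1, a2 = annotate_sentence(s), annotate_sentence(s)
        assert a1 == a2
        assert len(a1.tokens) == len(a1.lemmas) == len(a1.pos)
        assert "randomize" in a1.lemmas
        spans = [(t[1], t[2]) for t in a1.tokens]
        assert spans == sorted(spans)
        assert all(0 <= b < e <= len(s.text) for b, e in spans)

    def test_empty_sentence_rejected(self):
        with pytest.raises(ValueError):
            annotate_sentence(sent(""))


class TestEntities:
    def entities(self, text):
        return tag_entities(annotate_sentence(sent(text)))

    @pytest.mark.parametrize("text,kind,normalized", [
        ("registered with ClinicalTrials.gov, NCT01148849", "REGISTRY_ID",
         "NCT01148849"),
        ("the ISRCTN registry (ISRCTN12345678)", "REGISTRY_ID",
         "ISRCTN12345678"),
        ("EudraCT, number 2015-452888-49", "REGISTRY_ID", "2015-452888-49"),
        ("randomly assigned in a 1:1 ratio", "ALLOCATION_RATIO", "1:1"),
        ("a 2 : 1 allocation", "ALLOCATION_RATIO", "2:1"),
        ("difference of 4.2 (95% CI, 1.8 to 6.6)", "CONFIDENCE_INTERVAL",
         "95% CI"),
        ("a 95% confidence interval of 0.4 to 0.9", "CONFIDENCE_INTERVAL",
         "95% CI"),
        ("achieved in 45% of patients", "PERCENTAGE", "45%"),
        ("enrolled between March 2015 and June 2017", "DATE_RANGE",
         "March 2015 and June 2017"),
        ("a total of 412 patients", "COUNT", "412"),
        ("significant at P < .001", "P_VALUE", "P<.001"),
        ("the World Health Organization recommends", "ORG",
         "World Health Organization"),
        ("a centre in New York", "LOCATION", "New York"),
    ])
    def test_kinds_and_normalization(self, text, kind, normalized):
        found = {(e.kind, e.normalized) for e in self.entities(text)}
        assert (kind, normalized) in found

    def test_spans_inside_sentence_and_nonoverlapping_per_kind(self):
        ents = self.entities(
            "Of 412 patients, 206 received 40 mg and 45% improved "
            "(95% CI, 30 to 60); NCT01148849.")
        by_kind = {}
        for e in ents:
            assert 0 <= e.start < e.end
            by_kind.setdefault(e.kind, []).append((e.start, e.end))
        for spans in by_kind.values():
            spans.sort()
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_normalized_registry_id_rematches_pattern(self):
        for text in ("NCT01148849 here", "ACTRN12612345678901 there",
                     "UMIN123456789 too"):
            for e in self.entities(text):
                if e.kind == "REGISTRY_ID":
                    assert _ENTITY_PATTERNS["REGISTRY_ID"].search(e.normalized)


class TestCueMatching:
    def test_sample_size_cues_brute_force_oracle(self):
        """Two hits, exactly where a naive window scan finds them."""
        s = sent("The sample size was calculated to provide 90% power")
        ann = annotate_sentence(s)
        patterns = [
            CuePattern("sample-size-calc", lemma_sequence=("sample", "size")),
            CuePattern("power-support", lemma_sequence=("power",),
                       weight="supporting"),
        ]
        hits = match_cues(ann, patterns)
        assert len(hits) == 2
        # independent O(n*m) oracle over lemma windows
        expected = []
        for pat in patterns:
            k = len(pat.lemma_sequence)
            for i in range(len(ann.lemmas) - k + 1):
                if ann.lemmas[i:i + k] == pat.lemma_sequence:
                    expected.append((pat.cue_id, ann.tokens[i][1],
                                     ann.tokens[i + k - 1][2]))
        assert sorted((h.cue_id, h.start, h.end) for h in hits) == \
            sorted(expected)

    def test_no_cues_empty(self):
        hits = match_cues(annotate_sentence(sent("Nothing relevant here.")),
                          [CuePattern("x", lemma_sequence=("absent",))])
        assert hits == []

    def test_overlapping_cues_all_reported(self):
        ann = annotate_sentence(sent("sample size calculation"))
        pats = [CuePattern("a", lemma_sequence=("sample", "size")),
                CuePattern("b", lemma_sequence=("size",))]
        assert {h.cue_id for h in match_cues(ann, pats)} == {"a", "b"}

    def test_malformed_regex_names_cue(self):
        ann = annotate_sentence(sent("text"))
        with pytest.raises(ConfigurationError, match="badcue"):
            match_cues(ann, [CuePattern("badcue", regex="(unclosed")])

    def test_pattern_needs_sequence_or_regex(self):
        with pytest.raises(ConfigurationError):
            CuePattern("empty")

    def test_agreement_with_naive_matcher_on_corpus_sentences(self):
        """match_cues equals a brute-force scan over 1,000 fixture sentences."""
        patterns = [
            CuePattern("rand", lemma_sequence=("randomly", "assign")),
            CuePattern("ss", lemma_sequence=("sample", "size")),
            CuePattern("blind", lemma_sequence=("blind",)),
            CuePattern("adverse", lemma_sequence=("adverse",)),
            CuePattern("ci", regex=r"95%\s*CI"),
        ]
        sentences = []
        for _d, _p, text, _t in cc.build_corpus(40, 7):
            man = cc.segment_sections(cc.parse_plaintext(text))
            for sec in man.sections:
                sentences.extend(s for s in sec.sentences if s.text.strip())
        assert len(sentences) >= 1000
        for s in sentences[:1000]:
            ann = annotate_sentence(s)
            hits = {(h.cue_id, h.start, h.end) for h in match_cues(ann, patterns)}
            naive = set()
            for pat in patterns:
                if pat.lemma_sequence:
                    k = len(pat.lemma_sequence)
                    for i in range(len(ann.lemmas) - k + 1):
                        if ann.lemmas[i:i + k] == pat.lemma_sequence:
                            naive.add((pat.cue_id, ann.tokens[i][1],
                                       ann.tokens[i + k - 1][2]))
                if pat.regex:
                    for m in re.finditer(pat.regex, s.text, re.IGNORECASE):
                        naive.add((pat.cue_id, m.start(), m.end()))
            assert hits == naive
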