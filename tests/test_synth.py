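import math
import os

import pytest

import consort_check as cc
from consort_check.detectors import run_checklist
from consort_check.ingest import parse_plaintext, segment_sections
from consort_check.nlp import ConfigurationError
from consort_check.synth import (
    CONDITIONAL_ITEMS,
    GeneratorConfig,
    generate_corpus,
    realize_manuscript,
    sample_manuscript_plan,
)


class TestPlanSampling:
    def test_seeded_determinism(self):
        assert sample_manuscript_plan(7) == sample_manuscript_plan(7)
        assert sample_manuscript_plan(7) != sample_manuscript_plan(8)

    def test_full_omission(self):
        cfg = GeneratorConfig(include_prob=0.0, conditional_include_prob=0.0)
        plan = sample_manuscript_plan(3, cfg)
        assert not any(plan.include.values())

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_manuscript_plan(1, GeneratorConfig(include_prob=1.5))
        with pytest.raises(ConfigurationError):
            sample_manuscript_plan(1, GeneratorConfig(misplace_prob=-0.1))

    def test_plan_invariants(self):
        for seed in range(50):
            plan = sample_manuscript_plan(seed)
            for iid, mis in plan.misplace.items():
                if mis:
                    assert plan.include[iid]
            for iid, fig in plan.figure_only.items():
                if fig:
                    assert iid in {"13a", "13b", "16"}
            assert not set(plan.include) & {"2a", "22", "17b"}

    def test_inclusion_frequency_binomial(self):
        """Inclusion frequency within 3 standard errors of the configured
        probability over 1,000 plans."""
        n = 1000
        cfg = GeneratorConfig()
        counts = {}
        for seed in range(n):
            plan = sample_manuscript_plan(seed, cfg)
            for iid, inc in plan.include.items():
                counts[iid] = counts.get(iid, 0) + inc
        for iid, count in counts.items():
            p = (cfg.conditional_include_prob if iid in CONDITIONAL_ITEMS
                 else cfg.include_prob)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(count / n - p) <= 3 * se, (iid, count / n, p)


class TestRealization:
    def test_registry_id_present_and_marked(self):
        for seed in range(30):
            plan = sample_manuscript_plan(seed)
            if plan.include.get("23"):
                text, truth = realize_manuscript(plan)
                entry = truth.entry("23")
                assert entry.present
                sec, idx = entry.sentences[0]
                man = segment_sections(parse_plaintext(text))
                sentence = man.sentence_at(sec, idx).text
                assert any(tag in sentence for tag in
                           ("NCT", "ISRCTN", "EudraCT"))
                break
        else:
            pytest.fail("no plan included item 23 in 30 seeds")

    def test_no_ratio_plan_yields_allocation_notification(self):
        for seed in range(60):
            plan = sample_manuscript_plan(seed)
            if plan.no_ratio and plan.include.get("3a") \
                    and not plan.misplace.get("3a"):
                text, _truth = realize_manuscript(plan)
                report = run_checklist(segment_sections(parse_plaintext(text)))
                m = report.matches["3a"]
                assert m.status == "notification"
                assert m.notification_code == "MISSING_ALLOCATION_RATIO"
                return
        pytest.fail("no suitable plan found")

    def test_misplaced_item_truth_records_actual_section(self):
        for seed in range(300):
            plan = sample_manuscript_plan(seed)
            misplaced = [iid for iid, m in plan.misplace.items() if m]
            if misplaced:
                text, truth = realize_manuscript(plan)
                iid = misplaced[0]
                sec, _idx = truth.entry(iid).sentences[0]
                assert sec == plan.placement[iid]
                assert plan.placement[iid] != \
                    next(iter(cc.load_registry()[iid].expected_sections))
                return
        pytest.fail("no plan with a misplaced item in 300 seeds")

    def test_truth_coordinates_valid_after_reparse(self, small_corpus):
        """Round-trip: re-parsing each document recovers every truth
        sentence at its recorded coordinates."""
        for (doc_id, _plan, text, truth), man in zip(
                small_corpus["docs"], small_corpus["manuscripts"]):
            for iid, entry in truth.items.items():
                for sec, idx in entry.sentences:
                    if sec == "TITLE":
                        assert man.title
                    else:
                        assert man.sentence_at(sec, idx) is not None, \
                            (doc_id, iid, sec, idx)

    def test_plan_truth_fidelity(self, small_corpus, registry):
        """truth_present(item) iff plan.include(item) for scored items."""
        for doc_id, plan, _text, truth in small_corpus["docs"]:
            for item in registry.scored_items():
                expected = plan.include.get(item.item_id, False)
                assert truth.entry(item.item_id).present == expected, \
                    (doc_id, item.item_id)

    def test_figure_only_items_confined_to_caption(self):
        for seed in range(200):
            plan = sample_manuscript_plan(seed)
            if plan.figure_only.get("13a"):
                text, truth = realize_manuscript(plan)
                assert not truth.entry("13a").present
                man = segment_sections(parse_plaintext(text))
                report = run_checklist(man)
                assert report.matches["13a"].status == "notification"
                assert report.matches["13a"].notification_code == \
                    "CHECK_FIGURE_OR_TABLE"
                return
        pytest.fail("no figure-only plan in 200 seeds")

    def test_parameterized_fixtures_differ(self):
        t1, _ = realize_manuscript(sample_manuscript_plan(1))
        t2, _ = realize_manuscript(sample_manuscript_plan(2))
        assert t1 != t2


class TestCorpusGeneration:
    def test_default_paper_scale_splits(self, tmp_path):
        manifest = generate_corpus(158, 0, outdir=None)
        sizes = {k: len(v) for k, v in manifest.splits.items()}
        assert sizes == {"training": 111, "testing": 25, "validation": 22}

    def test_single_document_corpus(self, tmp_path):
        outdir = tmp_path / "one"
        manifest = generate_corpus(1, 5, outdir=outdir)
        assert manifest.n_documents == 1
        assert (outdir / "training" / "doc0000.txt").exists()
        assert (outdir / "training_truth.json").exists()

    def test_bad_split_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_corpus(10, 0, split_sizes=(5, 5, 5))

    def test_byte_identical_reproducibility(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_corpus(6, 11, split_sizes=(4, 1, 1), outdir=a)
        generate_corpus(6, 11, split_sizes=(4, 1, 1), outdir=b)
        for root, _dirs, files in os.walk(a):
            for name in files:
                pa = os.path.join(root, name)
                pb = pa.replace(str(a), str(b), 1)
                with open(pa, "rb") as fa, open(pb, "rb") as fb:
                    assert fa.read() == fb.read(), name

    def test_manifest_digests_reproducible(self):
        m1 = generate_corpus(4, 2, split_sizes=(4, 0, 0))
        m2 = generate_corpus(4, 2, split_sizes=(4, 0, 0))
        assert m1.to_json() == m2.to_json()
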