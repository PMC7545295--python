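# consort-check

Rule-based screening of randomized-clinical-trial (RCT) manuscripts against
the CONSORT 2010 reporting checklist.

Inadequate reporting of RCTs hampers interpretation and reproducibility, and
filling in the 37-sub-item CONSORT 2010 checklist by hand takes tens of
minutes per manuscript. `consort-check` automates the screen: it ingests a
ready-to-submit manuscript (text-layer PDF or a small plain-text dialect),
reconstructs the article, segments it into IMRaD sections and sentences, and
applies deterministic natural-language rules per checklist sub-item to decide
whether, and where, each reporting item is described. It is aimed at trial
authors preparing a submission, and at reviewers and editors checking
adherence. It assists, rather than replaces, human review.

## Method

The pipeline runs in four steps:

1. **Text extraction** — per-page text from the PDF (a plain-text adapter
   bypasses this step), hyphenation repaired, columns linearized.
2. **Segmentation** — printed headings are canonicalized against a synonym
   lexicon (`Patients and Methods` → METHODS, `Comment` → DISCUSSION, …),
   figure/table captions are diverted, reference lists are excluded from
   detection, and each section body is split into sentences with exact
   character offsets.
3. **Item detection** — each sentence is tokenized, lemmatized with
   British→American normalization (*randomised* → *randomize*), and tagged
   with pattern/gazetteer entities (trial-registry IDs, allocation ratios,
   confidence intervals, counts, percentages, date ranges, organizations,
   locations). A per-item rule — cue-lemma groups plus, where required, a
   same-sentence entity — marks the matching sentences. Three conditions
   produce *notifications* rather than a plain found/not-found: a
   trial-design sentence without an allocation ratio (item 3a), evidence
   found only outside the checklist's expected section (WRONG_SECTION), and
   participant-flow items whose numbers may sit inside a flow-diagram figure
   (13a/13b/16: CHECK_FIGURE_OR_TABLE). Items 2a, 22, and 17b are registered
   as not implemented (subjective or recommendation-only).
4. **Reporting** — a filled checklist and a notifications summary are
   rendered as markdown or `.docx`, plus a lossless JSON report.

Evaluation follows the standard per-item accuracy definition: an article-item
is assessed correctly when the tool extracts a truly relevant sentence or
reports a null finding for an article that truly lacks the item; per-item
accuracy is correct assessments over articles, banded into <80%, 80–90%, and
>90%. A triage partition (positive / negative / undetected sentences)
supports detector tuning with the criterion
(negative + undetected) / total < 10%.

Because real journal PDFs are copyrighted, the package ships a seeded
synthetic-manuscript generator (`consort_check.synth`) that emulates RCT
reports — per-item evidence sentences from parameterized templates, near-miss
distractors, wrong-section placement, flow numbers confined to a figure
caption — together with exact ground-truth coordinates, so training-,
testing-, and validation-style experiments run with no downloads.

## Worked example

```bash
consort-check synth --n 4 --splits 2,1,1 --seed 3 --outdir corp
consort-check run corp/training/doc0000.txt --json --outdir demo
```

prints

```
corp/training/doc0000.txt: 27 found, 1 notifications, 6 not found
```

meaning 27 checklist sub-items were located in the text, 6 were not found
(this generated manuscript omits them), 3 are not implemented, and one item
carries a notification. `demo/doc0000.notifications.md` shows it:

```
- **Item 16** [CHECK_FIGURE_OR_TABLE]: No sentence in the text reports this
  item; please check whether Figure 1 (Screening, randomization, and
  follow-up of the study participants. 214 and 206 p...) contains the
  information.
```

— the analyzed-denominator counts exist only in the flow-diagram caption, so
the tool asks the author to verify the figure. `demo/doc0000.consort.md`
holds the filled 37-row checklist (each found row cites the section and the
matched sentence), and `demo/doc0000.report.json` is the machine-readable
report.

Scoring a corpus against ground truth:

```bash
consort-check evaluate --corpus corp/training \
    --truth corp/training_truth.json --out acc.tsv
# accuracy bands: >90%: 30, 80-90%: 0, <80%: 0
# triage: positive=57 negative=0 undetected=0 proportion_bad=0.0000
```

## Acceptance benchmarks

`scripts/acceptance.py` regenerates the two headline benchmark quantities
from scratch: it builds the seeded synthetic validation corpus (22 documents)
and training corpus (111 documents), runs the full checker on every document,
scores it against the generated ground truth, and writes the number of scored
items exceeding 90% accuracy and the triage badness percentage:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/consort_check/registry.py` — the 37 CONSORT 2010 sub-items
  (machine-readable TSV resource)
- `src/consort_check/ingest.py` — PDF/plain-text ingestion, section and
  sentence segmentation
- `src/consort_check/nlp.py` — lemmatizer, entity patterns, cue matching
- `src/consort_check/detectors.py` — per-item rules
  (`data/detector_rules.json`) and checklist assembly
- `src/consort_check/reporting.py` — markdown/docx/JSON rendering
- `src/consort_check/evaluation.py` — accuracy, bands, triage
- `src/consort_check/synth.py` — synthetic corpus generator
- `src/consort_check/cli.py` — `consort-check run|evaluate|synth`

See `docs/methods.md` for modeling assumptions, parameter defaults, and known
limitations.
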