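# Methods

This note records the modeling decisions behind `consort-check`: what the
rules assume, what the synthetic benchmark does and does not establish, and
where the design was genuinely open.

## Checklist registry

The CONSORT 2010 statement defines 25 numbered items; with lettered
sub-items the checklist has 37 entries. Three are carried as
`not_implemented` — 2a (background/rationale) and 22 (interpretation) are
judgments rather than extractable statements, and 17b is a recommendation —
leaving 34 detectable items. Four of those are excluded from accuracy
scoring: item 10 (who generated/enrolled/assigned) is detected best-effort
only because its definition is ambiguous at sentence granularity, and the
participant-flow items 13a, 13b, and 16 often live inside a flow-diagram
figure where sentence-level extraction cannot be graded. Thirty items are
scored.

The checklist itself never tabulates an expected section per item, but the
wrong-section notification presupposes one; expected sections follow the
public checklist's own layout (Introduction 2b; Methods 3a–12b; Results
13a–19; Discussion 20–21; Other information 23–25). Title/abstract items
(1a, 1b) are scoped to the title and abstract and never placement-checked.

## Ingestion

The core pipeline operates on a plain-text dialect (optional `TITLE:` line,
headings on their own line, `Figure N.` / `Table N.` caption lines); PDF
support is an adapter in front of it so detector logic never touches binary
parsing. The PDF reader handles text-layer PDFs whose content streams use
`Tj`/`TJ` operators (uncompressed or Flate), which covers the PDFs the
fixture generator writes; encrypted and image-only files fail fast — OCR is
out of scope. Caption lines wrapped across physical lines by PDF layout are
re-folded into the caption until the next blank line.

Sentence boundaries sit at `.?!` followed by whitespace and an
uppercase/digit, suppressed after a protected abbreviation list (checked as
whole tokens — `forms.` must not match `ms.`) and inside bracketed spans.
Offsets are 0-based half-open; reassembling spans plus whitespace gaps
reproduces each section body byte-for-byte, which the property tests assert.
Reference lists are segmented but excluded from detection: citation titles
otherwise trigger keyword cues.

## Linguistic primitives

Annotation is deterministic and rule-based throughout — no model downloads,
identical output on identical input.

* **Lemmatizer**: British→American suffix normalization (`randomise` →
  `randomize`), an irregular-form table for domain-critical words
  (`criteria`→`criterion`, `lost`→`lose`, `enrolled`→`enrol`), then
  suffix stripping with consonant dedup and selective final-`e` restoration.
  It is lemmatization, not stemming: `randomization` is not conflated with
  `randomize`. The generic rules are imperfect on words outside the cue
  vocabulary (e.g. `treated` → `treate`); this is harmless because cue
  lemmas and the lemmatizer are maintained together, and determinism is what
  detection requires.
* **Entities**: regular-expression patterns for registry IDs (NCT, ISRCTN,
  EudraCT including the bare `NNNN-NNNNNN-NN` form, ACTRN, ChiCTR, UMIN),
  allocation ratios, confidence intervals, percentages, counts, date ranges,
  and P values; organizations and locations come from a small packaged
  gazetteer plus a capitalization heuristic for institution-like phrases.
  Per kind, matches are greedy longest and non-overlapping.
* **Cues**: lemma sequences matched contiguously over the lemma stream, or
  regexes over the raw sentence (spaces matching any whitespace so wrapped
  PDF lines still match). All hits are reported; overlap is never
  suppressed.

Word-sense disambiguation is realized purely as context gating (e.g.
`blind` counts for item 11a only alongside a participant/investigator/
assessor lemma, or as `open-label`); relationship extraction is realized as
same-sentence co-occurrence between a cue and an entity (e.g. item 23
requires a registry-ID entity; item 4b requires a location or organization
in the setting sentence).

## Detection rules

No published per-item rule set exists, so the rule table in
`data/detector_rules.json` is this package's own reconstruction and its main
tuning surface; it is shipped as data so per-item tuning needs no code
changes. Conventions:

* Detectors search every in-scope body section except the abstract, so
  evidence placed in the wrong section is still found and then flagged
  WRONG_SECTION by the placement check (which demotes a `found` only when
  *no* matched sentence is in an expected section).
* Seven items prone to cross-item false positives are hard-filtered to
  their expected sections instead (2b, 3a, 3b, 12a, 12b, 18, 20, 21 —
  e.g. unrestricted item 18 (`subgroup`) would fire on item 12b's Methods
  sentence). The cost is that a misplaced instance of these items is
  missed; the benefit is that an omission of one item does not become a
  false positive of its sibling.
* Multiple matching sentences are all kept, ordered by document position.
* Item 15 (baseline table): evidence found only in a table caption is
  reported as CHECK_FIGURE_OR_TABLE rather than `found`, because a found
  match must cite a recoverable body sentence.

## Synthetic corpus

The generator emulates the document properties the detectors assume, with
exact ground truth obtained by re-parsing its own output through the
ingestion pipeline. Defaults (chosen a priori, not tuned to test outcomes):

| parameter | default | rationale |
| --- | --- | --- |
| `include_prob` | 0.9 | high-impact-journal RCT reports carry most core items |
| `conditional_include_prob` | 0.5 | "where applicable" items (3b, 6b, 7b, 11b, 14b, 24, 10) |
| `misplace_prob` | 0.05 | wrong-section placement is a rare, real event |
| `figure_only_prob` | 0.5 | flow numbers commonly live only in the diagram |
| `no_ratio_prob` | 0.25 | design sentences often omit the allocation ratio |
| `distractors_per_section` | 2 | near-miss boilerplate keeps accuracy below the ceiling |

Misplacement is restricted to Methods↔Results swaps — the phenomenon the
placement notification models; Discussion/Other-information items stay put,
as they do in practice. Templates are parameterized (drugs, conditions,
counts, dates, registry IDs from seeded pools) so no two fixtures are
textually identical. Corpus generation is deterministic: per-document seeds
derive from the master seed, and identical seeds yield byte-identical files.

What a green synthetic benchmark establishes: the pipeline is internally
consistent — segmentation, offsets, rules, scoring, and reporting agree end
to end under distractors, omissions, misplacements, and caption-only flow
data. What it does not establish: recall on real journal prose, whose
phrasing diversity far exceeds the template banks. The validation-style
numbers are scaled-down analogues, not reproductions of performance on
published articles.

## Evaluation

Correctness per article-item is exact: a found (or notification) match must
share a (section, sentence-index) coordinate with the truth; fuzzy overlap
would mask offset bugs. A notification with a correctly located sentence
counts as a correct extraction — an incomplete-but-located finding is still
a detection. Accuracy is exact rational arithmetic; the 0.90 band boundary
belongs to the 80–90% band (">90%" is strict). Triage is restricted to the
30 scored items: figure-check items have caption evidence without sentence
coordinates, the same reason they are excluded from accuracy.

## Known limitations

* Rule-based recall is bounded by the cue vocabulary; paraphrases outside
  it are missed (the hardest real-world item is allocation concealment).
* The PDF reader targets the fixture generator's output class plus simple
  well-formed text PDFs; exotic encodings, CID fonts, and multi-stream page
  content are unsupported.
* Section-filtered items are not found when misplaced.
* Table bodies are not parsed; only captions are inspected.
* CONSORT extensions (cluster, non-inferiority, abstracts) are not modeled.
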