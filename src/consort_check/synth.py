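"""Seeded generator of synthetic trial-manuscript fixtures with exact truth.

Each generated document imitates the structure the detectors assume: an IMRaD
body, a title that does or does not identify the study as randomized, one
evidence sentence per included checklist item (drawn from parameterized
template variants so no two fixtures are textually identical), near-miss
distractor sentences in every section, optional misplacement of
Methods/Results evidence into the sibling section, and participant-flow
numbers optionally confined to the flow-diagram caption.

Ground truth is exact by construction: the generator re-parses its own output
through the ingestion pipeline and records each evidence sentence's
(section, sentence-index) coordinates, so downstream scoring uses the same
coordinate system as the checker.

What this corpus does *not* emulate: real clinical narrative, journal
typography, tables with content, or the long tail of phrasing found in
practice — a green synthetic benchmark bounds implementation correctness,
not real-world recall.
"""

from __future__ import annotations

import hashlib
import json
import os
import random
from dataclasses import dataclass, field, asdict

from . import _pdf
from .evaluation import GroundTruth, GroundTruthEntry, dump_ground_truth
from .ingest import Manuscript, parse_plaintext, segment_sections
from .nlp import ConfigurationError
from .registry import (
    FIGURE_CHECK_ITEMS,
    NOT_IMPLEMENTED_ITEMS,
    load_registry,
)

__all__ = [
    "GeneratorConfig",
    "ManuscriptPlan",
    "CorpusManifest",
    "sample_manuscript_plan",
    "realize_manuscript",
    "build_corpus",
    "generate_corpus",
]

SPLIT_NAMES = ("training", "testing", "validation")

#: Items that real manuscripts report only "where applicable"; included less
#: often than the core items.
CONDITIONAL_ITEMS = frozenset({"3b", "6b", "7b", "11b", "14b", "24", "10"})

#: Items eligible for wrong-section placement: the Methods<->Results swap the
#: placement notification is designed around.
_SWAP = {"METHODS": "RESULTS", "RESULTS": "METHODS"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of the synthetic corpus (defaults chosen a priori).

    ``include_prob`` reflects that high-impact-journal RCT reports carry most
    core items; ``conditional_include_prob`` covers "where applicable" items.
    ``misplace_prob`` keeps wrong-section placement a rare but present event,
    ``figure_only_prob`` puts participant-flow numbers solely in the flow
    diagram about half the time (their common real location), and
    ``no_ratio_prob`` reproduces design sentences that omit the allocation
    ratio.  Two near-miss distractors per section keep accuracy from being
    trivially 1.0.
    """

    include_prob: float = 0.9
    conditional_include_prob: float = 0.5
    misplace_prob: float = 0.05
    figure_only_prob: float = 0.5
    no_ratio_prob: float = 0.25
    distractors_per_section: int = 2

    def validate(self) -> None:
        for name in ("include_prob", "conditional_include_prob",
                     "misplace_prob", "figure_only_prob", "no_ratio_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.distractors_per_section < 0:
            raise ConfigurationError("distractors_per_section must be >= 0")


@dataclass(frozen=True)
class ManuscriptPlan:
    """Fully determines one synthetic document."""

    seed: int
    include: dict[str, bool]
    placement: dict[str, str]
    misplace: dict[str, bool]
    variant: dict[str, int]
    figure_only: dict[str, bool]
    no_ratio: bool
    distractor_count: int

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def sample_manuscript_plan(seed: int,
                           config: GeneratorConfig | None = None) -> ManuscriptPlan:
    """Deterministically sample a document plan from a seed."""
    config = config or GeneratorConfig()
    config.validate()
    rng = random.Random(seed)
    registry = load_registry()
    include: dict[str, bool] = {}
    placement: dict[str, str] = {}
    misplace: dict[str, bool] = {}
    variant: dict[str, int] = {}
    figure_only: dict[str, bool] = {}
    for item in registry:
        iid = item.item_id
        if iid in NOT_IMPLEMENTED_ITEMS:
            continue  # never truth-bearing
        p = (config.conditional_include_prob if iid in CONDITIONAL_ITEMS
             else config.include_prob)
        include[iid] = rng.random() < p
        variant[iid] = rng.randrange(3)
        expected = next(iter(item.expected_sections), None) \
            if item.scope == "BODY" else None
        fig_only = (item.figure_check and include[iid]
                    and rng.random() < config.figure_only_prob)
        figure_only[iid] = fig_only
        mis = (include[iid] and not fig_only and expected in _SWAP
               and rng.random() < config.misplace_prob)
        misplace[iid] = mis
        if expected is not None:
            placement[iid] = _SWAP[expected] if mis else expected
    no_ratio = rng.random() < config.no_ratio_prob
    return ManuscriptPlan(
        seed=seed, include=include, placement=placement, misplace=misplace,
        variant=variant, figure_only=figure_only, no_ratio=no_ratio,
        distractor_count=config.distractors_per_section,
    )


# ------------------------------------------------------------- vocabulary

_DRUGS = ("hydroxychloroquine", "tofacitinib", "empagliflozin", "rivaroxaban",
          "sertraline", "atorvastatin", "metformin", "denosumab",
          "liraglutide", "colchicine")
_CONDITIONS = ("hand osteoarthritis", "refractory angina pectoris",
               "type 2 diabetes", "chronic heart failure",
               "major depressive disorder", "rheumatoid arthritis",
               "atrial fibrillation", "postmenopausal osteoporosis")
_OUTCOMES = ("pain score", "6-minute walk distance", "glycated hemoglobin level",
             "symptom score", "disease activity score",
             "treadmill exercise time")
_SEC_OUTCOMES = ("quality of life", "grip strength", "hospitalization rate",
                 "patient-reported fatigue")
_COUNTRIES = ("the United Kingdom", "Canada", "Australia", "the Netherlands",
              "Germany", "Spain", "the United States", "Denmark")
_CITIES = (("London", "the United Kingdom"), ("Toronto", "Canada"),
           ("Boston", "the United States"), ("Amsterdam", "the Netherlands"),
           ("Sydney", "Australia"))
_FUNDERS = ("National Institutes of Health", "Medical Research Council",
            "Wellcome Trust", "British Heart Foundation",
            "National Cancer Institute")
_MONTHS = ("January", "February", "March", "April", "May", "June", "July",
           "August", "September", "October", "November", "December")


def _sample_params(rng: random.Random) -> dict[str, str]:
    drug = rng.choice(_DRUGS)
    comp = rng.choice(("placebo", "placebo", "usual care"))
    cond = rng.choice(_CONDITIONS)
    outcome = rng.choice(_OUTCOMES)
    city, city_country = rng.choice(_CITIES)
    ntotal = rng.randrange(120, 900, 2)
    na = ntotal // 2 + rng.randrange(-5, 6)
    nb = ntotal - na
    year1 = rng.randrange(2008, 2017)
    m1, m2, m3 = rng.choice(_MONTHS), rng.choice(_MONTHS), rng.choice(_MONTHS)
    nwithdrew = rng.randrange(3, 30)
    nlost = rng.randrange(2, 20)
    p = {
        "drug": drug, "Drug_cap": drug.capitalize(),
        "comp": comp, "Comp_cap": comp.capitalize(),
        "cond": cond, "Cond_cap": cond[0].upper() + cond[1:],
        "Cond_title": cond.title(),
        "outcome": outcome, "Outcome_title": outcome.title(),
        "sec_outcome": rng.choice(_SEC_OUTCOMES),
        "country_phrase": rng.choice(_COUNTRIES),
        "country_phrase2": rng.choice(_COUNTRIES),
        "city": city, "country_for_city": city_country,
        "funder": rng.choice(_FUNDERS),
        "grant": f"{rng.choice('RHKU')}{rng.randrange(10, 99)}-"
                 f"{rng.randrange(100000, 999999)}",
        "nct": f"NCT{rng.randrange(0, 10**8):08d}",
        "isrctn": f"ISRCTN{rng.randrange(0, 10**8):08d}",
        "eudract": f"{rng.randrange(2008, 2018)}-"
                   f"{rng.randrange(100000, 999999):06d}-"
                   f"{rng.randrange(10, 99):02d}",
        "ratio": rng.choice(("1:1", "1:1", "2:1")),
        "dose": str(rng.choice((10, 20, 40, 50, 100, 200))),
        "weeks": str(rng.choice((12, 24, 52))),
        "visitk": str(rng.choice((2, 4, 6))),
        "nsites": str(rng.randrange(5, 40)),
        "ntotal": str(ntotal), "na": str(na), "nb": str(nb),
        "nscreened": str(ntotal + rng.randrange(20, 150)),
        "na2": str(na - rng.randrange(0, 8)),
        "nb2": str(nb - rng.randrange(0, 8)),
        "nwithdrew": str(nwithdrew), "nlost": str(nlost),
        "power": str(rng.choice((80, 85, 90))),
        "delta": str(rng.randrange(3, 9)), "dec": str(rng.randrange(0, 9)),
        "cilo": f"{rng.randrange(1, 4)}.{rng.randrange(0, 9)}",
        "cihi": f"{rng.randrange(5, 9)}.{rng.randrange(0, 9)}",
        "hr": f"{rng.randrange(55, 95):02d}",
        "cilo2": f"{rng.randrange(40, 60):02d}",
        "cihi2": f"{rng.randrange(90, 99):02d}",
        "month1": m1, "year1": str(year1),
        "month2": m2, "year2": str(year1 + rng.randrange(1, 4)),
        "month3": m3, "year3": str(year1 + rng.randrange(4, 6)),
        "age": str(rng.randrange(45, 75)),
        "pwomen": str(rng.randrange(30, 70)),
        "nae1": str(rng.randrange(10, 60)), "nae2": str(rng.randrange(10, 60)),
        "pae1": str(rng.randrange(5, 30)), "pae2": str(rng.randrange(5, 30)),
    }
    return p


# ------------------------------------------------------------- templates

_TITLES_RANDOMIZED = (
    "Effect of {Drug_cap} vs {Comp_cap} on the {Outcome_title} in Patients "
    "With {Cond_title}: A Randomized Clinical Trial",
    "{Drug_cap} for {Cond_title}: A Randomised, Controlled Trial",
    "A Randomized Study of {Drug_cap} in Adults With {Cond_title}",
)
_TITLES_PLAIN = (
    "Effect of {Drug_cap} vs {Comp_cap} on the {Outcome_title} in Patients "
    "With {Cond_title}: A Controlled Clinical Study",
    "{Drug_cap} Compared With {Comp_cap} for {Cond_title}",
)

_ABSTRACT_STRUCTURED = (
    "Background: {Cond_cap} causes pain and functional impairment, and "
    "better treatments are needed.",
    "Methods: In this multicenter trial, adults with {cond} received {drug} "
    "or {comp} for {weeks} weeks.",
    "Results: {Drug_cap} improved the {outcome} compared with {comp} at "
    "week {weeks}.",
    "Conclusions: {Drug_cap} was effective and generally well tolerated in "
    "adults with {cond}.",
)
_ABSTRACT_PLAIN = (
    "In this trial of {drug} for {cond}, we compared clinical responses "
    "with {comp} over {weeks} weeks.",
    "{Drug_cap} improved symptoms with an acceptable safety profile.",
)

TEMPLATES: dict[str, tuple[str, ...]] = {
    "2b": (
        "The objective of this trial was to determine whether {drug} is "
        "superior to {comp} in patients with {cond}.",
        "We hypothesized that {drug} would improve the {outcome} in patients "
        "with {cond}.",
        "The aim of this study was to assess the efficacy and safety of "
        "{drug} in {cond}.",
    ),
    "3a": (
        "In this multicenter, parallel-group trial, patients were randomly "
        "assigned in a {ratio} ratio to receive {drug} or {comp}.",
        "We conducted a randomized, parallel-group study in which "
        "participants were assigned to {drug} or {comp} in a {ratio} ratio.",
        "This was a {ratio} randomized, double-blind, crossover trial of "
        "{drug} and {comp}.",
    ),
    "3b": (
        "After trial commencement, the protocol was amended to modify the "
        "dosing schedule, and the reasons were documented.",
        "The methods were changed after the trial began: the follow-up "
        "duration was extended, and this amendment was approved by the "
        "ethics committee.",
    ),
    "4a": (
        "Patients were eligible if they were 18 years of age or older and "
        "had {cond}.",
        "Key inclusion criteria were an age of at least 18 years and a "
        "documented diagnosis of {cond}; exclusion criteria included "
        "pregnancy and prior use of {drug}.",
        "Eligibility required a confirmed diagnosis of {cond} and no "
        "contraindication to {drug}.",
    ),
    "4b": (
        "Participants were recruited at {nsites} hospitals in "
        "{country_phrase}.",
        "The study was conducted at {nsites} academic medical centers in "
        "{country_phrase} and {country_phrase2}.",
        "Patients attended outpatient clinics in {city}, {country_for_city}.",
    ),
    "5": (
        "Patients in the {drug} group received oral {drug} at a dose of "
        "{dose} mg once daily for {weeks} weeks, and those in the {comp} "
        "group received {comp}.",
        "The intervention group received {drug} administered once daily, "
        "whereas the control group received {comp}, with treatment continued "
        "for {weeks} weeks.",
    ),
    "6a": (
        "The primary outcome was the {outcome} at week {weeks}, and "
        "secondary outcomes were {sec_outcome} and safety.",
        "The prespecified primary end point was the {outcome}, assessed at "
        "{weeks} weeks.",
    ),
    "6b": (
        "After the trial commenced, the timing of outcome assessment was "
        "changed from week 12 to week {weeks}, and the reasons were "
        "documented.",
        "One outcome, {sec_outcome}, was modified after the trial had begun "
        "because of slow accrual.",
    ),
    "7a": (
        "We calculated that a sample size of {ntotal} patients would provide "
        "the trial with {power}% power to detect a between-group difference "
        "of {delta} points at a two-sided alpha level of 0.05.",
        "Enrollment of {ntotal} participants gave the study {power}% power "
        "to detect a clinically meaningful effect of {drug}.",
    ),
    "7b": (
        "One interim efficacy analysis was planned, with a stopping "
        "guideline based on O'Brien-Fleming boundaries.",
        "An independent data monitoring committee reviewed the interim "
        "results twice during the trial.",
    ),
    "8a": (
        "The randomization sequence was computer-generated by an independent "
        "statistician who had no role in patient care.",
        "Random numbers were generated with the use of a validated computer "
        "algorithm to create the randomization list.",
    ),
    "8b": (
        "Randomization was stratified according to study center, with the "
        "use of permuted blocks of four.",
        "We used block randomization with a block size of six, stratified "
        "according to sex.",
    ),
    "9": (
        "Treatment allocation was concealed by means of sequentially "
        "numbered, opaque, sealed envelopes.",
        "Allocation concealment was maintained with a central interactive "
        "web response system.",
    ),
    "10": (
        "An independent pharmacist enrolled participants and assigned them "
        "to the interventions.",
        "The trial coordinator assigned participants to the study "
        "interventions at each visit.",
    ),
    "11a": (
        "Patients, investigators, and outcome assessors were blinded to the "
        "group assignments.",
        "Outcome assessors were masked to treatment allocation throughout "
        "the trial.",
        "The trial had an open-label design, and no blinding was attempted.",
    ),
    "11b": (
        "The {drug} and placebo tablets were identical in appearance and "
        "taste.",
        "Matching placebo tablets were used to preserve the similarity of "
        "the interventions.",
    ),
    "12a": (
        "All efficacy analyses were performed on an intention-to-treat basis "
        "with the use of a mixed model for repeated measures.",
        "Survival curves were estimated with the Kaplan-Meier method and "
        "compared with the use of the log-rank test.",
        "Categorical variables were compared with the chi-square test, and "
        "continuous variables with the t test.",
    ),
    "12b": (
        "Prespecified subgroup analyses were performed according to age and "
        "sex, and sensitivity analyses excluded patients with major protocol "
        "deviations.",
        "Adjusted analyses with prespecified covariates were performed for "
        "the main comparison.",
    ),
    "13a": (
        "Of the {nscreened} patients who underwent randomization, {na} were "
        "assigned to {drug} and {nb} to {comp}.",
        "A total of {ntotal} patients were randomly assigned to receive "
        "{drug} ({na} patients) or {comp} ({nb} patients).",
    ),
    "13b": (
        "After randomization, {nwithdrew} patients withdrew consent and "
        "{nlost} were lost to follow-up.",
        "A total of {nwithdrew} patients discontinued the assigned "
        "intervention before week {weeks}.",
    ),
    "14a": (
        "Patients were enrolled between {month1} {year1} and {month2} "
        "{year2}.",
        "Recruitment took place from {month1} {year1} through {month2} "
        "{year2}, and follow-up ended in {month3} {year3}.",
    ),
    "14b": (
        "The trial ended as planned after the final study visit of the last "
        "patient.",
        "The trial was stopped early by the steering committee because of "
        "futility.",
    ),
    "15": (
        "The baseline demographic and clinical characteristics of the "
        "patients are shown in Table 1.",
        "Baseline characteristics were well balanced between the two groups "
        "(Table 1).",
    ),
    "16": (
        "A total of {na2} patients in the {drug} group and {nb2} in the "
        "{comp} group were included in the primary analysis.",
        "In all, {ntotal} patients who received at least one dose of {drug} "
        "or {comp} were included in the analyses.",
    ),
    "17a": (
        "At week {weeks}, the mean between-group difference in the {outcome} "
        "was {delta}.{dec} points (95% CI, {cilo} to {cihi}).",
        "Compared with {comp}, the hazard ratio for the primary event with "
        "{drug} was 0.{hr} (95% CI, 0.{cilo2} to 0.{cihi2}).",
    ),
    "18": (
        "In prespecified subgroup analyses, the effect of {drug} on the "
        "{outcome} was consistent across age and sex categories.",
        "Results of post hoc exploratory analyses were similar to those of "
        "the main analysis.",
    ),
    "19": (
        "Adverse events occurred in {nae1} of {na} patients ({pae1}%) in the "
        "{drug} group and in {nae2} of {nb} ({pae2}%) in the {comp} group.",
        "The incidence of serious adverse events was similar in the two "
        "groups, and no treatment-related deaths occurred.",
    ),
    "20": (
        "This trial has several limitations, including the relatively short "
        "duration of follow-up.",
        "Potential sources of bias include incomplete adherence and the "
        "limited duration of the intervention.",
    ),
    "21": (
        "These findings may not be generalizable to patients with more "
        "severe {cond}.",
        "The results are likely to be applicable to adults with {cond} "
        "managed in routine practice.",
    ),
    "23": (
        "This trial is registered with ClinicalTrials.gov, number {nct}.",
        "The trial was registered in the ISRCTN registry ({isrctn}) before "
        "the first patient was enrolled.",
        "This study is registered with EudraCT, number {eudract}.",
    ),
    "24": (
        "The full trial protocol is available with the full text of this "
        "article.",
        "The trial protocol has been published and is provided in the "
        "supplementary appendix.",
    ),
    "25": (
        "This trial was funded by the {funder} (grant {grant}).",
        "Supported by a grant ({grant}) from the {funder}.",
    ),
}

#: Near-miss distractors: trial-manuscript boilerplate that shares vocabulary
#: with real evidence but carries none of the cue combinations.
DISTRACTORS: dict[str, tuple[str, ...]] = {
    "INTRODUCTION": (
        "{Cond_cap} is a common condition that causes substantial disability "
        "worldwide.",
        "Current treatment options provide only modest symptomatic relief.",
        "Previous observational reports have suggested a possible benefit of "
        "{drug}.",
        "The optimal management of {cond} remains uncertain.",
    ),
    "METHODS": (
        "Patients were given a unique study identification number at the "
        "first visit.",
        "Data were collected with the use of electronic case-report forms.",
        "Participants attended study visits every {visitk} weeks.",
        "Serum samples were stored at -80 degrees Celsius until assayed.",
        "The study was approved by the institutional review board at each "
        "participating center, and all patients provided written informed "
        "consent.",
    ),
    "RESULTS": (
        "The mean age of the patients was {age} years, and {pwomen}% were "
        "women.",
        "Adherence to the assigned regimen was high in both groups.",
        "The median duration of treatment was {weeks} weeks.",
        "Laboratory values remained stable throughout the study period.",
    ),
    "DISCUSSION": (
        "Our findings are consistent with those of earlier reports of "
        "{drug}.",
        "Further research is needed to confirm these observations.",
        "In this trial, {drug} resulted in greater improvement in the "
        "{outcome} than {comp}.",
    ),
    "OTHER_INFO": (
        "We thank the patients and their families, as well as the site "
        "staff, for their contributions.",
        "The authors assume responsibility for the accuracy and completeness "
        "of the data.",
        "No other potential conflict of interest relevant to this article "
        "was reported.",
    ),
}

_SECTION_ITEM_ORDER = {
    "INTRODUCTION": ("2b",),
    "METHODS": ("4a", "4b", "3a", "3b", "5", "6a", "6b", "7a", "7b", "8a",
                "8b", "9", "10", "11a", "11b", "12a", "12b"),
    "RESULTS": ("13a", "13b", "14a", "14b", "15", "16", "17a", "18", "19"),
    "DISCUSSION": ("20", "21"),
    "OTHER_INFO": ("23", "24", "25"),
}
_SECTION_HEADINGS = {
    "INTRODUCTION": "Introduction", "METHODS": "Methods",
    "RESULTS": "Results", "DISCUSSION": "Discussion",
    "OTHER_INFO": "Acknowledgments",
}

# METHODS distractor 5 contains two sentences once split; count them when
# mapping list positions to sentence indices is not needed (we locate by text).


def _item_sentence(item_id: str, plan: ManuscriptPlan,
                   params: dict[str, str]) -> str:
    if item_id == "3a":
        bank = (TEMPLATES["3a"] if not plan.no_ratio else (
            "In this multicenter, parallel-group trial, patients were "
            "randomly assigned to receive {drug} or {comp}.",
            "Patients were randomly assigned to undergo treatment with "
            "{drug} or {comp}.",
        ))
    else:
        bank = TEMPLATES[item_id]
    template = bank[plan.variant.get(item_id, 0) % len(bank)]
    return template.format_map(params)


def _caption_lines(plan: ManuscriptPlan, params: dict[str, str]) -> list[str]:
    base = ("Figure 1. Screening, randomization, and follow-up of the study "
            "participants.")
    extras = []
    if plan.figure_only.get("13a"):
        extras.append("Of the {nscreened} patients assessed for eligibility, "
                      "{ntotal} underwent randomization ({na} assigned to "
                      "{drug} and {nb} to {comp}).".format_map(params))
    if plan.figure_only.get("13b"):
        extras.append("After randomization, {nwithdrew} patients withdrew and "
                      "{nlost} were lost to follow-up.".format_map(params))
    if plan.figure_only.get("16"):
        extras.append("{na2} and {nb2} patients were included in the analysis "
                      "of the primary outcome.".format_map(params))
    lines = [base + (" " + " ".join(extras) if extras else "")]
    if plan.include.get("15"):
        lines.append("Table 1. Baseline Demographic and Clinical "
                     "Characteristics of the Participants.")
    return lines


def realize_manuscript(plan: ManuscriptPlan) -> tuple[str, GroundTruth]:
    """Render one plan to dialect plain text plus exact ground truth."""
    rng = random.Random((plan.seed + 1) * 7919)
    params = _sample_params(rng)

    if plan.include.get("1a", False):
        title = rng.choice(_TITLES_RANDOMIZED).format_map(params)
    else:
        title = rng.choice(_TITLES_PLAIN).format_map(params)

    if plan.include.get("1b", False):
        abstract_lines = [t.format_map(params) for t in _ABSTRACT_STRUCTURED]
    else:
        abstract_lines = [t.format_map(params) for t in _ABSTRACT_PLAIN]

    # evidence sentences per section, canonical order, misplacements applied
    section_sentences: dict[str, list[str]] = {
        label: [] for label in _SECTION_ITEM_ORDER
    }
    item_sentence_text: dict[str, tuple[str, str]] = {}  # item -> (section, text)
    for label, order in _SECTION_ITEM_ORDER.items():
        for iid in order:
            if not plan.include.get(iid, False) or plan.figure_only.get(iid):
                continue
            target = plan.placement.get(iid, label)
            text = _item_sentence(iid, plan, params)
            item_sentence_text[iid] = (target, text)
    for iid, (target, text) in item_sentence_text.items():
        section_sentences[target].append(text)

    # interleave near-miss distractors at random positions
    for label, bank in DISTRACTORS.items():
        k = min(plan.distractor_count, len(bank))
        for text in rng.sample(bank, k):
            pos = rng.randrange(len(section_sentences[label]) + 1)
            section_sentences[label].insert(pos, text.format_map(params))

    lines = [title, "", "Abstract"]
    lines.extend(abstract_lines)
    for label in ("INTRODUCTION", "METHODS", "RESULTS"):
        lines += ["", _SECTION_HEADINGS[label],
                  " ".join(section_sentences[label])]
    lines.append("")
    lines.extend(_caption_lines(plan, params))
    for label in ("DISCUSSION", "OTHER_INFO"):
        lines += ["", _SECTION_HEADINGS[label],
                  " ".join(section_sentences[label])]
    text = "\n".join(lines) + "\n"

    truth = _ground_truth(plan, text, title, item_sentence_text)
    return text, truth


def _ground_truth(plan: ManuscriptPlan, text: str, title: str,
                  item_sentence_text: dict[str, tuple[str, str]]) -> GroundTruth:
    """Re-parse the rendered document and record exact truth coordinates."""
    manuscript = segment_sections(parse_plaintext(text))
    items: dict[str, GroundTruthEntry] = {}

    def locate(section_label: str, sentence_text: str) -> tuple[str, int]:
        sec = manuscript.section(section_label)
        if sec is None:
            raise AssertionError(f"section {section_label} missing after "
                                 "re-parse")
        for sent in sec.sentences:
            if sent.text == sentence_text:
                return (section_label, sent.index)
        raise AssertionError(
            f"generated sentence not recovered in {section_label}: "
            f"{sentence_text!r}"
        )

    items["1a"] = (GroundTruthEntry(True, (("TITLE", 0),))
                   if plan.include.get("1a") else GroundTruthEntry(False))
    if plan.include.get("1b"):
        abstract = manuscript.section("ABSTRACT")
        coords = tuple(("ABSTRACT", s.index) for s in abstract.sentences)
        items["1b"] = GroundTruthEntry(True, coords)
    else:
        items["1b"] = GroundTruthEntry(False)

    for iid, (target, sentence_text) in item_sentence_text.items():
        items[iid] = GroundTruthEntry(True, (locate(target, sentence_text),))
    registry = load_registry()
    for item in registry:
        if item.status == "not_implemented":
            continue
        items.setdefault(item.item_id, GroundTruthEntry(False))
    return GroundTruth(article_id="", items=items)


# ---------------------------------------------------------------- corpora

@dataclass
class CorpusManifest:
    n_documents: int
    master_seed: int
    splits: dict[str, list[dict]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"n_documents": self.n_documents, "master_seed": self.master_seed,
             "splits": self.splits},
            indent=1, sort_keys=True,
        )


def build_corpus(n: int, master_seed: int,
                 config: GeneratorConfig | None = None
                 ) -> list[tuple[str, ManuscriptPlan, str, GroundTruth]]:
    """Generate ``n`` documents in memory, deterministically from the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(master_seed)
    docs = []
    for i in range(n):
        seed = rng.randrange(2**31)
        plan = sample_manuscript_plan(seed, config)
        text, truth = realize_manuscript(plan)
        doc_id = f"doc{i:04d}"
        truth.article_id = doc_id
        docs.append((doc_id, plan, text, truth))
    return docs


def generate_corpus(n: int, master_seed: int,
                    split_sizes: tuple[int, int, int] | None = None,
                    outdir=None,
                    config: GeneratorConfig | None = None,
                    pdf: bool = False) -> CorpusManifest:
    """Generate a corpus, optionally writing documents/truth/manifest to disk.

    Defaults mirror a 158-article corpus split 111/25/22 into training,
    testing, and validation; any other ``n`` defaults to a single training
    split.  Identical seeds yield byte-identical corpora.
    """
    if split_sizes is None:
        split_sizes = (111, 25, 22) if n == 158 else (n, 0, 0)
    if sum(split_sizes) != n:
        raise ValueError(f"split sizes {split_sizes} do not sum to n={n}")
    docs = build_corpus(n, master_seed, config)
    manifest = CorpusManifest(n_documents=n, master_seed=master_seed)
    idx = 0
    for split, size in zip(SPLIT_NAMES, split_sizes):
        split_docs = docs[idx:idx + size]
        idx += size
        manifest.splits[split] = [
            {"doc_id": doc_id, "seed": plan.seed, "digest": plan.digest()}
            for doc_id, plan, _text, _truth in split_docs
        ]
        if outdir is not None and split_docs:
            split_dir = os.path.join(outdir, split)
            os.makedirs(split_dir, exist_ok=True)
            truths = []
            for doc_id, _plan, text, truth in split_docs:
                with open(os.path.join(split_dir, f"{doc_id}.txt"), "w",
                          encoding="utf-8") as fh:
                    fh.write(text)
                if pdf:
                    pages = _pdf.wrap_text_pages(text)
                    _pdf.write_pdf(os.path.join(split_dir, f"{doc_id}.pdf"),
                                   pages)
                truths.append(truth)
            with open(os.path.join(outdir, f"{split}_truth.json"), "w",
                      encoding="utf-8") as fh:
                fh.write(dump_ground_truth(truths))
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "manifest.json"), "w",
                  encoding="utf-8") as fh:
            fh.write(manifest.to_json())
    return manifest


def split_documents(docs, split_sizes: tuple[int, int, int]):
    """Slice an in-memory corpus into (training, testing, validation)."""
    out = []
    idx = 0
    for size in split_sizes:
        out.append(docs[idx:idx + size])
        idx += size
    return tuple(out)
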