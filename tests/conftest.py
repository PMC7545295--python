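import pytest

import consort_check as cc
from consort_check.ingest import parse_plaintext, segment_sections


@pytest.fixture(scope="session")
def registry():
    return cc.load_registry()


SAMPLE_MANUSCRIPT = """\
Hydroxychloroquine for Hand Osteoarthritis: A Randomised, Controlled Trial

Abstract
Background: Hand osteoarthritis is common. Methods: We compared drug and placebo. Results: The drug improved symptoms. Conclusions: The drug was effective.

Introduction
The objective of this trial was to determine whether hydroxychloroquine is superior to placebo.

Patients and Methods
Patients were eligible if they were 18 years of age or older. In this multicenter, parallel-group trial, patients were randomly assigned in a 1:1 ratio to receive hydroxychloroquine or placebo. The sample size of 248 patients provided 90% power to detect a difference of 5 points.

Results
Of the 260 patients who underwent randomization, 124 were assigned to hydroxychloroquine and 124 to placebo. Adverse events occurred in 20 of 124 patients (16%) in the drug group.

Figure 1. Screening, randomization, and follow-up of the study participants.

Discussion
This trial has several limitations, including the short follow-up.

Acknowledgments
This trial is registered with ClinicalTrials.gov, number NCT01148849. This trial was funded by the Wellcome Trust (grant R01-123456).
"""


@pytest.fixture
def sample_manuscript():
    return segment_sections(parse_plaintext(SAMPLE_MANUSCRIPT))


def make_manuscript(text: str):
    return segment_sections(parse_plaintext(text))


#: A comparing-two-therapies fixture: design sentence without an allocation
#: ratio, participant-flow numbers confined to the flow-diagram caption, and
#: every other expected item present, so exactly three notifications result.
SPIRIT_LIKE = """\
Percutaneous Myocardial Revascularization Compared With Spinal Cord Stimulation for Refractory Angina: A Randomized Trial

Abstract
Background: Refractory angina is disabling. Methods: We compared PMR and SCS. Results: Exercise time was similar. Conclusions: Both options improved symptoms.

Introduction
The objective of this trial was to compare the effect of PMR and SCS on treadmill exercise time.

Methods
Patients were eligible if they had refractory angina pectoris. Patients were randomly assigned to undergo treatment with PMR or SCS. The primary outcome was the treadmill exercise time at week 52. Treatment allocation was concealed by means of sequentially numbered, opaque, sealed envelopes. Outcome assessors were masked to treatment allocation throughout the trial. All efficacy analyses were performed on an intention-to-treat basis with a mixed model. We calculated that a sample size of 100 patients would provide 80% power to detect a difference of 30 seconds.

Results
Patients were enrolled between March 1999 and June 2001. The baseline demographic and clinical characteristics of the patients are shown in Table 1. In all, 96 patients who received at least one dose were included in the analyses. At week 52, the mean between-group difference in the treadmill exercise time was 10 points (95% CI, 2 to 18). Adverse events occurred in 5 of 48 patients (10%) in the PMR group.

Figure 1. Trial profile: screening, randomization, and follow-up of the study participants. Of the 104 patients assessed for eligibility, 100 underwent randomization (50 assigned to PMR and 50 to SCS). After randomization, 2 patients withdrew and 2 were lost to follow-up.

Discussion
This trial has several limitations, including the unblinded design of the procedures. These findings may not be generalizable to patients with milder angina.

Acknowledgments
This trial is registered with ClinicalTrials.gov, number NCT00001234. This trial was funded by the British Heart Foundation (grant PG-97).
"""


@pytest.fixture
def spirit_like_manuscript():
    return make_manuscript(SPIRIT_LIKE)


@pytest.fixture(scope="session")
def small_corpus():
    """12 generated documents with reports and truths (seed 42)."""
    docs = cc.build_corpus(12, 42)
    reports, truths, manuscripts = [], [], []
    for doc_id, _plan, text, truth in docs:
        man = make_manuscript(text)
        manuscripts.append(man)
        reports.append(cc.run_checklist(man, source=doc_id))
        truths.append(truth)
    return {"docs": docs, "manuscripts": manuscripts,
            "reports": reports, "truths": truths}
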