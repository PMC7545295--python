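# CONSORT 2010 checklist registry, v1.
# Columns: item_id	scope	expected_sections	status	in_accuracy	figure_check	prompt
# expected_sections is a comma-separated subset of INTRODUCTION,METHODS,RESULTS,DISCUSSION,OTHER_INFO ("-" = none).
1a	TITLE	-	detectable	1	0	Identification as a randomised trial in the title
1b	ABSTRACT	-	detectable	1	0	Structured summary of trial design, methods, results, and conclusions
2a	BODY	INTRODUCTION	not_implemented	0	0	Scientific background and explanation of rationale
2b	BODY	INTRODUCTION	detectable	1	0	Specific objectives or hypotheses
3a	BODY	METHODS	detectable	1	0	Description of trial design (such as parallel, factorial) including allocation ratio
3b	BODY	METHODS	detectable	1	0	Important changes to methods after trial commencement (such as eligibility criteria), with reasons
4a	BODY	METHODS	detectable	1	0	Eligibility criteria for participants
4b	BODY	METHODS	detectable	1	0	Settings and locations where the data were collected
5	BODY	METHODS	detectable	1	0	The interventions for each group with sufficient details to allow replication, including how and when they were actually administered
6a	BODY	METHODS	detectable	1	0	Completely defined pre-specified primary and secondary outcome measures, including how and when they were assessed
6b	BODY	METHODS	detectable	1	0	Any changes to trial outcomes after the trial commenced, with reasons
7a	BODY	METHODS	detectable	1	0	How sample size was determined
7b	BODY	METHODS	detectable	1	0	When applicable, explanation of any interim analyses and stopping guidelines
8a	BODY	METHODS	detectable	1	0	Method used to generate the random allocation sequence
8b	BODY	METHODS	detectable	1	0	Type of randomisation; details of any restriction (such as blocking and block size)
9	BODY	METHODS	detectable	1	0	Mechanism used to implement the random allocation sequence (such as sequentially numbered containers), describing any steps taken to conceal the sequence until interventions were assigned
10	BODY	METHODS	detectable	0	0	Who generated the random allocation sequence, who enrolled participants, and who assigned participants to interventions
11a	BODY	METHODS	detectable	1	0	If done, who was blinded after assignment to interventions (for example, participants, care providers, those assessing outcomes) and how
11b	BODY	METHODS	detectable	1	0	If relevant, description of the similarity of interventions
12a	BODY	METHODS	detectable	1	0	Statistical methods used to compare groups for primary and secondary outcomes
12b	BODY	METHODS	detectable	1	0	Methods for additional analyses, such as subgroup analyses and adjusted analyses
13a	BODY	RESULTS	detectable	0	1	For each group, the numbers of participants who were randomly assigned, received intended treatment, and were analysed for the primary outcome
13b	BODY	RESULTS	detectable	0	1	For each group, losses and exclusions after randomisation, together with reasons
14a	BODY	RESULTS	detectable	1	0	Dates defining the periods of recruitment and follow-up
14b	BODY	RESULTS	detectable	1	0	Why the trial ended or was stopped
15	BODY	RESULTS	detectable	1	0	A table showing baseline demographic and clinical characteristics for each group
16	BODY	RESULTS	detectable	0	1	For each group, number of participants (denominator) included in each analysis and whether the analysis was by original assigned groups
17a	BODY	RESULTS	detectable	1	0	For each primary and secondary outcome, results for each group, and the estimated effect size and its precision (such as 95% confidence interval)
17b	BODY	RESULTS	not_implemented	0	0	For binary outcomes, presentation of both absolute and relative effect sizes is recommended
18	BODY	RESULTS	detectable	1	0	Results of any other analyses performed, including subgroup analyses and adjusted analyses, distinguishing pre-specified from exploratory
19	BODY	RESULTS	detectable	1	0	All important harms or unintended effects in each group
20	BODY	DISCUSSION	detectable	1	0	Trial limitations, addressing sources of potential bias, imprecision, and, if relevant, multiplicity of analyses
21	BODY	DISCUSSION	detectable	1	0	Generalisability (external validity, applicability) of the trial findings
22	BODY	DISCUSSION	not_implemented	0	0	Interpretation consistent with results, balancing benefits and harms, and considering other relevant evidence
23	BODY	OTHER_INFO	detectable	1	0	Registration number and name of trial registry
24	BODY	OTHER_INFO	detectable	1	0	Where the full trial protocol can be accessed, if available
25	BODY	OTHER_INFO	detectable	1	0	Sources of funding and other support (such as supply of drugs), role of funders
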