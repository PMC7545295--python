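# Entity gazetteer, v1. Format: KIND<TAB>Name (one per line, # = comment).
# ORG: funders, sponsors, agencies commonly named in trial reports.
ORG	World Health Organization
ORG	National Institutes of Health
ORG	National Cancer Institute
ORG	National Heart, Lung, and Blood Institute
ORG	Medical Research Council
ORG	Wellcome Trust
ORG	British Heart Foundation
ORG	American Heart Association
ORG	European Commission
ORG	Bill & Melinda Gates Foundation
ORG	Patient-Centered Outcomes Research Institute
ORG	Canadian Institutes of Health Research
ORG	National Institute for Health Research
ORG	Deutsche Forschungsgemeinschaft
ORG	Pfizer
ORG	Novartis
ORG	AstraZeneca
ORG	Merck
ORG	Sanofi
ORG	GlaxoSmithKline
ORG	Boehringer Ingelheim
ORG	Eli Lilly
ORG	Bayer
ORG	Amgen
ORG	Food and Drug Administration
ORG	European Medicines Agency
ORG	American Society of Clinical Oncology
LOCATION	New York
LOCATION	London
LOCATION	Boston
LOCATION	Chicago
LOCATION	Toronto
LOCATION	Sydney
LOCATION	Amsterdam
LOCATION	Berlin
LOCATION	Madrid
LOCATION	Paris
LOCATION	Copenhagen
LOCATION	Stockholm
LOCATION	Hong Kong
LOCATION	Singapore
LOCATION	United States
LOCATION	United Kingdom
LOCATION	Canada
LOCATION	Australia
LOCATION	Germany
LOCATION	France
LOCATION	Italy
LOCATION	Spain
LOCATION	Netherlands
LOCATION	Belgium
LOCATION	Switzerland
LOCATION	Sweden
LOCATION	Denmark
LOCATION	Norway
LOCATION	Finland
LOCATION	Austria
LOCATION	Ireland
LOCATION	Portugal
LOCATION	Poland
LOCATION	China
LOCATION	Japan
LOCATION	South Korea
LOCATION	India
LOCATION	Brazil
LOCATION	Mexico
LOCATION	Argentina
LOCATION	South Africa
LOCATION	New Zealand
LOCATION	Israel
LOCATION	California
LOCATION	Texas
LOCATION	Massachusetts
LOCATION	Minnesota
LOCATION	Ohio
LOCATION	Pennsylvania
LOCATION	North Carolina
LOCATION	Connecticut
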