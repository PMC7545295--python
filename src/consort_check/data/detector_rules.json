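{
  "version": 1,
  "comment": "Per-item detection rules. Groups are lists of alternatives; an alternative is a lemma sequence (list) or a regex ('re:...'). A clause matches a sentence when every group has at least one hit and, if 'entities' is given, at least one entity of a listed kind is present. 'sections' is a hard section filter; items without it search every in-scope body section except the abstract.",
  "items": {
    "1a": {
      "title_regex": "\\brandomi[sz]ed\\b.*\\b(?:trial|study)\\b"
    },
    "1b": {
      "abstract_labels": ["background", "objective", "objectives", "design",
                          "setting", "participants", "interventions", "methods",
                          "results", "conclusion", "conclusions"],
      "min_labels": 2
    },
    "2b": {
      "sections": ["INTRODUCTION", "ABSTRACT"],
      "clauses": [
        {"all": [[["objective"], ["aim"], ["hypothesis"], ["hypothesize"],
                  ["we", "assess"], ["to", "determine"]]]}
      ]
    },
    "3a": {
      "sections": ["METHODS"],
      "ratio_required": true,
      "clauses": [
        {"all": [[["parallel"], ["parallel-group"], ["crossover"],
                  ["cross-over"], ["factorial"]],
                 [["trial"], ["study"], ["design"]]]},
        {"all": [[["randomly", "assign"]]]}
      ]
    },
    "3b": {
      "sections": ["METHODS"],
      "clauses": [
        {"all": [[["amend"], ["amendment"],
                  "re:changes? to the (?:protocol|methods)",
                  ["protocol", "change"]]]}
      ]
    },
    "4a": {
      "clauses": [
        {"all": [[["eligible"], ["eligibility"], ["inclusion"], ["exclusion"]]]}
      ]
    },
    "4b": {
      "entities_note": "settings need a place or institution in the same sentence",
      "clauses": [
        {"all": [[["recruit"], ["hospital"], ["clinic"], ["site"],
                  ["center"], ["setting"]]],
         "entities": ["LOCATION", "ORG"]}
      ]
    },
    "5": {
      "clauses": [
        {"all": [[["receive"], ["administer"], ["dose"], ["mg"]],
                 [["group"], ["arm"]]]}
      ]
    },
    "6a": {
      "clauses": [
        {"all": [[["primary"], ["secondary"]],
                 [["outcome"], ["endpoint"], ["end", "point"]]]}
      ]
    },
    "6b": {
      "clauses": [
        {"all": [[["outcome"]], [["change"], ["modify"]]]}
      ]
    },
    "7a": {
      "clauses": [
        {"all": [[["sample", "size"], ["power"]]],
         "entities": ["PERCENTAGE", "COUNT"]}
      ]
    },
    "7b": {
      "clauses": [
        {"all": [[["interim"], ["stop", "rule"], ["stop", "guideline"],
                  ["data", "monitoring"]]]}
      ]
    },
    "8a": {
      "clauses": [
        {"all": [["re:computer-?generated", ["random", "number"],
                  ["randomization", "list"], ["randomization", "schedule"]]]}
      ]
    },
    "8b": {
      "clauses": [
        {"all": [[["block"], ["stratify"], ["permute"], ["minimization"]],
                 [["randomization"], ["randomize"], ["random"], ["randomly"]]]}
      ]
    },
    "9": {
      "clauses": [
        {"all": [[["conceal"], ["concealment"], ["sealed", "envelope"],
                  ["opaque"], ["central", "randomization"],
                  ["interactive", "voice"], ["interactive", "web"]]]}
      ]
    },
    "10": {
      "clauses": [
        {"all": [[["pharmacist"], ["coordinator"], ["statistician"]],
                 [["enrol"], ["assign"], ["dispense"], ["generate"]]]}
      ]
    },
    "11a": {
      "clauses": [
        {"all": [[["blind"], ["mask"]],
                 [["participant"], ["patient"], ["investigator"], ["assessor"],
                  ["clinician"], ["caregiver"], ["personnel"],
                  ["care", "provider"]]]},
        {"all": [[["open-label"]]]}
      ]
    },
    "11b": {
      "clauses": [
        {"all": [[["identical"], ["match"]],
                 [["placebo"], ["appearance"], ["taste"]]]}
      ]
    },
    "12a": {
      "sections": ["METHODS"],
      "clauses": [
        {"all": [[["intention-to-treat"], ["regression"], ["log-rank"],
                  ["chi-square"], ["t", "test"], ["kaplan-meier"],
                  ["mixed", "model"], ["proportional-hazards"], ["cox"],
                  ["analysis", "of", "covariance"], ["wilcoxon"], ["fisher"]]]}
      ]
    },
    "12b": {
      "sections": ["METHODS"],
      "clauses": [
        {"all": [[["subgroup"], ["sensitivity"], ["adjust"]],
                 [["analysis"]]]}
      ]
    },
    "13a": {
      "caption_kind": "figure",
      "caption_regex": "flow|profile|consort|random|enrol|screening",
      "clauses": [
        {"all": [[["randomly", "assign"], ["undergo", "randomization"]]],
         "entities": ["COUNT"]}
      ]
    },
    "13b": {
      "caption_kind": "figure",
      "caption_regex": "flow|profile|consort|random|enrol|screening",
      "clauses": [
        {"all": [[["withdraw"], ["withdrawal"], ["lose", "to", "follow-up"],
                  ["discontinue"]]],
         "entities": ["COUNT"]}
      ]
    },
    "14a": {
      "clauses": [
        {"all": [[["enrol"], ["recruit"], ["recruitment"], ["enrolment"],
                  ["enrollment"]]],
         "entities": ["DATE_RANGE"]}
      ]
    },
    "14b": {
      "clauses": [
        {"all": [[["stop", "early"], ["terminate", "early"],
                  ["complete", "follow-up"], ["final", "visit"],
                  "re:trial (?:was )?(?:stopped|ended|terminated)"]]}
      ]
    },
    "15": {
      "caption_kind": "table",
      "caption_regex": "baseline|characteristic",
      "clauses": [
        {"all": [[["baseline"]], [["characteristic"], ["demographic"]]]}
      ]
    },
    "16": {
      "caption_kind": "figure",
      "caption_regex": "flow|profile|consort|random|enrol|screening",
      "clauses": [
        {"all": [[["include", "in"], ["analyze"]]],
         "entities": ["COUNT"]}
      ]
    },
    "17a": {
      "clauses": [
        {"all": [[["difference"], ["ratio"], ["hazard"], ["odds"],
                  ["mean", "change"]]],
         "entities": ["CONFIDENCE_INTERVAL"]}
      ]
    },
    "18": {
      "sections": ["RESULTS"],
      "clauses": [
        {"all": [[["subgroup"], ["exploratory"], ["post", "hoc"],
                  ["ancillary"]]]}
      ]
    },
    "19": {
      "clauses": [
        {"all": [[["adverse"], ["harm"], ["toxicity"], ["side", "effect"]]]}
      ]
    },
    "20": {
      "sections": ["DISCUSSION"],
      "clauses": [
        {"all": [[["limitation"], ["bias"], ["imprecision"], ["caveat"]]]}
      ]
    },
    "21": {
      "sections": ["DISCUSSION"],
      "clauses": [
        {"all": [[["generalizable"], ["generalizability"], ["applicability"],
                  ["applicable"], ["external", "validity"]]]}
      ]
    },
    "23": {
      "clauses": [
        {"all": [], "entities": ["REGISTRY_ID"]}
      ]
    },
    "24": {
      "clauses": [
        {"all": [[["protocol"]],
                 [["available"], ["publish"], ["appendix"], ["supplement"],
                  ["supplementary"], ["access"]]]}
      ]
    },
    "25": {
      "clauses": [
        {"all": [[["fund"], ["funding"], ["grant"]]]}
      ]
    }
  }
}
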