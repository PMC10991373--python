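{
  "keywords": {
    "iv_drug_names": [
      "iv/intravenous/inject(s/ed/ing) heroin/meth/methamphetamine/cocaine/crack",
      "speedball"
    ],
    "visible_signs": [
      "track marks",
      "needle track(s)"
    ],
    "risky_needle": [
      "sharing/shared/dirty needle(s)"
    ],
    "skin_popping": [
      "skin popping"
    ],
    "harm_reduction": [
      "community/clean/safe syringe service/program(s)",
      "ssp",
      "ris4e",
      "counseled on safe(r) injection",
      "safe injection technique(s)"
    ],
    "generic_idu": [
      "ivdu",
      "idu",
      "ivda",
      "iv/intravenous/injection drug use/abuse",
      "inject/injected drug(s)",
      "drug(s) by injection",
      "iv/intravenous drug injector/injection",
      "illicit iv/intravenous drug(s)",
      "iv/intravenous drug paraphernalia",
      "suspect injecting",
      "injecting",
      "pwid"
    ]
  },
  "questions": {
    "drug_names": {
      "base": "Which iv drugs has the patient used?",
      "variants": [
        "Which iv drugs has the patient used?",
        "To what IV drugs has the patient been exposed?",
        "Which IV drugs have the pt used?",
        "Which intravenous drugs has the patient used?",
        "Which illicit drugs has the patient injected?"
      ]
    },
    "visible_signs": {
      "base": "Does the patient have any needle track marks?",
      "variants": [
        "Does the patient have any needle track marks?",
        "Does the pt have any needle track marks?",
        "Are there visible signs of injection drug use?"
      ]
    },
    "risky_needle": {
      "base": "Has the patient ever shared needles?",
      "variants": [
        "Has the patient ever shared needles?",
        "Has the pt ever shared needles?",
        "Does the patient engage in risky needle use?"
      ]
    },
    "active_historical": {
      "base": "Is the patient actively using iv drugs?",
      "variants": [
        "Is the patient actively using iv drugs?",
        "Is the pt actively using intravenous drugs?",
        "Does the patient have a history of using intravenous drugs?"
      ]
    },
    "frequency": {
      "base": "How frequently has the patient used iv drug?",
      "variants": [
        "How frequently has the patient used iv drug?",
        "How often does the pt use iv drugs?"
      ]
    },
    "last_use": {
      "base": "When did the patient last use iv drugs?",
      "variants": [
        "When did the patient last use iv drugs?",
        "When did the pt last use iv drugs?"
      ]
    },
    "skin_popping": {
      "base": "Does the patient have any history of skin popping?",
      "variants": [
        "Does the patient have any history of skin popping?",
        "Does the pt have a hx of skin popping?"
      ]
    },
    "harm_reduction": {
      "base": "Has the patient been counseled on safe injection techniques?",
      "variants": [
        "Has the patient been counseled on safe injection techniques?",
        "Has the pt been counseled on safer injection?"
      ]
    },
    "existence": {
      "base": "Does the patient have any history of IDU?",
      "variants": [
        "Does the patient have any history of IDU?",
        "Does the pt have a history of IDU?",
        "Does the pt have a history of IVDU?",
        "Has the pt ever injected drugs?",
        "Has the pt ever used IV drugs?"
      ]
    }
  },
  "triggers": {
    "drug_names": ["heroin", "meth", "methamphetamine", "cocaine", "crack", "speedball", "bnz", "benzodiazepines", "opioids"],
    "visible_signs": ["track marks", "needle track marks", "skin popping"],
    "risky_needle": ["shared", "sharing", "dirty needle", "dirty needles"],
    "active_historical": ["active", "actively", "hx", "h/o", "history", "historical", "recent", "current", "currently", "relapse"],
    "frequency": ["daily", "weekly", "occasionally", "frequently", "frequency", "often"],
    "last_use": ["last"],
    "skin_popping": ["skin popping"],
    "harm_reduction": ["clean needles", "counseled", "syringe", "ssp", "ris4e", "safe injection", "safer injection", "harm reduction"],
    "existence": ["idu", "ivdu", "ivda", "pwid"]
  },
  "substitutions": {
    "abbreviation": [["patient", "pt"], ["intravenous", "iv"], ["history", "hx"]],
    "synonym": [["IDU", "IVDU"], ["injection", "intravenous"]]
  },
  "syntax_templates": [
    ["^Which (.+) has the patient used\\?$", "To which \\1 has the patient been exposed?"],
    ["^Does the (patient|pt) have a history of (.+)\\?$", "Has the \\1 ever used \\2?"]
  ],
  "rules": {
    "priority": ["negation", "temporal", "track_marks_status", "oud_specific", "fallback"],
    "negation": {
      "cues": ["denies", "denied", "no history of", "no h/o", "never", "negative for", "no", "without"]
    },
    "temporal": {
      "cues": ["last", "ago", "since", "recent", "recently", "prior", "quit"]
    },
    "track_marks_status": {
      "cues": ["track marks", "needle track", "needle tracks"]
    },
    "oud_specific": {
      "cues": ["oud", "opioid use disorder"]
    },
    "label_strip_distance": 40
  }
}
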