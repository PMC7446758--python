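{
  "name": "drug abuse",
  "kind": "theme",
  "terms": ["drug abuse", "substance abuse"],
  "children": [
    {
      "name": "opioid drug",
      "kind": "class",
      "terms": ["opioid", "opioids", "opiate", "opiates"],
      "children": [
        {
          "name": "prescription opioids",
          "kind": "subclass",
          "terms": ["oxycodone", "oxycontin", "hydrocodone", "vicodin", "percocet", "codeine", "morphine", "tramadol"]
        },
        {
          "name": "illicit opioids",
          "kind": "subclass",
          "terms": ["heroin", "fentanyl", "carfentanil", "china white"]
        },
        {
          "name": "slang terms",
          "kind": "subclass",
          "terms": ["oxy", "percs", "hillbilly heroin", "smack", "dope", "on the nod", "lean", "roxy"]
        }
      ]
    },
    {
      "name": "symptoms",
      "kind": "class",
      "terms": ["overdose", "withdrawal", "addiction", "addicted", "craving", "dependence", "relapse", "tolerance"]
    },
    {
      "name": "recovery",
      "kind": "class",
      "terms": ["rehab", "detox", "naloxone", "narcan", "methadone", "suboxone", "buprenorphine", "sober", "clean time", "recovery"]
    },
    {
      "name": "related behaviors",
      "kind": "class",
      "terms": ["doctor shopping", "pill mill", "street dealer", "prescription refill", "snorting", "injecting"]
    }
  ]
}
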