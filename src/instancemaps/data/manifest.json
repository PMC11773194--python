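{
  "files": [
    {
      "name": "daphnia_culture_log.csv",
      "description": "Data capture template for monitoring the health and performance of running Daphnia magna cultures: per-jar adult counts, offspring flags per brood, daily algal food ration (mL) and medium-change days over a 16-day window. Attached as the raw-data resource of the daphnia_culture fixture map; the package stores it opaquely and never parses it analytically.",
      "media_type": "text/csv"
    }
  ]
}
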