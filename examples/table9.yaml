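# Scenario mirroring the study cohort's marginal smoking structure:
# per-stratum cases/controls (non 321/752, former 742/656, current 431/315,
# unknown smoking 101/37) with a planted two-way conjunction in non-smokers.
strata:
  non: [321, 752]
  former: [742, 656]
  current: [431, 315]
  unknown: [101, 37]
allele_freq:
  rs1014971: 0.63
  rs11892031: 0.08
  rs1495741: 0.22
  rs710521: 0.74
  rs8102137: 0.33
  rs9642880: 0.46
deletion_null_freq: 0.5
baseline_logit: -1.0
planted:
  - combination: "rs9642880:12,rs1014971:2"
    stratum: non
    odds_ratio: 2.0
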