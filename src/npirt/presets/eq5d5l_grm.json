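{
 "comment": "GRM constants for the synthetic EQ-5D-5L preset. Step locations are root-found by Gauss-Hermite quadrature so marginal step-endorsement rates match the committed cumulative targets (from the published survey table); AD mixes in a second latent factor (primary-factor correlation 0.55) to depress its scalability with the physical items.",
 "items": [
  "MO",
  "SC",
  "UA",
  "PD",
  "AD"
 ],
 "discriminations": [
  3.3,
  3.3,
  3.3,
  3.3,
  3.3
 ],
 "second_loadings": [
  0.0,
  0.0,
  0.0,
  0.0,
  0.835165
 ],
 "cumulative_targets": {
  "MO": [
   0.34917433505609474,
   0.1339972267742342,
   0.036808269255010684,
   0.006050674398083933
  ],
  "SC": [
   0.11962687507878478,
   0.04096810790369343,
   0.008445733013992207,
   0.0010084457330139518
  ],
  "UA": [
   0.34917433505609474,
   0.1339972267742342,
   0.036808269255010684,
   0.006050674398083933
  ],
  "PD": [
   0.706164124543048,
   0.3010210513046767,
   0.09996218328501194,
   0.013866128828942448
  ],
  "AD": [
   0.49804613639228534,
   0.20572292953485438,
   0.0685743098449515,
   0.02029497037690664
  ]
 },
 "thresholds": {
  "MO": [
   0.439311,
   1.258472,
   2.041557,
   2.886032
  ],
  "SC": [
   1.337503,
   1.984337,
   2.743523,
   3.585661
  ],
  "UA": [
   0.439311,
   1.258472,
   2.041557,
   2.886032
  ],
  "PD": [
   -0.614812,
   0.59126,
   1.457556,
   2.521946
  ],
  "AD": [
   0.00555,
   0.932062,
   1.692488,
   2.342393
  ]
 }
}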