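strain,n_tetrads,viability_pct,comparison
wild-type,153,98.4,
dmc1-E157D,215,57.6,wild-type
rad51,40,<0.6,
rad51-II3A,19,82.9,wild-type
rdh54,40,91.9,wild-type
dmc1-E157D mei5,267,50.3,dmc1-E157D
dmc1-E157D rad51,34,0.7,
dmc1-E157D rad51-II3A,22,17.0,dmc1-E157D
dmc1-E157D sae3,39,57.0,dmc1-E157D
DMC1+/dmc1-E157D,47,91.2,wild-type
DMC1+/dmc1-E157D mei5,69,58.8,dmc1-E157D mei5
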