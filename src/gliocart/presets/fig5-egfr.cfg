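# EGFRvIII single dose, delay model
name = fig5-egfr
model = delay
schedule = egfr:5e8
horizon = 800
endpoints = ttp, peak_time:C, first_below:C:1000
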