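# HER2/CMV, seven doses of 1.89e8 every 5 weeks
name = fig10-high
model = delay
schedule = her2:1.89e8:6:35
horizon = 1500
endpoints = ttp
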