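# HER2/CMV, seven doses of 1e8 every 10 weeks
name = fig11-mid
model = delay
schedule = her2:1e8:6:70
horizon = 2500
endpoints = ttp
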