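# HER2/CMV, highest dose every 12 weeks, delay model
name = fig4-her2-high
model = delay
schedule = her2:1.89e8:6:84
horizon = 1500
endpoints = ttp, value_at:T:540
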