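# HER2/CMV, lowest dose every 6 weeks, delay model
name = fig3-her2-low
model = delay
schedule = her2:1.89e6:6:42
horizon = 540
endpoints = value_at:T:540, ttp
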