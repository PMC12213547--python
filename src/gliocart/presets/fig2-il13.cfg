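# IL13Ralpha2 intracranial protocol, resistance model
name = fig2-il13
model = resistance
schedule = il13
horizon = 540
endpoints = max_value:R, value_at:T:540, ttp
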