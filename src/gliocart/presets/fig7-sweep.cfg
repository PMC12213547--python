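# HER2/CMV dose x count x interval sweep: tumor burden at day 540
kind = sweep
family = her2
endpoint = value_at:T:540
doses = 1.89e6,1.89e7,1.89e8
n_additional = 1,2,3,4,5,6
intervals = 42,49,56,63,70,77,84
horizon = 540
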