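# HER2/CMV highest dose: TTP vs count and interval
kind = sweep
family = her2
endpoint = ttp
doses = 1.89e8
n_additional = 1,2,3,4,5,6
intervals = 42,49,56,63,70,77,84
horizon = 1500
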