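# HER2/CMV seven-dose interval sweep (1-15 weeks): TTP
kind = sweep
family = her2
endpoint = ttp
doses = 7.23e7,1e8,1.89e8
n_additional = 6
intervals = 7,14,21,28,35,42,49,56,63,70,77,84,91,98,105
horizon = 2500
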