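# IL13Ralpha2 equal-split sweep: tumor burden at day 540
kind = sweep
family = il13
endpoint = value_at:T:540
n_doses = 1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19
intervals = 4,5,6,7,8,9,10
horizon = 540
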