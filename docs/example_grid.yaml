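designs: [PT(1:1:1:1:k), PT(1:1:1:1:1)]
n_drugs: 4
scenarios: [2, 3, 4, 5]
rp: [0.075, 0.10, 0.125, 0.15]
accrual_mean: [100, 200, 300, 400]
n_reps: 1000
alpha: 0.05
seed: 17
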