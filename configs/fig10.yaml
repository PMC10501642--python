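# universality of the mutation-selection balance among loop-free graphs
experiment: fig10
seed: 1
replicates: 200
N: 10
n_steps: 5000
out_dir: results/fig10
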