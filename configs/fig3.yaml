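# high-mutation reference: self-looped complete graph at mu = 1
experiment: fig3
seed: 1
replicates: 200
N_list: [10, 20]
n_steps: 5000
out_dir: results/fig3
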