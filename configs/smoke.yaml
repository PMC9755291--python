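# one-replicate smoke run; completes in seconds
name: smoke
design: clustered_null
m: 20
p: 10
rho_c: 0.5
n_replicates: 1
n_perms: 100
seed: 1
tests: cluster_hsic:permutation
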