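# i.i.d. Gaussian null, N=50, p=q=50: size of the classical HSIC test
name: table1_row1
design: iid_normal
N: 50
p: 50
n_replicates: 1000
n_perms: 1000
seed: 101
tests: hsic:pearson3, hsic:permutation
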