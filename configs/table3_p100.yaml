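# clustered null, m=100 clusters of 3, p=q=100, rho_W=0.5, rho_c=0.5:
# the cluster-aware test holds its size while the pooled HSIC inflates
name: table3_p100
design: clustered_null
m: 100
p: 100
rho_W: 0.5
rho_c: 0.5
n_replicates: 1000
seed: 103
tests: cluster_hsic:pearson3, hsic:pearson3
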