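# power at m=100, p=q=100, rho_c=0.7 with 80% of outcomes exposed
name: power_eta08
design: clustered_alternative
m: 100
p: 100
rho_W: 0.5
rho_c: 0.7
eta: 0.8
n_replicates: 500
seed: 105
tests: cluster_hsic:pearson3, cluster_mean_hsic:pearson3
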