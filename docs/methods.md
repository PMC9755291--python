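# Methods

## Problem and model

`clusterhsic` tests the independence of two multivariate variables,
H0: f_XY = f_X f_Y, from N paired observations (X_i, Y_i), X in R^p and
Y in R^q, when the samples are partitioned into m mutually independent
clusters (subjects with repeated visits, families, litters) that share an
arbitrary, identical within-cluster dependence structure. The motivating
setting is longitudinal multi-omics screening — e.g. microbiome
composition against groups of metabolites measured at several clinical
visits per participant — where both high dimension and within-subject
correlation defeat classical correlation measures and the i.i.d.
assumptions of standard kernel tests.

The test statistic family is built on the Hilbert–Schmidt independence
criterion (HSIC). Given kernel matrices K_X and K_Y and the centering
matrix H_n = I − 11ᵗ/n, the empirical HSIC is

    HSIC = trace(H_N K_X H_N · H_N K_Y H_N) / N².

With a characteristic kernel (e.g. Gaussian) the population HSIC vanishes
iff X and Y are independent. Under clustering the N samples are not
exchangeable, so permuting them does not emulate the null and the pooled
HSIC test grossly over-rejects (the package's simulations measure
inflation up to 1.000 at nominal level 0.05). The cluster-aware statistic
replaces the N×N kernels with m×m cluster-wise kernels K^cl obtained by
averaging each between-cluster (and within-cluster) block of kernel
values, and drops the size normalization:

    cluster-HSIC = trace(H_m K_X^cl H_m · H_m K_Y^cl H_m).

Collapse is the congruence K^cl = Mᵗ K M with the column-stochastic
averaging matrix M, so K^cl inherits symmetry and positive
semi-definiteness exactly; diagonal blocks average all l_a² entries
including the kernel diagonal, which is what makes M's columns sum to
one and the PSD argument exact. Exchangeable units are now the m clusters,
and permuting cluster indices is a valid null. The absent 1/m² factor is
deliberate: all inference is permutation-based and therefore invariant to
the statistic's scale, and with all-singleton clusters the statistic
reduces to N²·HSIC with an identical permutation p-value.

## Inference

Conditioning on the observed kernels, the null distribution is that of

    T(π) = Σ_ij A_ij B_π(i)π(j),     A = H K_X^(cl) H,  B = H K_Y^(cl) H,

over uniform permutations π of the exchangeable units (one side only;
permuting the other side gives the same distribution).

* **Monte Carlo permutation** (default up to 100 units): p = (1 +
  #{T_π ≥ T_obs}) / (1 + n_perms) with n_perms = 1000 by default. The +1
  correction guarantees validity and p > 0; at 1000 permutations it
  differs from the raw proportion by less than Monte Carlo resolution.

* **Pearson type III approximation** (default above 100 units, and the
  route that makes screens at very small α feasible): the permutation
  null is approximated by a shifted (and, for negative skewness,
  reflected) gamma distribution matched to the exact first three
  permutation moments, with shape a = 4/γ², scale s = σγ/2 and shift
  λ = μ − 2σ/γ. For |γ| < 1e−8 the normal upper tail is used.

The moments μ, σ², γ are computed exactly, not estimated. The r-th raw
moment of T expands over r index pairs; because a uniform permutation
maps any d distinct indices to a uniform ordered d-subset, E[T^r] is a
sum over set partitions σ of the 2r index slots of
N_A(σ)·N_B(σ)/(k)_d, where N(σ) is the sum of entry products over index
assignments with equality pattern exactly σ and (k)_d is a falling
factorial. Each unconstrained pattern sum is a small tensor contraction
(one `einsum`); exact-pattern sums follow by subtracting coarser
partitions, coarsest first. For doubly centered inputs every pattern with
a singleton block contracts a row sum of A and vanishes, leaving 41
surviving contractions for the third moment; the implementation
re-centers its inputs so this shortcut is exact to machine precision.
This derivation is valid for every k ≥ 2 and is gated in the test suite
against brute-force enumeration of all k! permutations for k ∈ {4,…,7}
(agreement to 10 significant digits over 100 random matrix pairs) before
anything else relies on it. The public API still requires k ≥ 4: below
that a three-moment fit is meaningless. At k = 7 the fitted tail tracks
the exact permutation tail to within ≈0.04–0.08 absolute; the
approximation sharpens rapidly with k, and at m = 100 it agrees with
Monte Carlo permutation p-values within Monte Carlo error replicate by
replicate (checked in the acceptance suite).

## Kernels and the bandwidth convention

The default kernel is Gaussian with the median heuristic: bandwidth h =
median of all N(N−1)/2 pairwise Euclidean distances (self-pairs excluded,
midpoint convention for even counts), and

    k(x, x') = exp(−‖x − x'‖² / h²).

The exponent convention — no factor 2 in the denominator, equivalently
exp(−d²/median(d²)) since the median commutes with squaring — is pinned
by the module constant `GAUSSIAN_EXPONENT_SCALE` and was chosen because
it is the convention under which the simulation study reproduces the
reference rejection rates of the cluster-correlated benchmark (the
alternative exp(−d²/2h²) convention leaves size valid but roughly halves
the pooled-HSIC inflation and shifts power, i.e. it changes which
alternatives the test is sensitive to, not its validity). No feature
scaling is applied before the median heuristic.

For compositional data a Bray–Curtis kernel is provided: the squared
dissimilarities d(i,j) = Σ|x_i−x_j|/Σ(x_i+x_j) are Gower double-centered,
K = −½ H D² H, and projected to the PSD cone by clamping negative
eigenvalues (Bray–Curtis is not Euclidean-embeddable, so small negative
eigenvalues are expected; the projection is idempotent and a no-op on PSD
input, with relative tolerance 1e−8). Missing values are rejected rather
than imputed throughout.

The cluster-mean baseline (`cluster_mean_hsic`) averages each cluster's
observations feature-wise, rebuilds kernels on the m averaged rows
(median heuristic recomputed on the collapsed data) and applies the
classical HSIC; it is implemented as the comparison target that the
cluster-wise statistic consistently outperforms, since feature averaging
discards within-cluster variation that block-averaged kernels retain.

## Synthetic data

The simulation module generates the three study designs used by the test
suite and the acceptance script; its defaults are the study conditions,
not tuning knobs.

* i.i.d. nulls: X and Y drawn independently, N_p(0, Σ) with AR(1)
  Σ_ij = 0.4^|i−j| (log-normal variant: elementwise exp). Probes the size
  of the classical HSIC and its Pearson III approximation at
  N ∈ {50, 100, 200}, p = q ∈ {50, 100, 200}.
* Clustered null: m independent clusters of l = 3 repeated observations;
  each cluster of X is one 3p-vector draw N_3p(5·1, Σ_W ⊗ Σ_c) with
  exchangeable Σ_W (correlation ρ_W across the p features) and AR(1) Σ_c
  (correlation ρ_c across the 3 time points), laid out feature-major so
  Σ_c acts on the innermost time axis (verified by a lag-correlation
  moment check in the tests). Y is an independent draw with mean 0 and
  the same covariance. Sampling uses the matrix-normal identity
  L_W Z L_cᵗ with one Cholesky pair per configuration, shared across
  replicates.
* Clustered alternative: X as above; one exposure feature r (uniform at
  random, redrawn per replicate) drives the first round(η·p) outcomes,
  Y_s,t = β_s X_r,t + ε_s,t with β_s ~ Uniform(0, √(25/m)) and ε an
  independent null draw. With η = 0 this reduces bitwise to the null
  generator under the same seed.

What the generators emulate: high-dimensional, moderately correlated
continuous features with separable (feature × time) within-cluster
covariance and a sparse linear exposure effect. What they do not: heavy
tails beyond log-normality, zero inflation and compositionality of real
count data, unequal cluster sizes, missingness, or genuinely nonlinear
alternatives. Passing sizes and power orderings here therefore certify
the permutation machinery and the approximation quality, not robustness
to every feature of real omics data (the test itself is valid for any
PSD kernels, so validity — unlike power — does not depend on these
features).

## Numerical and design choices

* Unequal cluster sizes are supported by the block-mean definition; the
  equal-size (l = 3) path is the one validated by simulation.
* Cluster order follows first appearance in the assignment; results are
  invariant to relabeling and to reordering within clusters (tested).
* All kernel constructors symmetrize, K ← (K+Kᵗ)/2; PSD checks use a
  relative eigenvalue tolerance of 1e−8.
* Degenerate permutation distributions (σ² = 0, e.g. a constant kernel)
  are flagged on the moments object; the Pearson III routine refuses
  them rather than returning an arbitrary p-value.
* Ties in the permutation test count as "as extreme" (T_π ≥ T_obs).
* Monte Carlo experiments spawn one child random stream per replicate
  from the configuration seed, so rejection tables are bitwise
  reproducible for any worker count; the permutation seed of each test is
  drawn from the replicate stream even when a moment-based method is used,
  keeping the streams aligned across method choices.
* Problem sizes in the shipped experiment suite: size studies use 1000
  Monte Carlo replicates (binomial SE ≈ 0.007 at the 0.05 level), the
  power comparison 500 matched replicates; these match the scale at which
  the reference rejection rates were reported and keep the full study in
  the minutes range on a single CPU.
* Multiple testing in the screening command is Bonferroni only, matching
  standard practice for pre-specified pathway lists.

## Limitations

* Clusters are treated as exchangeable bags of repeated measurements;
  the temporal ordering within a cluster is not modeled.
* The Pearson III fit matches three moments; in extreme tails at very
  small unit counts (m ≲ 10) the exact permutation test should be
  preferred (and is the default there).
* Kernel choice is fixed per run; no kernel learning or combination is
  attempted, although any user-supplied PSD kernel matrix can be tested
  through the lower-level API.
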