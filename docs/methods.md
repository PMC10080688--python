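# Methods

This note documents the models implemented in `phquench`, their
assumptions, the defaults that matter, and what the synthetic-data
generators do and do not emulate.

## Coupled titration model

Titratable sites are described by an Ising-like pairwise model in pH
units. With s_i = 1 for a protonated site and d_i = 1 − s_i,

    βE(s) / ln 10 = Σ_i d_i (pKa_int,i − pH) + Σ_{i<j} w_ij d_i d_j

An isolated site follows the Henderson–Hasselbalch curve with midpoint
pKa_int; a positive coupling w_ij (dimensionless in the exponent,
interpretable as pH units of shift) penalizes *joint* deprotonation of a
pair — the minimal, exactly solvable mechanism producing both
nonmonotonic single-site titration curves and positive/negative
correlation between sites. The sign convention is s = 1 = protonated
throughout (matching the P microstate label).

`simulate_coupled_titration` runs Metropolis Monte Carlo with
single-site flips, one attempted flip per recorded frame, mirroring the
periodic single-exchange attempts of discrete constant-pH MD. The
initial state is drawn from the independent-site probabilities.
`exact_titration` Boltzmann-averages over all 2^N microstates (N ≤ 20)
and is the oracle for every downstream recovery test.

*Known generator artifact.* At pH = pKa_int an isolated site's flip
costs nothing, so Metropolis accepts every attempt and the chain
alternates deterministically (lag-1 autocorrelation −1). The generator
therefore *under*-disperses near the midpoint relative to real CpHMD,
where solvent relaxation intervenes. Tests that need positively
autocorrelated occupancy (the blocked-bootstrap validity check) use a
sticky two-state Markov chain instead.

Coupling magnitudes are free fixture parameters (no experimental
estimate is available); the demo triad uses w = 3.0 with intrinsic pKas
4.5 / 4.2 / 6.3, chosen so that the first site's exact curve is clearly
nonmonotonic (it dips to ≈0.71 near pH 5 and rebounds to ≈0.93 by pH 8
as its partners sequentially take over the deprotonated role) — the
qualitative phenomenology of a proton-sharing acidic triad.

## Hill fits and blocked bootstrap

The Hill equation is fitted for the *protonated* fraction,
f(pH) = 1/(1 + 10^{n(pH−pKa)}), decreasing in pH for n > 0. (Whether
one fits the protonated or deprotonated fraction is a pure sign
convention on n; the decreasing-protonation form is adopted and
documented here.) Fitting is bounded nonlinear least squares with
n ∈ (0, 10], pKa ∈ [0, 14], initial guess pKa at the half-maximum
crossing and n = 1.

A curve is declared nonmonotonic — and the fit non-converged, instead of
reporting a meaningless pKa — when any increase between consecutive pH
points exceeds twice its pooled point error. Point errors are taken
from the blocked bootstrap itself (one bootstrap SE per point) so the
test respects autocorrelation; flat curves (spread < 0.05) are likewise
non-converged.

Errors on pKa and n are 2× the standard deviation over bootstrap
replicates; each replicate resamples whole non-overlapping blocks with
replacement within every pH trajectory (replicas resampled separately,
then averaged) and refits. Default block length corresponds to the
10-ns windowing granularity used throughout (30 frames in the demo's
frame economy); 500–1000 replicates are typical. On i.i.d. data the
errors are insensitive to block length and scale as 1/√n; on correlated
data short blocks underestimate them — both behaviours are tested.

Sensor classification: a converged fit with pKa more than 1.0 unit
above the residue class's water reference (Glu 4.3, Asp 3.9) is a
`sensor_candidate`; converged with smaller shift, `non_sensor`;
non-converged, `coupled_undetermined`.

## Microstate Markov model

The triad's per-frame P/D labels form a chain over 2³ = 8 states.
Transition counts use every frame pair (t, t+τ) (sliding window,
symmetrization off by default); rows are normalized to a stochastic
matrix; states never visited are retained with a self-transition of 1
and population 0 so that networks at different pH share a state space.
Populations are empirical visit frequencies — the natural quantity for
finite simulations — with the stationary left eigenvector available
separately for comparison. The default lag equals one windowing unit
(10 ns equivalent); no spectral or metastability analysis is attempted.
Replicas are merged (labels concatenated) before counting by default.

Pairwise coupling is diagnosed from the Pearson correlation of
windowed (10-ns-equivalent, non-overlapping) protonation fractions:
r > 0.3 positive (sites protonate together), r < −0.3 negative (sites
share a proton), otherwise undetermined; zero-variance series are
undetermined with r undefined.

## tICA and clustering

Covariances are estimated symmetrically over lagged pairs:
C(0) = (X_l'X_l + X_r'X_r)/2m, C(τ) = (X_l'X_r + X_r'X_l)/2m, making
C(τ) symmetric by construction and bounding eigenvalues by 1. The
generalized problem C(τ)v = λC(0)v is solved with a relative ridge of
10⁻⁶·tr(C0)/d on C(0) (sin/cos dihedral features are near-collinear);
eigenvectors are C(0)-orthonormal, so training projections have unit
variance per component. Eigenvalues are invariant under invertible
linear reparameterization of the features (tested to 10⁻⁶ with the
ridge sent to 0), and the implementation is cross-checked against an
independent dense eigensolver route to 10⁻⁸. Defaults: lag = one
windowing unit, 2 components kept.

Clustering uses HDBSCAN (scikit-learn implementation) on the projected
coordinates with `min_cluster_size` defaulting to 0.5 % of the frames;
noise points get label −1, and each cluster carries the microstate
composition of its member frames. Tests compare partitions, not label
identities. A 200-ns-equivalent burn-in is excluded from landscape
fixtures by convention.

## Free-energy reweighting

Boosted sampling is reweighted per bin by the second-order cumulant
expansion of the exponential average,

    F(bin) = −kT [ ln p_b(bin) + β⟨ΔV⟩_bin + β²σ²_ΔV,bin/2 ] + C,

with C fixing min F = 0 over reliable bins (≥ 10 frames by default;
under-occupied bins are reported as NaN). The expansion is exact when
ΔV is Gaussian within each bin — precisely the regime the synthetic
generator produces: `simulate_biased_samples` draws collective-variable
values from the *boosted* density ∝ exp(−β(F + ΔV)) (the boost is added
to the surface, flattening wells, as in Gaussian accelerated MD) and
records per-frame boosts with optional Gaussian per-bin fluctuation,
carrying the matching −β²σ²/2 normalization so the generative model and
the estimator are mutually consistent. Binning default: 50×50 uniform
bins over the occupied range (40 bins in 1-D fixtures). Surfaces are
computed in the joint projection space, not per-microstate subspaces.

## Stratified sampling and representatives

Per cluster, n frames (default 30) are allocated to microstate strata
by largest-remainder rounding of composition × n (ties broken by
remainder, then alphabetically) and drawn uniformly without replacement
within each stratum; a stratum smaller than its allocation falls back
to with-replacement with a warning. The representative structure of a
cluster is the frame nearest (Euclidean, in projection space) to the
cluster mean, ties to the lowest index.

## Quenching-site geometry

The chlorin frame has its origin on the Mg ion; z is the least-squares
plane normal of the four ring nitrogens (oriented deterministically
from the nitrogen input order), x is the in-plane projection of a
designated N→N direction (default first→third in input order —
configurable, and the sign of the stromal-displacement coordinate is
convention-dependent on this choice), y = z × x. Displacements are
mass-weighted centroids expressed in that frame; all geometric
observables are rigid-motion invariant to 10⁻⁸ Å.

The coverage ellipse is the mean-centered covariance ellipse scaled by
the χ²(2) quantile at the requested coverage (default 40 %); for
Gaussian data the empirical containment converges to the nominal
coverage. BLA is mean single-bond minus mean double-bond length along
the conjugated chain, with the bond pattern supplied explicitly.

## TrEsp couplings

V_raw = K_e Σ_{i∈A,j∈B} q_i q_j / r_ij with
K_e = 116140 cm⁻¹·Å·e⁻² (e²/4πε₀ = 14.3996 eV·Å × 8065.54 cm⁻¹/eV), a
full double sum with no cutoff and a hard error below 0.5 Å interatomic
separation. The interaction is computed in vacuum; environment
screening is absorbed in the empirical rescale factor (default 3.7).
The literature does not fix whether that factor multiplies or divides;
division (attenuation) is the default and the convention is an explicit
argument recorded in output metadata. In the far field V converges to
the transition-dipole interaction computed from the same charges
(< 1 % at ten molecular extents — tested).

## Marcus energetics and lifetime model

Linear response gives λ_X = σ²_X/(2k_BT) and G_X = ⟨E_X⟩ − λ_X per
electronic state; ΔG = G_CT − G_LE. The effective reorganization energy
of the LE→CT process is λ_eff = σ²(ΔE_CT,LE)/(2k_BT) over paired
samples — adopted by direct analogy with the per-state formula, since
the published form of this quantity is not machine-readable; the choice
is flagged here. Variances are sample variances (ddof = 1). Constants:
k_B = 0.6950348 cm⁻¹·K⁻¹, T = 300 K default.

The charge-separation rate is the standard high-temperature
nonadiabatic Marcus expression

    k_cs = (2π/ħ) V² (4πλk_BT)^{−1/2} exp(−(ΔG+λ)²/4λk_BT),

with ħ = 5.3088×10⁻¹² cm⁻¹·s so that cm⁻¹ inputs give s⁻¹. The reverse
rate follows detailed balance, k_back = k_cs·exp(ΔG/k_BT).

The complex lifetime uses a coarse-grained scheme: one excited manifold
(the quenching chlorophyll in fast equilibrium with the pool of the
other chlorophylls, weight p_quencher = 1/8 by default for an
eight-chlorophyll pool; Boltzmann weights over user-supplied site
energies are an option) feeding a CT state at p·k_cs, returning at
k_back, recombining at k_rec = (10 ps)⁻¹, with intrinsic decay
k_intr = (4 ns)⁻¹ (a typical chlorophyll-a fluorescence rate,
configurable). τ_complex is the time integral of total survival from a
fully excited manifold, in closed form from the 2×2 rate matrix:

    τ = (k_back + k_rec + p k_cs) /
        [ (k_intr + p k_cs)(k_back + k_rec) − k_back p k_cs ]

This agrees with numerical integration of the master equation to 10⁻⁶
relative (tested), reduces to 1/k_intr when k_cs = 0 and to
1/(k_intr + p k_cs) in the irreversible (fast-recombination) limit.
Both the reversible (default) and irreversible schemes are exposed; no
quantum-corrected (Marcus–Levich–Jortner) rates and no explicit
eight-site exciton dynamics are implemented.

The published cluster-level observables for the two main conformational
clusters (mean LE/CT vertical energies with 95 % CIs from 30 samples,
and LE–CT couplings) ship as `energetics.TABLE_REFERENCE` and serve as
inputs where real QM/MM ensembles would otherwise be required.

## Demo / fixture conditions and problem sizes

The demo emulates the study design at reduced scale, as the package's
own choice of fixture size: 6 pH values (3–8), 2 replicas × 600 frames
per pH (standing in for 600-ns replicas at a coarse reporting rate);
500 bootstrap replicates; a landscape of 3 microstate groups × 1500
frames in a 5-feature space (2 slow AR(1) features with group-specific
means, 3 fast noise features) under a Gaussian boost; 200 coupling
frames per cluster; 30 energy samples per cluster drawn at the
published means with SDs implied by the published CIs. The demo λ/ΔG
sets (2500/1560 and 3000/1040 cm⁻¹) are plausible literature-scale
parameterizations in which the CT reorganization energy dominates the
spread; the data-derived "effective" set is computed from the synthetic
energy series at run time. Because the demo's LE and CT series are
sampled independently, the effective gap variance (hence λ_eff and the
effective ΔG) is large and the effective-set rates are conservatively
small — correlated LE/CT fluctuations of a shared environment are one
of the features of real data the generator does **not** emulate.

Other emulation limits worth keeping in mind: the titration generator
has no explicit solvent, force field, or conformation–protonation
coupling; the landscape fixture's slow modes are linear and Gaussian by
construction (a favourable case for tICA); the geometry fixtures are
rigid toys with isotropic jitter. Passing tests therefore demonstrate
correctness of the estimators under their stated assumptions, not the
validity of those assumptions for any particular protein system.

## Numerical choices

Ridge 10⁻⁶·tr(C0)/d on C(0); PMF reliability threshold 10 frames per
bin; Hill bounds n ∈ (0, 10], pKa ∈ [0, 14]; flat-curve threshold 0.05;
correlation threshold 0.3; chlorin-plane degeneracy rejected below a
10⁻⁸ singular-value ratio; bootstrap SDs below 10⁻¹² reported as
exactly 0; all stage seeds derive from one master seed via
`SeedSequence((master, stage_index))` reduced mod 2³¹; reruns of a
given config are byte-identical.
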