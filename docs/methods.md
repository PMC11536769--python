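# Methods

## Model and assumptions

The package implements a linear (first-order) reaction network for a
single gene copy: G sequential promoter states with one reversible
off-switch (U1 ⇌ U0 at rates k_off, k_on), per-step initiation rates
k_1..k_G, a deterministic elongation/termination delay T, S nuclear
mRNA stages (processing rate δ for stages 1..S−1, export rate δ1), R
cytoplasmic stages (rate λ each, the last exit being degradation),
translation from the first cytoplasmic stage (λ1) and first-order
protein decay (λ2, which also stands in for dilution by division). All
rates are 1/min, delays in min. Excluded by design: multiple gene
copies, replication/division extrinsic noise, feedback regulation,
time-dependent rates and spatial effects.

Because every propensity is linear in the copy numbers, (i) the
deterministic rate equations are exactly the moment equations of the
master equation, and (ii) the linear noise approximation is exact for
first and second moments. The "full LNA" Lyapunov solve is therefore an
exact oracle, not an approximation; only the *slow-scale* (reduced)
closed forms carry a timescale-separation error.

### Elongation delay

The delay step M0_N ⟹(T) M1_N shifts the arrival process in time but
leaves every steady-state distribution of the downstream species
unchanged. The ergodic simulator therefore collapses it
(U_G → U1 + M1_N) by default; an explicit delay queue (binary heap of
scheduled completions interleaved with the exponential clocks) is kept
in the Python engine and verified against the collapsed dynamics by a
two-sample test. The default T_elong is 0: no analysed steady-state
quantity depends on it.

### Timescales

Species timescales are inverse real parts of Jacobian eigenvalues,
grouped by block. The network is block lower-triangular (gene → nuclear
→ cytoplasmic → protein), so the block spectra are exact: the gene block
contributes the eigenvalues of the isolated promoter sub-Jacobian, the
nuclear chain {δ × (S−1), δ1}, the cytoplasmic chain {λ × R}, the
protein row {λ2}. The separation parameter is
Λ_{i,j} = max(τ_i)/min(τ_j); the slow-scale forms for block j are
accurate when Λ_{i,j} ≪ 1 for all upstream blocks i.

## Queueing engine

Transcription initiations form a renewal process; the interarrival
density has the rational Laplace transform

φ(s) = k1 (s + k_on) / (s² + s(k1 + k_on + k_off) + k1 k_on) · Π_{i≥2} k_i/(s + k_i),

built as coprime polynomials (for k_off = 0 the activation factor is
cancelled analytically before any root finding). The first-passage
master equation — with the production step *absorbing* — serves as the
time-domain oracle for φ. The renewal function R(x) = x/α − Σ A_r(1 −
e^{−s_r x}) comes from partial fractions of φ/(s(1−φ)): numpy
companion-matrix roots polished by three Newton steps, residues by the
exact-derivative formula A_r = p(−s_r)/q′(−s_r); repeated nonzero roots
(|Δ| < 1e−8 × scale) raise an error asking for an infinitesimal
parameter perturbation, matching the simple-pole assumption. Complex
pole/residue pairs are conjugate; all outputs take real parts and the
residual imaginary part is asserted < 1e−9 in tests.

Service times are hypoexponential: Erlang(S−1, δ) ⊛ Exp(δ1) for nuclear
residence, plus Erlang(R, λ) for the total mRNA lifetime. Two
representations are used:

* closed form via regularized incomplete-gamma sums (valid for negative
  arguments through the finite-sum definition, so δ < δ1 needs no
  special casing), with an analytic Erlang(S, δ) branch at δ = δ1 — and
  an automatic switch to the matrix-exponential representation when
  (max(δ,δ1)/|δ−δ1|)^{S−1} > 1e6, where the two-term closed form would
  cancel catastrophically;
* the phase-type generator Q (bidiagonal), giving
  ∫₀ᵗ e^{−s(t−u)}(1−H(u))du = e₁ᵀ(Q+sI)^{−1}(e^{Qt} − e^{−st}I)𝟙
  exactly. This path is the semantic reference for B1(t) and drives the
  B2* quadrature for any S and for the total-mRNA service law.

B1* = ρ/α always; B2* is an adaptive quadrature of B1(t)(1−H(t)) on
[0, t_hi] with t_hi the first doubling point where 1−H < 1e−12,
interior break points at multiples of max(α, ρ), absolute tolerance
1e−10 (non-convergence raises with the achieved error). Closed forms
for FF at S=1 (two equivalent expressions, cross-asserted) and S=2 are
used when applicable; the S=2 pole weight was re-derived symbolically
and equals s_r(δ+δ1)³ + s_r²(δ²+3δδ1+δ1²) over
(δ+δ1)²(δ+s_r)(δ1+s_r), verified against the quadrature pipeline to
1e−13.

In the many-stage limit (k_off = 0, equal k, δ = δ1, S/δ = T_N fixed,
S → ∞) the service is a Dirac mass and the count pmf is explicit. It is
evaluated through weighted Poisson cumulative sums h(n) = n F(n−1) −
x F(n−2) (F the Poisson(x) CDF), which is overflow-safe for large kT;
the pmf is truncated when the accumulated mass exceeds 1 − 1e−12. The
closed-form Fano factor uses g(x, y) = [1 − cos(x sin y)e^{−x(1−cos y)}]
/ [x(1−cos y)] summed over θ_r = 2πr/G and is cross-checked against the
pmf moments.

## Simulator

Steady-state distributions come from one long trajectory with
time-weighted occupancy (ergodic averaging) rather than an ensemble:
the steady-state focus makes this strictly more sample-efficient, and
an independent-snapshot mode exists for the two-sample delay check.
Burn-in defaults to 10× the slowest relevant block timescale; a sampling
horizon under 100× the slowest timescale logs a warning. Monte-Carlo
standard errors are batch means over 20 (default) or 40 equal windows;
intervals are attributed to the window containing their start, a
negligible end-effect for the event densities used. Species strictly
downstream of the tracked total are not simulated (they cannot affect
upstream statistics). The histogram cap is mean + 25·sqrt(mean+1) + 80;
overflowing counts clamp to the last bin (never observed in tests). The
numba core uses the legacy numpy RNG seeded per run (seeds folded to
< 2³¹); every CLI output records seed, horizon and species in a JSON
sidecar.

## Slow-scale closed forms

The cytoplasmic Fano factor is
FF_C = 1 + 2 e_G (1 − (2R−1)!!/(2R)!!) ν / den², with
ν = k_off(e_{G−1}(k_2..) − k_on e_{G−2}(k_2..)) − k_on² e_{G−2}(k_1..)
and den = k_off e_{G−1}(k_2..) + k_on e_{G−1}(k_1..). The sign of ν is
the sign of FF_C − 1; ν = 0 defines the threshold k_off*, and the same
quantity controls the off-diagonal covariance signs and the
monotonicity of FF_C in R. The stage covariance matrix is obtained by
solving the reduced R×R Lyapunov equation exactly (vectorized
Schur-based scipy solver; the matrices are tiny) with the reduced
diffusion matrix whose (1,1) entry carries the upstream noise
correction — this choice of representation makes the residual
criterion hold by construction and reproduces the closed-form total
exactly. The protein Fano factor is implemented from its final closed
form (verified through its G=1 and k_off=0 reductions, both exact
identities in the elementary symmetric polynomials, using
e_{G−1}(k²) = e_{G−1}² − 2 e_G e_{G−2}).

The interior extremum of FF_C over k_off (cases 1 and 3 of the
classification) has no closed form here; it is located by bounded
scalar minimization on log10 k_off ∈ [−6, 4] (xatol 1e−8). Elementary
symmetric polynomials use the O(nG) Newton recursion; the double
factorial ratio is an iterative product with a log-space fallback for
R > 150.

## Sensitivity ensembles

Δ(x) is a central finite difference of ln FF in ln x (default relative
step 1e−4; the Fano path may involve quadrature, so symbolic
differentiation is deliberately avoided). The three sampling groups
(G=2, S=2; 1000 sets each) use the stated intervals — group 1:
k_off ∈ (0.1,10), k_on, k1, k2 ∈ (10,100); group 2: all four ∈
(0.1,100); group 3: k_off, k1, k2 ∈ (10,100), k_on ∈ (0.1,1); δ, δ1 ∈
(0.1,100) throughout. Sampling is **uniform on the log scale** by
default: under it the bursty group shows its characteristic strong
burst-control sensitivities (mean Δ(k_off) ≈ −0.36, mean Δ(k1) ≈ +0.40),
whereas linear-uniform sampling dilutes them to ≈ −0.16/+0.24; a linear
mode is retained as an option.
"Typical" group behaviour is distributional, not absolute: ~1–2% of
group-1 draws at the interval edges (k_off ≈ k_on ≈ 10) land slightly
above FF = 1 under either scale, so the tests assert the mass below 1,
not the maximum.

## What the synthetic conditions do and do not show

All inputs are parameter sets — there is no external data. The fixtures
define the study conditions (threshold points, accuracy grids, sampling
regions), so passing tests demonstrate the internal
consistency of simulation, queueing theory and the linear-noise
reductions *under the model's assumptions*: single gene copy, linear
kinetics, no extrinsic noise. They do not show that real genes satisfy
those assumptions; in particular, measured Fano factors include
extrinsic and technical noise components that this model deliberately
omits.

## Problem sizes and tolerances used by the tests

Deterministic oracles run at machine-precision tolerances (1e−8 to
1e−12 as stated per check). Stochastic checks use: 20 models spanning
Λ_{G,N} ∈ [0.01, 100] with horizons of max(5000 × slowest timescale,
1e5 min) and 40 batch windows (compared at 3 Monte-Carlo SE); the
stage-count convergence comparison at S ∈ {2, 5, 10} with 3e4 min
horizons; the three threshold-point simulations at 1e5 min; sign/bound
corollaries at 2 × 1000 and 2 × 10000 closed-form samples. These sizes
were chosen so each stochastic check resolves the effect it tests by a
comfortable margin while the whole suite stays interactive.

## Known limitations

* The queueing pipeline returns moments for general S but distributions
  only in the deterministic-service limit; transient queue laws and
  batch arrivals are out of scope.
* The slow-scale forms are asymptotic in Λ → 0; on the accuracy grid
  the relative error is below 1% only where both Λ_{G,C} and Λ_{N,C}
  are ≲ 0.02, and grows to several percent by Λ ≈ 0.1.
* Near-degenerate renewal poles are rejected rather than handled by
  confluent partial fractions; perturbing a rate by one part in 1e6 is
  the documented workaround.
* The protein/nuclear "G=1 is noisiest" inequality is asserted only
  under the equal-rate, matched-throughput mapping between models with
  different G; other matching conventions are not tested.
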