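# Methods

## Scope and model chain

`nfkbinfo` quantifies information transmission along the chain

    ligand identity L  →  nuclear NFκB trajectory  →  gene-expression trajectory

for a panel of five ligands at one dose each (TNF 10 ng/ml, LPS 10 ng/ml,
PolyIC 30 µg/ml, CpG 1 µM, Pam3CSK 300 ng/ml; doses are metadata only).  The
receptor-to-NFκB encoding step is represented by a parametric waveform
surrogate rather than a mechanistic reaction network: the analysis downstream
(information estimation, optimization) only needs ligand-distinct dynamics
with controllable extrinsic noise, and the surrogate provides exactly that
while staying cheap enough for thousands of cells per condition.  Users who
have trajectories from a mechanistic encoding model can load them from
long-format CSV (`ligand,cell_id,time_min,value`) and run the identical
downstream analysis.

## Encoding surrogate

One cell's nuclear-NFκB activity is

    N(t) = B + A · env(t′) · osc(t′),      t′ = max(0, t − t_lag)
    env(t′) = (1 − e^(−t′/t_r)) · e^(−max(0, t′−t_0)/t_f)
    osc(t′) = 1 + w·cos(2π t′/T_osc)

i.e. a lagged rise (timescale `t_r`, minutes), a plateau ending at `t_0`, an
exponential fall (`t_f`), and an optional damped-looking oscillation of
weight `w ∈ [0, 0.95]` and period `T_osc`.  Amplitudes are dimensionless.
The bundled reference panel (a JSON config, `data/reference_waveforms.json`,
deliberately not a code constant so it can be swapped per study) encodes the
qualitative ligand phenotypes: TNF damped-oscillatory (w=0.6, T≈95 min), LPS
sustained biphasic, CpG sustained non-oscillatory, Pam3CSK fast transient,
PolyIC delayed (60 min lag) slow response.  All five have basal B=0.05 and
amplitude A=1.

Extrinsic (cell-state) noise: every waveform parameter is drawn
independently log-normal with the reference value at the distribution
*median* (µ = ln ref, σ = √ln(1+CV²)), one common CV for all parameters.
Median centering keeps the reference inside the distribution at any CV; a
`centering="mean"` switch rescales so the mean equals the reference instead.
Zero-valued references (e.g. `t_lag` for non-delayed ligands) stay zero —
multiplicative noise cannot move them.  `w` is sampled like the others and
clipped to [0, 0.95] to preserve non-negativity of the waveform.

The default grid is 1-minute resolution over [1, 480] min.  Ensembles are
non-dimensionalized by dividing *all* values by the single global maximum of
the realized 5-ligand ensemble (not a noise-free reference run); the maximum
is therefore exactly 1 in every normalized ensemble, and the choice is made
per realization because the noisy maximum is what a downstream promoter
actually sees.

What the surrogate does **not** emulate: dose–response behavior (one dose
per ligand), intrinsic stochastic-kinetics noise during encoding, and the
fine-grained trajectory irregularity of a mechanistic network.  One
consequence worth knowing: for transient ligands the late time points
collapse onto the basal level, which is a single log-normal scalar per cell,
so some embedding coordinates are nearly deterministic functions of others.
Passing tests therefore demonstrate correct behavior of the estimator and
pipeline on realistic *statistical structure* (distinct dynamics + extrinsic
noise), not agreement with any particular mechanistic model.

## Gene-expression model

A single non-dimensionalized ODE with six parameters:

    dG/dt = k0 + ks · hill(x(t−τ); kb, n) − kd·G,
    hill(x; kb, n) = xⁿ / (kbⁿ + xⁿ),
    G(t_start) = k0/kd.

`x` is the normalized NFκB input; all parameters are dimensionless except τ
(minutes).  The functional form — basal production plus Hill-activated
production minus first-order degradation — is the canonical reading of the
six parameter roles (basal rate, driven rate, mRNA degradation, half
saturation, cooperativity, transcriptional delay); it is isolated behind
`hill`/`simulate_gene` so a variant form is a one-function change.  The
initial condition is the pre-stimulus steady state k0/kd, which avoids a
spurious ligand-independent transient; for t−τ before the grid start the
input is held at its first value (basal pre-history).

Default parameter bounds (used for uniform guess draws and as "biologically
relevant" ranges): k0 ∈ [2.7·10⁻³, 0.7], ks ∈ [0.06, 1.72],
kd ∈ [5·10⁻⁴, 0.023], kb ∈ [0.04, 2.46], n ∈ [2, 6], τ ∈ [24, 120] min.
The package's nominal (reference) parameter set is the geometric mid-range
of the multiplicative parameters and the arithmetic mid-range of n and τ:
k0≈0.0435, ks≈0.321, kd≈3.39·10⁻³, kb≈0.314, n=4, τ=72 min.  Geometric
centering is the natural choice for rate constants whose bounds span orders
of magnitude; the nominal set is a package default, exposed in the run
config, not a fitted quantity.

Numerics: classical fixed-step 4th-order Runge–Kutta on the trajectory grid,
vectorized across cells, with the (delayed) input linearly interpolated and
clamped at the grid edges.  The input is measured data rather than a state
variable, so no delay-differential machinery is needed.  Accuracy is
validated against two closed forms (constant-input steady state and the
saturated-Hill linear ODE) at 10⁻⁶ relative tolerance, and against the exact
time-shift identity for grid-aligned delays.  Per-cell noisy parameters use
the same log-normal sampler; the sampled Hill coefficient is clipped at 1
to keep every cell a valid model.

## Mutual information estimation

Trajectories are embedded by reading each one at d time points (linear
interpolation).  The default embedding [50, 100, 150, 300, 450] min spans
early, mid and late response; the equispaced alternative for the
convergence diagnostic takes the V interior points of V+2 equally spaced
values on [1, 480].

Differential entropy is estimated with the Kozachenko–Leonenko kNN
estimator in its full-Euclidean form:

    Ĥ = ψ(N) − ψ(k) + ln c_d + (d/N) Σᵢ ln εᵢ,     c_d = π^(d/2)/Γ(d/2+1)

with εᵢ the distance to the k-th nearest neighbor (self excluded), k = 10 by
default.  Entropies are computed in nats and MI reported in bits:
MI = (H(R) − Σᵢ qᵢ H(R|lᵢ))/ln 2, equiprobable qᵢ = 1/5 by default (the
conditional term accepts arbitrary weights, but no capacity maximization
over q is performed).  Constant-offset conventions of the estimator cancel
between the marginal and conditional terms.  Both the raw and the
zero-clipped MI are reported; the clipped value is the user-facing one.
Distances below 10⁻¹² are floored (with a logged warning) so log 0 cannot
occur, e.g. for CV = 0 ensembles where differential MI is degenerate
anyway.  kNN ties are broken by the neighbor query's index order and are
non-semantic.

### Estimator bias, measured

Two bias properties of this estimator matter for interpretation and are
characterized by the test suite:

* **Resolution bias in d.**  For a d-dimensional Gaussian the estimator's
  bias scales like (k/N)^(2/d).  At N = 5000 it is ≲0.03 nats for d ≤ 3 at
  k = 10, but −0.075 nats at d = 5, k = 10 and −0.048 nats at d = 5 with
  the classical k = 1 estimator — i.e. at the edge of a ±0.05 tolerance.
  The entropy-oracle tests therefore use k = 10 for d ≤ 3 and k = 1 for
  d ∈ {4, 5}, averaged over replicates so they measure bias rather than
  sampling noise.  MI is far more accurate than either entropy because the
  marginal and conditional biases largely cancel.

* **Negative null bias on clustered data.**  With shuffled labels the raw
  MI estimate on strongly clustered ensembles is biased *negative* (per-class
  entropies at N/5 samples resolve cluster fine-structure at a coarser scale
  than the pooled entropy at N; the surrogate's near-degenerate coordinates
  amplify this).  The estimator is conservative under the null — label
  shuffling never fakes positive information — and the clipped MI is 0.  On
  smooth unimodal data the raw null is unbiased within ±0.05 bits.

Diagnostics mirror this: `mi_dimension_convergence` (MI vs embedding
dimension V = 1..8) and `mi_samplesize_bias` (MI vs 1/N under per-class
subsampling) are flat, respectively for V ≥ 4 and across N, on
well-separated ensembles (CV ≈ 10%); at CV 25% the same diagnostics reveal
the residual resolution bias, which is why MI differences in all A-vs-B
experiments are computed on *paired* ensembles.

## Simulated annealing

Proposals change exactly one uniformly chosen parameter by the
multiplicative rule param′ = param·(1 + (−1)ᵇ·δ·u) with b ∈ {0,1}, u ~
U(0,1) and δ = 5% (an optional log10-space step mode applies the same
amplitude to log₁₀ param).  Acceptance is Metropolis — always accept
improvements, accept a ΔMI < 0 move with probability exp(ΔMI/T) — with
geometric cooling T ← 0.995·T from T₀ = 0.1 bits.  No box constraints are
imposed during search; proposals violating model validity (n < 1) are
resampled.  Termination: |ΔMI| < 10⁻² bits over a window (default 10) of
consecutive *accepted* iterations, or max_iter = 2000.  A single small ΔMI
occurs constantly by chance, hence the window; even so the rule is
permissive — with δ = 5% single-parameter moves, many accepted steps are
small, so runs can stop well before the global optimum.  The trace records
every proposal, so best-so-far monotonicity and the stopping reason are
auditable.

Because the MI objective is itself a stochastic estimate, the default
objective freezes the noise realization per optimization run (common random
numbers: one standard-normal matrix behind the log-normal per-cell
parameters), making the objective deterministic in the parameters — a ΔMI
< 10⁻² stopping rule is only meaningful when estimator noise is controlled.
A resample-per-iteration mode (`freeze_noise=False`) is available.
Repeated runs (default 4) start from independent uniform guesses on the
parameter ranges, report per-parameter mean ± sd of the optima, and align
MI traces by padding shorter runs with their final value.

## Experiments

All A-vs-B comparisons are paired: the same NFκB ensemble and the same
frozen noise realization are used on both sides, so differences reflect the
quantity being varied.  Specifics:

* **MI vs CV sweep** (stages: encoding, noise-free gene, noisy gene): per CV
  and replicate, one ensemble drives all three stages; the noisy gene stage
  uses the same CV for its parameters.  Defaults: CV grid
  {10,15,20,25,30,35}%, 1000 cells/ligand, 3 replicate ensembles.
* **MI distribution over gene parameters**: references drawn uniformly from
  the bounds; noisy and noiseless modes share reference draws at the same
  seed (paired).
* **Parameter attribution**: all 2³ nominal/optimized assignments of
  {kd, n, τ} plus both references, one shared noise realization.
* **Single-parameter variability sweep**: one parameter receives noise at
  each CV on the grid (same normal draws rescaled, so the sweep is smooth);
  the NFκB ensemble is generated at CV 25% by default (switchable to 0).
* **Expression variability**: time-averaged across-cell coefficient of
  variation (sample sd / mean, averaged over time points with mean > 10⁻⁹),
  per ligand and pooled; scale-invariant.
* **Ligand specificity**: per-ligand mean and grand-mean trajectories are
  both divided by the summed grand mean; the metric is the Euclidean
  distance between each scaled ligand mean and the scaled grand mean
  (squared-distance variant behind a flag); scale-invariant.

## Reproducibility

A single master seed spawns named child seeds per stage (SHA-256 of
`"{seed}:{stage}"`, reduced below 2³¹), so stages are independently
re-runnable; all randomness flows through injected numpy Generators.  CLI
runs write a config copy and a manifest of SHA-256 content hashes; identical
(config, seed) pairs are byte-identical.  CSV values are written at 17
significant digits and parsed with round-trip float precision, so trajectory
files reload bit-identically.

`scripts/acceptance.py` uses 1000 cells/ligand (N = 5000) for the MI
quantities, 500 cells/ligand for the CV sweep, and 200 cells/ligand with a
300-iteration cap for the annealing stage; these sizes keep the whole script
in the tens of seconds on one CPU while leaving the MI estimates within a
few hundredths of a bit of their large-N values (see the sample-size
diagnostic).

## Known limitations

* The encoding surrogate carries no dose information and no intrinsic
  noise; conclusions about absolute information values apply to the
  surrogate's statistical structure, not to any mechanistic model.
* Differential MI at CV = 0 is degenerate (point masses); the distance
  floor makes the estimator return finite values, but they are not
  meaningful and generating code should use CV > 0.
* The kNN estimator's resolution bias grows with embedding dimension and
  shrinking class size (measured above); per-class sizes below ~100·k are
  not recommended at d = 5.
* The annealer's windowed ΔMI stopping rule can halt before the optimum on
  flat objectives; raise `window`/`max_iter` or lower `dmi_tol` for
  higher-precision optima.
* Single-gene, single-TF model: no multi-state promoters, no feed-forward
  loops, no translation step, no transcriptional bursting.
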