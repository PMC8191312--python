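# Methods

This note documents the models implemented in `bridgemsm`, the synthetic
data they are exercised on, the numerical choices, and what the tests do
and do not establish about real molecular data.

## Scope and intent

The package implements the MSM protocol used to analyze how a modified
template base (e.g. 5-carboxylcytosine) pauses RNA polymerase II
translocation: feature engineering, tICA, K-centers clustering, MSM
estimation and validation, spectral coarse-graining, transition path
theory, and MSM-weighted structural observables (bridge-helix kinking,
hydrogen bonds, odds ratios). Molecular-dynamics generation itself is
out of scope; trajectories enter as delimited-text feature matrices or
are produced by the synthetic generator. Everything stochastic flows
from one seed: each stage derives a child seed from the master seed and
its stage name, so runs are bit-reproducible and adding a stage never
perturbs another stage's stream.

## Feature engineering (`features`)

Features are interatomic distances between labelled atom pairs;
`compute_pair_distances` evaluates them for frame x atom x 3 coordinate
arrays. Large feature sets are pruned by tICA loading magnitude:
`prune_features_by_loading` keeps the union of the top-n1/n2/n3 features
by |loading| on the first three tICs (the protocol's 1000/600/400
rule), retaining all ties at the selection rank so the result is
independent of input order. Whether features are scaled before
covariance estimation is a configuration choice; the default is mean
centering only. The human judgement of a "visually connected"
projection is replaced by a diagnostic, `projection_connectivity` (the
fraction of frames with a neighbour within a radius in tIC space),
deliberately not an automatic pruner.

## tICA (`tica`)

Symmetrized estimators: the mean and instantaneous covariance average
the `t` and `t+tau` marginals, and `C_tau` is the symmetrized lagged
covariance, so the generalized eigenproblem
`C_tau v = lambda (C_0 + eps I) v` has a real spectrum (the standard
reversible estimator). Default ridge `eps = 1e-10 tr(C_0)/d`.
Components are normalized to unit `C_0`-norm and sign-fixed (largest
entry positive). Multiple trajectories contribute independent lagged
pairs; there are no cross-trajectory pairs. Fitting on one ensemble and
projecting another (the reference-system mode) is supported by
`transform` on any trajectory sharing the model's feature labels.

## Microstates (`microstates`)

Greedy K-centers (farthest-point traversal) with a caller-supplied seed
frame (default 0) and ties broken by lowest frame index; the covering
radius is at most twice optimal, which the tests verify against
exhaustive search. Assignment labels frames by nearest center with
ties to the lower center index.

## MSM estimation and validation (`msm`)

Sliding-window transition counts at an integer frame lag; the count
graph is trimmed to its largest strongly connected component before
estimation. The default estimator is reversible: `T` row-normalizes the
symmetrized counts `(C + C')/2` and `pi` is proportional to the
symmetrized row sums, guaranteeing detailed balance and the real
spectrum that spectral lumping and tICA-consistent analysis require; a
non-reversible row-normalization is available by flag and warns on
complex eigenvalue pairs. Implied timescales `t_k = -tau / ln lambda_k`
are scanned over lags for the usual leveling-off diagnostic.

**GMRQ cross-validation.** Whole trajectories are split 1:1 into train
and test sets (five splits by default); for each hyperparameter value
the discretization is fit on the training half, an MSM estimated, and
the generalized matrix Rayleigh quotient of its top-m eigenvectors
evaluated on the held-out correlation matrices. `m` defaults to 5.
Test sets missing training states are scored on the intersection and
flagged.

**Residence probability test.** For the `n_top = 12` most populated
microstates, the model curve `(T^k)_ii` at lag multiples (0, 1, 2) is
compared to the window-smoothed fraction of trajectory starts (spaced at
least a minimum number of frames apart) still or again in the state
after `k` lags. The confidence band is a trajectory-level bootstrap:
because the verdict demands *every* tested state to pass at *every* lag
multiple, the band is a Student-t (df = n_trajectories - 1) multiple of
the bootstrap SD, Bonferroni-adjusted for simultaneous 95% coverage
over the whole family of comparisons. Percentile bands from a few
hundred resamples of ten trajectory means cannot resolve the required
tail quantiles and mis-flag correct models roughly half the time; the t
band restores the nominal ~5% family-wise false-alarm rate while still
detecting genuinely perturbed dynamics in every tested case.

**MCMC observables.** Macrostate populations, hydrogen-bond percentages
and straight-helix fractions are estimated from ten chains of 1e5 steps
sampled from `T` (starts drawn from `pi`), discarding the first 20% of
each chain; reported as across-chain mean and SD, with a 95% percentile
band over 1000 bootstrap resamples of chains on request. `mcmc_mfpt`
averages the time to the next target visit over every source-occupied
frame — the chain analogue of the pi-weighted linear-solve MFPT it is
cross-checked against (3% agreement on random chains).

**Block bootstrap.** Contiguous blocks (last partial block kept) are
resampled with replacement to the original length; 95% intervals are
percentile-based. Coverage for AR(1) means is verified at 90–99% over
200 replicates.

## Coarse-graining and kinetics (`kinetics`)

The macrostate count is chosen at the largest eigenvalue-gap ratio
`lambda_k / lambda_{k+1}` over `2 <= k <= max_k`; the choice is flagged
low-confidence unless the discarded process is at least three times
faster than the slowest kept one (`ln lambda_{k+1} / ln lambda_k >= 3`).
Lumping embeds microstates in the top slow right eigenvectors
(pi-orthonormal) and clusters with k-means (10 restarts, fixed seed,
pi-weighted samples); macrostates are relabeled by descending
population, and the pipeline re-orders them along mean tIC1 so state 1
is the pre-translocation-like end.

TPT: the committor solves `(I - T) q = 0` with absorbing boundaries;
for reversible models `q- = 1 - q+`; gross flux
`f_ij = pi_i q-_i T_ij q+_j`, net flux `max(0, f - f')`, total flux the
net flow out of the source set, all per lag time. TPT runs at the
microstate level and is aggregated onto macrostates (gross fluxes summed
between groups, committors carried as pi-weighted member averages);
pathway decomposition repeatedly extracts the widest (max-min
bottleneck) source-to-sink path on the net-flux graph — acyclic in
committor order, asserted via topological sort — and subtracts its
bottleneck flux until 95% of the total flux is covered. MFPTs are
reported both by deterministic linear solve and by the MCMC protocol;
the MCMC value is primary in reports, the linear solve is the ground
truth it is checked against.

## Structural observables (`structmetrics`)

**Cylinder fits and kink angles.** Cylinders are fit by nonlinear least
squares (sum of squared radial deviations) to 6-residue C-alpha windows;
the kink angle at residue r is the angle between the axes of the windows
`[r-5, r]` and `[r, r+5]`, and the wobble azimuth is the downstream
axis direction in the plane normal to the upstream axis, referenced to
the helix radial vector at r. The cost surface of a short helical
segment is multi-modal, and for windows that straddle a kink the
*global* optimum is an oblique interpolating cylinder that reports
angles larger than the kink itself; the solver therefore starts from the
principal axis with the lowest initial cylinder cost and keeps the local
solution continuous with it, which makes noiseless single-kink profiles
peak exactly at the hinge. The parameterization is built from the data
(not a fixed laboratory frame) so fits are equivariant under rigid
motion to optimizer precision (~1e-6 degrees). A conformation is
classified *straight* when no kink angle reaches the 35-degree
threshold; thresholds use strict inequalities (boundary cases are
measure-zero). Profiles around multiple nearby kinks are qualitative
only: windows containing a second kink in their interior report
attenuated, position-smeared angles.

**Hinge aggregation.** Ensembles are pooled over named hinge residue
ranges: normalized angle histograms per hinge, and per-residue kink
frequencies counting the conformations whose within-hinge maximum falls
on that residue and exceeds the threshold (the per-hinge-maximum
convention; multiple simultaneous kinks never count a conformation
twice).

**Hydrogen bonds and odds ratios.** The geometric criterion (distance
< 0.35 nm, deviation < 30 degrees, strict) is applied per frame;
per-microstate frame averages feed the MCMC machinery for MSM-weighted
macrostate percentages. The kink-bond odds ratio
`(B_s/B_k)/(NB_s/NB_k)` is computed from the four MSM-weighted cell
populations; it is undefined (reported with the zero cell named) when a
denominator cell is empty.

**Perturbation-run diagnostics.** `tic_shift_histogram` pools per-frame
tIC shifts relative to each trajectory's start into a unit-area
histogram (the mutant-run readout), and `barrier_start_selection` picks
from each macrostate the n member microstates with the highest one-step
probability mass into the other macrostate (ties by higher pi) — the
rule for seeding simulations near the inter-state barrier.

## Synthetic data (`synthgen`)

The generator supplies every input with known ground truth:

* **Langevin trajectories.** Euler–Maruyama overdamped dynamics,
  `x <- x - D grad U dt + sqrt(2 D dt) xi`, with `U` in kT units.
  The default `dt = 0.01` (D = kT = 1) keeps the harmonic stationary
  variance within 1% of `kT/kappa`. The stationary density
  `exp(-U)/Z` is verified against trapezoid quadrature.
* **The triple-well landscape** stands in for the translocation
  free-energy surface: Gaussian wells at (-1.7, -0.6), (0, 0.6),
  (1.7, -0.6) with depths 4.5/4.1/3.7 kT and width 0.6, a quartic
  confinement of length scale 2.0, and two 5 kT Gaussian ridges at
  (0, -1.3) and (0, -2.4) (width 0.8). The ridges close the shortcut
  around the outside of the bend and fill the shallow pocket that would
  otherwise form between ridge and confinement; with them, the
  eigenvalue gap selects three states confidently, the sequential
  1-2-3 pathway carries >= 99% of the reactive flux, and the three
  populations (~0.29/0.54/0.16 by quadrature) are recovered within
  sampling error — the linear translocation topology with unequal
  state stabilities. A two-well variant provides the two-state control
  topology.
* **Discrete Markov chains** from arbitrary row-stochastic matrices
  (row sums checked to 1e-9), with a vectorized multi-chain sampler for
  the MCMC protocol.
* **Helices.** Ideal alpha-helix C-alpha traces (rise 1.5 A, twist 100
  degrees, radius 2.3 A by default) with programmable kinks: downstream
  residues are rotated about an axis perpendicular to the local helix
  axis through the hinge C-alpha, so the hinge residue lies exactly on
  both cylinder surfaces and the inter-axis angle equals the requested
  kink angle by construction. Kink residues must sit at least 6
  residues from each terminus (0-based indices).
* **Hydrogen-bond geometries** realizing exact (distance, deviation)
  pairs, for probing the criterion on either side of its thresholds.

In the pipeline's synthetic mode, per-frame structural ground truth is
planted by free-energy basin: straight-helix probabilities
(0.30/0.15/0.30) and hydrogen-bond geometry distributions (donor–
acceptor distances centered at 0.320/0.335/0.365 nm; hydrogen deviation
scales 12/15/14 degrees, tightened by 0.7x in straight frames so bonds
associate with straight conformations within a basin). A small helix
ensemble with basin-dependent kinks exercises the cylinder-fit path.

What the synthetic data does *not* emulate: high-dimensional feature
spaces with redundant/noisy distances, non-Markovian memory from
unresolved degrees of freedom, force-field physics, or real bridge-helix
geometry beyond an ideal kinked helix. Passing tests therefore
establish the correctness of the estimators and operators under known
dynamics — not that any particular molecular system satisfies their
assumptions.

## Problem sizes

Default synthetic runs use ten trajectories of 2e4 steps, 120
microstates, tICA lag 20 frames and MSM lag 25 frames; the MCMC
protocol in the synthetic preset uses ten chains of 2e4 steps (the
full-size 1e5-step protocol remains the default for external data).
These sizes give ~1–2% population errors and complete in seconds; the
verification script (`scripts/acceptance.py`) runs the full battery,
including a 2e5-frame end-to-end pipeline, in well under a minute.

## Known limitations

* Crisp (non-fuzzy) lumping: no PCCA+ memberships; transition-region
  microstates are hard-assigned, which can blur macrostate boundaries
  on poorly sampled data.
* The non-reversible estimator reports complex eigenvalue pairs with a
  warning but does not attempt a rate-matrix or Bayesian treatment.
* Effective-count corrections for sliding-window counting are not
  implemented; error bars on MSM quantities come from trajectory
  bootstraps and across-chain spreads instead.
* Kink profiles are quantitative for isolated kinks; closely spaced
  kinks interact through shared fit windows.
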