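# bridgemsm

Markov state model (MSM) analysis of template-nucleotide translocation
pausing in RNA polymerase II, packaged as a tested, reusable pipeline.

Oxidized epigenetic cytosine bases such as 5-carboxylcytosine (5caC)
stall Pol II as the template base crosses the bridge helix into the +1
site. The kinetics of that process can be characterized from molecular
dynamics ensembles by a now-standard protocol: reduce interatomic
distance features with time-lagged independent component analysis
(tICA), cluster the slow coordinates into microstates with K-centers,
estimate a lag-time Markov state model and validate it (GMRQ
cross-validation, implied timescales, residence probability test),
coarse-grain into metastable macrostates by spectral lumping at the
eigenvalue gap, and extract mechanism with transition path theory (TPT):
committors, reactive flux, dominant pathways and mean first-passage
times. The structural readouts — bridge-helix kink angles from
cylinder fits, geometric hydrogen bonds, and the odds ratio coupling the
two — are weighted by the MSM through Markov-chain Monte Carlo sampling.

`bridgemsm` implements that entire protocol as a library with a thin
CLI, plus a synthetic-data generator (multi-well Langevin dynamics,
discrete Markov chains, kinked helices, hydrogen-bond geometries) whose
ground truth is known in closed form or by quadrature, so every stage is
testable end to end without the original trajectories.

## The models in brief

* **tICA** solves `C_tau v = lambda (C_0 + eps I) v` for instantaneous
  and symmetrized time-lagged covariances; the top components (tICs)
  approximate the slowest collective coordinates.
* **MSM**: a row-stochastic transition matrix `T` at lag `tau`,
  estimated reversibly by symmetrized-count normalization; stationary
  distribution `pi`, implied timescales `t_k = -tau / ln lambda_k`.
* **TPT**: forward committor `q+` by linear solve, gross flux
  `f_ij = pi_i q-_i T_ij q+_j`, net flux its positive antisymmetric
  part, pathways by bottleneck subtraction until 95% of the total flux
  is covered.
* **Kink classification**: cylinders fit to 6-residue C-alpha windows on
  either side of each residue; a conformation is *straight* when no
  inter-axis angle reaches 35 degrees.
* **Hydrogen bond**: donor-acceptor distance < 0.35 nm and hydrogen
  deviation < 30 degrees from the donor-acceptor line.
* **Odds ratio**: `OR = (B_s/B_k)/(NB_s/NB_k)` over straight/kinked x
  bond/no-bond populations, MSM-weighted.

## Worked example

Run the scaled-down synthetic pipeline: ten overdamped Langevin
trajectories on a bent three-well landscape (the stand-in for the
translocation free-energy surface), through tICA, 120 K-centers
microstates, a reversible MSM, gap-based lumping, TPT and the planted
structural observables:

```python
from bridgemsm.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig.synthetic_default(seed=1))
print(report.summary())
```

prints

```
macrostates: 3 (gap confident: True)
populations (MCMC mean +/- SD): 0.318+/-0.019, 0.542+/-0.010, 0.139+/-0.012
total reactive flux (per lag): 9.577e-03
pathway coverage: 0.994
  pathway 1->2->3: 99.4% of flux
MFPT 1->3 (linear): 16.7
MFPT 1->3 (MCMC): 16.8
straight helix fraction per state: 0.30, 0.15, 0.29
kink-bond odds ratio (overall): 1.03
```

Reading this: the eigenvalue gap selects three metastable states, whose
MCMC-estimated populations (0.32/0.54/0.14) match the landscape's
quadrature Boltzmann weights (0.29/0.54/0.16) within the sampling error;
essentially all reactive flux from state 1 to state 3 passes through
state 2 (the linear translocation topology); the MCMC mean first-passage
time agrees with the deterministic linear solve; and the MSM-weighted
straight-helix fractions recover the planted per-basin probabilities
(0.30/0.15/0.30).

The same stages are available as CLI verbs operating on a workspace
directory:

```sh
bridgemsm run-all --outdir run1 --seed 1
bridgemsm simulate --config cfg.yaml --workspace ws
bridgemsm tica --workspace ws --lag 0.2
bridgemsm cluster --workspace ws --k 120
bridgemsm msm --workspace ws --lag 25
bridgemsm lump --workspace ws
bridgemsm tpt --workspace ws
```

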