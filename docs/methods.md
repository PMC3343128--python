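# Methods

## The model

`nettension` studies how one biochemical network reconciles several
qualitatively different dynamical tasks. The bundled reference system is
the RB-E2F switch that gates mammalian cell-cycle entry. The base
variant tracks nine species — MYC (`M`), Cyclin D (`D`), E2F mRNA (`m`)
and protein (`P`), active and phosphorylated RB (`Rb`, `Rp`), Cyclin E
(`E`), a lumped negative-feedback effector (`A`, standing for the
CycA/SKP2 axis) and a lumped MYC-induced repressor (`X`, standing for
miR-17-92/ARF) — with mass-action/Michaelis-Menten kinetics:

    dM/dt  = ke_MYC*sigma(S) + ke_const - d_MYC*M,   sigma(S) = S/(K_S+S)
    dD/dt  = k_CDm*M/(K_M+M) + k_CDs*sigma(S) - d_CD*D
    dm/dt  = [k_E2Fm*M/(K_M+M) + k_auto*P/(K_P+P)]
              * K_RB/(K_RB+Rb) * K_X/(K_X+X) - d_E2Fm*m
    dP/dt  = k_tl*m - d_E2Fp*P - k_Adeg*A*P
    dRb/dt = k_RB - d_RB*Rb - k_phD*D*Rb/(K_phD+Rb)
              - k_phE*E*Rb/(K_phE+Rb) + k_deph*Rp
    dRp/dt = k_phD*D*Rb/(K_phD+Rb) + k_phE*E*Rb/(K_phE+Rb)
              - k_deph*Rp - d_RP*Rp
    dE/dt  = k_CE*P/(K_P+P) - d_CE*E
    dA/dt  = k_A*P/(K_P+P) - d_A*A
    dX/dt  = k_X*M^2/(K_XM^2+M^2) - d_X*X

Units: first-order rates 1/h, synthesis rates uM/h, half-saturation
constants uM, serum in % with half-saturation `K_S`. Design choices made
where the network cartoon leaves the kinetics open:

* the repression module acts as Hill repression of E2F transcription
  (`K_X/(K_X+X)`) driven by Hill-2 MYC activation of `X`, so repression
  only engages when MYC is high — this single species is what makes a
  biphasic MYC response possible;
* negative feedback is lumped into A-dependent degradation of E2F
  protein (`k_Adeg*A*P`), merging CycA-mediated inactivation and
  SKP2-mediated proteolysis;
* RB phosphorylation/dephosphorylation is a covalent-modification
  cycle; with small `K_phD`/`K_phE` it operates near saturation, which
  sharpens the OFF-to-ON transition.

The duplicated-E2F variant (`dup_e2f`) adds a second E2F gene (m', P')
with independent synthesis and degradation (`k_E2Fm'`, `k_auto'`,
`k_tl'`, `d_E2Fm'`, `d_E2Fp'`) but identical biochemical activity:
wherever E2F protein acts as a regulator, the total P + P' enters, the
NFB degradation term applies to both copies, and readouts sum the
copies. Setting the primed synthesis rates to (effectively) zero
recovers the base variant exactly; this degeneration limit is enforced
by a regression test at 1e-8 relative tolerance.

Every parameter belongs to exactly one module — sensor, positive
feedback (PFB), negative feedback (NFB), repression (R) — or to an
`unassigned` pool (half-saturation constants of ambiguous orientation
plus the RB turnover cycle). Module *strength* is the product of member
parameters with degradation constants entering as reciprocals, reported
as log10. `K_X` enters the R module inversely (a larger `K_X` means
weaker repression).

## Protocols and task objectives

All protocols integrate with LSODA (`scipy.integrate.odeint`, rtol 1e-6,
atol 1e-9; batched dose grids use the banded-Jacobian form of the same
solver). "Steady state" is operationalised as 100 h of pre-equilibration;
the quiescent initial condition starts from all-zero concentrations
except Rb at its synthesis/decay balance `k_RB/d_RB`, at 0.01% serum.
Solver failures are mapped to score 0 inside searches rather than
aborting them.

* **Hysteresis** (readout: E2F mRNA). 21 log-spaced serum doses in
  [0.01%, 10%]. The up branch simulates 24 h at each dose from
  quiescence; the down branch from the state after 100 h at 10% serum.
  Score: Delta-P, the trapezoidal integral of max(down - up, 0) over
  log10(dose); integrating over log-dose makes the score independent of
  grid resolution. Solution iff Delta-P >= 0.5.
* **Temporal adaptation** (readout: E2F protein). Serum step 0.01% ->
  10% from quiescence, 25 h. Delta-I = peak - initial, Delta-F = peak -
  final; solution iff Delta-F/Delta-I >= 0.80 with Delta-I >= 0.2 uM.
* **Biphasic MYC response** (readout: E2F mRNA). "Direct MYC
  stimulation": the serum factor sigma is clamped to 1 and the
  constitutive synthesis rate `ke_const` is swept over 21 log-spaced
  doses spanning the `ke_MYC` search range; readout at 36 h from
  quiescence. Scored like adaptation but along the dose axis.

Two refinements to the ratio-based gates, both exposed in the task
configuration:

* The search *score* applies the Delta-I gate softly
  (ratio * min(1, Delta-I/Delta-I_min)) so the walk does not face a flat
  landscape; the *solution* criterion applies it hard.
* A solution must rise from a silenced baseline: Delta-I >= readout at
  t = 0 (or at the lowest dose). Without this condition the search
  discovers parameter sets whose E2F level is enormous before the
  stimulus and merely drifts downward — formally a peak-and-return, but
  nothing is induced, and such sets carry none of the negative-feedback
  signature that defines adaptation. The condition implements the
  biological premise that quiescent cells hold E2F off through RB.

Dual objectives normalise each task score by its threshold and combine
them by product (default) or sum; either combination only guides the
search, while the solution criterion is always conjunctive.

## The adaptive walk

Each iteration draws every free parameter log-uniformly from its range
(default: four decades centred on the bundled reference bistable set),
then repeats: mutate one uniformly chosen parameter by 10^u,
u ~ Uniform(-1, 1), clamped into range; keep the mutant only if the
score strictly improves. The iteration ends at the first solution or
after 100 consecutive non-improvements (stall limit), with a safety cap
of 1500 mutations per walk — profiling shows walks that solve do so
within a few hundred moves, while longer walks accumulate ever-smaller
score improvements and stall anyway. Requiring *strict* improvement means ties revert,
and the accepted-score sequence is strictly increasing — a property the
tests replay and check. Iterations are independent; each derives its
RNG seed from (master seed, iteration index), so serial and parallel
runs give identical archives. Warm-start mode replaces the random
initialisation with draws from an existing archive.

## Metrics

* **Tension (median form)**: weighted mean |log10(median_A/median_B)|
  per parameter, equal weights 1/n by default — the average number of
  decades a parameter's median shifts between the two tasks' solution
  sets. log10 is used because ranges span decades; the absolute value
  keeps tension nonnegative and symmetric.
* **Tension (KL form)**: per parameter, log10 values are histogrammed on
  20 equal bins spanning the search range with an add-one pseudocount;
  tension is the mean symmetrised KL divergence
  (½[KL(p‖q) + KL(q‖p)], nats). The estimator is checked against a
  direct-summation oracle on hand-built distributions at 1e-12.
* **Accessibility**: every solution of task A is re-scored on task B and
  vice versa; accessibility = pooled dual fraction
  (n_A-dual + n_B-dual)/(|A| + |B|). The pooled denominator matches the
  published arithmetic for this network ((146+14)/(4541+4878) = 0.017).
* **Representative selection**: solutions are placed by the log10
  strengths of a module pair, each axis scaled by its IQR; the k
  solutions with smallest Chebyshev distance to the coordinate-wise
  median are kept (the smallest centred box containing k points), with
  position-in-archive tie-breaks for determinism.
* **Module substitution**: all parameters of one module are replaced by
  a donor archive's per-parameter medians; modules are disjoint, so
  substitutions commute.
* **Resilience**: n joint perturbations draw eps_i ~ Normal(0, sigma)
  in log10 per free parameter (default sigma = 0.2, i.e. a typical
  ~1.6-fold change per parameter), clamped into range; a perturbation is
  resilient if the re-scored objective retains >= 10% of the original.
  K = sum_i |log10 fold-change_i| records the total applied variation.
* **Notched comparison**: median +/- 1.57*IQR/sqrt(n); non-overlapping
  notches indicate medians differing at roughly the 5% level.
* **Adjacency**: one row per task pair collecting both tension
  estimates, cross-evaluated accessibility and (optionally) median
  representative resilience.

## Reference parameter sets and archives

The package bundles, as JSON/CSV produced by its own pipeline:

* `reference_bistable` — a hand-tuned hysteresis solution (Delta-P ~
  1.3) that also serves as the centre of the default search ranges, with
  a tight-tolerance (rtol 1e-10) 24-h endpoint stored for regression;
* `reference_biphasic`, `reference_adaptive` — solutions picked from
  adaptive-walk archives, filtered to physiological concentration scales;
* `archive_{hysteresis,adaptation,biphasic}_base.csv` — single-task
  archives from 100-iteration searches (parameters rounded to 9
  significant digits), used by the metrics tests;
* `dual_hb`, `dual_ha` — representative dual-task solutions used by the
  module-substitution demonstrations.

## Problem sizes and numerical choices

Searches in the test-suite and in `scripts/acceptance.py` use 100
iterations per task on the base variant (and 60 on the duplicated
variant) — the published stability check found rates and accessibility
already representative at 500 iterations, and the package's own
three-seed spot checks show the tension ordering stable at 100. Tension
values from runs this size carry sampling noise of roughly +/-0.05;
the resilience readout uses 1000 perturbations instead of 10,000 for
the same reason. The search-vs-grid validation freezes all but two
parameters, classifies a 50x50 log-grid by direct evaluation and
requires search solutions to fall inside (and cover at least half of)
the grid-positive region at grid resolution.

Degenerate inputs are handled explicitly: a single-dose sweep scores 0;
a flat trajectory scores 0 without dividing by Delta-I = 0; empty
archives are contract errors for tension/substitution; zero IQR
collapses the notch interval to the median.

## What the synthetic archive generator does and does not emulate

`synth_archive` draws independent per-parameter log-normals with
prescribed medians. It reproduces the *marginal* location/spread
structure that the tension metrics summarise — which is exactly what
makes analytic recovery tests possible — but real search archives have
correlated parameters (e.g. compensating synthesis/degradation pairs)
and non-Gaussian, range-clipped shapes. Metrics tests that pass on
synthetic archives therefore validate the estimators, not the
biological claims; the end-to-end claims are exercised by the search
pipeline itself.

## Known limitations

* The kinetic reconstruction is constrained by the network diagram and
  named parameters, not by a published equation listing; absolute
  numbers (rates, tension values) depend on it, and only
  order-relations between task pairs should be read as robust.
* Bistability is detected operationally through the 24-h bidirectional
  sweep, not by continuation; very slow relaxers can register
  hysteresis-like path differences.
* No stochastic simulation; resilience covers parameter perturbation,
  not intrinsic noise.
* The walk's stall rule estimates solution *accessibility*, not the
  posterior volume of the viable space; rates depend on the mutation
  kernel (one parameter per move, |log10 step| <= 1).
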