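# Methods

`flipkin` implements the quantitative workflow used to resolve how the SRA
domain of UHRF1 recognises hemi-methylated CpG DNA and flips the
5-methylcytosine base: equilibrium binding from fluorescence-anisotropy
titrations, exponential analysis of stopped-flow traces, and a constrained
global fit of a three-step mass-action mechanism to trace ensembles. This
note records the model, the assumptions, the numerical choices and the
design decisions, and states explicitly what the synthetic-data tests do
and do not demonstrate.

## The reaction scheme

The mechanism couples a bimolecular encounter to up to two unimolecular
isomerisations:

    N + P  <==[k1 / k-1]==>  NPns  <==[k2 / k-2]==>  NPfl  <==[k3 / k-3]==>  NPst

* `N` — free labelled DNA duplex; `P` — free SRA protein.
* `NPns` — non-specific encounter complex (binding plus sliding to the CpG
  site). This is the only species formed by the flipping-incompetent
  mutant SRA G448D (`binding_only` variant).
* `NPfl` — base-flipped intermediate: the final species for non-methylated
  (NM) duplexes (`two_step` variant, k3 = k-3 = 0).
* `NPst` — stabilised complex after a slow conformational rearrangement,
  reached only with hemi-methylated (HM) duplexes (`three_step` variant).

Stepwise equilibrium constants K1 = k1/k-1, K2 = k2/k-2, K3 = k3/k-3 close
the scheme against independently measured association constants:
K(G448D) = K1, K(NM) = K1·K2, K(HM) = K1·K2·K3. This *final-state*
convention (the default) equates each measured constant with the stepwise
product up to the last populated species. A *total-bound* convention
(K(NM) = K1·(1+K2), K(HM) = K1·(1+K2+K2K3)) — what an anisotropy titration
physically reports — is also implemented; the package quantifies the
discrepancy ratio (1+K2+K2K3)/(K2K3), which is ~15% at representative
values (K2 = 5, K3 = 3.75). The synthetic titration generator deliberately
uses the total-bound convention, exposing rather than hiding this gap.

Default parameter scales (units s^-1 unless noted): k1 = 3e9 M^-1 s^-1
(fixed; see below), k-1 = k1/K(G448D) = 6000 with K(G448D) = 5e5 M^-1,
k2 in 400–550, k-2 in 80–110, k3 in 14–35, k-3 in 3–18 — the
experimentally characterised ranges the synthetic generator draws from.

## Relaxation analysis and its validity envelope

With the encounter step equilibrated within the instrument dead time and
step 2 much faster than step 3, the two resolvable phases follow

    kobs1 = k2 + k-2
    kobs2 = k3 * (k2/k-2) / (1 + k2/k-2) + k-3 .

`relaxation_rates_exact` provides the exact oracle: the eigenvalues of the
mass-action Jacobian linearised at equilibrium. Two caveats the exact
analysis makes explicit:

* The **slow-rate** identity is accurate (< 7% over randomised draws in the
  characterised ranges at 0.3 uM duplex / 7.5 uM protein) whenever
  k1·P_eq >= 10·kobs1 and kobs1 >= 10·kobs2.
* The **fast-rate** identity additionally requires a *saturating* encounter
  step, K1·P >> 1. At the experimental concentrations K1·P is only
  0.75–4.5, so the observed fast rate is k2·K1P/(1+K1P) + k-2, i.e.
  15–50% below the plateau value k2 + k-2 and concentration-dependent.
  Tests of fitted fast rates therefore use the exact eigenvalue at the
  trace's concentration as the reference, not k2 + k-2.

## Anisotropy titrations

The anisotropy of a titrated duplex is the quantum-yield-weighted mixture
r = [θR·r_t − r_d(θ−1)] / (1 + Rθ − θ) with θ the bound duplex fraction
from the quadratic 1:n mass balance. Choices:

* θ is implemented as the *duplex*-bound fraction: the closed form is
  normalised by 2Nt and saturates at 1 in excess protein, and it enters the
  anisotropy mixing as the duplex-state population.
* n is fixed at 1 by default (the measured stoichiometry; left floating it
  refits to 1.000 on synthetic curves) with an optional lower bound of 0.1
  when floated.
* Ka is fitted as log10(Ka) since it spans 1e5–1e7 M^-1; weights are
  inverse-variance when per-point uncertainties exist.
* R (bound/free quantum-yield ratio) floats by default but can be fixed at
  its measured value (`fix_R`). A Cramér–Rao analysis during development
  showed that with R floating, Ka is essentially unidentifiable at
  realistic anisotropy noise (the 1.96σ bound exceeds 100% for any
  12-point design); R is measured directly from the intensity change
  recorded during the same titration, so the recovery studies fix it.
* The per-point noise model mirrors the acquisition protocol: each recorded
  anisotropy is the average of 10 raw readings of sd 0.003, giving
  ~0.00095 per point. The Ka-recovery study titrates 0.2 uM duplex
  (Ka·Nt ≈ 1.6, the standard design for determining a constant of
  8e6 M^-1); the generator default stays at the experimental 1 uM, which
  sits in the stoichiometric regime and determines Ka much more weakly.
* Batch validation: an estimate passes when within 20% (inclusive) of its
  target constant. Free-energy comparisons use ΔΔG = RT·ln(ratio) with
  R = 1.987 cal mol^-1 K^-1 at 293.15 K.

## Stopped-flow instrument model

Ideal fluorescence is linear in species concentrations,
F(t) = I0[N] + Ins[NPns] + Ifl[NPfl] + Ist[NPst], with responses per uM.
Defaults anchor the bound-species responses to steady-state emission
fold-changes over free duplex: 1.25x (non-specific complex), 2.5x (flipped
intermediate), 5.5x (stabilised complex, most sensitive label position);
these are config-editable since they derive from bar-plot magnitudes, not
printed numbers. The instrument samples two acquisition regimes (10000
points in 0.1 s or 2000 points in 0.1 s, each followed by 9000 points to
1 s), discards everything before the 2.7 ms dead time, adds homoscedastic
Gaussian noise (default 1% of the free-duplex level I0·Nt — the detector
noise is not characterised further), and block-averages by 4. Dead time is
handled by discarding samples, not convolution; mixing is instantaneous.

Chase dissociation mixes a pre-equilibrated complex with excess unlabelled
competitor DNA, modelled as a pseudo-first-order sink on free protein with
site concentration = nucleotides/12 and a bimolecular trap constant equal
to k1. At the experimental 750 uM (nucleotide) excess the effective trap
(~1.9e5 s^-1) exceeds rebinding (k1·Nt ≈ 900 s^-1) by ~200x, so the decay
is insensitive to these defaults; a warning fires if the margin drops
below 10x.

## Exponential fitting

Traces are fitted to y = I_f − (I_f − I_i)[a·e^(−kobs1 t) + (1−a)·e^(−kobs2 t)]
with model time running from the true mixing time, so the free intercept
I_i captures the burst hidden in the dead time (extrapolation contract).
kobs are fitted in log space, a through a logistic transform. Initial
guesses come from the log-slope of the first and last decades of signal
change; because that guess can collapse both phases into one local
minimum, the biphasic fit retries from fast-rate starts dispersed by one
and two decades and keeps the best. Phases are declared unresolved when
the fitted rates lie within 10% of each other, when the amplitude
collapses (a outside [0.01, 0.99]), or when the amplitude split is
statistically indeterminate; the trace is then refitted mono-exponentially
and flagged. Rates above the Nyquist-like limit 1/(2·median Δt) are
flagged "beyond time resolution". A flat trace (block-mean span below 8x
the point noise) short-circuits with no rates. Concentration series are
summarised by regressing kobs on protein concentration; a slope whose 95%
interval covers zero is declared concentration-independent.

## Global fitting

The global fit integrates the scheme for every ensemble member (all
association traces of both duplex types across protein concentrations,
stacked into one stiff system solved per iteration) and minimises the
weighted squared residual by Levenberg–Marquardt. Conventions:

* k1 is fixed at 3e9 M^-1 s^-1 — between the instrument lower bound
  kobs_max/P_min = 1000 s^-1 / 2 uM = 5e8 M^-1 s^-1 and the 1e10 diffusion
  limit — and everything else floats.
* I0 is anchored from the buffer-control trace (mean intensity / Nt);
  Ins, Ifl, Ist float from their fold-change initial values.
* Titration constants supply *initial estimates only* through the closure
  relations and the relaxation identities; they are never hard constraints.
* Rates are parameterised linearly with a lower bound of zero (not in log
  space) so that a confidence interval on k3 can cover zero — required for
  honest two-step vs three-step model discrimination.
* Per-trace weights default to the inverse variance of the final 5% of
  points; non-convergence triggers a multiplicative (x3 / /3) restart
  schedule and is reported, never silent.

**The dissociation constraint.** Association ensembles alone leave
(k3, k-3, Ist) nearly degenerate: equilibrium intensities constrain only
K3 jointly with the responses (through Ifl + K3·Ist) and the slow phase
constrains kobs2, so the cost varies by ~1e-10 over a 45% displacement of
k-3 along the compensated direction — below any realistic noise floor.
The experimental analysis resolves exactly this by the chase-dissociation
experiment: its observed decay rate is the rate-limiting exit rate, i.e.
the slowest eigenvalue of the bound chain NPst -> NPfl -> NPns -> N with
rebinding blocked. The global fit therefore fits each dissociation decay
mono-exponentially on its asymptotic tail (beyond 10/kobs1, where the
fast modes have died; fitting the full decay biases the rate by up to ~1%)
and includes the result as a constraint observable with a 0.5% uncertainty
floor. With this constraint a noiseless paper-design ensemble is recovered
to <0.5% in all five floated rates, and at 1% noise the median recovery
error of k2, k-2, k3, k-3 over 50 replicates is well inside 15%.

**k1 sensitivity.** Refitting with k1 at 1e10 leaves the flipping
constants k2, k-2 within ~6%; the rearrangement constants are *not*
insensitive — with the dissociation constraint active they absorb the
wrong k-1 along their shallow direction (k3 can double). Refitting at the
5e8 lower bound degrades the fit ~100-fold in cost because the encounter
relaxation (k1·P = 750–4500 s^-1) then overlaps the flipping phase: the
data themselves disfavour slow k1.

**Uncertainties.** Standard errors come from the LM covariance; a
residual-resampling bootstrap (within-trace resampling, warm-started
refits, percentile intervals, fully seeded) is offered as an alternative
without claiming equivalence to any particular published error bar.

## Numerical choices

* Internal unit is micromolar with k1 rescaled to uM^-1 s^-1: the rate
  scales span four decades (k1·Pt ≈ 2e4 s^-1 vs k-3 ≈ 4 s^-1) and the
  rescaling conditions the stiff system.
* LSODA with analytic Jacobian everywhere; rtol 1e-9, atol 1e-12 uM.
  Conservation of duplex and protein is asserted at every output point to
  1e-6 relative. The ensemble path stacks all traces into one
  block-diagonal system (one solver call per LM iteration).
* Equilibria are closed-form: the bound total solves a single quadratic
  with effective constant K1·(1+K2+K2K3); species follow from detailed
  balance. Degenerate relaxation eigenvalues are reported with
  multiplicities (grouped at 1e-6 relative), removing sort ambiguity.
* An optional analytic pre-equilibration of the encounter step before t=0
  is available as a documented approximation mode (default off; the full
  scheme is always fitted).

## What the synthetic data do and do not show

The generator reproduces the experimental design — concentrations, dead
time, acquisition regimes, block averaging, competitor excess, measurement
averaging — with additive homoscedastic Gaussian noise and a single global
gain per trace set. It does not emulate lamp drift, mixing artifacts,
photobleaching, inner-filter effects, shot-to-shot gain variation, or
model error (data are generated by the same scheme that is fitted, with
an independent integrator path). Passing recovery tests therefore
demonstrate that the estimation machinery is correct and well-conditioned
under the stated design; they do not certify the mechanism against real
traces, nor the absence of systematic instrument effects.

Problem sizes used by the shipped studies: association ensembles of 4
concentrations x 2 duplex types (~2700 points per reduced trace), 50
replicate global fits for the recovery and model-discrimination studies,
200 replicates for titration recovery, 100 draws for the relaxation sweep.

## Known limitations

* The three fixed mechanism variants are the only schemes supported; there
  is no reaction DSL and no spatial model of target search.
* k-3 identifiability rests on the dissociation constraint; without
  dissociation data, only kobs2 and the K3-response product are
  determined.
* The two equilibrium-constant conventions differ by ~10–20% at
  representative parameters; which one a given published constant follows
  must be decided by the user.
* Bootstrap intervals assume exchangeable within-trace residuals
  (homoscedastic noise); they will understate uncertainty under
  correlated drift.
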