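# flipkin

Kinetic and equilibrium analysis of protein–DNA base flipping, built around
the three-step mechanism by which the SRA domain of UHRF1 reads
hemi-methylated CpG sites:

    N + P  <==[k1/k-1]==>  NPns  <==[k2/k-2]==>  NPfl  <==[k3/k-3]==>  NPst

A fast non-specific encounter (NPns, equilibrated within the stopped-flow
dead time) is followed by base flipping of the target cytosine (NPfl) and,
for hemi-methylated duplexes only, a slow conformational rearrangement to
the stabilised complex (NPst). Non-methylated duplexes stop at NPfl; the
flipping-incompetent mutant G448D stops at NPns. The package is aimed at
biophysicists analysing stopped-flow fluorescence and anisotropy titration
data for this class of sequential binding/isomerisation mechanisms.

It provides, as importable modules and a `flipkin` command line:

* **mechanism** — stiff mass-action simulation of the scheme, closed-form
  equilibria, equilibrium-constant closures (K_G448D = K1, K_NM = K1·K2,
  K_HM = K1·K2·K3), relaxation analysis
  (kobs1 = k2 + k-2, kobs2 = k3·K2/(1+K2) + k-3) with an exact
  eigenvalue oracle, and instrument bounds on k1.
* **titration** — the quantum-yield-corrected anisotropy isotherm
  r = [θR·r_t − r_d(θ−1)]/(1 + Rθ − θ) with θ from the quadratic 1:n mass
  balance; weighted fitting, the ±20% batch-validation gate, and
  RT·ln(ratio) free-energy comparisons.
* **traces** — linear species-response fluorescence model, stopped-flow
  instrument emulation (2.7 ms dead time, dual acquisition regimes,
  reduce-by-4 block averaging, Gaussian detector noise), and
  competitor-chase dissociation.
* **expfit** — mono/bi-exponential fitting with extrapolation to true time
  zero across the dead time, phase-resolution diagnostics, and
  concentration-dependence summaries.
* **globalfit** — Levenberg–Marquardt global fit of the mechanism to whole
  trace ensembles (k1 fixed, responses anchored to the buffer control,
  dissociation rates as constraint observables), bootstrap uncertainties,
  k1-sensitivity refits, and two-step vs three-step model discrimination.
* **synth** — complete synthetic experiments with known ground truth
  matching the published design (0.3 uM duplex, 1.5–9 uM protein, 750 uM
  competitor, 1 uM titrations), for end-to-end validation.

## Worked example

Generate a synthetic hemi-methylated + non-methylated ensemble with known
rate constants, fit one trace exponentially, then globally fit the whole
ensemble:

```python
from flipkin import fit_exponential
from flipkin.globalfit import build_global_problem, run_global_fit
from flipkin.synth import (make_ground_truth, simulate_association_dataset,
                           simulate_dissociation_dataset)

truth = make_ground_truth("HM", seed=7)     # k2=493.8, k-2=106.9, k3=30.3, k-3=6.4 s^-1
traces, diss = [], []
for scen in ("HM", "NM"):
    t = truth.to_scenario(scen)
    traces += simulate_association_dataset(t, Pt_series_uM=[1.5, 3.0, 4.5, 7.5])
    diss.append(simulate_dissociation_dataset(t)[0])

fit = fit_exponential(traces[3], n_phases=2)        # HM trace at 7.5 uM
print(f"kobs1 = {fit.kobs1:.1f} s^-1, kobs2 = {fit.kobs2:.2f} s^-1")

problem = build_global_problem(
    traces, {"K_G448D": 5e5, "K_NM": 2.5e6, "K_HM": 1.2e7},
    dissociation_traces=diss)
report = run_global_fit(problem)
for name in ("k_m1", "k2", "k_m2", "k3", "k_m3"):
    print(f"{name:5s} = {getattr(report.rates, name):8.2f} s^-1"
          f"   (truth {getattr(truth.rates, name):.2f})")
```

Output:

```
kobs1 = 500.6 s^-1, kobs2 = 29.69 s^-1
k_m1  =  5840.29 s^-1   (truth 6000.00)
k2    =   487.49 s^-1   (truth 493.76)
k_m2  =   109.61 s^-1   (truth 106.92)
k3    =    30.56 s^-1   (truth 30.29)
k_m3  =     6.35 s^-1   (truth 6.38)
```

The observed fast rate (500.6 s^-1) sits below the plateau value
k2 + k-2 = 600.7 s^-1 because the encounter step is only partially
saturating at 7.5 uM protein (K1·P ≈ 3.6) — the exact relaxation
eigenvalue, not the plateau, is what a trace reports. The global fit
recovers all four floated unimolecular constants within ~2.5% of the
generating truth at 1% detector noise; the dissociation decays are what
pin k-3 (see `docs/methods.md`).

The same pipeline runs end-to-end from a shell:

```bash
flipkin demo --seed 1 --out demo_run      # generate -> titrations -> exponentials -> global fit
flipkin simulate --scenario HM --seed 7 --out sim/
flipkin fit-trace --input sim/hm_assoc_03_association.csv --phases 2
```

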