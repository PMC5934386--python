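# gatekin

Quantitative analysis of active-site gating in E2 ubiquitin-conjugating
enzymes, built around the human enzyme E2-25K and its gate mutants.

E2 enzymes carry activated ubiquitin as a thioester (E2~Ub) and transfer it
to substrate lysines. A short loop — the active-site gate — buttresses the
catalytic cysteine and fluctuates between a closed, catalytically competent
conformation and an open one. `gatekin` implements the quantitative models
used to characterise this gate from enzyme assays, NMR, and molecular
dynamics trajectories:

- **Enzyme kinetics** — exponential fits for E1-catalysed conjugation and
  thioester hydrolysis (k_obs, k_app = k_obs/[E1]); the quadratic
  neutral-lysine aminolysis rate law
  k_obs = k_cat,1·[lys⁰] + k_cat,2·[lys⁰]², with [lys⁰] from
  Henderson–Hasselbalch; and the six-species coupled-ODE model of
  K48-linked di-ubiquitin synthesis (E2, E2~Ub, Ub·E2~Ub, E2·Ub, Ub, Ub₂)
  with bounded least-squares optimisation of the catalytic constant k_Ub2.
- **NMR binding** — combined amide chemical-shift perturbations
  Δδ = √(Δδ²(¹Hᴺ) + (Δδ(¹⁵N)/5)²), the mean + 1σ significance rule, global
  1:1 binding-isotherm K_D fitting with ligand depletion, and two-site
  Bloch–McConnell ¹⁵N lineshape simulation/fitting for k_on and k_off.
- **¹⁵N relaxation** — five-parameter correlation-function fits
  (C(t) = A∞ + A₁e^(−t/τ₁) + A₂e^(−t/τ₂)), the matching spectral density
  J(ω), back-calculation of R₁/R₂/NOE (dipolar + CSA), τc from the R₂/R₁
  ratio, and open/closed population weighting of rates.
- **Gate dynamics** — two-state digitisation of gate-distance trajectories
  at a 12 Å cutoff, transition-count rate estimates, Eyring conversion
  ΔG‡ = −RT·ln(k·h/k_B·T), and steered-work free-energy profiles via the
  second-order Jarzynski cumulant expansion
  ΔG(x) = ⟨W(x)⟩ − β·Var W(x)/2.
- **Synthetic data** — seeded generators for every input class above, so
  each analysis is validated by parameter-recovery round trips.

## Worked example

Fit the di-ubiquitin chain-synthesis rate constant from a noisy synthetic
progress curve, holding the binding kinetics (k_on = 2.9×10⁷ M⁻¹s⁻¹,
k_off = 5886 s⁻¹ from lineshape analysis) and hydrolysis
(k_H2O = 0.001 min⁻¹) fixed:

```python
import numpy as np
from gatekin import kinetics as kin, synthetic_data as sd

model = kin.ChainSynthesisModel(kon=2.9e7, koff=5886.0, k_h2o=0.001/60,
                                k_ub2=0.002,
                                initial={"E2~Ub": 8e-6, "Ub": 100e-6})
times = np.linspace(0, 3600, 61)
noisy = sd.gen_chain_dataset(model, times, noise_sd=0.03, seed=1)["Ub2"]
fixed = kin.ChainSynthesisModel(2.9e7, 5886.0, 0.001/60, 0.0,
                                {"E2~Ub": 8e-6, "Ub": 100e-6})
fit = kin.fit_kub2(noisy, fixed)
print(f"k_Ub2 = {fit.k_ub2:.5f} +/- {fit.stderr:.5f} s^-1")
```

prints

```
k_Ub2 = 0.00198 +/- 0.00002 s^-1
```

i.e. the generating value 0.002 s⁻¹ is recovered within its standard error
from a 3%-noise trace. The same round-trip logic runs the gate pipeline:

```python
from gatekin import gate_dynamics as gd
k = gd.rate_from_barrier(9.2, 298.0)            # 1.112e+06 s^-1
traj = sd.gen_gate_trajectory(k, k, dt_ps=1000.0, duration_s=120e-6, seed=1)
seq = gd.digitize(traj, cutoff=12.0, min_dwell_frames=3)
rates = gd.transition_rates(seq)
print(gd.barrier_from_rate(rates.k_open, 298.0).dg_kcal)
```

gives 65 opening events, k_open = 1.089×10⁶ s⁻¹, and a recovered barrier of
9.21 kcal/mol.

## Command line

A `gatekin` executable wraps each stage (CSV in, JSON out, provenance
embedded): `simulate`, `fit-conjugation`, `fit-hydrolysis`,
`fit-aminolysis`, `fit-chain`, `fit-titration`, `fit-lineshape`,
`relax-calc`, `tauc`, `gate-analyze`, `smd-pmf`, plus `run --config` for
YAML-configured runs. Example:

```sh
gatekin gate-analyze --trajectory traj.csv --cutoff 12 --out gate.json
```

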