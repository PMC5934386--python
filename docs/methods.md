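# Methods

This note documents the models implemented in `gatekin`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter.

## Enzyme kinetics

**Units.** Seconds and molar internally, everywhere. Assay literature mixes
min⁻¹ and s⁻¹; conversion happens only at the I/O boundary (`time_min`
columns require an explicit unit flag — ambiguity is a hard error).

**Exponential fits.** Conjugation build-up and hydrolysis/aminolysis decay
traces are fit to offset + amplitude·(1 − e^(−kt)) or
offset + amplitude·e^(−kt) by Levenberg–Marquardt (lmfit), with the rate
initialised from the 63%-evolution time of the trace. Amplitude and offset
are always free parameters; we do not assume normalised intensities.
A constant trace makes the rate unidentifiable and returns a flagged
result, never a silent zero.

**Aminolysis rate law.** Observed aminolysis rates are quadratic in the
neutral-amine lysine concentration:
k_obs = k_cat,1[lys⁰] + k_cat,2[lys⁰]². Fitting is ordinary least squares
of k_obs/[lys⁰] on [lys⁰] (intercept k_cat,1, slope k_cat,2), exactly
invariant to point permutation and to unit rescaling. [lys⁰] uses
Henderson–Hasselbalch with defaults pKa = 10.54 and pH = 8.0 (the dialysis
buffer pH); the reaction pH of the original assays is not recorded, so both
are explicit parameters rather than buried constants.

**Chain synthesis.** Di-ubiquitin formation is modelled by six coupled rate
equations over {E2, E2~Ub, Ub·E2~Ub, E2·Ub, Ub, Ub₂}: reversible acceptor-Ub
binding (k_on, k_off) to both free enzyme and thioester, hydrolysis of both
thioester species with a single k_H2O, and catalysis Ub·E2~Ub → E2 + Ub₂
with rate constant k_Ub2. Two stoichiometric sums — total enzyme, and total
ubiquitin counting Ub₂ twice — are conserved exactly by the scheme and to
integrator tolerance by the solver; both are asserted in tests. Integration
uses LSODA with rtol 10⁻⁸ and atol 10⁻¹² M: with k_on ≈ 3×10⁷ M⁻¹s⁻¹ at
micromolar concentrations the binding equilibrium relaxes ~10⁶-fold faster
than catalysis, so a stiff-capable method is required. An independent
fixed-step RK4 integrator lives in the test suite as a cross-check, run on
a short window where its step count is affordable.

**k_Ub2 optimisation.** k_on, k_off (from lineshape analysis) and k_H2O
(from hydrolysis assays) are held fixed; k_Ub2 is the single free parameter
and is found by bounded scalar minimisation (Brent, [0, 10 s⁻¹]) of the
sum of squared residuals of the Ub₂ trace. The standard error comes from
the local curvature of the SSE surface. A flat trace pins the estimate near
zero with a wide, flagged uncertainty.

**ASA regression.** The rate-versus-side-chain-ASA trend uses a packaged
standard Gly-X-Gly side-chain accessibility scale (Miller et al. 1987);
any other scale can be supplied as YAML. This is a descriptive OLS trend,
not a mechanistic model.

## NMR binding

**CSP.** Δδ = √(Δδ²(¹Hᴺ) + (Δδ(¹⁵N)/5)²); the 1/5 factor maps the ¹⁵N
range onto the ¹H scale. Significant residues are those above
mean + 1σ computed over all assigned residues.

**K_D isotherm.** Protein is at ~K_D-level concentration in the titration,
so free ligand comes from the quadratic 1:1 depletion mass balance at every
point; Δδ(i, r) = Δδ_max,r·[L]free/([L]free + K_D). The default fit is
global (one shared K_D, per-residue Δδ_max) in log-K_D. Because "an average
dissociation constant" can equally mean the mean of per-residue fits, a
`per_residue=True` mode fits each residue separately and averages; the two
agree to 10⁻⁶ on clean data (tested) and we assert neither as *the*
original convention. Fits whose top titration point is below 50%
saturation are flagged as poorly determined.

**Lineshapes.** One-dimensional ¹⁵N lineshapes (the dimension in which the
analysed peaks are resolved), not 2D shapes. The two-site Bloch–McConnell
spectrum is evaluated by direct closed-form inversion of the 2×2 complex
evolution matrix at each frequency, with exchange rates k_on·[L]free
(free→bound) and k_off, populations from the depletion equilibrium, and
unit-area normalisation. Limits verified in tests: single Lorentzian of
HWHM R₂/2π Hz with no ligand, two population-weighted Lorentzians in slow
exchange, one population-averaged line in fast exchange.

**Exchange fitting.** All titration spectra are fit simultaneously with
shared log k_on, log k_off, both shifts, and R₂ (one shared R₂ by default,
since the original choice is unrecorded; distinct free/bound R₂ is an
option). Spectra are area-normalised so only shape enters. Deep fast
exchange leaves only k_off/k_on and the exchange broadening identifiable;
such fits are returned flagged with K_D still reported. Frequency grid:
512 points; ppm↔Hz conversion via the spectrometer frequency (600 MHz ¹H →
60.8 MHz ¹⁵N default).

## ¹⁵N relaxation

Internal motion is modelled as C_int(t) = A∞ + A₁e^(−t/τ₁) + A₂e^(−t/τ₂)
(two internal exponentials plus a plateau — the assumed form of the
five-parameter decay; amplitudes bounded to [0, 1], closure A∞+A₁+A₂ = 1
imposed through the C(0) = 1 normalisation of the data). Combined with
isotropic tumbling at τc:

J(ω) = (2/5)[A∞τc/(1+(ωτc)²) + Σᵢ Aᵢτᵢ′/(1+(ωτᵢ′)²)], 1/τᵢ′ = 1/τc + 1/τᵢ.

The 2/5 lives in J(ω) so that C_int is unit-normalised — stated because
conventions differ. R₁, R₂ and NOE use the standard dipolar + CSA
expressions with signed γH/γN in the NOE. Constants default to
r_NH = 1.02 Å and Δσ(¹⁵N) = −172 ppm at 600 MHz, all configurable since
the original values are unrecorded and reported literature values vary.
Correlation functions are fit per 20 ns trajectory window and the
back-calculated rates averaged over windows (not fit to the averaged
correlation function); open- and closed-state rates combine by state
occupancy, with the NOE combined through the cross-relaxation rate
σ = (NOE−1)R₁ rather than the ratio itself.

τc is recovered per residue by numerically inverting the rigid-rotor
R₂/R₁ ratio (Brent bracketing on [0.5, 100] ns) and taking a 10%-trimmed
mean; residues whose ratio falls outside the rigid-rotor attainable range
(flexible or exchange-broadened) are excluded.

## Gate dynamics

**Digitisation.** Frames with gate distance > 12 Å are open (the cutoff is
a parameter). Default behaviour is plain frame-wise thresholding. Because
Gaussian emission noise near the cutoff creates spurious recrossings, a
documented `min_dwell_frames` option reassigns interior runs shorter than
the minimum to the flanking state (edge runs are never touched); at the
generator defaults (means 7/14 Å, sd 1 Å) `min_dwell_frames=3` removes
≥ 90% of noise-induced crossings while real dwells, orders of magnitude
longer, are unaffected (tested against hidden-state truth).

**Rates and barriers.** k_open = (opening transitions)/(total time
closed), symmetrically for closing — the closing barrier uses time-in-open
normalisation symmetric to opening. A state with no observed exits yields
the one-sided upper bound k < 1/(time in state), flagged, never a failure —
mirroring trajectories in which the gate never opens. Rate→barrier
conversion is Eyring with prefactor k_B·T/h and transmission coefficient 1
at 298 K: at a 9.2 kcal/mol barrier this predicts ~1.1×10⁶ s⁻¹, i.e. a
handful of opening events per microsecond-scale trajectory, which is the
self-consistent reading of sparse-transition simulations; the prefactor is
configurable since transition-state prefactor conventions differ.

**Steered-work PMF.** ΔG(x) = ⟨W(x)⟩ − β·Var W(x)/2 (β = 1/RT), the
second-order cumulant expansion of the Jarzynski equality, exact for
Gaussian work. The profile is anchored to zero at the start position; the
barrier is the profile maximum, with a seeded 1000-resample bootstrap over
runs for its confidence interval. Runs on different grids are linearly
interpolated onto their common overlap; non-overlapping runs are rejected.

## Synthetic data

Generators take explicit seeds (no global random state); identical seeds
reproduce byte-identical output. What they emulate, and what they do not:

- **Kinetic traces** — exact exponential means with pointwise Gaussian
  noise proportional to amplitude (default 2%, a choice: assay noise
  magnitudes are unrecorded). No baseline drift, no gel-quantification
  artefacts.
- **Chain progress curves** — exact ODE solutions plus proportional
  Gaussian noise; no pipetting/timing errors between aliquots.
- **Titration lineshapes** — exact Bloch–McConnell spectra at depletion
  equilibrium; no phase/baseline errors, no t₁ noise.
- **Gate trajectories** — continuous-time two-state Markov chains
  (Gillespie dwell sampling) with Gaussian emission about state means
  7 Å/14 Å (sd 1 Å), matching the observed closed ~6–8 Å and open
  ~12–16 Å distance bands. Within-state autocorrelation is omitted:
  barrier estimation uses dwell statistics, not distance shape, so an
  AR(1) emission would change nothing downstream (the knob is documented
  but off by default). Real trajectories may have non-Markovian
  recrossing dynamics near the barrier top; passing round trips here
  validates the estimator, not the Markov assumption about real gates.
- **Work ensembles** — marginally W(x) ~ N(G(x) + βσ²/2, σ²), the
  Gaussian form that satisfies the Jarzynski fluctuation relation exactly
  at second order, so estimator-bias tests are clean. Along the pulling
  coordinate the noise is a stationary Gaussian process with correlation
  length half the pulling range, mimicking the smoothness of accumulated
  work; white-in-position noise would make the profile maximum an
  extreme-value statistic and bias the recovered barrier upward by the
  expected maximum of ~n_grid independent errors.

## Problem sizes

Defaults used by the tests and the acceptance script: 61-point progress
curves over 1 h; 6-point titrations at the recorded concentrations
(protein 417–428 µM, ligand 0–1600 µM); 512-point spectra; gate
trajectories of ~120 µs at 1 ns frames (~65 opening events at the wildtype
barrier); 150-run work ensembles on 200-point grids. These sizes put
counting statistics (≥ 50 events, √n ≈ 8%) and estimator noise
(σ/√150 ≈ 0.08 kcal/mol) comfortably inside the tolerances asserted.

## Known limitations

- No gel densitometry, 2D spectral processing, resonance assignment, or
  MD trajectory-format reading; inputs are plain tabular series.
- No hidden-Markov state assignment (thresholding + dwell filtering only)
  and no WHAM/umbrella analysis.
- The K_D isotherm assumes a single shared binding site (1:1); no
  multi-site or cooperative models.
- Relaxation back-calculation assumes isotropic tumbling; no anisotropic
  diffusion tensor, and no model-free fitting of experimental rates.
- The aminolysis analysis stops at (k_cat,1, k_cat,2); the gated-aminolysis
  kinetic scheme linking barrier changes to rate-fold predictions is out
  of scope.
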