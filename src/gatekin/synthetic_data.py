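"""Seeded generators for every input class the analysis pipeline consumes.

Each generator emulates the statistical structure one analysis stage
assumes — exponential fluorescence build-up/decay with Gaussian noise,
quadratic-in-lysine aminolysis rates, six-species chain-synthesis progress
curves, two-site exchange titration lineshapes, two-state continuous-time
Markov gate trajectories with Gaussian within-state emission, and
Jarzynski-consistent Gaussian steered-work ensembles — so every downstream
fit is testable by round-trip without external data.

All generators take an explicit integer seed and never touch global random
state; a fixed seed reproduces output bit-for-bit.
"""

from __future__ import annotations

import logging
from typing import Literal, Sequence

import numpy as np

from .kinetics import ChainSynthesisModel, KineticTrace, simulate_chain_synthesis
from .nmr_binding import Lineshape1D, TitrationSeries, bound_fraction, simulate_lineshape
from .gate_dynamics import (CLOSED, OPEN, PMF, GateTrajectory, R_KCAL,
                            WorkEnsemble)

__all__ = [
    "gen_exponential_trace",
    "gen_aminolysis_dataset",
    "gen_chain_dataset",
    "gen_csp_titration",
    "gen_titration_lineshapes",
    "gen_gate_trajectory",
    "gen_work_ensemble",
    "make_smooth_pmf",
]

logger = logging.getLogger(__name__)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Kinetic traces
# --------------------------------------------------------------------------

def gen_exponential_trace(rate: float, amplitude: float, offset: float,
                          mode: Literal["rise", "decay"], times: np.ndarray,
                          noise_sd: float = 0.0, seed: int = 0,
                          species: str = "thioester",
                          metadata: dict | None = None) -> KineticTrace:
    """Exponential build-up or decay trace with proportional Gaussian noise.

    Noiseless mean: offset + amplitude*(1 - exp(-rate t)) for a rise,
    offset + amplitude*exp(-rate t) for a decay.  Noise sd is
    ``noise_sd * amplitude``, added pointwise.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be sorted ascending")
    if mode == "rise":
        mean = offset + amplitude * (1.0 - np.exp(-rate * times))
    elif mode == "decay":
        mean = offset + amplitude * np.exp(-rate * times)
    else:
        raise ValueError("mode must be 'rise' or 'decay'")
    y = mean
    if noise_sd > 0:
        y = mean + _rng(seed).normal(0.0, noise_sd * abs(amplitude),
                                     size=times.shape)
    return KineticTrace(times=times, intensities=y, species=species,
                        metadata=metadata or {})


def gen_aminolysis_dataset(kcat1: float, kcat2: float,
                           lys_totals: Sequence[float], pH: float = 8.0,
                           pKa: float = 10.54, noise_sd: float = 0.0,
                           seed: int = 0) -> list[tuple[float, float]]:
    """Observed aminolysis rates over a lysine concentration series.

    Noiseless k_obs = kcat1*[lys0] + kcat2*[lys0]^2 with [lys0] the
    neutral-amine concentration at (pH, pKa); proportional Gaussian noise
    of sd ``noise_sd * k_obs`` is applied per point.
    """
    from .kinetics import neutral_lysine
    if len(lys_totals) == 0:
        raise ValueError("empty lysine series")
    if len(set(lys_totals)) < 2:
        raise ValueError("need >= 2 distinct lysine concentrations")
    rng = _rng(seed)
    out = []
    for lt in lys_totals:
        l0 = neutral_lysine(lt, pH, pKa)
        k = kcat1 * l0 + kcat2 * l0 * l0
        if noise_sd > 0:
            k += rng.normal(0.0, noise_sd * abs(k) if k != 0 else noise_sd)
        out.append((float(lt), float(k)))
    return out


def gen_chain_dataset(model: ChainSynthesisModel, times: np.ndarray,
                      noise_sd: float = 0.0, seed: int = 0
                      ) -> dict[str, KineticTrace]:
    """Six-species chain-synthesis progress curves with optional noise.

    Integrates the coupled rate equations exactly (stiff adaptive solver),
    then adds Gaussian noise of sd ``noise_sd * max|trace|`` per species.
    Noiseless output satisfies both stoichiometric conservation laws to
    integrator tolerance.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    conc = simulate_chain_synthesis(model, times)
    rng = _rng(seed)
    traces = {}
    for sp, y in conc.items():
        yy = y
        if noise_sd > 0:
            scale = float(np.abs(y).max())
            scale = scale if scale > 0 else 1.0
            yy = y + rng.normal(0.0, noise_sd * scale, size=y.shape)
        traces[sp] = KineticTrace(times=np.asarray(times, dtype=float),
                                  intensities=yy, species=sp,
                                  metadata={"model": model})
    return traces


# --------------------------------------------------------------------------
# NMR titrations
# --------------------------------------------------------------------------

def gen_csp_titration(kd: float, dmax: dict[str, float],
                      ligand_totals: Sequence[float],
                      protein_totals: Sequence[float],
                      noise_sd: float = 0.0, seed: int = 0
                      ) -> TitrationSeries:
    """Per-residue CSP titration from a 1:1 depletion binding model.

    ``dmax`` maps residue -> saturation CSP in ppm.  Noise sd is
    ``noise_sd * dmax_r`` per point (reference point stays exactly 0).
    """
    L = np.asarray(ligand_totals, dtype=float)
    P = np.asarray(protein_totals, dtype=float)
    residues = list(dmax)
    frac = bound_fraction(L, P, kd)
    delta = np.outer(frac, np.array([dmax[r] for r in residues]))
    if noise_sd > 0:
        noise = _rng(seed).normal(0.0, noise_sd, size=delta.shape)
        delta = delta + noise * np.array([dmax[r] for r in residues])
        delta[0] = 0.0
        delta = np.abs(delta)
    return TitrationSeries(ligand_totals=L, protein_totals=P,
                           residues=residues, delta=delta)


def gen_titration_lineshapes(kon: float, koff: float,
                             shift_free_hz: float, shift_bound_hz: float,
                             r2_free: float, r2_bound: float,
                             protein_totals: Sequence[float],
                             ligand_totals: Sequence[float],
                             noise_sd: float = 0.0, seed: int = 0,
                             freq_hz: np.ndarray | None = None,
                             n_points: int = 512) -> list[Lineshape1D]:
    """Two-site exchange 15N lineshapes across a titration.

    Each spectrum is the Bloch-McConnell absorption lineshape at the
    equilibrium populations implied by K_D = koff/kon and the 1:1 depletion
    mass balance.  Noise sd is ``noise_sd * max(intensity)`` per point.
    A common frequency grid covering both endpoint shifts is used so the
    series is directly fittable.
    """
    P = np.asarray(protein_totals, dtype=float)
    L = np.asarray(ligand_totals, dtype=float)
    if P.size != L.size:
        raise ValueError("protein and ligand arrays must have equal length")
    if freq_hz is None:
        lo = min(shift_free_hz, shift_bound_hz)
        hi = max(shift_free_hz, shift_bound_hz)
        pad = 10.0 * max(r2_free, r2_bound) / (2 * np.pi) + 0.5 * (hi - lo) + 5.0
        freq_hz = np.linspace(lo - pad, hi + pad, n_points)
    rng = _rng(seed)
    out = []
    for p_tot, l_tot in zip(P, L):
        ls = simulate_lineshape(kon, koff, shift_free_hz, shift_bound_hz,
                                r2_free, r2_bound, p_tot, l_tot,
                                freq_hz=freq_hz)
        if noise_sd > 0:
            y = ls.intensity + rng.normal(
                0.0, noise_sd * ls.intensity.max(), size=ls.intensity.shape)
            ls = Lineshape1D(freq_hz=ls.freq_hz, intensity=y,
                             spectrometer_mhz=ls.spectrometer_mhz,
                             metadata=ls.metadata)
        out.append(ls)
    return out


# --------------------------------------------------------------------------
# Gate trajectories (two-state continuous-time Markov chain)
# --------------------------------------------------------------------------

def gen_gate_trajectory(k_open: float, k_close: float, dt_ps: float,
                        duration_s: float, closed_mean: float = 7.0,
                        open_mean: float = 14.0, emission_sd: float = 1.0,
                        seed: int = 0, start_state: int = CLOSED,
                        label: str = "") -> GateTrajectory:
    """Gate-distance trajectory from a hidden two-state Markov chain.

    Hidden state dwells are exponential (Gillespie sampling) with the given
    opening/closing rates; the emitted distance at each frame is the state
    mean plus Gaussian noise of sd ``emission_sd``.  Defaults place the
    closed state at 7 A and the open state at 14 A, bracketing the 12 A
    digitisation cutoff.  The hidden state sequence is stored in
    ``metadata["hidden_states"]`` for estimator validation.

    ``k_open = 0`` (or ``k_close = 0``) pins the chain in its start state.
    """
    if k_open < 0 or k_close < 0:
        raise ValueError("rates must be >= 0")
    if dt_ps <= 0 or duration_s <= 0:
        raise ValueError("dt and duration must be positive")
    if emission_sd < 0:
        raise ValueError("emission_sd must be >= 0")
    rates = {CLOSED: k_open, OPEN: k_close}
    mean_dwell = sum(1.0 / r for r in rates.values() if r > 0)
    if mean_dwell and duration_s < 10.0 * mean_dwell / 2.0:
        logger.warning("trajectory duration %.3g s is short relative to "
                       "expected dwell times; rate estimates will be poor",
                       duration_s)

    rng = _rng(seed)
    # Gillespie dwell sequence covering the full duration.
    switch_times = [0.0]
    dwell_states = [start_state]
    t, state = 0.0, start_state
    while t < duration_s:
        r = rates[state]
        if r == 0:
            break
        t += rng.exponential(1.0 / r)
        if t >= duration_s:
            break
        switch_times.append(t)
        state = 1 - state
        dwell_states.append(state)

    n_frames = int(round(duration_s / (dt_ps * 1e-12)))
    frame_t = np.arange(n_frames) * dt_ps * 1e-12
    idx = np.searchsorted(np.asarray(switch_times), frame_t, side="right") - 1
    hidden = np.asarray(dwell_states, dtype=np.int8)[idx]
    means = np.where(hidden == OPEN, open_mean, closed_mean)
    dist = means + rng.normal(0.0, emission_sd, size=n_frames) \
        if emission_sd > 0 else means.astype(float)
    dist = np.clip(dist, 1e-6, None)   # distances are physical (> 0)
    return GateTrajectory(dt_ps=dt_ps, distances=dist, label=label,
                          metadata={"hidden_states": hidden,
                                    "k_open": k_open, "k_close": k_close,
                                    "closed_mean": closed_mean,
                                    "open_mean": open_mean,
                                    "emission_sd": emission_sd,
                                    "seed": seed})


# --------------------------------------------------------------------------
# Steered-work ensembles
# --------------------------------------------------------------------------

def make_smooth_pmf(barrier: float, length: float = 10.0,
                    n_points: int = 200) -> PMF:
    """A smooth single-barrier free-energy profile over [0, length] A.

    G(x) = barrier * sin^2(pi x / (2 * x_max)) rises monotonically from 0
    to the barrier at the end of the pulling coordinate — the shape of a
    gate-opening PMF as probed by one-directional pulling.
    """
    x = np.linspace(0.0, length, n_points)
    g = barrier * np.sin(np.pi * x / (2.0 * length)) ** 2
    return PMF(positions=x, values=g)


def gen_work_ensemble(pmf: PMF, sigma_w: float | np.ndarray = 1.0,
                      n_runs: int = 150, temperature: float = 298.0,
                      seed: int = 0, corr_length: float | None = None,
                      pulling_speed_a_per_ns: float = 0.3,
                      spring_kcal_mol_a2: float = 10.0) -> WorkEnsemble:
    """Jarzynski-consistent Gaussian work curves around a target PMF.

    Each run's work at position x is marginally
        W_i(x) ~ Normal( G(x) + beta sigma_w(x)^2 / 2, sigma_w(x)^2 ),
    the mean dissipation beta sigma^2/2 chosen so that the second-order
    cumulant estimator <W> - beta Var(W)/2 is pointwise unbiased for
    G(x) — the fluctuation-dissipation form Gaussian work must take for
    the Jarzynski equality to hold exactly.

    Along the pulling coordinate the noise is a stationary Gaussian
    process with correlation length ``corr_length`` (default: half the
    pulling range), mimicking the smoothness of accumulated pulling work;
    white noise across the grid would make the profile maximum an
    extreme-value statistic and bias the barrier upward.
    """
    if n_runs < 2:
        raise ValueError("need >= 2 runs")
    x = pmf.positions
    if np.any(np.diff(x) <= 0):
        raise ValueError("position grid must be monotone increasing")
    sigma = np.broadcast_to(np.asarray(sigma_w, dtype=float), x.shape)
    if np.any(sigma < 0):
        raise ValueError("sigma_w must be >= 0")
    if corr_length is None:
        corr_length = 0.5 * (x[-1] - x[0])
    beta = 1.0 / (R_KCAL * temperature)
    mean = pmf.values + 0.5 * beta * sigma**2
    rng = _rng(seed)
    # Unit-variance stationary Gaussian process via Cholesky of a squared-
    # exponential kernel (jitter keeps it positive definite).
    gap = np.subtract.outer(x, x)
    cov = np.exp(-0.5 * (gap / corr_length) ** 2)
    cov[np.diag_indices_from(cov)] += 1e-10
    chol = np.linalg.cholesky(cov)
    work = mean + sigma * (rng.standard_normal((n_runs, x.size)) @ chol.T)
    return WorkEnsemble(positions=x.copy(), work=work,
                        metadata={"pulling_speed_a_per_ns":
                                  pulling_speed_a_per_ns,
                                  "spring_kcal_mol_a2": spring_kcal_mol_a2,
                                  "sigma_w": np.asarray(sigma_w).tolist(),
                                  "temperature": temperature, "seed": seed})
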