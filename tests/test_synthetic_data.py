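"""Generator determinism, trivial limits, and statistical structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gatekin import gate_dynamics as gd
from gatekin import kinetics as kin
from gatekin import synthetic_data as sd

from conftest import KOFF, KON, LIGAND_TOTALS, PROTEIN_TOTALS


# --------------------------------------------------------------------------
# Determinism: same seed, same bytes
# --------------------------------------------------------------------------

def test_generators_are_seed_deterministic(wt_chain_model):
    times = np.linspace(0.0, 600.0, 20)
    a = sd.gen_exponential_trace(0.01, 1.0, 0.0, "decay", times,
                                 noise_sd=0.05, seed=7)
    b = sd.gen_exponential_trace(0.01, 1.0, 0.0, "decay", times,
                                 noise_sd=0.05, seed=7)
    assert np.array_equal(a.intensities, b.intensities)
    c = sd.gen_exponential_trace(0.01, 1.0, 0.0, "decay", times,
                                 noise_sd=0.05, seed=8)
    assert not np.array_equal(a.intensities, c.intensities)

    t1 = sd.gen_gate_trajectory(1e6, 1e6, 1000.0, 10e-6, seed=3)
    t2 = sd.gen_gate_trajectory(1e6, 1e6, 1000.0, 10e-6, seed=3)
    assert np.array_equal(t1.distances, t2.distances)

    w1 = sd.gen_work_ensemble(sd.make_smooth_pmf(5.0), 1.0, 10, seed=4)
    w2 = sd.gen_work_ensemble(sd.make_smooth_pmf(5.0), 1.0, 10, seed=4)
    assert np.array_equal(w1.work, w2.work)

    d1 = sd.gen_chain_dataset(wt_chain_model, times, noise_sd=0.03, seed=5)
    d2 = sd.gen_chain_dataset(wt_chain_model, times, noise_sd=0.03, seed=5)
    assert np.array_equal(d1["Ub2"].intensities, d2["Ub2"].intensities)


# --------------------------------------------------------------------------
# Exponential traces
# --------------------------------------------------------------------------

def test_exponential_trace_trivial_points():
    times = np.linspace(0.0, 100.0, 11)
    decay = sd.gen_exponential_trace(0.19 / 60, 10.0, 2.0, "decay", times)
    assert decay.intensities[0] == pytest.approx(12.0)   # offset + amplitude
    rise = sd.gen_exponential_trace(0.5, 10.0, 2.0, "rise", times)
    assert rise.intensities[0] == pytest.approx(2.0)     # offset at t=0

    with pytest.raises(ValueError, match="positive"):
        sd.gen_exponential_trace(-0.1, 1.0, 0.0, "decay", times)


def test_exponential_trace_noise_scale():
    times = np.linspace(0.0, 10.0, 5000)
    tr = sd.gen_exponential_trace(1e-6, 100.0, 0.0, "decay", times,
                                  noise_sd=0.02, seed=0)
    resid = tr.intensities - 100.0 * np.exp(-1e-6 * times)
    assert np.std(resid) == pytest.approx(2.0, rel=0.05)


# --------------------------------------------------------------------------
# Aminolysis datasets
# --------------------------------------------------------------------------

def test_aminolysis_dataset_trivial_limits():
    lys = [0.01, 0.03, 0.05]
    zeros = sd.gen_aminolysis_dataset(0.0, 0.0, lys)
    assert all(k == 0.0 for _, k in zeros)

    linear = sd.gen_aminolysis_dataset(100.0, 0.0, lys)
    l0 = [kin.neutral_lysine(lt) for lt, _ in linear]
    ratios = [k / x for (_, k), x in zip(linear, l0)]
    assert np.ptp(ratios) < 1e-9 * ratios[0]

    with pytest.raises(ValueError, match="empty|distinct"):
        sd.gen_aminolysis_dataset(1.0, 1.0, [])


# --------------------------------------------------------------------------
# Chain datasets
# --------------------------------------------------------------------------

def test_chain_dataset_conservation_noiseless(wt_chain_model):
    times = np.linspace(0.0, 1800.0, 31)
    traces = sd.gen_chain_dataset(wt_chain_model, times)
    y = np.stack([traces[sp].intensities for sp in kin.CHAIN_SPECIES],
                 axis=-1)
    enz, ub = kin.conservation_sums(y)
    assert np.ptp(enz) < 1e-8 * enz[0]
    assert np.ptp(ub) < 1e-8 * ub[0]


def test_chain_dataset_no_catalysis_no_product():
    m = kin.ChainSynthesisModel(kon=KON, koff=KOFF, k_h2o=1e-5, k_ub2=0.0,
                                initial={"E2~Ub": 8e-6, "Ub": 100e-6})
    traces = sd.gen_chain_dataset(m, np.linspace(0, 600, 11))
    assert np.allclose(traces["Ub2"].intensities, 0.0, atol=1e-14)


# --------------------------------------------------------------------------
# Titration lineshapes
# --------------------------------------------------------------------------

def test_titration_lineshape_series_structure():
    shapes = sd.gen_titration_lineshapes(KON, KOFF, 0.0, 120.0, 20.0, 20.0,
                                         PROTEIN_TOTALS, LIGAND_TOTALS)
    assert len(shapes) == 6
    assert shapes[0].metadata["p_bound"] == pytest.approx(0.0, abs=1e-12)
    # bound population rises along the titration
    pbs = [ls.metadata["p_bound"] for ls in shapes]
    assert np.all(np.diff(pbs) > 0)
    # all share one frequency grid
    assert all(np.array_equal(ls.freq_hz, shapes[0].freq_hz)
               for ls in shapes)

    with pytest.raises(ValueError, match="equal length"):
        sd.gen_titration_lineshapes(KON, KOFF, 0.0, 120.0, 20.0, 20.0,
                                    PROTEIN_TOTALS[:3], LIGAND_TOTALS)


# --------------------------------------------------------------------------
# Gate trajectories
# --------------------------------------------------------------------------

def test_gate_trajectory_frozen_when_rate_zero():
    traj = sd.gen_gate_trajectory(0.0, 1e6, dt_ps=1000.0, duration_s=5e-6,
                                  seed=1, emission_sd=0.0)
    assert np.all(traj.distances == 7.0)     # never leaves closed


def test_gate_trajectory_symmetric_occupancy():
    traj = sd.gen_gate_trajectory(1e6, 1e6, dt_ps=1000.0, duration_s=400e-6,
                                  seed=2, emission_sd=0.0)
    hidden = traj.metadata["hidden_states"]
    occ = float(np.mean(hidden))
    n_dwells = 1 + int(np.sum(np.abs(np.diff(hidden))))
    assert abs(occ - 0.5) < 3.0 * np.sqrt(0.25 / n_dwells)


def test_gate_trajectory_occupancy_converges_to_rate_ratio():
    k_open, k_close = 3e6, 1e6
    traj = sd.gen_gate_trajectory(k_open, k_close, dt_ps=1000.0,
                                  duration_s=400e-6, seed=6,
                                  emission_sd=0.0)
    hidden = traj.metadata["hidden_states"]
    expected = k_open / (k_open + k_close)
    n_dwells = 1 + int(np.sum(np.abs(np.diff(hidden))))
    tol = 3.0 * np.sqrt(expected * (1 - expected) / n_dwells)
    assert abs(float(np.mean(hidden)) - expected) < tol


def test_gate_trajectory_estimator_roundtrip_three_sd():
    k = 1e6
    traj = sd.gen_gate_trajectory(k, k, dt_ps=1000.0, duration_s=100e-6,
                                  seed=8)
    seq = gd.digitize(traj, min_dwell_frames=3)
    rates = gd.transition_rates(seq)
    assert abs(rates.k_open - k) < 3.0 * k / np.sqrt(rates.n_opening_events)
    assert abs(rates.k_close - k) < 3.0 * k / np.sqrt(rates.n_closing_events)


def test_gate_trajectory_short_duration_warns(caplog):
    import logging
    with caplog.at_level(logging.WARNING, logger="gatekin.synthetic_data"):
        sd.gen_gate_trajectory(1e3, 1e3, dt_ps=1000.0, duration_s=1e-6,
                               seed=0)
    assert any("short" in rec.message for rec in caplog.records)


# --------------------------------------------------------------------------
# Work ensembles
# --------------------------------------------------------------------------

def test_work_ensemble_zero_sigma_identical_runs():
    pmf = sd.make_smooth_pmf(6.1, n_points=50)
    ens = sd.gen_work_ensemble(pmf, sigma_w=0.0, n_runs=5, seed=0)
    assert np.allclose(ens.work, pmf.values[None, :])


def test_work_ensemble_flat_pmf_mean_dissipation():
    # G = 0, sigma = 1: mean work = beta/2 kcal/mol at every position
    pmf = gd.PMF(positions=np.linspace(0, 10, 40), values=np.zeros(40))
    ens = sd.gen_work_ensemble(pmf, sigma_w=1.0, n_runs=4000, seed=1)
    beta = 1.0 / (gd.R_KCAL * 298.0)
    assert np.mean(ens.work) == pytest.approx(beta / 2.0, abs=0.05)
    assert np.std(ens.work) == pytest.approx(1.0, rel=0.05)


def test_work_ensemble_validation():
    pmf = sd.make_smooth_pmf(5.0, n_points=10)
    with pytest.raises(ValueError, match="2 runs"):
        sd.gen_work_ensemble(pmf, 1.0, n_runs=1)
    bad = gd.PMF.__new__(gd.PMF)   # bypass PMF validation to hit the check
    bad.positions = np.array([0.0, 2.0, 1.0])
    bad.values = np.zeros(3)
    with pytest.raises(ValueError, match="monotone"):
        sd.gen_work_ensemble(bad, 1.0, n_runs=5)


# --------------------------------------------------------------------------
# Property tests
# --------------------------------------------------------------------------

@given(rate=st.floats(1e-5, 1e-1), amp=st.floats(0.1, 1e3),
       off=st.floats(-10, 10))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_noiseless_exponential_roundtrip_property(rate, amp, off):
    times = np.linspace(0.0, 5.0 / rate, 25)
    tr = sd.gen_exponential_trace(rate, amp, off, "decay", times)
    res = kin.fit_exponential(tr, "decay")
    assert res.ok
    assert res.rate == pytest.approx(rate, rel=1e-6)


@given(k1=st.floats(1.0, 1e3), k2=st.floats(1e6, 1e9))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_noiseless_aminolysis_roundtrip_property(k1, k2):
    data = sd.gen_aminolysis_dataset(k1, k2, [0.01, 0.02, 0.04, 0.075])
    res = kin.fit_aminolysis(data)
    assert res.k_cat1 == pytest.approx(k1, rel=1e-6, abs=1e-9 * k2 * 1e-4)
    assert res.k_cat2 == pytest.approx(k2, rel=1e-6)
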