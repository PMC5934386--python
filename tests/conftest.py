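import numpy as np
import pytest

from gatekin.kinetics import ChainSynthesisModel

#: Study conditions reused across tests: titration concentrations (M).
LIGAND_TOTALS = np.array([0.0, 200.0, 400.0, 560.0, 790.0, 1600.0]) * 1e-6
PROTEIN_TOTALS = np.array([417.0, 420.0, 421.0, 424.0, 424.0, 428.0]) * 1e-6

#: Wildtype binding kinetics from the lineshape analysis.
KON = 2.9e7          # M^-1 s^-1
KOFF = 5886.0        # s^-1


@pytest.fixture
def titration_concs():
    return LIGAND_TOTALS.copy(), PROTEIN_TOTALS.copy()


@pytest.fixture
def wt_chain_model():
    """Wildtype chain-synthesis model: thioester preformed, acceptor added."""
    return ChainSynthesisModel(
        kon=KON, koff=KOFF, k_h2o=0.001 / 60.0, k_ub2=0.002,
        initial={"E2~Ub": 8e-6, "Ub": 100e-6})


def rk4_chain(model, times):
    """Independent fixed-step RK4 integrator for the six-species scheme.

    Deliberately separate from the package's adaptive solver so the two
    routes cross-validate each other.  Step size is chosen well below the
    fastest relaxation time 1/(kon*[Ub]0 + koff).
    """
    def rhs(y):
        e2, te, bte, be2, ub, ub2 = y
        bf, bt = model.kon * e2 * ub, model.kon * te * ub
        kh, k2, ko = model.k_h2o, model.k_ub2, model.koff
        return np.array([
            kh * te - bf + ko * be2 + k2 * bte,
            ko * bte - bt - kh * te,
            -ko * bte + bt - k2 * bte - kh * bte,
            -ko * be2 + bf + kh * bte,
            ko * bte + ko * be2 - bt - bf + kh * te + kh * bte,
            k2 * bte,
        ])

    fastest = model.kon * max(model.initial.get("Ub", 0.0), 1e-6) + model.koff
    h = 0.02 / fastest
    out = np.empty((len(times), 6))
    y = model.y0()
    t = times[0]
    out[0] = y
    for i, t_next in enumerate(times[1:], start=1):
        n = max(int(np.ceil((t_next - t) / h)), 1)
        hh = (t_next - t) / n
        for _ in range(n):
            k1 = rhs(y)
            k2_ = rhs(y + hh / 2 * k1)
            k3 = rhs(y + hh / 2 * k2_)
            k4 = rhs(y + hh * k3)
            y = y + hh / 6 * (k1 + 2 * k2_ + 2 * k3 + k4)
        t = t_next
        out[i] = y
    return out
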