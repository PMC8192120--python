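import numpy as np
import pytest

import monokin as mk
from monokin.scheme import KineticScheme, State, Transition


@pytest.fixture(scope="session")
def two_state_scheme():
    """Minimal reversible scheme A <-> B with k12=2, k21=1 (no ligands)."""
    return KineticScheme(
        states=[State("A", "outward"), State("B", "inward")],
        transitions=[Transition("A", "B", 2.0, 1.0, 0.0)],
    )


@pytest.fixture(scope="session")
def empty_conditions():
    return mk.IonConditions()


@pytest.fixture(scope="session")
def physiological():
    return mk.get_condition_preset("physiological")


@pytest.fixture(scope="session")
def dat_model():
    return mk.build_dat_model()


@pytest.fixture(scope="session")
def net_model():
    return mk.build_net_model()


@pytest.fixture(scope="session")
def sert_model():
    return mk.build_sert_model()


@pytest.fixture(scope="session")
def binding_scheme():
    """Single reversible substrate-binding step: occupancy is an exact
    hyperbola of the external substrate concentration."""
    return KineticScheme(
        states=[
            State("T", "outward"),
            State("TS", "outward", {"S": 1}),
        ],
        transitions=[
            Transition("T", "TS", 1.0e6, 10.0, 0.0, ligand_fwd=("S", "out"))
        ],
    )


@pytest.fixture(scope="session")
def dat_application(dat_model, physiological):
    """One 15 s application of 30 uM substrate on DAT at -60 mV (shared)."""
    return mk.simulate_application(dat_model, physiological, -0.060, 30e-6, 15.0)


def collapsed_conditions(value: float = 0.01) -> mk.IonConditions:
    """All gradients collapsed: every species at the same concentration on
    both sides (equilibrium reference for thermodynamic checks)."""
    conc = {}
    for sp in ("Na", "K", "Cl", "H", "Li", "S"):
        conc[(sp, "in")] = value
        conc[(sp, "out")] = value
    return mk.IonConditions(conc)
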