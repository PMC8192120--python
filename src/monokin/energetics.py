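"""Gibbs free-energy profiles along reaction paths of a kinetic scheme.

The free-energy change of a step is read off its effective rate ratio,

    ΔG = −RT·ln(k_fwd_eff / k_rev_eff),

where the effective rates include the symmetric-barrier voltage factor and
pseudo-first-order ligand concentrations (standard state 1 M). For a closed
walk, the total ΔG therefore equals the net chemiosmotic driving energy of
the cycle — ion/substrate gradient terms plus Σ zQ·F·V — and is zero under
collapsed gradients at 0 mV for any thermodynamically consistent scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .engine import voltage_scaled_rate
from .scheme import IonConditions, KineticScheme, Transition

__all__ = ["EnergyProfile", "step_delta_g", "loop_profile", "DAT_OUTER_LOOP"]

# Conformational trajectory of DAT in the presence of intracellular K+:
# the substrate-translocating path that visits the K+-bound states.
DAT_OUTER_LOOP = [
    "ToCl", "ToClNa", "ToClNaS", "ToccClNaS", "TiClNaS",
    "TiClS", "TiCl", "TiClK", "ToccClK", "ToccCl", "ToCl",
]


@dataclass
class EnergyProfile:
    """Per-step and cumulative ΔG (J·mol⁻¹) along an ordered state path."""

    path: list[str]
    step_delta_g: np.ndarray
    V: float
    conditions: IonConditions
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.step_delta_g = np.asarray(self.step_delta_g, float)
        self.cumulative = np.concatenate(([0.0], np.cumsum(self.step_delta_g)))

    @property
    def total(self) -> float:
        return float(self.cumulative[-1])

    @property
    def is_closed(self) -> bool:
        return self.path[0] == self.path[-1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.path,
                "cumulative_dG_J_per_mol": self.cumulative,
                "step_dG_J_per_mol": np.concatenate(([np.nan], self.step_delta_g)),
            }
        )


def _effective_rates(
    tr: Transition,
    conditions: IonConditions,
    V: float,
    forward: bool,
    constants: PhysicalConstants,
) -> tuple[float, float]:
    kf = voltage_scaled_rate(tr.k0_fwd, tr.zQ, V, constants, "fwd")
    kr = voltage_scaled_rate(tr.k0_rev, tr.zQ, V, constants, "rev")
    if tr.ligand_fwd is not None:
        kf *= conditions.get(*tr.ligand_fwd)
    if tr.ligand_rev is not None:
        kr *= conditions.get(*tr.ligand_rev)
    return (kf, kr) if forward else (kr, kf)


def step_delta_g(
    scheme: KineticScheme,
    conditions: IonConditions,
    V: float,
    from_state: str,
    to_state: str,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """ΔG (J·mol⁻¹) of traversing the edge ``from_state`` → ``to_state``.

    A zero effective rate in either direction (for example a binding step
    with the ligand absent) makes ΔG infinite; this is flagged by raising
    rather than silently returning ±inf.
    """
    tr = scheme.find_transition(from_state, to_state)
    forward = tr.from_state == from_state
    k_f, k_r = _effective_rates(tr, conditions, V, forward, constants)
    if k_f <= 0.0 or k_r <= 0.0:
        raise ValueError(
            f"infinite step free energy on {from_state}->{to_state}: one "
            "direction has zero effective rate (ligand absent or zero base rate)"
        )
    return float(-constants.RT * np.log(k_f / k_r))


def loop_profile(
    scheme: KineticScheme,
    conditions: IonConditions,
    V: float,
    path: list[str],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> EnergyProfile:
    """Free-energy profile along an ordered walk through existing edges.

    For a closed walk the total equals −RT·ln of the product of effective
    rate ratios around the loop; it is invariant under cyclic permutation
    of the starting state and changes sign when the walk is reversed.
    """
    if len(path) < 2:
        raise ValueError("path needs at least two states")
    steps = [
        step_delta_g(scheme, conditions, V, a, b, constants)
        for a, b in zip(path[:-1], path[1:])
    ]
    return EnergyProfile(path=list(path), step_delta_g=np.array(steps), V=V,
                         conditions=conditions)


def loop_charge(scheme: KineticScheme, path: list[str]) -> float:
    """Σ zQ along a walk, signed by traversal direction."""
    total = 0.0
    for a, b in zip(path[:-1], path[1:]):
        tr = scheme.find_transition(a, b)
        total += tr.zQ if tr.from_state == a else -tr.zQ
    return total
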