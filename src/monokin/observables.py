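"""Measurable signals derived from occupancy trajectories.

Three observables connect the kinetic model to a patch-fluorometry
experiment:

* the **coupled current** I = −F·NC/N_A · Σ zQ_ij (p_i k_ij − p_j k_ji),
  the net charge displacement of all electrogenic transitions;
* the **uncoupled current** I = P_o·γ·NC·(V − V_rev), a Na⁺-channel-like
  current through the conducting state (P_o = its occupancy);
* the **substrate uptake flux** through the intracellular substrate-release
  step, (p_TiClS·k_off − p_TiCl·k_on·S_in)·NC molecules·s⁻¹, whose running
  integral is what the fluorescence channel reports.

Inward current is negative throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .engine import (
    ApplicationProtocol,
    OccupancyTrajectory,
    concentration_profile,
    voltage_scaled_rate,
)
from .models import TransporterModelSpec
from .scheme import IonConditions, KineticScheme

__all__ = [
    "ChannelParams",
    "PopulationParams",
    "CurrentTrace",
    "FluorescenceTrace",
    "coupled_current",
    "uncoupled_current",
    "total_current",
    "substrate_uptake",
    "extract_peak",
    "extract_steady",
    "extract_uptake_slope",
]


@dataclass(frozen=True)
class ChannelParams:
    """Conducting-state (uncoupled current) parameters."""

    gamma: float = 2.4e-12  # single-channel conductance, S
    V_rev: float = 0.100  # Na+ reversal potential, V
    state_name: str = "Tcond"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class PopulationParams:
    """Whole-cell scaling: number of transporters per cell."""

    NC: float = 4.0e6

    def __post_init__(self) -> None:
        if self.NC <= 0:
            raise ValueError("NC must be positive")


@dataclass
class CurrentTrace:
    time: np.ndarray
    current: np.ndarray  # A
    component: str = "total"  # coupled | uncoupled | total

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.current = np.asarray(self.current, float)
        if self.time.shape != self.current.shape:
            raise ValueError("time and current grids differ")

    def __add__(self, other: "CurrentTrace") -> "CurrentTrace":
        if self.time.shape != other.time.shape or not np.allclose(self.time, other.time):
            raise ValueError("cannot add traces on different grids")
        return CurrentTrace(self.time, self.current + other.current, "total")


@dataclass
class FluorescenceTrace:
    """Cumulative intracellular substrate (molecules) and its flux."""

    time: np.ndarray
    cumulative: np.ndarray  # molecules (or AU if scaled)
    flux: np.ndarray  # molecules / s
    brightness: float = 1.0  # AU per molecule

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.cumulative = np.asarray(self.cumulative, float)
        self.flux = np.asarray(self.flux, float)

    def scaled(self, brightness: float) -> "FluorescenceTrace":
        return FluorescenceTrace(
            self.time, self.cumulative * brightness, self.flux * brightness, brightness
        )


def _edge_fluxes(
    traj: OccupancyTrajectory,
    scheme: KineticScheme,
    conditions: IonConditions,
    V: float,
    constants: PhysicalConstants,
    protocol: ApplicationProtocol | None = None,
):
    """Per-edge net forward probability flux (s⁻¹) and the edge zQ values.

    When a protocol is supplied, external concentrations follow its
    solution-exchange time course; internal concentrations are always the
    baseline ones (protocols never vary the pipette side).
    """
    varied = (
        concentration_profile(protocol, conditions, traj.time)
        if protocol is not None
        else {}
    )

    def conc(key: tuple[str, str]):
        return varied[key] if key in varied else conditions.get(*key)

    fluxes = []
    zqs = []
    for tr in scheme.transitions:
        kf = voltage_scaled_rate(tr.k0_fwd, tr.zQ, V, constants, "fwd")
        kr = voltage_scaled_rate(tr.k0_rev, tr.zQ, V, constants, "rev")
        kf = kf * conc(tr.ligand_fwd) if tr.ligand_fwd is not None else kf
        kr = kr * conc(tr.ligand_rev) if tr.ligand_rev is not None else kr
        pi = traj.state(tr.from_state)
        pj = traj.state(tr.to_state)
        fluxes.append(pi * kf - pj * kr)
        zqs.append(tr.zQ)
    return np.array(fluxes), np.array(zqs)


def coupled_current(
    traj: OccupancyTrajectory,
    scheme: KineticScheme,
    conditions: IonConditions,
    V: float,
    pop: PopulationParams = PopulationParams(),
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    protocol: ApplicationProtocol | None = None,
) -> CurrentTrace:
    """Transport-cycle (stoichiometrically coupled) membrane current.

    Vanishes identically when every edge's net flux is zero (equilibrium).
    """
    fluxes, zqs = _edge_fluxes(traj, scheme, conditions, V, constants, protocol)
    total = (zqs[:, None] * fluxes).sum(axis=0)
    current = -constants.F * pop.NC / constants.NA * total
    return CurrentTrace(traj.time, current, "coupled")


def uncoupled_current(
    traj: OccupancyTrajectory,
    channel: ChannelParams = ChannelParams(),
    pop: PopulationParams = PopulationParams(),
    V: float = -0.060,
) -> CurrentTrace:
    """Channel-like current through the conducting state.

    Returns an identically zero trace when the scheme has no conducting
    state of the configured name.
    """
    if channel.state_name in traj.state_names:
        p_cond = traj.state(channel.state_name)
    else:
        p_cond = np.zeros_like(traj.time)
    current = p_cond * channel.gamma * pop.NC * (V - channel.V_rev)
    return CurrentTrace(traj.time, current, "uncoupled")


def total_current(
    traj: OccupancyTrajectory,
    model: TransporterModelSpec,
    conditions: IonConditions,
    V: float,
    pop: PopulationParams = PopulationParams(),
    channel: ChannelParams = ChannelParams(),
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    protocol: ApplicationProtocol | None = None,
) -> CurrentTrace:
    """Coupled plus uncoupled current on the trajectory's grid."""
    trace = coupled_current(traj, model.scheme, conditions, V, pop, constants, protocol)
    trace = trace + uncoupled_current(traj, channel, pop, V)
    trace.component = "total"
    return trace


def substrate_uptake(
    traj: OccupancyTrajectory,
    model: TransporterModelSpec,
    conditions: IonConditions,
    V: float,
    pop: PopulationParams = PopulationParams(),
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> FluorescenceTrace:
    """Cumulative substrate delivery into the cell.

    The flux is the net rate of the intracellular substrate-release step,
    p_TiClS·k_off − p_TiCl·k_on·S_in (voltage-scaled rates), times NC. With
    the default S_in = 0 it is non-negative during application and the
    cumulative trace rises monotonically.
    """
    try:
        tr = model.scheme.find_transition(
            model.substrate_bound_inward_state, model.inward_empty_state
        )
    except KeyError as exc:
        raise ValueError(
            "scheme lacks the annotated substrate-release transition"
        ) from exc
    # orient: forward direction is substrate release (TiClS -> TiCl)
    if tr.from_state == model.substrate_bound_inward_state:
        k_off = voltage_scaled_rate(tr.k0_fwd, tr.zQ, V, constants, "fwd")
        k_on = voltage_scaled_rate(tr.k0_rev, tr.zQ, V, constants, "rev")
    else:
        k_off = voltage_scaled_rate(tr.k0_rev, tr.zQ, V, constants, "rev")
        k_on = voltage_scaled_rate(tr.k0_fwd, tr.zQ, V, constants, "fwd")
    s_in = conditions.get("S", "in")
    p_bound = traj.state(model.substrate_bound_inward_state)
    p_empty = traj.state(model.inward_empty_state)
    flux = (p_bound * k_off - p_empty * k_on * s_in) * pop.NC
    cumulative = np.concatenate(
        ([0.0], np.cumsum(0.5 * (flux[1:] + flux[:-1]) * np.diff(traj.time)))
    )
    return FluorescenceTrace(traj.time, cumulative, flux)


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed its start")
    if t0 < time[0] - 1e-12 or t1 > time[-1] + 1e-12:
        raise ValueError("window outside the trace grid")
    return (time >= t0) & (time <= t1)


def _baseline(trace: CurrentTrace, onset: float) -> float:
    before = trace.time < onset
    if not before.any():
        return 0.0
    return float(trace.current[before][-1])


def extract_peak(
    trace: CurrentTrace,
    window: tuple[float, float],
    peak_span: float = 0.200,
    sign: str = "either",
) -> float:
    """Baseline-subtracted extremum within ``peak_span`` after onset.

    ``window`` is (application onset, application end); the baseline is the
    current immediately before onset and the sign of the excursion is kept.
    ``sign="negative"`` restricts the search to the inward (negative-going)
    deflection — what an experimenter tracking transport-associated peaks
    measures when a slowly decaying tail from a previous application would
    otherwise masquerade as a positive excursion.
    """
    onset, _t_end = window
    mask = _window_mask(trace.time, (onset, min(onset + peak_span, trace.time[-1])))
    seg = trace.current[mask] - _baseline(trace, onset)
    if sign == "negative":
        return float(min(seg.min(), 0.0))
    if sign != "either":
        raise ValueError("sign must be 'either' or 'negative'")
    return float(seg[np.argmax(np.abs(seg))])


def extract_steady(trace: CurrentTrace, window: tuple[float, float]) -> float:
    """Baseline-subtracted mean current over the final 20% of the window."""
    onset, t_end = window
    t0 = t_end - 0.2 * (t_end - onset)
    mask = _window_mask(trace.time, (t0, t_end))
    return float(np.mean(trace.current[mask]) - _baseline(trace, onset))


def extract_uptake_slope(
    trace: FluorescenceTrace,
    window: tuple[float, float],
    edge_exclusion: float = 0.5,
) -> float:
    """Least-squares linear slope of the cumulative trace (units·s⁻¹).

    Excludes ``edge_exclusion`` seconds at each end of the window to stay
    clear of wash-in/wash-out transients; the remaining span must be at
    least 1 s.
    """
    t0, t1 = window[0] + edge_exclusion, window[1] - edge_exclusion
    if t1 - t0 < 1.0:
        raise ValueError("uptake-slope window shorter than 1 s after edge exclusion")
    mask = _window_mask(trace.time, (t0, t1))
    t = trace.time[mask]
    y = trace.cumulative[mask]
    slope = np.polyfit(t, y, 1)[0]
    return float(slope)
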