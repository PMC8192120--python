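"""Virtual electrophysiology / fluorescence-uptake experiments.

Each protocol voltage-clamps the model cell, superfuses substrate according
to an :class:`~monokin.engine.ApplicationProtocol`, extracts the observables
an experimenter would measure (peak current, steady current, uptake slope),
normalizes them to the conventional reference, and attaches curve fits:

* concentration–response: 15 s applications over a concentration grid,
  rectangular-hyperbola fit (K_M), normalized to the highest concentration;
* current–voltage (IV): one application per voltage, uptake slopes
  normalized to −90 mV, currents to −60 mV; Boltzmann and line fits are both
  computed and the lower-residual one is reported;
* two-pulse recovery: a reference pulse, a variable wash, and a test pulse;
  the test/reference peak ratio versus wash time is fitted with a
  mono-exponential whose rate is the catalytic (cycle-completion) rate;
* ion sweep: any of the above repeated across intracellular presets,
  returned as a tidy long-format table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .engine import (
    ApplicationProtocol,
    OccupancyTrajectory,
    build_generator,
    integrate_occupancies,
    steady_state,
)
from .fitting import (
    MonoExpFit,
    fit_boltzmann,
    fit_hyperbola,
    fit_line,
    fit_monoexp,
    normalize_to_reference,
)
from .models import TransporterModelSpec, get_condition_preset
from .observables import (
    ChannelParams,
    PopulationParams,
    extract_peak,
    extract_steady,
    extract_uptake_slope,
    substrate_uptake,
    total_current,
)
from .scheme import IonConditions

__all__ = [
    "ProtocolResult",
    "simulate_application",
    "run_concentration_response",
    "run_iv",
    "run_two_pulse",
    "run_ion_sweep",
]

PRE_BASELINE_S = 0.2  # quiet baseline before application onset
POST_WASH_S = 0.5
DT_S = 0.001


def _resolve_conditions(preset: str | IonConditions) -> IonConditions:
    if isinstance(preset, IonConditions):
        return preset
    return get_condition_preset(preset)


@dataclass
class ProtocolResult:
    """Extracted observables over an independent variable.

    ``values`` maps readout name to the raw extracted array; ``normalized``
    holds the same readouts divided by their reference entry; ``fits`` maps
    readout name to the fit object(s) attached by the protocol.
    """

    independent: np.ndarray
    independent_name: str
    values: dict[str, np.ndarray] = field(default_factory=dict)
    normalized: dict[str, np.ndarray] = field(default_factory=dict)
    reference: dict[str, float] = field(default_factory=dict)
    fits: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def normalize(self, readout: str, reference_value: float) -> np.ndarray:
        x = self.independent
        idx = int(np.argmin(np.abs(x - reference_value)))
        if not np.isclose(x[idx], reference_value, rtol=1e-9, atol=1e-12):
            idx = int(np.argmin(np.abs(x - reference_value)))
        series = dict(zip(range(x.size), self.values[readout]))
        normed = normalize_to_reference(series, idx)
        arr = np.array([normed[i] for i in range(x.size)])
        self.normalized[readout] = arr
        self.reference[readout] = float(x[idx])
        return arr

    def to_dataframe(self) -> pd.DataFrame:
        rows = {self.independent_name: self.independent}
        rows.update({k: v for k, v in self.values.items()})
        rows.update({f"{k}_norm": v for k, v in self.normalized.items()})
        return pd.DataFrame(rows)


def simulate_application(
    model: TransporterModelSpec,
    conditions: IonConditions,
    V: float,
    concentration: float,
    duration: float = 15.0,
    pre: float = PRE_BASELINE_S,
    post: float = POST_WASH_S,
    dt: float = DT_S,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    pop: PopulationParams = PopulationParams(),
    channel: ChannelParams = ChannelParams(),
):
    """One substrate application under voltage clamp.

    Returns the trajectory, the current and fluorescence traces, and the
    (onset, end) application window.
    """
    protocol = ApplicationProtocol(
        V=V,
        segments=[(pre, pre + duration, {("S", "out"): concentration})],
        t_end=pre + duration + post,
    )
    t_grid = np.arange(0.0, protocol.duration + dt / 2, dt)
    traj = integrate_occupancies(model.scheme, conditions, protocol, t_grid=t_grid,
                                 constants=constants)
    current = total_current(
        traj, model, conditions, V, pop=pop, channel=channel,
        constants=constants, protocol=protocol,
    )
    fluorescence = substrate_uptake(traj, model, conditions, V, pop=pop,
                                    constants=constants)
    return traj, current, fluorescence, (pre, pre + duration)


def run_concentration_response(
    model: TransporterModelSpec,
    concentrations: np.ndarray | None = None,
    V: float = -0.060,
    preset: str | IonConditions = "physiological",
    duration: float = 15.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ProtocolResult:
    """Uptake slope and steady current versus substrate concentration.

    Readouts are normalized to the highest concentration and fitted with a
    rectangular hyperbola; the fitted ``K_M`` of the uptake readout is the
    protocol's headline number.
    """
    if concentrations is None:
        concentrations = np.array([1, 3, 10, 30, 100, 300, 600]) * 1e-6
    concentrations = np.asarray(concentrations, float)
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be positive")
    concentrations = np.sort(concentrations)
    conditions = _resolve_conditions(preset)

    slopes, steadies, peaks = [], [], []
    for conc in concentrations:
        _traj, current, fluo, window = simulate_application(
            model, conditions, V, conc, duration, constants=constants
        )
        slopes.append(extract_uptake_slope(fluo, window))
        steadies.append(extract_steady(current, window))
        peaks.append(extract_peak(current, window))

    result = ProtocolResult(
        independent=concentrations,
        independent_name="concentration_M",
        values={
            "uptake_slope": np.array(slopes),
            "steady_current": np.array(steadies),
            "peak_current": np.array(peaks),
        },
        meta={"V": V, "duration_s": duration, "transporter": model.transporter_id},
    )
    ref = float(concentrations[-1])
    for readout in ("uptake_slope", "steady_current", "peak_current"):
        try:
            result.normalize(readout, ref)
        except ZeroDivisionError:
            continue
    for readout in ("uptake_slope", "steady_current"):
        y = result.normalized.get(readout)
        if y is None:
            continue
        try:
            result.fits[readout] = fit_hyperbola(concentrations, np.abs(y))
        except (ValueError, RuntimeError):
            continue
    return result


def run_iv(
    model: TransporterModelSpec,
    voltages: np.ndarray | None = None,
    concentration: float = 30e-6,
    preset: str | IonConditions = "physiological",
    duration: float = 15.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ProtocolResult:
    """Uptake slope and currents versus membrane voltage.

    Uptake slopes are normalized to −90 mV (or the most negative voltage in
    the grid), peak/steady currents to −60 mV (same fallback). Boltzmann and
    line fits of each normalized readout are both stored; the lower-residual
    family is flagged as ``preferred``.
    """
    if voltages is None:
        voltages = np.array([-90, -70, -50, -30, -10, 10, 30]) * 1e-3
    voltages = np.asarray(voltages, float)
    if voltages.size == 0:
        raise ValueError("voltage grid is empty")
    conditions = _resolve_conditions(preset)

    slopes, steadies, peaks = [], [], []
    for V in voltages:
        _traj, current, fluo, window = simulate_application(
            model, conditions, V, concentration, duration, constants=constants
        )
        slopes.append(extract_uptake_slope(fluo, window))
        steadies.append(extract_steady(current, window))
        peaks.append(extract_peak(current, window))

    result = ProtocolResult(
        independent=voltages,
        independent_name="voltage_V",
        values={
            "uptake_slope": np.array(slopes),
            "steady_current": np.array(steadies),
            "peak_current": np.array(peaks),
        },
        meta={
            "concentration_M": concentration,
            "duration_s": duration,
            "transporter": model.transporter_id,
        },
    )

    v_min = float(voltages.min())
    uptake_ref = -0.090 if np.any(np.isclose(voltages, -0.090)) else v_min
    current_ref = -0.060 if np.any(np.isclose(voltages, -0.060)) else v_min
    result.normalize("uptake_slope", uptake_ref)
    for readout in ("steady_current", "peak_current"):
        try:
            result.normalize(readout, current_ref)
        except ZeroDivisionError:
            continue

    for readout, y in result.normalized.items():
        fits = {}
        try:
            fits["line"] = fit_line(voltages, y)
        except (ValueError, RuntimeError):
            pass
        try:
            fits["boltzmann"] = fit_boltzmann(voltages, y)
        except (ValueError, RuntimeError):
            pass
        if "line" in fits and "boltzmann" in fits:
            fits["preferred"] = (
                "boltzmann"
                if fits["boltzmann"].residuals["rss"] < fits["line"].residuals["rss"]
                and not fits["boltzmann"].warnings
                else "line"
            )
        elif fits:
            fits["preferred"] = next(iter(fits))
        result.fits[readout] = fits
    return result


def _recovery_timescale(
    model: TransporterModelSpec,
    conditions: IonConditions,
    V: float,
    constants: PhysicalConstants,
) -> float:
    """Slowest nonzero relaxation rate (s⁻¹) under wash conditions.

    Used only to pick a sensible wash-time grid; the reported catalytic rate
    always comes from the simulated two-pulse data themselves.
    """
    Q = build_generator(model.scheme, conditions, V, constants)
    eig = np.linalg.eigvals(Q)
    rates = np.sort(np.abs(eig.real))
    nonzero = rates[rates > 1e-9]
    return float(nonzero[0]) if nonzero.size else 1.0


def run_two_pulse(
    model: TransporterModelSpec,
    wash_times: np.ndarray | None = None,
    concentration: float = 30e-6,
    V: float = -0.060,
    preset: str | IonConditions = "physiological",
    pulse_duration: float | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> tuple[ProtocolResult, MonoExpFit]:
    """Two-pulse peak-current recovery: the catalytic rate of the cycle.

    A reference substrate pulse recruits transporters into the cycle; after
    a variable wash the test pulse's peak reports how many have completed it.
    The normalized test/reference peak ratio versus wash time is fitted with
    a mono-exponential whose rate estimates the transporter turnover.
    """
    conditions = _resolve_conditions(preset)
    if pulse_duration is None:
        pulse_duration = 2.0 if model.transporter_id == "NET" else 0.5
    if wash_times is None:
        lam = _recovery_timescale(model, conditions, V, constants)
        # floor at 5 solution-exchange time constants: shorter washes leave
        # residual substrate and off-relaxation currents in the test window
        t_min = max(0.05 / lam, 5.0 * ApplicationProtocol(V=V).tau_app)
        wash_times = np.geomspace(t_min, 5.0 / lam, 9)
    wash_times = np.asarray(wash_times, float)
    if np.any(wash_times <= 0):
        raise ValueError("wash times must be positive")

    p0 = steady_state(model.scheme, conditions, V, constants)
    ratios = []
    ref_peak = None
    for wash in wash_times:
        t1_on = PRE_BASELINE_S
        t1_off = t1_on + pulse_duration
        t2_on = t1_off + wash
        t2_off = t2_on + pulse_duration
        protocol = ApplicationProtocol(
            V=V,
            segments=[
                (t1_on, t1_off, {("S", "out"): concentration}),
                (t2_on, t2_off, {("S", "out"): concentration}),
            ],
            t_end=t2_off + 0.1,
        )
        # dense sampling around the pulses, sparse during the wash
        grid = np.unique(
            np.concatenate(
                [
                    np.arange(0.0, t1_off + 0.05, DT_S),
                    np.linspace(t1_off, t2_on, 201),
                    np.arange(t2_on - 0.02, protocol.duration + DT_S / 2, DT_S),
                ]
            )
        )
        traj = integrate_occupancies(
            model.scheme, conditions, protocol, p0=p0, t_grid=grid,
            constants=constants,
        )
        current = total_current(
            traj, model, conditions, V, constants=constants, protocol=protocol
        )
        peak1 = extract_peak(current, (t1_on, t1_off), sign="negative")
        peak2 = extract_peak(current, (t2_on, t2_off), sign="negative")
        if abs(peak1) < 1e-18:
            raise ValueError("reference peak below numeric floor")
        ref_peak = peak1
        ratios.append(peak2 / peak1)

    ratios = np.array(ratios)
    result = ProtocolResult(
        independent=wash_times,
        independent_name="wash_time_s",
        values={"test_peak_ratio": ratios},
        normalized={"test_peak_ratio": ratios},
        reference={"test_peak_ratio": float(ref_peak)},
        meta={
            "V": V,
            "concentration_M": concentration,
            "pulse_duration_s": pulse_duration,
            "transporter": model.transporter_id,
        },
    )
    fit = fit_monoexp(wash_times, ratios)
    result.fits["test_peak_ratio"] = fit
    return result, fit


def run_ion_sweep(
    model_builder,
    presets: list[str],
    protocol: str = "iv",
    builder_kwargs: dict | None = None,
    **protocol_kwargs,
) -> pd.DataFrame:
    """Repeat a protocol across intracellular condition presets.

    ``model_builder`` is one of the ``build_*_model`` callables (or
    equivalent); a fresh model is built per preset so cognate/variant flags
    apply uniformly. Returns a tidy long table: one row per preset ×
    independent-variable value × readout.
    """
    runners = {
        "iv": run_iv,
        "cr": run_concentration_response,
        "two_pulse": lambda m, **kw: run_two_pulse(m, **kw)[0],
    }
    if protocol not in runners:
        raise ValueError(f"unknown protocol {protocol!r}")
    rows = []
    for preset in presets:
        conditions = _resolve_conditions(preset)  # validates the name early
        model = model_builder(**(builder_kwargs or {}))
        result = runners[protocol](model, preset=conditions, **protocol_kwargs)
        name = preset if isinstance(preset, str) else "custom"
        for readout, values in result.values.items():
            normed = result.normalized.get(readout)
            for i, xval in enumerate(result.independent):
                rows.append(
                    {
                        "preset": name,
                        "transporter": model.transporter_id,
                        result.independent_name: float(xval),
                        "readout": readout,
                        "value": float(values[i]),
                        "normalized": float(normed[i]) if normed is not None else np.nan,
                    }
                )
    return pd.DataFrame(rows)
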