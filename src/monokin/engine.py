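"""Master-equation solver for voltage- and ligand-dependent kinetic schemes.

The occupancy vector p(t) obeys dp/dt = Q(t)·p with a generator matrix Q
whose off-diagonal entry Q[j, i] is the effective rate from state i to
state j. Effective rates combine three factors:

* the base rate constant of the transition,
* a symmetric-barrier voltage factor exp(∓zQ·F·V/2RT) (− for the forward
  direction, + for the reverse), and
* for ligand-coupled directions, the concentration of the coupled species
  on the declared membrane side (pseudo-first-order mass action).

External concentrations never step instantaneously: each protocol segment's
targets are approached as exponential relaxations with time constant
``tau_app`` (solution-exchange kinetics of a fast superfusion system).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .scheme import IonConditions, KineticScheme

__all__ = [
    "ApplicationProtocol",
    "OccupancyTrajectory",
    "IntegrationError",
    "voltage_scaled_rate",
    "build_generator",
    "steady_state",
    "integrate_occupancies",
]

OCCUPANCY_TOL = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or probability drifts beyond tolerance."""


def voltage_scaled_rate(
    k0: float,
    zQ: float,
    V: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    direction: str = "fwd",
) -> float:
    """Scale a base rate by the symmetric-barrier Boltzmann factor.

    Forward rates gain exp(−zQ·F·V/2RT); reverse rates the reciprocal
    factor, so the forward×reverse product is voltage-independent.

    Parameters
    ----------
    k0 : base rate constant (s⁻¹, or M⁻¹·s⁻¹ for bimolecular directions).
    zQ : equivalent elementary charge moved inward during the forward step.
    V : membrane voltage (intracellular minus extracellular), volts.
    """
    if not (np.isfinite(k0) and np.isfinite(zQ) and np.isfinite(V)):
        raise ValueError("voltage_scaled_rate requires finite inputs")
    if k0 < 0:
        raise ValueError("base rate must be non-negative")
    if direction not in ("fwd", "rev"):
        raise ValueError(f"direction must be 'fwd' or 'rev', got {direction!r}")
    sign = -1.0 if direction == "fwd" else 1.0
    return k0 * math.exp(sign * zQ * constants.beta_half * V)


@dataclass
class ApplicationProtocol:
    """Voltage-clamp superfusion protocol.

    ``segments`` are non-overlapping, ordered ``(t_start, t_end, targets)``
    triples where ``targets`` maps ``(species, side)`` to a concentration
    target (M). Outside every segment the external solution relaxes back to
    the baseline conditions. All concentration changes follow an exponential
    with time constant ``tau_app`` (s).
    """

    V: float
    segments: list[tuple[float, float, dict[tuple[str, str], float]]] = field(
        default_factory=list
    )
    tau_app: float = 0.010
    t_end: float | None = None

    def __post_init__(self) -> None:
        if self.tau_app <= 0:
            raise ValueError("tau_app must be positive")
        last = -np.inf
        for t0, t1, _targets in self.segments:
            if t1 <= t0:
                raise ValueError("segment end must exceed its start")
            if t0 < last:
                raise ValueError("segments must be ordered and non-overlapping")
            last = t1

    @property
    def duration(self) -> float:
        if self.t_end is not None:
            return self.t_end
        return self.segments[-1][1] if self.segments else 0.0

    def varied_keys(self) -> list[tuple[str, str]]:
        keys: list[tuple[str, str]] = []
        for _t0, _t1, targets in self.segments:
            for key in targets:
                if key not in keys:
                    keys.append(key)
        return keys

    def breakpoints(self) -> list[float]:
        pts = {0.0, self.duration}
        for t0, t1, _ in self.segments:
            pts.add(t0)
            pts.add(t1)
        return sorted(p for p in pts if 0.0 <= p <= self.duration)

    def targets_at(self, t: float) -> dict[tuple[str, str], float] | None:
        """Active segment targets at time ``t`` (None outside segments)."""
        for t0, t1, targets in self.segments:
            if t0 <= t < t1:
                return targets
        return None


@dataclass
class OccupancyTrajectory:
    """Time-resolved state probabilities on a shared grid."""

    time: np.ndarray
    occupancies: np.ndarray  # shape (n_times, n_states)
    state_names: list[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        if self.occupancies.shape != (self.time.size, len(self.state_names)):
            raise ValueError("occupancy matrix shape mismatch")

    def check(self, tol: float = OCCUPANCY_TOL) -> None:
        sums = self.occupancies.sum(axis=1)
        drift = np.max(np.abs(sums - 1.0))
        if drift > tol:
            raise IntegrationError(f"probability drift {drift:.2e} exceeds {tol:.0e}")
        if self.occupancies.min() < -tol or self.occupancies.max() > 1.0 + tol:
            raise IntegrationError("occupancies out of [0, 1] bounds")

    def state(self, name: str) -> np.ndarray:
        return self.occupancies[:, self.state_names.index(name)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancies, columns=self.state_names)
        df.insert(0, "time_s", self.time)
        return df


class GeneratorAssembler:
    """Precompiled structure for fast Q(t) assembly during integration."""

    def __init__(
        self,
        scheme: KineticScheme,
        conditions: IonConditions,
        V: float,
        constants: PhysicalConstants = DEFAULT_CONSTANTS,
        varied_keys: list[tuple[str, str]] | None = None,
    ):
        self.scheme = scheme
        self.n = scheme.n_states
        self.varied_keys = varied_keys or []
        idx = scheme.state_index

        src, dst, base, lig_slot = [], [], [], []
        for tr in scheme.transitions:
            for direction, k0, lig in (
                ("fwd", tr.k0_fwd, tr.ligand_fwd),
                ("rev", tr.k0_rev, tr.ligand_rev),
            ):
                i = idx(tr.from_state) if direction == "fwd" else idx(tr.to_state)
                j = idx(tr.to_state) if direction == "fwd" else idx(tr.from_state)
                k = voltage_scaled_rate(k0, tr.zQ, V, constants, direction)
                slot = -1
                if lig is not None:
                    species, side = lig
                    if (species, side) in self.varied_keys:
                        slot = self.varied_keys.index((species, side))
                    elif (species, side) not in conditions.concentrations:
                        raise ValueError(
                            f"transition {tr.from_state}<->{tr.to_state} couples to "
                            f"species {species!r} ({side}) absent from the ion conditions"
                        )
                    else:
                        k = k * conditions.get(species, side)
                src.append(i)
                dst.append(j)
                base.append(k)
                lig_slot.append(slot)
        self.src = np.array(src, dtype=int)
        self.dst = np.array(dst, dtype=int)
        self.base = np.array(base, dtype=float)
        self.lig_slot = np.array(lig_slot, dtype=int)

    def generator(self, varied_conc: np.ndarray | None = None) -> np.ndarray:
        rates = self.base.copy()
        if varied_conc is not None:
            mask = self.lig_slot >= 0
            rates[mask] *= varied_conc[self.lig_slot[mask]]
        elif np.any(self.lig_slot >= 0):
            raise ValueError("time-varying concentrations required but not supplied")
        Q = np.zeros((self.n, self.n))
        np.add.at(Q, (self.dst, self.src), rates)
        np.subtract.at(Q, (self.src, self.src), rates)
        return Q


def build_generator(
    scheme: KineticScheme,
    conditions: IonConditions,
    V: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Assemble the master-equation generator at fixed conditions.

    Columns sum to zero (probability conservation); off-diagonal entries are
    the non-negative effective rates i→j in Q[j, i].
    """
    asm = GeneratorAssembler(scheme, conditions, V, constants, varied_keys=None)
    return asm.generator()


def steady_state(
    scheme: KineticScheme,
    conditions: IonConditions,
    V: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Stationary occupancy vector: the normalized null space of the generator.

    Raises if the null space is not one-dimensional (disconnected scheme or
    states rendered unreachable by zero concentrations); unreachable states
    are tolerated when a unique probability vector still exists.
    """
    if not scheme.is_connected():
        raise ValueError("steady state undefined: scheme graph is disconnected")
    Q = build_generator(scheme, conditions, V, constants)
    ns = null_space(Q, rcond=1e-12)
    candidates = []
    for k in range(ns.shape[1]):
        v = ns[:, k]
        total = v.sum()
        if abs(total) < 1e-12:
            continue
        v = v / total
        if v.min() >= -1e-9:
            candidates.append(v)
    if ns.shape[1] != 1:
        if len(candidates) == 1:
            v = candidates[0]
            return np.clip(v, 0.0, None) / np.clip(v, 0.0, None).sum()
        raise ValueError(
            f"stationary distribution is not unique (null space dim {ns.shape[1]})"
        )
    if not candidates:
        raise ValueError("null-space vector is not a probability distribution")
    v = np.clip(candidates[0], 0.0, None)
    return v / v.sum()


def _concentration_track(
    protocol: ApplicationProtocol, conditions: IonConditions
) -> tuple[list[float], np.ndarray, np.ndarray]:
    """Per-interval targets and initial values for the varied external species.

    Returns interval start times, the target matrix (n_intervals × n_keys)
    and the concentration at each interval start, propagating the exponential
    relaxation across breakpoints.
    """
    keys = protocol.varied_keys()
    pts = protocol.breakpoints()
    baseline = np.array([conditions.get(sp, side) for sp, side in keys])
    starts = pts[:-1]
    n_int = len(starts)
    targets = np.empty((n_int, len(keys)))
    c_start = np.empty((n_int, len(keys)))
    c_now = baseline.copy()
    for m, t0 in enumerate(starts):
        seg = protocol.targets_at(t0)
        tgt = baseline.copy()
        if seg is not None:
            for k, key in enumerate(keys):
                if key in seg:
                    tgt[k] = seg[key]
        targets[m] = tgt
        c_start[m] = c_now
        dt = pts[m + 1] - t0
        c_now = tgt + (c_now - tgt) * np.exp(-dt / protocol.tau_app)
    return starts + [pts[-1]], targets, c_start


def concentration_profile(
    protocol: ApplicationProtocol,
    conditions: IonConditions,
    t_grid: np.ndarray,
) -> dict[tuple[str, str], np.ndarray]:
    """External concentrations of the protocol-varied species on a grid.

    Reproduces exactly the exponential solution-exchange model the
    integrator uses, so observables computed from these traces are
    consistent with the trajectory.
    """
    t_grid = np.asarray(t_grid, float)
    keys = protocol.varied_keys()
    boundaries, targets, c_start = _concentration_track(protocol, conditions)
    out = {key: np.empty(t_grid.size) for key in keys}
    for m in range(len(boundaries) - 1):
        t0, t1 = boundaries[m], boundaries[m + 1]
        last = m == len(boundaries) - 2
        mask = (t_grid >= t0 - 1e-12) & (
            (t_grid <= t1 + 1e-12) if last else (t_grid < t1)
        )
        if not mask.any():
            continue
        decay = np.exp(-(t_grid[mask] - t0) / protocol.tau_app)
        for k, key in enumerate(keys):
            out[key][mask] = targets[m, k] + (c_start[m, k] - targets[m, k]) * decay
    return out


def integrate_occupancies(
    scheme: KineticScheme,
    conditions: IonConditions,
    protocol: ApplicationProtocol,
    p0: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OccupancyTrajectory:
    """Integrate dp/dt = Q(t)·p over the protocol with a stiff solver.

    ``p0`` defaults to the steady state at the holding voltage in the
    baseline (pre-application) conditions. Occupancies are returned raw —
    conservation is verified, not enforced, and drift beyond 1e−6 raises
    :class:`IntegrationError`.
    """
    if p0 is None:
        p0 = steady_state(scheme, conditions, protocol.V, constants)
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-8:
        raise ValueError("initial occupancies must sum to 1")
    if t_grid is None:
        t_grid = np.arange(0.0, protocol.duration + 1e-12, 0.001)
    t_grid = np.asarray(t_grid, dtype=float)

    keys = protocol.varied_keys()
    asm = GeneratorAssembler(scheme, conditions, protocol.V, constants, varied_keys=keys)
    boundaries, targets, c_start = _concentration_track(protocol, conditions)

    tau = protocol.tau_app
    out = np.empty((t_grid.size, scheme.n_states))
    p = p0.copy()
    for m in range(len(boundaries) - 1):
        t0, t1 = boundaries[m], boundaries[m + 1]
        tgt, c0 = targets[m], c_start[m]

        if keys:

            def conc(t: float) -> np.ndarray:
                return tgt + (c0 - tgt) * np.exp(-(t - t0) / tau)

            rhs = lambda t, y: asm.generator(conc(t)) @ y  # noqa: E731
            jac = lambda t, y: asm.generator(conc(t))  # noqa: E731
        else:
            Q = asm.generator(None) if not np.any(asm.lig_slot >= 0) else None
            rhs = lambda t, y: Q @ y  # noqa: E731
            jac = lambda t, y: Q  # noqa: E731

        if m == len(boundaries) - 2:  # absorb float fuzz on the final grid point
            mask = (t_grid >= t0) & (t_grid <= t1 + 1e-9)
            t_eval = np.minimum(t_grid[mask], t1)
        else:
            mask = (t_grid >= t0) & (t_grid <= t1)
            t_eval = t_grid[mask]
        sol = solve_ivp(
            rhs,
            (t0, t1),
            p,
            method="LSODA",
            jac=jac,
            t_eval=t_eval if t_eval.size else None,
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{t0:.4g}, {t1:.4g}] s: {sol.message}"
            )
        if t_eval.size:
            out[mask] = sol.y.T
        # continue from the exact segment boundary, not the last output point
        p = sol.sol(t1)

    traj = OccupancyTrajectory(time=t_grid, occupancies=out, state_names=scheme.state_names)
    traj.check()
    return traj
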