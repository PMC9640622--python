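"""Zero-dimensional excitable signal-relay unit (Schmitt trigger).

Each agent carries a two-variable signaling circuit: a chemical signal
concentration ``c`` and an internal refractoriness state ``s``.  The unit is
quiescent at ``(c, s) = (0, 0)``; a super-threshold signal input triggers a
large, stereotyped excursion in phase space (signal emission) followed by a
slow refractory recovery at rate ``epsilon``.  The detection threshold rises
linearly with the refractoriness, ``c_th(s) = (s + b) / a``, and the emission
rate falls linearly, ``beta * (1 - s)`` — together these implement a
threshold element with hysteresis.

The well-mixed dynamics is

    ds/dt = epsilon * (c - s)
    dc/dt = -alpha * c + beta * (1 - s) * Theta(c - c_th(s))

with a strict Heaviside function ``Theta`` (``Theta(0) = 0``).  A relaxation
(fast excitation, slow recovery) response requires ``beta / epsilon >> 1``.

The same threshold/production nonlinearity is reused by the spatial
simulators (:mod:`commswarm.abm`, :mod:`commswarm.hydro`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SignalingParams",
    "ExcitableState",
    "Trajectory",
    "ResponseSummary",
    "ParameterError",
    "IntegrationError",
    "threshold_c_th",
    "production_phi",
    "step_well_mixed",
    "simulate_response",
    "response_summary",
    "write_trajectory",
]


class ParameterError(ValueError):
    """A signaling/model parameter violates its validity constraints."""


class IntegrationError(RuntimeError):
    """Time integration produced non-finite values."""


@dataclass(frozen=True)
class SignalingParams:
    """Rate constants of the excitable relay unit.

    Parameters
    ----------
    alpha : float
        Signal degradation rate (1/time).
    beta : float
        Signal release rate (concentration/time).
    epsilon : float
        Relaxation rate of the refractoriness state (1/time).  The
        refractory period scales as ``1 / epsilon``.
    a : float
        Inverse slope of the detection threshold (dimensionless, > 0).
    b : float
        Baseline threshold offset (dimensionless, >= 0); the quiescent-state
        threshold is ``b / a``.
    """

    alpha: float = 1.0
    beta: float = 5.0
    epsilon: float = 0.05
    a: float = 0.5
    b: float = 0.2

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ParameterError(f"threshold slope parameter a must be > 0, got {self.a}")
        for name in ("alpha", "beta", "epsilon"):
            if getattr(self, name) < 0:
                raise ParameterError(f"rate {name} must be >= 0, got {getattr(self, name)}")
        if self.b < 0:
            raise ParameterError(f"threshold offset b must be >= 0, got {self.b}")
        if self.epsilon > 0 and self.beta / self.epsilon < 10:
            warnings.warn(
                "beta/epsilon = %.3g < 10: response is not of relaxation type "
                "(fast emission, slow recovery requires beta/epsilon >> 1)"
                % (self.beta / self.epsilon),
                stacklevel=2,
            )


@dataclass(frozen=True)
class ExcitableState:
    """Instantaneous state (signal concentration, refractoriness)."""

    c: float
    s: float


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered trajectory of the well-mixed unit."""

    t: np.ndarray
    c: np.ndarray
    s: np.ndarray
    producing: np.ndarray  # bool: was the production term active at this step

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ResponseSummary:
    classification: str  # "decay" | "excursion"
    peak_c: float
    refractory_duration: float


def threshold_c_th(s, params: SignalingParams):
    """State-dependent detection threshold ``c_th(s) = (s + b) / a``.

    Strictly increasing in the refractoriness ``s`` with slope ``1/a``;
    the quiescent threshold is ``c_th(0) = b/a``.
    """
    return (np.asarray(s) + params.b) / params.a if np.ndim(s) else (s + params.b) / params.a


def production_phi(s, c, params: SignalingParams):
    """Signal source rate ``beta * (1 - s) * Theta(c - c_th(s))``.

    The Heaviside factor is strict: exactly at threshold the unit does not
    emit.  Returns a scalar or array matching the inputs.
    """
    active = np.greater(c, threshold_c_th(s, params))
    out = params.beta * (1.0 - np.asarray(s, dtype=float)) * active
    return out if np.ndim(out) else float(out)


def step_well_mixed(
    state: ExcitableState,
    params: SignalingParams,
    dt: float,
    *,
    stability: str = "warn",
) -> ExcitableState:
    """One forward-Euler update of the well-mixed two-component dynamics.

    Uses the state at the beginning of the step for both right-hand sides, so
    the quiescent fixed point ``(0, 0)`` maps exactly to ``(0, 0)`` (the
    production term is exactly zero below threshold, with no floating drift).

    The guard ``dt * max(alpha, epsilon) < 0.1`` keeps the explicit scheme
    well inside its stability/accuracy region; violations warn or raise per
    ``stability`` ("warn" | "error").
    """
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    if dt * max(params.alpha, params.epsilon) >= 0.1:
        msg = (
            f"dt*max(alpha, epsilon) = {dt * max(params.alpha, params.epsilon):.3g} "
            ">= 0.1: forward-Euler step too coarse"
        )
        if stability == "error":
            raise ParameterError(msg)
        warnings.warn(msg, stacklevel=2)
    c, s = state.c, state.s
    c_new = c + dt * (-params.alpha * c + production_phi(s, c, params))
    s_new = s + dt * params.epsilon * (c - s)
    return ExcitableState(c=c_new, s=s_new)


def simulate_response(
    c_in: float,
    params: SignalingParams,
    t_max: float,
    dt: float,
    *,
    s_in: float = 0.0,
    stability: str = "warn",
) -> Trajectory:
    """Integrate the unit from ``(c_in, s_in)`` for ``t_max`` time units.

    Forward Euler with step ``dt``; records at every step whether the
    production term was active (used by :func:`response_summary` to locate
    the refractory window).  For ``t_max >> 1/epsilon`` the terminal state
    returns to the quiescent fixed point.
    """
    if c_in < 0:
        raise ParameterError(f"c_in must be >= 0, got {c_in}")
    n = int(round(t_max / dt))
    t = np.arange(n + 1) * dt
    c = np.empty(n + 1)
    s = np.empty(n + 1)
    producing = np.zeros(n + 1, dtype=bool)
    c[0], s[0] = c_in, s_in
    # guard once, not per step
    step_kw = {"stability": stability}
    if dt * max(params.alpha, params.epsilon) >= 0.1:
        step_well_mixed(ExcitableState(c_in, s_in), params, dt, **step_kw)  # emit warn/raise
    for i in range(n):
        ci, si = c[i], s[i]
        phi = params.beta * (1.0 - si) if ci > (si + params.b) / params.a else 0.0
        producing[i] = phi > 0.0
        c[i + 1] = ci + dt * (-params.alpha * ci + phi)
        s[i + 1] = si + dt * params.epsilon * (ci - si)
        if not (np.isfinite(c[i + 1]) and np.isfinite(s[i + 1])):
            raise IntegrationError(
                f"non-finite state at step {i + 1} (t = {t[i + 1]:.6g}): "
                f"c = {c[i + 1]}, s = {s[i + 1]}"
            )
    producing[n] = c[n] > (s[n] + params.b) / params.a and s[n] < 1.0
    return Trajectory(t=t, c=c, s=s, producing=producing)


def response_summary(traj: Trajectory, *, reexcite_frac: float = 0.05) -> ResponseSummary:
    """Classify a trajectory and measure its peak and refractory period.

    An *excursion* is any trajectory on which production was triggered;
    otherwise the input simply decays.  The refractory duration is measured
    from the last production step until the refractoriness ``s`` first falls
    below ``reexcite_frac`` times its peak value — a configurable
    re-excitability criterion (the recovery time scales as ``1/epsilon``
    regardless of the exact fraction).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    peak_c = float(np.max(traj.c))
    if not traj.producing.any():
        return ResponseSummary("decay", peak_c, 0.0)
    i_last = int(np.nonzero(traj.producing)[0][-1])
    peak_s = float(np.max(traj.s))
    below = np.nonzero((traj.s < reexcite_frac * peak_s) & (np.arange(len(traj)) > i_last))[0]
    if len(below) == 0:
        # never recovered within the window; report the remaining time
        duration = float(traj.t[-1] - traj.t[i_last])
    else:
        duration = float(traj.t[below[0]] - traj.t[i_last])
    return ResponseSummary("excursion", peak_c, duration)


def write_trajectory(traj: Trajectory, path) -> None:
    """Export a trajectory as tab-delimited text (t, c, s)."""
    with open(path, "w") as fh:
        fh.write("t\tc\ts\n")
        for t, c, s in zip(traj.t, traj.c, traj.s):
            fh.write(f"{t:.10g}\t{c:.10g}\t{s:.10g}\n")
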