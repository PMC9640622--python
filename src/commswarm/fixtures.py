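"""Synthetic fixtures: planted cluster fields, coarsening curves and
information traces with known ground truth.

These generators define controlled test surfaces for the analysis modules:
planted droplet/stream/vortex fields whose class labels follow from their
construction, cluster-number series drawn from a chosen coarsening law,
and information traces generated from the processing-rate model with a
known decay rate.  Optional noise emulates measurement scatter; the
generators do not emulate the spatial correlations, interfaces or wave
structure of real simulation output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .information import predict_information
from .signaling import ParameterError

__all__ = ["PlantedField", "make_fixtures"]

KINDS = ("planted_vortex", "planted_stream", "planted_droplet",
         "coarsening_series", "info_trace")


@dataclass
class PlantedField:
    """A density/polarity field pair with known dominant-cluster class."""

    rho: np.ndarray
    p: np.ndarray  # (M, M, 2)
    L: float
    expected_class: str


def _grid(M: int, L: float):
    x = np.arange(M) * (L / M)
    X, Y = np.meshgrid(x, x, indexing="ij")
    return X, Y


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def make_fixtures(kind: str, params: dict | None = None, seed: int = 0):
    """Generate one synthetic fixture of the requested kind.

    planted_* kinds return a :class:`PlantedField` (background density 0.6,
    a planted aggregate of density 1.5); ``coarsening_series`` returns
    ``(t, N_c)`` drawn from a power/stream/log law; ``info_trace`` returns
    ``(t, I, R)`` generated from ``dI/dt = gamma_R R - lambda I``.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind.startswith("planted_"):
        return _planted(kind, p, rng)
    if kind == "coarsening_series":
        return _coarsening_series(p, rng)
    return _info_trace(p, rng)


def _planted(kind: str, p: dict, rng) -> PlantedField:
    M = int(p.get("M", 128))
    L = float(p.get("L", 128.0))
    background = float(p.get("background", 0.6))
    rho_in = float(p.get("rho_in", 1.5))
    noise = float(p.get("noise", 0.0))
    X, Y = _grid(M, L)
    cx, cy = p.get("center", (L / 2, L / 2))
    dx = _min_image(X - cx, L)
    dy = _min_image(Y - cy, L)
    rho = np.full((M, M), background)
    pol = np.zeros((M, M, 2))
    if kind == "planted_stream":
        theta = float(p.get("orientation", 0.0))  # radians
        sig_u = float(p.get("sigma_major", 8.0))
        sig_v = float(p.get("sigma_minor", 2.0))
        if sig_u <= sig_v:
            raise ParameterError("stream fixture needs sigma_major > sigma_minor")
        if 6 * sig_u > L:
            raise ParameterError(f"stream length {6 * sig_u:.3g} does not fit in L = {L}")
        u = np.cos(theta) * dx + np.sin(theta) * dy
        v = -np.sin(theta) * dx + np.cos(theta) * dy
        amp = rho_in - background + 0.5  # comfortably super-threshold core
        rho = background + amp * np.exp(-0.5 * (u**2 / sig_u**2 + v**2 / sig_v**2))
        ridge = np.exp(-0.5 * (u**2 / sig_u**2 + v**2 / sig_v**2)) > 0.05
        pol[..., 0] = np.where(ridge, np.cos(theta), 0.0)
        pol[..., 1] = np.where(ridge, np.sin(theta), 0.0)
        expected = "stream"
    else:
        radius = float(p.get("radius", 10.0))
        if radius >= L / 2:
            raise ParameterError(f"disc radius {radius} must be < L/2 = {L / 2}")
        r = np.hypot(dx, dy)
        inside = r < radius
        rho[inside] = rho_in
        if kind == "planted_vortex":
            amp = float(p.get("p_amplitude", 0.5))
            # rigid azimuthal rotation: curl = 2*amp/radius inside the disc
            pol[..., 0] = np.where(inside, -amp * dy / radius, 0.0)
            pol[..., 1] = np.where(inside, amp * dx / radius, 0.0)
            expected = "vortex"
        else:
            expected = "droplet"
    if noise > 0:
        rho = rho + noise * rng.standard_normal((M, M))
        pol = pol + noise * rng.standard_normal((M, M, 2))
    return PlantedField(rho=rho, p=pol, L=L, expected_class=expected)


def _coarsening_series(p: dict, rng):
    law = p.get("law", "power")
    t = np.asarray(
        p.get("t", np.geomspace(p.get("t0", 1.0), p.get("t1", 1e3),
                                int(p.get("n", 200)))),
        dtype=float,
    )
    if law == "power":
        n_c = p.get("A", 1000.0) * t ** (-p.get("eta", 1.0))
    elif law == "stream":
        n_c = (p.get("N0", 1000.0) - p.get("kappa", 0.01) * t**2) / t
        if np.any(n_c <= 0):
            raise ParameterError("stream-law fixture produced non-positive counts; "
                                 "shrink the time range or kappa")
    elif law == "log":
        if np.any(t <= 1.0):
            raise ParameterError("log-law fixture requires t > 1")
        n_c = p.get("A", 1000.0) / np.log(t)
    else:
        raise ValueError(f"unknown coarsening law {law!r}")
    noise = float(p.get("noise", 0.0))
    if noise > 0:
        n_c = n_c * (1.0 + noise * rng.standard_normal(len(t)))
    return t, n_c


def _info_trace(p: dict, rng):
    lam = float(p.get("lam", 0.01))
    gamma_R = float(p.get("gamma_R", 1.0))
    I0 = float(p.get("I0", 1000.0))
    T = float(p.get("T", 2000.0))
    n = int(p.get("n", 201))
    t = np.linspace(0.0, T, n)
    if "R" in p:
        R = np.asarray(p["R"], dtype=float)
        if len(R) != n:
            raise ParameterError("supplied R must match the sample count")
    else:
        R = float(p.get("R0", 5.0)) * np.exp(-t / float(p.get("tau_R", T / 4)))
    I = predict_information(I0, t, R, lam, gamma_R)
    noise = float(p.get("noise", 0.0))
    if noise > 0:
        I = I * (1.0 + noise * rng.standard_normal(n))
    return t, I, R
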