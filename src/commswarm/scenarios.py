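"""Scaled-down demonstration scenarios for the hydrodynamic model.

Production-scale aggregation runs (domains of several hundred units over
tens of thousands of time units) develop spiral-wave pacemakers and vortex
aggregates spontaneously.  Desk-scale domains do not reach that regime by
brute force: the continuum model has no fluctuations, so once the initial
excitation fronts annihilate, signaling is silent; and the spiral
wavelength set by the refractory period is comparable to a 128-unit box,
so free spirals are short-lived.  The scenarios here therefore prepare the
configurations the long transient would produce — bulk excitation kernels
with broken (spiral-seeded) fronts, and a dense ring aggregate carrying a
circulating ("whispering-gallery") signaling pulse — and let the model
evolve them.  Everything downstream (wave propagation, chemotactic mass
transport, droplet ripening, stream formation, rotational imprinting of
the polarity and vortex formation) is the model's own dynamics.
"""

from __future__ import annotations

import numpy as np

from .hydro import HydroFields, HydroParams, KernelSpec, init_fields

__all__ = [
    "vortex_regime_params",
    "add_ring_excitation",
    "vortex_regime_demo",
]


def vortex_regime_params(**overrides) -> HydroParams:
    """Parameter point in the vortex-forming regime of the phase diagram:
    low motility, signal susceptibility strong enough that chemotactic
    transport outweighs self-propulsion.

    Polar relaxation is set to an intermediate rate (sigma = 0.1) with weak
    cubic saturation (delta = 0.02), so aggregates above the critical
    density develop and retain substantial polar order within a few
    hundred time units; signaling rates give pulse widths of a few length
    units at the default 1-unit grid spacing.
    """
    base = dict(v0=0.2, omega=0.2, D_c=0.25, epsilon=0.1, alpha=1.0,
                beta=5.0, sigma=0.1, delta=0.02, D_p=0.05, D_rho=0.1,
                chi=0.01)
    base.update(overrides)
    return HydroParams(**base)


def add_ring_excitation(
    fields: HydroFields,
    center: tuple,
    *,
    radius: float = 20.0,
    width: float = 4.0,
    rho_boost: float = 0.9,
    pulse_c: float = 1.0,
    wake_s: float = 0.85,
) -> HydroFields:
    """Plant a dense annular aggregate carrying a circulating pulse.

    The ring density is raised by ``rho_boost``; one angular sector of the
    ring is excited (``c = pulse_c``) with a refractory wake behind it
    (``s = wake_s``), so the pulse can only run one way around the ring —
    the whispering-gallery mode that stabilizes ring-shaped aggregates.
    The circulating wave drags the local polarity tangentially; because
    the ring is above the critical density, that rotation is retained
    after the wave ends and the collapsing aggregate is left rotating (a
    vortex in the classifier's sense).

    Modifies and returns ``fields``.  Note the added mass changes the
    domain mean of rho (it is a planted aggregate, not noise).
    """
    M, L = fields.M, fields.L
    x = np.arange(M) * L / M
    X, Y = np.meshgrid(x, x, indexing="ij")
    dx = X - center[0]
    dx -= L * np.round(dx / L)
    dy = Y - center[1]
    dy -= L * np.round(dy / L)
    r = np.hypot(dx, dy)
    th = np.arctan2(dy, dx)
    ring = np.abs(r - radius) < width
    fields.rho = fields.rho + np.where(ring, rho_boost, 0.0)
    pulse = ring & (np.abs(th) < 0.5)
    wake = ring & (th < -0.5) & (th > -1.8)
    fields.c = fields.c.copy()
    fields.c[pulse] = np.maximum(fields.c[pulse], pulse_c)
    fields.s = fields.s.copy()
    fields.s[wake] = np.maximum(fields.s[wake], wake_s)
    return fields


def vortex_regime_demo(seed: int, *, M: int = 128, L: float = 128.0,
                       rho0: float = 0.6, n_kernels: int = 6) -> tuple:
    """Initial state for the scaled-down aggregation demonstration.

    A homogeneous sub-critical background (``rho0 = 0.6``) with
    spiral-seeded excitation kernels in the bulk (these nucleate droplets
    and streams) plus one ring aggregate with a circulating pulse (the
    proto-vortex).  Returns ``(params, fields)`` ready for
    :func:`commswarm.hydro.run_hydro`.
    """
    params = vortex_regime_params()
    kernels = KernelSpec(count=n_kernels, amplitude=2 * params.b / params.a,
                         length_range=(12, 20), width=3.0, spiral_seed=True)
    fields = init_fields(params, M, L, rho0, kernels=kernels, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    center = tuple(rng.uniform(0.3 * L, 0.7 * L, size=2))
    add_ring_excitation(fields, center)
    return params, fields
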