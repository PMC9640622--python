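"""Agent-based simulator for communicating self-propelled particles.

``N`` disk-shaped agents of radius ``r_p`` move at constant speed ``v0`` in a
periodic square of side ``L``.  Headings evolve by a Langevin equation
combining polar alignment with neighbors (rate ``Gamma``, weighted by the
inverse pair distance, within radius ``r_c``), chemotactic alignment along
the gradient of a chemical signal field (susceptibility ``omega``), and
rotational diffusion ``D_R``.  Overlapping agents are pushed apart
symmetrically until hard-core contact at distance ``2 r_p`` is restored.

Each agent carries the excitable relay unit of :mod:`commswarm.signaling`:
above its state-dependent threshold it deposits a Gaussian signal source of
width ``w = 2 r_p`` and total strength ``beta * (1 - s)``; the signal field
diffuses (``D_c``), degrades (``alpha``) and is integrated spectrally by a
per-mode forward-Euler step.  Internal states relax toward the locally
sampled signal at rate ``epsilon``.

Update order per time step (position update -> source deposition -> field
step -> state step) follows the reference scheme of the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._spectral import (
    bilinear_sample,
    cic_deposit,
    gaussian_filter_hat,
    rfft2_wavenumbers,
)
from .signaling import ParameterError, SignalingParams

__all__ = [
    "ABMParams",
    "AgentEnsemble",
    "SignalGrid",
    "ABMSnapshot",
    "init_agents",
    "neighbor_pairs",
    "resolve_overlaps",
    "sample_signal",
    "step_agents",
    "deposit_sources",
    "step_signal_field",
    "run_abm",
    "density_from_agents",
    "wrap_angle",
]

#: gradient-magnitude floor below which the chemotactic direction is
#: considered undefined and the chemotactic torque is suppressed
G_MIN = 1e-12


def wrap_angle(phi):
    """Wrap angles to the interval (-pi, pi]; in-range values pass through
    bit-exactly."""
    phi = np.asarray(phi, dtype=float)
    return phi - 2.0 * np.pi * np.ceil((phi - np.pi) / (2.0 * np.pi))


@dataclass(frozen=True)
class ABMParams:
    """Parameters of the agent-based model (repo defaults unless noted).

    ``v0`` self-propulsion speed; ``Gamma`` alignment rate (torque weighted
    by 1/r); ``omega`` chemotactic susceptibility; ``D_R`` rotational
    diffusion; ``r_p`` particle radius; ``r_c`` alignment radius; ``L``
    domain side; ``N`` agent count; ``dt`` time step; ``M`` Fourier modes
    per direction; ``D_c`` signal diffusion; ``w`` source width (defaults to
    ``2 r_p``).
    """

    v0: float = 0.5
    Gamma: float = 0.1
    omega: float = 0.5
    D_R: float = 0.05
    r_p: float = 0.5
    r_c: float = 1.5
    L: float = 200.0
    N: int = 4000
    dt: float = 0.01
    M: int = 200
    D_c: float = 5.0
    w: float | None = None
    signaling: SignalingParams = field(default_factory=SignalingParams)

    def __post_init__(self) -> None:
        if self.r_c <= 2 * self.r_p:
            raise ParameterError(
                f"alignment radius r_c = {self.r_c} must exceed the contact "
                f"distance 2*r_p = {2 * self.r_p}"
            )
        if self.w is None:
            object.__setattr__(self, "w", 2.0 * self.r_p)
        if self.w < self.L / self.M:
            warnings.warn(
                f"source width w = {self.w} is below one grid cell "
                f"({self.L / self.M:.3g}); the Gaussian source is under-resolved",
                stacklevel=2,
            )
        if self.v0 > 0 and self.D_c / (self.r_p * self.v0) < 1.0:
            warnings.warn(
                "D_c/(r_p*v0) = %.3g < 1: signal diffusion is not fast compared "
                "to self-propulsion" % (self.D_c / (self.r_p * self.v0)),
                stacklevel=2,
            )

    @property
    def dx(self) -> float:
        return self.L / self.M


@dataclass
class AgentEnsemble:
    """Positions in [0, L)^2, headings in (-pi, pi], refractoriness states."""

    positions: np.ndarray  # (N, 2)
    headings: np.ndarray  # (N,)
    states: np.ndarray  # (N,)

    @property
    def n(self) -> np.ndarray:
        """Unit heading vectors, shape (N, 2)."""
        return np.stack([np.cos(self.headings), np.sin(self.headings)], axis=1)

    def copy(self) -> "AgentEnsemble":
        return AgentEnsemble(
            self.positions.copy(), self.headings.copy(), self.states.copy()
        )


@dataclass
class SignalGrid:
    """Signal concentration on the M x M periodic grid."""

    c: np.ndarray
    L: float

    @property
    def M(self) -> int:
        return self.c.shape[0]

    def copy(self) -> "SignalGrid":
        return SignalGrid(self.c.copy(), self.L)

    @classmethod
    def zeros(cls, M: int, L: float) -> "SignalGrid":
        return cls(np.zeros((M, M)), L)


@dataclass
class ABMSnapshot:
    t: float
    ensemble: AgentEnsemble
    grid: SignalGrid


def init_agents(params: ABMParams, seed: int) -> AgentEnsemble:
    """Uniformly random positions and headings, quiescent states.

    Deterministic given the seed.  Raises if the requested packing fraction
    exceeds 0.9 (hard cores cannot be accommodated).
    """
    if params.N < 1:
        raise ParameterError(f"N must be >= 1, got {params.N}")
    if params.N * np.pi * params.r_p**2 > 0.9 * params.L**2:
        raise ParameterError(
            f"packing infeasible: N*pi*r_p^2 = {params.N * np.pi * params.r_p**2:.3g} "
            f"> 0.9 * L^2 = {0.9 * params.L**2:.3g}"
        )
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, params.L, size=(params.N, 2))
    headings = wrap_angle(rng.uniform(-np.pi, np.pi, size=params.N))
    states = np.zeros(params.N)
    return AgentEnsemble(positions, headings, states)


def neighbor_pairs(
    ensemble: AgentEnsemble, cutoff: float, params: ABMParams
) -> np.ndarray:
    """Index pairs (i < j) with minimum-image distance strictly < cutoff.

    Backed by a periodic k-d tree (the classic virtual-grid cell list with a
    better constant); pairs at exactly the cutoff are excluded.
    """
    if cutoff > params.L / 2:
        raise ParameterError(
            f"cutoff {cutoff} exceeds L/2 = {params.L / 2}; minimum-image "
            "convention invalid"
        )
    pos = np.mod(ensemble.positions, params.L)
    tree = cKDTree(pos, boxsize=params.L)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    d = _min_image_dist(pos[pairs[:, 0]], pos[pairs[:, 1]], params.L)
    return pairs[d < cutoff]


def _min_image_vec(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    """Minimum-image displacement a - b."""
    d = a - b
    d -= L * np.round(d / L)
    return d


def _min_image_dist(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    return np.linalg.norm(_min_image_vec(a, b, L), axis=-1)


def resolve_overlaps(
    ensemble: AgentEnsemble,
    params: ABMParams,
    *,
    max_sweeps: int = 10,
) -> AgentEnsemble:
    """Restore the hard-core constraint by symmetric pairwise shifts.

    Each overlapping pair (minimum-image distance < ``2 r_p``) is shifted
    apart along its distance vector by equal amounts until contact distance
    is exactly restored.  Pairs are processed sequentially in ascending
    (i, j) order; sweeps repeat until no overlap remains or ``max_sweeps``
    is reached (residual overlap then warns with the worst violation).
    """
    contact = 2.0 * params.r_p
    pos = np.mod(ensemble.positions.copy(), params.L)
    for _ in range(max_sweeps):
        pairs = neighbor_pairs(
            AgentEnsemble(pos, ensemble.headings, ensemble.states),
            min(contact, params.L / 2),
            params,
        )
        if len(pairs) == 0:
            break
        # ascending (i, j) order, sequential so later pairs see fresh positions
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        moved = False
        for i, j in pairs[order]:
            d = _min_image_vec(pos[i], pos[j], params.L)
            r = float(np.hypot(d[0], d[1]))
            if r >= contact - 1e-7 * params.r_p:  # rounding-level residuals pass
                continue
            if r < 1e-12:  # coincident: deterministic tie-break along x
                u = np.array([1.0, 0.0])
            else:
                u = d / r
            shift = 0.5 * (contact - r)
            pos[i] = (pos[i] + shift * u) % params.L
            pos[j] = (pos[j] - shift * u) % params.L
            moved = True
        if not moved:
            break
    else:
        pairs = neighbor_pairs(
            AgentEnsemble(pos, ensemble.headings, ensemble.states),
            min(contact, params.L / 2),
            params,
        )
        if len(pairs):
            d = _min_image_dist(pos[pairs[:, 0]], pos[pairs[:, 1]], params.L)
            if contact - d.min() > 1e-7 * params.r_p:
                warnings.warn(
                    f"overlap resolution hit sweep cap ({max_sweeps}); worst "
                    f"residual overlap {contact - d.min():.3g}",
                    stacklevel=2,
                )
    return AgentEnsemble(pos, ensemble.headings, ensemble.states)


def sample_signal(grid: SignalGrid, positions: np.ndarray):
    """Signal value, gradient and gradient direction at agent positions.

    The gradient is computed spectrally on the grid and bilinearly
    interpolated to the (off-grid) agent positions.  Where the gradient
    magnitude is below ``G_MIN`` the direction angle ``phi_c`` is undefined
    (flagged False in the returned mask) and set to 0.

    Returns ``(c_values, gradients (N, 2), phi_c, defined_mask)``.
    """
    if not np.all(np.isfinite(grid.c)):
        raise IntegrationErrorLike("signal grid contains non-finite values")
    M, L = grid.M, grid.L
    kx, ky = rfft2_wavenumbers(M, L)
    ch = np.fft.rfft2(grid.c)
    gx = np.fft.irfft2(1j * kx * ch, s=grid.c.shape)
    gy = np.fft.irfft2(1j * ky * ch, s=grid.c.shape)
    c_i = bilinear_sample(grid.c, positions, L)
    gx_i = bilinear_sample(gx, positions, L)
    gy_i = bilinear_sample(gy, positions, L)
    grad = np.stack([gx_i, gy_i], axis=1)
    mag = np.hypot(gx_i, gy_i)
    defined = mag > G_MIN
    phi_c = np.where(defined, np.arctan2(gy_i, gx_i), 0.0)
    return c_i, grad, phi_c, defined


class IntegrationErrorLike(RuntimeError):
    pass


def _heading_update(
    ensemble: AgentEnsemble,
    grid: SignalGrid,
    params: ABMParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Euler-Maruyama heading increment (alignment + chemotaxis + noise)."""
    N = len(ensemble.headings)
    torque = np.zeros(N)
    if params.Gamma != 0.0:
        pairs = neighbor_pairs(ensemble, params.r_c, params)
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            rij = _min_image_dist(
                ensemble.positions[i], ensemble.positions[j], params.L
            )
            sin_ij = np.sin(ensemble.headings[i] - ensemble.headings[j]) / rij
            np.add.at(torque, i, -params.Gamma * sin_ij)
            np.add.at(torque, j, +params.Gamma * sin_ij)
    if params.omega != 0.0:
        _, _, phi_c, defined = sample_signal(grid, ensemble.positions)
        torque += np.where(
            defined, params.omega * np.sin(phi_c - ensemble.headings), 0.0
        )
    noise = np.sqrt(2.0 * params.D_R * params.dt) * rng.standard_normal(N)
    return torque * params.dt + noise


def step_agents(
    ensemble: AgentEnsemble,
    grid: SignalGrid,
    params: ABMParams,
    rng: np.random.Generator,
    *,
    update_states: bool = True,
) -> AgentEnsemble:
    """Advance agents by one time step against a fixed signal field.

    Headings get the alignment/chemotaxis torque plus rotational noise,
    positions stream with ``v0`` and are wrapped, overlaps are resolved, and
    (optionally) the refractoriness states relax toward the signal sampled
    at the updated positions.
    """
    dphi = _heading_update(ensemble, grid, params, rng)
    headings = wrap_angle(ensemble.headings + dphi)
    n = np.stack([np.cos(headings), np.sin(headings)], axis=1)
    positions = np.mod(ensemble.positions + params.v0 * params.dt * n, params.L)
    out = resolve_overlaps(
        AgentEnsemble(positions, headings, ensemble.states.copy()), params
    )
    if update_states:
        c_i = bilinear_sample(grid.c, out.positions, params.L)
        out.states = out.states + params.dt * params.signaling.epsilon * (
            c_i - out.states
        )
    if not (np.all(np.isfinite(out.positions)) and np.all(np.isfinite(out.headings))):
        bad = np.nonzero(
            ~(np.isfinite(out.positions).all(axis=1) & np.isfinite(out.headings))
        )[0]
        raise IntegrationErrorLike(f"non-finite agent update for indices {bad[:10]}")
    return out


def deposit_sources(
    ensemble: AgentEnsemble, grid: SignalGrid, params: ABMParams
) -> np.ndarray:
    """Gaussian signal sources of the currently emitting agents.

    An agent emits iff the locally sampled signal strictly exceeds its
    state-dependent threshold ``(s + b)/a``; it then contributes a
    periodically wrapped normalized Gaussian of width ``w`` and integral
    ``beta * (1 - s)`` (mass-conserving cloud-in-cell deposition followed by
    a spectral Gaussian filter whose k = 0 gain is exactly 1).
    """
    sp = params.signaling
    c_i = bilinear_sample(grid.c, ensemble.positions, params.L)
    active = c_i > (ensemble.states + sp.b) / sp.a
    if not active.any():
        return np.zeros((params.M, params.M))
    weights = np.where(active, sp.beta * (1.0 - ensemble.states), 0.0)
    raw = cic_deposit(
        ensemble.positions[active], weights[active], params.M, params.L
    )
    ghat = gaussian_filter_hat(params.M, params.L, params.w)
    return np.fft.irfft2(np.fft.rfft2(raw) * ghat, s=raw.shape)


def step_signal_field(
    grid: SignalGrid, source: np.ndarray, params: ABMParams
) -> SignalGrid:
    """One forward-Euler step of the signal field, diagonal in Fourier space.

    Per mode: ``c_hat <- c_hat * (1 - dt*(D_c k^2 + alpha)) + dt * s_hat``.
    With no sources the spatial mean therefore decays by exactly
    ``(1 - alpha*dt)`` per step.  Raises if the stiffest mode violates the
    Euler stability bound ``dt*(D_c k_max^2 + alpha) < 2``.
    """
    sp = params.signaling
    M, L = grid.M, grid.L
    kx, ky = rfft2_wavenumbers(M, L)
    k2 = kx**2 + ky**2
    lam_max = params.dt * (params.D_c * k2.max() + sp.alpha)
    if lam_max >= 2.0:
        raise ParameterError(
            f"signal-field Euler step unstable: dt*(D_c*k_max^2 + alpha) = "
            f"{lam_max:.3g} >= 2"
        )
    ch = np.fft.rfft2(grid.c)
    sh = np.fft.rfft2(source)
    ch = ch * (1.0 - params.dt * (params.D_c * k2 + sp.alpha)) + params.dt * sh
    return SignalGrid(np.fft.irfft2(ch, s=grid.c.shape), L)


def run_abm(
    params: ABMParams,
    seed: int,
    *,
    t_end: float,
    snapshot_interval: float,
    c0: np.ndarray | None = None,
) -> list[ABMSnapshot]:
    """March the coupled agent/field system and collect snapshots.

    Per step, in order: agent update (headings, positions, overlap
    resolution) -> source deposition from the updated positions -> signal
    field step -> state relaxation step using the updated field.  Fully
    reproducible given the seed (separate RNG streams for initialization
    and rotational noise).
    """
    seq = np.random.SeedSequence(seed)
    init_seed, noise_seed = seq.spawn(2)
    ensemble = init_agents(params, init_seed)
    rng = np.random.default_rng(noise_seed)
    grid = SignalGrid(
        np.zeros((params.M, params.M)) if c0 is None else np.array(c0, dtype=float),
        params.L,
    )
    n_steps = int(round(t_end / params.dt))
    snap_every = max(1, int(round(snapshot_interval / params.dt)))
    snaps = [ABMSnapshot(0.0, ensemble.copy(), grid.copy())]
    sp = params.signaling
    for step in range(1, n_steps + 1):
        try:
            ensemble = step_agents(ensemble, grid, params, rng, update_states=False)
            source = deposit_sources(ensemble, grid, params)
            grid = step_signal_field(grid, source, params)
            c_i = bilinear_sample(grid.c, ensemble.positions, params.L)
            ensemble.states = ensemble.states + params.dt * sp.epsilon * (
                c_i - ensemble.states
            )
        except Exception as exc:
            raise IntegrationErrorLike(
                f"ABM step {step} (t = {step * params.dt:.6g}) failed: {exc}"
            ) from exc
        if step % snap_every == 0:
            snaps.append(ABMSnapshot(step * params.dt, ensemble.copy(), grid.copy()))
    return snaps


def density_from_agents(
    ensemble: AgentEnsemble, M: int, L: float, kernel_width: float
) -> np.ndarray:
    """Gridded agent density: Gaussian deposition, domain integral = N.

    Cloud-in-cell binning followed by a spectral Gaussian of the given
    width; the kernel width must resolve at least one grid cell.
    """
    if kernel_width < L / M:
        raise ParameterError(
            f"kernel width {kernel_width} below one grid cell {L / M:.3g}"
        )
    raw = cic_deposit(ensemble.positions, 1.0, M, L)
    ghat = gaussian_filter_hat(M, L, kernel_width)
    return np.fft.irfft2(np.fft.rfft2(raw) * ghat, s=raw.shape)
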