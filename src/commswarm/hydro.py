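"""Hydrodynamic theory of communicating active matter.

Continuum fields on a periodic square: particle density ``rho``, polarity
``p = (p_x, p_y)``, signal concentration ``c`` and refractoriness ``s``,
evolving as an active polar fluid coupled to an excitable signaling medium:

    dt rho = -v0 div p + D_rho lap rho
    dt p   = sigma (rho - 1) p - delta |p|^2 p + D_p lap p
             - chi (p . grad) p - Q(rho) grad rho + rho omega grad c
    dt c   = D_c lap c - alpha c + rho beta Theta(c - c_th) (1 - s)
    dt s   = D_rho lap s + epsilon (c - s) - vbar (p . grad) s

Density units set the mean-field critical density of the isotropic-polar
transition to 1: a uniform state is polar iff ``rho > 1``, with stationary
amplitude ``|p|* = sqrt(sigma (rho - 1) / delta)``.  The density-polarity
coupling amplitude ``Q(rho)`` interpolates between a low-density pressure
``v0/2`` and a high-density steric barrier at ``rho = 2``; ``vbar``
regularizes the advection speed of the state field.

Time integration is quasi-spectral with second-order exponential time
differencing (ETD2): the linear dynamics is integrated exactly per Fourier
mode, the nonlinear terms enter through the phi1/phi2 weights of a two-step
Adams-Bashforth-type rule (first step bootstrapped with ETD1).  Nonlinear
products are optionally 2/3-rule dealiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from ._spectral import dealias_mask, rfft2_wavenumbers
from .signaling import ParameterError, SignalingParams

__all__ = [
    "HydroParams",
    "HydroFields",
    "SpectralOperator",
    "BlowUpError",
    "q_amplitude",
    "regularized_speed",
    "homogeneous_polar_amplitude",
    "diffusion_length",
    "phi1",
    "phi2",
    "nonlinear_rhs",
    "build_linear_operator",
    "etd2_step",
    "init_fields",
    "run_hydro",
]

FIELD_NAMES = ("rho", "px", "py", "c", "s")


class BlowUpError(RuntimeError):
    """Integration diverged; carries the last finite snapshot if available."""

    def __init__(self, msg, last_good=None):
        super().__init__(msg)
        self.last_good = last_good


@dataclass(frozen=True)
class HydroParams:
    """Parameters of the continuum model (repo defaults unless noted).

    ``sigma`` polar relaxation rate (0.02 in the reference phase diagram),
    ``delta`` cubic saturation, ``D_p`` orientational elasticity (one Frank
    constant), ``chi`` self-advection (small), ``D_rho`` center-of-mass
    diffusion of density and state, ``omega`` signal susceptibility, ``v0``
    self-propulsion speed; signaling constants as in
    :class:`~commswarm.signaling.SignalingParams`.  ``rho_c`` is fixed at 1
    by the choice of density units.
    """

    v0: float = 0.5
    D_rho: float = 0.2
    sigma: float = 0.02
    delta: float = 0.02
    D_p: float = 0.2
    chi: float = 0.01
    omega: float = 0.05
    D_c: float = 5.0
    alpha: float = 1.0
    beta: float = 5.0
    epsilon: float = 0.05
    a: float = 0.5
    b: float = 0.2
    rho_c: float = 1.0
    #: "sharp" Heaviside threshold as written, or "smooth" sigmoid of width kappa
    theta_mode: str = "sharp"
    kappa: float = 0.02
    #: threshold argument: state-dependent c_th(s) = (s+b)/a, or constant b/a
    threshold_state_dependent: bool = True

    def __post_init__(self) -> None:
        for name in ("D_rho", "D_p", "D_c", "alpha", "beta", "epsilon"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.delta <= 0:
            raise ParameterError(f"delta must be > 0, got {self.delta}")
        if self.a <= 0:
            raise ParameterError(f"a must be > 0, got {self.a}")
        if self.rho_c != 1.0:
            raise ParameterError("density units fix the critical density rho_c at 1")

    @property
    def signaling(self) -> SignalingParams:
        return SignalingParams(
            alpha=self.alpha, beta=self.beta, epsilon=self.epsilon, a=self.a, b=self.b
        )


@dataclass
class HydroFields:
    """Field state on an M x M periodic grid of side L at time t."""

    rho: np.ndarray
    p: np.ndarray  # (M, M, 2)
    c: np.ndarray
    s: np.ndarray
    L: float
    t: float = 0.0

    @property
    def M(self) -> int:
        return self.rho.shape[0]

    def copy(self) -> "HydroFields":
        return HydroFields(
            self.rho.copy(), self.p.copy(), self.c.copy(), self.s.copy(), self.L, self.t
        )

    def as_dict(self) -> dict:
        return {
            "rho": self.rho,
            "px": self.p[..., 0],
            "py": self.p[..., 1],
            "c": self.c,
            "s": self.s,
        }


# ---------------------------------------------------------------------------
# closed-form pieces

def q_amplitude(rho, v0: float):
    """Density-polarity coupling amplitude
    ``Q(rho) = (v0/2) [exp(-32 rho) + exp(16 (rho - 2))]``.

    Tends to ``v0/2`` as rho -> 0 (bare pressure), is exponentially small at
    intermediate densities (collective effects cancel steric repulsion), and
    rises again toward the maximum packing density rho = 2.
    """
    rho = np.asarray(rho, dtype=float)
    out = 0.5 * v0 * (np.exp(-32.0 * rho) + np.exp(16.0 * (rho - 2.0)))
    return out if out.ndim else float(out)


def regularized_speed(p_norm, rho, v0: float):
    """Effective advection factor ``vbar = v0 tanh(|p|/rho) / |p|``.

    Bounded: ``|vbar * p| <= v0`` always.  The ``|p| -> 0`` limit ``v0/rho``
    is taken analytically below ``|p| = 1e-8``.
    """
    p_norm = np.asarray(p_norm, dtype=float)
    rho = np.asarray(rho, dtype=float)
    rho_safe = np.maximum(rho, 1e-12)
    small = p_norm < 1e-8
    out = np.where(
        small,
        v0 / rho_safe,
        v0 * np.tanh(p_norm / rho_safe) / np.where(small, 1.0, p_norm),
    )
    return out if out.ndim else float(out)


def homogeneous_polar_amplitude(rho: float, sigma: float, delta: float) -> float:
    """Stationary uniform polarity ``sqrt(sigma (rho - 1) / delta)`` above
    the critical density 1, and 0 at or below it."""
    if delta <= 0:
        raise ParameterError(f"delta must be > 0, got {delta}")
    if rho <= 1.0:
        return 0.0
    return float(np.sqrt(sigma * (rho - 1.0) / delta))


def diffusion_length(D_c: float, alpha: float) -> float:
    """Signal decay length ``sqrt(D_c / alpha)``; infinite if alpha = 0."""
    if alpha == 0:
        return float("inf")
    return float(np.sqrt(D_c / alpha))


def phi1(z: complex) -> complex:
    """``(e^z - 1)/z`` with the series limit 1 at z = 0."""
    if abs(z) < 1e-7:
        return 1.0 + z / 2.0 + z * z / 6.0
    return (np.exp(z) - 1.0) / z


def phi2(z: complex) -> complex:
    """``(e^z - 1 - z)/z^2`` with the series limit 1/2 at z = 0."""
    if abs(z) < 1e-5:
        return 0.5 + z / 6.0 + z * z / 24.0
    return (np.exp(z) - 1.0 - z) / (z * z)


# ---------------------------------------------------------------------------
# nonlinear right-hand side

def _theta(x, params: HydroParams):
    if params.theta_mode == "smooth":
        return 1.0 / (1.0 + np.exp(-x / params.kappa))
    return (x > 0.0).astype(float)


def nonlinear_rhs(fields: HydroFields, params: HydroParams) -> dict:
    """Nonlinear field tendencies (everything the linear operator omits).

    Density: zero (its equation is fully linear).  Polarity:
    ``sigma rho p - delta |p|^2 p - chi (p.grad)p - Q(rho) grad rho
    + rho omega grad c`` (the linear part ``-sigma p`` lives in the
    operator, so the full ``sigma (rho - 1) p`` is recovered).  Signal:
    threshold production ``rho beta Theta(c - c_th)(1 - s)``.  State:
    advection ``-vbar (p.grad) s``.  Gradients are spectral.
    """
    L, M = fields.L, fields.M
    kx, ky = rfft2_wavenumbers(M, L)
    rho = np.maximum(fields.rho, 0.0)  # guard Q and vbar against ringing
    px, py = fields.p[..., 0], fields.p[..., 1]
    c, s = fields.c, fields.s

    # batched spectral gradients of (rho, px, py, c, s)
    stack = np.stack([fields.rho, px, py, c, s], axis=-1)
    sh = np.fft.rfft2(stack, axes=(0, 1))
    gx = np.fft.irfft2(1j * kx[..., None] * sh, s=(M, M), axes=(0, 1))
    gy = np.fft.irfft2(1j * ky[..., None] * sh, s=(M, M), axes=(0, 1))
    drx, dpxx, dpyx, dcx, dsx = np.moveaxis(gx, -1, 0)
    dry, dpxy, dpyy, dcy, dsy = np.moveaxis(gy, -1, 0)

    p2 = px * px + py * py
    Q = q_amplitude(rho, params.v0)
    Gx = (
        params.sigma * rho * px
        - params.delta * p2 * px
        - params.chi * (px * dpxx + py * dpxy)
        - Q * drx
        + rho * params.omega * dcx
    )
    Gy = (
        params.sigma * rho * py
        - params.delta * p2 * py
        - params.chi * (px * dpyx + py * dpyy)
        - Q * dry
        + rho * params.omega * dcy
    )
    if params.threshold_state_dependent:
        c_th = (s + params.b) / params.a
    else:
        c_th = params.b / params.a
    Gc = rho * params.beta * _theta(c - c_th, params) * (1.0 - s)
    vbar = regularized_speed(np.sqrt(p2), rho, params.v0)
    Gs = -vbar * (px * dsx + py * dsy)
    for name, arr in (("p", Gx), ("p", Gy), ("c", Gc), ("s", Gs)):
        if not np.all(np.isfinite(arr)):
            raise BlowUpError(f"non-finite nonlinear tendency in field '{name}'")
    return {"rho": np.zeros_like(rho), "px": Gx, "py": Gy, "c": Gc, "s": Gs}


# ---------------------------------------------------------------------------
# linear operator and ETD2 weights

@dataclass
class SpectralOperator:
    """Per-mode 5x5 linear dynamics over (rho, p_x, p_y, c, s) with cached
    ETD2 propagators for a fixed time step.

    ``E = exp(dt L)``, ``W1 = dt phi1(dt L)``, ``W2 = dt phi2(dt L)``;
    an ETD1 step is ``u+ = E u + W1 F`` and the ETD2 step is
    ``u+ = E u + (W1 + W2) F_n - W2 F_{n-1}``.  At k = 0 the density row of
    L vanishes identically (exact mass conservation).
    """

    M: int
    L: float
    dt: float
    Lmat: np.ndarray  # (M, M//2+1, 5, 5) complex
    E: np.ndarray
    W1: np.ndarray
    W2: np.ndarray

    def eigenvalues(self, ikx: int = 0, iky: int = 0) -> np.ndarray:
        """Eigenvalues of the linear operator at one wavenumber index."""
        return np.linalg.eigvals(self.Lmat[ikx, iky])


def _linear_matrices(params: HydroParams, M: int, L: float) -> np.ndarray:
    kx, ky = rfft2_wavenumbers(M, L)
    kx = np.broadcast_to(kx, (M, M // 2 + 1))
    ky = np.broadcast_to(ky, (M, M // 2 + 1))
    k2 = kx**2 + ky**2
    A = np.zeros((M, M // 2 + 1, 5, 5), dtype=complex)
    # rho: -D_rho k^2 rho - i v0 k . p
    A[..., 0, 0] = -params.D_rho * k2
    A[..., 0, 1] = -1j * params.v0 * kx
    A[..., 0, 2] = -1j * params.v0 * ky
    # p: (-sigma - D_p k^2) p   (sigma*rho*p is handled nonlinearly)
    A[..., 1, 1] = -params.sigma - params.D_p * k2
    A[..., 2, 2] = -params.sigma - params.D_p * k2
    # c: (-D_c k^2 - alpha) c
    A[..., 3, 3] = -params.D_c * k2 - params.alpha
    # s: -D_rho k^2 s + eps c - eps s
    A[..., 4, 3] = params.epsilon
    A[..., 4, 4] = -params.D_rho * k2 - params.epsilon
    return A


def build_linear_operator(params: HydroParams, M: int, L: float, dt: float) -> SpectralOperator:
    """Assemble the per-mode linear matrices and their ETD2 weights.

    The matrix functions exp, phi1, phi2 are extracted jointly from one
    exponential of the 15x15 augmented block matrix

        [[dt L, dt I, 0], [0, 0, dt I], [0, 0, 0]]

    whose top block row is ``[exp(dt L), dt phi1(dt L), dt^2 phi2(dt L)]``.
    This is exact for defective and zero eigenvalues alike, with no
    eigendecomposition conditioning issues.
    """
    A = _linear_matrices(params, M, L)
    nkx, nky = A.shape[:2]
    Z = np.zeros((nkx, nky, 15, 15), dtype=complex)
    Z[..., 0:5, 0:5] = dt * A
    Z[..., 0:5, 5:10] = dt * np.eye(5)
    Z[..., 5:10, 10:15] = dt * np.eye(5)
    EZ = expm(Z)
    E = EZ[..., 0:5, 0:5]
    W1 = EZ[..., 0:5, 5:10]  # dt * phi1
    W2 = EZ[..., 0:5, 10:15] / dt  # dt^2 * phi2 / dt
    if not np.all(np.isfinite(E)):
        raise BlowUpError("non-finite spectrum in linear propagator")
    return SpectralOperator(M=M, L=L, dt=dt, Lmat=A, E=E, W1=W1, W2=W2)


def _to_hat(fields: HydroFields) -> np.ndarray:
    stack = np.stack(
        [fields.rho, fields.p[..., 0], fields.p[..., 1], fields.c, fields.s],
        axis=-1,
    )
    return np.fft.rfft2(stack, axes=(0, 1))


def _from_hat(uhat: np.ndarray, L: float, t: float) -> HydroFields:
    M = uhat.shape[0]
    re = np.fft.irfft2(uhat, s=(M, M), axes=(0, 1))
    p = np.stack([re[..., 1], re[..., 2]], axis=-1)
    return HydroFields(rho=re[..., 0], p=p, c=re[..., 3], s=re[..., 4], L=L, t=t)


def etd2_step(
    fields: HydroFields,
    op: SpectralOperator,
    params: HydroParams,
    *,
    prev_nl_hat: np.ndarray | None = None,
    dealias: bool = True,
    nonlinear: bool = True,
):
    """One ETD2 step; returns ``(fields at t + dt, nl_hat)`` where
    ``nl_hat`` must be passed back as ``prev_nl_hat`` on the next call.

    With ``prev_nl_hat = None`` the step is bootstrapped with ETD1.  The
    linear part is integrated exactly per mode; with ``nonlinear = False``
    (verification mode) the flow is therefore the matrix exponential of the
    linear operator to machine precision.
    """
    uh = _to_hat(fields)
    un, Fh = _etd2_step_hat(uh, op, params, prev_nl_hat, dealias, nonlinear,
                            fields.L)
    out = _from_hat(un, fields.L, fields.t + op.dt)
    return out, Fh


def _etd2_step_hat(uh, op, params, prev_nl_hat, dealias, nonlinear, L):
    """Core update in spectral space (state round-trips exactly)."""
    Eu = np.einsum("xyij,xyj->xyi", op.E, uh)
    if not nonlinear:
        return Eu, None
    fields = _from_hat(uh, L, 0.0)
    nl = nonlinear_rhs(fields, params)
    Fh = np.fft.rfft2(
        np.stack([nl[n] for n in FIELD_NAMES], axis=-1), axes=(0, 1)
    )
    if dealias:
        Fh *= dealias_mask(op.M)[..., None]
    if prev_nl_hat is None:
        un = Eu + np.einsum("xyij,xyj->xyi", op.W1, Fh)
    else:
        un = (
            Eu
            + np.einsum("xyij,xyj->xyi", op.W1 + op.W2, Fh)
            - np.einsum("xyij,xyj->xyi", op.W2, prev_nl_hat)
        )
    return un, Fh


# ---------------------------------------------------------------------------
# initialization and time marching

@dataclass(frozen=True)
class KernelSpec:
    """Random anisotropic Gaussian excitation kernels for the signal field.

    Major characteristic lengths uniform in ``length_range`` (sigma = half
    the length), fixed ``width`` (sigma = width/2), amplitude defaulting to
    twice the quiescent threshold so nucleation is super-threshold.

    With ``spiral_seed`` each kernel is flanked by a refractory patch in the
    state field (a half-plane strip across one side of the kernel), so the
    outgoing excitation front is broken at birth and curls into a spiral
    pair.  In large domains spirals emerge spontaneously from front
    collisions over long transients; in desk-scale domains this seeding is
    the practical way to obtain the persistent spiral activity that drives
    aggregation.
    """

    count: int
    amplitude: float
    length_range: tuple = (20.0, 30.0)
    width: float = 5.0
    spiral_seed: bool = False
    seed_state: float = 0.8


def init_fields(
    params: HydroParams,
    M: int,
    L: float,
    rho0: float,
    *,
    noise_amplitude: float = 1e-3,
    kernels: KernelSpec | None = None,
    seed: int = 0,
) -> HydroFields:
    """Noisy homogeneous start with localized signal excitations.

    ``rho = rho0`` plus zero-mean white noise (the residual sample mean is
    re-subtracted exactly), ``p`` zero-mean white noise, ``s = 0``, and
    ``c`` a sum of randomly positioned and oriented anisotropic Gaussian
    kernels (periodically wrapped).  Deterministic given the seed.
    """
    if rho0 <= 0:
        raise ParameterError(f"rho0 must be > 0, got {rho0}")
    rng = np.random.default_rng(seed)
    if kernels is None:
        kernels = KernelSpec(
            count=int(np.ceil(L**2 / 1e4)), amplitude=2.0 * params.b / params.a
        )
    if kernels.count > 0 and max(kernels.length_range) > L / 2:
        raise ParameterError(
            f"kernel length {max(kernels.length_range)} exceeds L/2 = {L / 2}"
        )
    rho = rho0 + noise_amplitude * rng.standard_normal((M, M))
    rho -= rho.mean() - rho0  # exact mean
    p = noise_amplitude * rng.standard_normal((M, M, 2))
    p -= p.mean(axis=(0, 1))
    c = np.zeros((M, M))
    s = np.zeros((M, M))
    x = np.arange(M) * (L / M)
    X, Y = np.meshgrid(x, x, indexing="ij")
    for _ in range(kernels.count):
        cx, cy = rng.uniform(0.0, L, size=2)
        theta = rng.uniform(0.0, np.pi)
        length = rng.uniform(*kernels.length_range)
        sig_u, sig_v = length / 2.0, kernels.width / 2.0
        dx = X - cx
        dx -= L * np.round(dx / L)
        dy = Y - cy
        dy -= L * np.round(dy / L)
        u = np.cos(theta) * dx + np.sin(theta) * dy
        v = -np.sin(theta) * dx + np.cos(theta) * dy
        c += kernels.amplitude * np.exp(-0.5 * (u**2 / sig_u**2 + v**2 / sig_v**2))
        if kernels.spiral_seed:
            # refractory strip along one flank of the kernel: the outgoing
            # front cannot propagate into it and breaks into two free ends
            strip = (v > 0.0) & (v < 4.0 * kernels.width) & (
                np.abs(u) < 2.0 * sig_u
            )
            s[strip] = np.maximum(s[strip], kernels.seed_state)
    return HydroFields(rho=rho, p=p, c=c, s=s, L=L, t=0.0)


def run_hydro(
    params: HydroParams,
    fields: HydroFields,
    *,
    t_end: float,
    dt: float,
    snapshot_interval: float,
    dealias: bool = True,
    neg_tol: float = 1e-8,
    neg_policy: str = "error",
    blowup_threshold: float = 1e6,
) -> list[HydroFields]:
    """ETD2 march from the given initial fields, collecting snapshots.

    Density values in ``(-neg_tol, 0)`` arising from spectral ringing are
    clipped to zero in the recorded snapshots; deeper negative excursions
    raise (``neg_policy = "error"``) or warn-and-clip
    (``neg_policy = "clip"``).  If any field magnitude exceeds
    ``blowup_threshold`` the run aborts with a :class:`BlowUpError`
    carrying the last good snapshot.
    """
    op = build_linear_operator(params, fields.M, fields.L, dt)
    n_steps = int(round(t_end / dt))
    snap_every = max(1, int(round(snapshot_interval / dt)))
    uh = _to_hat(fields)
    snaps = [_snapshot(fields.copy(), neg_tol, neg_policy)]
    prev = None
    for step in range(1, n_steps + 1):
        try:
            uh, prev = _etd2_step_hat(uh, op, params, prev, dealias, True,
                                      fields.L)
        except BlowUpError as exc:
            raise BlowUpError(
                f"hydro step {step} (t = {step * dt:.6g}): {exc}", last_good=snaps[-1]
            ) from exc
        if step % snap_every == 0:
            state = _from_hat(uh, fields.L, fields.t + step * dt)
            if not np.all(np.isfinite(state.rho)) or max(
                np.abs(state.rho).max(), np.abs(state.p).max(),
                np.abs(state.c).max(), np.abs(state.s).max(),
            ) > blowup_threshold:
                raise BlowUpError(
                    f"field magnitude exceeded {blowup_threshold:g} at t = "
                    f"{state.t:.6g}", last_good=snaps[-1],
                )
            snaps.append(_snapshot(state, neg_tol, neg_policy))
    return snaps


def _snapshot(state: HydroFields, neg_tol: float, neg_policy: str) -> HydroFields:
    out = state.copy()
    rmin = out.rho.min()
    if rmin < -neg_tol:
        msg = (
            f"density reached {rmin:.3g}, below the ringing tolerance "
            f"-{neg_tol:g} at t = {state.t:.6g}"
        )
        if neg_policy == "error":
            raise BlowUpError(msg, last_good=None)
        warnings.warn(msg, stacklevel=2)
    np.clip(out.rho, 0.0, None, out=out.rho)
    return out
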