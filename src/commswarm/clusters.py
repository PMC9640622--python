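"""Aggregate identification, classification and coarsening kinetics.

Dense aggregates are the connected components of the super-threshold
density mask (``rho > 0.7`` by default, strictly above the typical mean
density 0.6), labeled with periodic wrap-around.  Each aggregate is
described by its integrated mass, periodic-aware centroid, equivalent-
ellipse axes from the second central moments of the binarized domain, mean
polarity, and mean vorticity ``curl p``, and classified as

* **stream** - shape factor (major/minor diameter) > 1.4 and the angle
  between the major axis and the mean polarity < pi/4;
* **vortex** - shape factor < 1.4 and |mean vorticity| > 0.01;
* **droplet** - everything else (boundary equalities included).

Cluster-number kinetics: the mean-field binary-coalescence model
``dn/dt = -D0 S^gamma n^2`` with ``S ~ 1/n`` predicts ``N_c ~ t^(-z)``
with ``z = 1/(1 - gamma)``; for size-independent diffusion (gamma = 0)
this is the interface-controlled ripening law ``N_c ~ 1/t``.  The
streaming phase is described by ``N_c ~ (N0 - kappa t^2)/t`` and the
final vortex-competition phase by logarithmic coarsening ``N_c ~ A/ln t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.integrate import solve_ivp

from ._spectral import spectral_curl
from .signaling import ParameterError

__all__ = [
    "ClusterRecord",
    "CoarseningFit",
    "binarize_and_label",
    "cluster_shape",
    "cluster_flow",
    "classify_cluster",
    "analyze_field",
    "cluster_series",
    "coalescence_model",
    "fit_coarsening",
    "aggregation_time",
    "SHAPE_FACTOR_STREAM",
    "VORTICITY_MIN",
]

SHAPE_FACTOR_STREAM = 1.4
VORTICITY_MIN = 0.01
DENSITY_THRESHOLD = 0.7


@dataclass
class ClusterRecord:
    """Descriptors of one labeled aggregate."""

    label: int
    n_pixels: int
    mass: float
    centroid: tuple  # periodic-aware, in length units
    major_axis: float  # equivalent-ellipse diameters
    minor_axis: float
    orientation: float  # major-axis angle, mod pi
    shape_factor: float
    mean_polarity: np.ndarray | None = None  # (2,)
    mean_vorticity: float | None = None
    third_moments: dict | None = None  # central moments mu_30, mu_21, mu_12, mu_03
    cls: str | None = None


def binarize_and_label(rho: np.ndarray, threshold: float = DENSITY_THRESHOLD,
                       *, connectivity: int = 4):
    """Label connected components of the strict super-threshold mask.

    Components are merged across the periodic boundary, so an aggregate
    straddling an edge is a single cluster.  Returns ``(labels, count)``
    with labels 1..count (0 = background).
    """
    mask = rho > threshold
    structure = (
        ndimage.generate_binary_structure(2, 1)
        if connectivity == 4
        else ndimage.generate_binary_structure(2, 2)
    )
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels, 0
    # union-find merge across periodic edges
    parent = np.arange(n + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    edges = [(labels[0, :], labels[-1, :]), (labels[:, 0], labels[:, -1])]
    if connectivity == 8:
        edges += [
            (labels[0, :], np.roll(labels[-1, :], 1)),
            (labels[0, :], np.roll(labels[-1, :], -1)),
            (labels[:, 0], np.roll(labels[:, -1], 1)),
            (labels[:, 0], np.roll(labels[:, -1], -1)),
        ]
    for a, b in edges:
        both = (a > 0) & (b > 0)
        for x, y in zip(a[both], b[both]):
            union(x, y)
    roots = np.array([find(x) for x in range(n + 1)])
    _, compact = np.unique(roots, return_inverse=True)
    labels = compact[labels]
    return labels, int(labels.max())


def _periodic_centroid(coords: np.ndarray, M: int) -> float:
    """Circular-mean centroid of pixel indices on a ring of size M."""
    theta = coords * (2.0 * np.pi / M)
    ang = math.atan2(np.sin(theta).mean(), np.cos(theta).mean())
    return (ang * M / (2.0 * np.pi)) % M


def cluster_shape(labels: np.ndarray, rho: np.ndarray, L: float) -> list:
    """Moment-based shape descriptors for every labeled aggregate.

    Central moments up to third order of the binarized domain are taken
    about the periodic-aware centroid with minimum-image pixel offsets.
    Axis lengths are the equivalent-ellipse diameters ``4 sqrt(lambda)``
    of the second-moment tensor eigenvalues; a single-pixel cluster has
    shape factor 1 by definition.
    """
    M = labels.shape[0]
    dx = L / M
    out = []
    for lab in range(1, labels.max() + 1):
        ii, jj = np.nonzero(labels == lab)
        npix = len(ii)
        ci = _periodic_centroid(ii, M)
        cj = _periodic_centroid(jj, M)
        di = (ii - ci + M / 2) % M - M / 2
        dj = (jj - cj + M / 2) % M - M / 2
        di = di * dx
        dj = dj * dx
        # include the moment of each pixel's own square footprint (dx^2/12):
        # a single pixel is then an exact circle (shape factor 1) and thin
        # lines keep a finite minor axis of one pixel width
        mu20 = float(np.mean(di * di)) + dx * dx / 12.0
        mu02 = float(np.mean(dj * dj)) + dx * dx / 12.0
        mu11 = float(np.mean(di * dj))
        third = {
            "mu30": float(np.mean(di**3)),
            "mu21": float(np.mean(di**2 * dj)),
            "mu12": float(np.mean(di * dj**2)),
            "mu03": float(np.mean(dj**3)),
        }
        cov = np.array([[mu20, mu11], [mu11, mu02]])
        evals, evecs = np.linalg.eigh(cov)
        lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
        major = 4.0 * math.sqrt(lam_major)
        minor = 4.0 * math.sqrt(lam_minor)
        shape = major / minor if minor > 0 else float("inf")
        v = evecs[:, 1]  # major-axis direction (di, dj) = (x, y)
        orientation = math.atan2(v[1], v[0]) % math.pi
        mass = float(rho[ii, jj].sum() * dx * dx)
        out.append(
            ClusterRecord(
                label=lab,
                n_pixels=npix,
                mass=mass,
                centroid=((ci * dx) % L, (cj * dx) % L),
                major_axis=major,
                minor_axis=minor,
                orientation=orientation,
                shape_factor=shape,
                third_moments=third,
            )
        )
    return out


def cluster_flow(labels: np.ndarray, p: np.ndarray, L: float, records: list) -> list:
    """Attach mean polarity and mean vorticity to each cluster record.

    The vorticity ``curl p = d(p_y)/dx - d(p_x)/dy`` is evaluated
    spectrally on the full grid and averaged over each cluster.
    """
    vort = spectral_curl(p[..., 0], p[..., 1], L)
    for rec in records:
        sel = labels == rec.label
        rec.mean_polarity = np.array(
            [p[..., 0][sel].mean(), p[..., 1][sel].mean()]
        )
        rec.mean_vorticity = float(vort[sel].mean())
    return records


def classify_cluster(rec: ClusterRecord) -> str:
    """Apply the stream/vortex/droplet rule table.

    Boundary equalities (shape factor exactly 1.4, axis-polarity angle
    exactly pi/4, |vorticity| exactly 0.01) resolve to droplet, and the
    axis-polarity angle is folded to [0, pi/2] because the major axis is
    undirected.
    """
    if rec.shape_factor > SHAPE_FACTOR_STREAM:
        if rec.mean_polarity is not None and np.linalg.norm(rec.mean_polarity) > 0:
            pol_angle = math.atan2(rec.mean_polarity[1], rec.mean_polarity[0])
            dang = abs((pol_angle - rec.orientation + math.pi / 2) % math.pi - math.pi / 2)
            if dang < math.pi / 4:
                return "stream"
        return "droplet"
    if rec.shape_factor < SHAPE_FACTOR_STREAM:
        if rec.mean_vorticity is not None and abs(rec.mean_vorticity) > VORTICITY_MIN:
            return "vortex"
    return "droplet"


def analyze_field(
    rho: np.ndarray,
    p: np.ndarray | None,
    L: float,
    *,
    threshold: float = DENSITY_THRESHOLD,
    connectivity: int = 4,
    min_pixels: int = 1,
) -> list:
    """Full pipeline: binarize, label, measure and classify one frame."""
    labels, n = binarize_and_label(rho, threshold, connectivity=connectivity)
    if n == 0:
        return []
    records = cluster_shape(labels, rho, L)
    records = [r for r in records if r.n_pixels >= min_pixels]
    if p is not None:
        cluster_flow(labels, p, L, records)
    for rec in records:
        rec.cls = classify_cluster(rec)
    return records


def cluster_series(frames: list, L: float, *, threshold: float = DENSITY_THRESHOLD,
                   min_pixels: int = 1) -> dict:
    """Cluster counts over time from a list of (t, rho, p) snapshots.

    Returns arrays ``t``, ``N_c`` and per-class counts; class counts
    partition ``N_c`` at every frame.
    """
    if len(frames) < 2:
        raise ValueError("need at least two snapshots for a time series")
    t, total = [], []
    per = {"droplet": [], "stream": [], "vortex": []}
    for ti, rho, p in frames:
        recs = analyze_field(rho, p, L, threshold=threshold, min_pixels=min_pixels)
        t.append(ti)
        total.append(len(recs))
        for k in per:
            per[k].append(sum(1 for r in recs if r.cls == k))
    return {
        "t": np.asarray(t, dtype=float),
        "N_c": np.asarray(total),
        **{k: np.asarray(v) for k, v in per.items()},
    }


def coalescence_model(n0: float, D0: float, gamma: float, times: np.ndarray):
    """Mean-field binary coalescence ``dn/dt = -D0 S^gamma n^2`` with
    ``S = 1/n`` (total mass normalized), i.e. ``dn/dt = -D0 n^(2-gamma)``.

    Returns ``(n(t), z)`` with the late-time exponent ``z = 1/(1-gamma)``;
    the exponent is undefined for gamma >= 1.
    """
    if gamma >= 1.0:
        raise ParameterError(f"exponent z = 1/(1-gamma) undefined for gamma = {gamma}")
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        lambda t, n: -D0 * n ** (2.0 - gamma),
        (times[0], times[-1]),
        [n0],
        t_eval=times,
        rtol=1e-10,
        atol=1e-14,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"coalescence integration failed: {sol.message}")
    return sol.y[0], 1.0 / (1.0 - gamma)


@dataclass
class CoarseningFit:
    model: str
    params: dict
    residual: float


def fit_coarsening(t: np.ndarray, n_c: np.ndarray, model: str = "power",
                   window: tuple | None = None) -> CoarseningFit:
    """Least-squares fit of a coarsening law to a cluster-number series.

    Models: ``power`` ``N_c = A t^-eta`` (linear fit in log-log),
    ``stream`` ``N_c = (N0 - kappa t^2)/t`` (linear in N0, kappa), and
    ``log`` ``N_c = A / ln t``.  ``window = (t_lo, t_hi)`` restricts the
    fit; at least 5 points are required.
    """
    t = np.asarray(t, dtype=float)
    n_c = np.asarray(n_c, dtype=float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, n_c = t[sel], n_c[sel]
    if len(t) < 5:
        raise ValueError(f"need >= 5 points in the fit window, got {len(t)}")
    if model == "power":
        if np.any(t <= 0) or np.any(n_c <= 0):
            raise ValueError("power-law fit requires positive times and counts")
        coef, res = np.polyfit(np.log(t), np.log(n_c), 1, full=True)[:2]
        eta = -coef[0]
        A = math.exp(coef[1])
        resid = float(res[0]) if len(res) else 0.0
        return CoarseningFit("power", {"A": A, "eta": eta}, resid)
    if model == "stream":
        # N_c * t = N0 - kappa t^2  is linear in (N0, kappa)
        Amat = np.stack([np.ones_like(t), -(t**2)], axis=1)
        sol, res, *_ = np.linalg.lstsq(Amat, n_c * t, rcond=None)
        resid = float(res[0]) if len(res) else 0.0
        return CoarseningFit("stream", {"N0": sol[0], "kappa": sol[1]}, resid)
    if model == "log":
        if np.any(t <= 1.0):
            raise ValueError("log-law fit requires times > 1")
        x = 1.0 / np.log(t)
        A = float(np.dot(x, n_c) / np.dot(x, x))
        resid = float(np.sum((n_c - A * x) ** 2))
        return CoarseningFit("log", {"A": A}, resid)
    raise ValueError(f"unknown model '{model}'")


def aggregation_time(times: np.ndarray, max_rho: np.ndarray, rho_c: float = 1.0):
    """First time the maximum density crosses the polar-onset density.

    Linear interpolation between snapshots; returns ``None`` if the
    criterion is never met within the series.
    """
    times = np.asarray(times, dtype=float)
    max_rho = np.asarray(max_rho, dtype=float)
    above = max_rho > rho_c
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    r0, r1 = max_rho[i - 1], max_rho[i]
    return float(t0 + (rho_c - r0) / (r1 - r0) * (t1 - t0))
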