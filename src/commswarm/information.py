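"""Compression-based information content and the processing-rate model.

The information stored in a field configuration is proxied by the size of
its losslessly compressed 8-bit encoding (computable information content).
Fields are block-averaged to a fixed resolution (128 x 128 by default),
affinely quantized to 256 gray values, tiled into a mosaic in a fixed field
order, and compressed with DEFLATE at a fixed level — the codec behind the
PNG format — measuring only the compressed pixel stream, so the measure is
deterministic and free of container headers.

Information processing is quantified by the rate ``R``: the area fraction
of the domain in the refractory (super-threshold, ``c > 1``) state.  The
total information is modeled as

    dI/dt = gamma_R * R - lambda * I

where ``lambda`` is the relaxation rate toward the disordered homogeneous
state and ``gamma_R`` a units-matching scale (the model fixes only the
proportionality).  Both are fit jointly by non-negative least squares
against central-difference estimates of dI/dt.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "QuantizationSpec",
    "InformationTrace",
    "quantize_field",
    "quantize_mosaic",
    "compressed_information",
    "processing_rate",
    "fit_lambda",
    "predict_information",
    "information_trace",
]

#: fixed DEFLATE level; part of the codec configuration, not a tunable
_DEFLATE_LEVEL = 9

DEFAULT_LAYOUT = ("rho", "px", "py", "c", "s")


@dataclass(frozen=True)
class QuantizationSpec:
    """How fields are mapped to 8-bit images.

    ``ranges`` maps field name -> (min, max) used for the affine 0..255
    mapping; ranges are global across a run so information values are
    comparable over time.  ``resolution`` is the per-field pixel size
    (must be reachable from the simulation grid by block averaging);
    ``mode`` selects anti-aliased block averaging or nearest-neighbor
    subsampling; ``layout`` fixes the mosaic tile order.
    """

    ranges: dict
    resolution: int = 128
    mode: str = "block"
    layout: tuple = DEFAULT_LAYOUT

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValueError(f"invalid range for field '{name}': ({lo}, {hi})")


@dataclass
class InformationTrace:
    """Per-snapshot compressed sizes (bytes) and processing rates."""

    times: np.ndarray
    I_total: np.ndarray
    I_field: dict  # field name -> bytes array
    R: np.ndarray
    lam: float | None = None
    gamma_R: float | None = None


def _downsample(a: np.ndarray, target: int, mode: str) -> np.ndarray:
    M = a.shape[0]
    if M == target:
        return a
    if M % target != 0:
        raise ValueError(
            f"grid size {M} is not an integer multiple of the target "
            f"resolution {target}"
        )
    f = M // target
    if mode == "nearest":
        return a[::f, ::f]
    return a.reshape(target, f, target, f).mean(axis=(1, 3))


def quantize_field(a: np.ndarray, lo: float, hi: float, target: int,
                   mode: str = "block") -> np.ndarray:
    """Block-average then affinely quantize one field to uint8.

    The mapping is ``floor((v - lo)/(hi - lo) * 256)`` clipped to [0, 255];
    values outside the range saturate.
    """
    if a.size == 0:
        raise ValueError("empty field")
    small = _downsample(np.asarray(a, dtype=float), target, mode)
    q = np.floor((small - lo) / (hi - lo) * 256.0)
    return np.clip(q, 0, 255).astype(np.uint8)


def quantize_mosaic(fields: dict, spec: QuantizationSpec):
    """Tile all fields into one collective 8-bit image.

    Returns ``(mosaic, sub_images)`` where the mosaic concatenates the
    per-field sub-images horizontally in the spec's layout order.
    """
    subs = {}
    for name in spec.layout:
        if name not in fields:
            raise KeyError(f"field '{name}' missing from input")
        lo, hi = spec.ranges[name]
        subs[name] = quantize_field(fields[name], lo, hi, spec.resolution, spec.mode)
    mosaic = np.concatenate([subs[name] for name in spec.layout], axis=1)
    return mosaic, subs


def compressed_information(image: np.ndarray) -> int:
    """Size in bytes of the DEFLATE-compressed raw pixel stream.

    Deterministic: identical images give identical sizes.  Only the
    compressed data stream is measured (no file/container headers beyond
    the zlib framing).
    """
    img = np.ascontiguousarray(image, dtype=np.uint8)
    return len(zlib.compress(img.tobytes(), _DEFLATE_LEVEL))


def processing_rate(c: np.ndarray, threshold: float = 1.0) -> float:
    """Area fraction of the domain in the refractory state (c strictly
    above the threshold)."""
    return float(np.mean(np.asarray(c) > threshold))


def fit_lambda(t: np.ndarray, I: np.ndarray, R: np.ndarray,
               method: str = "trajectory"):
    """Joint non-negative least squares for (gamma_R, lambda) in
    ``dI/dt = gamma_R R - lambda I``.

    Two estimators are available.  ``"trajectory"`` (default) integrates
    the model forward and minimizes the misfit to the measured I(t); it is
    unbiased under measurement noise on I.  ``"derivative"`` regresses
    central-difference estimates of dI/dt on (R, -I); it is direct but
    attenuation-biased when I is noisy (noise enters both sides of the
    regression), so it serves as a quick diagnostic only.

    Requires >= 10 aligned samples; a degenerate input (constant I with
    R = 0) is rejected.  Returns ``(lam, gamma_R, r2)``, with r2 measured
    on the quantity the chosen estimator fits.
    """
    t = np.asarray(t, dtype=float)
    I = np.asarray(I, dtype=float)
    R = np.asarray(R, dtype=float)
    if not (len(t) == len(I) == len(R)):
        raise ValueError("t, I, R must be aligned")
    if len(t) < 10:
        raise ValueError(f"need >= 10 samples, got {len(t)}")
    dIdt = (I[2:] - I[:-2]) / (t[2:] - t[:-2])
    Ii, Ri = I[1:-1], R[1:-1]
    if np.allclose(dIdt, 0.0) and np.allclose(Ri, 0.0):
        raise ValueError("undetermined lambda: constant information and zero rate")
    A = np.stack([Ri, -Ii], axis=1)
    x, rnorm = nnls(A, dIdt)
    gamma_R, lam = float(x[0]), float(x[1])
    if method == "derivative":
        ss_tot = float(np.sum((dIdt - dIdt.mean()) ** 2))
        r2 = 1.0 - rnorm**2 / ss_tot if ss_tot > 0 else float("nan")
        return lam, gamma_R, r2
    if method != "trajectory":
        raise ValueError(f"unknown method {method!r}")

    from scipy.optimize import least_squares

    def resid(x):
        lam_, g_, i0_ = x
        return predict_information(i0_, t, R, lam_, g_) - I

    x0 = np.array([max(lam, 1e-6), max(gamma_R, 1e-6), I[0]])
    sol = least_squares(resid, x0, bounds=([0, 0, 0], [np.inf] * 3))
    lam, gamma_R = float(sol.x[0]), float(sol.x[1])
    ss_tot = float(np.sum((I - I.mean()) ** 2))
    r2 = 1.0 - float(np.sum(sol.fun**2)) / ss_tot if ss_tot > 0 else float("nan")
    return lam, gamma_R, r2


def predict_information(I0: float, t: np.ndarray, R: np.ndarray, lam: float,
                        gamma_R: float = 1.0) -> np.ndarray:
    """Forward-integrate ``dI/dt = gamma_R R - lambda I`` from I0.

    Exact exponential update per sampling interval with the trapezoidal
    mean of R; for R = 0 this is the closed form ``I0 exp(-lambda t)`` and
    for constant R the fixed point ``gamma_R R / lambda`` is approached.
    """
    t = np.asarray(t, dtype=float)
    R = np.asarray(R, dtype=float)
    out = np.empty_like(t)
    out[0] = I0
    for i in range(1, len(t)):
        h = t[i] - t[i - 1]
        rbar = 0.5 * (R[i] + R[i - 1])
        if lam * h < 1e-12:
            out[i] = out[i - 1] + gamma_R * rbar * h
        else:
            e = np.exp(-lam * h)
            out[i] = out[i - 1] * e + gamma_R * rbar * (1.0 - e) / lam
    return out


def information_trace(frames: list, spec: QuantizationSpec,
                      *, r_threshold: float = 1.0) -> InformationTrace:
    """Information and processing-rate time series for a snapshot list.

    ``frames`` is a list of ``(t, fields_dict)``; per frame the mosaic and
    per-field compressed sizes are measured and R is the refractory area
    fraction of the signal field.
    """
    times, I_tot, R = [], [], []
    I_field = {name: [] for name in spec.layout}
    for ti, fields in frames:
        mosaic, subs = quantize_mosaic(fields, spec)
        times.append(ti)
        I_tot.append(compressed_information(mosaic))
        for name in spec.layout:
            I_field[name].append(compressed_information(subs[name]))
        R.append(processing_rate(fields["c"], r_threshold))
    return InformationTrace(
        times=np.asarray(times, dtype=float),
        I_total=np.asarray(I_tot, dtype=float),
        I_field={k: np.asarray(v, dtype=float) for k, v in I_field.items()},
        R=np.asarray(R, dtype=float),
    )
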