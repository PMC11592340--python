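"""Desired-force-curve design for biarticular thigh-exosuit assistance.

The empirical controller's reference signal is built from blocked-motor
force recordings of the two artificial muscles (HAM and RF analogs):

    difference (HAM - RF)  ->  8th-order Fourier fit  ->  analytic
    derivative  ->  periodic Gaussian smoothing  ->  rescale to the
    hardware force range.

The resulting curve is positive where the artificial HAM should be
pulled (bulk of stance) and negative where the artificial RF should be
pulled (bulk of swing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .trace import ForceTrace


class CurveDesignError(ValueError):
    """Invalid input to a curve-design stage."""


@dataclass
class FourierCurve:
    """Real trigonometric polynomial on the unit phase circle.

    ``eval(phi) = a0 + sum_k a[k-1] cos(2 pi k phi) + b[k-1] sin(2 pi k phi)``
    with period 1.
    """

    a0: float
    a: np.ndarray  # cosine coefficients, length = order
    b: np.ndarray  # sine coefficients, length = order

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape:
            raise CurveDesignError("cosine/sine coefficient lengths differ")

    @property
    def order(self) -> int:
        return len(self.a)

    @property
    def n_coefficients(self) -> int:
        return 2 * self.order + 1

    def __call__(self, phase):
        return eval_fourier(self, phase)

    def to_dict(self) -> dict:
        return {"order": self.order, "a0": self.a0,
                "a": self.a.tolist(), "b": self.b.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FourierCurve":
        return cls(a0=float(d["a0"]), a=np.asarray(d["a"]), b=np.asarray(d["b"]))


@dataclass
class DesiredCurve:
    """Final assistance reference: Fourier shape + scale + cycle duration.

    Sign convention: positive force = pull the artificial HAM, negative =
    pull the artificial RF.  ``cycle_duration`` is adapted online from the
    step detector; the stored value is only an initial estimate.
    """

    fourier: FourierCurve
    force_scale: float  # N; max |F_d| over the cycle
    cycle_duration: float = 1.2  # s

    def force_at_phase(self, phase):
        """Desired force F_d (N), clipped to +-force_scale for safety."""
        return np.clip(eval_fourier(self.fourier, phase),
                       -self.force_scale, self.force_scale)

    def to_json(self) -> str:
        d = self.fourier.to_dict()
        d["force_scale"] = self.force_scale
        d["cycle_duration"] = self.cycle_duration
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "DesiredCurve":
        d = json.loads(s)
        return cls(fourier=FourierCurve.from_dict(d),
                   force_scale=float(d["force_scale"]),
                   cycle_duration=float(d.get("cycle_duration", 1.2)))


def fit_fourier(trace: ForceTrace, order: int = 8) -> FourierCurve:
    """Least-squares Fourier fit of a periodic phase-domain trace.

    Ordinary least squares on the design matrix of harmonics; on a uniform
    grid this coincides with the discrete Fourier projection, but the OLS
    form also handles non-uniform grids.
    """
    if order < 1:
        raise CurveDesignError("order must be >= 1")
    phi = np.asarray(trace.grid, dtype=float)
    y = np.asarray(trace.values, dtype=float)
    if len(y) < 2 * order + 1:
        raise CurveDesignError(
            f"need >= {2 * order + 1} samples for order {order}, got {len(y)}")
    k = np.arange(1, order + 1)
    ang = 2.0 * np.pi * np.outer(phi, k)
    X = np.hstack([np.ones((len(phi), 1)), np.cos(ang), np.sin(ang)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return FourierCurve(a0=float(coef[0]), a=coef[1:order + 1], b=coef[order + 1:])


def eval_fourier(curve: FourierCurve, phase):
    """Evaluate the trigonometric polynomial; phase is wrapped mod 1."""
    phi = np.mod(np.asarray(phase, dtype=float), 1.0)
    k = np.arange(1, curve.order + 1)
    ang = 2.0 * np.pi * np.multiply.outer(phi, k)
    out = curve.a0 + np.cos(ang) @ curve.a + np.sin(ang) @ curve.b
    return out if out.ndim else float(out)


def differentiate_periodic(curve: FourierCurve) -> FourierCurve:
    """Analytic term-wise derivative with respect to phase.

    d/dphi [a_k cos(2 pi k phi)] = -2 pi k a_k sin(...), and symmetrically
    for the sine terms; the constant term drops.
    """
    k = np.arange(1, curve.order + 1)
    return FourierCurve(a0=0.0, a=2.0 * np.pi * k * curve.b,
                        b=-2.0 * np.pi * k * curve.a)


def wrapped_gaussian_kernel(n: int, sigma: float) -> np.ndarray:
    """Discrete wrapped (periodic) Gaussian kernel on an n-point phase grid.

    ``sigma`` is in phase-fraction units.  The kernel sums to 1, so circular
    convolution preserves the trace mean and never increases max |trace|.
    """
    if sigma < 0:
        raise CurveDesignError("sigma must be >= 0")
    if sigma == 0:
        k = np.zeros(n)
        k[0] = 1.0
        return k
    # wrap enough images of the Gaussian that the tail truncation is negligible
    offsets = np.arange(-3, 4)
    dist = (np.arange(n) / n)[None, :] + offsets[:, None]
    with np.errstate(over="ignore"):
        k = np.exp(-0.5 * (dist / sigma) ** 2).sum(axis=0)
    if k.sum() == 0.0:  # sigma far below one grid cell: discrete delta
        k = np.zeros(n)
        k[0] = 1.0
        return k
    return k / k.sum()


def gaussian_smooth_periodic(trace: ForceTrace, sigma: float) -> ForceTrace:
    """Circular convolution with a wrapped Gaussian (sigma in cycle fraction)."""
    kern = wrapped_gaussian_kernel(len(trace), sigma)
    sm = np.real(np.fft.ifft(np.fft.fft(trace.values) * np.fft.fft(kern)))
    return trace.copy_with(sm)


def rescale_to_range(trace: ForceTrace, target_max_abs: float) -> ForceTrace:
    """Uniformly rescale so max |trace| equals ``target_max_abs``."""
    if target_max_abs <= 0:
        raise CurveDesignError("target_max_abs must be > 0")
    peak = float(np.max(np.abs(trace.values)))
    if peak == 0.0:
        raise CurveDesignError("cannot rescale an identically zero trace")
    return trace.copy_with(trace.values * (target_max_abs / peak))


def design_empirical_curve(
    ham: ForceTrace,
    rf: ForceTrace,
    order: int = 8,
    sigma: float = 0.03,
    target_max_abs: float = 23.0,
    cycle_duration: float = 1.2,
) -> DesiredCurve:
    """Run the full design workflow on measured artificial-muscle forces.

    Stages: HAM - RF difference -> Fourier fit of the given order ->
    analytic derivative -> periodic Gaussian smoothing (``sigma`` in cycle
    fraction) -> rescale to ``target_max_abs`` (N) -> re-fit so the result
    is again stored as a Fourier curve.

    The defaults (sigma = 0.03 cycle, 23 N target) reflect the hardware
    range observed on the physical suit; both are free parameters.
    """
    if ham.values.shape != rf.values.shape or not np.allclose(ham.grid, rf.grid):
        raise CurveDesignError("HAM and RF traces must share one phase grid")
    diff = ham.copy_with(ham.values - rf.values, label="HAM-RF")
    fc = fit_fourier(diff, order=order)
    dcurve = differentiate_periodic(fc)
    # The HAM-RF difference falls through stance and recovers through
    # swing, so its derivative is negative where the HAM should pull.
    # Under this package's sign convention (positive = HAM pull) the
    # reference is therefore the negated derivative.
    sampled = diff.copy_with(-eval_fourier(dcurve, diff.grid), label="-d(HAM-RF)")
    smoothed = gaussian_smooth_periodic(sampled, sigma)
    scaled = rescale_to_range(smoothed, target_max_abs)
    final = fit_fourier(scaled, order=order)
    return DesiredCurve(fourier=final, force_scale=float(target_max_abs),
                        cycle_duration=cycle_duration)
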