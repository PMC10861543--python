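"""Diffusion-encoding gradient waveform design and analysis.

Two encoding families are supported:

* **Stejskal-Tanner (M0)** -- the classic pulsed pair straddling the
  refocusing pulse.  The effective gradient (sign-flipped after the 180°)
  is bipolar, so the zeroth moment is nulled by construction, but the
  first and second moments are generically nonzero and couple to bulk
  velocity and acceleration of the tissue.
* **Motion-compensated (M01 / M012)** -- multi-lobe designs whose
  effective gradient nulls all moments up to the requested order, making
  the acquired phase insensitive to rigid translation, velocity and
  (for order 2) acceleration.  This is the encoding that makes diffusion
  imaging of the beating heart possible.

Waveforms are discretized on a uniform raster: ``samples[k]`` is the
gradient amplitude held constant over the bin ``[k*dt, (k+1)*dt)``, and
moment/b-value integrals are evaluated exactly for that piecewise-constant
model.  Hardware limits (amplitude and slew rate) are enforced sample-wise
on the physically played waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "HardwareLimits",
    "EncodingSpec",
    "MomentVector",
    "GradientWaveform",
    "InfeasibleEncodingError",
    "gradient_moments",
    "numerical_bvalue",
    "bvalue_stejskal_tanner",
    "rectangular_stejskal_tanner",
    "zero_waveform",
    "design_stejskal_tanner",
    "design_motion_compensated",
]

#: Proton gyromagnetic ratio (rad/s/T).
GAMMA_PROTON = 2.675221874e8

#: Default encoding duration cap (s).
DEFAULT_DURATION_CAP = 30e-3

#: Moment-nulling tolerances for orders 0, 1, 2 (T*s/m, T*s^2/m, T*s^3/m).
MOMENT_TOLERANCES = (1e-9, 1e-12, 1e-15)


class InfeasibleEncodingError(RuntimeError):
    """Raised when no waveform within the hardware limits and duration cap
    reaches the requested b-value.  Carries the best achievable b."""

    def __init__(self, message: str, achieved_b: float | None = None,
                 moments: "MomentVector | None" = None):
        super().__init__(message)
        self.achieved_b = achieved_b
        self.moments = moments


@dataclass(frozen=True)
class HardwareLimits:
    """Gradient hardware limits.

    Parameters
    ----------
    g_max : float
        Maximum gradient amplitude (T/m).
    slew_max : float
        Maximum slew rate (T/m/s).
    dt : float
        Raster time (s).  Default 10 µs.
    """

    g_max: float = 0.440
    slew_max: float = 3440.0
    dt: float = 10e-6

    def __post_init__(self) -> None:
        if self.g_max <= 0 or self.slew_max <= 0 or self.dt <= 0:
            raise ValueError("g_max, slew_max and dt must all be positive")


@dataclass(frozen=True)
class EncodingSpec:
    """Requested diffusion weighting.

    Parameters
    ----------
    b_target : float
        Diffusion weighting (s/mm²).
    nulling_order : int
        Highest gradient-moment index forced to zero: 0 (Stejskal-Tanner),
        1 (velocity-compensated) or 2 (velocity+acceleration compensated).
    gamma : float
        Gyromagnetic ratio (rad/s/T).
    """

    b_target: float = 350.0
    nulling_order: int = 2
    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        if self.b_target < 0:
            raise ValueError("b_target must be non-negative")
        if self.nulling_order not in (0, 1, 2):
            raise ValueError("nulling_order must be 0, 1 or 2")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class MomentVector:
    """Gradient moments of the effective waveform.

    ``m0`` couples to position (T*s/m), ``m1`` to velocity (T*s²/m) and
    ``m2`` to acceleration (T*s³/m).
    """

    m0: float
    m1: float
    m2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m0, self.m1, self.m2])

    def max_order_nulled(self, tolerances=MOMENT_TOLERANCES) -> int:
        """Highest n such that |m0|..|mn| are all within tolerance (-1 if none)."""
        order = -1
        for n, (m, tol) in enumerate(zip(self.as_array(), tolerances)):
            if abs(m) > tol:
                break
            order = n
        return order


@dataclass
class GradientWaveform:
    """A scalar gradient waveform played along one encoding direction.

    ``samples[k]`` (T/m) is held over ``[k*dt, (k+1)*dt)``.  The effective
    gradient seen by transverse magnetization flips sign at the refocusing
    pulse: samples at index >= ``refocus_index`` count with sign -1 in all
    moment and b-value integrals.  ``axis`` is the unit direction the scalar
    waveform is played along (may be None for direction-agnostic designs).
    """

    samples: np.ndarray
    dt: float
    refocus_index: Optional[int] = None
    axis: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.axis is not None:
            self.axis = np.asarray(self.axis, dtype=float)
            n = np.linalg.norm(self.axis)
            if not np.isclose(n, 1.0, rtol=1e-6):
                raise ValueError("axis must be a unit vector")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total duration (s)."""
        return self.samples.size * self.dt

    @property
    def times(self) -> np.ndarray:
        """Bin-center sample times (s)."""
        return (np.arange(self.samples.size) + 0.5) * self.dt

    @property
    def effective_signs(self) -> np.ndarray:
        s = np.ones(self.samples.size)
        if self.refocus_index is not None:
            s[self.refocus_index:] = -1.0
        return s

    @property
    def effective_samples(self) -> np.ndarray:
        """Sign-flipped gradient as seen by the transverse magnetization."""
        return self.samples * self.effective_signs

    def scaled(self, factor: float) -> "GradientWaveform":
        """Amplitude-scaled copy (moments scale linearly, b quadratically)."""
        return GradientWaveform(self.samples * factor, self.dt,
                                self.refocus_index, self.axis,
                                dict(self.meta))

    def validate(self, hw: HardwareLimits) -> None:
        """Raise ValueError if the waveform violates the hardware limits."""
        if np.max(np.abs(self.samples)) > hw.g_max * (1 + 1e-9):
            raise ValueError("gradient amplitude exceeds g_max")
        slew = np.abs(np.diff(self.samples)) / self.dt
        if slew.size and slew.max() > hw.slew_max * (1 + 1e-9):
            raise ValueError("slew rate exceeds slew_max")
        if self.samples[0] != 0.0 or self.samples[-1] != 0.0:
            raise ValueError("waveform must start and end at zero amplitude")


def gradient_moments(wf: GradientWaveform) -> MomentVector:
    """Zeroth, first and second moments of the effective waveform.

    m_n = sum_k s_k * G_k * t_k**n * dt  with s_k = -1 after the refocusing
    pulse and t_k the bin-center times.  Exact for the piecewise-constant
    raster model.
    """
    g = wf.effective_samples
    t = wf.times
    m0 = float(np.sum(g) * wf.dt)
    m1 = float(np.sum(g * t) * wf.dt)
    m2 = float(np.sum(g * t * t) * wf.dt)
    return MomentVector(m0, m1, m2)


def numerical_bvalue(wf: GradientWaveform, gamma: float = GAMMA_PROTON) -> float:
    """b-value (s/mm²) by exact integration of |q(t)|² on the raster.

    q(t) = gamma * int_0^t G_eff dt' is piecewise linear for the
    piecewise-constant gradient model, so int q² dt is evaluated exactly
    per bin as dt*(q0² + q0*q1 + q1²)/3.  For an ideal rectangular
    Stejskal-Tanner pair aligned to the raster this reproduces
    gamma²G²delta²(Delta - delta/3) to machine precision.
    """
    g = wf.effective_samples
    q = np.empty(g.size + 1)
    q[0] = 0.0
    np.cumsum(g * gamma * wf.dt, out=q[1:])
    q0, q1 = q[:-1], q[1:]
    b_si = float(np.sum(q0 * q0 + q0 * q1 + q1 * q1) * wf.dt / 3.0)  # s/m^2
    return b_si * 1e-6  # s/mm^2


def bvalue_stejskal_tanner(g: float, delta: float, big_delta: float,
                           gamma: float = GAMMA_PROTON) -> float:
    """Closed-form b = gamma² G² delta² (Delta - delta/3), in s/mm².

    G in T/m, delta and Delta in seconds.  The rectangular-pulse idealization
    used as the analytic oracle for the numerical integrator.
    """
    return gamma ** 2 * g ** 2 * delta ** 2 * (big_delta - delta / 3.0) * 1e-6


def zero_waveform(dt: float = 10e-6, n_samples: int = 2) -> GradientWaveform:
    """The b=0 encoding: no gradient, no diffusion weighting."""
    return GradientWaveform(np.zeros(n_samples), dt, meta={"b_value": 0.0})


def rectangular_stejskal_tanner(g: float, delta: float, big_delta: float,
                                dt: float = 10e-6) -> GradientWaveform:
    """Ideal rectangular pulse pair: G over [0, delta] and [Delta, Delta+delta],
    refocusing pulse between the lobes.  delta and Delta are rounded to the
    raster.  Not hardware-feasible (infinite slew); used as an analytic
    reference shape.
    """
    nd = int(round(delta / dt))
    ns = int(round(big_delta / dt))
    if nd < 1 or ns < nd:
        raise ValueError("need delta >= dt and Delta >= delta")
    samples = np.zeros(ns + nd + 1)
    samples[:nd] = g
    samples[ns:ns + nd] = g
    refocus = nd + (ns - nd) // 2
    return GradientWaveform(samples, dt, refocus_index=refocus,
                            meta={"delta": nd * dt, "Delta": ns * dt})


def _ramp_steps(g: float, hw: HardwareLimits) -> int:
    """Number of intermediate ramp samples so each raster step obeys slew_max."""
    return max(int(np.ceil(g / (hw.slew_max * hw.dt))) - 1, 0)


def _trapezoid_lobe(n_flat: int, n_ramp: int) -> np.ndarray:
    """Unit-amplitude trapezoid: ramp up, flat top, ramp down.

    Consecutive-sample steps are all 1/(n_ramp+1), so an amplitude-g lobe
    obeys slew_max whenever g/(n_ramp+1) <= slew_max*dt.
    """
    up = np.arange(1, n_ramp + 1) / (n_ramp + 1)
    return np.concatenate([up, np.ones(n_flat), up[::-1]])


def _assemble(lobes: list[np.ndarray]) -> np.ndarray:
    """Concatenate lobes with one leading and trailing zero sample."""
    return np.concatenate([[0.0], *lobes, [0.0]])


def design_stejskal_tanner(spec: EncodingSpec, hw: HardwareLimits,
                           duration_cap: float = DEFAULT_DURATION_CAP
                           ) -> GradientWaveform:
    """Minimal-duration trapezoidal Stejskal-Tanner pair hitting b_target.

    Two identical trapezoid lobes played back-to-back around the (instant)
    refocusing pulse.  The flat-top duration is found by bisection on the
    numerically integrated b; the final exact match is obtained by scaling
    the amplitude down (b scales with G²), so the achieved b equals
    ``spec.b_target`` to machine precision.  The effective gradient is
    bipolar, hence m0 = 0 by construction.

    Raises
    ------
    InfeasibleEncodingError
        If b_target is not reachable within ``duration_cap`` at ``g_max``.
    """
    if spec.b_target == 0.0:
        return zero_waveform(hw.dt)
    n_ramp = _ramp_steps(hw.g_max, hw)

    def build(n_flat: int) -> GradientWaveform:
        lobe = _trapezoid_lobe(n_flat, n_ramp) * hw.g_max
        samples = _assemble([lobe, lobe])
        refocus = 1 + lobe.size  # boundary between the two lobes
        delta = (n_flat + n_ramp) * hw.dt  # area-equivalent rectangle duration
        return GradientWaveform(samples, hw.dt, refocus_index=refocus,
                                meta={"design": "stejskal_tanner",
                                      "delta": delta,
                                      "Delta": lobe.size * hw.dt,
                                      "nulling_order": 0})

    n_max = int(duration_cap / hw.dt - 2) // 2 - 2 * n_ramp
    if n_max < 1:
        raise InfeasibleEncodingError("duration cap too short for a single ramp")
    b_hi = numerical_bvalue(build(n_max), spec.gamma)
    if b_hi < spec.b_target:
        raise InfeasibleEncodingError(
            f"b={spec.b_target} s/mm^2 unreachable within {duration_cap*1e3:.1f} ms "
            f"(best {b_hi:.1f} s/mm^2)", achieved_b=b_hi)
    lo, hi = 0, n_max  # smallest n_flat with b >= target
    while lo < hi:
        mid = (lo + hi) // 2
        if numerical_bvalue(build(mid), spec.gamma) >= spec.b_target:
            hi = mid
        else:
            lo = mid + 1
    wf = build(lo)
    b = numerical_bvalue(wf, spec.gamma)
    wf = wf.scaled(np.sqrt(spec.b_target / b))
    return _finalize(wf, spec, hw)


def design_motion_compensated(spec: EncodingSpec, hw: HardwareLimits,
                              n_lobes: int | None = None,
                              duration_cap: float = DEFAULT_DURATION_CAP
                              ) -> GradientWaveform:
    """Moment-nulled multi-lobe diffusion encoding (M01 / M012).

    The effective waveform is K = ``nulling_order`` + 2 contiguous
    equal-duration trapezoid lobes.  Because every lobe shares the same
    unit shape, the moments are linear in the lobe amplitudes; the
    amplitude vector is taken from the one-dimensional nullspace of the
    discretized moment matrix, which nulls m0..m_order to machine
    precision on the raster.  Lobe duration is the smallest (by bisection)
    that reaches b_target with the largest lobe at g_max; the exact
    b match is then obtained by scaling all amplitudes (which preserves
    the nulling).  The refocusing pulse sits at the mid-lobe boundary;
    the physical waveform flips sign there.

    ``nulling_order=0`` delegates to :func:`design_stejskal_tanner`.
    """
    if spec.nulling_order == 0:
        return design_stejskal_tanner(spec, hw, duration_cap)
    if spec.b_target == 0.0:
        return zero_waveform(hw.dt)
    order = spec.nulling_order
    k = n_lobes if n_lobes is not None else order + 2
    if k < order + 2:
        raise ValueError(f"need at least {order + 2} lobes to null m0..m{order}")
    n_ramp = _ramp_steps(hw.g_max, hw)
    k_half = k // 2

    def build(n_flat: int) -> GradientWaveform:
        # one zero sample between lobes keeps the slew check local to each
        # lobe and puts the refocusing pulse on a zero-gradient sample
        lobe = np.concatenate([_trapezoid_lobe(n_flat, n_ramp), [0.0]])
        L = lobe.size
        t = (np.arange(1, 1 + k * L) + 0.5) * hw.dt  # bin centers, after lead zero
        # moment matrix: rows m0..m_order, columns = lobes (unit amplitude)
        rows = []
        for n in range(order + 1):
            contrib = np.array([np.sum(lobe * t[j * L:(j + 1) * L] ** n) * hw.dt
                                for j in range(k)])
            rows.append(contrib / np.linalg.norm(contrib))
        m = np.vstack(rows)
        # nullspace direction (smallest right singular vector)
        w = np.linalg.svd(m)[2][-1]
        w = w / np.max(np.abs(w))
        if w[np.argmax(np.abs(w) > 1e-12)] < 0:
            w = -w
        samples_eff = _assemble([wi * hw.g_max * lobe for wi in w])
        refocus = k_half * L  # the zero separator after lobe k_half
        signs = np.ones(samples_eff.size)
        signs[refocus:] = -1.0
        wf = GradientWaveform(samples_eff * signs, hw.dt, refocus_index=refocus,
                              meta={"design": f"m{''.join(map(str, range(order + 1)))}",
                                    "n_lobes": k, "lobe_duration": L * hw.dt,
                                    "lobe_weights": w.tolist(),
                                    "nulling_order": order})
        return wf

    n_max = (int(duration_cap / hw.dt) - 2) // k - 2 * n_ramp - 1
    if n_max < 1:
        raise InfeasibleEncodingError("duration cap too short for the lobe count")
    top = build(n_max)
    b_hi = numerical_bvalue(top, spec.gamma)
    if b_hi < spec.b_target:
        raise InfeasibleEncodingError(
            f"b={spec.b_target} s/mm^2 unreachable within {duration_cap*1e3:.1f} ms "
            f"with {k} lobes (best {b_hi:.1f} s/mm^2)",
            achieved_b=b_hi, moments=gradient_moments(top))
    lo, hi = 1, n_max
    while lo < hi:
        mid = (lo + hi) // 2
        if numerical_bvalue(build(mid), spec.gamma) >= spec.b_target:
            hi = mid
        else:
            lo = mid + 1
    wf = build(lo)
    b = numerical_bvalue(wf, spec.gamma)
    wf = wf.scaled(np.sqrt(spec.b_target / b))
    return _finalize(wf, spec, hw)


def _finalize(wf: GradientWaveform, spec: EncodingSpec,
              hw: HardwareLimits) -> GradientWaveform:
    """Validate against hardware limits and record achieved b and moments."""
    wf.validate(hw)
    mom = gradient_moments(wf)
    wf.meta.update({
        "b_value": numerical_bvalue(wf, spec.gamma),
        "gamma": spec.gamma,
        "moments": [mom.m0, mom.m1, mom.m2],
    })
    return wf
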