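"""Mitral inflow velocity waveforms.

A transmitral velocity profile in sinus rhythm has two diastolic peaks: the
early-filling E-wave and the atrial-contraction A-wave.  Atrial fibrillation
abolishes the atrial kick, so simulations of AF drive the flow with the
E-wave only; :func:`remove_a_wave` splices the A-wave out while keeping the
first derivative continuous and the waveform periodic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass
class VelocityWaveform:
    """One period of a uniformly sampled velocity waveform.

    times are in s, spanning [0, T); velocity in m/s; period T in s.
    """

    times: np.ndarray
    velocity: np.ndarray
    period: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if len(self.times) != len(self.velocity):
            raise ValueError("times and velocity must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] >= self.period:
            raise ValueError("times must span [0, T)")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity must be finite")

    def spline(self) -> CubicSpline:
        """Periodic cubic interpolant over one period."""
        t = np.append(self.times, self.times[0] + self.period)
        v = np.append(self.velocity, self.velocity[0])
        return CubicSpline(t, v, bc_type="periodic")

    def evaluate(self, t) -> np.ndarray:
        return self.spline()(np.mod(t, self.period))

    def local_maxima(self, rel_prominence: float = 0.01) -> np.ndarray:
        """Sample indices of local maxima, with periodic wrap.

        Maxima are counted with a prominence floor of ``rel_prominence``
        times the waveform range: physiological peaks (E- and A-waves) have
        prominences of several percent of the range, while the ripple a C1
        splice can leave near diastasis stays well below one percent.  Pass
        0 for raw strict maxima.
        """
        from scipy.signal import find_peaks

        v = self.velocity
        n = len(v)
        rng = float(np.ptp(v))
        if rng == 0:
            return np.array([], dtype=int)
        vv = np.r_[v, v, v]
        pk, _ = find_peaks(vv, prominence=rel_prominence * rng if rel_prominence else None)
        pk = pk[(pk >= n) & (pk < 2 * n)] - n
        return np.sort(pk)

    def mean_velocity(self) -> float:
        t = np.append(self.times, self.times[0] + self.period)
        v = np.append(self.velocity, self.velocity[0])
        return float(np.trapezoid(v, t) / self.period)


def _periodic_gaussian(t, center, width, period):
    """Gaussian bump summed over periodic images, exactly T-periodic in value
    and slope (three images suffice at the widths used here)."""
    acc = np.zeros_like(t, dtype=float)
    for k in (-1, 0, 1):
        acc += np.exp(-0.5 * ((t - center + k * period) / width) ** 2)
    return acc


def generate_mitral_waveform(
    e_peak: float = 0.8,
    a_peak: float = 0.5,
    period: float = 1.0,
    n_samples: int = 64,
) -> VelocityWaveform:
    """Two-peaked (E/A) transmitral velocity fixture.

    The E-wave peaks near 0.3 T and the A-wave near 0.75 T, mimicking a
    pulsed-wave Doppler trace.  ``a_peak = 0`` yields a single-peaked profile.
    An A-wave larger than the E-wave is physiologically atypical (impaired
    relaxation pattern) and is accepted with a warning.
    """
    if e_peak < 0 or a_peak < 0:
        raise ValueError("peak velocities must be >= 0")
    if period <= 0:
        raise ValueError("period must be > 0")
    if n_samples < 32:
        raise ValueError("n_samples must be >= 32")
    if a_peak > e_peak:
        import warnings

        warnings.warn("a_peak > e_peak: atypical (E/A reversal) waveform", stacklevel=2)
    t = np.arange(n_samples) * (period / n_samples)
    v = e_peak * _periodic_gaussian(t, 0.30 * period, 0.07 * period, period)
    if a_peak > 0:
        v = v + a_peak * _periodic_gaussian(t, 0.75 * period, 0.06 * period, period)
    return VelocityWaveform(times=t, velocity=v, period=period)


def _hermite(t_eval, t0, t1, v0, s0, v1, s1):
    """Cubic Hermite segment values at ``t_eval`` in [t0, t1]."""
    h = t1 - t0
    tau = (t_eval - t0) / h
    h00 = 2 * tau**3 - 3 * tau**2 + 1
    h10 = tau**3 - 2 * tau**2 + tau
    h01 = -2 * tau**3 + 3 * tau**2
    h11 = tau**3 - tau**2
    return h00 * v0 + h10 * h * s0 + h01 * v1 + h11 * h * s1


def remove_a_wave(waveform: VelocityWaveform) -> VelocityWaveform:
    """Remove the second (A) peak, keeping the first derivative continuous.

    The E-wave up to diastasis (the minimum between the two peaks) is
    preserved sample-for-sample; the remainder of the cycle is replaced by a
    cubic Hermite branch whose endpoint values and slopes match the retained
    signal, so the result is C1 at both splice points and periodic.  If that
    single segment would go negative or leave a residual hump (it can for
    small A-waves, where the sampled diastasis sits on a slope), the branch
    is rebuilt as descend / flat-floor / rise Hermite segments whose lengths
    keep each sloped segment in the monotone (Fritsch-Carlson) regime.  A
    single-peaked input is returned unchanged.
    """
    peaks = waveform.local_maxima()
    if len(peaks) <= 1:
        return waveform
    order = peaks[np.argsort(waveform.velocity[peaks])[::-1]]
    p1, p2 = sorted(order[:2])
    v = waveform.velocity
    t = waveform.times
    T = waveform.period
    spl = waveform.spline()
    v_end, s_end = v[0], float(spl(0.0, 1))
    i_min = p1 + 1 + int(np.argmin(v[p1 + 1 : p2]))

    def assemble(i_d, branch_fn):
        t_d, v_d, s_d = t[i_d], v[i_d], float(spl(t[i_d], 1))
        new_v = v.copy()
        new_v[i_d + 1 :] = branch_fn(t[i_d + 1 :], t_d, v_d, s_d)
        return new_v

    def single(te, t_d, v_d, s_d):
        return _hermite(te, t_d, T, v_d, s_d, v_end, s_end)

    def three_piece(te, t_d, v_d, s_d):
        # descend -> flat diastolic floor -> rise, each segment short enough
        # to stay in the monotone (Fritsch-Carlson) regime of its slopes
        span = T - t_d
        v_mid = 0.4 * min(v_d, v_end)
        if s_d < -1e-12 and v_d > v_mid:
            len1 = min(2.0 * (v_d - v_mid) / -s_d, 0.45 * span)
        else:
            len1 = 0.45 * span
        if s_end > 1e-12 and v_end > v_mid:
            len3 = min(2.0 * (v_end - v_mid) / s_end, 0.45 * span)
        else:
            len3 = 0.45 * span
        len3 = max(len3, 1e-6 * span)
        t_a, t_b = t_d + len1, T - len3
        out = np.empty_like(te)
        lo = te <= t_a
        hi = te > t_b
        mid = ~lo & ~hi
        out[lo] = _hermite(te[lo], t_d, t_a, v_d, s_d, v_mid, 0.0)
        out[mid] = v_mid
        out[hi] = _hermite(te[hi], t_b, T, v_mid, 0.0, v_end, s_end)
        return out

    def acceptable(new_v):
        if new_v.min() < -1e-9 * max(v.max(), 1e-12):
            return False
        cand = VelocityWaveform(t.copy(), np.maximum(new_v, 0.0), T)
        return len(cand.local_maxima()) == 1

    candidates = [(i_min, single)]
    i_back = i_min
    while i_back > p1 + 1 and float(spl(t[i_back], 1)) > 0:
        i_back -= 1
    candidates += [(i_min, three_piece), (i_back, three_piece)]
    for i_d, fn in candidates:
        new_v = assemble(i_d, fn)
        if acceptable(new_v):
            return VelocityWaveform(t.copy(), np.maximum(new_v, 0.0), T)
    raise ValueError("could not construct a valid single-peak replacement branch")
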