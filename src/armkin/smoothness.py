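"""Movement-smoothness metrics.

Five complementary measures, all computed per movement segment:

- velocity ratio MV/PV — how evenly speed is distributed;
- number of velocity peaks (NPV) — thresholded local-maxima count, a proxy
  for the number of submovements;
- zero-crossings of the (tangential or angular) acceleration — corrective
  direction changes;
- log dimensionless jerk (LDJ) — negative log of the time- and
  length-normalized integrated squared jerk of the 3D position;
- spectral arc length (SPARC) — negative arc length of the normalized
  Fourier magnitude spectrum of the speed profile up to a cutoff.

For LDJ and SPARC, smoother movement gives values closer to zero (less
negative); for NPV and zero-crossings, smaller counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .diffkin import Path3D, ScalarProfile, differentiate, path_length, resample_uniform
from .io import Segment
from .metrics import mean_velocity, peak_velocity

#: Relative spread of sampling intervals above which a profile is treated as
#: non-uniform and resampled before spectral analysis.
_JITTER_TOL = 0.01


@dataclass(frozen=True)
class PeakParams:
    """Velocity-peak detection thresholds.

    ``delta`` is the minimum rise (mm/s) of a peak over the preceding local
    minimum; ``tau`` the refractory interval (s) since the last accepted peak.
    Defaults of 20 mm/s and 150 ms suit reaching-scale movements and can be
    adjusted to the speed profiles at hand.
    """

    delta: float = 20.0
    tau: float = 0.150

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")


@dataclass(frozen=True)
class SparcParams:
    """Spectral arc-length parameters.

    ``omega_c`` (rad/s, default 40π ≙ 20 Hz) bounds the frequency band
    relevant to human movement; ``amp_threshold`` sets the adaptive cutoff on
    the normalized magnitude spectrum; ``pad_level`` controls zero-padding
    (FFT length 2^(⌈log2 N⌉ + pad_level)).  ``resample_rate`` overrides the
    rate used when a non-uniform profile must be resampled first.
    """

    omega_c: float = 40.0 * math.pi
    pad_level: int = 4
    amp_threshold: float = 0.05
    resample_rate: float | None = None

    def __post_init__(self) -> None:
        if self.omega_c <= 0:
            raise ValueError("omega_c must be positive")
        if not 0 < self.amp_threshold < 1:
            raise ValueError("amp_threshold must be in (0, 1)")
        if self.pad_level < 0:
            raise ValueError("pad_level must be non-negative")


def velocity_ratio(profile: ScalarProfile) -> float:
    """Mean over peak velocity, in (0, 1]; 1 means perfectly even speed."""
    pv = peak_velocity(profile)
    if pv == 0:
        raise ValueError("undefined ratio for an all-zero speed profile")
    return mean_velocity(profile) / pv


def count_velocity_peaks(profile: ScalarProfile, params: PeakParams = PeakParams()) -> int:
    """Count speed-profile peaks passing amplitude and refractory conditions.

    A sample is an accepted peak when, scanned left to right:

    1. it is a strict local maximum (plateaus are collapsed to their first
       sample and treated as one candidate);
    2. it rises more than ``delta`` above the most recent local minimum (or
       the segment's first sample if none precedes it);
    3. at least ``tau`` seconds have passed since the last *accepted* peak —
       a candidate rejected here does not reset the refractory clock.
    """
    if len(profile) < 3:
        raise ValueError("need at least 3 samples to count peaks")
    v = profile.values
    t = profile.times
    keep = np.concatenate([[True], np.diff(v) != 0])
    idx = np.flatnonzero(keep)
    w = v[idx]
    tw = t[idx]
    count = 0
    last_accepted = -math.inf
    ref_min = w[0]
    for i in range(1, len(w) - 1):
        if w[i - 1] < w[i] > w[i + 1]:
            if (w[i] - ref_min > params.delta) and (tw[i] - last_accepted >= params.tau):
                count += 1
                last_accepted = tw[i]
        elif w[i - 1] > w[i] < w[i + 1]:
            ref_min = w[i]
    return count


def zero_crossings_accel(accel: ScalarProfile) -> int:
    """Count sign changes of a signed acceleration series.

    Exact-zero samples are skipped and the comparison uses the nearest
    non-zero neighbours, so a touch-without-cross counts 0 and a sign change
    passing exactly through zero counts 1.
    """
    if len(accel) < 2:
        raise ValueError("need at least 2 acceleration samples")
    a = accel.values[accel.values != 0]
    if len(a) < 2:
        return 0
    return int(np.sum(a[:-1] * a[1:] < 0))


def log_dimensionless_jerk(path: Path3D, seg: Segment | None = None) -> float:
    """LDJ = -ln( MT^5 / PL^2 * ∫ ||j(t)||^2 dt ), dimensionless.

    ``j(t)`` is the third derivative of the 3D position, the integral is the
    trapezoidal rule over the segment, MT the duration and PL the path
    length.  Scale- and duration-invariant by construction; an ideally smooth
    straight reach gives -ln(720).  More negative means less smooth.
    """
    if seg is not None:
        mask = (path.times >= seg.t0) & (path.times <= seg.t1)
        path = Path3D(times=path.times[mask], points=path.points[mask])
    if len(path) < 4:
        raise ValueError("need at least 4 samples for jerk")
    mt = float(path.times[-1] - path.times[0])
    pl = path_length(path)
    if mt <= 0:
        raise ValueError("zero movement duration")
    if pl <= 0:
        raise ValueError("zero path length")
    jerk = differentiate(path, 3).points
    integral = float(np.trapezoid(np.sum(jerk**2, axis=1), path.times))
    return -math.log(mt**5 / pl**2 * integral)


def sparc(profile: ScalarProfile, params: SparcParams = SparcParams()) -> float:
    """Spectral arc length of a speed profile (negative; ≤ -1).

    The speed signal is zero-padded and Fourier-transformed; the magnitude
    spectrum is normalized by its DC value V(0); an adaptive cutoff keeps the
    band from 0 up to the last frequency ≤ ω_c where the normalized magnitude
    still reaches ``amp_threshold``; the arc length of the spectrum over that
    band (frequency axis normalized to [0, 1]) is returned negated.
    """
    if len(profile) < 8:
        raise ValueError("need at least 8 samples for SPARC")
    dt = np.diff(profile.times)
    if (dt.max() - dt.min()) / dt.mean() > _JITTER_TOL:
        rate = params.resample_rate or round(1.0 / float(np.median(dt)))
        profile = resample_uniform(profile, rate)
        dt = np.diff(profile.times)
    fs = 1.0 / float(np.mean(dt))
    v = profile.values
    nfft = int(2 ** (np.ceil(np.log2(len(v))) + params.pad_level))
    freqs = np.arange(nfft) * (fs / nfft)
    mag = np.abs(np.fft.fft(v, nfft))
    if mag[0] == 0:
        raise ValueError("zero-mean signal: V(0) = 0, spectrum cannot be normalized")
    mag = mag / mag[0]
    fc = params.omega_c / (2.0 * math.pi)
    sel = freqs <= fc
    f_sel, m_sel = freqs[sel], mag[sel]
    above = np.flatnonzero(m_sel >= params.amp_threshold)
    f_sel = f_sel[above[0] : above[-1] + 1]
    m_sel = m_sel[above[0] : above[-1] + 1]
    band = f_sel[-1] - f_sel[0]
    if band <= 0:
        raise ValueError("degenerate spectral band")
    return -float(np.sum(np.sqrt((np.diff(f_sel) / band) ** 2 + np.diff(m_sel) ** 2)))
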