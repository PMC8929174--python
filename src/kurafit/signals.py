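"""Band-limited signal preparation for coupling estimation.

This module turns raw multivariate region time courses into the objects the
estimators consume: zero-phase band-pass filtered series, analytic-signal
instantaneous phases and amplitudes, per-region eigenfrequencies, and the
Kuramoto order parameter / metastability screening utility.

Conventions
-----------
* A cohort member is a :class:`TimeCourseSet`: an ``r x T`` real matrix of
  region time courses sampled every ``dt`` seconds.
* Phases are always *unwrapped* along time (continuous, not folded to
  ``(-pi, pi]``); downstream least-squares fitting differences them, so a
  ``2*pi`` fold would inject spurious jumps.
* Eigenfrequencies are expressed in radians per sample step (the iteration
  step of the discretised phase model is 1 sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InvalidBandError, UndefinedPhaseError, ValidationError

__all__ = [
    "TimeCourseSet",
    "AnalyticPhaseSet",
    "EigenfrequencySpec",
    "bandpass_filter",
    "analytic_phase",
    "eigenfrequencies",
    "order_parameter_metastability",
    "metastability_band_screen",
]

#: Default narrow analysis band (Hz) used for phase-based measures.
NARROW_BAND = (0.05, 0.075)
#: Default wide band (Hz) used for correlation / autoregressive measures.
WIDE_BAND = (0.01, 0.1)


@dataclass
class TimeCourseSet:
    """One subject's region time courses.

    Parameters
    ----------
    data : ndarray, shape (r, T)
        Real-valued region time courses, one row per region.
    dt : float
        Sampling interval in seconds (``> 0``).
    region_labels : list of str, optional
        Length-``r`` region names; defaults to ``"R00", "R01", ...``.
    subject_id : str
        Identifier carried through to cohort stacks and reports.
    """

    data: np.ndarray
    dt: float
    region_labels: list[str] | None = None
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D (regions x time) matrix")
        r, T = self.data.shape
        if r < 2:
            raise ValidationError(f"need at least 2 regions, got {r}")
        if T < r + 2:
            raise ValidationError(
                f"need T >= r + 2 samples for an over-determined system, "
                f"got T={T}, r={r}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("time courses contain non-finite values")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValidationError(f"dt must be positive and finite, got {self.dt}")
        if self.region_labels is None:
            self.region_labels = [f"R{i:02d}" for i in range(r)]
        if len(self.region_labels) != r:
            raise ValidationError("region_labels length must match region count")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt


@dataclass
class AnalyticPhaseSet:
    """Unwrapped instantaneous phases and amplitudes of a band-limited set.

    ``amplitudes * cos(phases)`` reconstructs the band-passed input (the real
    part of the analytic signal is the input itself).
    """

    phases: np.ndarray
    amplitudes: np.ndarray
    band: tuple[float, float]
    dt: float
    region_labels: list[str] | None = None
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.phases.shape != self.amplitudes.shape or self.phases.ndim != 2:
            raise ValidationError("phases and amplitudes must share an (r, T) shape")
        if np.any(self.amplitudes < 0):
            raise ValidationError("amplitudes must be nonnegative")
        if self.region_labels is None:
            self.region_labels = [f"R{i:02d}" for i in range(self.phases.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.phases.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[1]


@dataclass
class EigenfrequencySpec:
    """Per-region eigenfrequencies in radians per sample step.

    ``mode="band_mean"`` sets every entry to ``2*pi*mean(band)*dt`` (the band
    centre expressed per step); ``mode="fft_peak"`` takes each region's
    largest in-band spectral peak.
    """

    mode: str
    values: np.ndarray
    fallback_regions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("band_mean", "fft_peak"):
            raise ValidationError(f"unknown eigenfrequency mode {self.mode!r}")
        if self.values.ndim != 1 or np.any(self.values <= 0):
            raise ValidationError("eigenfrequencies must be a positive vector")


def _validate_band(band: tuple[float, float], nyquist: float) -> tuple[float, float]:
    low, high = float(band[0]), float(band[1])
    if not (0.0 < low < high < nyquist):
        raise InvalidBandError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist} Hz)"
        )
    return low, high


def bandpass_filter(
    tc: TimeCourseSet,
    low_hz: float,
    high_hz: float,
    order: int = 7,
) -> TimeCourseSet:
    """Zero-phase Butterworth band-pass filter, applied per region.

    The filter is applied forward and backward (``sosfiltfilt``) so the
    response has exactly zero phase — causal filtering would bias the
    instantaneous phases that are the estimation substrate downstream.
    ``order`` is the one-pass Butterworth order (the two-pass magnitude
    response is its square).
    """
    low, high = _validate_band((low_hz, high_hz), tc.nyquist)
    if order < 1:
        raise ValidationError(f"filter order must be >= 1, got {order}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=1.0 / tc.dt, output="sos")
    filtered = sps.sosfiltfilt(sos, tc.data, axis=1)
    return TimeCourseSet(
        data=filtered,
        dt=tc.dt,
        region_labels=list(tc.region_labels),
        subject_id=tc.subject_id,
    )


def analytic_phase(
    tc: TimeCourseSet,
    band: tuple[float, float],
    trim_edges: int = 0,
) -> AnalyticPhaseSet:
    """Instantaneous phase/amplitude via the analytic signal.

    The Hilbert transform supplies the quadrature (quarter-cycle shifted)
    component; the analytic signal ``x + i*H{x}`` then yields amplitude
    ``a(t) = |x_a(t)|`` and phase ``phi(t) = angle(x_a(t))``, unwrapped along
    time.  The caller is expected to band-limit ``tc`` first (``band`` is
    recorded for band-discipline checks downstream).

    Edge transients of the transform are kept by default (every sample
    contributes an estimation equation); ``trim_edges=k`` drops the first
    and last ``k`` samples instead.
    """
    if trim_edges < 0 or 2 * trim_edges >= tc.n_samples - 2:
        raise ValidationError(f"cannot trim {trim_edges} samples from each end")
    zero_rows = np.flatnonzero(np.all(tc.data == 0.0, axis=1))
    if zero_rows.size:
        labels = [tc.region_labels[i] for i in zero_rows]
        raise UndefinedPhaseError(
            f"phase undefined for all-zero region series: {labels}"
        )
    analytic = sps.hilbert(tc.data, axis=1)
    phases = np.unwrap(np.angle(analytic), axis=1)
    amplitudes = np.abs(analytic)
    if trim_edges:
        phases = phases[:, trim_edges:-trim_edges]
        amplitudes = amplitudes[:, trim_edges:-trim_edges]
    return AnalyticPhaseSet(
        phases=phases,
        amplitudes=amplitudes,
        band=(float(band[0]), float(band[1])),
        dt=tc.dt,
        region_labels=list(tc.region_labels),
        subject_id=tc.subject_id,
    )


def eigenfrequencies(
    tc: TimeCourseSet,
    band: tuple[float, float],
    mode: str = "band_mean",
) -> EigenfrequencySpec:
    """Per-region eigenfrequencies (rad per sample step).

    band_mean
        All regions share the band-centre frequency: for a narrow analysis
        band every oscillator is assumed to drift at the band mean.
    fft_peak
        Each region's frequency is the argmax of its amplitude spectrum
        (plain, untapered periodogram) restricted to the band.  Regions with
        no usable in-band peak fall back to the band mean and are listed in
        ``fallback_regions`` (a warning is emitted).
    """
    low, high = _validate_band(band, tc.nyquist)
    r, T = tc.data.shape
    centre = 2.0 * np.pi * 0.5 * (low + high) * tc.dt
    if mode == "band_mean":
        return EigenfrequencySpec(mode=mode, values=np.full(r, centre))
    if mode != "fft_peak":
        raise ValidationError(f"unknown eigenfrequency mode {mode!r}")

    freqs = np.fft.rfftfreq(T, d=tc.dt)
    spectrum = np.abs(np.fft.rfft(tc.data, axis=1))
    in_band = (freqs >= low) & (freqs <= high)
    values = np.full(r, centre)
    fallback: list[int] = []
    if not np.any(in_band):
        fallback = list(range(r))
    else:
        band_freqs = freqs[in_band]
        band_spec = spectrum[:, in_band]
        for i in range(r):
            s = band_spec[i]
            if not np.any(s > 0) or np.allclose(s, s[0]):
                fallback.append(i)
            else:
                values[i] = 2.0 * np.pi * band_freqs[int(np.argmax(s))] * tc.dt
    if fallback:
        warnings.warn(
            f"no in-band spectral peak for region(s) {fallback}; "
            "falling back to the band-mean eigenfrequency",
            stacklevel=2,
        )
    return EigenfrequencySpec(mode=mode, values=values, fallback_regions=fallback)


def order_parameter_metastability(
    phases: AnalyticPhaseSet | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Kuramoto order parameter R(t) and metastability.

    ``R(t) = |mean_j exp(i*phi_j(t))|`` measures instantaneous global
    synchrony (1 = all regions phase-aligned, ~1/sqrt(r) for incoherent
    phases).  Metastability is the temporal standard deviation of R(t): how
    much the system wanders between synchronised and desynchronised states.
    """
    phi = phases.phases if isinstance(phases, AnalyticPhaseSet) else np.asarray(phases)
    if phi.ndim != 2 or phi.shape[0] < 2:
        raise ValidationError("need an (r >= 2, T) phase matrix")
    R_t = np.abs(np.mean(np.exp(1j * phi), axis=0))
    return R_t, float(np.std(R_t))


def metastability_band_screen(
    tc: TimeCourseSet,
    bands: list[tuple[float, float]],
    order: int = 7,
) -> list[dict]:
    """Metastability over caller-supplied frequency bands.

    For each band: band-pass, extract phases, compute the order-parameter
    standard deviation.  Used to screen for bands in which global synchrony
    fluctuates; the bands are entirely the caller's choice.
    """
    out = []
    for band in bands:
        filtered = bandpass_filter(tc, band[0], band[1], order=order)
        aps = analytic_phase(filtered, band)
        R_t, meta = order_parameter_metastability(aps)
        out.append(
            {
                "band": (float(band[0]), float(band[1])),
                "metastability": meta,
                "mean_R": float(np.mean(R_t)),
            }
        )
    return out
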