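"""Deterministic signal conditioning.

EMG envelope extraction (30-500 Hz band-pass, full-wave rectification, 6 Hz
low-pass), MVC normalisation, zero-phase Butterworth filtering of mechanics
channels, and time-normalisation of stance-phase curves onto a fixed
percentage grid.  All filters are 2nd-order Butterworth applied forward and
backward (zero phase; the bidirectional pass squares the single-pass
magnitude response, so the gain at the cutoff is 0.5), with odd-reflection
edge padding of three filter lengths so outputs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .errors import InputError

logger = logging.getLogger(__name__)

STANCE_GRID_POINTS = 101


@dataclass
class TimeSeries:
    """Uniformly sampled, named multi-channel series."""

    time: np.ndarray
    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or t.size != len(self.data):
            raise InputError("time vector must be 1-D and match the data length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise InputError("time must be strictly increasing")
            if np.ptp(dt) > 1e-9:
                raise InputError("sampling must be uniform (jitter > 1 ns)")
        self.time = t

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def copy_with(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(self.time.copy(),
                          pd.DataFrame(values, columns=self.data.columns),
                          dict(self.units))


def _butter_sos(kind: str, cutoff_hz, fs: float, order: int):
    nyq = fs / 2.0
    cutoffs = np.atleast_1d(np.asarray(cutoff_hz, dtype=float))
    if np.any(cutoffs >= nyq) or np.any(cutoffs <= 0):
        raise InputError(f"cutoff(s) {cutoffs} must lie in (0, Nyquist={nyq:g}) Hz")
    if kind == "lowpass":
        return _sig.butter(order, float(cutoffs[0]), btype="low", fs=fs, output="ba")
    if kind == "bandpass":
        if cutoffs.size != 2:
            raise InputError("bandpass requires (low, high) cutoffs")
        return _sig.butter(order, cutoffs, btype="band", fs=fs, output="ba")
    raise InputError(f"unknown filter kind {kind!r}")


def _filtfilt(x: np.ndarray, kind: str, cutoff_hz, fs: float, order: int = 2) -> np.ndarray:
    b, a = _butter_sos(kind, cutoff_hz, fs, order)
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= padlen:
        raise InputError(f"series too short ({x.shape[0]} samples) for padlen {padlen}")
    return _sig.filtfilt(b, a, x, axis=0, padtype="odd", padlen=padlen)


def filter_bidirectional(x: TimeSeries, kind: str, cutoff_hz, order: int = 2) -> TimeSeries:
    """Zero-phase Butterworth filter of every channel (default 2nd order per pass)."""
    return x.copy_with(_filtfilt(x.data.to_numpy(dtype=float), kind, cutoff_hz, x.fs, order))


def emg_envelope(raw: TimeSeries, band=(30.0, 500.0), lowpass_hz: float = 6.0) -> TimeSeries:
    """Linear envelopes: band-pass 30-500 Hz, full-wave rectify, low-pass 6 Hz.

    Requires a sampling rate of at least 1000 Hz; small negative excursions
    introduced by the final low-pass are clipped to zero.
    """
    if raw.fs < 1000.0:
        raise InputError(f"EMG sampling rate {raw.fs:g} Hz is too low (need >= 1000 Hz)")
    x = raw.data.to_numpy(dtype=float)
    hi = min(band[1], 0.99 * raw.fs / 2.0)
    x = _filtfilt(x, "bandpass", (band[0], hi), raw.fs)
    x = np.abs(x)
    x = _filtfilt(x, "lowpass", lowpass_hz, raw.fs)
    return raw.copy_with(np.clip(x, 0.0, None))


def normalize_to_mvc(envelopes: TimeSeries, mvc_max: dict) -> TimeSeries:
    """Scale each envelope channel by its MVC maximum; clip excursions above 1.

    Raises :class:`~tfsupport.errors.ConfigError`-style input error if a
    channel has no MVC value; the number of clipped samples is logged.
    """
    from .errors import ConfigError

    missing = [c for c in envelopes.data.columns if c not in mvc_max]
    if missing:
        raise ConfigError(f"missing MVC maxima for channels: {missing}")
    bad = [c for c in envelopes.data.columns if not mvc_max[c] > 0]
    if bad:
        raise InputError(f"MVC maxima must be > 0; offending channels: {bad}")
    x = envelopes.data.to_numpy(dtype=float) / np.array(
        [mvc_max[c] for c in envelopes.data.columns]
    )
    n_clip = int(np.sum(x > 1.0))
    if n_clip:
        logger.info("MVC normalisation clipped %d samples above 1.0", n_clip)
    return envelopes.copy_with(np.clip(x, 0.0, 1.0))


def time_normalize_stance(
    x: TimeSeries, t_contact: float, t_toeoff: float, n_points: int = STANCE_GRID_POINTS
):
    """Resample channels onto ``n_points`` equally spaced across stance.

    Returns ``(grid_pct, DataFrame)`` where ``grid_pct`` runs 0-100% of the
    foot-contact-to-toe-off interval.  Linear interpolation; endpoints are the
    boundary interpolants, so resampling a resampled curve is idempotent.
    """
    if not (t_contact < t_toeoff):
        raise InputError("t_contact must precede t_toeoff")
    if t_contact < x.time[0] - 1e-12 or t_toeoff > x.time[-1] + 1e-12:
        raise InputError("stance events lie outside the series")
    if n_points < 2:
        raise InputError("n_points must be >= 2")
    tq = np.linspace(t_contact, t_toeoff, n_points)
    out = {
        c: np.interp(tq, x.time, x.data[c].to_numpy(dtype=float))
        for c in x.data.columns
    }
    grid = np.linspace(0.0, 100.0, n_points)
    return grid, pd.DataFrame(out)
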