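"""Baseline removal, FIR band-limiting, rate conversion and trimming.

The stages mirror a conventional clinical-ECG cleanup chain: a running-median
baseline estimate is subtracted per lead (a ~0.9 s window exceeds one beat at
normal rates, so the median tracks drift rather than QRS energy), an FIR
low-pass plus high-pass pair band-limits the signal, the record is resampled
from the acquisition rate (500 Hz) down to 200 Hz, and 50 samples are dropped
from each end to discard handling artefacts, leaving the 12 x 1900 matrix the
classifier consumes.

All stages operate per lead independently and preserve finiteness.  The FIR
pair is applied forward-backward (zero phase) so R-peak positions are not
displaced by group delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal as sps

from .io import ECGRecord


@dataclass
class PreprocessConfig:
    alpha_median: float = 0.9   # median window length, seconds
    f_clp: float = 40.0         # low-pass cutoff, Hz
    f_chp: float = 2.0          # high-pass cutoff, Hz
    F_order: int = 8            # FIR order (taps = order + 1)
    target_fs: float = 200.0
    trim_head: int = 50
    trim_tail: int = 50

    def validate(self) -> None:
        if not (0 < self.f_chp < self.f_clp < self.target_fs / 2):
            raise ValueError("need 0 < f_chp < f_clp < target_fs/2")
        if self.F_order < 1:
            raise ValueError("F_order must be >= 1")
        if self.alpha_median <= 0:
            raise ValueError("alpha_median must be > 0")


def median_window(alpha_median: float, fs: float) -> int:
    """Median window in samples: round(alpha_median * fs), forced odd."""
    w = int(round(alpha_median * fs))
    return w + 1 if w % 2 == 0 else w


def remove_baseline(record: ECGRecord, alpha_median: float = 0.9) -> ECGRecord:
    """Subtract the per-lead running-median baseline estimate.

    Edges are handled by reflection; output length equals input length.
    """
    w = median_window(alpha_median, record.fs)
    if w >= record.n_samples:
        raise ValueError(
            f"record length {record.n_samples} shorter than median window {w}")
    baseline = ndimage.median_filter(record.signal, size=(1, w), mode="reflect")
    return record.with_signal(record.signal - baseline)


def design_firs(f_clp: float, f_chp: float, F_order: int, fs: float):
    """Hamming-window FIR low-pass and high-pass taps (order + 1 each)."""
    if f_clp >= fs / 2:
        raise ValueError(f"f_clp={f_clp} must be below Nyquist {fs / 2}")
    ntaps = F_order + 1
    if ntaps % 2 == 0:
        ntaps += 1  # high-pass needs a Type-I (odd-tap) linear-phase FIR
    lp = sps.firwin(ntaps, f_clp, window="hamming", fs=fs)
    hp = sps.firwin(ntaps, f_chp, window="hamming", pass_zero=False, fs=fs)
    return lp, hp


def fir_frequency_response(taps: np.ndarray, f: float, fs: float,
                           zero_phase: bool = True) -> float:
    """|H(f)| of the designed filter; squared when applied forward-backward."""
    _, h = sps.freqz(taps, worN=[f], fs=fs)
    mag = float(np.abs(h[0]))
    return mag ** 2 if zero_phase else mag


def fir_bandlimit(record: ECGRecord, f_clp: float = 40.0, f_chp: float = 2.0,
                  F_order: int = 8) -> ECGRecord:
    """Low-pass then high-pass FIR filtering, zero-phase, per lead."""
    lp, hp = design_firs(f_clp, f_chp, F_order, record.fs)
    out = sps.filtfilt(lp, [1.0], record.signal, axis=1)
    out = sps.filtfilt(hp, [1.0], out, axis=1)
    return record.with_signal(out)


def downsample(record: ECGRecord, target_fs: float = 200.0) -> ECGRecord:
    """Polyphase rational resampling with built-in anti-aliasing."""
    if target_fs > record.fs:
        raise ValueError("upsampling is out of scope (target_fs > fs)")
    if target_fs == record.fs:
        return record.copy()
    frac = Fraction(target_fs / record.fs).limit_denominator(1000)
    out = sps.resample_poly(record.signal, frac.numerator, frac.denominator,
                            axis=1)
    return record.with_signal(out, fs=target_fs)


def trim(record: ECGRecord, trim_head: int = 50, trim_tail: int = 50) -> ECGRecord:
    """Drop ``trim_head``/``trim_tail`` samples from each lead."""
    if trim_head < 0 or trim_tail < 0:
        raise ValueError("trim counts must be non-negative")
    if record.n_samples <= trim_head + trim_tail:
        raise ValueError(
            f"record of {record.n_samples} samples too short to trim "
            f"{trim_head}+{trim_tail}")
    stop = record.n_samples - trim_tail if trim_tail else record.n_samples
    return record.with_signal(record.signal[:, trim_head:stop])
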