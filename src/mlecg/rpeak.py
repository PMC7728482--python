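"""Wavelet-based R-peak detection and Q/S boundary delineation.

The detector decomposes a single lead with a 5-level Haar discrete wavelet
transform, keeps only the level-4 and level-5 detail bands, and inverts the
transform to obtain a "detection sequence" in which QRS energy dominates.
Candidate peaks are local maxima of the absolute detection sequence above a
relative amplitude threshold, pruned by a physiological refractory period,
and finally refined to the apex of the original waveform.  Q and S
boundaries are then located as the lowest-amplitude extrema in a window on
either side of each R apex.

Detection is conventionally run on lead II; the resulting annotation is
shared across all leads of a record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps


@dataclass
class RPeakConfig:
    wavelet: str = "haar"
    levels: int = 5
    detail_levels: tuple = (4, 5)       # 1 = finest band
    amp_threshold_frac: float = 0.5     # fraction of detection-sequence max
    refractory: float = 0.2             # s, minimum peak separation
    refine_window: float = 0.05         # s, half-width for apex refinement
    search_window: float = 0.1          # s, Q/S boundary search half-width
    keep_approx: bool = False           # keep the approximation band too

    def validate(self) -> None:
        if not set(self.detail_levels) <= set(range(1, self.levels + 1)):
            raise ValueError("detail_levels must be a subset of 1..levels")
        if not (0 < self.amp_threshold_frac < 1):
            raise ValueError("amp_threshold_frac must lie in (0, 1)")
        if self.refractory <= 0:
            raise ValueError("refractory must be > 0")


@dataclass
class RPeakAnnotation:
    """Per-beat R apex and Q/S boundary sample indices (0-based).

    The QRS region of beat ``i`` is the closed interval
    ``[q_locs[i], s_locs[i]]``.  ``clamped[i]`` marks beats whose search
    window hit a record edge.
    """

    r_locs: np.ndarray
    q_locs: np.ndarray
    s_locs: np.ndarray
    clamped: np.ndarray = field(default=None)

    def __post_init__(self):
        self.r_locs = np.asarray(self.r_locs, dtype=int)
        self.q_locs = np.asarray(self.q_locs, dtype=int)
        self.s_locs = np.asarray(self.s_locs, dtype=int)
        if self.clamped is None:
            self.clamped = np.zeros(len(self.r_locs), dtype=bool)
        if not (len(self.r_locs) == len(self.q_locs) == len(self.s_locs)):
            raise ValueError("r/q/s index arrays must have equal length")

    def to_dict(self) -> dict:
        return {"r": self.r_locs.tolist(), "q": self.q_locs.tolist(),
                "s": self.s_locs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RPeakAnnotation":
        return cls(np.asarray(d["r"]), np.asarray(d["q"]), np.asarray(d["s"]))


def detection_sequence(signal: np.ndarray, config: RPeakConfig | None = None) -> np.ndarray:
    """Inverse DWT keeping only the configured detail bands.

    Non-dyadic lengths are handled by symmetric extension inside the DWT;
    the reconstruction is truncated back to the input length.
    """
    config = config or RPeakConfig()
    config.validate()
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 2 ** config.levels:
        raise ValueError(
            f"signal of {x.size} samples too short for {config.levels} DWT levels")
    coeffs = pywt.wavedec(x, config.wavelet, level=config.levels,
                          mode="symmetric")
    # coeffs = [cA_L, cD_L, cD_{L-1}, ..., cD_1]
    kept = []
    for i, c in enumerate(coeffs):
        if i == 0:
            kept.append(c if config.keep_approx else np.zeros_like(c))
        else:
            level = config.levels - i + 1
            kept.append(c if level in config.detail_levels else np.zeros_like(c))
    rec = pywt.waverec(kept, config.wavelet, mode="symmetric")
    return rec[: x.size]


def detect_r_peaks(signal: np.ndarray, config: RPeakConfig | None = None,
                   fs: float = 200.0) -> np.ndarray:
    """R-apex sample indices from the wavelet detection sequence.

    Candidates are local maxima of ``|detection sequence|`` exceeding
    ``amp_threshold_frac`` of its maximum; candidates closer than the
    refractory period keep the larger one; each survivor is refined to the
    argmax of the original signal within ``±refine_window``.
    """
    config = config or RPeakConfig()
    x = np.asarray(signal, dtype=np.float64)
    det = np.abs(detection_sequence(x, config))
    m = det.max()
    if m <= 0:
        return np.asarray([], dtype=int)
    distance = max(1, int(round(config.refractory * fs)))
    peaks, _ = sps.find_peaks(det, height=config.amp_threshold_frac * m,
                              distance=distance)
    if peaks.size == 0:
        return peaks
    half = max(1, int(round(config.refine_window * fs)))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.asarray(sorted(set(refined)), dtype=int)
    # Refinement can merge neighbours; re-apply the refractory rule.
    keep = []
    for p in refined:
        if keep and p - keep[-1] < distance:
            if x[p] > x[keep[-1]]:
                keep[-1] = p
        else:
            keep.append(p)
    return np.asarray(keep, dtype=int)


def delineate_qrs(signal: np.ndarray, r_locs: np.ndarray,
                  search_window: float = 0.1, fs: float = 200.0) -> tuple:
    """Locate Q and S as the lowest-amplitude extrema around each R apex.

    Within ``(r - window, r)`` (resp. ``(r, r + window)``) the local minimum
    of the signal is taken; windows that hit the record edge are clamped and
    flagged.  Returns ``(q_locs, s_locs, clamped)``.
    """
    x = np.asarray(signal, dtype=np.float64)
    r_locs = np.asarray(r_locs, dtype=int)
    if r_locs.size == 0:
        empty = np.asarray([], dtype=int)
        return empty, empty, np.asarray([], dtype=bool)
    w = max(1, int(round(search_window * fs)))
    q_locs, s_locs, clamped = [], [], []
    for r in r_locs:
        lo = r - w
        hi = r + w
        clip = lo < 0 or hi >= x.size
        lo, hi = max(0, lo), min(x.size - 1, hi)
        q = lo + int(np.argmin(x[lo:r])) if r > lo else max(0, r - 1)
        s = (r + 1) + int(np.argmin(x[r + 1:hi + 1])) if hi > r else min(x.size - 1, r + 1)
        q = min(q, r - 1) if r > 0 else 0
        s = max(s, r + 1) if r < x.size - 1 else x.size - 1
        q_locs.append(q)
        s_locs.append(s)
        clamped.append(bool(clip))
    return (np.asarray(q_locs, dtype=int), np.asarray(s_locs, dtype=int),
            np.asarray(clamped, dtype=bool))


def annotate(signal: np.ndarray, config: RPeakConfig | None = None,
             fs: float = 200.0) -> RPeakAnnotation:
    """Detect R peaks then delineate Q/S boundaries on one lead."""
    config = config or RPeakConfig()
    r = detect_r_peaks(signal, config, fs=fs)
    q, s, clamped = delineate_qrs(signal, r, config.search_window, fs=fs)
    return RPeakAnnotation(r_locs=r, q_locs=q, s_locs=s, clamped=clamped)


def detection_f1(detected: np.ndarray, truth: np.ndarray, fs: float,
                 tol: float = 0.05) -> dict:
    """Match detections to ground truth within ``tol`` seconds (greedy,
    one-to-one) and return sensitivity, positive predictivity and F1."""
    detected = np.asarray(detected, dtype=int)
    truth = np.asarray(truth, dtype=int)
    tol_samp = tol * fs
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for d in detected:
        if truth.size == 0:
            break
        idx = np.argmin(np.abs(truth - d) + 1e9 * used)
        if not used[idx] and abs(int(truth[idx]) - int(d)) <= tol_samp:
            used[idx] = True
            tp += 1
    fp = detected.size - tp
    fn = truth.size - tp
    se = tp / (tp + fn) if tp + fn else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn, "sensitivity": se,
            "ppv": ppv, "f1": f1}
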