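"""Preprocessing: wavelet detail reconstruction, adaptive ventilator-noise
cancellation, and segmentation into labeled 7 s analysis windows.

The raw recording is decomposed with a 7-level Daubechies-6 filter bank;
the cardiac band is kept as d3+...+d7 while d7 alone feeds the noise
reference.  A leaky LMS filter (64 taps, alpha=1, mu=1e-8) then cancels
the quasi-periodic ventilator pulse using a reference built from the
per-3-s largest-amplitude extrema plus the low-frequency d7 component,
smoothed with a Savitzky-Golay filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .synth import FS, LABELS, RawRecording
from .wavelets import mra

logger = logging.getLogger(__name__)

SEGMENT_SAMPLES = 875  # 7 s at 125 Hz

#: window shift per class, in samples: non-overlapping for SR, 3 s for MA, 1 s for VF
SEGMENT_STRIDES = {"SR": 875, "MA": 375, "VF": 125}


@dataclass
class WaveletDecomp:
    """Reconstructed detail signals d1..d7 plus the level-7 smooth."""

    details: tuple[np.ndarray, ...]  # d1 (finest) .. d7 (coarsest)
    approx: np.ndarray

    def __post_init__(self) -> None:
        if len(self.details) != 7:
            raise ValueError("expected 7 detail components")


@dataclass
class LmsState:
    """Leaky LMS adaptive filter state."""

    length: int = 64
    alpha: float = 1.0
    mu: float = 1e-8
    rng_seed: int = 0
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.weights is None:
            # random small-variance initialization; scale is a config choice
            rng = np.random.default_rng(self.rng_seed)
            self.weights = rng.uniform(-1e-3, 1e-3, self.length)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != self.length:
            raise ValueError("weight vector length mismatch")


@dataclass
class Segment:
    """One 7 s / 875-sample analysis window."""

    samples: np.ndarray
    label: str
    subject_id: str
    t0: int  # start sample in the source recording

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size != SEGMENT_SAMPLES:
            raise ValueError(f"segment must have {SEGMENT_SAMPLES} samples")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def dwt_decompose(x: np.ndarray) -> WaveletDecomp:
    """7-level Daubechies-6 decomposition with same-length reconstructed details."""
    x = np.asarray(x, dtype=float)
    if x.size < 2**7:
        raise ValueError("input must have at least 128 samples for 7 levels")
    details, approx = mra(x, level=7)
    return WaveletDecomp(tuple(details), approx)


def detail_reconstruct(dec: WaveletDecomp) -> tuple[np.ndarray, np.ndarray]:
    """Return (d3+d4+d5+d6+d7, d7): cardiac-band signal and low-frequency part."""
    d = dec.details
    return d[2] + d[3] + d[4] + d[5] + d[6], d[6]


def build_noise_reference(
    x: np.ndarray,
    d7: np.ndarray,
    half_width: int = 30,
    sg_window: int = 31,
    sg_order: int = 3,
) -> np.ndarray:
    """Ventilator-noise reference for the adaptive filter.

    In each non-overlapping 3 s (375-sample) window the extremum of
    largest absolute amplitude is located; the signal within
    ``half_width`` samples of each extremum forms the pulse component,
    zero elsewhere.  d7 is added and the result is Savitzky-Golay
    smoothed.
    """
    x = np.asarray(x, dtype=float)
    d7 = np.asarray(d7, dtype=float)
    if x.shape != d7.shape:
        raise ValueError("x and d7 must have equal length")
    if x.size < 3 * FS:
        raise ValueError("need at least one 3 s window")
    n = x.size
    pulse = np.zeros(n)
    win = 3 * FS
    for start in range(0, n - win + 1, win):
        i = start + int(np.argmax(np.abs(x[start : start + win])))
        lo, hi = max(0, i - half_width), min(n, i + half_width + 1)
        pulse[lo:hi] = x[lo:hi]
    ref = pulse + d7
    if n >= sg_window:
        ref = savgol_filter(ref, sg_window, sg_order)
    return ref


def lms_cancel(d: np.ndarray, ref: np.ndarray, state: LmsState | None = None) -> np.ndarray:
    """Leaky LMS noise cancellation.

    Iterates ``y(n) = w^T(n-1) x(n)``, ``e(n) = d(n) - y(n)``,
    ``w(n) = alpha w(n-1) + mu e(n) x(n)`` where ``x(n)`` holds the 64
    most recent reference samples (zero-padded at the start).  Returns
    the error signal e, i.e. the noise-canceled BCG.
    """
    d = np.asarray(d, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if d.shape != ref.shape:
        raise ValueError("signal and reference must have equal length")
    state = state or LmsState()
    L = state.length
    w = state.weights.copy()
    alpha, mu = state.alpha, state.mu
    padded = np.concatenate([np.zeros(L - 1), ref])
    e = np.empty_like(d)
    for n in range(d.size):
        xn = padded[n : n + L][::-1]  # most recent sample first
        y = w @ xn
        e[n] = d[n] - y
        w = alpha * w + mu * e[n] * xn
    state.weights = w
    return e


def preprocess_recording(
    rec: RawRecording,
    use_lms: bool = True,
    lms_state: LmsState | None = None,
) -> RawRecording:
    """Full preprocessing of one recording; annotations are preserved."""
    dec = dwt_decompose(rec.samples)
    bcg, d7 = detail_reconstruct(dec)
    if use_lms:
        ref = build_noise_reference(rec.samples, d7)
        bcg = lms_cancel(bcg, ref, lms_state)
    return RawRecording(bcg, rec.fs, rec.subject_id, list(rec.annotations))


def segment(rec: RawRecording) -> list[Segment]:
    """Split a recording into labeled 875-sample windows.

    Stride depends on the class: 875 samples for SR (non-overlapping),
    375 for MA (3 s shift), 125 for VF (1 s shift).  Windows never cross
    annotation boundaries; incomplete tails are discarded.
    """
    if not rec.annotations:
        raise ValueError("recording has no annotations")
    out: list[Segment] = []
    for ext in rec.annotations:
        stride = SEGMENT_STRIDES[ext.label]
        span = ext.end - ext.start
        if span < SEGMENT_SAMPLES:
            logger.info(
                "extent %s [%d,%d) shorter than one window; skipped",
                ext.label, ext.start, ext.end,
            )
            continue
        for t0 in range(ext.start, ext.end - SEGMENT_SAMPLES + 1, stride):
            out.append(
                Segment(rec.samples[t0 : t0 + SEGMENT_SAMPLES], ext.label, rec.subject_id, t0)
            )
    return out
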