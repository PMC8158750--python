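"""The 22-element feature vector computed per segment.

Five feature sequences (SC, IF, QA, PI, SD), each summarized by mean,
variance, skewness and kurtosis, plus two scalars (FWHM, RM):

====== =========================================== ==================
index  feature                                     source
====== =========================================== ==================
1-4    SC   slice correlation                      power map S(f,t)
5-8    IF   instantaneous frequency                power map S(f,t)
9-12   QA   quantized amplitude                    time marginal
13-16  PI   peak intervals                         time marginal
17-20  SD   spectral density                       frequency marginal
21     FWHM dominant-peak full width, Hz           frequency marginal
22     RM   range (max - min)                      time-domain segment
====== =========================================== ==================

Degenerate inputs (constant marginals, fewer than two peaks, ...) fall
back to documented sentinel values so feature extraction is total; every
sentinel is recorded in the vector's quality flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .preprocess import Segment
from .transform import DEFAULT_CONFIG, TimeFreqMap, TransformConfig, transform_segment

FEATURE_NAMES = (
    "SC_mean", "SC_var", "SC_skew", "SC_kurt",
    "IF_mean", "IF_var", "IF_skew", "IF_kurt",
    "QA_mean", "QA_var", "QA_skew", "QA_kurt",
    "PI_mean", "PI_var", "PI_skew", "PI_kurt",
    "SD_mean", "SD_var", "SD_skew", "SD_kurt",
    "FWHM", "RM",
)


@dataclass
class FeatureVector:
    values: np.ndarray  # length 22, ordered as FEATURE_NAMES
    quality_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(FEATURE_NAMES):
            raise ValueError("feature vector must have 22 entries")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def four_stats(seq: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, variance, skewness and (non-excess) kurtosis.

    Skewness = m3 / m2^(3/2), kurtosis = m4 / m2^2.  For sequences
    shorter than 3 or with zero variance both shape moments are 0.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0:
        raise ValueError("empty sequence")
    mean = float(seq.mean())
    d = seq - mean
    m2 = float(np.mean(d**2))
    if seq.size < 3 or m2 == 0.0:
        return mean, m2, 0.0, 0.0
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return mean, m2, m3 / m2**1.5, m4 / m2**2


def slice_correlation(tfm: TimeFreqMap) -> tuple[np.ndarray, list[str]]:
    """Correlation of adjacent hbl-wide slices of the power map.

    ``SC[k]`` is the Pearson correlation between the J x hbl blocks
    starting at columns ``(k-1)*hbl`` and ``k*hbl`` (vectorized), for
    ``k = 1 .. floor(I/hbl) - 1``.
    """
    hbl = tfm.hbl
    if hbl <= 0:
        raise ValueError("map has no beat-length estimate")
    n_slices = tfm.S.shape[1] // hbl
    if n_slices < 2:
        return np.array([0.0]), ["SC:single-slice"]
    flags: list[str] = []
    sc = np.empty(n_slices - 1)
    for k in range(n_slices - 1):
        a = tfm.S[:, k * hbl : (k + 1) * hbl].ravel()
        b = tfm.S[:, (k + 1) * hbl : (k + 2) * hbl].ravel()
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom == 0:
            sc[k] = 0.0
            flags.append(f"SC:zero-variance-slice-{k}")
        else:
            sc[k] = (a @ b) / denom
    return sc, flags


def instantaneous_frequency(tfm: TimeFreqMap) -> tuple[np.ndarray, list[str]]:
    """Power-weighted mean frequency per time column."""
    col = tfm.S.sum(axis=0)
    flags: list[str] = []
    if_seq = np.empty(col.size)
    ok = col > 0
    if_seq[ok] = (tfm.f_grid @ tfm.S[:, ok]) / col[ok]
    if not np.all(ok):
        if_seq[~ok] = 0.5 * (tfm.f_grid[0] + tfm.f_grid[-1])
        flags.append("IF:zero-columns")
    return if_seq, flags


def marginal_time(tfm: TimeFreqMap, sg_window: int = 31, sg_order: int = 3) -> np.ndarray:
    """Time marginal: column means smoothed with a Savitzky-Golay filter."""
    st = tfm.S.mean(axis=0)
    win = min(sg_window, st.size if st.size % 2 else st.size - 1)
    if win > sg_order:
        st = savgol_filter(st, win, sg_order)
    return st


def quantize_amplitude(st: np.ndarray, q: int = 10) -> tuple[np.ndarray, list[str]]:
    """Quantize the time marginal to 11 levels {0, 0.1, ..., 1.0}.

    The marginal is affine-normalized onto [0, Q] and each value mapped
    to ``floor(v + 1/2) / Q`` (half rounds up).
    """
    st = np.asarray(st, dtype=float)
    lo, hi = st.min(), st.max()
    if hi == lo:
        return np.zeros(st.size), ["QA:constant-marginal"]
    norm = (st - lo) / (hi - lo) * q
    return np.floor(norm + 0.5) / q, []


def peak_intervals(
    st: np.ndarray, prominence_frac: float = 0.1, min_separation: int = 20
) -> tuple[np.ndarray, list[str]]:
    """Intervals between successive local maxima of the time marginal.

    Peaks must exceed their neighbors with prominence at least
    ``prominence_frac`` of the marginal's range and be at least
    ``min_separation`` samples apart (both config choices).
    """
    st = np.asarray(st, dtype=float)
    rng = float(np.ptp(st))
    if rng == 0:
        return np.array([0.0]), ["PI:constant-marginal"]
    peaks, _ = find_peaks(st, prominence=prominence_frac * rng, distance=min_separation)
    if peaks.size < 2:
        return np.array([0.0]), ["PI:fewer-than-two-peaks"]
    return np.diff(peaks).astype(float), []


def spectral_density(tfm: TimeFreqMap) -> tuple[np.ndarray, np.ndarray]:
    """Frequency marginal (row means over time) and the SD sequence (identity)."""
    sf = tfm.S.mean(axis=1)
    return sf, sf.copy()


def fwhm(sf: np.ndarray, f_grid: np.ndarray) -> tuple[float, list[str]]:
    """Full width at half maximum of the dominant spectral peak, in Hz.

    Half-height crossings on either side of the (lowest-frequency) global
    maximum are located by linear interpolation between grid points; a
    side that never crosses within the band is clamped to the band edge.
    """
    sf = np.asarray(sf, dtype=float)
    f_grid = np.asarray(f_grid, dtype=float)
    if np.all(sf == 0):
        return float(f_grid[-1] - f_grid[0]), ["FWHM:zero-spectrum"]
    j = int(np.argmax(sf))  # argmax returns the first (lowest-frequency) tie
    half = sf[j] / 2.0

    def _cross(indices: range) -> float | None:
        prev = j
        for i in indices:
            if sf[i] <= half:
                frac = (sf[prev] - half) / (sf[prev] - sf[i])
                return float(f_grid[prev] + frac * (f_grid[i] - f_grid[prev]))
            prev = i
        return None

    left = _cross(range(j - 1, -1, -1))
    right = _cross(range(j + 1, len(sf)))
    lo = f_grid[0] if left is None else left
    hi = f_grid[-1] if right is None else right
    return float(abs(hi - lo)), []


def range_metric(seg: Segment | np.ndarray) -> float:
    """Range (max - min) of the time-domain segment."""
    x = seg.samples if isinstance(seg, Segment) else np.asarray(seg, dtype=float)
    return float(np.ptp(x))


def extract_features(seg: Segment, cfg: TransformConfig = DEFAULT_CONFIG) -> FeatureVector:
    """Run the transformation stage and compute all 22 features."""
    tfm = transform_segment(seg, cfg)
    flags: list[str] = []

    sc, f = slice_correlation(tfm)
    flags += f
    if_seq, f = instantaneous_frequency(tfm)
    flags += f
    st = marginal_time(tfm)
    qa, f = quantize_amplitude(st, cfg.quantization)
    flags += f
    pi, f = peak_intervals(st)
    flags += f
    sf, sd = spectral_density(tfm)
    width, f = fwhm(sf, tfm.f_grid)
    flags += f

    values = np.concatenate(
        [
            four_stats(sc),
            four_stats(if_seq),
            four_stats(qa),
            four_stats(pi),
            four_stats(sd),
            [width, range_metric(seg)],
        ]
    )
    return FeatureVector(values, flags)
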