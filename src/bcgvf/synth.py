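"""Synthetic multi-subject BCG-like cohort generator.

Produces annotated single-channel recordings at 125 Hz that carry the
statistical structure the detection pipeline relies on:

* sinus rhythm (SR): a quasi-periodic train of damped-oscillation beat
  clusters (tri-lobe, "W-shaped") with per-subject morphology and
  amplitude, timing jitter, per-beat amplitude jitter, a respiration
  baseline, optionally a large ventilator pulse every 3.0 s, and white
  noise;
* ventricular fibrillation (VF): band-limited (3-10 Hz) stochastic
  oscillation with slow random amplitude modulation and no stable period;
* motion artifact (MA): irregular low-frequency transients whose
  peak-to-peak amplitude is several times the beat amplitude.

Amplitudes are in arbitrary units; their scale is chosen so that the
fixed-step LMS stage downstream stays well inside its stability bound.
None of the numeric defaults are physiological claims; they are
engineering choices pinned in :class:`SynthConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

FS = 125
"""Sampling rate in Hz; the whole pipeline is fixed to this."""

LABELS = ("SR", "VF", "MA")


@dataclass(frozen=True)
class Extent:
    """Half-open annotated span ``[start, end)`` in sample indices."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.end <= self.start or self.start < 0:
            raise ValueError("extent must satisfy 0 <= start < end")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generation parameters."""

    subject_id: str
    beat_amplitude_scale: float = 120.0
    beat_morphology_seed: int = 0
    baseline_heart_rate: float = 75.0
    noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if not 50.0 <= self.baseline_heart_rate <= 170.0:
            raise ValueError("baseline_heart_rate must lie in [50, 170] bpm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.beat_amplitude_scale <= 0:
            raise ValueError("beat_amplitude_scale must be positive")


@dataclass
class RawRecording:
    """Continuous sampled signal with subject ID and rhythm annotations."""

    samples: np.ndarray
    fs: int
    subject_id: str
    annotations: list[Extent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs != FS:
            raise ValueError(f"sampling rate must be {FS} Hz")
        n = self.samples.size
        spans = sorted((a.start, a.end) for a in self.annotations)
        prev_end = 0
        for s, e in spans:
            if e > n:
                raise ValueError("annotation extends past end of recording")
            if s < prev_end:
                raise ValueError("annotation extents overlap")
            prev_end = e


@dataclass(frozen=True)
class SynthConfig:
    """Documented defaults for the waveform generators (tests pin these)."""

    timing_jitter: float = 0.015      # SD of beat-period jitter, fraction of period (<=5%)
    amplitude_jitter: float = 0.10    # per-beat uniform amplitude jitter, fraction
    beat_freq_range: tuple[float, float] = (5.0, 9.0)   # Hz, dominant beat oscillation
    beat_cycles: float = 1.5          # oscillation periods per beat -> 3 lobes
    resp_amp_frac: float = 0.25       # respiration amplitude as fraction of beat amp
    resp_freq_range: tuple[float, float] = (0.2, 0.4)   # Hz
    vent_period_s: float = 3.0        # ventilator pulse period
    vent_amp_frac: float = 3.5        # ventilator amplitude as fraction of beat amp
    vf_band: tuple[float, float] = (3.0, 10.0)          # Hz passband of VF noise
    vf_rms_frac: float = 0.35         # VF RMS as fraction of beat amp
    ma_amp_ratio: float = 6.0         # MA peak-to-peak : beat amplitude (>= 5)
    ma_cutoff_hz: float = 1.5         # MA lowpass corner


DEFAULT_SYNTH = SynthConfig()


def _check_duration(duration_s: float) -> int:
    if duration_s < 7:
        raise ValueError("duration_s must be at least 7 s (one analysis window)")
    return int(round(duration_s * FS))


def _beat_template(profile: SubjectProfile, cfg: SynthConfig) -> np.ndarray:
    """Damped-oscillation beat cluster, unit peak amplitude.

    The oscillation frequency and a small second-harmonic admixture are
    drawn from the subject's morphology seed, giving stable per-subject
    waveform individuality.
    """
    rng = np.random.default_rng(profile.beat_morphology_seed)
    f_lo, f_hi = cfg.beat_freq_range
    f_b = rng.uniform(f_lo, f_hi)
    harm = rng.uniform(0.0, 0.3)
    n = max(int(round(cfg.beat_cycles / f_b * FS)), 8)
    t = np.arange(n) / FS
    env = np.exp(-3.0 * t * f_b / cfg.beat_cycles)
    w = (np.sin(2 * np.pi * f_b * t) + harm * np.sin(4 * np.pi * f_b * t)) * env
    return w / np.max(np.abs(w))


def _ventilator_pulse(amp: float) -> np.ndarray:
    """Large slow biphasic pulse, ~0.7 s support, content below ~3 Hz."""
    t = np.arange(int(0.7 * FS)) / FS
    win = np.exp(-0.5 * ((t - 0.35) / 0.12) ** 2)
    return amp * np.sin(2 * np.pi * 2.0 * (t - 0.35)) * win


def generate_sr(
    duration_s: float,
    profile: SubjectProfile,
    seed: int,
    ventilator: bool = False,
    cfg: SynthConfig = DEFAULT_SYNTH,
) -> RawRecording:
    """Quasi-periodic sinus-rhythm recording annotated SR over its full extent."""
    n = _check_duration(duration_s)
    rng = np.random.default_rng(seed)
    amp = profile.beat_amplitude_scale
    x = np.zeros(n)

    beat = _beat_template(profile, cfg)
    period = 60.0 / profile.baseline_heart_rate  # seconds
    t_beat = rng.uniform(0, period)
    while t_beat * FS < n:
        i0 = int(round(t_beat * FS))
        a = amp * (1.0 + rng.uniform(-cfg.amplitude_jitter, cfg.amplitude_jitter))
        seg = beat[: max(0, min(len(beat), n - i0))]
        x[i0 : i0 + len(seg)] += a * seg
        jit = np.clip(rng.normal(0.0, cfg.timing_jitter), -0.05, 0.05)
        t_beat += period * (1.0 + jit)

    t = np.arange(n) / FS
    f_r = rng.uniform(*cfg.resp_freq_range)
    x += cfg.resp_amp_frac * amp * np.sin(2 * np.pi * f_r * t + rng.uniform(0, 2 * np.pi))

    if ventilator:
        pulse = _ventilator_pulse(cfg.vent_amp_frac * amp)
        t_v = 0.5
        while t_v * FS < n:
            i0 = int(round(t_v * FS))
            seg = pulse[: max(0, min(len(pulse), n - i0))]
            x[i0 : i0 + len(seg)] += seg
            t_v += cfg.vent_period_s

    x += rng.normal(0.0, profile.noise_sd, n)
    return RawRecording(x, FS, profile.subject_id, [Extent(0, n, "SR")])


def generate_vf(
    duration_s: float,
    profile: SubjectProfile,
    seed: int,
    cfg: SynthConfig = DEFAULT_SYNTH,
) -> RawRecording:
    """Aperiodic fibrillatory oscillation annotated VF."""
    n = _check_duration(duration_s)
    rng = np.random.default_rng(seed)
    amp = profile.beat_amplitude_scale

    sos = sps.butter(4, cfg.vf_band, btype="bandpass", fs=FS, output="sos")
    base = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * FS))[FS : FS + n]

    # slow random amplitude modulation (no stable period)
    sos_lp = sps.butter(2, 0.4, btype="lowpass", fs=FS, output="sos")
    env = sps.sosfiltfilt(sos_lp, rng.standard_normal(n + 2 * FS))[FS : FS + n]
    env = 1.0 + 0.5 * env / max(np.std(env), 1e-12)
    env = np.clip(env, 0.2, None)

    x = base * env
    x *= cfg.vf_rms_frac * amp / max(np.std(x), 1e-12)
    x += rng.normal(0.0, profile.noise_sd, n)
    return RawRecording(x, FS, profile.subject_id, [Extent(0, n, "VF")])


def generate_ma(
    duration_s: float,
    profile: SubjectProfile,
    seed: int,
    cfg: SynthConfig = DEFAULT_SYNTH,
) -> RawRecording:
    """Large irregular low-frequency motion-artifact recording annotated MA."""
    n = _check_duration(duration_s)
    rng = np.random.default_rng(seed)
    amp = profile.beat_amplitude_scale

    sos = sps.butter(4, cfg.ma_cutoff_hz, btype="lowpass", fs=FS, output="sos")
    base = sps.sosfiltfilt(sos, rng.standard_normal(n + 4 * FS))[2 * FS : 2 * FS + n]
    ptp = np.ptp(base)
    # beat p2p is ~2*amp (positive and negative lobes of unit-peak template)
    x = base * (cfg.ma_amp_ratio * 2.0 * amp / max(ptp, 1e-12))

    # faint residual cardiac activity underneath the artifact
    beat = _beat_template(profile, cfg)
    period = 60.0 / profile.baseline_heart_rate
    t_beat = rng.uniform(0, period)
    while t_beat * FS < n:
        i0 = int(round(t_beat * FS))
        seg = beat[: max(0, min(len(beat), n - i0))]
        x[i0 : i0 + len(seg)] += 0.5 * amp * seg
        t_beat += period * (1.0 + np.clip(rng.normal(0, 0.015), -0.05, 0.05))

    x += rng.normal(0.0, profile.noise_sd, n)
    return RawRecording(x, FS, profile.subject_id, [Extent(0, n, "MA")])


@dataclass(frozen=True)
class CohortSpec:
    """Per-subject recording plan for :func:`generate_cohort`."""

    sr_duration_s: float = 84.0
    vf_duration_s: float = 21.0
    ma_duration_s: float = 28.0
    ventilator: bool = True
    hr_range: tuple[float, float] = (55.0, 110.0)
    amp_range: tuple[float, float] = (80.0, 160.0)
    noise_frac_range: tuple[float, float] = (0.04, 0.10)  # noise SD / beat amplitude

    @classmethod
    def with_sr_vf_ratio(cls, ratio: float, sr_duration_s: float = 84.0, **kw) -> "CohortSpec":
        """Choose the VF duration so segmentation yields ~``ratio``:1 SR:VF counts.

        SR windows are non-overlapping (7 s each) while VF uses a 1 s
        shift, so ``n_vf`` segments need ``7 + (n_vf - 1)`` seconds.
        """
        n_sr = int(sr_duration_s // 7)
        n_vf = max(1, round(n_sr / ratio))
        return cls(sr_duration_s=sr_duration_s, vf_duration_s=7.0 + (n_vf - 1), **kw)


def draw_profile(subject_id: str, seed_seq: np.random.SeedSequence, spec: CohortSpec) -> SubjectProfile:
    rng = np.random.default_rng(seed_seq)
    amp = rng.uniform(*spec.amp_range)
    return SubjectProfile(
        subject_id=subject_id,
        beat_amplitude_scale=amp,
        beat_morphology_seed=int(rng.integers(0, 2**31)),
        baseline_heart_rate=rng.uniform(*spec.hr_range),
        noise_sd=amp * rng.uniform(*spec.noise_frac_range),
    )


def generate_cohort(
    n_subjects: int,
    spec: CohortSpec | None = None,
    seed: int = 0,
    cfg: SynthConfig = DEFAULT_SYNTH,
) -> list[RawRecording]:
    """Generate one SR, one VF and one MA recording per subject.

    The master ``seed`` fully determines the cohort: subject profiles and
    all per-recording randomness are drawn from spawned seed sequences.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (leave-one-subject-out needs 2)")
    spec = spec or CohortSpec()
    master = np.random.SeedSequence(seed)
    recs: list[RawRecording] = []
    for i, child in enumerate(master.spawn(n_subjects)):
        sid = f"S{i + 1:02d}"
        prof_seq, sr_seq, vf_seq, ma_seq = child.spawn(4)
        profile = draw_profile(sid, prof_seq, spec)
        s_sr, s_vf, s_ma = (int(s.generate_state(1)[0]) for s in (sr_seq, vf_seq, ma_seq))
        if spec.sr_duration_s >= 7:
            recs.append(generate_sr(spec.sr_duration_s, profile, s_sr, spec.ventilator, cfg))
        if spec.vf_duration_s >= 7:
            recs.append(generate_vf(spec.vf_duration_s, profile, s_vf, cfg))
        if spec.ma_duration_s >= 7:
            recs.append(generate_ma(spec.ma_duration_s, profile, s_ma, cfg))
    return recs
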