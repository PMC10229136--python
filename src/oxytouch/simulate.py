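"""Synthetic cohort generator.

Emulates the statistical structure of a randomized three-arm oxytocin (OT)
administration study of social touch: intranasal OT (n=56), oral/lingual OT
(n=57) and placebo (n=58) groups, two touch conditions (gentle stroking
touch vs medium pressure massage), 26-channel oxy-Hb recordings under a
20-block design at 6.78 Hz, behavioural ratings on 1-9 scales, four plasma
OT samples per subject, RR-interval series and skin-conductance traces.

Key generative assumptions
--------------------------
* fNIRS forward model: per channel, the signal is the sum over blocks of
  ``amplitude x (HRF-convolved boxcar)``, where the boxcar is extended past
  block offset by an exponential tail with time constant ``prolongation_tau``
  (the group-specific response prolongation seen in mOFC/mlOFC/pSTS for
  gentle touch in the OT groups), plus Gaussian sensor noise, systemic
  physiological oscillations (cardiac / respiratory / Mayer waves) and
  occasional spike or baseline-step motion artifacts.
* Mediation structure: plasma change M = a*X + eps_M and gentle-touch
  pleasantness Y = intercept + c'*X + b*M + eps_Y, with X a 0/1 treatment
  indicator per OT route versus placebo.  Default path coefficients are
  a=6.57, b=0.06, c'=0.37 (intranasal) and a=2.41, b=0.06, c'=0.50 (oral).
* Reproducibility: a master seed spawns per-subject sub-seeds through
  ``numpy.random.SeedSequence(seed).spawn``; subject ``i`` in roster order
  always receives child ``i``, so enlarging a cohort never perturbs
  previously generated subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .design import (
    GENTLE_TOUCH,
    MEDIUM_MASSAGE,
    BlockDesign,
    make_block_design,
)
from .glm import HrfParams, canonical_hrf
from .montage import Montage, make_montage
from .recording import FnirsRecording

__all__ = [
    "INTRANASAL_OT",
    "ORAL_OT",
    "PLC",
    "GROUPS",
    "EffectSpec",
    "default_effect_spec",
    "RRSeries",
    "ScrTrace",
    "SubjectRecord",
    "CohortData",
    "CohortConfig",
    "simulate_subject_fnirs",
    "simulate_rr",
    "simulate_scr",
    "simulate_cohort",
]

INTRANASAL_OT = "intranasal_OT"
ORAL_OT = "oral_OT"
PLC = "PLC"
GROUPS = (INTRANASAL_OT, ORAL_OT, PLC)

RATING_NAMES = ("pleasantness", "arousal", "intensity", "payment")


# ---------------------------------------------------------------------------
# effect specification


@dataclass
class EffectSpec:
    """Parameters of the fNIRS forward model.

    ``amplitude`` maps (ROI, condition) to the sustained response amplitude
    in µM; ``prolongation_tau`` maps (ROI, condition, group) to the
    exponential decay constant (s) that extends the neural drive past block
    offset.  ``physio_components`` are (frequency Hz, amplitude µM) sinusoid
    pairs; ``artifact_rate`` is the expected motion-artifact count per
    channel per minute.
    """

    amplitude: dict[tuple[str, str], float] = field(default_factory=dict)
    prolongation_tau: dict[tuple[str, str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.3
    physio_components: tuple[tuple[float, float], ...] = ()
    artifact_rate: float = 0.0
    spike_magnitude: float = 3.0
    step_magnitude: float = 1.0
    hrf_params: HrfParams = field(default_factory=HrfParams)

    def __post_init__(self) -> None:
        for v in self.amplitude.values():
            if not np.isfinite(v):
                raise ValueError("amplitudes must be finite")
        for v in self.prolongation_tau.values():
            if v < 0:
                raise ValueError("prolongation_tau must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def tau_for(self, roi: str, condition: str, group: Optional[str]) -> float:
        if group is not None and (roi, condition, group) in self.prolongation_tau:
            return self.prolongation_tau[(roi, condition, group)]
        return 0.0


def default_effect_spec() -> EffectSpec:
    """Study-default forward model.

    Gentle touch preferentially drives mOFC/mlOFC/pSTS and massage drives
    S1; both OT routes prolong the gentle-touch response in mOFC, mlOFC and
    pSTS (tau = 8 s) while the placebo response decays promptly.  Physio
    components model cardiac (1.1 Hz), respiratory (0.25 Hz) and Mayer-wave
    (0.1 Hz) oscillations.
    """
    amplitude = {
        ("mOFC", GENTLE_TOUCH): 0.40,
        ("mlOFC", GENTLE_TOUCH): 0.40,
        ("pSTS", GENTLE_TOUCH): 0.30,
        ("lOFC", GENTLE_TOUCH): 0.20,
        ("S1", GENTLE_TOUCH): 0.15,
        ("mOFC", MEDIUM_MASSAGE): 0.25,
        ("mlOFC", MEDIUM_MASSAGE): 0.25,
        ("pSTS", MEDIUM_MASSAGE): 0.20,
        ("lOFC", MEDIUM_MASSAGE): 0.20,
        ("S1", MEDIUM_MASSAGE): 0.40,
    }
    tau = {}
    for roi in ("mOFC", "mlOFC", "pSTS"):
        for group in (INTRANASAL_OT, ORAL_OT):
            tau[(roi, GENTLE_TOUCH, group)] = 8.0
    return EffectSpec(
        amplitude=amplitude,
        prolongation_tau=tau,
        noise_sd=0.3,
        physio_components=((1.1, 0.08), (0.25, 0.08), (0.10, 0.12)),
        artifact_rate=0.5,
    )


# ---------------------------------------------------------------------------
# physiological containers


@dataclass
class RRSeries:
    """Ordered beat-to-beat intervals in ms."""

    rr_intervals: np.ndarray

    def __post_init__(self) -> None:
        self.rr_intervals = np.asarray(self.rr_intervals, dtype=float)
        if self.rr_intervals.ndim != 1 or self.rr_intervals.size < 2:
            raise ValueError("need at least 2 RR intervals")
        if np.any(self.rr_intervals < 250) or np.any(self.rr_intervals > 2500):
            raise ValueError("RR intervals outside physiological range (250-2500 ms)")

    @property
    def n_beats(self) -> int:
        return self.rr_intervals.size

    @property
    def beat_times(self) -> np.ndarray:
        """Cumulative beat times in seconds (first beat at t=RR0)."""
        return np.cumsum(self.rr_intervals) / 1000.0


@dataclass
class ScrTrace:
    """Skin conductance in µS at a fixed sampling rate."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("SCR trace contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


# ---------------------------------------------------------------------------
# subject-level simulators


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_subject_fnirs(
    montage: Montage,
    design: BlockDesign,
    effect_spec: EffectSpec,
    seed,
    group: Optional[str] = None,
) -> FnirsRecording:
    """One subject's oxy-Hb recording under the forward model.

    Deterministic for identical (inputs, seed).  Raises if the effect spec
    references an ROI absent from the montage.
    """
    rois = set(montage.roi_map)
    for (roi, _cond) in effect_spec.amplitude:
        if roi not in rois:
            raise ValueError(f"unknown ROI {roi!r} in effect_spec.amplitude")
    for (roi, _cond, _grp) in effect_spec.prolongation_tau:
        if roi not in rois:
            raise ValueError(f"unknown ROI {roi!r} in effect_spec.prolongation_tau")

    rng = _rng(seed)
    fs = design.sampling_rate
    n = design.n_samples
    t = np.arange(n) / fs
    kernel = canonical_hrf(fs, effect_spec.hrf_params)
    scale = kernel.sum()

    # per-ROI neural drive -> hemodynamic signal
    roi_signal: dict[str, np.ndarray] = {}
    for roi in montage.roi_map:
        drive = np.zeros(n)
        for ev in design.events:
            amp = effect_spec.amplitude.get((roi, ev.condition), 0.0)
            if amp == 0.0:
                continue
            on = (t >= ev.onset - 1e-9) & (t < ev.offset - 1e-9)
            drive[on] += amp
            tau = effect_spec.tau_for(roi, ev.condition, group)
            if tau > 0:
                post = t >= ev.offset - 1e-9
                drive[post] += amp * np.exp(-(t[post] - ev.offset) / tau)
        roi_signal[roi] = np.convolve(drive, kernel)[:n] / scale

    data = np.empty((montage.n_channels, n))
    for i, cid in enumerate(montage.channel_ids):
        data[i] = roi_signal[montage.roi_of(cid)]

    # systemic physiological oscillations (shared phase across channels)
    for freq, amp in effect_spec.physio_components:
        phase = rng.uniform(0, 2 * np.pi)
        data += amp * np.sin(2 * np.pi * freq * t + phase)

    if effect_spec.noise_sd > 0:
        data += rng.normal(0.0, effect_spec.noise_sd, size=data.shape)

    if effect_spec.artifact_rate > 0:
        expected = effect_spec.artifact_rate * design.total_duration / 60.0
        for ch in range(data.shape[0]):
            for _ in range(rng.poisson(expected)):
                idx = rng.integers(1, n - 1)
                sign = rng.choice([-1.0, 1.0])
                if rng.random() < 0.5:  # motion spike, ~0.5-1.5 s
                    width = rng.integers(3, max(4, int(1.5 * fs)))
                    mag = effect_spec.spike_magnitude * rng.uniform(0.5, 1.5)
                    data[ch, idx : idx + width] += sign * mag
                else:  # baseline step
                    mag = effect_spec.step_magnitude * rng.uniform(0.5, 1.5)
                    data[ch, idx:] += sign * mag

    return FnirsRecording(
        data=data,
        sampling_rate=fs,
        signal_kind="concentration",
        chromophore="HbO",
        montage=montage,
    )


def simulate_rr(
    duration_s: float,
    mean_hr_bpm: float = 70.0,
    lf_amp: float = 20.0,
    hf_amp: float = 25.0,
    hf_freq: float = 0.25,
    seed=None,
    lf_freq: float = 0.1,
    jitter_ms: float = 3.0,
) -> RRSeries:
    """RR-interval series with sinusoidal LF/HF modulation plus white jitter."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not 30.0 < mean_hr_bpm < 200.0:
        raise ValueError("mean_hr_bpm must be in (30, 200)")
    rng = _rng(seed)
    base = 60000.0 / mean_hr_bpm
    intervals: list[float] = []
    t = 0.0
    while t < duration_s:
        rr = base
        if lf_amp:
            rr += lf_amp * np.sin(2 * np.pi * lf_freq * t)
        if hf_amp:
            rr += hf_amp * np.sin(2 * np.pi * hf_freq * t)
        if jitter_ms:
            rr += jitter_ms * rng.normal()
        rr = float(np.clip(rr, 250.0, 2500.0))
        intervals.append(rr)
        t += rr / 1000.0
    return RRSeries(rr_intervals=np.array(intervals))


def scr_kernel(times: np.ndarray, rise_s: float = 0.7, decay_s: float = 3.0) -> np.ndarray:
    """Fast-rise / slow-decay phasic kernel, peak-normalized to 1."""
    k = np.zeros_like(times, dtype=float)
    pos = times >= 0
    tp = times[pos]
    k[pos] = np.exp(-tp / decay_s) - np.exp(-tp / rise_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def simulate_scr(
    design: BlockDesign,
    event_amplitude: float = 1.2,
    seed=None,
    sampling_rate: float = 10.0,
    tonic_level: float = 2.0,
    noise_sd: float = 0.02,
    rise_s: float = 0.7,
    decay_s: float = 3.0,
) -> ScrTrace:
    """Tonic level plus event-locked phasic responses at stimulation onsets."""
    if event_amplitude < 0:
        raise ValueError("event_amplitude must be >= 0")
    rng = _rng(seed)
    n = int(round(design.total_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    trace = np.full(n, tonic_level)
    for ev in design.events:
        if ev.condition.startswith("rest"):
            continue
        trace += event_amplitude * scr_kernel(t - ev.onset, rise_s, decay_s)
    if noise_sd > 0:
        trace += noise_sd * rng.normal(size=n)
    return ScrTrace(samples=trace, sampling_rate=sampling_rate)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SubjectRecord:
    """One enrolled subject: grouping, behaviour, plasma, recordings."""

    id: str
    group: str
    enrolled_flag: bool = True
    exclusion_reason: Optional[str] = None  # None | "incomplete" | "technical"
    ratings: dict[str, dict[str, float]] = field(default_factory=dict)  # condition -> name -> value
    plasma_ot: Optional[np.ndarray] = None  # 4 concentrations, pg/ml
    recordings: dict[str, FnirsRecording] = field(default_factory=dict)  # condition -> recording
    rr_series: dict[str, RRSeries] = field(default_factory=dict)  # condition -> series
    scr_trace: dict[str, ScrTrace] = field(default_factory=dict)  # condition -> trace

    @property
    def analyzed(self) -> bool:
        return self.enrolled_flag and self.exclusion_reason is None

    @property
    def plasma_delta(self) -> float:
        """Post-treatment plasma OT change (30 min post minus baseline), pg/ml."""
        return float(self.plasma_ot[1] - self.plasma_ot[0])


@dataclass
class MediationPaths:
    a: float  # treatment -> plasma delta (pg/ml)
    b: float  # plasma delta -> pleasantness (points per pg/ml)
    c_prime: float  # direct treatment -> pleasantness


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the study conditions."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {INTRANASAL_OT: 56, ORAL_OT: 57, PLC: 58}
    )
    n_incomplete: int = 5
    n_technical: int = 4
    paths: dict[str, MediationPaths] = field(
        default_factory=lambda: {
            INTRANASAL_OT: MediationPaths(a=6.57, b=0.06, c_prime=0.37),
            ORAL_OT: MediationPaths(a=2.41, b=0.06, c_prime=0.50),
        }
    )
    sigma_m: float = 4.0  # plasma-change residual SD, pg/ml
    sigma_y: float = 1.1  # pleasantness residual SD, rating points
    pleasantness_intercept: float = 5.5  # placebo gentle-touch mean
    baseline_ot_mean: float = 8.8  # pg/ml
    baseline_ot_sd: float = 2.5
    clip_ratings: bool = True
    effect_spec: EffectSpec = field(default_factory=default_effect_spec)
    amplitude_cv: float = 0.2  # between-subject gain variability
    tau_jitter_sd: float = 1.5  # s, between-subject prolongation variability
    n_blocks: int = 20
    stim_s: float = 30.0
    rest_s: float = 15.0
    sampling_rate: float = 6.78
    include_fnirs: bool = True
    include_autonomic: bool = True
    scr_sampling_rate: float = 10.0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group size for {g} must be positive")


@dataclass
class CohortData:
    subjects: list[SubjectRecord]
    config: CohortConfig
    seed: int

    @property
    def analyzed_subjects(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.analyzed]

    def group(self, name: str) -> list[SubjectRecord]:
        return [s for s in self.analyzed_subjects if s.group == name]


# condition-specific autonomic generator settings: HR higher for gentle
# stroking; massage recruits more vagal modulation and larger SCRs.
_AUTONOMIC_DEFAULTS = {
    GENTLE_TOUCH: {"hr": 73.0, "hf_amp": 25.0, "scr_amp": 1.2},
    MEDIUM_MASSAGE: {"hr": 71.5, "hf_amp": 30.0, "scr_amp": 2.5},
}

# condition means for the non-mediation ratings (massage is rated more
# arousing, more intense and worth paying more for).
_RATING_MEANS = {
    GENTLE_TOUCH: {"arousal": 4.8, "intensity": 3.5, "payment": 4.5},
    MEDIUM_MASSAGE: {"arousal": 5.5, "intensity": 6.5, "payment": 5.5},
}
_RATING_SDS = {"arousal": 1.3, "intensity": 1.0, "payment": 1.5}


def _clip_rating(value: float, clip: bool) -> float:
    return float(np.clip(value, 1.0, 9.0)) if clip else float(value)


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortData:
    """Generate a full cohort (roster with exclusions, behaviour, plasma,
    optional fNIRS recordings and autonomic traces).

    Excluded subjects are enrolled-roster entries flagged with a reason and
    carry no data; analyzed group sizes equal ``config.group_sizes`` exactly.
    """
    config = config or CohortConfig()
    master = np.random.SeedSequence(seed)
    montage = make_montage()

    # roster: exclusions allocated round-robin across groups so the analyzed
    # sizes are exact; reasons shuffled deterministically.
    groups = list(config.group_sizes)
    n_excluded = config.n_incomplete + config.n_technical
    reasons = ["incomplete"] * config.n_incomplete + ["technical"] * config.n_technical
    roster_rng = np.random.default_rng(master.spawn(1)[0])
    roster_rng.shuffle(reasons)
    extra = {g: 0 for g in groups}
    for j in range(n_excluded):
        extra[groups[j % len(groups)]] += 1

    plan: list[tuple[str, Optional[str]]] = []
    reason_iter = iter(reasons)
    for g in groups:
        for _ in range(config.group_sizes[g]):
            plan.append((g, None))
        for _ in range(extra[g]):
            plan.append((g, next(reason_iter)))

    children = np.random.SeedSequence(seed).spawn(len(plan) + 1)[1:]  # child 0 is the roster rng

    designs = {
        cond: make_block_design(
            config.n_blocks, config.stim_s, config.rest_s, config.sampling_rate, condition=cond
        )
        for cond in (GENTLE_TOUCH, MEDIUM_MASSAGE)
    }

    subjects: list[SubjectRecord] = []
    for i, (group, reason) in enumerate(plan):
        sid = f"sub-{i + 1:03d}"
        if reason is not None:
            subjects.append(SubjectRecord(id=sid, group=group, exclusion_reason=reason))
            continue
        rng = np.random.default_rng(children[i])
        sub_seeds = children[i].spawn(8)

        # --- plasma + mediation structure
        paths = config.paths.get(group, MediationPaths(a=0.0, b=0.06, c_prime=0.0))
        x = 0.0 if group == PLC else 1.0
        baseline = max(0.5, config.baseline_ot_mean + config.baseline_ot_sd * rng.normal())
        m = paths.a * x + config.sigma_m * rng.normal()
        post_treat = max(0.5, baseline + m)
        post_sessions = [
            max(0.5, baseline + 0.4 * paths.a * x + 0.5 + 2.5 * rng.normal()) for _ in range(2)
        ]
        plasma = np.array([baseline, post_treat, *post_sessions])
        m_real = post_treat - baseline  # equals m unless the floor clipped

        # --- ratings
        ratings: dict[str, dict[str, float]] = {}
        y_gentle = (
            config.pleasantness_intercept
            + paths.c_prime * x
            + paths.b * m_real
            + config.sigma_y * rng.normal()
        )
        ratings[GENTLE_TOUCH] = {"pleasantness": _clip_rating(y_gentle, config.clip_ratings)}
        ratings[MEDIUM_MASSAGE] = {
            "pleasantness": _clip_rating(6.9 + config.sigma_y * rng.normal(), config.clip_ratings)
        }
        for cond in (GENTLE_TOUCH, MEDIUM_MASSAGE):
            for name in ("arousal", "intensity", "payment"):
                v = _RATING_MEANS[cond][name] + _RATING_SDS[name] * rng.normal()
                ratings[cond][name] = _clip_rating(v, config.clip_ratings)

        record = SubjectRecord(id=sid, group=group, plasma_ot=plasma, ratings=ratings)

        # --- fNIRS
        if config.include_fnirs:
            gain = max(0.2, 1.0 + config.amplitude_cv * rng.normal())
            spec = config.effect_spec
            amp = {k: gain * v for k, v in spec.amplitude.items()}
            tau = {
                k: max(0.0, v + config.tau_jitter_sd * rng.normal())
                for k, v in spec.prolongation_tau.items()
            }
            sub_spec = EffectSpec(
                amplitude=amp,
                prolongation_tau=tau,
                noise_sd=spec.noise_sd,
                physio_components=spec.physio_components,
                artifact_rate=spec.artifact_rate,
                spike_magnitude=spec.spike_magnitude,
                step_magnitude=spec.step_magnitude,
                hrf_params=spec.hrf_params,
            )
            for j, cond in enumerate((GENTLE_TOUCH, MEDIUM_MASSAGE)):
                record.recordings[cond] = simulate_subject_fnirs(
                    montage, designs[cond], sub_spec, seed=sub_seeds[j], group=group
                )

        # --- autonomic
        if config.include_autonomic:
            hr_offset = 6.0 * rng.normal()
            for j, cond in enumerate((GENTLE_TOUCH, MEDIUM_MASSAGE)):
                p = _AUTONOMIC_DEFAULTS[cond]
                record.rr_series[cond] = simulate_rr(
                    duration_s=designs[cond].total_duration,
                    mean_hr_bpm=float(np.clip(p["hr"] + hr_offset, 45.0, 120.0)),
                    hf_amp=max(2.0, p["hf_amp"] + 5.0 * rng.normal()),
                    seed=sub_seeds[2 + j],
                )
                record.scr_trace[cond] = simulate_scr(
                    designs[cond],
                    event_amplitude=max(0.0, p["scr_amp"] + 0.5 * rng.normal()),
                    seed=sub_seeds[4 + j],
                    sampling_rate=config.scr_sampling_rate,
                )

        subjects.append(record)

    return CohortData(subjects=subjects, config=config, seed=seed)
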