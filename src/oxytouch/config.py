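"""Pipeline configuration: one YAML-serialisable object aggregating every
stage's parameters, with defaults equal to the study protocol (20 blocks of
30 s + 15 s rest at 6.78 Hz, 0.01-0.08 Hz band, 5-35 s feature window,
10,000 permutations, 5,000 bootstrap resamples, groups 56/57/58)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import DEFAULT_WINDOW, FEATURE_ROIS
from .glm import HrfParams
from .preprocess import PreprocessConfig
from .simulate import CohortConfig, EffectSpec, MediationPaths

__all__ = ["ClassifyConfig", "MediationConfig", "AutonomicConfig", "PipelineConfig"]


@dataclass
class ClassifyConfig:
    window: tuple[float, float] = DEFAULT_WINDOW
    rois: tuple[str, ...] = FEATURE_ROIS
    n_permutations: int = 10000
    similarity: str = "pearson"
    add_one: bool = False
    baseline_correct: bool = False
    pairs: tuple[tuple[str, str], ...] = (
        ("intranasal_OT", "PLC"),
        ("oral_OT", "PLC"),
        ("intranasal_OT", "oral_OT"),
    )


@dataclass
class MediationConfig:
    n_boot: int = 5000
    routes: tuple[str, ...] = ("intranasal_OT", "oral_OT")
    control: str = "PLC"


@dataclass
class AutonomicConfig:
    hf_band: tuple[float, float] = (0.15, 0.40)
    dfa_scales: tuple[int, ...] = tuple(range(4, 17))
    scr_window_s: float = 15.0


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hrf: HrfParams = field(default_factory=HrfParams)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    mediation: MediationConfig = field(default_factory=MediationConfig)
    autonomic: AutonomicConfig = field(default_factory=AutonomicConfig)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "cohort": _cohort_to_dict(self.cohort),
            "preprocess": _preprocess_to_dict(self.preprocess),
            "hrf": asdict(self.hrf),
            "classify": _plain(asdict(self.classify)),
            "mediation": _plain(asdict(self.mediation)),
            "autonomic": _plain(asdict(self.autonomic)),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            seed=int(d.get("seed", 0)),
            cohort=_cohort_from_dict(d.get("cohort", {})),
            preprocess=_preprocess_from_dict(d.get("preprocess", {})),
            hrf=HrfParams(**d.get("hrf", {})),
            classify=_from_plain(ClassifyConfig, d.get("classify", {})),
            mediation=_from_plain(MediationConfig, d.get("mediation", {})),
            autonomic=_from_plain(AutonomicConfig, d.get("autonomic", {})),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# helpers: tuple-keyed dicts and tuples do not survive YAML natively


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _tuplify(cls, d: dict) -> dict:
    """Convert lists back to tuples for tuple-annotated dataclass fields."""
    out = {}
    for f in cls.__dataclass_fields__.values():  # type: ignore[attr-defined]
        if f.name not in d:
            continue
        v = d[f.name]
        if isinstance(v, list):
            v = tuple(tuple(i) if isinstance(i, list) else i for i in v)
        out[f.name] = v
    return out


def _from_plain(cls, d: dict):
    return cls(**_tuplify(cls, d))


def _effect_to_dict(spec: EffectSpec) -> dict:
    amp: dict[str, dict[str, float]] = {}
    for (roi, cond), v in spec.amplitude.items():
        amp.setdefault(roi, {})[cond] = float(v)
    tau: dict[str, dict[str, dict[str, float]]] = {}
    for (roi, cond, group), v in spec.prolongation_tau.items():
        tau.setdefault(roi, {}).setdefault(cond, {})[group] = float(v)
    return {
        "amplitude": amp,
        "prolongation_tau": tau,
        "noise_sd": spec.noise_sd,
        "physio_components": [[float(f), float(a)] for f, a in spec.physio_components],
        "artifact_rate": spec.artifact_rate,
        "spike_magnitude": spec.spike_magnitude,
        "step_magnitude": spec.step_magnitude,
        "hrf_params": asdict(spec.hrf_params),
    }


def _effect_from_dict(d: dict) -> EffectSpec:
    amp = {
        (roi, cond): float(v)
        for roi, conds in d.get("amplitude", {}).items()
        for cond, v in conds.items()
    }
    tau = {
        (roi, cond, group): float(v)
        for roi, conds in d.get("prolongation_tau", {}).items()
        for cond, groups in conds.items()
        for group, v in groups.items()
    }
    return EffectSpec(
        amplitude=amp,
        prolongation_tau=tau,
        noise_sd=float(d.get("noise_sd", 0.3)),
        physio_components=tuple((float(f), float(a)) for f, a in d.get("physio_components", [])),
        artifact_rate=float(d.get("artifact_rate", 0.0)),
        spike_magnitude=float(d.get("spike_magnitude", 3.0)),
        step_magnitude=float(d.get("step_magnitude", 1.0)),
        hrf_params=HrfParams(**d.get("hrf_params", {})),
    )


def _cohort_to_dict(c: CohortConfig) -> dict:
    return {
        "group_sizes": dict(c.group_sizes),
        "n_incomplete": c.n_incomplete,
        "n_technical": c.n_technical,
        "paths": {g: asdict(p) for g, p in c.paths.items()},
        "sigma_m": c.sigma_m,
        "sigma_y": c.sigma_y,
        "pleasantness_intercept": c.pleasantness_intercept,
        "baseline_ot_mean": c.baseline_ot_mean,
        "baseline_ot_sd": c.baseline_ot_sd,
        "clip_ratings": c.clip_ratings,
        "effect_spec": _effect_to_dict(c.effect_spec),
        "amplitude_cv": c.amplitude_cv,
        "tau_jitter_sd": c.tau_jitter_sd,
        "n_blocks": c.n_blocks,
        "stim_s": c.stim_s,
        "rest_s": c.rest_s,
        "sampling_rate": c.sampling_rate,
        "include_fnirs": c.include_fnirs,
        "include_autonomic": c.include_autonomic,
        "scr_sampling_rate": c.scr_sampling_rate,
    }


def _cohort_from_dict(d: dict) -> CohortConfig:
    kwargs = {k: v for k, v in d.items() if k not in ("paths", "effect_spec", "group_sizes")}
    if "group_sizes" in d:
        kwargs["group_sizes"] = {str(g): int(n) for g, n in d["group_sizes"].items()}
    if "paths" in d:
        kwargs["paths"] = {g: MediationPaths(**p) for g, p in d["paths"].items()}
    if "effect_spec" in d:
        kwargs["effect_spec"] = _effect_from_dict(d["effect_spec"])
    return CohortConfig(**kwargs)


def _preprocess_to_dict(p: PreprocessConfig) -> dict:
    return {
        "wavelengths": [float(w) for w in p.wavelengths],
        "extinction": {str(w): dict(v) for w, v in p.extinction.items()},
        "dpf": {str(w): float(v) for w, v in p.dpf.items()},
        "distance_cm": p.distance_cm,
        "detrend_order": p.detrend_order,
        "band": [float(b) for b in p.band],
        "filter_order": p.filter_order,
        "tddr_tuning": p.tddr_tuning,
    }


def _preprocess_from_dict(d: dict) -> PreprocessConfig:
    kwargs = dict(d)
    if "wavelengths" in kwargs:
        kwargs["wavelengths"] = tuple(float(w) for w in kwargs["wavelengths"])
    if "extinction" in kwargs:
        kwargs["extinction"] = {float(w): dict(v) for w, v in kwargs["extinction"].items()}
    if "dpf" in kwargs:
        kwargs["dpf"] = {float(w): float(v) for w, v in kwargs["dpf"].items()}
    if "band" in kwargs:
        kwargs["band"] = tuple(float(b) for b in kwargs["band"])
    return PreprocessConfig(**kwargs)
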