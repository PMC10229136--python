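"""End-to-end pipeline: simulate -> preprocess -> glm -> classify /
autonomic / mediate -> stats -> report.

Stages communicate through files in a run directory, so each can also be
invoked standalone (the CLI maps one subcommand onto each).  A stage is
re-executed when resume mode is off, one of its outputs is missing, or an
upstream stage re-ran — deleting an intermediate therefore regenerates
only that stage and its dependents.  All result files are deterministic
functions of (config, seed); timestamps live only in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import stats as st
from .autonomic import compute_indices
from .config import PipelineConfig
from .design import GENTLE_TOUCH, MEDIUM_MASSAGE, concat_designs, make_block_design
from .glm import build_design, contrast_stim_minus_rest, fit_glm, roi_aggregate
from .montage import make_montage
from .preprocess import preprocess_recording
from .simulate import RRSeries, ScrTrace, simulate_cohort
from .snirf import read_snirf, write_snirf

__all__ = ["RunManifest", "run_pipeline", "STAGES"]

log = logging.getLogger("oxytouch")

CONDITIONS_2 = (GENTLE_TOUCH, MEDIUM_MASSAGE)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    files: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def _design_for(cfg: PipelineConfig, condition: str):
    c = cfg.cohort
    return make_block_design(c.n_blocks, c.stim_s, c.rest_s, c.sampling_rate, condition=condition)


def _subject_file(outdir: Path, sub: str, cond: str, stage: str) -> Path:
    return outdir / stage / f"{sub}_{cond}.snirf"


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    cohort = simulate_cohort(cfg.cohort, seed=cfg.seed)
    (outdir / "fnirs").mkdir(parents=True, exist_ok=True)

    roster = pd.DataFrame(
        {
            "subject": [s.id for s in cohort.subjects],
            "group": [s.group for s in cohort.subjects],
            "exclusion_reason": [s.exclusion_reason or "none" for s in cohort.subjects],
        }
    )
    roster.to_csv(outdir / "roster.csv", index=False)

    ratings_rows, plasma_rows, rr_rows, scr_rows = [], [], [], []
    timepoints = ("baseline", "post_treatment_30min", "post_session_1", "post_session_2")
    for s in cohort.analyzed_subjects:
        for cond, r in s.ratings.items():
            ratings_rows.append({"subject": s.id, "group": s.group, "condition": cond, **r})
        for tp, v in zip(timepoints, s.plasma_ot):
            plasma_rows.append({"subject": s.id, "group": s.group, "timepoint": tp, "pg_ml": v})
        for cond, rr in s.rr_series.items():
            for k, iv in enumerate(rr.rr_intervals):
                rr_rows.append({"subject": s.id, "condition": cond, "beat": k, "interval_ms": iv})
        for cond, trace in s.scr_trace.items():
            for t, v in zip(trace.times, trace.samples):
                scr_rows.append(
                    {"subject": s.id, "condition": cond, "time_s": t, "microsiemens": v}
                )
        for cond, rec in s.recordings.items():
            write_snirf(outdir / "fnirs" / f"{s.id}_{cond}.snirf", [rec], subject_id=s.id)

    pd.DataFrame(ratings_rows).to_csv(outdir / "ratings.csv", index=False)
    pd.DataFrame(plasma_rows).to_csv(outdir / "plasma.csv", index=False)
    if rr_rows:
        pd.DataFrame(rr_rows).to_csv(outdir / "rr.csv", index=False)
    if scr_rows:
        pd.DataFrame(scr_rows).to_csv(outdir / "scr.csv", index=False)
    cfg.to_yaml(outdir / "config.yaml")


def _analyzed_roster(outdir: Path) -> pd.DataFrame:
    roster = pd.read_csv(outdir / "roster.csv")
    return roster[roster["exclusion_reason"] == "none"]


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> None:
    (outdir / "preprocessed").mkdir(parents=True, exist_ok=True)
    roster = _analyzed_roster(outdir)
    for sub in roster["subject"]:
        for cond in CONDITIONS_2:
            src = outdir / "fnirs" / f"{sub}_{cond}.snirf"
            if not src.exists():
                continue
            recs, _ = read_snirf(src)
            out = preprocess_recording(recs[0], cfg.preprocess)
            write_snirf(_subject_file(outdir, sub, cond, "preprocessed"), [out], subject_id=sub)


def stage_glm(cfg: PipelineConfig, outdir: Path) -> None:
    roster = _analyzed_roster(outdir)
    montage = make_montage()
    designs = {c: _design_for(cfg, c) for c in CONDITIONS_2}
    combined = concat_designs(designs[GENTLE_TOUCH], designs[MEDIUM_MASSAGE])
    beta_rows, contrast_rows, roi_rows = [], [], []
    for sub, group in zip(roster["subject"], roster["group"]):
        recs = []
        for cond in CONDITIONS_2:
            path = _subject_file(outdir, sub, cond, "preprocessed")
            if not path.exists():
                continue
            recs.append(read_snirf(path)[0][0])
        if len(recs) != 2:
            continue
        rec = recs[0].concat(recs[1])
        dm = build_design(combined, rec.sampling_rate, cfg.hrf, n_samples=rec.n_samples)
        result = fit_glm(rec, dm)
        for ch, row in result.betas.iterrows():
            for reg, v in row.items():
                beta_rows.append(
                    {"subject": sub, "group": group, "channel": ch, "regressor": reg, "value": v}
                )
        for cond in CONDITIONS_2:
            contrast = contrast_stim_minus_rest(result, cond)
            for ch, v in contrast.items():
                contrast_rows.append(
                    {"subject": sub, "group": group, "channel": ch, "condition": cond, "value": v}
                )
            for roi, v in roi_aggregate(contrast, montage).items():
                roi_rows.append(
                    {"subject": sub, "group": group, "condition": cond, "roi": roi, "value": v}
                )
    pd.DataFrame(beta_rows).to_csv(outdir / "betas.csv", index=False)
    pd.DataFrame(contrast_rows).to_csv(outdir / "contrasts.csv", index=False)
    pd.DataFrame(roi_rows).to_csv(outdir / "roi.csv", index=False)


def stage_classify(cfg: PipelineConfig, outdir: Path) -> None:
    roster = _analyzed_roster(outdir)
    montage = make_montage()
    design = _design_for(cfg, GENTLE_TOUCH)
    feats, labels, subs = [], [], []
    for sub, group in zip(roster["subject"], roster["group"]):
        path = _subject_file(outdir, sub, GENTLE_TOUCH, "preprocessed")
        if not path.exists():
            continue
        rec = read_snirf(path)[0][0]
        feats.append(
            clf.extract_features(
                rec,
                design,
                montage,
                rois=cfg.classify.rois,
                window=cfg.classify.window,
                baseline_correct=cfg.classify.baseline_correct,
            )
        )
        labels.append(group)
        subs.append(sub)
    X = np.array(feats)
    feat_rows = [
        {"subject": s, "group": g, "feature_index": j, "value": v}
        for s, g, vec in zip(subs, labels, X)
        for j, v in enumerate(vec)
    ]
    pd.DataFrame(feat_rows).to_csv(outdir / "features.csv", index=False)

    results = {}
    labels = np.array(labels)
    for g1, g2 in cfg.classify.pairs:
        mask = np.isin(labels, [g1, g2])
        if mask.sum() < 4 or len(set(labels[mask])) < 2:
            continue
        res = clf.permutation_test(
            X[mask],
            labels[mask].tolist(),
            n_permutations=cfg.classify.n_permutations,
            seed=cfg.seed,
            similarity=cfg.classify.similarity,
            add_one=cfg.classify.add_one,
        )
        results[f"{g1}_vs_{g2}"] = {
            "accuracy": res.accuracy,
            "p_value": res.p_value,
            "n_permutations": res.n_permutations,
            "n_ties": res.n_ties,
            "seed": cfg.seed,
            "null_mean": float(np.mean(res.null_distribution)),
            "null_q95": float(np.quantile(res.null_distribution, 0.95)),
        }
    _dump_json(results, outdir / "classification.json")


def stage_autonomic(cfg: PipelineConfig, outdir: Path) -> None:
    if not (outdir / "rr.csv").exists():
        _dump_json({"skipped": "no autonomic traces"}, outdir / "autonomic.skip.json")
        return
    rr = pd.read_csv(outdir / "rr.csv")
    scr = pd.read_csv(outdir / "scr.csv")
    rows = []
    for (sub, cond), g in rr.groupby(["subject", "condition"]):
        series = RRSeries(g.sort_values("beat")["interval_ms"].to_numpy())
        s = scr[(scr["subject"] == sub) & (scr["condition"] == cond)].sort_values("time_s")
        fs = 1.0 / float(np.median(np.diff(s["time_s"].to_numpy())))
        trace = ScrTrace(s["microsiemens"].to_numpy(), fs)
        onsets = [ev.onset for ev in _design_for(cfg, cond).events if ev.condition == cond]
        idx = compute_indices(
            series,
            trace,
            onsets,
            hf_band=cfg.autonomic.hf_band,
            dfa_scales=cfg.autonomic.dfa_scales,
            scr_window_s=cfg.autonomic.scr_window_s,
        )
        for name, value in (
            ("scr_amplitude", idx.scr_amplitude),
            ("heart_rate", idx.heart_rate),
            ("hf_power", idx.hf_power),
            ("dfa_alpha1", idx.dfa_alpha1),
        ):
            rows.append({"subject": sub, "condition": cond, "index": name, "value": value})
    pd.DataFrame(rows).to_csv(outdir / "autonomic.csv", index=False)


def stage_mediate(cfg: PipelineConfig, outdir: Path) -> None:
    plasma = pd.read_csv(outdir / "plasma.csv")
    ratings = pd.read_csv(outdir / "ratings.csv")
    wide = plasma.pivot_table(index=["subject", "group"], columns="timepoint", values="pg_ml")
    wide["delta"] = wide["post_treatment_30min"] - wide["baseline"]
    pleas = ratings[ratings["condition"] == GENTLE_TOUCH].set_index("subject")["pleasantness"]
    out = {}
    for route in cfg.mediation.routes:
        rows = wide.reset_index()
        rows = rows[rows["group"].isin([route, cfg.mediation.control])]
        if rows["group"].nunique() < 2:
            continue
        x = (rows["group"] == route).to_numpy(float)
        m = rows["delta"].to_numpy(float)
        y = pleas.loc[rows["subject"]].to_numpy(float)
        res = st.mediate(x, m, y, n_boot=cfg.mediation.n_boot, seed=cfg.seed)
        out[f"{route}_vs_{cfg.mediation.control}"] = {
            "a": res.a,
            "b": res.b,
            "c": res.c,
            "c_prime": res.c_prime,
            "indirect": res.indirect,
            "se_boot": res.se_boot,
            "ci_95": list(res.ci_95),
            "n_boot": res.n_boot,
            "seed": cfg.seed,
            "p_a": res.p_a,
            "p_b": res.p_b,
            "p_c": res.p_c,
            "p_c_prime": res.p_c_prime,
        }
    _dump_json(out, outdir / "mediation.json")


def stage_stats(cfg: PipelineConfig, outdir: Path) -> None:
    tables = []

    plasma = pd.read_csv(outdir / "plasma.csv")
    wide = plasma.pivot_table(
        index=["subject", "group"], columns="timepoint", values="pg_ml"
    ).reset_index()
    if wide["group"].nunique() >= 2 and wide.groupby("group").size().min() >= 2:
        t = st.one_way_anova(wide["baseline"], wide["group"])
        t["analysis"] = "plasma_baseline"
        tables.append(t)
        delta = wide["post_treatment_30min"] - wide["baseline"]
        t = st.one_way_anova(delta, wide["group"])
        t["analysis"] = "plasma_delta"
        tables.append(t)

    ratings = pd.read_csv(outdir / "ratings.csv")
    for rating in ("pleasantness", "arousal", "intensity", "payment"):
        t = st.mixed_anova(
            ratings.rename(columns={rating: "value"}),
            dv="value",
            subject="subject",
            between="group",
            within="condition",
        )
        t["analysis"] = f"rating_{rating}"
        tables.append(t)

    roi_path = outdir / "roi.csv"
    if roi_path.exists():
        roi = pd.read_csv(roi_path)
        if len(roi):
            t = st.mixed_anova(
                roi, dv="value", subject="subject", between="group", within=["condition", "roi"]
            )
            t["analysis"] = "roi_oxyhb"
            tables.append(t)

    auto_path = outdir / "autonomic.csv"
    if auto_path.exists():
        auto = pd.read_csv(auto_path)
        roster = _analyzed_roster(outdir)[["subject", "group"]]
        auto = auto.merge(roster, on="subject")
        for index_name, g in auto.groupby("index"):
            t = st.mixed_anova(
                g, dv="value", subject="subject", between="group", within="condition"
            )
            t["analysis"] = f"autonomic_{index_name}"
            tables.append(t)

    pd.concat(tables, ignore_index=True).to_csv(outdir / "anova_tables.csv", index=False)


def stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    roster = pd.read_csv(outdir / "roster.csv")
    reasons = roster["exclusion_reason"].replace("none", None)
    accounting = st.exclusion_accounting(
        [{"exclusion_reason": r} for r in reasons.where(pd.notna(reasons), None)]
    )
    report = {
        "exclusion_accounting": accounting,
        "group_sizes": roster[roster["exclusion_reason"] == "none"]["group"]
        .value_counts()
        .to_dict(),
    }
    for name in ("classification", "mediation"):
        path = outdir / f"{name}.json"
        if path.exists():
            report[name] = json.loads(path.read_text())
    _dump_json(report, outdir / "report.json")


STAGES: list[tuple[str, Callable[[PipelineConfig, Path], None], list[str]]] = [
    ("simulate", stage_simulate, ["roster.csv", "ratings.csv", "plasma.csv", "config.yaml"]),
    ("preprocess", stage_preprocess, ["preprocessed"]),
    ("glm", stage_glm, ["betas.csv", "contrasts.csv", "roi.csv"]),
    ("classify", stage_classify, ["features.csv", "classification.json"]),
    ("autonomic", stage_autonomic, ["autonomic.csv"]),
    ("mediate", stage_mediate, ["mediation.json"]),
    ("stats", stage_stats, ["anova_tables.csv"]),
    ("report", stage_report, ["report.json"]),
]

_STAGE_DEPS = {
    "simulate": [],
    "preprocess": ["simulate"],
    "glm": ["preprocess"],
    "classify": ["preprocess"],
    "autonomic": ["simulate"],
    "mediate": ["simulate"],
    "stats": ["glm", "autonomic", "simulate"],
    "report": ["classify", "mediate", "stats"],
}


def _outputs_present(outdir: Path, outputs: list[str]) -> bool:
    for rel in outputs:
        p = outdir / rel
        if rel == "preprocessed":
            if not (p.is_dir() and any(p.iterdir())):
                return False
        elif rel == "autonomic.csv":
            if not p.exists() and not (outdir / "autonomic.skip.json").exists():
                return False
        elif not p.exists():
            return False
    return True


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    resume: bool = False,
    stages: Optional[list[str]] = None,
) -> RunManifest:
    """Execute the pipeline end to end, writing artifacts and a manifest.

    With ``resume=True`` a stage whose outputs exist is skipped unless an
    upstream stage re-ran.  ``stages`` restricts execution to a subset (in
    canonical order); dependencies are not auto-added.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_yaml = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_yaml.encode()).hexdigest(), seed=cfg.seed
    )
    ran: set[str] = set()
    try:
        for name, func, outputs in STAGES:
            if stages is not None and name not in stages:
                continue
            upstream_ran = any(dep in ran for dep in _STAGE_DEPS[name])
            if resume and not upstream_ran and _outputs_present(outdir, outputs):
                log.info("stage %s: outputs present, skipped", name)
                manifest.stages.append({"stage": name, "status": "skipped"})
                continue
            log.info("stage %s: running (seed=%d)", name, cfg.seed)
            t0 = time.time()
            func(cfg, outdir)
            manifest.stages.append(
                {"stage": name, "status": "completed", "elapsed_s": round(time.time() - t0, 3)}
            )
            manifest.files[name] = outputs
            ran.add(name)
    finally:
        manifest.to_json(outdir / "manifest.json")
    return manifest
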