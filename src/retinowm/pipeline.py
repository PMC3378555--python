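"""Cohort orchestration: simulate → map → segment → fit → stats → report.

A single :class:`RunConfig` drives the whole pipeline.  Every stochastic
stage derives its own seed deterministically from the run seed, the subject
index, and the stage name, so any stage can be recomputed in isolation and
two runs of the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from retinowm import glm, io, roi, stats, synthetic
from retinowm.design import dct_basis
from retinowm.protocol import AREAS, INSTRUCTIONS, EffectSpec, MappingProtocol, TaskTiming
from retinowm.retinotopy import crosscorr_map, significance_mask

log = logging.getLogger("retinowm")

STAGES = ("simulate", "map", "segment", "fit", "stats", "report")


@dataclass
class RunConfig:
    """Everything a reproducible cohort run needs.

    ``delay_overrides`` confines injected delay effects to specific
    (instruction, area) cells, e.g. ``{"categorical": {"V3": {"match": 0.5,
    "mismatch": 0.0}}}``; unlisted cells fall back to the base amplitudes.
    ``subject_amp_sd`` adds a Gaussian per-subject shift common to both
    delay amplitudes (a random subject effect).
    """

    seed: int = 0
    n_subjects: int = 10
    n_per_area: int = 48
    noise_sd: float = 3.0
    gain: float = 1.0
    amp_s1: float = 1.0
    amp_s2: float = 1.0
    delay_match_amp: float = 0.0
    delay_mismatch_amp: float = 0.0
    delay_overrides: dict = field(default_factory=dict)
    subject_amp_sd: float = 0.0
    ar1_rho: float = 0.0
    drift_coeffs: list = field(default_factory=list)
    accuracy: dict = field(default_factory=lambda: {"categorical": 0.97, "coordinate": 0.81})
    rt_mean_ms: dict = field(default_factory=lambda: {"categorical": 900.0, "coordinate": 1080.0})
    rt_sd_ms: float = 200.0
    protocol: dict = field(default_factory=dict)
    timing: dict = field(default_factory=dict)
    include_own_quadrant: bool = False
    use_ground_truth_segments: bool = False
    n_dct: int = 8
    alpha: float = 0.05
    write_bold: bool = False

    def mapping_protocol(self) -> MappingProtocol:
        return MappingProtocol(**self.protocol)

    def task_timing(self) -> TaskTiming:
        return TaskTiming(**self.timing)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def stage_seed(base_seed: int, subject: int, stage: str) -> int:
    """Deterministic per-(subject, stage) seed below 2^31."""
    h = hashlib.sha256(f"{base_seed}:{subject}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def _effects_for(config: RunConfig, instruction: str, subject_shift: float) -> dict:
    out = {}
    for area in AREAS:
        override = config.delay_overrides.get(instruction, {}).get(area, {})
        out[area] = EffectSpec(
            amp_s1=config.amp_s1,
            amp_s2=config.amp_s2,
            delay_match_amp=float(override.get("match", config.delay_match_amp)) + subject_shift,
            delay_mismatch_amp=float(override.get("mismatch", config.delay_mismatch_amp))
            + subject_shift,
            ar1_rho=config.ar1_rho,
            drift_coeffs=tuple(config.drift_coeffs),
        )
    return out


@dataclass
class SubjectResult:
    subject: int
    estimates: pd.DataFrame
    segment_maps: pd.DataFrame
    trials: dict
    delay_betas: pd.DataFrame
    stimulus_betas: pd.DataFrame
    contrasts: pd.DataFrame
    behavior: pd.DataFrame


def analyze_subject(config: RunConfig, subject: int) -> SubjectResult:
    """Run the full single-subject pipeline on synthetic data."""
    protocol = config.mapping_protocol()
    timing = config.task_timing()
    sheet = synthetic.generate_voxel_sheet(
        config.n_per_area, protocol,
        seed=stage_seed(config.seed, subject, "sheet"),
        noise_sd=config.noise_sd, gain=config.gain,
    )
    meta = sheet.table[["voxel_id", "area"]]
    hp = dct_basis(protocol.n_volumes, config.n_dct)

    est_frames = {}
    for stimulus in ("wedge", "ring"):
        series = synthetic.simulate_mapping_series(
            sheet, protocol, stimulus,
            seed=stage_seed(config.seed, subject, f"map_{stimulus}"),
        )
        est = crosscorr_map(series, protocol, stimulus, highpass=hp, meta=meta)
        est = significance_mask(est, alpha=config.alpha)
        est["stimulus"] = stimulus
        est_frames[stimulus] = est

    if config.use_ground_truth_segments:
        segmaps = {m: roi.segment_map_from_truth(sheet, m) for m in ("quadrant", "ring")}
    else:
        segmaps = {
            "quadrant": roi.assign_polar_segments(est_frames["wedge"]),
            "ring": roi.assign_ecc_segments(est_frames["ring"]),
        }

    rng_subj = np.random.default_rng(stage_seed(config.seed, subject, "subject_amp"))
    subject_shift = float(rng_subj.normal(0.0, config.subject_amp_sd)) if config.subject_amp_sd else 0.0

    positions = synthetic.generate_stimulus_positions()
    trials_by_instruction = {}
    delay_rows, stim_rows, contrast_rows, behav_frames = [], [], [], []
    for instruction in INSTRUCTIONS:
        trials = synthetic.generate_trial_sequence(
            instruction, positions,
            seed=stage_seed(config.seed, subject, f"trials_{instruction}"),
            timing=timing,
        )
        trials_by_instruction[instruction] = trials
        effects = _effects_for(config, instruction, subject_shift)
        series = synthetic.simulate_task_series(
            sheet, trials, effects,
            seed=stage_seed(config.seed, subject, f"task_{instruction}"),
            include_own_quadrant=config.include_own_quadrant,
        )
        mode = "quadrant" if instruction == "categorical" else "ring"
        for area in AREAS:
            db = glm.delay_betas(
                series, segmaps[mode], trials, area,
                include_own_quadrant=config.include_own_quadrant,
                n_dct=config.n_dct,
            )
            delay_rows.append(db)
            sb = glm.stimulus_betas(
                series, segmaps[mode], trials, area,
                include_own_quadrant=config.include_own_quadrant,
                n_dct=config.n_dct,
            )
            stim_rows.append(sb)
        # reliability contrasts: both segmentations, V1-V3 pooled per area mean
        for cmode in ("quadrant", "ring"):
            vals = [
                glm.contrast_activation(series, segmaps[cmode], trials, area)
                for area in AREAS
            ]
            contrast_rows.append(
                {"instruction": instruction, "mode": cmode, "contrast": float(np.mean(vals))}
            )
        behav = synthetic.simulate_behavior(
            trials,
            accuracy=config.accuracy[instruction],
            rt_mean_ms=config.rt_mean_ms[instruction],
            rt_sd_ms=config.rt_sd_ms,
            seed=stage_seed(config.seed, subject, f"behavior_{instruction}"),
        )
        behav_frames.append(behav)

    def _tag(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df.insert(0, "subject", subject)
        return df

    seg_tables = []
    for m, sm in segmaps.items():
        t = sm.table.copy()
        t["mode"] = m
        seg_tables.append(t)

    return SubjectResult(
        subject=subject,
        estimates=_tag(pd.concat(est_frames.values(), ignore_index=True)),
        segment_maps=_tag(pd.concat(seg_tables, ignore_index=True)),
        trials=trials_by_instruction,
        delay_betas=_tag(pd.concat(delay_rows, ignore_index=True)),
        stimulus_betas=_tag(pd.concat(stim_rows, ignore_index=True)),
        contrasts=_tag(pd.DataFrame(contrast_rows)),
        behavior=_tag(pd.concat(behav_frames, ignore_index=True)),
    )


def run_cohort(config: RunConfig) -> dict:
    """All subjects' tables concatenated, ready for group statistics."""
    results = [analyze_subject(config, s) for s in range(config.n_subjects)]
    return {
        "estimates": pd.concat([r.estimates for r in results], ignore_index=True),
        "segment_maps": pd.concat([r.segment_maps for r in results], ignore_index=True),
        "delay_betas": pd.concat([r.delay_betas for r in results], ignore_index=True),
        "stimulus_betas": pd.concat([r.stimulus_betas for r in results], ignore_index=True),
        "contrasts": pd.concat([r.contrasts for r in results], ignore_index=True),
        "behavior": pd.concat([r.behavior for r in results], ignore_index=True),
        "subjects": results,
    }


def group_statistics(tables: dict) -> dict:
    """Second-level tests on the cohort tables."""
    anova = stats.delay_rm_anova(tables["delay_betas"])
    followups, posthocs = [], []
    for area in AREAS:
        fu = stats.followup_per_roi(tables["delay_betas"], area)
        a = fu["anova"].copy()
        a.insert(0, "area", area)
        followups.append(a)
        posthocs.append(fu["posthoc"])
    stim_anovas = []
    for area in AREAS:
        sub = tables["stimulus_betas"][tables["stimulus_betas"]["area"] == area]
        sa = stats.rm_anova(sub, dv="beta", subject="subject", within=["instruction", "stimulus"])
        sa.insert(0, "area", area)
        stim_anovas.append(sa)
    behav = stats.behavioral_tests(tables["behavior"])
    contrast = stats.contrast_activation_anova(tables["contrasts"])
    return {
        "delay_anova": anova,
        "followups": pd.concat(followups, ignore_index=True),
        "posthocs": pd.concat(posthocs, ignore_index=True),
        "stimulus_anovas": pd.concat(stim_anovas, ignore_index=True),
        "behavior_tests": pd.DataFrame([t.__dict__ for t in behav]),
        "contrast_oneway": contrast["oneway"],
        "contrast_twoway": contrast["twoway"],
    }


def run_pipeline(config: RunConfig, outdir, upto: str = "report") -> Path:
    """Execute the pipeline, writing each stage's outputs and a manifest.

    ``upto`` stops after the named stage ("simulate" .. "report").
    Rerunning with the same config reproduces every output bit-identically.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; expected one of {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    last = STAGES.index(upto)
    manifest: dict = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "package_version": __import__("retinowm").__version__,
        "numpy_version": np.__version__,
        "stages": {},
    }

    t0 = time.time()
    try:
        tables = run_cohort(config)
    except Exception as e:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline failed in stage 'simulate/map/fit': {e}") from e
    log.info("cohort of %d subjects analyzed in %.1fs", config.n_subjects, time.time() - t0)

    outputs: dict[str, list[str]] = {s: [] for s in STAGES}

    def _write(stage: str, name: str, df: pd.DataFrame):
        io.write_table(df, outdir / name)
        outputs[stage].append(name)

    for r in tables["subjects"]:
        for instruction, trials in r.trials.items():
            name = f"events_sub-{r.subject:02d}_{instruction}.tsv"
            io.write_events_tsv(trials, outdir / name)
            outputs["simulate"].append(name)
    _write("simulate", "behavior.tsv", tables["behavior"])
    if last >= 1:
        _write("map", "retinotopy_estimates.tsv", tables["estimates"])
    if last >= 2:
        _write("segment", "segment_maps.tsv", tables["segment_maps"])
    if last >= 3:
        _write("fit", "betas_delay.tsv", tables["delay_betas"])
        _write("fit", "betas_stimulus.tsv", tables["stimulus_betas"])
        _write("fit", "contrast_activation.tsv", tables["contrasts"])
    if last >= 4:
        try:
            results = group_statistics(tables)
        except Exception as e:  # pragma: no cover
            raise RuntimeError(f"pipeline failed in stage 'stats': {e}") from e
        _write("stats", "anova_delay.tsv", results["delay_anova"])
        _write("stats", "anova_followups.tsv", results["followups"])
        _write("stats", "posthoc_contrasts.tsv", results["posthocs"])
        _write("stats", "anova_stimulus.tsv", results["stimulus_anovas"])
        _write("stats", "behavior_tests.tsv", results["behavior_tests"])
        _write("stats", "anova_contrast_oneway.tsv", results["contrast_oneway"])
        _write("stats", "anova_contrast_twoway.tsv", results["contrast_twoway"])
    if last >= 5:
        report = make_report(outdir)
        outputs["report"].append(report.name)

    manifest["stages"] = {s: outputs[s] for s in STAGES[: last + 1]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _fmt_anova(df: pd.DataFrame) -> str:
    keep = [c for c in ("area", "effect", "method", "F", "df_num", "df_den", "p") if c in df]
    return df[keep].to_markdown(index=False, floatfmt=".4g")


def make_report(rundir) -> Path:
    """Markdown report with bar summaries (mean ± SEM) from a run directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rundir = Path(rundir)
    lines = ["# retinowm run report", ""]

    betas_path = rundir / "betas_delay.tsv"
    if betas_path.exists():
        betas = io.read_table(betas_path)
        lines += ["## Delay-period betas (mean ± SEM)", ""]
        fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharey=True)
        for ax, area in zip(axes, AREAS):
            sub = betas[betas["area"] == area]
            g = sub.groupby(["instruction", "region"])["beta"]
            m, sem = g.mean(), g.sem()
            labels = [f"{i[:3]}\n{r}" for i, r in m.index]
            ax.bar(range(len(m)), m.to_numpy(), yerr=sem.to_numpy(), capsize=3)
            ax.set_xticks(range(len(m)), labels, fontsize=7)
            ax.set_title(area)
        fig.tight_layout()
        fig.savefig(rundir / "fig_delay_betas.png", dpi=100)
        plt.close(fig)
        lines += ["![delay betas](fig_delay_betas.png)", ""]

    for title, name in [
        ("Three-way ROI × instruction × region ANOVA", "anova_delay.tsv"),
        ("Per-ROI follow-up ANOVAs", "anova_followups.tsv"),
        ("Instruction × stimulus ANOVAs", "anova_stimulus.tsv"),
        ("Contrast-activation reliability ANOVA (one-way)", "anova_contrast_oneway.tsv"),
    ]:
        p = rundir / name
        if p.exists():
            lines += [f"## {title}", "", _fmt_anova(io.read_table(p)), ""]

    p = rundir / "posthoc_contrasts.tsv"
    if p.exists():
        lines += ["## Post-hoc match vs mismatch contrasts", "",
                  io.read_table(p).to_markdown(index=False, floatfmt=".4g"), ""]

    p = rundir / "behavior_tests.tsv"
    if p.exists():
        lines += ["## Behavioral paired t-tests", "",
                  io.read_table(p).to_markdown(index=False, floatfmt=".4g"), ""]
    else:
        lines += ["## Behavioral paired t-tests", "", "_No behavioral data in this run._", ""]

    out = rundir / "report.md"
    out.write_text("\n".join(lines))
    return out
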