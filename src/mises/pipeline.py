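"""End-to-end cohort pipeline and report generation.

Runs simulate -> preprocess (two branches) -> decode -> stratify -> ERSP ->
relative SampEn -> wPLI edge counts -> group statistics, and emits a
deterministic, fully seeded JSON report.  Every random choice derives from
the single configured seed, so rerunning an identical configuration
reproduces the report byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .complexity import relative_sampen
from .connectivity import PermutationSpec, significant_edge_count
from .decoding import loo_accuracy, stratify_performers
from .montage import DEFAULT_MONTAGE
from .preprocess import preprocess_analysis, preprocess_decoding
from .simulate import (
    NoiseModel,
    ParadigmSpec,
    cohort_profiles,
    simulate_subject,
)
from .spectral import ALPHA_BAND, BETA_BAND, band_average, ersp
from .stats import gated_paired_test, rm_anova_posthoc

#: classifier pairs evaluated per subject, in report order
DECODE_PAIRS: tuple[tuple[str, str], ...] = (
    ("MI", "REST"),
    ("MI_SES", "SES"),
    ("MI_SES", "REST"),
    ("SES", "REST"),
)

BANDS = {"alpha": ALPHA_BAND, "beta": BETA_BAND}


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-cohort analysis run."""

    n_high: int = 10
    n_low: int = 10
    seed: int = 0
    fs: float = 250.0
    n_trials_per_condition: int = 40
    channel: str = "C3"
    task_window: tuple[float, float] = (3.0, 5.0)
    baseline_window: tuple[float, float] = (-1.0, -0.2)
    n_perm: int = 400
    perm_threshold: float = 0.005
    reject_ptp: float = 150.0
    connectivity: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(**d)
        for name in ("task_window", "baseline_window"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class SubjectRecord:
    """Per-subject quantities feeding the group statistics."""

    subject_id: str
    profile_label: str
    group: str = ""
    n_kept_trials: int = 0
    accuracies: dict = field(default_factory=dict)
    ersp_band_means: dict = field(default_factory=dict)
    rel_sampen: dict = field(default_factory=dict)
    connectivity_edges: dict = field(default_factory=dict)


def analyze_subject(
    subject_id: str,
    profile,
    record,
    events,
    cfg: PipelineConfig,
    subject_seed: int,
) -> SubjectRecord:
    """All per-subject analysis stages on one simulated (or loaded) record."""
    rec = SubjectRecord(subject_id=subject_id, profile_label=profile.label)

    dec = preprocess_decoding(record, events)
    for a, b in DECODE_PAIRS:
        acc, _ = loo_accuracy(dec.select(a), dec.select(b), seed=subject_seed)
        rec.accuracies[f"{a}:{b}"] = acc
    rec.group = stratify_performers(rec.accuracies["MI:REST"])

    ana = preprocess_analysis(record, events, reject_ptp=cfg.reject_ptp)
    rec.n_kept_trials = int(ana.kept_mask.sum())
    for cond in ("MI", "SES", "MI_SES"):
        tf = ersp(ana, condition=cond, channels=[cfg.channel],
                  baseline=cfg.baseline_window)
        for band_name, band in BANDS.items():
            rec.ersp_band_means[f"{cond}:{band_name}"] = band_average(
                tf, band, cfg.task_window, cfg.channel
            )
    for cond in ("MI", "MI_SES", "SES"):
        _, mean = relative_sampen(
            ana, cond, channel=cfg.channel,
            task_window=cfg.task_window, baseline_window=cfg.baseline_window,
        )
        rec.rel_sampen[cond] = mean
    if cfg.connectivity:
        spec = PermutationSpec(
            n_perm=cfg.n_perm, threshold=cfg.perm_threshold, seed=subject_seed
        )
        for cond in ("MI", "MI_SES"):
            for band_name, band in BANDS.items():
                rec.connectivity_edges[f"{cond}:{band_name}"] = (
                    significant_edge_count(
                        ana, cond, band, time_window=cfg.task_window, spec=spec
                    )
                )
    return rec


def _group_statistics(records: list[SubjectRecord]) -> dict:
    """Within-group comparisons mirroring the study's analyses."""
    out: dict = {}
    for group in ("HIGH", "LOW"):
        members = [r for r in records if r.group == group]
        g: dict = {"n": len(members), "subjects": [r.subject_id for r in members]}
        if len(members) >= 3:
            acc = {
                pair: np.array([r.accuracies[f"{pair}"] for r in members])
                for pair in ("MI:REST", "MI_SES:SES", "MI_SES:REST", "SES:REST")
            }
            g["accuracy_means"] = {k: float(v.mean()) for k, v in acc.items()}
            g["accuracy_sds"] = {k: float(v.std(ddof=1)) for k, v in acc.items()}
            try:
                g["mises_ses_vs_mi_rest"] = gated_paired_test(
                    acc["MI_SES:SES"], acc["MI:REST"]
                ).to_dict()
            except ValueError as err:
                g["mises_ses_vs_mi_rest"] = {"error": str(err)}
            anova_cols = np.column_stack(
                [acc["MI_SES:REST"], acc["MI:REST"], acc["SES:REST"]]
            )
            g["rm_anova_vs_rest"] = [
                t.to_dict()
                for t in rm_anova_posthoc(
                    anova_cols, ["MI_SES:REST", "MI:REST", "SES:REST"]
                )
            ]
            for band in ("alpha", "beta"):
                a = np.array([r.ersp_band_means[f"MI_SES:{band}"] for r in members])
                b = np.array([r.ersp_band_means[f"MI:{band}"] for r in members])
                g[f"ersp_{band}_mises_vs_mi"] = gated_paired_test(a, b).to_dict()
                g[f"ersp_{band}_means"] = {
                    "MI_SES": float(a.mean()),
                    "MI": float(b.mean()),
                }
            a = np.array([r.rel_sampen["MI_SES"] for r in members])
            b = np.array([r.rel_sampen["MI"] for r in members])
            g["sampen_mises_vs_mi"] = gated_paired_test(a, b).to_dict()
            g["rel_sampen_means"] = {"MI_SES": float(a.mean()), "MI": float(b.mean())}
            if members[0].connectivity_edges:
                g["connectivity_edge_means"] = {
                    key: float(
                        np.mean([r.connectivity_edges[key] for r in members])
                    )
                    for key in members[0].connectivity_edges
                }
        out[group] = g
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full cohort analysis; returns the report dictionary."""
    paradigm = ParadigmSpec(n_trials_per_condition=cfg.n_trials_per_condition)
    noise = NoiseModel()
    profiles = cohort_profiles(cfg.n_high, cfg.n_low, cfg.seed)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(profiles)) % (2**31)

    records = []
    for i, (profile, seed) in enumerate(zip(profiles, seeds)):
        subject_id = f"S{i + 1:02d}"
        record, events = simulate_subject(
            profile, paradigm, noise, fs=cfg.fs, montage=DEFAULT_MONTAGE,
            seed=int(seed),
        )
        records.append(
            analyze_subject(subject_id, profile, record, events, cfg, int(seed))
        )

    report = {
        "pipeline_version": __version__,
        "config": asdict(cfg),
        "subject_seeds": [int(s) for s in seeds],
        "subjects": [asdict(r) for r in records],
        "group_stats": _group_statistics(records),
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, fixed layout), so that
    identical configurations reproduce byte-identical reports."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"


def save_report(report: dict, path) -> None:
    Path(path).write_text(report_to_json(report))
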