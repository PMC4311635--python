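"""End-to-end orchestration: rates -> NMF -> networks -> metrics -> report.

The in-memory entry point is :func:`analyze_trials`, which takes per-trial
spike records and returns rate matrices, the harmonized NMF embedding,
per-window pruned causality networks in neuron ("original") and component
("nmf") space, metric time courses, and a summary with group comparisons.
:func:`run_pipeline` wraps it with file input, artifact writing, and a
hash manifest so a run is fully reproducible from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .granger import window_networks
from .metrics import compare_groups, metric_timecourse, peak_window_stats, MetricTimecourse
from .nmf import harmonize_rank
from .rates import RateMatrix, WindowSpec, build_rate_matrix, sliding_windows
from .simulate import TrialRecord, read_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "analyze_trials", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Every knob of a run; round-trips through YAML unchanged."""

    spikes: str = ""
    events: str = ""
    out_dir: str = "spikegc_out"
    dt: float = 0.01            # rate-series grid (s); the source trains are unsampled
    delta: float = 0.25         # averaging window as fraction of mean ISI
    vaf_threshold: float = 0.9  # NMF rank criterion
    window_width: float = 0.5   # moving window (s)
    window_step: float = 0.125  # moving step (s)
    alpha: float = 0.05         # edge significance level (after FDR)
    p_max: int = 3              # maximum VAR order for BIC
    restarts: int = 10          # NMF random restarts
    seed: int = 0
    peak_pre: float = 0.25      # peak-window extraction (s)
    peak_post: float = 0.25
    spaces: tuple = ("original", "nmf")

    def __post_init__(self):
        if isinstance(self.spaces, list):
            self.spaces = tuple(self.spaces)
        if not set(self.spaces) <= {"original", "nmf"}:
            raise ValueError("spaces must be a subset of {'original', 'nmf'}")
        if not (0 < self.window_step <= self.window_width):
            raise ValueError("require 0 < window_step <= window_width")
        for name in ("dt", "alpha", "peak_pre", "peak_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["spaces"] = list(self.spaces)
        Path(path).write_text(yaml.safe_dump(d))


@dataclass
class AnalysisResult:
    rate_matrices: dict = field(repr=False)       # trial_id -> RateMatrix
    rank_selection: object = None                 # RankSelection or None
    networks: dict = field(default=None, repr=False)      # (space, trial_id) -> [GCNetwork]
    timecourses: dict = field(default=None, repr=False)   # (space, trial_id) -> MetricTimecourse
    group_table: pd.DataFrame = None              # per-trial peak-window scalars
    summary: dict = None


def _mean_surviving_weight(networks: list) -> float:
    """Mean GC weight over surviving edges, pooled across windows."""
    vals = []
    for net in networks:
        if net.sig_mask is not None and net.sig_mask.any():
            vals.append(net.F[net.sig_mask])
    if not vals:
        return 0.0
    return float(np.concatenate(vals).mean())


def _mean_connection_weight_at_peak(networks_by_trial: list[list], pre=0.25, post=0.25) -> float:
    """Mean of the pruned connectivity matrices around each trial's peak.

    Per trial, the mean off-diagonal connection weight (zeros included) is
    traced across windows, its peak located, and the matrices within
    [peak - pre, peak + post] averaged; the per-trial values are then pooled.
    """
    vals = []
    for nets in networks_by_trial:
        if not nets:
            continue
        mw = [(n.window_center, float(n.F[~np.eye(n.n_nodes, dtype=bool)].mean()))
              for n in nets]
        t_peak = max(mw, key=lambda x: x[1])[0]
        sel = [v for t, v in mw if t_peak - pre - 1e-9 <= t <= t_peak + post + 1e-9]
        vals.append(float(np.mean(sel)))
    return float(np.mean(vals)) if vals else 0.0


def _group_mean_curve(tcs: list[MetricTimecourse], metric: str) -> tuple[np.ndarray, np.ndarray]:
    """Average a metric across trials at each shared window center."""
    acc: dict[float, list[float]] = {}
    for tc in tcs:
        values = tc.cd if metric == "cd" else tc.eff
        for t, v in zip(tc.times, values):
            acc.setdefault(round(float(t), 6), []).append(float(v))
    times = np.array(sorted(acc))
    means = np.array([np.mean(acc[t]) for t in times])
    return times, means


def analyze_trials(trials: list[TrialRecord], config: PipelineConfig) -> AnalysisResult:
    """Run the full analysis on in-memory trials; no files are touched."""
    if not trials:
        raise ValueError("no trials to analyze")
    spec = WindowSpec(config.window_width, config.window_step)

    rate_matrices = {
        t.trial_id: build_rate_matrix(t.trains, dt=config.dt, delta=config.delta)
        for t in trials
    }

    rank_selection = None
    if "nmf" in config.spaces:
        rank_selection = harmonize_rank(
            [(t.trial_id, rate_matrices[t.trial_id].values) for t in trials],
            threshold=config.vaf_threshold,
            seed=config.seed,
            n_restarts=config.restarts,
        )

    networks: dict = {}
    timecourses: dict = {}
    for trial in trials:
        rm = rate_matrices[trial.trial_id]
        spaces_data = {}
        if "original" in config.spaces:
            spaces_data["original"] = rm
        if "nmf" in config.spaces:
            H = rank_selection.results[trial.trial_id].H
            spaces_data["nmf"] = RateMatrix(list(range(H.shape[0])), rm.grid_t0, rm.dt, H)
        for space, mat in spaces_data.items():
            wins = sliding_windows(mat, spec, rt=trial.rt)
            nets = window_networks(
                wins, space_tag=space, p_max=config.p_max, alpha=config.alpha,
                node_ids=mat.neuron_ids,
            )
            networks[(space, trial.trial_id)] = nets
            if nets:
                timecourses[(space, trial.trial_id)] = metric_timecourse(
                    nets, trial.label, trial_id=trial.trial_id
                )
            else:
                logger.warning("trial %s (%s space): no usable windows", trial.trial_id, space)

    rows = []
    for (space, trial_id), tc in timecourses.items():
        rows.append({
            "trial_id": trial_id,
            "space": space,
            "label": tc.label,
            "cd_peak": peak_window_stats(tc, "cd", config.peak_pre, config.peak_post),
            "eff_peak": peak_window_stats(tc, "eff", config.peak_pre, config.peak_post),
        })
    group_table = pd.DataFrame(rows)

    summary: dict = {"n_trials": len(trials), "spaces": list(config.spaces)}
    if rank_selection is not None:
        summary["animal_rank"] = rank_selection.animal_rank
        summary["mean_vaf_at_animal_rank"] = float(
            np.mean(list(rank_selection.per_trial_vaf_at_animal_rank.values()))
        )
    labels = {t.trial_id: t.label for t in trials}
    for space in config.spaces:
        nets_correct = [n for (s, tid), ns in networks.items() if s == space
                        and labels[tid] == "correct" for n in ns]
        summary[f"mean_edge_weight_{space}"] = _mean_surviving_weight(nets_correct)
        summary[f"mean_connection_weight_{space}"] = _mean_connection_weight_at_peak(
            [ns for (s, tid), ns in networks.items()
             if s == space and labels[tid] == "correct"],
            pre=config.peak_pre, post=config.peak_post,
        )
        tcs_correct = [tc for (s, tid), tc in timecourses.items()
                       if s == space and tc.label == "correct"]
        for metric in ("cd", "eff"):
            if tcs_correct:
                times, means = _group_mean_curve(tcs_correct, metric)
                summary[f"{metric}_peak_time_{space}"] = float(times[int(np.argmax(means))])
            for la, lb in (("correct", "baseline"), ("error", "baseline")):
                col = f"{metric}_peak"
                a = group_table.query("space == @space and label == @la")[col].to_numpy()
                b = group_table.query("space == @space and label == @lb")[col].to_numpy()
                if a.size >= 2 and b.size >= 2:
                    cmp = compare_groups(a, b)
                    summary[f"{metric}_{la}_vs_{lb}_{space}"] = {
                        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                        "statistic": cmp.statistic, "pvalue": cmp.pvalue,
                        "direction": cmp.effect_direction,
                    }

    return AnalysisResult(rate_matrices, rank_selection, networks, timecourses,
                          group_table, summary)


def validate_inputs(spikes_path: str | Path, events_path: str | Path) -> dict:
    """Sanity-check spike and event tables; returns a report with issues."""
    issues: list[str] = []
    spikes = pd.read_csv(spikes_path, sep="\t")
    events = pd.read_csv(events_path, sep="\t")
    need_s = {"trial_id", "neuron_id", "spike_time_s"}
    need_e = {"trial_id", "t_start_s", "t_end_s", "rt_s", "label"}
    if not need_s <= set(spikes.columns):
        issues.append(f"spikes table missing columns {need_s - set(spikes.columns)}")
    if not need_e <= set(events.columns):
        issues.append(f"events table missing columns {need_e - set(events.columns)}")
    if issues:
        return {"issues": issues, "n_trials": 0, "label_counts": {}}

    bad = events.loc[~events["label"].isin(["correct", "error", "baseline"])]
    for line, row in bad.iterrows():
        issues.append(f"events row {line + 2}: unknown label {row['label']!r}")
    for line, row in events.iterrows():
        if not (row["t_start_s"] < row["rt_s"] < row["t_end_s"]):
            issues.append(
                f"trial {row['trial_id']}: RT {row['rt_s']} outside bounds "
                f"({row['t_start_s']}, {row['t_end_s']})"
            )
    bounds = events.set_index("trial_id")[["t_start_s", "t_end_s"]]
    for (tid, nid), grp in spikes.groupby(["trial_id", "neuron_id"]):
        times = grp["spike_time_s"].to_numpy()
        if np.any(np.diff(times) <= 0):
            issues.append(f"trial {tid}, neuron {nid}: spike times not strictly increasing")
        if tid in bounds.index:
            lo, hi = bounds.loc[tid]
            if times.min() < lo or times.max() > hi:
                issues.append(f"trial {tid}, neuron {nid}: spikes outside trial bounds")
        else:
            issues.append(f"trial {tid}: spikes present but no events row")
    return {
        "issues": issues,
        "n_trials": int(len(events)),
        "label_counts": events["label"].value_counts().to_dict(),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based end-to-end run; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stages: list[str] = []

    report = validate_inputs(config.spikes, config.events)
    if report["issues"]:
        raise ValueError("input validation failed: " + "; ".join(report["issues"][:5]))
    stages.append("validate")

    trials = read_dataset(config.spikes, config.events)
    result = analyze_trials(trials, config)
    stages.append("convert")

    rates_dir = out / "rates"
    rates_dir.mkdir(exist_ok=True)
    for tid, rm in result.rate_matrices.items():
        p = rates_dir / f"trial{tid}.tsv"
        sio.write_rate_matrix(rm, p)
        written += [p, p.with_suffix(".json")]

    if result.rank_selection is not None:
        nmf_dir = out / "nmf"
        for tid, res in result.rank_selection.results.items():
            written += sio.write_nmf_result(res, nmf_dir, tid, config.seed)
        stages.append("embed")

    for (space, tid), nets in result.networks.items():
        for k, net in enumerate(nets):
            written += sio.write_network(net, out / "networks" / space, tid, k)
    stages.append("network")

    metrics_path = out / "metrics.tsv"
    result.group_table.to_csv(metrics_path, sep="\t", index=False)
    written.append(metrics_path)
    tc_dir = out / "timecourses"
    tc_dir.mkdir(exist_ok=True)
    for (space, tid), tc in result.timecourses.items():
        p = tc_dir / f"trial{tid}_{space}.tsv"
        pd.DataFrame({"time_rel_rt_s": tc.times, "cd": tc.cd, "eff": tc.eff}).to_csv(
            p, sep="\t", index=False)
        written.append(p)
    stages.append("metrics")

    report_path = out / "report.json"
    report_path.write_text(json.dumps(result.summary, indent=2, default=float))
    written.append(report_path)
    stages.append("report")

    manifest = {
        "stages": stages,
        "parameters": {**asdict(config), "spaces": list(config.spaces)},
        "validation": report,
        "files": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
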