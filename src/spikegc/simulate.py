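"""Synthetic multi-neuron spike datasets with known directed coupling.

Emulates recordings in which a small set of shared non-negative latent
components ("cell assemblies") drives the firing of a larger neuron
population. Latent components follow a rectified first-order
autoregression with directed cross-component coupling; in "correct"
trials the cross-coupling is multiplied by a gain ramp that peaks 0.25 s
before the trial's reference time (RT, the behavioural choice point) —
in "error" and "baseline" trials the gain stays at 1. Neurons spike as
inhomogeneous Poisson processes whose intensity is a non-negative
mixture of the latents plus a baseline rate.

Every stage is deterministic given the configuration seed: a global
``numpy.random.SeedSequence`` is expanded into per-trial / per-purpose /
per-neuron substreams via spawn keys ``(trial_index, purpose[, neuron])``
with purpose 0 = latent innovations, 1 = spike thinning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .rates import SpikeTrain

__all__ = [
    "SimConfig",
    "TrialRecord",
    "SpikeDataset",
    "default_config",
    "simulate_latent_rates",
    "simulate_spike_trains",
    "simulate_var_series",
    "build_dataset",
    "write_dataset",
    "read_dataset",
]

_LATENT, _SPIKES, _SILENCE = 0, 1, 2


@dataclass
class SimConfig:
    """Generative settings for one synthetic 'animal'.

    ``loading_matrix`` (neurons x components, non-negative) maps latent
    component rates to neuron firing intensity; ``component_coupling`` is the
    full latent AR(1) matrix whose diagonal carries self-persistence and
    whose off-diagonal entries carry directed cross-component coupling.
    ``coupling_peak_gain`` multiplies only the off-diagonal entries on a
    piecewise-linear ramp rising over [rt-0.75, rt-0.25] s and decaying back
    to 1 by rt+0.25 s, in correct trials only.
    """

    n_neurons: int
    n_components: int
    trial_duration: float
    rt_time: float
    n_correct: int
    n_error: int
    n_baseline: int
    baseline_rate: float
    loading_matrix: np.ndarray
    component_coupling: np.ndarray
    coupling_peak_gain: float
    noise_sd: float
    sample_dt: float
    seed: int
    latent_mean: float = 4.0  # stationary target of each latent, rate units
    # probability that a neuron is silent for a whole trial (recordings show
    # different neurons active in different trials); off by default
    silence_prob: float = 0.0

    def __post_init__(self):
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        self.component_coupling = np.asarray(self.component_coupling, dtype=float)
        self.validate()

    def validate(self) -> None:
        L, C = self.loading_matrix, self.component_coupling
        if L.shape != (self.n_neurons, self.n_components):
            raise ValueError("loading_matrix must be n_neurons x n_components")
        if C.shape != (self.n_components, self.n_components):
            raise ValueError("component_coupling must be square n_components")
        if np.any(L < 0):
            raise ValueError("loading_matrix entries must be >= 0")
        if np.any(L.sum(axis=1) <= 0):
            raise ValueError("every neuron must load on at least one component")
        if not (0 < self.rt_time < self.trial_duration):
            raise ValueError("require 0 < rt_time < trial_duration")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be positive")
        if not (0 <= self.silence_prob < 1):
            raise ValueError("silence_prob must lie in [0, 1)")
        for name in ("n_correct", "n_error", "n_baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        rho = _peak_spectral_radius(C, self.coupling_peak_gain)
        if rho >= 1:
            raise ValueError(
                f"unstable latent dynamics: spectral radius {rho:.3f} >= 1 at "
                f"coupling_peak_gain={self.coupling_peak_gain}"
            )

    def rng(self, trial_index: int, purpose: int, stream: int = 0) -> np.random.Generator:
        """Deterministic substream for one trial / purpose / extra index."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(trial_index, purpose, stream))
        return np.random.default_rng(ss)


def _peak_spectral_radius(coupling: np.ndarray, gain: float) -> float:
    a = coupling.copy()
    off = ~np.eye(a.shape[0], dtype=bool)
    a[off] *= gain
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-condition defaults: 20 neurons driven by 8 coupled assemblies.

    A hub component (0) drives every other component (coefficient 0.2), and
    a few feed-forward links run between target components (coefficient
    0.15); self-persistence is 0.9. The off-diagonal part is strictly
    triangular (nilpotent), so the spectral radius stays at 0.9 for any
    coupling gain and the network cannot run away during the pre-choice
    ramp. Loadings assign each neuron to one or two components with weights
    drawn once from the seed, giving ~15-40 spikes/s with strong
    assembly-driven modulation on a 3 spikes/s floor.
    """
    n_neurons = overrides.pop("n_neurons", 20)
    n_components = overrides.pop("n_components", 8)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999, 0)))
    L = np.zeros((n_neurons, n_components))
    for i in range(n_neurons):
        k = rng.choice(n_components, size=rng.integers(1, 3), replace=False)
        L[i, k] = rng.uniform(0.8, 2.0, size=k.size)
    C = 0.9 * np.eye(n_components)
    C[1:, 0] = 0.2
    for src, dst in ((1, 2), (3, 4), (5, 6), (1, 7)):
        if max(src, dst) < n_components:
            C[dst, src] = 0.15
    cfg = dict(
        n_neurons=n_neurons,
        n_components=n_components,
        trial_duration=2.0,
        rt_time=1.5,
        n_correct=40,
        n_error=40,
        n_baseline=40,
        baseline_rate=3.0,
        loading_matrix=L,
        component_coupling=C,
        coupling_peak_gain=4.0,
        noise_sd=2.0,
        sample_dt=0.01,
        seed=seed,
        latent_mean=5.0,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def _gain_profile(config: SimConfig, t: np.ndarray) -> np.ndarray:
    """Ramp from 1 to coupling_peak_gain peaking at rt - 0.25 s."""
    g = np.ones_like(t)
    peak_t = config.rt_time - 0.25
    rise_t = config.rt_time - 0.75
    fall_t = config.rt_time + 0.25
    gain = config.coupling_peak_gain
    rising = (t >= rise_t) & (t <= peak_t)
    g[rising] = 1 + (gain - 1) * (t[rising] - rise_t) / max(peak_t - rise_t, 1e-12)
    falling = (t > peak_t) & (t <= fall_t)
    g[falling] = gain + (1 - gain) * (t[falling] - peak_t) / max(fall_t - peak_t, 1e-12)
    return g


def simulate_latent_rates(
    config: SimConfig, trial_kind: str, trial_index: int = 0
) -> np.ndarray:
    """Rectified AR(1) latent component rates, n_components x n_samples.

    In correct trials the off-diagonal coupling is scaled by the gain ramp;
    in error and baseline trials the scale is identically 1.
    """
    if trial_kind not in ("correct", "error", "baseline"):
        raise ValueError(f"unknown trial_kind {trial_kind!r}")
    r = config.n_components
    n = int(np.floor(config.trial_duration / config.sample_dt + 1e-9)) + 1
    t = config.sample_dt * np.arange(n)
    gain = _gain_profile(config, t) if trial_kind == "correct" else np.ones(n)

    diag = np.diag(np.diag(config.component_coupling))
    off = config.component_coupling - diag
    mu = np.full(r, config.latent_mean)

    # autoregression on deviations from the target mean: the coupling (and
    # its gain ramp) propagates fluctuations without shifting the fixed point
    rng = config.rng(trial_index, _LATENT)
    eps = rng.standard_normal((r, n))
    z = np.empty((r, n))
    z[:, 0] = np.maximum(mu, 0.0)
    for k in range(1, n):
        a = diag + gain[k] * off
        z[:, k] = np.maximum(
            0.0, mu + a @ (z[:, k - 1] - mu) + config.noise_sd * eps[:, k]
        )
    return z


def simulate_spike_trains(
    latent: np.ndarray,
    config: SimConfig,
    trial_index: int = 0,
    t_start: float = 0.0,
) -> list[SpikeTrain]:
    """Inhomogeneous Poisson spikes driven by the latent rates.

    Neuron i fires with intensity baseline_rate + loading_matrix[i] . latent(t),
    realized by thinning a homogeneous process at the trial's peak intensity.
    With ``silence_prob > 0`` each neuron is independently silent for the
    whole trial with that probability (off by default).
    """
    if np.any(latent < 0):
        raise ValueError("latent rates must be non-negative")
    n = latent.shape[1]
    duration = config.sample_dt * (n - 1)
    grid = config.sample_dt * np.arange(n)
    intensity = config.baseline_rate + config.loading_matrix @ latent
    assert np.all(intensity >= 0), "intensity must be non-negative by construction"

    silenced = np.zeros(config.n_neurons, dtype=bool)
    if config.silence_prob > 0:
        silenced = (config.rng(trial_index, _SILENCE).uniform(size=config.n_neurons)
                    < config.silence_prob)

    trains = []
    for i in range(config.n_neurons):
        rng = config.rng(trial_index, _SPIKES, i)
        if silenced[i]:
            trains.append(SpikeTrain(i, np.empty(0), t_start, t_start + duration))
            continue
        lam_max = float(intensity[i].max())
        if lam_max <= 0:
            trains.append(SpikeTrain(i, np.empty(0), t_start, t_start + duration))
            continue
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        keep = rng.uniform(0.0, 1.0, size=n_cand) < np.interp(cand, grid, intensity[i]) / lam_max
        times = np.unique(cand[keep])  # thinning can't duplicate, but be safe
        trains.append(SpikeTrain(i, t_start + times, t_start, t_start + duration))
    return trains


def simulate_var_series(
    coeffs: np.ndarray,
    noise_cov: np.ndarray,
    n_samples: int,
    seed: int,
    burn_in: int | None = None,
) -> np.ndarray:
    """Gaussian VAR(p) realization, shape (n_vars, n_samples).

    ``coeffs`` has shape (p, N, N); stability is checked on the companion
    matrix; a burn-in of at least 10*p samples is discarded.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    p, n_vars, _ = coeffs.shape
    companion = np.zeros((n_vars * p, n_vars * p))
    companion[:n_vars] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        companion[n_vars:, :-n_vars] = np.eye(n_vars * (p - 1))
    rho = np.max(np.abs(np.linalg.eigvals(companion)))
    if rho >= 1:
        raise ValueError(f"unstable VAR coefficients: spectral radius {rho:.3f} >= 1")
    noise_cov = np.asarray(noise_cov, dtype=float)
    chol = np.linalg.cholesky(noise_cov)
    if burn_in is None:
        burn_in = max(10 * p, 100)
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    e = chol @ rng.standard_normal((n_vars, total))
    x = np.zeros((n_vars, total))
    for t in range(p, total):
        acc = e[:, t].copy()
        for lag in range(p):
            acc += coeffs[lag] @ x[:, t - lag - 1]
        x[:, t] = acc
    return x[:, burn_in:]


@dataclass
class TrialRecord:
    trial_id: int
    label: str  # correct | error | baseline
    t_start: float
    t_end: float
    rt: float
    trains: list[SpikeTrain] = field(repr=False)


@dataclass
class SpikeDataset:
    trials: list[TrialRecord]
    config_echo: SimConfig

    def __post_init__(self):
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise ValueError("trial ids must be unique")

    def by_label(self, label: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.label == label]


def build_dataset(config: SimConfig) -> SpikeDataset:
    """Simulate all trials of one synthetic animal (correct, error, baseline)."""
    trials = []
    idx = 0
    inter_trial_gap = 1.0
    for label, count in (
        ("correct", config.n_correct),
        ("error", config.n_error),
        ("baseline", config.n_baseline),
    ):
        for _ in range(count):
            t_start = idx * (config.trial_duration + inter_trial_gap)
            latent = simulate_latent_rates(config, label, trial_index=idx)
            trains = simulate_spike_trains(latent, config, trial_index=idx, t_start=t_start)
            trials.append(
                TrialRecord(
                    trial_id=idx,
                    label=label,
                    t_start=t_start,
                    t_end=t_start + config.trial_duration,
                    rt=t_start + config.rt_time,
                    trains=trains,
                )
            )
            idx += 1
    return SpikeDataset(trials, config)


def _spike_table(dataset: SpikeDataset) -> pd.DataFrame:
    rows = []
    for trial in dataset.trials:
        for tr in trial.trains:
            for t in tr.times:
                rows.append((trial.trial_id, tr.neuron_id, t))
    return pd.DataFrame(rows, columns=["trial_id", "neuron_id", "spike_time_s"])


def _events_table(dataset: SpikeDataset) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.trial_id, t.t_start, t.t_end, t.rt, t.label)
            for t in dataset.trials
        ],
        columns=["trial_id", "t_start_s", "t_end_s", "rt_s", "label"],
    )


def write_dataset(dataset: SpikeDataset, out_dir: str | Path) -> dict:
    """Write spikes.tsv, events.tsv and a ground-truth sidecar; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spikes_path = out / "spikes.tsv"
    events_path = out / "events.tsv"
    truth_path = out / "ground_truth.json"
    _spike_table(dataset).to_csv(spikes_path, sep="\t", index=False, float_format="%.9f")
    _events_table(dataset).to_csv(events_path, sep="\t", index=False)
    cfg = asdict(dataset.config_echo)
    cfg["loading_matrix"] = dataset.config_echo.loading_matrix.tolist()
    cfg["component_coupling"] = dataset.config_echo.component_coupling.tolist()
    truth_path.write_text(json.dumps(cfg, indent=2))
    return {"spikes": str(spikes_path), "events": str(events_path), "ground_truth": str(truth_path)}


def read_dataset(spikes_path: str | Path, events_path: str | Path) -> list[TrialRecord]:
    """Load spike + event tables back into per-trial records.

    Neurons present in the dataset but silent in a given trial are included
    as empty trains so the rate matrix keeps a fixed row set across trials.
    """
    spikes = pd.read_csv(spikes_path, sep="\t")
    events = pd.read_csv(events_path, sep="\t")
    all_neurons = sorted(spikes["neuron_id"].unique())
    trials = []
    grouped = dict(iter(spikes.groupby("trial_id")))
    for _, ev in events.iterrows():
        tid = ev["trial_id"]
        sub = grouped.get(tid)
        trains = []
        for nid in all_neurons:
            if sub is not None:
                times = np.sort(sub.loc[sub["neuron_id"] == nid, "spike_time_s"].to_numpy())
            else:
                times = np.empty(0)
            trains.append(SpikeTrain(nid, times, ev["t_start_s"], ev["t_end_s"]))
        trials.append(
            TrialRecord(int(tid), str(ev["label"]), float(ev["t_start_s"]),
                        float(ev["t_end_s"]), float(ev["rt_s"]), trains)
        )
    return trials
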