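"""Text-table writers/readers for pipeline artifacts (TSV + JSON sidecars)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .granger import GCNetwork
from .nmf import NMFResult
from .rates import RateMatrix

__all__ = ["write_rate_matrix", "read_rate_matrix", "write_nmf_result", "write_network"]


def write_rate_matrix(matrix: RateMatrix, path: str | Path, meta: dict | None = None) -> None:
    """TSV with a time column plus one column per neuron; JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix.values.T, columns=[str(c) for c in matrix.neuron_ids])
    df.insert(0, "time_s", matrix.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {"dt": matrix.dt, "grid_t0": matrix.grid_t0,
               "neuron_ids": [str(c) for c in matrix.neuron_ids]}
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_rate_matrix(path: str | Path) -> RateMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return RateMatrix(sidecar["neuron_ids"], sidecar["grid_t0"], sidecar["dt"],
                      df.drop(columns="time_s").to_numpy().T)


def write_nmf_result(res: NMFResult, out_dir: str | Path, trial_id, seed: int) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    w_path = out / f"trial{trial_id}_W.tsv"
    h_path = out / f"trial{trial_id}_H.tsv"
    m_path = out / f"trial{trial_id}_nmf.json"
    np.savetxt(w_path, res.W, delimiter="\t", fmt="%.6f")
    np.savetxt(h_path, res.H, delimiter="\t", fmt="%.6f")
    m_path.write_text(json.dumps({
        "trial_id": str(trial_id), "rank": res.rank, "vaf": res.vaf,
        "n_iter": res.n_iter, "objective": res.objective, "seed": seed,
    }, indent=2))
    return [w_path, h_path, m_path]


def write_network(net: GCNetwork, out_dir: str | Path, trial_id, index: int) -> list[Path]:
    """Pruned adjacency as TSV (rows = targets, columns = sources) + metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a_path = out / f"trial{trial_id}_win{index:03d}.tsv"
    m_path = out / f"trial{trial_id}_win{index:03d}.json"
    np.savetxt(a_path, net.F, delimiter="\t", fmt="%.6g")
    m_path.write_text(json.dumps({
        "trial_id": str(trial_id),
        "window_center_rel_rt_s": net.window_center,
        "space": net.space_tag,
        "order": net.order,
        "t_eff": net.t_eff,
        "usable": net.usable,
        "orientation": "entry [i][j] is the causality from source j to target i",
    }, indent=2))
    return [a_path, m_path]
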