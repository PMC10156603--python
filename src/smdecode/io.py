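"""Plain-text dataset I/O: trace TSV + JSON sidecar + ground-truth TSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from smdecode.simulate import GroundTruth, SimulationConfig, TraceDataset
from smdecode.trace_processing import FluorescenceTrace

__all__ = ["save_dataset", "load_dataset"]


def save_dataset(dataset: TraceDataset, out_dir: str | Path) -> Path:
    """Write a dataset as traces.tsv + meta.json (+ ground_truth.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.to_frame().to_csv(out / "traces.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "meta.json").write_text(json.dumps(dataset.metadata(), indent=2, default=float))
    if dataset.truths:
        rows = []
        for tr in dataset.truths:
            for state, t0, t1 in tr.events:
                rows.append((tr.trace_id, state, t0, t1))
        pd.DataFrame(rows, columns=["trace_id", "state", "t_enter_s", "t_exit_s"]).to_csv(
            out / "ground_truth.tsv", sep="\t", index=False, float_format="%.6g"
        )
    return out


def load_dataset(in_dir: str | Path) -> TraceDataset:
    """Load a dataset written by :func:`save_dataset` (truth not reloaded)."""
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    config = SimulationConfig(**meta["config"])
    df = pd.read_csv(src / "traces.tsv", sep="\t")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("frame")
        traces.append(
            FluorescenceTrace(
                trace_id=str(tid),
                frame_interval=config.frame_interval,
                donor=grp["donor"].to_numpy(),
                acceptor=grp["acceptor"].to_numpy(),
                corrected=False,
                meta={"alpha": config.crosstalk_alpha, "gamma": config.gamma},
            )
        )
    return TraceDataset(
        traces=traces,
        truths=[],
        config=config,
        model_name=meta.get("model_name", ""),
        concentration=float(meta.get("concentration_uM", 0.0)),
    )
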