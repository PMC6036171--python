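"""Plain-text readers/writers for the pipeline's on-disk formats.

Everything is text: catalogs and events as TSV, matrices as TSV with a
JSON sidecar (subject, modality, trial order), skin-conductance traces as
single-column text with a sampling-rate header, ground truth and reports
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import TrialDesign
from .lss import BetaSeries

__all__ = ["write_events", "read_events", "write_betas", "read_betas",
           "write_scr_trace", "read_scr_trace", "write_json", "read_json"]


def write_events(design: TrialDesign, path) -> None:
    path = Path(path)
    design.events.to_csv(path, sep="\t", index=False)
    meta = {"tr": design.tr, "run_length_s": design.run_length_s,
            "report": design.report}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_events(path) -> TrialDesign:
    path = Path(path)
    events = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    return TrialDesign(events=events, tr=meta["tr"],
                       run_length_s=meta["run_length_s"],
                       report=meta.get("report", {}))


def write_betas(betas: BetaSeries, path) -> None:
    path = Path(path)
    np.savetxt(path, betas.data, delimiter="\t")
    sidecar = {"subject": betas.subject, "modality": betas.modality,
               "stimulus_ids": [int(s) if isinstance(s, (int, np.integer))
                                else str(s) for s in betas.stimulus_ids]}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_betas(path) -> BetaSeries:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return BetaSeries(data=data, modality=sidecar["modality"],
                      stimulus_ids=np.asarray(sidecar["stimulus_ids"]),
                      subject=sidecar["subject"])


def write_scr_trace(trace: np.ndarray, fs: float, path) -> None:
    header = f"sampling_rate_hz: {fs}"
    np.savetxt(path, np.asarray(trace, float), header=header, comments="# ")


def read_scr_trace(path) -> tuple[np.ndarray, float]:
    first = Path(path).read_text().splitlines()[0]
    if "sampling_rate_hz" not in first:
        raise ValueError("SCR trace lacks a sampling-rate header")
    fs = float(first.split(":")[1])
    return np.loadtxt(path, comments="#"), fs


def write_json(obj: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, default=_default))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
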