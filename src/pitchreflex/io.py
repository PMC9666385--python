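"""Reading and writing trace datasets, configs and result summaries.

Trace data travels as a long-format delimited table with one row per
(subject, trial, time) sample and commented metadata lines up front:

    # units: hz
    # dt_ms: 5
    subject,trial,perturbed,direction,onset_ms,time_ms,f0

Units are declared, never guessed: ``hz`` rows carry absolute f_o,
``deviation`` rows carry fractional deviation from baseline.  Times are
stored in milliseconds (relative to trial start for raw data), matching
the axis convention of perturbation-experiment figures; internal code
works in seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import StudyDesign, SubjectTruth, Trial
from .models import ControllerParams

__all__ = [
    "write_trials",
    "read_trials",
    "write_truths",
    "read_truths",
    "load_config",
]

_COLUMNS = ["subject", "trial", "perturbed", "direction", "onset_ms", "time_ms", "f0"]


def write_trials(path, dataset: dict[str, list[Trial]], units: str = "hz") -> None:
    """Write a cohort of raw trials as a long-format CSV."""
    path = Path(path)
    frames = []
    for subject, trials in dataset.items():
        for k, tr in enumerate(trials):
            t_ms = np.round(np.arange(tr.f0_hz.size) * tr.dt * 1000.0, 6)
            frames.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "trial": k,
                        "perturbed": int(tr.perturbed),
                        "direction": tr.direction,
                        "onset_ms": round(tr.onset_s * 1000.0, 6),
                        "time_ms": t_ms,
                        "f0": tr.f0_hz,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    dt_ms = next(iter(dataset.values()))[0].dt * 1000.0
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n# dt_ms: {dt_ms:g}\n")
        table.to_csv(fh, index=False, float_format="%.8g")


def read_trials(path) -> tuple[dict[str, list[Trial]], str]:
    """Read a long-format trial table; returns (dataset, units)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        table = pd.read_csv(fh)
    if "units" not in meta:
        raise ValueError("missing '# units:' header; units are never guessed")
    units = meta["units"]
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    dataset: dict[str, list[Trial]] = {}
    dts = set()
    for (subject, trial), g in table.groupby(["subject", "trial"], sort=True):
        t = g["time_ms"].to_numpy() / 1000.0
        if t.size < 2:
            raise ValueError(f"trial {subject}/{trial} has fewer than 2 samples")
        dt = float(np.round(np.median(np.diff(t)), 9))
        dts.add(dt)
        if len(dts) > 1:
            raise ValueError(f"mixed sampling steps in file: {sorted(dts)}")
        dataset.setdefault(str(subject), []).append(
            Trial(
                f0_hz=g["f0"].to_numpy(dtype=float),
                dt=dt,
                onset_s=float(g["onset_ms"].iloc[0]) / 1000.0,
                direction=int(g["direction"].iloc[0]),
                perturbed=bool(g["perturbed"].iloc[0]),
            )
        )
    return dataset, units


def write_truths(path, truths: dict[str, SubjectTruth]) -> None:
    """Ground-truth sidecar JSON for a synthetic cohort."""
    payload = {
        subject: {
            "model": tr.model,
            "params": tr.params.as_dict(),
            "f_T": tr.f_T,
            "noise_sd": tr.noise_sd,
            "noise_ar1": tr.noise_ar1,
            "baseline_drift_sd": tr.baseline_drift_sd,
        }
        for subject, tr in truths.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truths(path) -> dict[str, SubjectTruth]:
    payload = json.loads(Path(path).read_text())
    return {
        subject: SubjectTruth(
            model=d["model"],
            params=ControllerParams.from_dict(d["params"]),
            f_T=d["f_T"],
            noise_sd=d["noise_sd"],
            noise_ar1=d["noise_ar1"],
            baseline_drift_sd=d["baseline_drift_sd"],
        )
        for subject, d in payload.items()
    }


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)
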