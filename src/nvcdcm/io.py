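"""Plain-text readers and writers for the pipeline's interchange formats.

Events travel as BIDS-style TSV (onset, duration, condition); numeric
matrices as comma-separated CSV with a JSON sidecar carrying the sampling
metadata; inversion results as JSON.  Every writer's output is readable by
its paired reader with a bit-identical payload (floats are serialised with
repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .drives import DriveSignal, EventSchedule
from .errors import ValidationError
from .inference import GaussianDensity, InversionResult


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def write_events_tsv(path, schedule: EventSchedule,
                     duration_value: float = 0.0) -> None:
    rows = []
    for c in schedule.condition_names:
        for t in schedule.onsets[c]:
            rows.append((t, duration_value, c))
    df = pd.DataFrame(sorted(rows), columns=["onset", "duration", "condition"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path, duration: float, tr: float,
                    dt: float = 0.1) -> EventSchedule:
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "condition"}
    if not required.issubset(df.columns):
        raise ValidationError(f"events file must have columns {sorted(required)}")
    names = tuple(dict.fromkeys(df["condition"].astype(str)))
    onsets = {c: df.loc[df["condition"] == c, "onset"].to_numpy(float)
              for c in names}
    return EventSchedule(names, onsets, duration=duration, tr=tr, dt=dt)


# ---------------------------------------------------------------------------
# numeric matrices
# ---------------------------------------------------------------------------

def write_matrix_csv(path, matrix: np.ndarray, columns=None) -> None:
    matrix = np.asarray(matrix)
    if columns is None:
        columns = [f"c{i}" for i in range(matrix.shape[1])]
    pd.DataFrame(matrix, columns=list(columns)).to_csv(path, index=False)


def read_matrix_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    return df.to_numpy(float), list(df.columns)


def write_bold_csv(path, bold: np.ndarray, tr: float, region_names) -> None:
    """Long-format region series: time, region, value."""
    n_scans, R = bold.shape
    times = np.arange(n_scans) * tr
    rows = []
    for r, name in enumerate(region_names):
        for i in range(n_scans):
            rows.append((times[i], name, bold[i, r]))
    pd.DataFrame(rows, columns=["time", "region", "value"]).to_csv(path, index=False)


def read_bold_csv(path) -> tuple[np.ndarray, list[str], float]:
    df = pd.read_csv(path)
    regions = list(dict.fromkeys(df["region"].astype(str)))
    times = np.sort(df["time"].unique())
    bold = np.column_stack([
        df[df["region"] == r].sort_values("time")["value"].to_numpy(float)
        for r in regions
    ])
    tr = float(times[1] - times[0]) if len(times) > 1 else 0.0
    return bold, regions, tr


def write_drives_csv(path, z: np.ndarray, dt: float, region_names,
                     channel_names) -> None:
    """Long-format drive series: time, region, channel, value."""
    R, C, T = z.shape
    times = np.arange(T) * dt
    frames = []
    for r, rname in enumerate(region_names):
        for c, cname in enumerate(channel_names):
            frames.append(pd.DataFrame({
                "time": times, "region": rname, "channel": cname,
                "value": z[r, c],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_trajectory_csv(path, times: np.ndarray, V: np.ndarray,
                         region_names, population_labels) -> None:
    """Long-format ERP trajectory: time, region, population, V."""
    frames = []
    for r, rname in enumerate(region_names):
        for p, pname in enumerate(population_labels):
            frames.append(pd.DataFrame({
                "time": times, "region": rname, "population": pname,
                "V": V[:, r, p],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# inversion results
# ---------------------------------------------------------------------------

def inversion_to_dict(result: InversionResult) -> dict:
    return {
        "posterior_mean": result.posterior.mean.tolist(),
        "posterior_cov": result.posterior.cov.tolist(),
        "labels": result.posterior.labels,
        "free_energy": result.free_energy,
        "trace": list(result.trace),
        "noise_log_precision": (None if result.noise_log_precision is None
                                else result.noise_log_precision.tolist()),
        "converged": result.converged,
        "n_data": result.n_data,
    }


def write_inversion_json(path, result: InversionResult, extra: dict | None = None):
    payload = inversion_to_dict(result)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_inversion_json(path) -> InversionResult:
    d = json.loads(Path(path).read_text())
    post = GaussianDensity(np.array(d["posterior_mean"]),
                           np.array(d["posterior_cov"]), labels=d["labels"])
    lam = d.get("noise_log_precision")
    return InversionResult(
        posterior=post, free_energy=d["free_energy"], trace=d["trace"],
        noise_log_precision=None if lam is None else np.array(lam),
        converged=d["converged"], n_data=d["n_data"],
    )


def write_comparison_csv(path, names, free_energies, probabilities) -> None:
    pd.DataFrame({
        "model": list(names),
        "free_energy": np.asarray(free_energies, float),
        "probability": np.asarray(probabilities, float),
    }).to_csv(path, index=False)
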