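"""Reading and writing the package's on-disk formats.

Tidy trace tables (CSV/TSV, one row per punctum per time point), FRAP
tables (bleached + reference series with pre-bleach rows at t < 0),
multi-frame TIFF image stacks, and ground-truth sidecar JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import NeuronRecord, PunctumTrace, TraceStatus
from .errors import SchemaError
from .frap import FRAPRecord
from .synthkit import GroundTruth, ImageStack

__all__ = [
    "write_trace_table",
    "read_trace_table",
    "write_frap_table",
    "read_frap_table",
    "write_image_stack",
    "read_image_stack",
    "write_ground_truth",
    "read_ground_truth",
]

TRACE_COLUMNS = ["experiment", "neuron", "punctum", "t_min", "fluorescence", "status"]
_VALID_STATUS = {s.value for s in TraceStatus}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def write_trace_table(records: list[NeuronRecord], path) -> Path:
    """Write neuron records as a tidy CSV/TSV trace table."""
    path = Path(path)
    rows = []
    for rec in records:
        for tr in rec.traces:
            for t, f in zip(tr.t, tr.F):
                rows.append(
                    {
                        "experiment": rec.experiment_id,
                        "neuron": rec.neuron_id,
                        "punctum": tr.punctum_id,
                        "t_min": t,
                        "fluorescence": f,
                        "status": tr.status.value,
                        "genotype": rec.genotype,
                        "condition": rec.condition,
                        "loss_time": tr.loss_time if tr.loss_time is not None else "",
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_trace_table(path) -> list[NeuronRecord]:
    """Read a tidy trace table back into neuron records.

    Schema violations (missing columns, non-numeric values, unknown status
    flags, non-increasing times) raise :class:`SchemaError` with offending
    row numbers where applicable.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input table")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: table has no data rows")

    bad = df.index[pd.to_numeric(df["t_min"], errors="coerce").isna()].tolist()
    bad += df.index[pd.to_numeric(df["fluorescence"], errors="coerce").isna()].tolist()
    if bad:
        raise SchemaError(f"{path}: non-numeric t_min/fluorescence", rows=sorted(set(bad)))
    bad = df.index[~df["status"].isin(_VALID_STATUS)].tolist()
    if bad:
        raise SchemaError(
            f"{path}: unknown status flags (expected one of {sorted(_VALID_STATUS)})", rows=bad
        )
    df["t_min"] = df["t_min"].astype(float)
    df["fluorescence"] = df["fluorescence"].astype(float)

    records = []
    for (exp, neuron), nd in df.groupby(["experiment", "neuron"], sort=False):
        rec = NeuronRecord(
            neuron_id=str(neuron),
            experiment_id=str(exp),
            genotype=str(nd["genotype"].iloc[0]) if "genotype" in nd else "",
            condition=str(nd["condition"].iloc[0]) if "condition" in nd and pd.notna(nd["condition"].iloc[0]) else "",
        )
        for pid, pdx in nd.groupby("punctum", sort=False):
            pdx = pdx.sort_values("t_min")
            if pdx["t_min"].duplicated().any():
                raise SchemaError(
                    f"{path}: duplicated time points for punctum {pid} of neuron {neuron}",
                    rows=pdx.index[pdx["t_min"].duplicated()].tolist(),
                )
            status = TraceStatus(pdx["status"].iloc[0])
            loss_time = None
            if status is TraceStatus.LOST:
                lt = pdx["loss_time"].iloc[0] if "loss_time" in pdx else np.nan
                loss_time = float(lt) if pd.notna(lt) and lt != "" else float(pdx["t_min"].iloc[-1])
            rec.traces.append(
                PunctumTrace(
                    punctum_id=str(pid),
                    t=pdx["t_min"].to_numpy(),
                    F=np.clip(pdx["fluorescence"].to_numpy(), 0.0, None),
                    status=status,
                    loss_time=loss_time,
                )
            )
        if rec.traces and len(rec.traces[0]) > 1:
            rec.dt_min = float(rec.traces[0].t[1] - rec.traces[0].t[0])
        records.append(rec)
    return records


def write_frap_table(record: FRAPRecord, path, n_prebleach: int = 3) -> Path:
    """Write one FRAP experiment as a long-format table.

    Pre-bleach baseline rows carry negative times; the bleached punctum has
    role ``bleached`` and each reference punctum role ``reference``.
    """
    path = Path(path)
    rows = []
    for k in range(n_prebleach, 0, -1):
        rows.append(
            {"punctum": record.punctum_id, "role": "bleached", "t_min": -5.0 * k,
             "fluorescence": record.F0}
        )
    for t, f in zip(record.t, record.F_t):
        rows.append({"punctum": record.punctum_id, "role": "bleached", "t_min": t, "fluorescence": f})
    for i in range(record.n_reference):
        pid = f"ref{i}"
        for k in range(n_prebleach, 0, -1):
            rows.append(
                {"punctum": pid, "role": "reference", "t_min": -5.0 * k,
                 "fluorescence": record.F_nb[i, 0]}
            )
        for t, f in zip(record.t, record.F_nb[i]):
            rows.append({"punctum": pid, "role": "reference", "t_min": t, "fluorescence": f})
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_frap_table(path) -> FRAPRecord:
    """Read a long-format FRAP table into a :class:`FRAPRecord`.

    The pre-bleach fluorescence ``F0`` is the mean of the bleached
    punctum's t < 0 rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input table")
    required = ["punctum", "role", "t_min", "fluorescence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: table has no data rows")
    bad = df.index[~df["role"].isin(["bleached", "reference"])].tolist()
    if bad:
        raise SchemaError(f"{path}: role must be 'bleached' or 'reference'", rows=bad)
    df["t_min"] = pd.to_numeric(df["t_min"], errors="coerce")
    df["fluorescence"] = pd.to_numeric(df["fluorescence"], errors="coerce")
    bad = df.index[df[["t_min", "fluorescence"]].isna().any(axis=1)].tolist()
    if bad:
        raise SchemaError(f"{path}: non-numeric t_min/fluorescence", rows=bad)

    bl = df[df["role"] == "bleached"].sort_values("t_min")
    pre = bl[bl["t_min"] < 0]
    post = bl[bl["t_min"] >= 0]
    if pre.empty:
        raise SchemaError(f"{path}: no pre-bleach (t < 0) rows for the bleached punctum")
    if post.empty:
        raise SchemaError(f"{path}: no post-bleach rows for the bleached punctum")
    t = post["t_min"].to_numpy()
    refs = df[(df["role"] == "reference") & (df["t_min"] >= 0)]
    if refs.empty:
        raise SchemaError(f"{path}: no reference punctum rows")
    mats = []
    for pid, rdx in refs.groupby("punctum", sort=False):
        rdx = rdx.sort_values("t_min")
        if not np.array_equal(rdx["t_min"].to_numpy(), t):
            raise SchemaError(
                f"{path}: reference punctum {pid} does not share the bleached time base"
            )
        mats.append(rdx["fluorescence"].to_numpy())
    return FRAPRecord(
        F0=float(pre["fluorescence"].mean()),
        t=t,
        F_t=post["fluorescence"].to_numpy(),
        F_nb=np.vstack(mats),
        punctum_id=str(bl["punctum"].iloc[0]),
    )


def write_image_stack(stack: ImageStack, path) -> Path:
    """Write a stack as multi-frame 32-bit float TIFF with minimal metadata."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        metadata={
            "frame_times_min": list(map(float, stack.frame_times)),
            "psf_sd": stack.psf_sd,
            "background": stack.background,
        },
    )
    return path


def read_image_stack(path, frame_times=None, psf_sd: float = 1.5, background: float = 0.0) -> ImageStack:
    """Read a multi-frame TIFF into an :class:`ImageStack`.

    Metadata written by :func:`write_image_stack` is recovered when
    present; otherwise the keyword arguments supply it.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray().astype(float)
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if frame_times is None:
        frame_times = meta.get("frame_times_min")
    if frame_times is None:
        frame_times = np.arange(frames.shape[0], dtype=float)
    return ImageStack(
        frames=frames,
        frame_times=np.asarray(frame_times, float),
        psf_sd=float(meta.get("psf_sd", psf_sd)),
        background=float(meta.get("background", background)),
    )


def write_ground_truth(truth: GroundTruth, path) -> Path:
    """Serialise ground truth (setpoints, loss times, positions) as JSON."""
    path = Path(path)
    payload = {
        "seed": truth.seed,
        "setpoints": [s.tolist() for s in truth.setpoints],
        "loss_times": [
            [None if not np.isfinite(v) else float(v) for v in lt] for lt in truth.loss_times
        ],
        "positions": truth.positions.tolist() if truth.positions is not None else None,
    }
    path.write_text(json.dumps(payload))
    return path


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        setpoints=[np.asarray(s, float) for s in payload["setpoints"]],
        loss_times=[
            np.array([np.nan if v is None else v for v in lt], dtype=float)
            for lt in payload["loss_times"]
        ],
        positions=None if payload["positions"] is None else np.asarray(payload["positions"], float),
        seed=payload.get("seed"),
    )
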