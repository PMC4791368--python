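"""TSV I/O for matrices, cohort manifests and per-subject files.

All on-disk formats are plain tab-separated text: time series as
volume x ROI tables with an ROI-label header, motion traces with the six
parameter names, square matrices with matching label header row and index
column, graphs additionally as (node_i, node_j, weight) edge lists.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import WeightedGraph
from .preprocess import MotionTrace, SubjectTimeSeries
from .synthetic import CohortSpec, SubjectRecord

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_timeseries",
    "write_timeseries",
    "read_motion",
    "write_motion",
    "write_graph_edges",
    "write_cohort",
    "read_cohort",
]

_MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
_NUIS_COLS = ["global", "wm", "csf"]


def _read_tsv(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row {i + 1} has {len(row)} fields, expected {width}"
            )
    header = rows[0]
    body = rows[1:]
    if index_col is not None:
        index = [r[index_col] for r in body]
        data_cols = [j for j in range(width) if j != index_col]
        columns = [header[j] for j in data_cols]
        cells = [[r[j] for j in data_cols] for r in body]
    else:
        index = list(range(len(body)))
        columns = header
        cells = body
    values = np.empty((len(body), len(columns)))
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {i + 2}, column "
                    f"{columns[j]!r}: {cell!r}"
                ) from None
    return pd.DataFrame(values, index=index, columns=columns)


def read_matrix(path: str | Path, labels: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Square labelled matrix; reordered to ``labels`` (with a warning) if given."""
    df = _read_tsv(path, index_col=0)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ValueError(f"{path}: matrix must be square with matching labels")
    if labels is not None and list(df.index) != list(labels):
        if sorted(df.index) != sorted(labels):
            raise ValueError(f"{path}: labels do not match the manifest set")
        import warnings

        warnings.warn(f"{path}: reordering labels to manifest order", stacklevel=2)
        df = df.loc[labels, labels]
    return df.to_numpy(), list(df.index)


def write_matrix(matrix: np.ndarray, path: str | Path, labels: list[str]) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="roi")


def write_timeseries(ts: SubjectTimeSeries, path: str | Path, labels: list[str]) -> None:
    # volumes as rows, ROIs as columns
    pd.DataFrame(ts.values.T, columns=labels).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_timeseries(path: str | Path, tr: float) -> SubjectTimeSeries:
    df = _read_tsv(path)
    return SubjectTimeSeries(df.to_numpy().T, tr)


def write_motion(motion: MotionTrace, path: str | Path) -> None:
    data = np.hstack([motion.translations, motion.rotations])
    pd.DataFrame(data, columns=_MOTION_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_motion(path: str | Path) -> MotionTrace:
    df = _read_tsv(path)
    if list(df.columns) != _MOTION_COLS:
        raise ValueError(f"{path}: expected columns {_MOTION_COLS}")
    arr = df.to_numpy()
    return MotionTrace(arr[:, :3], arr[:, 3:])


def write_graph_edges(g: WeightedGraph, path: str | Path) -> None:
    u, v, w = g.edge_list()
    labels = g.labels or tuple(f"roi{i + 1:02d}" for i in range(g.n_nodes))
    df = pd.DataFrame(
        {
            "node_i": [labels[i] for i in u],
            "node_j": [labels[j] for j in v],
            "weight": w,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def roi_labels(n: int) -> list[str]:
    return [f"roi{i + 1:02d}" for i in range(n)]


def write_cohort(records: list[SubjectRecord], spec: CohortSpec, out_dir: str | Path) -> Path:
    """One TSV per subject per modality plus a manifest and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = roi_labels(spec.n_rois)
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "subject_id": rec.subject_id,
            "group": rec.group_label,
            "ahrs_total": "" if rec.ahrs_total is None else f"{rec.ahrs_total:.6g}",
        }
        if rec.timeseries is not None:
            ts_path = out / f"{rec.subject_id}_timeseries.tsv"
            write_timeseries(rec.timeseries, ts_path, labels)
            row["timeseries_path"] = ts_path.name
            motion_path = out / f"{rec.subject_id}_motion.tsv"
            write_motion(rec.motion, motion_path)
            row["motion_path"] = motion_path.name
            nuis_path = out / f"{rec.subject_id}_nuisance.tsv"
            pd.DataFrame(rec.nuisance_signals, columns=_NUIS_COLS).to_csv(
                nuis_path, sep="\t", index=False, float_format="%.17g"
            )
            row["nuisance_path"] = nuis_path.name
        if rec.fiber_counts is not None:
            fn_path = out / f"{rec.subject_id}_fibercounts.tsv"
            write_matrix(rec.fiber_counts, fn_path, labels)
            row["fiber_path"] = fn_path.name
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    cfg = {
        k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
        for k, v in vars(spec).items()
    }
    with open(out / "cohort_spec.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out / "manifest.tsv"


def read_cohort(manifest_path: str | Path) -> tuple[list[SubjectRecord], CohortSpec]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(base / "cohort_spec.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["group_sizes"] = tuple(raw["group_sizes"])
    spec = CohortSpec(**raw)
    df = pd.read_csv(manifest_path, sep="\t", dtype={"subject_id": str})
    records = []
    for _, row in df.iterrows():
        ahrs = row.get("ahrs_total")
        ahrs = None if pd.isna(ahrs) else float(ahrs)
        rec = SubjectRecord(
            subject_id=row["subject_id"],
            group_label=row["group"],
            ahrs_total=ahrs,
        )
        if "timeseries_path" in df.columns and isinstance(row.get("timeseries_path"), str):
            rec.timeseries = read_timeseries(base / row["timeseries_path"], spec.tr)
            rec.motion = read_motion(base / row["motion_path"])
            rec.nuisance_signals = _read_tsv(base / row["nuisance_path"]).to_numpy()
        if "fiber_path" in df.columns and isinstance(row.get("fiber_path"), str):
            fn, _ = read_matrix(base / row["fiber_path"])
            rec.fiber_counts = fn.astype(int)
        records.append(rec)
    return records, spec
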