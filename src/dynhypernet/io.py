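"""Plain-text file formats for cohorts, hypernetworks and derived tables.

The pipeline starts from component time series; imaging formats are a
preprocessing prerequisite and are deliberately not handled here.  Formats:

* subject time series — TSV, T rows x N columns, optional single header row;
* cohort manifest — CSV with header ``subject_id,path,group`` (paths are
  resolved relative to the manifest's directory);
* hyperedge list — ``#nodes=<M>`` header, then one line per hyperedge:
  ``<seed>\t<lambda1>\t<comma-separated node ids>``;
* metric tables / kernels — TSV with id headers;
* reports — JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynconn import SubjectTimeSeries
from .hypernet import Hyperedge, Hypernetwork
from .hypermetrics import METRIC_NAMES, NodeMetricTable

__all__ = [
    "read_time_series",
    "read_cohort",
    "write_cohort",
    "read_hypernetwork",
    "write_hypernetwork",
    "write_metric_table",
    "write_kernel",
    "write_report",
]


class CohortParseError(ValueError):
    """Malformed manifest or subject file."""


def read_time_series(path: str | Path) -> np.ndarray:
    """Read a T x N TSV signal matrix; a single non-numeric first row is
    treated as an optional header."""
    path = Path(path)
    if not path.exists():
        raise CohortParseError(f"time-series file not found: {path}")
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    has_header = first.iloc[0].map(_is_not_number).any()
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    try:
        data = df.to_numpy(dtype=float)
    except ValueError as exc:
        bad = _first_non_numeric(df)
        raise CohortParseError(
            f"{path}: non-numeric cell at row {bad[0]}, column {bad[1]}"
        ) from exc
    return data


def _is_not_number(v) -> bool:
    try:
        float(v)
        return False
    except (TypeError, ValueError):
        return True


def _first_non_numeric(df: pd.DataFrame) -> tuple[int, int]:
    for i, row in df.iterrows():
        for j, v in enumerate(row):
            if _is_not_number(v):
                return int(i), int(j)
    return -1, -1


def read_cohort(manifest_path: str | Path) -> list[SubjectTimeSeries]:
    """Read subjects in manifest order, validating a common component count."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    subjects: list[SubjectTimeSeries] = []
    seen_ids: set[str] = set()
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "path", "group"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise CohortParseError(
                f"manifest must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            sid = row["subject_id"].strip()
            if sid in seen_ids:
                raise CohortParseError(f"duplicate subject id {sid!r}")
            seen_ids.add(sid)
            p = Path(row["path"])
            data = read_time_series(p if p.is_absolute() else base / p)
            subjects.append(
                SubjectTimeSeries(subject_id=sid, group=row["group"].strip(), data=data)
            )
    if not subjects:
        raise CohortParseError("manifest lists no subjects")
    n0 = subjects[0].n_components
    for s in subjects[1:]:
        if s.n_components != n0:
            raise CohortParseError(
                f"component count mismatch: {subjects[0].subject_id} has {n0} "
                f"but {s.subject_id} has {s.n_components}"
            )
    return subjects


def write_cohort(
    subjects: list[SubjectTimeSeries], out_dir: str | Path, header: bool = False
) -> Path:
    """Write per-subject TSVs plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "path", "group"])
        for s in subjects:
            fname = f"{s.subject_id}.tsv"
            df = pd.DataFrame(
                s.data,
                columns=[f"c{i}" for i in range(s.n_components)] if header else None,
            )
            df.to_csv(out_dir / fname, sep="\t", index=False, header=header)
            w.writerow([s.subject_id, fname, s.group])
    return manifest


def write_hypernetwork(H: Hypernetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#nodes={H.node_count}\n")
        for e in H.hyperedges:
            ids = ",".join(str(v) for v in sorted(e.nodes))
            fh.write(f"{e.seed}\t{e.lambda1:g}\t{ids}\n")


def read_hypernetwork(path: str | Path, subject_id: str = "") -> Hypernetwork:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#nodes="):
            raise CohortParseError(f"{path}: missing '#nodes=' header")
        node_count = int(header.split("=", 1)[1])
        edges = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            seed_s, lam_s, ids_s = line.split("\t")
            nodes = frozenset(int(v) for v in ids_s.split(","))
            edges.append(
                Hyperedge(nodes=nodes, seed=int(seed_s), lambda1=float(lam_s))
            )
    return Hypernetwork(node_count=node_count, hyperedges=edges, subject_id=subject_id)


def write_metric_table(
    table: NodeMetricTable, node_labels: list[str], path: str | Path
) -> None:
    df = pd.DataFrame(table.values, columns=list(METRIC_NAMES))
    df.insert(0, "connection", node_labels)
    df.to_csv(path, sep="\t", index=False)


def write_kernel(K: np.ndarray, subject_ids: list[str], path: str | Path) -> None:
    df = pd.DataFrame(K, index=subject_ids, columns=subject_ids)
    df.to_csv(path, sep="\t")


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
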