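"""Flat-file I/O contracts: diff-able TSVs with ``#`` metadata headers.

Every output carries provenance (seed, config hash, stage) as
``# key = value`` comment lines above the header row, so any stage can be
rerun in isolation and outputs can be compared byte-for-byte.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import COHORT_COLUMNS, MeasureMatrix

NA_VALUES = ["NA", "", "nan", "NaN"]

MANDATORY_COHORT_COLUMNS = ["subject_id", "group", "sex", "age", "schedule"]


class CohortFormatError(ValueError):
    """Raised when a cohort table violates the documented contract."""


def _meta_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k} = {v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep="NA", lineterminator="\n")
    path.write_text(_meta_lines(meta) + buf.getvalue())


def read_table(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t", na_values=NA_VALUES,
                         keep_default_na=False)
    return df, meta


def write_cohort(cohort: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(cohort, path, meta)


def load_cohort(path) -> pd.DataFrame:
    """Read a cohort table, enforcing the documented column contract.

    Mandatory columns: subject_id, group, sex, age, schedule. Unknown
    columns are preserved; "NA", "" and "nan" parse to null; duplicate
    subject ids are an error.
    """
    df, _ = read_table(path)
    missing = [c for c in MANDATORY_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing mandatory column(s): {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortFormatError(f"duplicate subject_id: {dupes[:5]}")
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    for col in df.columns:
        if col not in MANDATORY_COHORT_COLUMNS and col not in ("site",):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                pass  # leave non-numeric extras as-is
    # canonical column order first, extras preserved after
    known = [c for c in COHORT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in known]
    return df[known + extra]


def write_matrix(values: np.ndarray, path, vertex_ids=None,
                 meta: dict | None = None, float_fmt: str = "%.6g") -> None:
    """Subjects x vertices matrix as TSV with a vertex-id header row."""
    values = np.atleast_2d(np.asarray(values))
    if vertex_ids is None:
        vertex_ids = np.arange(values.shape[1])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("\t".join(f"v{int(v)}" for v in vertex_ids) + "\n")
        np.savetxt(fh, values, fmt=float_fmt, delimiter="\t")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray, dict]:
    df, meta = read_table(path)
    vertex_ids = np.array([int(c.lstrip("v")) for c in df.columns])
    return df.to_numpy(dtype=float), vertex_ids, meta


def write_measure_matrix(matrix: MeasureMatrix, path,
                         meta: dict | None = None) -> None:
    meta = dict(meta or {})
    meta.setdefault("measure", matrix.measure)
    write_matrix(matrix.values, path, matrix.vertex_ids, meta)


def read_measure_matrix(path) -> MeasureMatrix:
    values, vertex_ids, meta = read_matrix(path)
    return MeasureMatrix(values=values, vertex_ids=vertex_ids,
                         measure=meta.get("measure", "thickness"))


def write_parcellation(region_of_vertex: np.ndarray, path,
                       meta: dict | None = None) -> None:
    df = pd.DataFrame({"vertex": np.arange(len(region_of_vertex)),
                       "region": np.asarray(region_of_vertex, dtype=int)})
    write_table(df, path, meta)


def read_parcellation(path) -> np.ndarray:
    df, _ = read_table(path)
    df = df.sort_values("vertex")
    return df["region"].to_numpy(dtype=int)
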