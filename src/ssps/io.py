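"""Delimited-text I/O for time courses, edge matrices and run outputs.

All formats are comma-separated UTF-8 with a header row and '.' decimals.

Time courses: one row per (replicate, timepoint); columns ``replicate``,
``time``, then one column per variable.

Edge matrices (priors, truths, predictions) come in two interchangeable
forms: a dense |V| x |V| table with variable names as header and index, or a
sparse 3-column edge list (parent, child, confidence) where unlisted pairs
default to 0.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import PriorConfidences, TimeCourseSet
from .diagnostics import EdgePosterior

__all__ = [
    "read_time_courses",
    "write_time_courses",
    "read_edge_matrix",
    "read_prior",
    "write_edge_list",
    "write_dense_matrix",
    "write_edge_posterior",
    "load_yaml",
    "file_digest",
]

_EDGE_LIST_COLUMNS = ("parent", "child", "confidence")


def read_time_courses(path) -> TimeCourseSet:
    """Read a time-course CSV (replicate, time, one column per variable)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns[:2]]
    if cols[0] not in ("replicate", "course") or cols[1] not in ("time", "timepoint"):
        raise ValueError(
            f"{path}: expected leading columns 'replicate' and 'time', got {list(df.columns[:2])}"
        )
    rep_col, time_col = df.columns[0], df.columns[1]
    variables = [str(c) for c in df.columns[2:]]
    if not variables:
        raise ValueError(f"{path}: no variable columns found")
    courses = []
    for rep, grp in df.groupby(rep_col, sort=False):
        grp = grp.sort_values(time_col)
        try:
            courses.append(grp[df.columns[2:]].to_numpy(dtype=float))
        except ValueError as exc:
            raise ValueError(f"{path}: replicate {rep!r}: {exc}") from exc
    return TimeCourseSet(variables, courses)


def write_time_courses(path, data: TimeCourseSet) -> None:
    frames = []
    for m, course in enumerate(data.courses):
        df = pd.DataFrame(course, columns=list(data.variables))
        df.insert(0, "time", np.arange(1, course.shape[0] + 1))
        df.insert(0, "replicate", m)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _is_edge_list(df: pd.DataFrame) -> bool:
    return (
        df.shape[1] == 3
        and tuple(c.strip().lower() for c in df.columns) == _EDGE_LIST_COLUMNS
    )


def read_edge_matrix(path, variables=None) -> tuple[tuple[str, ...], np.ndarray]:
    """Read an edge matrix (dense or edge-list CSV).

    For edge lists, ``variables`` fixes the ordering (required when the file
    does not mention every variable); unlisted pairs default to 0.
    Returns ``(variables, matrix)``.
    """
    head = pd.read_csv(path, nrows=0)
    if _is_edge_list(head):
        df = pd.read_csv(path)
        df.columns = _EDGE_LIST_COLUMNS
        names = (
            tuple(str(v) for v in variables)
            if variables is not None
            else tuple(sorted(set(df["parent"].astype(str)) | set(df["child"].astype(str))))
        )
        index = {v: k for k, v in enumerate(names)}
        mat = np.zeros((len(names), len(names)))
        for row in df.itertuples(index=False):
            p, c = str(row.parent), str(row.child)
            if p not in index or c not in index:
                raise KeyError(f"{path}: edge ({p!r}, {c!r}) names an unknown variable")
            mat[index[p], index[c]] = float(row.confidence)
        return names, mat
    df = pd.read_csv(path, index_col=0)
    names = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != names:
        raise ValueError(f"{path}: dense matrix header and index disagree")
    mat = df.to_numpy(dtype=float)
    if variables is not None:
        want = tuple(str(v) for v in variables)
        missing = set(want) - set(names)
        if missing:
            raise KeyError(f"{path}: missing variables: {sorted(missing)}")
        idx = np.array([names.index(v) for v in want])
        names, mat = want, mat[np.ix_(idx, idx)]
    return names, mat


def read_prior(path, variables=None) -> PriorConfidences:
    names, mat = read_edge_matrix(path, variables)
    return PriorConfidences(names, mat)


def write_edge_list(path, variables, matrix, tol: float = 0.0) -> None:
    """Write a sparse edge-list CSV, omitting entries <= ``tol``."""
    mat = np.asarray(matrix, dtype=float)
    names = np.asarray([str(v) for v in variables])
    ii, jj = np.nonzero(mat > tol)
    pd.DataFrame(
        {"parent": names[ii], "child": names[jj], "confidence": mat[ii, jj]}
    ).to_csv(path, index=False)


def write_dense_matrix(path, variables, matrix) -> None:
    names = [str(v) for v in variables]
    pd.DataFrame(np.asarray(matrix, dtype=float), index=names, columns=names).to_csv(path)


def write_edge_posterior(path, posterior: EdgePosterior) -> None:
    """Long-format posterior table: parent, child, probability, psrf, neff,
    converged."""
    posterior.to_frame().to_csv(path, index=False)


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    return out or {}


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
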