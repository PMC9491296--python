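"""Readers and writers for time courses, matrices, manifests and configs.

All tabular formats are delimited text (comma for ``.csv``, tab for
``.tsv``/``.txt``/``.tab``); cohort and run configurations are YAML.
Every writer's output is re-readable by the matching reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import CohortSpec, SubjectRecord

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "read_matrix",
    "write_matrix",
    "read_manifest",
    "write_manifest",
    "load_manifest_records",
    "load_cohort_spec",
]


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","


def _first_row_is_header(path: Path, sep: str) -> bool:
    with open(path) as fh:
        first = fh.readline()
    for tok in first.strip().split(sep):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_timecourses(path) -> tuple[np.ndarray, list[str]]:
    """Read a T x C time-course file (rows = timepoints).

    Returns the matrix and component labels (from the header row if
    present, else generated as C1..Cn).  Non-numeric or missing cells
    raise with the offending row/column named; a matrix with more
    columns than rows triggers an orientation warning, not a failure.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep(path)
    header = 0 if _first_row_is_header(path, sep) else None
    try:
        df = pd.read_csv(path, sep=sep, header=header)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc
    labels = (
        [str(c) for c in df.columns]
        if header == 0
        else [f"C{i + 1}" for i in range(df.shape[1])]
    )
    mat = df.to_numpy()
    if mat.dtype == object or not np.issubdtype(mat.dtype, np.number):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax())
                raise ValueError(
                    f"{path}: non-numeric value {df[col][row]!r} at row {row}, "
                    f"column {col!r}"
                )
        mat = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    mat = mat.astype(float)
    if np.isnan(mat).any():
        r, c = np.argwhere(np.isnan(mat))[0]
        raise ValueError(f"{path}: missing/NaN value at row {int(r)}, column {labels[int(c)]!r}")
    if mat.shape[0] < 10:
        raise ValueError(f"{path}: need at least 10 timepoints, got {mat.shape[0]}")
    if mat.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 components, got {mat.shape[1]}")
    if mat.shape[1] > mat.shape[0]:
        import warnings

        warnings.warn(
            f"{path}: more columns ({mat.shape[1]}) than rows ({mat.shape[0]}); "
            "expected rows = timepoints",
            stacklevel=2,
        )
    return mat, labels


def write_timecourses(matrix, labels, path) -> None:
    """Write a T x C matrix with a component-label header row."""
    path = Path(path)
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != len(labels):
        raise ValueError("matrix/labels dimension mismatch")
    pd.DataFrame(mat, columns=list(labels)).to_csv(path, sep=_sep(path), index=False)


def write_matrix(matrix, labels, path) -> None:
    """Write a labelled square matrix (labels as both index and header)."""
    path = Path(path)
    mat = np.asarray(matrix, dtype=float)
    if mat.size == 0:
        raise ValueError("empty matrix")
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("matrix must be square")
    if len(labels) != mat.shape[0]:
        raise ValueError("matrix/labels dimension mismatch")
    pd.DataFrame(mat, index=list(labels), columns=list(labels)).to_csv(
        path, sep=_sep(path), float_format="%.17g"
    )


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a labelled square matrix written by :func:`write_matrix`."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty matrix")
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row/column labels disagree")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def read_manifest(path, require_two_groups: bool = False) -> pd.DataFrame:
    """Read a subject manifest with columns subject_id, group, path.

    Relative paths resolve against the manifest's directory.  Subject
    ids must be unique; ``require_two_groups`` additionally demands
    exactly two distinct group labels.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"subject_id", "group", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"{path}: duplicate subject_id {dup!r}")
    groups = df["group"].unique()
    if require_two_groups and len(groups) != 2:
        raise ValueError(
            f"{path}: comparison needs exactly 2 groups, found {sorted(groups)}"
        )
    base = path.parent
    df["path"] = [str((base / p)) if not Path(p).is_absolute() else p for p in df["path"]]
    missing = [p for p in df["path"] if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"{path}: time-course file not found: {missing[0]}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep(path), index=False)


def load_manifest_records(path, require_two_groups: bool = False) -> list[SubjectRecord]:
    """Read a manifest and load every subject's time courses."""
    df = read_manifest(path, require_two_groups=require_two_groups)
    records = []
    shape = None
    for row in df.itertuples(index=False):
        mat, labels = read_timecourses(row.path)
        if shape is None:
            shape = mat.shape
        elif mat.shape != shape:
            raise ValueError(
                f"{row.path}: shape {mat.shape} differs from first subject {shape}"
            )
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                timecourses=mat,
                component_labels=tuple(labels),
            )
        )
    return records


def load_cohort_spec(path) -> CohortSpec:
    """Build a :class:`CohortSpec` from a YAML file.

    Coupling entries are lists ``[i, j, weight]``; ``domains`` is a
    list of per-component labels.  Unknown keys raise.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {
        "n_subjects_per_group", "n_components", "n_timepoints", "domains",
        "linear_coupling", "nonlinear_coupling", "group_delta",
        "noise_sd", "ar_coefficient", "seed", "group_labels",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")

    def pairs(key):
        out = {}
        for entry in raw.get(key, []) or []:
            if len(entry) != 3:
                raise ValueError(f"{path}: {key} entries must be [i, j, weight]")
            i, j, w = entry
            out[(int(i), int(j))] = float(w)
        return out

    kwargs = dict(
        linear_coupling=pairs("linear_coupling"),
        nonlinear_coupling=pairs("nonlinear_coupling"),
        group_delta=pairs("group_delta"),
    )
    for key in ("n_subjects_per_group", "n_components", "n_timepoints", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    for key in ("noise_sd", "ar_coefficient"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "domains" in raw:
        kwargs["domain_assignment"] = tuple(str(d) for d in raw["domains"])
    if "group_labels" in raw:
        kwargs["group_labels"] = tuple(str(g) for g in raw["group_labels"])
    return CohortSpec(**kwargs)
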