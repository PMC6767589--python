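"""Readers and writers: long-format growth tables and matrix containers.

Growth tables are delimited text with a header; the column mapping is
configurable so files from different sources can be ingested without
renaming.  Matrix containers are written either as HDF5 (bit-exact
round-trip of every layer plus grid metadata) or as CSV with bin
representative ages on the header row/column and ``NA`` marking masked
entries.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import h5py

from .grid import AgeGrid
from .containers import (
    CONTAINER_KINDS,
    GrowthRecordSet,
    IntegrityError,
)

log = logging.getLogger("growthcorr")

__all__ = [
    "read_growth_table",
    "read_growth_tables",
    "write_matrix",
    "read_matrix",
    "FormatError",
    "EmptyInputError",
    "DEFAULT_COLUMN_MAPPING",
    "Z_SCORE_LIMIT",
]

#: Hard plausibility cut on |z|: values beyond this are treated as data
#: errors (an impossible WHO z-score) and dropped at ingest.
Z_SCORE_LIMIT = 15.0

DEFAULT_COLUMN_MAPPING = {
    "study": "study",
    "child": "child",
    "age_days": "age_days",
    "z": "z",
    "measure": "measure",
}


class FormatError(ValueError):
    """The input file could not be parsed as a growth table."""


class EmptyInputError(ValueError):
    """No valid rows survived parsing and cleaning."""


def _load_frame(path, mapping, sep, measure, study_id):
    mapping = {**DEFAULT_COLUMN_MAPPING, **(mapping or {})}
    try:
        raw = pd.read_csv(path, sep=sep, engine="python")
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    cols = {}
    for key in ("child", "age_days", "z"):
        col = mapping[key]
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
        cols[key] = raw[col]
    if mapping["measure"] in raw.columns:
        cols["measure"] = raw[mapping["measure"]].astype(str).str.upper()
    elif measure is not None:
        cols["measure"] = measure
    else:
        raise FormatError(f"{path}: no measure column and no measure given")
    if mapping["study"] in raw.columns:
        cols["study"] = raw[mapping["study"]].astype(str)
    elif study_id is not None:
        cols["study"] = study_id
    else:
        raise FormatError(f"{path}: no study column and no study_id given")
    return pd.DataFrame(cols)


def _clean(df: pd.DataFrame, z_limit: float) -> pd.DataFrame:
    n0 = len(df)
    z = pd.to_numeric(df["z"], errors="coerce")
    age = pd.to_numeric(df["age_days"], errors="coerce")
    keep = z.notna() & np.isfinite(z.to_numpy(float)) & age.notna()
    n_badz = int((~keep).sum())
    if n_badz:
        log.warning("dropped %d rows with missing/non-finite z or age", n_badz)
    df = df[keep].copy()
    df["z"] = z[keep].astype(float)
    df["age_days"] = age[keep].round().astype(int)
    neg = df["age_days"] < 0
    if neg.any():
        log.warning("dropped %d rows with negative age", int(neg.sum()))
        df = df[~neg]
    wild = df["z"].abs() > z_limit
    if wild.any():
        log.warning(
            "dropped %d rows with |z| > %g (probable data errors, e.g. z=%g)",
            int(wild.sum()), z_limit, df.loc[wild, "z"].iloc[0],
        )
        df = df[~wild]
    dup = df.duplicated(["study", "child", "age_days", "measure"])
    if dup.any():
        log.warning("dropped %d duplicate (child, age, measure) rows", int(dup.sum()))
        df = df[~dup]
    log.info("ingest: kept %d of %d rows", len(df), n0)
    return df.reset_index(drop=True)


def read_growth_tables(path, mapping=None, sep=None, measure=None,
                       study_id=None, z_limit=Z_SCORE_LIMIT):
    """Read a delimited growth table and split it by study.

    Returns a dict mapping study id to :class:`GrowthRecordSet`.  Rows
    with missing or non-finite z-scores, negative ages, implausible
    ``|z| > z_limit`` values, or duplicated (child, age, measure) keys
    are dropped and counted in the log.
    """
    df = _clean(_load_frame(path, mapping, sep, measure, study_id), z_limit)
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows after cleaning")
    out = {}
    for sid, sub in df.groupby("study", sort=True):
        out[str(sid)] = GrowthRecordSet(
            str(sid), sub.drop(columns="study").reset_index(drop=True)
        )
    return out

def read_growth_table(path, mapping=None, sep=None, measure=None,
                      study_id=None, z_limit=Z_SCORE_LIMIT) -> GrowthRecordSet:
    """Read a growth table containing a single study.

    Thin wrapper over :func:`read_growth_tables`; raises
    :class:`FormatError` if the file mixes several studies.
    """
    sets = read_growth_tables(path, mapping, sep, measure, study_id, z_limit)
    if len(sets) != 1:
        raise FormatError(
            f"{path}: expected one study, found {sorted(sets)}; "
            "use read_growth_tables for pooled files"
        )
    return next(iter(sets.values()))


# ---------------------------------------------------------------------------
# Matrix containers

_PRIMARY_LAYER = {
    "study_correlation": "corr",
    "raw_combined_surface": "estimate",
    "smooth_correlation_matrix": "rho",
}


def write_matrix(matrix, path, format: str = "binary", extra_attrs=None) -> None:
    """Write a matrix container to ``path``.

    ``format="binary"`` stores every layer plus grid metadata in HDF5 and
    round-trips bit-exactly through :func:`read_matrix`.  ``format="csv"``
    writes the primary layer with representative ages on the header
    row/column and ``NA`` in masked cells.  ``extra_attrs`` (e.g.
    provenance: config hash, package version) are merged into the stored
    attributes.
    """
    grid, bins, layers, attrs = matrix.to_layers()
    if extra_attrs:
        attrs = {**attrs, **extra_attrs}
    path = Path(path)
    if format == "binary":
        with h5py.File(path, "w") as f:
            f.attrs["attrs_json"] = json.dumps(attrs)
            f.attrs["grid_json"] = json.dumps(grid.to_dict())
            f.create_dataset("bins", data=np.asarray(bins, dtype=np.int64))
            g = f.create_group("layers")
            for name, arr in layers.items():
                g.create_dataset(name, data=np.asarray(arr))
    elif format == "csv":
        primary = layers[_PRIMARY_LAYER[attrs["kind"]]].astype(float)
        out = primary.copy()
        if "mask" in layers:
            out = np.where(layers["mask"].astype(bool), out, np.nan)
        ages = np.asarray(bins) * grid.bin_width_days
        frame = pd.DataFrame(out, index=ages, columns=ages)
        with open(path, "w") as fh:
            fh.write(f"# {json.dumps({'grid': grid.to_dict(), 'attrs': attrs})}\n")
            frame.to_csv(fh, na_rep="NA")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_matrix(path):
    """Read an HDF5 matrix container written by :func:`write_matrix`.

    The container kind is stored in the file; the matching container
    class is reconstructed and re-validated, so a corrupted or mismatched
    file raises :class:`IntegrityError`.
    """
    with h5py.File(path, "r") as f:
        attrs = json.loads(f.attrs["attrs_json"])
        grid = AgeGrid.from_dict(json.loads(f.attrs["grid_json"]))
        bins = f["bins"][()]
        layers = {name: ds[()] for name, ds in f["layers"].items()}
    kind = attrs.get("kind")
    if kind not in CONTAINER_KINDS:
        raise IntegrityError(f"{path}: unknown container kind {kind!r}")
    return CONTAINER_KINDS[kind].from_layers(grid, bins, layers, attrs)
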