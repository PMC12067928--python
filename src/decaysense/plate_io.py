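"""Plate-level data model and I/O.

A plate file is tidy (long-format) CSV: one row per (well, replicate, time
point), columns ``well_id, sample_id, compound_id, replicate, time_min,
intensity``.  Intensities are instrument counts in arbitrary units and are
taken as given — no unit conversion is attempted.  Vehicle wells (no
compound added) carry the sentinel compound id ``BASELINE``; their
half-lives anchor the per-sample normalization downstream.

Sample metadata is a second CSV/TSV with columns ``sample_id, group,
batch_id``.  Group labels are an open set (AD, HC, MS, DB, RA, AD-MCI, ...)
and are preserved verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MetadataError, PlateFormatError, SchemaError

#: Compound id denoting a vehicle (no-compound) well.
BASELINE = "BASELINE"

#: Canonical plate-file columns, in write order.
PLATE_COLUMNS = ("well_id", "sample_id", "compound_id", "replicate", "time_min", "intensity")

#: Canonical metadata columns.
METADATA_COLUMNS = ("sample_id", "group", "batch_id")


@dataclass(frozen=True)
class DecayTrace:
    """One well's chemiluminescence intensity versus time.

    Parameters
    ----------
    times
        Acquisition times in minutes; strictly increasing, all >= 0.
    intensities
        Instrument counts (arbitrary units), same length as ``times``.
    """

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if times.ndim != 1 or intensities.ndim != 1:
            raise PlateFormatError("trace arrays must be one-dimensional")
        if len(times) != len(intensities):
            raise PlateFormatError("times and intensities differ in length")
        if len(times) < 4:
            raise PlateFormatError(f"trace needs >= 4 points, got {len(times)}")
        if not (np.isfinite(times).all() and np.isfinite(intensities).all()):
            raise PlateFormatError("trace contains non-finite values")
        if (times < 0).any():
            raise PlateFormatError("negative acquisition time")
        if not (np.diff(times) > 0).all():
            raise PlateFormatError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class WellRecord:
    """A single well: identity plus its decay trace."""

    well_id: str
    sample_id: str
    compound_id: str
    replicate: int
    trace: DecayTrace = field(repr=False)

    def __post_init__(self) -> None:
        if int(self.replicate) < 1:
            raise PlateFormatError(f"replicate must be >= 1, got {self.replicate}")
        object.__setattr__(self, "replicate", int(self.replicate))

    @property
    def is_baseline(self) -> bool:
        return self.compound_id == BASELINE


def _resolve_schema(columns: Sequence[str], schema: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical plate columns onto file columns, raising on any miss."""
    schema = dict(schema or {})
    resolved = {}
    for name in PLATE_COLUMNS:
        source = schema.get(name, name)
        if source not in columns:
            raise SchemaError(f"required column {name!r} (file column {source!r}) not found")
        resolved[name] = source
    return resolved


def read_plate(path: str | Path, schema: Mapping[str, str] | None = None) -> list[WellRecord]:
    """Read a long-format plate CSV into one :class:`WellRecord` per (well, replicate).

    Parameters
    ----------
    path
        Plate CSV with a header line.
    schema
        Optional mapping from canonical column names to the file's column
        names, for files with non-default headers.

    Raises
    ------
    SchemaError
        If a required column is missing.
    PlateFormatError
        If a well has duplicate or otherwise invalid time points, or a
        malformed trace.
    """
    # round_trip parsing: read(write(x)) must reproduce numerics exactly
    df = pd.read_csv(path, float_precision="round_trip")
    cols = _resolve_schema(list(df.columns), schema)
    df = df.rename(columns={v: k for k, v in cols.items()})
    if df[list(PLATE_COLUMNS)].isna().any().any():
        raise PlateFormatError(f"missing values in plate file {path}")

    records = []
    for (well_id, replicate), grp in df.groupby(["well_id", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(dtype=float)
        if len(np.unique(times)) != len(times):
            raise PlateFormatError(f"duplicate time points in well {well_id!r}")
        sample_ids = grp["sample_id"].unique()
        compound_ids = grp["compound_id"].unique()
        if len(sample_ids) != 1 or len(compound_ids) != 1:
            raise PlateFormatError(f"inconsistent sample/compound ids in well {well_id!r}")
        try:
            trace = DecayTrace(times, grp["intensity"].to_numpy(dtype=float))
        except PlateFormatError as exc:
            raise PlateFormatError(f"well {well_id!r}: {exc}") from exc
        records.append(
            WellRecord(
                well_id=str(well_id),
                sample_id=str(sample_ids[0]),
                compound_id=str(compound_ids[0]),
                replicate=int(replicate),
                trace=trace,
            )
        )
    seen = {}
    for rec in records:
        key = (rec.well_id, rec.replicate)
        if key in seen:
            raise PlateFormatError(f"well {rec.well_id!r} appears more than once")
        seen[key] = rec
    return records


def write_plate(records: Iterable[WellRecord], path: str | Path) -> None:
    """Write records as long-format CSV readable by :func:`read_plate`."""
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty record set")
    rows = []
    for rec in records:
        for t, y in zip(rec.trace.times, rec.trace.intensities):
            rows.append((rec.well_id, rec.sample_id, rec.compound_id, rec.replicate, t, y))
    pd.DataFrame(rows, columns=list(PLATE_COLUMNS)).to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata into a DataFrame indexed by ``sample_id``.

    The separator is sniffed between comma and tab from the header line.
    Group labels are kept verbatim; duplicate sample ids and empty groups
    are rejected with :class:`MetadataError`.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata file missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise MetadataError(f"duplicate sample ids: {sorted(set(dups))}")
    blank = df["group"].isna() | (df["group"].str.strip() == "")
    if blank.any():
        raise MetadataError(
            f"empty group label for samples: {df.loc[blank, 'sample_id'].tolist()}"
        )
    return df.set_index("sample_id")[["group", "batch_id"]]


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    """Write a metadata table (as produced by :func:`read_metadata`) to CSV."""
    metadata.reset_index().to_csv(path, index=False)


def group_indices(metadata: pd.DataFrame, group: str) -> list[str]:
    """Sample ids belonging to ``group`` (e.g. the HC index set A0)."""
    return metadata.index[metadata["group"] == group].tolist()
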