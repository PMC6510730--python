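"""Readers, writers and validators for microplate kinetic data.

The module handles three plain-text inputs:

* plate-reader kinetic exports -- a wide table with a time column followed by
  one column per well of raw OD600 readings;
* plate layouts -- a table mapping well IDs to a role (``sample``,
  ``background`` or ``empty``) and, for sample wells, a media combination ID;
* media composition tables -- one row per combination giving the
  concentration (mM) of each of the ten compounds of the growth assay.

Comma- and tab-separated files are accepted; the header row is mandatory and
well columns are keyed by header, never by position.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The fixed compound vocabulary of the growth assay (concentrations in mM).
COMPOUNDS = (
    "glucose",
    "(NH4)2SO4",
    "K2HPO4",
    "KH2PO4",
    "MgSO4",
    "thiamine_HCl",
    "FeSO4",
    "NaCl",
    "leucine",
    "histidine",
)

#: K2HPO4 : KH2PO4 molar ratio of the phosphate buffer stock.
PHOSPHATE_RATIO = 5.0 / 3.0

GROWTH_TABLE_COLUMNS = (
    "curve_id",
    "combination_id",
    "replicate_index",
    "r",
    "K",
    "qc_flags",
)


class PlateIOError(ValueError):
    """Raised when an input table violates a hard invariant."""


@dataclass
class TableDialect:
    """How to parse a kinetic export.

    Parameters
    ----------
    sep
        Field separator; ``None`` sniffs comma vs tab from the header line.
    time_unit
        ``"h"`` (canonical) or ``"min"``; minute input is divided by 60.
    tolerate_missing
        If True, a well whose readings end in a gap is truncated at its last
        valid reading instead of raising. Internal gaps always raise.
    """

    sep: str | None = None
    time_unit: str = "h"
    tolerate_missing: bool = False


@dataclass
class PlateRun:
    """One plate's kinetic record: a shared time grid and per-well readings."""

    run_id: str
    times: np.ndarray  # hours, strictly increasing
    wells: dict[str, np.ndarray]  # well_id -> readings, one per timepoint
    truncated_wells: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise PlateIOError("a plate run needs at least two timepoints")
        if not np.all(np.diff(self.times) > 0):
            raise PlateIOError(f"run {self.run_id!r}: times are not strictly increasing")
        for well, od in self.wells.items():
            od = np.asarray(od, dtype=float)
            self.wells[well] = od
            n_expected = self.truncated_wells.get(well, len(self.times))
            if len(od) != n_expected:
                raise PlateIOError(
                    f"run {self.run_id!r}, well {well!r}: {len(od)} readings "
                    f"for {n_expected} timepoints"
                )
            if not np.all(np.isfinite(od)) or np.any(od < 0):
                raise PlateIOError(
                    f"run {self.run_id!r}, well {well!r}: readings must be finite and >= 0"
                )

    @property
    def well_ids(self) -> list[str]:
        return list(self.wells)

    def well_times(self, well_id: str) -> np.ndarray:
        """Time grid for one well (shorter than ``times`` if truncated)."""
        return self.times[: len(self.wells[well_id])]


@dataclass
class PlateLayout:
    """Mapping of wells to roles and media combinations."""

    roles: dict[str, str]  # well_id -> sample | background | empty
    combinations: dict[str, str]  # well_id -> combination_id (samples only)

    def __post_init__(self) -> None:
        valid = {"sample", "background", "empty"}
        for well, role in self.roles.items():
            if role not in valid:
                raise PlateIOError(f"well {well!r}: unknown role {role!r}")
            if role == "sample" and well not in self.combinations:
                raise PlateIOError(f"sample well {well!r} has no combination_id")
        if not self.background_wells:
            raise PlateIOError("layout has no background wells")

    @property
    def sample_wells(self) -> list[str]:
        return [w for w, role in self.roles.items() if role == "sample"]

    @property
    def background_wells(self) -> list[str]:
        return [w for w, role in self.roles.items() if role == "background"]


def _read_table(path: str | Path | io.IOBase, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = None  # let pandas sniff via the python engine
        return pd.read_csv(path, sep=sep, engine="python")
    return pd.read_csv(path, sep=sep)


def read_plate_run(
    path: str | Path,
    dialect: TableDialect | None = None,
    run_id: str | None = None,
) -> PlateRun:
    """Read a wide kinetic export: first column time, remaining columns wells."""
    dialect = dialect or TableDialect()
    df = _read_table(path, dialect.sep)
    if df.shape[1] < 2:
        raise PlateIOError(f"{path}: expected a time column plus well columns")
    times = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        raise PlateIOError(f"{path}: non-numeric entries in the time column")
    if dialect.time_unit == "min":
        times = times / 60.0
    elif dialect.time_unit != "h":
        raise PlateIOError(f"unknown time unit {dialect.time_unit!r}")
    if not np.all(np.diff(times) > 0):
        raise PlateIOError(f"{path}: time column is not strictly increasing")

    wells: dict[str, np.ndarray] = {}
    truncated: dict[str, int] = {}
    for col in df.columns[1:]:
        od = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        nan = ~np.isfinite(od)
        if nan.any():
            first_nan = int(np.argmax(nan))
            if not nan[first_nan:].all() or not dialect.tolerate_missing:
                raise PlateIOError(
                    f"{path}: well {col!r} has missing readings"
                    + ("" if dialect.tolerate_missing else " (set tolerate_missing to truncate trailing gaps)")
                )
            od = od[:first_nan]
            truncated[str(col)] = first_nan
        wells[str(col)] = od
    rid = run_id if run_id is not None else Path(str(path)).stem
    return PlateRun(run_id=rid, times=times, wells=wells, truncated_wells=truncated)


def read_layout(path: str | Path, sep: str | None = None) -> PlateLayout:
    """Read a plate layout table with columns well_id, role, combination_id."""
    df = _read_table(path, sep)
    required = {"well_id", "role"}
    if not required.issubset(df.columns):
        raise PlateIOError(f"{path}: layout needs columns well_id and role")
    if df["well_id"].duplicated().any():
        dup = df.loc[df["well_id"].duplicated(), "well_id"].tolist()
        raise PlateIOError(f"{path}: duplicate well_id rows: {dup}")
    roles = dict(zip(df["well_id"].astype(str), df["role"].astype(str)))
    combos: dict[str, str] = {}
    if "combination_id" in df.columns:
        for well, combo in zip(df["well_id"].astype(str), df["combination_id"]):
            if pd.notna(combo) and str(combo) != "":
                combos[well] = str(combo)
    return PlateLayout(roles=roles, combinations=combos)


def read_media_table(
    path: str | Path,
    sep: str | None = None,
    allow_extra: bool = False,
    ratio_lock: bool = False,
) -> pd.DataFrame:
    """Read a media composition table (combination_id + the 10 compounds, mM).

    Returns a DataFrame indexed by combination_id with exactly the canonical
    compound columns. With ``ratio_lock``, rows where both phosphates are
    present must keep the 5:3 K2HPO4/KH2PO4 ratio of the buffer stock.
    """
    df = _read_table(path, sep)
    if "combination_id" not in df.columns:
        raise PlateIOError(f"{path}: media table needs a combination_id column")
    extra = [c for c in df.columns if c not in COMPOUNDS and c != "combination_id"]
    if extra and not allow_extra:
        raise PlateIOError(f"{path}: unknown compound columns {extra}")
    missing = [c for c in COMPOUNDS if c not in df.columns]
    if missing:
        raise PlateIOError(f"{path}: missing compound columns {missing}")
    media = df.set_index(df["combination_id"].astype(str))[list(COMPOUNDS)].astype(float)
    media.index.name = "combination_id"
    return validate_media(media, ratio_lock=ratio_lock)


def validate_media(media: pd.DataFrame, ratio_lock: bool = False) -> pd.DataFrame:
    """Validate an in-memory media table (see :func:`read_media_table`)."""
    if media.index.duplicated().any():
        raise PlateIOError("duplicate combination_id rows in media table")
    if (media.to_numpy() < 0).any() or not np.isfinite(media.to_numpy()).all():
        bad = media.index[(media < 0).any(axis=1) | ~np.isfinite(media).all(axis=1)]
        raise PlateIOError(f"negative or non-finite concentrations for {list(bad)}")
    if ratio_lock:
        both = (media["K2HPO4"] > 0) & (media["KH2PO4"] > 0)
        ratio = media.loc[both, "K2HPO4"] / media.loc[both, "KH2PO4"]
        off = ratio.index[~np.isclose(ratio, PHOSPHATE_RATIO, rtol=1e-6)]
        if len(off):
            raise PlateIOError(
                f"phosphate ratio lock: K2HPO4/KH2PO4 != 5:3 for {list(off)}"
            )
    return media


def make_growth_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Assemble and validate a growth-record table from row mappings."""
    df = pd.DataFrame(list(rows), columns=list(GROWTH_TABLE_COLUMNS))
    return validate_growth_table(df)


def validate_growth_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GROWTH_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateIOError(f"growth table missing columns {missing}")
    df = df[list(GROWTH_TABLE_COLUMNS)].copy()
    if len(df):
        if (df["r"] < 0).any() or (df["K"] < 0).any():
            raise PlateIOError("growth table has negative r or K")
        dup = df.duplicated(subset=["combination_id", "replicate_index"])
        if dup.any():
            raise PlateIOError(
                "duplicate (combination_id, replicate_index) pairs: "
                f"{df.loc[dup, ['combination_id', 'replicate_index']].to_records(index=False).tolist()}"
            )
    df["replicate_index"] = df["replicate_index"].astype(int)
    df["qc_flags"] = df["qc_flags"].fillna("").astype(str)
    return df


def write_growth_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a growth-record table as CSV, numeric values to 6 significant digits."""
    table = validate_growth_table(table)
    out = table.copy()
    for col in ("r", "K"):
        out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, index=False)


def read_growth_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_growth_table`."""
    df = pd.read_csv(path, dtype={"curve_id": str, "combination_id": str})
    if "qc_flags" not in df.columns:
        raise PlateIOError(f"{path}: not a growth table")
    return validate_growth_table(df)


@dataclass
class ValidationReport:
    """Report-only consistency check of a run/layout/media trio."""

    issues: list[str]
    replicate_counts: dict[str, int]

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(
    run: PlateRun,
    layout: PlateLayout,
    media: pd.DataFrame,
    n_min: int = 3,
) -> ValidationReport:
    """List orphan wells, unknown combinations and low replicate counts."""
    issues: list[str] = []
    for well in layout.roles:
        if well not in run.wells:
            issues.append(f"layout well {well!r} absent from run {run.run_id!r}")
    for well in run.wells:
        if well not in layout.roles:
            issues.append(f"run well {well!r} absent from layout")
    counts: dict[str, int] = {}
    for well in layout.sample_wells:
        combo = layout.combinations[well]
        if combo not in media.index:
            issues.append(f"well {well!r} cites unknown combination {combo!r}")
        else:
            counts[combo] = counts.get(combo, 0) + 1
    for combo, n in sorted(counts.items()):
        if n < n_min:
            issues.append(f"combination {combo!r} has only {n} replicate wells (< {n_min})")
    return ValidationReport(issues=issues, replicate_counts=counts)
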