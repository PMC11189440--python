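"""Reading and writing spectra tables, band-assignment tables and reports.

The on-disk container is a single flat CSV: fixed metadata columns first,
then one intensity column per channel, headed by the wavenumber in cm^-1.
Band-assignment tables are CSVs with columns
``center_cm1, tol_cm1, assignment, sign``.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SpectraFormatError

#: Metadata columns, in serialization order.
META_COLUMNS = (
    "cell_id",
    "donor_id",
    "batch_id",
    "sorted_label",
    "true_label",
    "subpop",
    "qc_flag",
)

SORTED_LABELS = ("Tconv", "Treg", "FrIII")
TRUE_LABELS = ("Tconv", "Treg", "unknown")
SUBPOPS = ("naive", "effector", "mixed")
QC_FLAGS = ("pass", "outlier", "pruned")

_AXIS_FMT = "%.6f"
_INTENSITY_FMT = "%.9g"


def validate_axis(values: np.ndarray) -> np.ndarray:
    """Validate a wavenumber axis: 1-D, finite, strictly increasing, len >= 2."""
    axis = np.asarray(values, dtype=float)
    if axis.ndim != 1:
        raise SpectraFormatError("axis must be one-dimensional")
    if axis.size < 2:
        raise SpectraFormatError("axis must have at least 2 channels")
    if not np.all(np.isfinite(axis)):
        raise SpectraFormatError("axis contains non-finite values")
    if not np.all(np.diff(axis) > 0):
        bad = int(np.argmax(np.diff(axis) <= 0))
        raise SpectraFormatError(
            f"axis not increasing at channel {bad} "
            f"({axis[bad]:.4f} followed by {axis[bad + 1]:.4f})"
        )
    return axis


def make_metadata(
    cell_ids: Sequence[str],
    donor_id: str | Sequence[str] = "d1",
    batch_id: str | Sequence[str] = "b1",
    sorted_label: str | Sequence[str] = "Tconv",
    true_label: str | Sequence[str] = "unknown",
    subpop: str | Sequence[str] = "mixed",
    qc_flag: str | Sequence[str] = "pass",
) -> pd.DataFrame:
    """Build a metadata frame with the canonical columns, broadcasting scalars."""
    n = len(cell_ids)
    cols = {
        "cell_id": list(cell_ids),
        "donor_id": donor_id,
        "batch_id": batch_id,
        "sorted_label": sorted_label,
        "true_label": true_label,
        "subpop": subpop,
        "qc_flag": qc_flag,
    }
    data = {}
    for name, val in cols.items():
        if isinstance(val, str):
            data[name] = [val] * n
        else:
            data[name] = list(val)
    return pd.DataFrame(data, columns=list(META_COLUMNS))


@dataclass
class SpectrumSet:
    """An intensity matrix on a shared wavenumber axis with per-cell metadata.

    Attributes
    ----------
    axis : ndarray, shape (p,)
        Channel centers in cm^-1, strictly increasing (may contain one
        internal gap after silent-region removal).
    intensities : ndarray, shape (n, p)
        One spectrum per row; arbitrary counts units.
    meta : DataFrame
        One row per cell with columns :data:`META_COLUMNS`.
    """

    axis: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.axis = validate_axis(self.axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise SpectraFormatError("intensities must be a 2-D matrix")
        if self.intensities.shape[1] != self.axis.size:
            raise SpectraFormatError(
                f"intensity columns ({self.intensities.shape[1]}) do not match "
                f"axis length ({self.axis.size})"
            )
        if not isinstance(self.meta, pd.DataFrame):
            raise SpectraFormatError("meta must be a DataFrame")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SpectraFormatError(f"metadata missing columns: {missing}")
        self.meta = self.meta.loc[:, list(META_COLUMNS)].reset_index(drop=True)
        if len(self.meta) != self.intensities.shape[0]:
            raise SpectraFormatError(
                f"metadata rows ({len(self.meta)}) do not match intensity rows "
                f"({self.intensities.shape[0]})"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraFormatError("intensities contain non-finite values")
        ids = self.meta["cell_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SpectraFormatError(f"duplicate cell_id {dup!r}")

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    @property
    def cell_ids(self) -> list[str]:
        return self.meta["cell_id"].tolist()

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            self.axis.copy(), self.intensities.copy(), self.meta.copy()
        )

    def select(self, mask: np.ndarray) -> "SpectrumSet":
        """Row subset by boolean mask or integer positions."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return SpectrumSet(
            self.axis.copy(),
            self.intensities[idx],
            self.meta.iloc[idx].reset_index(drop=True),
        )

    def select_ids(self, cell_ids: Iterable[str]) -> "SpectrumSet":
        wanted = list(cell_ids)
        pos = pd.Index(self.meta["cell_id"]).get_indexer(wanted)
        if (pos < 0).any():
            missing = [w for w, p in zip(wanted, pos) if p < 0]
            raise KeyError(f"unknown cell ids: {missing[:5]}")
        return self.select(pos)

    def labels(self, source: str = "sorted") -> np.ndarray:
        """Return the 'sorted' or 'true' label column as an object array."""
        if source not in ("sorted", "true"):
            raise ValueError(f"unknown label source {source!r}")
        return self.meta[f"{source}_label"].to_numpy()


@dataclass
class BandAssignmentTable:
    """Band centers with tolerances, assignment text and expected sign."""

    entries: pd.DataFrame  # columns: center_cm1, tol_cm1, assignment, sign

    COLUMNS = ("center_cm1", "tol_cm1", "assignment", "sign")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.entries.columns]
        if missing:
            raise SpectraFormatError(f"band table missing columns: {missing}")
        self.entries = self.entries.loc[:, list(self.COLUMNS)].reset_index(
            drop=True
        )
        if len(self.entries):
            if (self.entries["center_cm1"] <= 0).any():
                raise SpectraFormatError("band centers must be positive")
            if (self.entries["tol_cm1"] <= 0).any():
                raise SpectraFormatError("band tolerances must be > 0")
            bad = ~self.entries["sign"].isin(["negative", "positive"])
            if bad.any():
                raise SpectraFormatError(
                    f"band sign must be 'negative' or 'positive', "
                    f"got {self.entries.loc[bad, 'sign'].iloc[0]!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)


def _atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_spectra_table(sset: SpectrumSet, path: str | Path) -> None:
    """Write a SpectrumSet as a flat CSV (metadata columns, then channels).

    The write is atomic (temp file + rename) and deterministic: two writes of
    the same set produce byte-identical files.
    """
    header = list(META_COLUMNS) + [_AXIS_FMT % w for w in sset.axis]
    lines = [",".join(header)]
    meta_vals = sset.meta.astype(str).to_numpy()
    for i in range(sset.n_cells):
        row = list(meta_vals[i]) + [
            _INTENSITY_FMT % v for v in sset.intensities[i]
        ]
        lines.append(",".join(row))
    _atomic_write_text(Path(path), "\n".join(lines) + "\n")


def read_spectra_table(path: str | Path) -> SpectrumSet:
    """Read a flat spectra CSV written by :func:`write_spectra_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={c: str for c in META_COLUMNS})
    cols = list(df.columns)
    if cols[: len(META_COLUMNS)] != list(META_COLUMNS):
        raise SpectraFormatError(
            f"expected metadata columns {list(META_COLUMNS)}, "
            f"got {cols[:len(META_COLUMNS)]}"
        )
    chan_cols = cols[len(META_COLUMNS):]
    if len(chan_cols) < 2:
        raise SpectraFormatError("spectra table needs at least 2 channels")
    try:
        axis = np.array([float(c) for c in chan_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric channel header: {exc}") from None
    axis = validate_axis(axis)
    meta = df.loc[:, list(META_COLUMNS)].copy()
    intensities = df.loc[:, chan_cols].to_numpy(dtype=float)
    if len(df) == 0:
        intensities = np.empty((0, axis.size))
    return SpectrumSet(axis, intensities, meta)


def load_band_table(path: str | Path) -> BandAssignmentTable:
    """Load a band-assignment CSV (center_cm1, tol_cm1, assignment, sign)."""
    df = pd.read_csv(path)
    missing = [c for c in BandAssignmentTable.COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"band table missing columns: {missing}")
    return BandAssignmentTable(df)


def default_band_table(organism: str = "murine") -> BandAssignmentTable:
    """Packaged band tables for the murine and human discriminating bands."""
    name = {"murine": "bands_murine.csv", "human": "bands_human.csv"}.get(
        organism
    )
    if name is None:
        raise ValueError(f"unknown organism {organism!r}")
    ref = resources.files("ramanpheno.data").joinpath(name)
    with resources.as_file(ref) as p:
        return load_band_table(p)


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a report dict as pretty JSON (atomic)."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    _atomic_write_text(
        Path(path), json.dumps(report, indent=2, default=_default) + "\n"
    )
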