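"""The pore-water depth profile container and its delimited-table I/O.

A :class:`PorewaterProfile` is a thin, validated wrapper around a pandas
DataFrame with canonical column names.  Depths are centimeters below the
seafloor (cmbsf, positive downward); concentrations are micromolar except
alkalinity (millimolar); nitrate isotope compositions are per-mil against
AIR (d15N) and V-SMOW (d18O).  Rows where nitrate falls below the
reporting threshold carry no isotope values and are flagged in
``qc_flag``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "REQUIRED_COLUMNS",
    "ProfileFormatError",
    "PorewaterProfile",
    "read_profile_table",
    "write_profile_table",
]

CANONICAL_COLUMNS: tuple[str, ...] = (
    "depth_cmbsf",
    "no3_uM",
    "no2_uM",
    "nh4_uM",
    "po4_uM",
    "alkalinity_mM",
    "d15n_no3_permil",
    "d18o_no3_permil",
    "qc_flag",
)

REQUIRED_COLUMNS: tuple[str, ...] = ("depth_cmbsf", "no3_uM")

_CONCENTRATION_COLUMNS = ("no3_uM", "no2_uM", "nh4_uM", "po4_uM", "alkalinity_mM")

QC_OK = "ok"
QC_BELOW_THRESHOLD = "no3_below_threshold"


class ProfileFormatError(ValueError):
    """A profile table violates the format contract (columns, order, units)."""


@dataclass
class PorewaterProfile:
    """Depth-indexed pore-water chemistry and nitrate isotope table."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ProfileFormatError(f"missing required column(s): {', '.join(missing)}")
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col == "qc_flag" else np.nan
        extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
        if extra:
            raise ProfileFormatError(f"unknown column(s): {', '.join(extra)}")
        df = df[list(CANONICAL_COLUMNS)].reset_index(drop=True)
        for col in CANONICAL_COLUMNS[:-1]:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df["qc_flag"] = df["qc_flag"].astype(str).replace({"nan": "", "None": ""})
        depth = df["depth_cmbsf"].to_numpy()
        if np.any(~np.isfinite(depth)):
            raise ProfileFormatError("depth_cmbsf contains missing or non-numeric entries")
        bad = np.flatnonzero(np.diff(depth) <= 0)
        if bad.size:
            rows = ", ".join(f"{i + 1}->{i + 2}" for i in bad)
            raise ProfileFormatError(
                f"depth_cmbsf must be strictly increasing; violated at row(s) {rows}"
            )
        for col in _CONCENTRATION_COLUMNS:
            vals = df[col].to_numpy()
            if np.any(vals[np.isfinite(vals)] < 0):
                raise ProfileFormatError(f"negative values in column {col}")
        self.data = df

    # -- convenience views -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def depth(self) -> np.ndarray:
        return self.data["depth_cmbsf"].to_numpy()

    @property
    def no3(self) -> np.ndarray:
        return self.data["no3_uM"].to_numpy()

    @property
    def d15n(self) -> np.ndarray:
        return self.data["d15n_no3_permil"].to_numpy()

    @property
    def d18o(self) -> np.ndarray:
        return self.data["d18o_no3_permil"].to_numpy()

    @property
    def isotope_mask(self) -> np.ndarray:
        """Rows bearing both nitrate isotope values."""
        return np.isfinite(self.d15n) & np.isfinite(self.d18o)

    @classmethod
    def from_columns(cls, columns: Mapping[str, np.ndarray | list]) -> "PorewaterProfile":
        return cls(pd.DataFrame(dict(columns)))

    def apply_reporting_threshold(self, threshold_uM: float = 0.5) -> "PorewaterProfile":
        """Blank isotope values where nitrate is below the reporting threshold."""
        df = self.data.copy()
        below = df["no3_uM"].to_numpy() < threshold_uM
        df.loc[below, ["d15n_no3_permil", "d18o_no3_permil"]] = np.nan
        df["qc_flag"] = np.where(below, QC_BELOW_THRESHOLD, QC_OK)
        return PorewaterProfile(df)

    def equals_approx(self, other: "PorewaterProfile", tol: float = 1e-6) -> bool:
        a, b = self.data, other.data
        if len(a) != len(b):
            return False
        for col in CANONICAL_COLUMNS[:-1]:
            x, y = a[col].to_numpy(), b[col].to_numpy()
            both = np.isfinite(x) & np.isfinite(y)
            if not np.array_equal(np.isfinite(x), np.isfinite(y)):
                return False
            if np.any(np.abs(x[both] - y[both]) > tol):
                return False
        return True


def _detect_delimiter(path: Path, dialect: str | None) -> str:
    if dialect in ("\t", "tab", "tsv"):
        return "\t"
    if dialect in (",", "comma", "csv"):
        return ","
    if dialect is not None:
        raise ProfileFormatError(f"unknown table dialect {dialect!r}")
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def read_profile_table(path: str | Path, dialect: str | None = None) -> PorewaterProfile:
    """Read a delimited pore-water profile table.

    Lines starting with ``#`` are metadata comments and are skipped.  The
    header must use the canonical column names; ``depth_cmbsf`` and
    ``no3_uM`` are required, all other columns optional.  Empty cells are
    missing values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"profile table not found: {path}")
    sep = _detect_delimiter(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ProfileFormatError(f"no header found in {path}") from None
    # numeric coercion in PorewaterProfile turns empty cells into NaN
    return PorewaterProfile(df)


def _format_value(x: float) -> str:
    if isinstance(x, str):
        return x
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{x:.6g}"


def write_profile_table(
    profile: PorewaterProfile,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
    dialect: str | None = None,
) -> None:
    """Write a profile as a delimited table with a ``#`` metadata block.

    Output is deterministic: fixed column order, floats at six significant
    digits, missing values as empty fields.
    """
    path = Path(path)
    sep = _detect_delimiter(path, dialect)
    buf = _io.StringIO()
    for key in sorted(metadata or {}):
        buf.write(f"# {key}: {metadata[key]}\n")
    buf.write(sep.join(CANONICAL_COLUMNS) + "\n")
    for _, row in profile.data.iterrows():
        cells = [_format_value(row[c]) for c in CANONICAL_COLUMNS[:-1]]
        cells.append(str(row["qc_flag"]))
        buf.write(sep.join(cells) + "\n")
    path.write_text(buf.getvalue())
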