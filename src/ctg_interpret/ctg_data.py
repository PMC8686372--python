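"""Reading, validation and summary of the 21-feature CTG table.

The canonical input is the widely circulated cardiotocography summary table:
one row per monitoring session, 21 diagnostic features produced by automated
FHR/UC signal processing, plus the expert consensus label NSP
(1 = normal, 2 = suspicious, 3 = pathology).  The in-memory container is a
thin wrapper over a :class:`pandas.DataFrame`, which every downstream stage
consumes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Canonical feature order (NSP label excluded).
CTG_FEATURES: tuple[str, ...] = (
    "LB", "AC", "FM", "UC", "DL", "DS", "DP",
    "ASTV", "MSTV", "ALTV", "MLTV",
    "Width", "Min", "Max", "Nmax", "Nzeros",
    "Mode", "Mean", "Median", "Variance", "Tendency",
)

#: Columns required in any input table.
REQUIRED_COLUMNS: tuple[str, ...] = CTG_FEATURES + ("NSP",)

#: Features that are rates or counts and must be non-negative.
NONNEGATIVE_FEATURES: tuple[str, ...] = (
    "AC", "FM", "UC", "DL", "DS", "DP", "MSTV", "MLTV",
    "Width", "Nmax", "Nzeros", "Variance",
)

#: FIGO-guideline thresholds for the three fetal-state categories.  Shipped
#: as documentation only; the pipeline never executes these rules.
FIGO_GUIDELINES: dict[str, dict[str, str]] = {
    "baseline_bpm": {
        "normal": "110-150",
        "suspicious": "100-110 or 150-170",
        "pathology": "<100 or >170",
    },
    "variability_bpm": {
        "normal": "5-25",
        "suspicious": "5-10 for >40 s",
        "pathology": "<5 for >40 s",
    },
}


class SchemaError(ValueError):
    """Input table is missing a required column."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class EmptyTableError(ValueError):
    """Input file holds no data rows."""


class ValidationError(ValueError):
    """Strict-mode validation failure; carries the full report."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        first = report.violations[0]
        super().__init__(
            f"record {first[0]}: invariant '{first[1]}' violated ({first[2]})"
        )


@dataclasses.dataclass
class CTGDataset:
    """Ordered collection of CTG records sharing the 21-feature schema."""

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        self.frame = self.frame.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return CTG_FEATURES

    @property
    def n(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def features(self) -> pd.DataFrame:
        return self.frame[list(CTG_FEATURES)]

    @property
    def nsp(self) -> np.ndarray:
        return self.frame["NSP"].to_numpy(dtype=int)

    def copy(self) -> "CTGDataset":
        return CTGDataset(self.frame.copy(), provenance=self.provenance)


@dataclasses.dataclass
class ValidationReport:
    """Per-record invariant violations: (record index, invariant, detail)."""

    violations: list[tuple[int, str, str]] = dataclasses.field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, name, _ in self.violations:
            out[name] = out.get(name, 0) + 1
        return out

    def __bool__(self) -> bool:  # truthy iff violations present
        return bool(self.violations)


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Match columns case-insensitively against the canonical names."""
    lookup = {c.strip().lower(): c for c in df.columns}
    rename = {}
    for want in REQUIRED_COLUMNS:
        got = lookup.get(want.lower())
        if got is not None and got != want:
            rename[got] = want
    return df.rename(columns=rename)


def read_ctg_table(path: str | Path, dialect: str = "auto") -> CTGDataset:
    """Read a CTG table from CSV or spreadsheet, selecting columns by name.

    Column order is irrelevant; matching is case-insensitive.  Numeric
    parsing uses the dot decimal separator regardless of locale.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"csv"``, ``"spreadsheet"``, or ``"auto"`` (by extension).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "spreadsheet" if path.suffix.lower() in {".xls", ".xlsx"} else "csv"
    if dialect == "spreadsheet":
        book = pd.read_excel(path, sheet_name=None)
        df = None
        for sheet in book.values():
            cand = _normalise_columns(sheet)
            if all(c in cand.columns for c in REQUIRED_COLUMNS):
                df = cand
                break
        if df is None:
            raise SchemaError(
                "no sheet contains all required columns "
                f"({', '.join(REQUIRED_COLUMNS)})"
            )
    elif dialect == "csv":
        df = _normalise_columns(pd.read_csv(path, dtype=str))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if len(df) == 0:
        raise EmptyTableError(f"{path}: no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    df = df.loc[:, list(REQUIRED_COLUMNS)]
    parsed = {}
    for col in REQUIRED_COLUMNS:
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() & series.notna() if series.dtype == object else numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {series.iloc[row]!r} at row {row}, "
                f"column {col}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ParseError(f"{path}: empty cell at row {row}, column {col}")
        parsed[col] = numeric
    out = pd.DataFrame(parsed)
    out["NSP"] = out["NSP"].astype(int)
    return CTGDataset(out, provenance=str(path))


def write_ctg_table(dataset: CTGDataset, path: str | Path) -> None:
    """Canonical CSV writer: fixed column order, 6-significant-digit floats."""
    df = dataset.frame.copy()

    def fmt(v: float) -> str:
        if float(v) == int(v):
            return str(int(v))
        return f"{v:.6g}"

    with open(path, "w", newline="") as fh:
        fh.write(",".join(REQUIRED_COLUMNS) + "\n")
        for _, row in df.iterrows():
            fh.write(",".join(fmt(row[c]) for c in REQUIRED_COLUMNS) + "\n")


def _iter_violations(frame: pd.DataFrame) -> Iterable[tuple[int, str, str]]:
    nsp = frame["NSP"].to_numpy()
    for i in np.flatnonzero(~np.isin(nsp, (1, 2, 3))):
        yield int(i), "nsp_domain", f"NSP={nsp[i]}"
    for col in ("ASTV", "ALTV"):
        v = frame[col].to_numpy(dtype=float)
        for i in np.flatnonzero((v < 0) | (v > 100)):
            yield int(i), f"{col.lower()}_range", f"{col}={v[i]}"
    for col in NONNEGATIVE_FEATURES:
        v = frame[col].to_numpy(dtype=float)
        for i in np.flatnonzero(v < 0):
            yield int(i), "nonnegative", f"{col}={v[i]}"
    tend = frame["Tendency"].to_numpy()
    for i in np.flatnonzero(~np.isin(tend, (-1, 0, 1))):
        yield int(i), "tendency_domain", f"Tendency={tend[i]}"
    # Histogram consistency; source rounding can break these by +-1, which is
    # why "warn" is the default level.
    mn = frame["Min"].to_numpy(dtype=float)
    mx = frame["Max"].to_numpy(dtype=float)
    width = frame["Width"].to_numpy(dtype=float)
    for i in np.flatnonzero(np.abs(width - (mx - mn)) > 1e-9):
        yield int(i), "width_consistency", f"Width={width[i]}, Max-Min={mx[i]-mn[i]}"
    for col in ("Mode", "Median"):
        v = frame[col].to_numpy(dtype=float)
        for i in np.flatnonzero((v < mn) | (v > mx)):
            yield int(i), f"{col.lower()}_in_range", f"{col}={v[i]} outside [{mn[i]}, {mx[i]}]"


def validate_records(dataset: CTGDataset, level: str = "warn") -> ValidationReport:
    """Check record invariants; ``strict`` raises on the first violation.

    ``warn`` returns the full report and never alters the data.
    """
    if dataset.n == 0:
        raise ValueError("dataset is empty")
    if level not in {"strict", "warn"}:
        raise ValueError(f"level must be 'strict' or 'warn', got {level!r}")
    report = ValidationReport()
    for violation in _iter_violations(dataset.frame):
        report.violations.append(violation)
        if level == "strict":
            raise ValidationError(report)
    return report


def class_counts(dataset: CTGDataset) -> dict:
    """Counts and proportions per NSP class (1, 2, 3).

    Empty datasets give zero counts with proportions flagged undefined.
    """
    nsp = dataset.frame["NSP"].to_numpy(dtype=int) if dataset.n else np.array([], int)
    counts = {c: int(np.sum(nsp == c)) for c in (1, 2, 3)}
    total = sum(counts.values())
    if total == 0:
        return {"counts": counts, "proportions": None, "n": 0}
    props = {c: counts[c] / total for c in (1, 2, 3)}
    return {"counts": counts, "proportions": props, "n": total}
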