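"""Packaged reference dataset of cation parameters, with lookup and validation.

The canonical dataset (``atomic_parameters.csv``) is a transcription of the
published compilation of 265 cations, H+ through Lw3+: per row the effective
principal quantum number n*, ultimate IE I_z, hybrid ionicity I_av, covalent
radius r_c and the derived columns r_c⁻¹, n*·r_c⁻¹, Z*, X_z, X_IC and IC as
printed.  Late-actinide rows print no ionization energies; they carry the
constant Z* = 3.900 directly and all their derived columns follow the
Z*-direct pathway.

Printed strings are preserved verbatim so that load → serialize → load
round-trips bit-identically; numeric access goes through float fields.

A small family of property tables (redox potentials, Mossbauer shifts,
melting points, lattice energies, complex-formation constants, ...) is
packaged alongside for the correlation utilities, together with a curated
known-issue list of printed inconsistencies (suspected typos) in the
canonical table.  Known issues are data, not code: the validator reports
them, it never corrects them.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .ic_core import DEFAULT_COEFFS, ScaleCoefficients, effective_nuclear_charge
from .hybridization import IonizationLadder

__all__ = [
    "DatasetRow",
    "KnownIssue",
    "ValidationReport",
    "DatasetError",
    "CationNotFoundError",
    "parse_cation_label",
    "load_dataset",
    "serialize_dataset",
    "lookup",
    "load_known_issues",
    "validate_dataset",
    "load_table",
    "load_ladder",
    "TABLE_NAMES",
]

_COLUMNS = [
    "atomic_number", "symbol", "charge", "n_star", "i_z", "i_av",
    "rc_inv", "n_star_rc_inv", "z_star", "r_c", "x_z", "x_ic", "ic",
]

#: property fixture tables loadable through :func:`load_table`
TABLE_NAMES = (
    "redox_potentials",
    "inert_pair",
    "coinage_metals",
    "moessbauer_iron",
    "melting_points",
    "lattice_energies",
    "mcl2_lattice",
    "log_beta",
    "melting_point_pairs",
    "hydride_lattice",
    "alt_chart_values",
    "ladders",
    "known_issues",
)


class DatasetError(ValueError):
    """Schema or parse failure while reading a dataset file."""


class CationNotFoundError(KeyError):
    """Requested symbol+charge has no row in the dataset."""


_LABEL_RE = re.compile(r"^([A-Z][a-z]?w?)\^?\(?(\d*)\+?\)?\^?\+?$")


def parse_cation_label(label: str) -> Tuple[str, int]:
    """Parse ``"Fe2+"``, ``"Fe^2+^"`` or ``"Fe+"`` into ``("Fe", 2)``."""
    text = label.strip().replace(" ", "")
    m = re.match(r"^([A-Z][a-z]?w?)\D*?(\d*)\+*\^?$", text.replace("^", ""))
    if not m or not m.group(1):
        raise DatasetError(f"cannot parse cation label {label!r}")
    sym, digits = m.groups()
    return sym, int(digits) if digits else 1


@dataclass(frozen=True)
class DatasetRow:
    """One printed row: numeric fields plus the verbatim printed strings."""

    atomic_number: int
    symbol: str
    charge: int
    n_star: float
    i_z: Optional[float]
    i_av: Optional[float]
    rc_inv: float
    n_star_rc_inv: float
    z_star: float
    r_c: float
    x_z: float
    x_ic: float
    ic: float
    printed: Mapping[str, str] = field(repr=False, hash=False, compare=False)
    provenance: str = "reference compilation; radius source unattributed"

    @property
    def label(self) -> str:
        return f"{self.symbol}{self.charge}+"

    @property
    def z_star_direct(self) -> bool:
        """True for rows whose printed Z* is the datum (no ionization energies)."""
        return self.i_av is None

    def quantity(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise DatasetError(f"{self.label}: column {name!r} is absent")
        return value


@dataclass(frozen=True)
class KnownIssue:
    symbol: str
    charge: int
    column: str
    reason: str


def _float(cell: str, row: int, col: str) -> Optional[float]:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise DatasetError(f"row {row}, column {col}: bad number {cell!r}") from exc


def _data_text(name: str) -> str:
    return resources.files("ionocov.data").joinpath(f"{name}.csv").read_text("utf-8")


def load_dataset(source: Union[None, str, Path] = None) -> List[DatasetRow]:
    """Load the canonical cation dataset (packaged by default).

    Blank I_z/I_av cells (late actinides) load as absent; their Z* is taken
    from the printed column.
    """
    if source is None:
        text = _data_text("atomic_parameters")
    else:
        path = Path(source)
        if not path.exists():
            raise DatasetError(f"dataset file not found: {path}")
        text = path.read_text("utf-8")
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames != _COLUMNS:
        raise DatasetError(
            f"unexpected dataset schema: {reader.fieldnames} (want {_COLUMNS})"
        )
    rows: List[DatasetRow] = []
    seen = set()
    for i, rec in enumerate(reader, start=2):
        if None in rec or any(v is None for v in rec.values()):
            raise DatasetError(f"row {i}: wrong number of fields")
        try:
            atomic_number = int(rec["atomic_number"])
            charge = int(rec["charge"])
        except ValueError as exc:
            raise DatasetError(f"row {i}: {exc}") from exc
        values: Dict[str, Optional[float]] = {
            c: _float(rec[c], i, c)
            for c in _COLUMNS
            if c not in ("atomic_number", "symbol", "charge")
        }
        for required in ("n_star", "rc_inv", "n_star_rc_inv", "z_star", "r_c",
                         "x_z", "x_ic", "ic"):
            if values[required] is None:
                raise DatasetError(f"row {i}: column {required!r} must not be blank")
        key = (rec["symbol"], charge)
        if key in seen:
            raise DatasetError(f"row {i}: duplicate cation {key}")
        seen.add(key)
        rows.append(
            DatasetRow(
                atomic_number=atomic_number,
                symbol=rec["symbol"],
                charge=charge,
                printed=dict(rec),
                **values,  # type: ignore[arg-type]
            )
        )
    return rows


def serialize_dataset(rows: Sequence[DatasetRow]) -> str:
    """Write rows back to CSV text using the verbatim printed strings."""
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_COLUMNS, lineterminator="\n")
    writer.writeheader()
    for row in rows:
        writer.writerow({c: row.printed[c] for c in _COLUMNS})
    return buf.getvalue()


def lookup(rows: Sequence[DatasetRow], symbol: str, charge: int) -> DatasetRow:
    """Return the unique row for ``symbol``/``charge``."""
    for row in rows:
        if row.symbol == symbol and row.charge == charge:
            return row
    available = sorted(r.charge for r in rows if r.symbol == symbol)
    if available:
        raise CationNotFoundError(
            f"{symbol}{charge}+ not in dataset; available charges for "
            f"{symbol}: {available}"
        )
    raise CationNotFoundError(f"element {symbol!r} not in dataset")


def load_known_issues() -> List[KnownIssue]:
    """Curated printed inconsistencies in the canonical table (reason-coded)."""
    reader = csv.DictReader(io.StringIO(_data_text("known_issues")))
    return [
        KnownIssue(r["symbol"], int(r["charge"]), r["column"], r["reason"])
        for r in reader
    ]


def load_table(name: str) -> pd.DataFrame:
    """Load one of the packaged property fixture tables as a DataFrame."""
    if name not in TABLE_NAMES:
        raise DatasetError(f"unknown table {name!r}; available: {TABLE_NAMES}")
    return pd.read_csv(io.StringIO(_data_text(name)))


def load_ladder(symbol: str) -> IonizationLadder:
    """Successive-IE ladder for one of the packaged worked-example elements."""
    df = load_table("ladders")
    sub = df[df["symbol"] == symbol].sort_values("ie_order")
    if sub.empty:
        available = sorted(df["symbol"].unique())
        raise CationNotFoundError(f"no ladder for {symbol!r}; available: {available}")
    return IonizationLadder(symbol, tuple(sub["energy_ev"]))


@dataclass
class ValidationReport:
    """Outcome of recomputing every derivable column of the dataset.

    ``deltas`` maps each cation label to per-column absolute differences
    between the printed value and the recomputation from that row's own
    inputs.  A row passes when every non-flagged recomputed column agrees
    within ``tolerance``.
    """

    tolerance: float
    deltas: Dict[str, Dict[str, float]]
    row_passed: Dict[str, bool]
    flagged: Dict[str, List[KnownIssue]]
    failures: Dict[str, List[str]]

    @property
    def n_rows(self) -> int:
        return len(self.row_passed)

    @property
    def n_passed(self) -> int:
        return sum(self.row_passed.values())

    @property
    def n_failed(self) -> int:
        return self.n_rows - self.n_passed

    @property
    def passed(self) -> bool:
        return self.n_failed == 0

    def summary(self) -> str:
        lines = [
            f"rows checked : {self.n_rows}",
            f"rows passed  : {self.n_passed}",
            f"rows failed  : {self.n_failed}",
            f"rows flagged : {len(self.flagged)} (known printed inconsistencies)",
            f"tolerance    : {self.tolerance}",
        ]
        for label, cols in sorted(self.failures.items()):
            deltas = ", ".join(f"{c}: |d|={self.deltas[label][c]:.4f}" for c in cols)
            lines.append(f"FAIL {label}: {deltas}")
        for label, issues in sorted(self.flagged.items()):
            for issue in issues:
                lines.append(f"flagged {label} [{issue.column}]: {issue.reason}")
        return "\n".join(lines)


def validate_dataset(
    rows: Sequence[DatasetRow],
    coeffs: ScaleCoefficients = DEFAULT_COEFFS,
    tolerance: float = 0.005,
    known_issues: Optional[Sequence[KnownIssue]] = None,
) -> ValidationReport:
    """Recompute every derivable column of every row and report the deltas.

    Checks per row (all against the printed value, tolerance = absolute):

    - ``rc_inv``        = 1 / r_c
    - ``n_star_rc_inv`` = n* / r_c
    - ``z_star``        = n*·(I_av/R)^(1/2)   (skipped for Z*-direct rows)
    - ``ic``            = Z*(I_av)·r_c⁻¹, or printed Z*·r_c⁻¹ when Z*-direct
    - ``x_ic``          = slope·IC_recomputed + intercept
    - ``x_z``           = slope·n*(I_z/R)^(1/2)·r_c⁻² + intercept
                          (Z*-direct rows: slope·Z*·r_c⁻² + intercept)
    - ``xic_linearity`` = slope·IC_printed + intercept vs printed X_IC

    Discrepancies are reported, never raised; rows carrying a known-issue
    flag for a column are excluded from that column's pass/fail decision.
    """
    if known_issues is None:
        known_issues = load_known_issues()
    flags: Dict[Tuple[str, int], List[KnownIssue]] = {}
    for issue in known_issues:
        flags.setdefault((issue.symbol, issue.charge), []).append(issue)

    deltas: Dict[str, Dict[str, float]] = {}
    row_passed: Dict[str, bool] = {}
    flagged: Dict[str, List[KnownIssue]] = {}
    failures: Dict[str, List[str]] = {}
    for row in rows:
        d: Dict[str, float] = {}
        d["rc_inv"] = abs(row.rc_inv - 1.0 / row.r_c)
        d["n_star_rc_inv"] = abs(row.n_star_rc_inv - row.n_star / row.r_c)
        if row.z_star_direct:
            ic_hat = row.z_star / row.r_c
            force_hat = row.z_star / row.r_c**2
        else:
            z_hat = effective_nuclear_charge(row.n_star, row.i_av, coeffs)
            d["z_star"] = abs(row.z_star - z_hat)
            ic_hat = z_hat / row.r_c
            force_hat = (
                effective_nuclear_charge(row.n_star, row.i_z, coeffs) / row.r_c**2
                if row.i_z is not None
                else None
            )
        d["ic"] = abs(row.ic - ic_hat)
        d["x_ic"] = abs(row.x_ic - (coeffs.xic_slope * ic_hat + coeffs.xic_intercept))
        if force_hat is not None:
            d["x_z"] = abs(row.x_z - (coeffs.xz_slope * force_hat + coeffs.xz_intercept))
        d["xic_linearity"] = abs(
            row.x_ic - (coeffs.xic_slope * row.ic + coeffs.xic_intercept)
        )
        row_flags = flags.get((row.symbol, row.charge), [])
        flagged_cols = {f.column for f in row_flags}
        bad = [c for c, v in d.items() if v > tolerance and c not in flagged_cols]
        deltas[row.label] = d
        row_passed[row.label] = not bad
        if bad:
            failures[row.label] = bad
        if row_flags:
            flagged[row.label] = list(row_flags)
    return ValidationReport(
        tolerance=tolerance,
        deltas=deltas,
        row_passed=row_passed,
        flagged=flagged,
        failures=failures,
    )
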