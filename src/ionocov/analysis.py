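"""Trend, ordering and correlation utilities built on the IC descriptor.

These quantify the model's qualitative claims: the diagonal relationship of
the top periods, strict orderings of IC along printed chains (chalcogen
acidity, the Irving-Williams series, halogen softness), rank/linear
correlations of IC against external properties (Mossbauer isomer shifts,
lattice energies, formation constants), cation polarizing-power
comparisons, and the Born-Lande lattice energy the IC potential is
correlated with.

Correlation claims in the source material are qualitative ("agrees well");
they are quantified here as rank correlations and only sign/monotonicity is
asserted, since no coefficients are printed.  Rank correlation uses average
ranks for ties (the lattice-energy series contains an exact tie).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import constants, stats

from .periodic_data import DatasetRow, lookup, parse_cation_label

__all__ = [
    "DiagonalPair",
    "CorrelationResult",
    "OrderingResult",
    "PolarizingComparison",
    "DEFAULT_DIAGONAL_PAIRS",
    "resolve",
    "diagonal_table",
    "correlate",
    "ordering_check",
    "born_lande",
    "polarizing_power_compare",
]

#: Default diagonal pairs: period-2 cation vs the period-3 cation one group
#: to the lower right, whose opposing n* and r_c trends nearly cancel.
DEFAULT_DIAGONAL_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("Li1+", "Mg2+"),
    ("Be2+", "Al3+"),
    ("B3+", "Si4+"),
    ("C4+", "P5+"),
    ("N5+", "S6+"),
)

_DIAGONAL_QUANTITIES = ("ic", "x_ic", "i_av", "n_star_rc_inv")

Label = Union[str, Tuple[str, int]]


def resolve(rows: Sequence[DatasetRow], label: Label) -> DatasetRow:
    """Resolve ``"Fe2+"`` or ``("Fe", 2)`` to its dataset row."""
    symbol, charge = label if isinstance(label, tuple) else parse_cation_label(label)
    return lookup(rows, symbol, charge)


def _overlay_value(
    overlay: Optional[pd.DataFrame], row: DatasetRow, quantity: str
) -> float:
    if overlay is not None:
        hit = overlay[(overlay["symbol"] == row.symbol) & (overlay["charge"] == row.charge)]
        if len(hit) and quantity in hit.columns:
            return float(hit.iloc[0][quantity])
    return row.quantity(quantity)


@dataclass(frozen=True)
class DiagonalPair:
    """One diagonal pair with its compared quantities (upper, lower, |diff|)."""

    upper: str
    lower: str
    quantities: Dict[str, Tuple[float, float, float]]

    def delta(self, quantity: str) -> float:
        return self.quantities[quantity][2]


def diagonal_table(
    rows: Sequence[DatasetRow],
    pair_spec: Sequence[Tuple[Label, Label]] = DEFAULT_DIAGONAL_PAIRS,
    overlay: Optional[pd.DataFrame] = None,
) -> List[DiagonalPair]:
    """Tabulate IC, X_IC, I_av and n*·r_c⁻¹ for each diagonal pair.

    ``overlay`` optionally supplies chart-specific printed values (an
    alternative Be/N/O parameterization) that take precedence over the
    canonical dataset where present.
    """
    table = []
    for upper_label, lower_label in pair_spec:
        upper = resolve(rows, upper_label)
        lower = resolve(rows, lower_label)
        quantities = {}
        for q in _DIAGONAL_QUANTITIES:
            u = _overlay_value(overlay, upper, q)
            v = _overlay_value(overlay, lower, q)
            quantities[q] = (u, v, abs(u - v))
        table.append(DiagonalPair(upper.label, lower.label, quantities))
    return table


@dataclass(frozen=True)
class CorrelationResult:
    property_name: str
    n: int
    method: str
    coefficient: float
    points: Tuple[Tuple[float, float], ...]


def correlate(
    series_x: Sequence[float],
    series_y: Sequence[float],
    method: str = "rank",
    property_name: str = "",
) -> CorrelationResult:
    """Rank (Spearman, average ranks for ties) or linear (Pearson) correlation."""
    x = np.asarray(series_x, dtype=float)
    y = np.asarray(series_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("absent values are not allowed")
    if method == "rank":
        coefficient = float(stats.spearmanr(x, y).statistic)
    elif method == "linear":
        coefficient = float(stats.pearsonr(x, y).statistic)
    else:
        raise ValueError(f"method must be 'rank' or 'linear', got {method!r}")
    return CorrelationResult(
        property_name=property_name,
        n=int(x.size),
        method=method,
        coefficient=coefficient,
        points=tuple(zip(x.tolist(), y.tolist())),
    )


@dataclass(frozen=True)
class OrderingResult:
    ok: bool
    quantity: str
    direction: str
    values: Tuple[float, ...]
    violations: Tuple[Tuple[str, str], ...]

    def __bool__(self) -> bool:
        return self.ok


def ordering_check(
    rows: Sequence[DatasetRow],
    labels: Sequence[Label],
    quantity: str,
    direction: str = "decreasing",
) -> OrderingResult:
    """True iff ``quantity`` is strictly ordered along ``labels``.

    Violating adjacent pairs are listed; a single label passes vacuously.
    """
    if direction not in ("decreasing", "increasing"):
        raise ValueError(f"direction must be 'decreasing' or 'increasing', got {direction!r}")
    resolved = [resolve(rows, label) for label in labels]
    values = [r.quantity(quantity) for r in resolved]
    violations = []
    for (ra, va), (rb, vb) in zip(
        zip(resolved, values), zip(resolved[1:], values[1:])
    ):
        ordered = va > vb if direction == "decreasing" else va < vb
        if not ordered:
            violations.append((ra.label, rb.label))
    return OrderingResult(
        ok=not violations,
        quantity=quantity,
        direction=direction,
        values=tuple(values),
        violations=tuple(violations),
    )


def born_lande(
    charge: int,
    madelung_constant: float,
    r0: float,
    born_exponent: float,
) -> float:
    """Born-Lande lattice energy U (kJ/mol, negative = bound).

    U = -N_A·A·z²e² / (4πε₀·r₀) · (1 - 1/n) with r₀ in Angstrom and CODATA
    physical constants.  |U| grows with z² and the Madelung constant A and
    shrinks with r₀; the Born exponent n must exceed 1 for the repulsion
    correction (1 - 1/n) to stay positive.
    """
    if charge <= 0 or madelung_constant <= 0 or r0 <= 0:
        raise ValueError("charge, madelung_constant and r0 must be positive")
    if not born_exponent > 1:
        raise ValueError(f"born_exponent must exceed 1, got {born_exponent}")
    coulomb = (
        constants.N_A
        * madelung_constant
        * charge**2
        * constants.e**2
        / (4 * np.pi * constants.epsilon_0 * r0 * 1e-10)
    )
    return -coulomb * (1 - 1 / born_exponent) / 1000.0


@dataclass(frozen=True)
class PolarizingComparison:
    """Polarizing-power (Fajans) comparison of two cations."""

    a: str
    b: str
    quantities: Dict[str, Tuple[float, float]]
    dominant: Dict[str, Optional[str]]


def polarizing_power_compare(
    rows: Sequence[DatasetRow], a: Label, b: Label
) -> PolarizingComparison:
    """Compare Z*, IC, X_IC and spatial covalency of two cations.

    The more polarizing cation (higher IC potential) induces more covalent
    character in its compounds.
    """
    ra, rb = resolve(rows, a), resolve(rows, b)
    quantities: Dict[str, Tuple[float, float]] = {}
    dominant: Dict[str, Optional[str]] = {}
    for q in ("z_star", "ic", "x_ic", "n_star_rc_inv"):
        va, vb = ra.quantity(q), rb.quantity(q)
        quantities[q] = (va, vb)
        dominant[q] = None if va == vb else (ra.label if va > vb else rb.label)
    return PolarizingComparison(a=ra.label, b=rb.label, quantities=quantities, dominant=dominant)
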