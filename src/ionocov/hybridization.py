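"""Hybrid ionicity from an element's successive ionization-energy ladder.

A k+ cation is formed by spending the first k successive ionization
energies.  The orbital-hybrid picture averages those k energies into a
single hybrid ionicity I_av (the energy of the identical hybridized valence
electrons); the k-th energy is the ultimate IE, I_z.  Both feed the IC
equations in :mod:`ionocov.ic_core`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

from .ic_core import DEFAULT_COEFFS, CationRecord, ScaleCoefficients

__all__ = ["IonizationLadder", "hybrid_ionicity", "ultimate_ie", "build_cation"]


class InsufficientLadderError(ValueError):
    """Raised when a ladder has fewer energies than the requested charge."""


@dataclass(frozen=True)
class IonizationLadder:
    """Ordered successive ionization energies of one element (eV, 1st, 2nd, ...)."""

    symbol: str
    energies: Tuple[float, ...]

    def __init__(self, symbol: str, energies: Sequence[float]) -> None:
        energies = tuple(float(e) for e in energies)
        if not energies:
            raise ValueError("ladder must contain at least one ionization energy")
        if any(e <= 0 for e in energies):
            raise ValueError("ionization energies must be strictly positive")
        if any(b <= a for a, b in zip(energies, energies[1:])):
            raise ValueError(
                f"successive ionization energies must be strictly increasing: {energies}"
            )
        object.__setattr__(self, "symbol", symbol)
        object.__setattr__(self, "energies", energies)

    def __len__(self) -> int:
        return len(self.energies)


def _check_k(ladder: IonizationLadder, k: int) -> None:
    if k < 1:
        raise ValueError(f"charge k must be >= 1, got {k}")
    if k > len(ladder):
        raise InsufficientLadderError(
            f"{ladder.symbol}: charge {k} requires {k} ionization energies, "
            f"ladder has {len(ladder)}"
        )


def hybrid_ionicity(ladder: IonizationLadder, k: int) -> float:
    """Arithmetic mean of the first k successive ionization energies (eV)."""
    _check_k(ladder, k)
    return sum(ladder.energies[:k]) / k


def ultimate_ie(ladder: IonizationLadder, k: int) -> float:
    """The k-th successive ionization energy (eV), the last one spent."""
    _check_k(ladder, k)
    return ladder.energies[k - 1]


def build_cation(
    ladder: IonizationLadder,
    k: int,
    n_star: float,
    r_c: float,
    coeffs: ScaleCoefficients = DEFAULT_COEFFS,
    atomic_number: Optional[int] = None,
    unhybridized: bool = False,
) -> CationRecord:
    """Derive a full :class:`CationRecord` for the k+ cation of ``ladder``.

    With ``unhybridized=True`` the ultimate IE replaces the hybrid ionicity
    in the IC potential, giving the (higher) unhybridized IC — e.g. carbon's
    5.702 against the energy-lowered sp3 hybrid 4.320.
    """
    i_z = ultimate_ie(ladder, k)
    i_av = i_z if unhybridized else hybrid_ionicity(ladder, k)
    return CationRecord(
        symbol=ladder.symbol,
        atomic_number=atomic_number,
        charge=k,
        n_star=n_star,
        r_c=r_c,
        i_z=i_z,
        i_av=i_av,
        coeffs=coeffs,
    )
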