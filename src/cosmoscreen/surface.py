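"""Raw molecular sigma-surfaces: charged cavity segments from continuum
solvation output.

A :class:`SigmaSurface` is the list of cavity segments produced by a
COSMO-type quantum-chemistry run: each segment carries a surface area (Å²)
and a screening charge density (e/Å²). The induced screening charge is
opposite in sign to the underlying molecular charge, so an anion with
formal charge -1 carries a total screening charge of +1 e.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: tolerance (e) for the mirror-charge invariant sum(a*sigma) = -formal_charge
CHARGE_TOL = 0.05


@dataclass
class SigmaSurface:
    """Molecular surface as an ordered collection of charged segments.

    Parameters
    ----------
    compound_id:
        Identifier, e.g. ``"EPA"`` or ``"[EMIM]"``.
    areas:
        Segment areas, Å², all positive.
    charge_densities:
        Screening charge density per segment, e/Å².
    volume:
        Cavity volume, Å³ (0 if unknown).
    formal_charge:
        Integer molecular charge in e.
    positions:
        Optional (n, 3) Cartesian segment centers, Å. Needed only for
        charge averaging; file round-trips preserve them when present.
    """

    compound_id: str
    areas: np.ndarray
    charge_densities: np.ndarray
    volume: float = 0.0
    formal_charge: int = 0
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.charge_densities = np.asarray(self.charge_densities, dtype=float)
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        if self.areas.ndim != 1 or self.areas.size == 0:
            raise ValueError("surface needs at least one segment")
        if self.charge_densities.shape != self.areas.shape:
            raise ValueError("areas and charge densities must align")
        if np.any(self.areas <= 0):
            raise ValueError("every segment area must be > 0")
        if self.positions is not None and self.positions.shape != (self.areas.size, 3):
            raise ValueError("positions must be (n_segments, 3)")
        q = self.net_screening_charge
        if abs(q + self.formal_charge) > CHARGE_TOL:
            raise ValueError(
                f"screening charge {q:+.4f} e inconsistent with formal charge "
                f"{self.formal_charge:+d} e (expected {-self.formal_charge:+d} "
                f"within {CHARGE_TOL})"
            )

    # -- derived quantities ---------------------------------------------

    @property
    def n_segments(self) -> int:
        return self.areas.size

    @property
    def total_area(self) -> float:
        """Total cavity area, Å²."""
        return float(self.areas.sum())

    @property
    def net_screening_charge(self) -> float:
        """Area-weighted total screening charge, e (≈ -formal_charge)."""
        return float(np.dot(self.areas, self.charge_densities))
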