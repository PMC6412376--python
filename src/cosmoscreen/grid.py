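"""Discretization of the screening-charge-density axis.

All charge densities are expressed in e/Å² throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SigmaGrid:
    """Uniform grid of screening-charge-density bins.

    The grid is defined by its bin *centers*: ``n_bins`` equally spaced
    points from ``sigma_min`` to ``sigma_max`` inclusive. The default
    covers [-0.025, +0.025] e/Å² with 51 bins (width 0.001 e/Å²), the
    conventional discretization for sigma-profile work.
    """

    sigma_min: float = -0.025
    sigma_max: float = 0.025
    n_bins: int = 51

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("grid needs at least 2 bins")
        if not (self.sigma_min < 0.0 < self.sigma_max):
            raise ValueError("grid must straddle sigma = 0")

    @property
    def bin_width(self) -> float:
        return (self.sigma_max - self.sigma_min) / (self.n_bins - 1)

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.sigma_min, self.sigma_max, self.n_bins)

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        return abs(self.sigma_min + self.sigma_max) < tol

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SigmaGrid):
            return NotImplemented
        return (
            abs(self.sigma_min - other.sigma_min) < 1e-12
            and abs(self.sigma_max - other.sigma_max) < 1e-12
            and self.n_bins == other.n_bins
        )

    def __hash__(self) -> int:
        return hash((round(self.sigma_min, 12), round(self.sigma_max, 12), self.n_bins))
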