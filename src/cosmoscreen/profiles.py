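"""Sigma-profiles: binned distributions of surface area over screening
charge density, and the operations that build and combine them.

The sigma-profile p(σ) is the whole molecular descriptor of the model: for
compound *i*, p_i(σ) is the amount of cavity surface area whose screening
charge density falls at σ. A solvent mixture's profile is the
mole-fraction-weighted sum of its components' profiles,

    p_S(σ) = Σ_i  X_i · p_i(σ),

and the profile of one compound is the area histogram of its segments,
p_i(σ) = A_i(σ) (absolute form, Å² per bin) or A_i(σ)/A_i (normalized
form). Profiles are conventionally split into three polarity regions at
±0.01 e/Å²: hydrogen-bond-donor surface (σ < -0.01), non-polar surface
(|σ| ≤ 0.01), and hydrogen-bond-acceptor surface (σ > +0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import SigmaGrid
from .surface import SigmaSurface

logger = logging.getLogger(__name__)

#: conventional polarity-region boundary, e/Å²
REGION_CUTOFF = 0.01


@dataclass
class SigmaProfile:
    """Area distribution p(σ) of a compound (or mixture) on a sigma grid.

    ``p`` holds area per bin. In the absolute form (``normalized=False``)
    Σp equals the total cavity area in Å²; in the normalized form Σp = 1
    and ``total_area`` remembers the original area.
    """

    grid: SigmaGrid
    p: np.ndarray
    compound_id: str = ""
    total_area: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.grid.n_bins,):
            raise ValueError("profile length must match grid")
        if np.any(self.p < -1e-12):
            raise ValueError("profile must be non-negative")
        self.p = np.clip(self.p, 0.0, None)
        s = float(self.p.sum())
        if self.total_area is None:
            self.total_area = 1.0 if self.normalized else s
        if self.normalized:
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"normalized profile sums to {s}, not 1")
        elif self.total_area > 0 and abs(s - self.total_area) > 1e-6 * max(1.0, self.total_area):
            raise ValueError("profile area inconsistent with total_area")

    # -- derived --------------------------------------------------------

    @property
    def net_screening_charge(self) -> float:
        """First moment Σ σ·p(σ), e, of the absolute profile."""
        scale = self.total_area if self.normalized else 1.0
        return float(np.dot(self.grid.centers, self.p)) * scale

    def normalize(self) -> "SigmaProfile":
        """Return the unit-sum (probability) form of this profile."""
        s = float(self.p.sum())
        if s <= 0:
            raise ValueError("cannot normalize an empty profile")
        if self.normalized:
            return self
        return SigmaProfile(
            grid=self.grid,
            p=self.p / s,
            compound_id=self.compound_id,
            total_area=self.total_area,
            normalized=True,
        )

    def to_absolute(self) -> "SigmaProfile":
        if not self.normalized:
            return self
        return SigmaProfile(
            grid=self.grid,
            p=self.p * self.total_area,
            compound_id=self.compound_id,
            total_area=self.total_area,
            normalized=False,
        )


@dataclass
class MixtureSpec:
    """Components of a solvent ensemble with their mole fractions."""

    components: list[tuple[SigmaProfile, float]]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        xs = np.array([x for _, x in self.components], dtype=float)
        if np.any(xs < 0):
            raise ValueError("mole fractions must be >= 0")
        if abs(xs.sum() - 1.0) > 1e-12:
            raise ValueError(f"mole fractions sum to {xs.sum()}, not 1")


@dataclass
class RegionDecomposition:
    """Surface area split into donor / non-polar / acceptor regions."""

    compound_id: str
    hbd_area: float
    nonpolar_area: float
    hba_area: float
    cutoff: float

    @property
    def total_area(self) -> float:
        return self.hbd_area + self.nonpolar_area + self.hba_area

    @property
    def nonpolar_fraction(self) -> float:
        t = self.total_area
        return self.nonpolar_area / t if t > 0 else 0.0


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------


def average_charges(surface: SigmaSurface, r_av: float = 0.5) -> SigmaSurface:
    """Smooth segment charge densities over an averaging radius.

    Raw cavity segments are much smaller than a thermodynamically
    effective contact patch, so each segment's density is replaced by a
    distance-weighted average over its neighbourhood with the radial
    kernel

        w_ij ∝ (r_j² r_av²)/(r_j² + r_av²) · exp(-d_ij²/(r_j² + r_av²)),

    where r_j is the radius of segment j (from its area) and d_ij the
    center distance. Total area is untouched. A uniform density offset
    is applied afterwards so the net screening charge is conserved
    exactly, since row-normalized kernel smoothing conserves it only
    approximately. Surfaces without segment positions are returned
    unchanged (with a logged notice) — there is no geometry to average
    over.
    """
    if r_av <= 0:
        raise ValueError("averaging radius must be > 0")
    if surface.positions is None:
        logger.info(
            "surface %s has no segment positions; charge averaging skipped",
            surface.compound_id,
        )
        return surface

    r2 = surface.areas / np.pi  # segment radius squared
    d2 = np.sum(
        (surface.positions[:, None, :] - surface.positions[None, :, :]) ** 2, axis=2
    )
    denom = r2[None, :] + r_av**2
    w = (r2[None, :] * r_av**2 / denom) * np.exp(-d2 / denom)
    sigma_av = (w @ surface.charge_densities) / w.sum(axis=1)

    # exact net-charge restoration (uniform shift over the cavity)
    q0 = surface.net_screening_charge
    q1 = float(np.dot(surface.areas, sigma_av))
    sigma_av = sigma_av + (q0 - q1) / surface.total_area

    return SigmaSurface(
        compound_id=surface.compound_id,
        areas=surface.areas.copy(),
        charge_densities=sigma_av,
        volume=surface.volume,
        formal_charge=surface.formal_charge,
        positions=surface.positions.copy(),
    )


def bin_profile(surface: SigmaSurface, grid: SigmaGrid | None = None) -> SigmaProfile:
    """Histogram a surface's segments onto a sigma grid.

    Each segment's area is split linearly between the two bin centers
    bracketing its charge density, which conserves both total area and
    the first charge moment of every segment. Densities outside the grid
    are clipped to the edge bins with a logged warning.
    """
    grid = grid or SigmaGrid()
    centers = grid.centers
    h = grid.bin_width

    sigma = surface.charge_densities
    n_out = int(np.sum((sigma < centers[0]) | (sigma > centers[-1])))
    if n_out:
        logger.warning(
            "%s: %d segment(s) outside grid [%g, %g]; clipped",
            surface.compound_id,
            n_out,
            centers[0],
            centers[-1],
        )
    sigma = np.clip(sigma, centers[0], centers[-1])

    pos = (sigma - centers[0]) / h
    lo = np.clip(np.floor(pos).astype(int), 0, grid.n_bins - 2)
    frac = pos - lo
    p = np.zeros(grid.n_bins)
    np.add.at(p, lo, surface.areas * (1.0 - frac))
    np.add.at(p, lo + 1, surface.areas * frac)

    return SigmaProfile(
        grid=grid,
        p=p,
        compound_id=surface.compound_id,
        total_area=surface.total_area,
        normalized=False,
    )


def mix_profiles(spec: MixtureSpec, compound_id: str = "mixture") -> SigmaProfile:
    """Mole-fraction-weighted mixture profile p_S(σ) = Σ X_i p_i(σ)."""
    grid = spec.components[0][0].grid
    norm = spec.components[0][0].normalized
    for prof, _ in spec.components[1:]:
        if prof.grid != grid:
            raise ValueError("all mixture components must share one grid")
        if prof.normalized != norm:
            raise ValueError("mixture components must share a normalization convention")

    p = np.zeros(grid.n_bins)
    area = 0.0
    for prof, x in spec.components:
        p += x * prof.p
        area += x * (prof.total_area or 0.0)

    if norm:
        # convex combination of unit-sum profiles is unit-sum
        return SigmaProfile(grid=grid, p=p, compound_id=compound_id,
                            total_area=area, normalized=True)
    return SigmaProfile(grid=grid, p=p, compound_id=compound_id, normalized=False)


def classify_regions(
    profile: SigmaProfile, cutoff: float = REGION_CUTOFF
) -> RegionDecomposition:
    """Split a profile's area into HB-donor, non-polar, and HB-acceptor
    regions at ±cutoff e/Å².

    Surface with σ below -cutoff is hydrogen-bond-donor-like (it screens
    positive nuclei, e.g. acidic H), surface above +cutoff is
    acceptor-like, and the band in between is non-polar.
    """
    if cutoff <= 0:
        raise ValueError("region cutoff must be > 0")
    centers = profile.grid.centers
    p = profile.p
    hbd = float(p[centers < -cutoff].sum())
    hba = float(p[centers > cutoff].sum())
    nonpolar = float(p.sum()) - hbd - hba
    return RegionDecomposition(
        compound_id=profile.compound_id,
        hbd_area=hbd,
        nonpolar_area=nonpolar,
        hba_area=hba,
        cutoff=cutoff,
    )
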