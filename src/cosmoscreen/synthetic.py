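"""Seeded synthetic sigma-surfaces and sigma-profiles.

Real sigma-profiles come from continuum-solvation quantum chemistry; the
generators here produce Gaussian-mixture stand-ins with the same
structural features, so the whole pipeline is testable without any
quantum-chemistry run. After mixture synthesis the profile is projected
(non-negative least-distance with two equality constraints) so that it
carries *exactly* the requested total area and net screening charge.

The packaged fixture library emulates the cast of an ionic-liquid screen
for a long-chain omega-3 fatty-acid solute:

* an EPA-like solute — almost entirely non-polar surface with small
  hydrogen-bond donor (carboxylic OH) and acceptor (carbonyl O)
  shoulders;
* compact inorganic anions (chloride-, bromide-, sulfate-like) whose
  small cavities concentrate the screening charge at high +σ, versus
  diffuse fluorinated anions (Tf2N-like) that spread it thin;
* cation families whose non-polar area grows with alkyl chain length
  while the charged head group stays fixed.

Fixture geometry (cavity areas in Å², charge placement) uses typical
literature magnitudes for these ions; the library makes no attempt to
match any specific compound's published profile quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import SigmaGrid
from .profiles import SigmaProfile
from .surface import SigmaSurface


@dataclass(frozen=True)
class ProfileSpec:
    """Recipe for one synthetic profile.

    ``peaks`` is a list of (center e/Å², width e/Å², weight fraction)
    Gaussian components; weights must be non-negative and sum to 1.
    """

    total_area: float
    formal_charge: int = 0
    peaks: tuple[tuple[float, float, float], ...] = ((0.0, 0.004, 1.0),)
    seed: int = 0
    compound_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.total_area <= 0:
            raise ValueError("total_area must be > 0")
        if not self.peaks:
            raise ValueError("at least one peak required")
        w = np.array([p[2] for p in self.peaks], dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("peak weights must be >= 0 and sum to 1")
        if any(p[1] <= 0 for p in self.peaks):
            raise ValueError("peak widths must be > 0")


def _project_moments(
    p0: np.ndarray, sigma: np.ndarray, area: float, charge_sum: float
) -> np.ndarray:
    """Least-distance projection of p0 >= 0 onto
    {p >= 0, Σp = area, Σ σ·p = charge_sum}.

    Active-set scheme: correct onto the affine subspace along the
    constraint normals, clamp negative entries to zero, repeat on the
    free set. Raises if the constraints are infeasible on the grid.
    """
    n = p0.size
    free = np.ones(n, dtype=bool)
    p = p0.astype(float).copy()
    for _ in range(n):
        B = np.vstack([np.ones(n), sigma])[:, free]
        c = np.array([area, charge_sum])
        defect = c - np.vstack([np.ones(n), sigma]) @ np.where(free, p, p)
        # correction restricted to free bins
        G = B @ B.T
        try:
            lam = np.linalg.solve(G, defect)
        except np.linalg.LinAlgError as exc:
            raise ValueError("moment constraints infeasible on this grid") from exc
        p_new = p.copy()
        p_new[free] = p[free] + B.T @ lam
        if np.all(p_new[free] >= -1e-12):
            p_new[p_new < 0] = 0.0
            return p_new
        # clamp the most negative bins and retry
        neg = (p_new < -1e-12) & free
        p[neg] = 0.0
        free &= ~neg
        if free.sum() < 2:
            raise ValueError("moment constraints infeasible on this grid")
    raise ValueError("moment projection did not converge")


def generate_profile(spec: ProfileSpec, grid: SigmaGrid | None = None) -> SigmaProfile:
    """Realize a spec as a profile on ``grid``: Gaussian mixture, seeded
    ruggedness, then exact projection to the requested area and charge.

    Deterministic per seed. Raises when the target mean density
    -formal_charge/total_area lies outside the grid.
    """
    grid = grid or SigmaGrid()
    target_charge = -float(spec.formal_charge)
    mean_sigma = target_charge / spec.total_area
    if not (grid.sigma_min < mean_sigma < grid.sigma_max):
        raise ValueError(
            f"required mean density {mean_sigma:+.4f} e/Å² is outside the grid"
        )

    centers = grid.centers
    p0 = np.zeros(grid.n_bins)
    for c, w, weight in spec.peaks:
        p0 += weight * np.exp(-0.5 * ((centers - c) / w) ** 2)
    s = p0.sum()
    if s <= 0:
        raise ValueError("all peaks fall outside the grid")
    p0 *= spec.total_area / s

    # mild seeded ruggedness, kept non-negative
    rng = np.random.default_rng(spec.seed)
    p0 *= np.clip(1.0 + 0.02 * rng.standard_normal(grid.n_bins), 0.0, None)

    p = _project_moments(p0, centers, spec.total_area, target_charge)
    return SigmaProfile(
        grid=grid, p=p, compound_id=spec.compound_id,
        total_area=spec.total_area, normalized=False,
    )


def generate_surface(
    spec: ProfileSpec, n_segments: int, grid: SigmaGrid | None = None
) -> SigmaSurface:
    """Realize a spec as a segment list whose binned profile converges to
    :func:`generate_profile`'s output as ``n_segments`` grows.

    Stratified sampling in cumulative-area coordinate: each segment
    carries area A/n and the area-weighted mean density of its stratum,
    which conserves total area and net charge exactly at any n. Segment
    order is shuffled per seed.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    grid = grid or SigmaGrid()
    profile = generate_profile(spec, grid)
    centers = grid.centers
    masses = profile.p
    A = profile.total_area
    seg_area = A / n_segments

    # distribute each bin's mass over the strata it spans
    dens_sum = np.zeros(n_segments)
    cum = 0.0
    for sigma_j, m in zip(centers, masses):
        if m <= 0:
            continue
        lo, hi = cum, cum + m
        k0 = min(int(lo / seg_area), n_segments - 1)
        k1 = min(int(np.nextafter(hi, lo) / seg_area), n_segments - 1)
        for k in range(k0, k1 + 1):
            overlap = min(hi, (k + 1) * seg_area) - max(lo, k * seg_area)
            if overlap > 0:
                dens_sum[k] += sigma_j * overlap
        cum = hi
    densities = dens_sum / seg_area

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n_segments)
    return SigmaSurface(
        compound_id=spec.compound_id,
        areas=np.full(n_segments, seg_area)[order],
        charge_densities=densities[order],
        formal_charge=spec.formal_charge,
        positions=None,
    )


# ----------------------------------------------------------------------
# packaged fixture library
# ----------------------------------------------------------------------

#: anion fixtures: cavity area Å², formal charge, charged-peak width,
#: fraction of surface in the charged peak (rest is non-polar organic skin)
ANION_SPECS: dict[str, tuple[float, int, float, float]] = {
    "[Cl]": (48.0, -1, 0.0018, 1.00),
    "[Br]": (57.0, -1, 0.0018, 1.00),
    "[BF4]": (92.0, -1, 0.0030, 0.95),
    "[PF6]": (110.0, -1, 0.0032, 0.95),
    "[NO3]": (80.0, -1, 0.0022, 0.95),
    "[DCN]": (105.0, -1, 0.0028, 0.90),
    "[DEP]": (180.0, -1, 0.0025, 0.55),
    "[AlCl4]": (140.0, -1, 0.0030, 0.95),
    "[MeSO4]": (125.0, -1, 0.0024, 0.70),
    "[SCN]": (85.0, -1, 0.0026, 0.95),
    "[MeSO3]": (115.0, -1, 0.0024, 0.70),
    "[EtSO4]": (150.0, -1, 0.0024, 0.60),
    "[Benzoate]": (140.0, -1, 0.0024, 0.55),
    "[SO4]": (92.0, -2, 0.0022, 1.00),
    "[HSO4]": (100.0, -1, 0.0024, 0.85),
    "[DMP]": (150.0, -1, 0.0025, 0.60),
    "[Propanoate]": (110.0, -1, 0.0024, 0.65),
    "[TOS]": (185.0, -1, 0.0026, 0.45),
    "[OTf]": (125.0, -1, 0.0035, 0.80),
    "[NHTf2]": (160.0, -1, 0.0040, 0.70),
    "[TFA]": (115.0, -1, 0.0030, 0.75),
    "[Tf2N]": (230.0, -1, 0.0050, 0.55),
}

#: cation fixtures: cavity area Å²; every cation carries a fixed 77 Å²
#: charged head (screening density -0.013 e/Å², past the HB-donor
#: threshold, as for acidic ring protons), so longer alkyl chains only
#: add non-polar surface
CATION_AREAS: dict[str, float] = {
    "[EMIM]": 150.0,
    "[BMIM]": 195.0,
    "[HMIM]": 240.0,
    "[OMIM]": 285.0,
    "[EMPyr]": 160.0,
    "[BMPyr]": 205.0,
    "[HMPyr]": 250.0,
    "[OMPyr]": 295.0,
    "[EMPyrro]": 165.0,
    "[BMPyrro]": 210.0,
    "[HMPyrro]": 255.0,
    "[MOPyrro]": 300.0,
    "[MPPIP]": 190.0,
    "[BMPIP]": 212.0,
    "[HMPIP]": 257.0,
    "[TMAm]": 118.0,
}

_CATION_HEAD_AREA = 77.0  # Å² of charged head surface per cation
_CATION_HEAD_WIDTH = 0.002
_NONPOLAR_WIDTH = 0.003

#: EPA-like solute: ~92% non-polar surface plus a small strong-donor
#: shoulder (the single carboxylic OH, σ ≈ -0.016) and a moderate
#: acceptor shoulder (the two carbonyl/hydroxyl oxygens, σ ≈ +0.012)
EPA_SPEC = ProfileSpec(
    total_area=430.0,
    formal_charge=0,
    peaks=(
        (0.0, 0.0035, 0.92),
        (-0.016, 0.002, 0.03),
        (+0.012, 0.002, 0.05),
    ),
    compound_id="EPA",
)


def anion_spec(ion_id: str, seed: int = 0) -> ProfileSpec:
    area, charge, width, f_polar = ANION_SPECS[ion_id]
    center = -charge / (area * f_polar)  # screening charge mirrors ion charge
    peaks: list[tuple[float, float, float]] = [(center, width, f_polar)]
    if f_polar < 1.0:
        peaks.append((0.0, _NONPOLAR_WIDTH, 1.0 - f_polar))
    return ProfileSpec(
        total_area=area, formal_charge=charge, peaks=tuple(peaks),
        seed=seed, compound_id=ion_id,
    )


def cation_spec(ion_id: str, seed: int = 0) -> ProfileSpec:
    area = CATION_AREAS[ion_id]
    f_head = _CATION_HEAD_AREA / area
    center = -1.0 / _CATION_HEAD_AREA  # head carries the full +1 charge
    return ProfileSpec(
        total_area=area,
        formal_charge=+1,
        peaks=(
            (center, _CATION_HEAD_WIDTH, f_head),
            (0.0, _NONPOLAR_WIDTH, 1.0 - f_head),
        ),
        seed=seed,
        compound_id=ion_id,
    )


def fixture_library(
    grid: SigmaGrid | None = None, seed: int = 0
) -> dict[str, SigmaProfile]:
    """All packaged fixture profiles: the EPA-like solute plus the full
    16-cation / 22-anion ion cast, keyed by manifest id."""
    grid = grid or SigmaGrid()
    lib: dict[str, SigmaProfile] = {}
    rng = np.random.default_rng(seed)
    for build, ids in ((cation_spec, CATION_AREAS), (anion_spec, ANION_SPECS)):
        for ion_id in ids:
            sub = int(rng.integers(0, 2**31 - 1))
            lib[ion_id] = generate_profile(build(ion_id, seed=sub), grid)
    epa = ProfileSpec(
        total_area=EPA_SPEC.total_area,
        formal_charge=EPA_SPEC.formal_charge,
        peaks=EPA_SPEC.peaks,
        seed=int(rng.integers(0, 2**31 - 1)),
        compound_id="EPA",
    )
    lib["EPA"] = generate_profile(epa, grid)
    return lib
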