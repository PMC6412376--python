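"""File formats: COSMO segment files, sigma-profile tables, and the
screening manifest.

The COSMO dialect follows the TURBOMOLE ``$segment_information`` layout:
a keyword-delimited text file whose segment block holds one line per
cavity segment with (index, atom, x, y, z, charge, area, charge/area)
columns. Column positions are configurable for foreign dialects; unknown
trailing columns are ignored. Charge densities are stored in e/Å²; inputs
declaring e/nm² are converted on read.

Sigma-profile tables are plain two-column (σ, p(σ)) text with ``#``
comments, the layout used by the public sigma-profile databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .grid import SigmaGrid
from .profiles import SigmaProfile
from .surface import SigmaSurface

logger = logging.getLogger(__name__)


class CosmoParseError(ValueError):
    """Raised when a COSMO or profile file cannot be parsed."""


# ----------------------------------------------------------------------
# COSMO segment files
# ----------------------------------------------------------------------

_SEGMENT_KEY = "$segment_information"


def read_cosmo_file(
    path: str | Path,
    *,
    area_col: int = 6,
    sigma_col: int = 7,
    position_cols: tuple[int, int, int] = (2, 3, 4),
    sigma_unit: str = "e/A^2",
) -> SigmaSurface:
    """Parse a TURBOMOLE-style ``.cosmo`` file into a :class:`SigmaSurface`.

    Parameters
    ----------
    area_col, sigma_col, position_cols:
        Zero-based column indices in the segment block. Defaults match
        the layout written by :func:`write_cosmo_file`.
    sigma_unit:
        ``"e/A^2"`` (native) or ``"e/nm^2"`` (converted by 1e-2 on read).
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    compound_id = path.stem
    volume = 0.0
    formal_charge = 0
    has_positions = True
    seg_start = None

    for i, line in enumerate(lines):
        s = line.strip()
        if s.startswith(_SEGMENT_KEY):
            seg_start = i + 1
            break
        if s.startswith("$info"):
            if i + 1 < len(lines) and lines[i + 1].strip():
                compound_id = lines[i + 1].strip()
        elif "=" in s and not s.startswith("#"):
            key, _, val = (t.strip() for t in s.partition("="))
            if key == "volume":
                volume = float(val)
            elif key == "formal_charge":
                formal_charge = int(float(val))
            elif key == "positions" and val == "absent":
                has_positions = False

    if seg_start is None:
        raise CosmoParseError(
            f"{path}: no '{_SEGMENT_KEY}' section found"
        )

    areas, sigmas, xyz = [], [], []
    for lineno, line in enumerate(lines[seg_start:], start=seg_start + 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith("$"):
            break
        cols = s.split()
        try:
            areas.append(float(cols[area_col]))
            sigmas.append(float(cols[sigma_col]))
            if has_positions:
                xyz.append([float(cols[c]) for c in position_cols])
        except (ValueError, IndexError) as exc:
            raise CosmoParseError(
                f"{path}:{lineno}: malformed segment line: {s!r}"
            ) from exc

    if not areas:
        raise CosmoParseError(f"{path}: segment block is empty")

    sigma_arr = np.array(sigmas)
    if sigma_unit == "e/nm^2":
        sigma_arr = sigma_arr * 1e-2
    elif sigma_unit != "e/A^2":
        raise ValueError(f"unknown sigma unit {sigma_unit!r}")

    return SigmaSurface(
        compound_id=compound_id,
        areas=np.array(areas),
        charge_densities=sigma_arr,
        volume=volume,
        formal_charge=formal_charge,
        positions=np.array(xyz) if has_positions else None,
    )


def write_cosmo_file(surface: SigmaSurface, path: str | Path) -> None:
    """Write a surface in the dialect read by :func:`read_cosmo_file`.

    Numeric fields are written at full double precision so a
    write-read round trip reproduces the surface exactly.
    """
    surface.validate()
    path = Path(path)
    out = [
        "$info",
        surface.compound_id,
        "$cosmo_data",
        f"  area = {surface.total_area:.17g}",
        f"  volume = {surface.volume:.17g}",
        f"  formal_charge = {surface.formal_charge}",
    ]
    if surface.positions is None:
        out.append("  positions = absent")
    out.append(_SEGMENT_KEY)
    out.append("#  n  atom  x / A  y / A  z / A  charge / e  area / A^2  charge/area / e/A^2")
    for i in range(surface.n_segments):
        a = surface.areas[i]
        sig = surface.charge_densities[i]
        if surface.positions is None:
            x = y = z = 0.0
        else:
            x, y, z = surface.positions[i]
        out.append(
            f"  {i + 1}  0  {x:.17g}  {y:.17g}  {z:.17g}  "
            f"{a * sig:.17g}  {a:.17g}  {sig:.17g}"
        )
    out.append("$end")
    path.write_text("\n".join(out) + "\n")


# ----------------------------------------------------------------------
# sigma-profile tables
# ----------------------------------------------------------------------


def read_sigma_profile(
    path: str | Path, grid: SigmaGrid | None = None, compound_id: str | None = None
) -> SigmaProfile:
    """Read a two-column (σ, p(σ)) table, re-binning onto ``grid``.

    Rows must be sorted by strictly increasing σ and non-negative in p.
    When the file's σ values coincide with the grid centers the values
    are copied verbatim; otherwise each row's area is split linearly
    between the bracketing grid bins, conserving total area.
    """
    grid = grid or SigmaGrid()
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        cols = s.split()
        try:
            rows.append((float(cols[0]), float(cols[1])))
        except (ValueError, IndexError) as exc:
            raise CosmoParseError(f"{path}:{lineno}: malformed row: {s!r}") from exc
    if not rows:
        raise CosmoParseError(f"{path}: no data rows")

    sigma = np.array([r[0] for r in rows])
    pvals = np.array([r[1] for r in rows])
    if np.any(np.diff(sigma) <= 0):
        raise ValueError(f"{path}: sigma values must be strictly increasing")
    if np.any(pvals < 0):
        raise ValueError(f"{path}: negative p(sigma) value")

    centers = grid.centers
    cid = compound_id or path.stem

    if sigma.size == grid.n_bins and np.allclose(sigma, centers, atol=1e-12):
        p = pvals.copy()
    else:
        # linear mass re-binning: conserves total area exactly
        h = grid.bin_width
        pos = np.clip((sigma - centers[0]) / h, 0.0, grid.n_bins - 1.0)
        lo = np.clip(np.floor(pos).astype(int), 0, grid.n_bins - 2)
        frac = pos - lo
        p = np.zeros(grid.n_bins)
        np.add.at(p, lo, pvals * (1.0 - frac))
        np.add.at(p, lo + 1, pvals * frac)

    return SigmaProfile(grid=grid, p=p, compound_id=cid, normalized=False)


def write_sigma_profile(profile: SigmaProfile, path: str | Path) -> None:
    """Write a profile as a two-column text table."""
    prof = profile.to_absolute()
    lines = [
        f"# sigma profile: {prof.compound_id}",
        f"# total area / A^2: {prof.total_area:.17g}",
        "# sigma / e/A^2    p(sigma) / A^2",
    ]
    for s, v in zip(prof.grid.centers, prof.p):
        lines.append(f"{s: .6f}  {v:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# screening manifest
# ----------------------------------------------------------------------


@dataclass
class ScreeningManifest:
    """The cation and anion lists defining a combinatorial screen."""

    cations: list[tuple[str, int]]
    anions: list[tuple[str, int]]
    solute_id: str
    temperature: float = 298.15

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.cations] + [j for j, _ in self.anions]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate ion id(s) in manifest: {sorted(dupes)}")
        if any(q <= 0 for _, q in self.cations):
            raise ValueError("cation charges must be positive")
        if any(q >= 0 for _, q in self.anions):
            raise ValueError("anion charges must be negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")

    @property
    def n_combinations(self) -> int:
        return len(self.cations) * len(self.anions)

    @property
    def ion_ids(self) -> list[str]:
        return [i for i, _ in self.cations] + [j for j, _ in self.anions]

    def charges(self) -> dict[str, int]:
        return dict(self.cations) | dict(self.anions)


def read_manifest(path: str | Path) -> ScreeningManifest:
    """Load a YAML screening manifest.

    Expected keys: ``solute`` (str), ``temperature`` (K, optional,
    default 298.15 with a logged notice), ``cations`` and ``anions``
    (lists of ``{id, charge}`` mappings or plain id strings with
    default charges +1 / -1).
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise CosmoParseError(f"{path}: manifest must be a mapping")

    def _ions(key: str, default_q: int) -> list[tuple[str, int]]:
        out = []
        for entry in doc.get(key, []):
            if isinstance(entry, str):
                out.append((entry, default_q))
            else:
                out.append((str(entry["id"]), int(entry.get("charge", default_q))))
        return out

    if "temperature" in doc:
        temperature = float(doc["temperature"])
    else:
        temperature = 298.15
        logger.info("%s: no temperature given, defaulting to 298.15 K", path)

    return ScreeningManifest(
        cations=_ions("cations", +1),
        anions=_ions("anions", -1),
        solute_id=str(doc.get("solute", "")),
        temperature=temperature,
    )


def default_manifest() -> ScreeningManifest:
    """The packaged 16-cation x 22-anion screening manifest."""
    from importlib.resources import files

    return read_manifest(files("cosmoscreen.data") / "default_manifest.yaml")
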