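"""Combinatorial ionic-liquid screening: assemble cation/anion solvent
ensembles, compute γ∞ and capacity for a solute against each, and rank.

An ionic liquid is modeled as a mole-fraction ensemble of its two bare
ions. The default "equimolar" pairing uses a 1:1 ensemble regardless of
ion valence — for a monocation with a divalent anion such as sulfate the
recorded net charge is then -1 e. The "electroneutral" mode instead
scales the stoichiometry (2:1 for divalent anions) so the ensemble is
neutral.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import (
    ActivityResult,
    ConvergenceError,
    EnergyParameters,
    ln_gamma_infinite_dilution,
    solve_sigma_potential,
)
from .io import ScreeningManifest
from .profiles import MixtureSpec, SigmaProfile, mix_profiles

logger = logging.getLogger(__name__)

PAIRING_MODES = ("equimolar", "electroneutral")

#: columns of the machine-readable ranking table
RESULT_COLUMNS = [
    "rank", "ionic_liquid", "cation", "anion", "solute", "T",
    "ln_gamma_inf", "gamma_inf", "capacity_inf", "converged",
]


@dataclass
class ILSolvent:
    """One cation/anion solvent ensemble."""

    cation_id: str
    anion_id: str
    n_cat: int
    n_an: int
    profile: SigmaProfile
    net_charge: float

    @property
    def il_id(self) -> str:
        return f"{self.cation_id}{self.anion_id}"


def build_il_solvent(
    cation: SigmaProfile,
    anion: SigmaProfile,
    cation_charge: int = +1,
    anion_charge: int = -1,
    mode: str = "equimolar",
) -> ILSolvent:
    """Mix an ion pair into an IL solvent ensemble.

    ``equimolar`` takes a 1:1 ion ensemble; ``electroneutral`` picks the
    smallest integer stoichiometry with zero net charge.
    """
    if mode not in PAIRING_MODES:
        raise ValueError(f"unknown pairing mode {mode!r}; choose from {PAIRING_MODES}")
    if cation_charge <= 0 or anion_charge >= 0:
        raise ValueError("cation charge must be positive and anion charge negative")

    if mode == "equimolar":
        n_cat, n_an = 1, 1
    else:
        g = np.gcd(cation_charge, -anion_charge)
        n_cat, n_an = (-anion_charge) // g, cation_charge // g

    total = n_cat + n_an
    profile = mix_profiles(
        MixtureSpec([(cation, n_cat / total), (anion, n_an / total)]),
        compound_id=f"{cation.compound_id}{anion.compound_id}",
    )
    return ILSolvent(
        cation_id=cation.compound_id,
        anion_id=anion.compound_id,
        n_cat=n_cat,
        n_an=n_an,
        profile=profile,
        net_charge=float(n_cat * cation_charge + n_an * anion_charge),
    )


@dataclass
class RankingTable:
    """Sorted screening output with its provenance fingerprint."""

    records: pd.DataFrame
    temperature: float
    parameter_fingerprint: str

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_failed(self) -> int:
        return int((~self.records["converged"]).sum())


def _fingerprint(manifest: ScreeningManifest, params: EnergyParameters, mode: str) -> str:
    payload = json.dumps(
        {
            "cations": manifest.cations,
            "anions": manifest.anions,
            "solute": manifest.solute_id,
            "T": manifest.temperature,
            "params": vars(params) | {},
            "pairing": mode,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_screen(
    manifest: ScreeningManifest,
    profiles: dict[str, SigmaProfile],
    params: EnergyParameters | None = None,
    pairing: str = "equimolar",
    combinatorial: bool = False,
    volumes: dict[str, float] | None = None,
) -> RankingTable:
    """Screen every cation x anion combination against the solute.

    One record per combination, sorted by capacity descending with a
    deterministic lexicographic (cation, anion) tie-break. Combinations
    whose sigma-potential fails to converge are recorded as failed rows
    rather than dropped. Output is invariant under permutation of the
    manifest's ion order.
    """
    params = (params or EnergyParameters()).at_temperature(manifest.temperature)
    charges = manifest.charges()

    missing = [i for i in manifest.ion_ids + [manifest.solute_id] if i not in profiles]
    if missing:
        raise KeyError(f"no sigma-profile for id(s): {missing}")

    solute = profiles[manifest.solute_id]
    solute_potential = solve_sigma_potential(solute, params)
    solute_volume = (volumes or {}).get(manifest.solute_id)

    rows = []
    for cat_id, q_cat in sorted(manifest.cations):
        for an_id, q_an in sorted(manifest.anions):
            il = build_il_solvent(
                profiles[cat_id], profiles[an_id],
                cation_charge=q_cat, anion_charge=q_an, mode=pairing,
            )
            try:
                res = ln_gamma_infinite_dilution(
                    solute,
                    il.profile,
                    params,
                    combinatorial=combinatorial,
                    solute_volume=solute_volume,
                    solvent_volume=_il_volume(volumes, il) if combinatorial else None,
                    solute_self_potential=solute_potential,
                )
                rows.append(
                    (il.il_id, cat_id, an_id, manifest.solute_id, params.T,
                     res.ln_gamma_inf, res.gamma_inf, res.capacity_inf, True)
                )
            except ConvergenceError as exc:
                logger.error("combination %s%s failed: %s", cat_id, an_id, exc)
                rows.append(
                    (il.il_id, cat_id, an_id, manifest.solute_id, params.T,
                     np.nan, np.nan, np.nan, False)
                )

    df = pd.DataFrame(
        rows,
        columns=RESULT_COLUMNS[1:],  # rank added after sorting
    )
    df = df.sort_values(
        by=["capacity_inf", "cation", "anion"],
        ascending=[False, True, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))

    return RankingTable(
        records=df,
        temperature=params.T,
        parameter_fingerprint=_fingerprint(manifest, params, pairing),
    )


def _il_volume(volumes: dict[str, float] | None, il: ILSolvent) -> float | None:
    if not volumes:
        return None
    try:
        tot = il.n_cat + il.n_an
        return (il.n_cat * volumes[il.cation_id] + il.n_an * volumes[il.anion_id]) / tot
    except KeyError:
        return None


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------


def report_table(ranking: RankingTable, top_n: int = 21) -> str:
    """Human-readable shortlist: rank, IL, γ∞, C∞ (3 significant
    figures, scientific notation)."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    df = ranking.records.head(top_n)
    lines = [f"{'#':>3}  {'ionic liquid':<24} {'gamma_inf':>12} {'capacity_inf':>12}"]
    for _, r in df.iterrows():
        lines.append(
            f"{r['rank']:>3}  {r['ionic_liquid']:<24} "
            f"{r['gamma_inf']:>12.3g} {r['capacity_inf']:>12.3g}"
        )
    return "\n".join(lines)


def write_ranking(ranking: RankingTable, path: str | Path) -> None:
    """Write the full ranking as a TSV at full float precision."""
    df = ranking.records.copy()
    for col in ("T", "ln_gamma_inf", "gamma_inf", "capacity_inf"):
        df[col] = df[col].map(lambda v: f"{v:.17g}")
    df.to_csv(path, sep="\t", index=False)


def read_ranking(path: str | Path) -> pd.DataFrame:
    """Read back a ranking TSV written by :func:`write_ranking`."""
    return pd.read_csv(path, sep="\t")


def write_metadata(
    ranking: RankingTable, manifest: ScreeningManifest,
    params: EnergyParameters, path: str | Path,
) -> None:
    """JSON sidecar recording the run's parameters and fingerprint."""
    meta = {
        "temperature": ranking.temperature,
        "n_records": ranking.n_records,
        "n_failed": ranking.n_failed,
        "n_cations": len(manifest.cations),
        "n_anions": len(manifest.anions),
        "solute": manifest.solute_id,
        "parameters": {k: float(v) for k, v in vars(params).items()},
        "fingerprint": ranking.parameter_fingerprint,
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
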