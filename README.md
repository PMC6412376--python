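# cosmoscreen

σ-profile statistical thermodynamics for screening ionic-liquid
solvents.

`cosmoscreen` ranks every cation/anion combination of a screening
manifest as an extraction solvent for a chosen solute. A molecule is
described entirely by its σ-profile p(σ) — the distribution of its
cavity surface area over screening charge density σ (e/Å²). For each
candidate solvent ensemble S the package solves the self-consistent
σ-potential

μ_S(σ) = −(RT/a_eff) · ln Σ_σ′ P_S(σ′) · exp[(a_eff/RT)(μ_S(σ′) − E_mf(σ,σ′) − E_hb(σ,σ′))]

with misfit and hydrogen-bond contact energies E_mf = (α′/2)(σ+σ′)² and
E_hb = c_hb·max(0, σ_acc−σ_hb)·min(0, σ_don+σ_hb), forms the
infinite-dilution activity coefficient of the solute X

ln γ∞ = [μ_X(in S) − μ_X(in pure X)] / RT,

and ranks all combinations by extraction capacity C∞ = 1/γ∞. Ionic
liquids are modeled as mole-fraction ensembles of their bare ions
(equimolar by default, or electroneutral stoichiometry). See
[docs/methods.md](docs/methods.md) for the full model, parameter
defaults, solver design, and limitations.

Real σ-profiles come from continuum-solvation quantum chemistry
(TURBOMOLE-style COSMO files are supported); for development and
testing the package ships a seeded synthetic fixture library — an
EPA-like (omega-3 fatty acid) solute plus 16 cations and 22 anions —
whose profiles carry exact area and net-charge moments.

## Worked example

Screen the full packaged manifest (16 cations × 22 anions = 352
combinations) against the synthetic EPA-like solute:

```
$ cosmoscreen screen --seed 1 --top 10 --out run
  #  ionic liquid                gamma_inf capacity_inf
  1  [TMAm][SO4]                   3.6e-62     2.78e+61
  2  [EMIM][SO4]                  3.68e-49     2.72e+48
  3  [EMPyr][SO4]                 6.57e-48     1.52e+47
  4  [EMPyrro][SO4]               1.09e-46      9.2e+45
  5  [MPPIP][SO4]                 1.58e-44     6.35e+43
  6  [BMIM][SO4]                  2.79e-44     3.58e+43
  7  [BMPyr][SO4]                 2.19e-43     4.57e+42
  8  [BMPIP][SO4]                  5.6e-43     1.78e+42
  9  [BMPyrro][SO4]               7.15e-43      1.4e+42
 10  [HMIM][SO4]                  4.62e-42     2.17e+41
```

The run writes `run/ranking.tsv` (full precision, byte-reproducible)
and `run/metadata.json` (parameters and a provenance fingerprint). The
shortlist shows the qualitative structure the model is built to
capture: compact high-charge-density anions dominate, shorter-chain
cations beat their longer homologues, and the small
tetramethylammonium/sulfate pair tops the table. Absolute capacities
from synthetic fixtures are not comparable to experimental values —
see docs/methods.md.

The same computation from Python:

```python
from cosmoscreen import (SigmaGrid, EnergyParameters, fixture_library,
                         build_il_solvent, ln_gamma_infinite_dilution)

grid = SigmaGrid()                      # 51 bins on [-0.025, 0.025] e/A^2
lib = fixture_library(grid, seed=1)     # EPA + 16 cations + 22 anions
il = build_il_solvent(lib["[EMIM]"], lib["[Cl]"])
res = ln_gamma_infinite_dilution(lib["EPA"], il.profile, EnergyParameters())
print(f"ln gamma_inf = {res.ln_gamma_inf:.3f}")
print(f"gamma_inf    = {res.gamma_inf:.3e}")
print(f"capacity     = {res.capacity_inf:.3e}")
```

prints

```
ln gamma_inf = -52.061
gamma_inf    = 2.455e-23
capacity     = 4.073e+22
```

Other subcommands: `cosmoscreen profile *.cosmo` converts COSMO segment
files to σ-profile tables plus a polarity-region CSV, `cosmoscreen
synth` writes the fixture library to disk, and `cosmoscreen rank`
re-displays an existing ranking TSV. All commands exit 0 on success, 1
on runtime/data failure, 2 on usage errors.

## Layout

- `src/cosmoscreen/grid.py`, `surface.py`, `profiles.py` — σ-grid,
  segment surfaces, charge averaging/binning/mixing, region
  decomposition
- `src/cosmoscreen/io.py` — COSMO files, σ-profile tables, screening
  manifests (packaged 16 × 22 default)
- `src/cosmoscreen/engine.py` — interaction energies, σ-potential
  solver, γ∞ and capacity
- `src/cosmoscreen/screen.py` — combinatorial screen, ranking,
  reporting
- `src/cosmoscreen/synthetic.py` — seeded profile/surface generators
  and the fixture library
- `src/cosmoscreen/cli.py` — `cosmoscreen` command-line interface
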