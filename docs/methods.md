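# Methods

This note records the scientific model behind `cosmoscreen`, the
parameters it uses, the numerical choices made, and the limits of the
synthetic data the package ships with.

## Problem

Liquid–liquid extraction of a dilute solute is governed by its
infinite-dilution activity coefficient γ∞ in the candidate solvent: the
extraction capacity is C∞ = 1/γ∞, so low-γ∞ solvents are good
extractants. Ionic liquids are attractive candidates because their
cation and anion can be varied independently, giving a combinatorial
design space. `cosmoscreen` ranks every cation/anion combination of a
screening manifest by C∞ for a chosen solute, using a conductor-like
screening model (COSMO-RS-style) statistical thermodynamics in which a
molecule's entire descriptor is its σ-profile.

## Model

**σ-profile.** A continuum-solvation calculation tiles the molecular
cavity with surface segments, each with an area (Å²) and a screening
charge density σ (e/Å²). The σ-profile p(σ) is the histogram of surface
area over σ. The package reads TURBOMOLE-style COSMO segment files,
optionally smooths raw segment charges over a radius r_av (Gaussian
spatial kernel, exactly conserving total area and net screening
charge), and bins segments onto a fixed σ-grid with linear splitting
between the two bracketing bin centers, which conserves both the total
area and the first moment (net screening charge).

Default grid: σ ∈ [−0.025, +0.025] e/Å², 51 bins (0.001 e/Å² wide).
Surface patches are classified as hydrogen-bond donor (σ < −0.01),
non-polar (|σ| ≤ 0.01), or hydrogen-bond acceptor (σ > +0.01), in the
convention that screening charge is opposite in sign to the underlying
molecular charge.

**Segment interaction energies** (per unit contact area, kcal mol⁻¹ Å⁻²):

- misfit: E_mf(σ,σ′) = (α′/2)(σ + σ′)², with α′ = 8419 kcal Å⁴ mol⁻¹ e⁻²;
- hydrogen bonding: E_hb(σ,σ′) = c_hb · max(0, σ_acc − σ_hb) ·
  min(0, σ_don + σ_hb), with σ_acc = max(σ,σ′), σ_don = min(σ,σ′),
  c_hb = 85580 kcal Å⁴ mol⁻¹ e⁻², σ_hb = 0.0084 e/Å².

**σ-potential.** The chemical potential per unit area of a patch of
density σ in solvent ensemble S solves the self-consistency relation

μ_S(σ) = −(RT/a_eff) · ln Σ_σ′ P_S(σ′) · exp[(a_eff/RT)(μ_S(σ′) − E_mf − E_hb)]

with effective contact area a_eff = 7.5 Å², R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹,
T = 298.15 K by default, and P_S the area-normalized solvent profile.

**Activity coefficient.** The residual pseudo-chemical potential of
solute X in S is the contraction of X's absolute (area-weighted)
profile with μ_S. Then

ln γ∞ = [μ_X(in S) − μ_X(in pure X)] / RT,  C∞ = 1/γ∞.

Infinite dilution is realized structurally: the solvent ensemble
contains no solute, so no extrapolation in composition is needed. An
optional Staverman–Guggenheim combinatorial term (z = 10, reference
area 79.53 Å², reference volume 66.69 Å³) can be added when cavity
volumes are available; it is off by default, and it vanishes
identically for a compound in itself.

**Ionic liquids.** An IL solvent is a mole-fraction ensemble of its two
bare ions. The default "equimolar" pairing mixes cation and anion 1:1
regardless of valence — for a monocation with a divalent anion such as
sulfate the ensemble then carries a net formal charge of −1 e, which is
deliberate: it reproduces the convention of treating the printed ion
lists combinatorially. An "electroneutral" mode instead uses the
smallest integer stoichiometry with zero net charge (2:1 for divalent
anions).

## Numerics

**Solver.** The self-consistency relation is a fixed-point problem
μ = G(μ). Damped successive substitution (damping 0.4) from μ ≡ 0 is
robust but can be very slow here: strong hydrogen bonding couples the
donor and acceptor wings of the profile bipartitely, and the Jacobian
of G then has an eigenvalue near −1, so plain substitution can need
thousands of sweeps. The solver therefore interleaves substitution
sweeps with a trust-region Newton stage (Powell hybrid method with the
analytic Jacobian I + W, where W is the softmax contact-weight matrix),
retrying with progressively longer pre-relaxation (25, 100, 300, 600,
1200 sweeps, capped at `max_iter`) until the max-norm fixed-point
residual falls below `tol` (default 1e-8; converged solutions typically
reach ~1e-13). All exponentials are evaluated through log-sum-exp, so
strongly repulsive contacts underflow safely. The solve is
deterministic, and a `ConvergenceError` carries the residual and sweep
count.

Two genuinely ill-posed regimes are worth knowing about:

- on tiny toy grids with |σ| well beyond the hydrogen-bond threshold,
  the donor/acceptor coupling saturates and a numerically flat valley
  of machine-precision roots appears (only the combination μ(σ) + μ(−σ)
  is well determined there);
- a purely bipartite solvent (all area in two complementary wings, no
  central mass) has no finite σ-potential at all — the iterate drifts
  along a translation-degenerate direction. The solver reports this as
  a `ConvergenceError` rather than returning a spurious answer.

**Screening.** The screen solves one σ-potential per IL ensemble plus
one for the pure solute (cached), sorts by capacity descending with a
deterministic lexicographic tie-break, and is invariant under
permutation of the manifest's ion order. A full 16 × 22 screen (352
combinations, 51-bin profiles) takes a few seconds on one CPU. Failed
combinations are kept as rows flagged `converged = False` rather than
dropped. Rankings are written as TSV at full float precision
(`%.17g`), so re-running a screen reproduces the file byte for byte.

## Synthetic data

Real σ-profiles require quantum-chemistry runs, so the package ships a
seeded generator instead. A `ProfileSpec` is a Gaussian mixture over σ
plus a total cavity area and formal charge; the realized profile gets
2% seeded multiplicative ruggedness and is then projected (non-negative
least-distance with two equality constraints, active-set scheme) so it
carries *exactly* the requested total area and net screening charge.
Synthetic segment surfaces are drawn by stratified sampling in the
cumulative-area coordinate, which conserves both moments exactly at any
segment count and converges to the parent profile as the count grows.

The packaged fixture library emulates the cast of an IL screen for a
long-chain omega-3 fatty-acid (EPA-like) solute:

- the solute is ~95% non-polar with a small strong donor shoulder
  (carboxylic OH, σ ≈ −0.016) and a moderate acceptor shoulder
  (carbonyl/hydroxyl O, σ ≈ +0.012);
- compact inorganic anions (chloride-, bromide-, sulfate-like, cavity
  areas 48–92 Å²) concentrate their screening charge at high +σ, while
  diffuse fluorinated anions (Tf2N-like, 230 Å²) spread it thin and
  carry a large non-polar skin;
- every cation has a fixed 77 Å² charged head at σ ≈ −0.013 — past the
  donor threshold, as for acidic ring protons — so longer alkyl chains
  only add non-polar surface.

This geometry makes the screen reproduce the qualitative structure
expected on physical grounds: small high-charge-density anions give the
highest capacities (their acceptor wing pairs with the solute's donor
shoulder and the cation's acidic head), capacity falls monotonically
with cation chain length (alkyl surface dilutes the favorable polar
contacts), and the compact tetramethylammonium/sulfate combination tops
the ranking. The library makes **no** attempt to match any specific
compound's published profile quantitatively, and absolute γ∞ values
computed from it are not comparable to experimental or
quantum-chemistry-derived numbers — the fixtures exist so the entire
pipeline is exercisable and its qualitative physics checkable without
any quantum-chemistry dependency.

## Limitations

- Segment interactions use misfit + hydrogen bonding only; there is no
  dispersion term, no temperature-dependent hydrogen-bond scaling, and
  no electrostatic correction beyond the misfit quadratic.
- The combinatorial contribution is optional and requires cavity
  volumes the synthetic generator does not fabricate.
- Ions are treated as independent ensemble components; ion pairing,
  long-range Coulomb ordering, and activity of the ions themselves are
  outside the model.
- The packaged shortlist of literature-reported γ∞/C∞ values is used
  only for the reciprocal-arithmetic check C∞ = 1/γ∞; the package does
  not claim to reproduce those absolute values from its own physics.
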