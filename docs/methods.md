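# Methods

## Bond-valence model

The coordination quality of a bound cation is scored by the bond-valence
sum: every ligand oxygen at distance *r* (Å) contributes a partial valence,
and the sum over the coordination shell should equal the ion's formal
charge when coordination is ideal (1.00 for K⁺ or Rb⁺). Two standard
functional forms are implemented:

- power: `v(r) = (r/r0)^(-N)` — parameters r₀ (Å, unit-valence distance)
  and dimensionless exponent N;
- exponential: `v(r) = exp((R0 − r)/b)` — R0 (Å) and softness b (Å).

Both equal 1 at r = r₀ and decrease strictly with distance.

**K⁺–O parameters.** The default is the classic alkali–oxygen power law,
r₀ = 2.276 Å, N = 9.1. This choice is validated rather than assumed: the
test suite recomputes every per-oxygen valence of the published occluded-
state coordination table from its printed distances and requires agreement
within ±0.01 per contact and ±0.02 on the total (1.05).

**Rb⁺–O parameters.** No printed parameter source reproduces the published
Rb⁺ columns, so Rb⁺–O parameters are obtained by least squares on the 16
published (distance, valence) pairs of the two occluded Rb⁺ structures.
The fit is linear in log space (`ln v = N·ln r0 − N·ln r`), giving
r₀ ≈ 2.199 Å, N ≈ 6.76 with an RMS log-residual of 0.055 — the residual is
dominated by the two-decimal rounding of the printed valences. Applied back
to the three Rb⁺ columns the calibration reproduces totals of 1.13, 1.07
and 0.40 against the printed 1.14, 1.07 and 0.39. Calibrated parameters are
carried in the output metadata of every report that uses them.

**Shell rules.** The inclusion cutoff is 4.0 Å (ligands at exactly the
cutoff are included — closed interval). Water oxygens (HOH/WAT/SOL…) are
excluded by default because the published shells list only protein oxygens;
`include_waters=True` restores them. Hydrogens are retained on input but
never enter distance analyses unless a selection names one explicitly.

**Trajectory averaging.** Frame-averaged valences rebuild the shell per
frame under the same cutoff, so a ligand drifting out of range contributes
exactly zero in that frame; per-ligand and total means are reported with
SEM over the analysed frame window. Frames are treated as independent
samples — a deliberate simplification (MD frames are autocorrelated, so
real-trajectory SEMs are underestimates; for the synthetic i.i.d.-frame
generators the assumption is exact). The analysis window is a half-open
`[start, stop)` range, matching the common practice of analysing only the
equilibrated tail of a run.

## Interaction geometry

- **Contacts**: all cross pairs of two selections within a threshold
  (default 3.5 Å, the usual heavy-atom H-bond/electrostatic criterion);
  distance-only, no angle term.
- **Salt bridges**: distance from a single basic nitrogen to the centre of
  mass of the two carboxylate oxygens, per frame; occupancy is the fraction
  of frames at or below the bound cutoff. The default cutoff is 4.0 Å —
  a documented package default, chosen so that typical bound distances
  (2.7–3.3 Å) and unbound ones (≥ 5 Å) separate cleanly.
- **RDF**: histogram of per-frame distances between one atom and a group
  centre of mass. The default normalisation is probability density (unit
  integral over the histogram range), which is the meaningful choice for an
  intramolecular pair where no bulk density exists. `shell_normalized`
  divides counts by the ideal-gas expectation 4πr²Δr·ρ per frame (ρ from
  the box volume, or supplied explicitly) so that a homogeneous system
  gives g(r) = 1; this mode is validated against uniform ideal-gas frames.
  Bins are half-open `[lo, hi)`; minimum-image distances are used only when
  the trajectory carries a box. Axes are Å internally with an nm export.
- **Superposition/RMSD**: Kabsch least-squares rigid-body fit via SVD with
  the determinant correction, so the rotation is always proper (no
  reflection); collinear fit sets are rejected. RMSD series superpose each
  frame on an explicit fit selection before measuring the analysis
  selection — the fit set is a required argument rather than a guessed
  default, because the choice materially changes the answer.

## Transport energetics

Moving one ion against its gradient costs
`Δμ = RT·ln(c_to/c_from) + zFΔψ` (kcal/mol), with R = 1.9872×10⁻³
kcal·mol⁻¹·K⁻¹, F = 23.061 kcal·mol⁻¹·V⁻¹, activities taken as
concentrations, and proton concentrations as 10^(−pH). A stoichiometry
(n_H out, n_K in) is feasible when the summed uphill work does not exceed
|ΔG_ATP| (closed boundary). The maximum pH gradient solves that boundary
for the proton term. Defaults are the parietal-cell conditions: cytoplasm
pH 7, 120 mM K⁺; gastric juice pH 1.0, 10 mM K⁺; Δψ = 0 mV because the
exchange cycle is electroneutral (non-zero potentials are supported);
T = 310 K. At these conditions the 1:1 sum of potentials is 10.0 kcal/mol
(9.7 at 298 K — both round to the quoted "about −10", so the temperature
default is body temperature and the comparison tolerance is ±0.5). Internal
totals are positive uphill work; every report also carries the negated
`paper_sign_total` so both sign conventions are explicit.

## Hill kinetics

The fitted model is `v = v0 + (v_max − v0)·f(c)` with
`f = cⁿ/(Kⁿ+cⁿ)` (activation) or `Kⁿ/(Kⁿ+cⁿ)` (inhibition). Both the
with-basal (default) and pinned-`v0 = 0` variants are exposed, since
published activity fits do not always state which was used. Initialisation
is deterministic: v0/v_max from the data extremes, K₀.₅ from the
concentration nearest half-range, multi-start over n ∈ {0.5, 1, 2} with the
lowest residual sum of squares winning and ties broken toward the smallest
n. The main fit uses bounded trust-region least squares (n ∈ [10⁻³, 20],
K > 0); bootstrap replicates refit from the point estimate with
unconstrained Levenberg–Marquardt under an |n|, |K| reparameterisation for
speed. Fits are unweighted by default (no error model is published for the
plate assays); per-concentration inverse-variance weights are optional.
Background subtraction (activity in saturating inhibitor) is a separate
helper applied by the caller. Case-resampling percentile bootstrap CIs are
seeded and, over 100 simulated 12-point curves at 2% noise with 500
resamples each, cover the true n and K₀.₅ in ≥ 90% of curves (measured in
the test suite).

## Synthetic data

The generators define the test conditions:

- **Coordination sites**: ion at the origin, one oxygen per ligand at its
  exact prescribed distance along deterministic spherical-Fibonacci
  directions (well separated, clash-checked at 1.5 Å). Geometry beyond the
  distances is irrelevant to bond valence, which depends only on r.
- **Trajectories**: frames are the reference plus independent isotropic
  Gaussian displacements (σ per atom, in Å) — a stationary-fluctuation
  idealisation of an equilibrated MD tail. An optional two-state atom hops
  between bound/unbound distances from an anchor by independent
  Bernoulli(p) draws per frame. Real MD frames are autocorrelated and
  anharmonic; passing tests therefore validate the estimators
  (occupancy → p at rate 1/√frames, mean displacement → σ√(8/π)), not any
  force-field realism.
- **Ideal gas**: uniform i.i.d. positions in an orthorhombic box per frame;
  the analytic g(r) = 1 oracle for shell normalisation.
- **Activity curves**: exact Hill values plus additive Gaussian noise (the
  assays publish no error model); the canonical test curve uses n = 1,
  K₀.₅ = 5 mM, 2% noise on a 12-point 0–50 mM dose ladder, mirroring a
  96-well activity assay.

All generators are bit-reproducible given their seed
(`numpy.random.default_rng`).

## Problem sizes

Statistical tests use 2 000–40 000 synthetic frames and 100 simulated
curves — sizes chosen so Monte-Carlo error sits well inside the asserted
tolerances while the whole suite stays fast on a laptop.

## Known limitations

- Published trajectory-derived numbers (mean RMSDs, RDF curves, MD-mean
  valences for the 18 protonation states) require ~100 ns all-atom MD of
  the deposited structures; the package validates the methodology on
  synthetic ground truth instead of reproducing those values.
- H-bond detection is distance-only; no donor–acceptor angle criterion.
- SEMs over trajectory frames assume independence (see above).
- PDB/mmCIF parsing keeps only blank/"A" alternate locations; occupancies
  are not otherwise used.
- No crystallographic symmetry expansion, structure-factor handling, or
  binary trajectory formats (DCD/XTC); multi-model PDB and XYZ cover the
  text-based trajectory path.
- pKa estimation is out of scope; protonation states are caller-supplied
  bookkeeping.
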