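# Methods

## Model and assumptions

The directional-reactivity factor treats the pre-binding encounter between
a small aromatic ligand and a charged receptor as a charge–dipole problem.
Its assumptions, in order of load-bearing importance:

1. **Electrostatics dominate at long range.** Before any contact, the
   field of the receptor's charged residues (screened and sign-flipped by
   the counter-ions trapped around them) torques the ligand until its
   dipole lies along the line of action. Hydrogen bonding, π-stacking and
   dispersion act only at short range and are ignored.
2. **Reactivity is local and frontier-orbital controlled.** Which atoms
   react is read from condensed Fukui functions — finite differences of
   partial charges over the N, N+1 and N−1 electron states at fixed
   geometry. This neglects orbital relaxation; negative per-atom values
   can appear as artifacts and are propagated as-is with a warning.
3. **Only terminal sites matter.** The reactive periphery is the set of
   carbon→substituent bonds (C–H, C–O of a hydroxyl, C–C of a methyl);
   each contributes its Fukui weight times the projection of its bond
   direction onto the dipole. Sites on the far side of the molecule
   (cos φ < 0) subtract, encoding that a favorable face-forward
   configuration on one side implies an unfavorable one on the other.
4. **The receptor enters as a single scalar.** Its net charge at the assay
   pH, from Henderson–Hasselbalch fractions summed over ionizable
   residues. No structure, no pKa shifts from the 3D environment, no
   specific contacts.

The score is linear in each factor, antisymmetric under dipole or charge
negation, and invariant under joint rigid rotation of geometry and dipole
— these exact symmetries are enforced by tests.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `c_lr` | 1 | Coulomb prefactor 1/(4π ε₀ ε_R r); constant for one receptor at fixed approach distance, so it only sets the score's absolute scale. ε_R and r are carried as metadata, never used numerically. |
| `tau` | cos 75° ≈ 0.2588 | half-width of the perpendicular band in the F/P/B orientation classifier. The classes are qualitative; a narrow band keeps "perpendicular" for dipoles genuinely near the plane normal. |
| Fukui mode | from sign(Q_net) | F⁺ when the receptor is positive (ion screening makes the ligand face an effectively negative potential), F⁻ when negative; explicit override available. Zero net charge has no defined mode and errors without an override. |
| pKa preset | `classic` | D 3.65, E 4.25, C 8.3, Y 10.1, H 6.0, K 10.5, R 12.5, termini 9.0/3.1. `emboss` and `sillero` presets ship as alternatives; published tables disagree at the ±0.1–0.5 level, which moves the example receptor's net charge by a few tenths of a unit. |
| termini | sequence: on, composition: off | a bare residue census does not imply a single chain, so termini are only assumed when a full sequence is supplied. |
| bond perception scale | 1.2 | slack factor on the covalent-radius sum (Cordero radii via rdkit); standard for idealized geometries. |
| hydrogen condensation | on | hydrogen Fukui weights fold into their bonded heavy atom before site lookup, matching the per-carbon convention of published tables. Atom-resolved mode is exposed. |

Units throughout: Å for coordinates, Debye for dipoles (conversion fixed
at 4.80320 D per e·Å), elementary charges for partial charges and Q_net,
μM for doses and EC50s. DRF is reported in model units (Fukui × Debye × e):
with `c_lr = 1` the absolute magnitude is arbitrary and only relative
scores carry meaning. The published per-compound table is shipped as
printed — including its dipole column in undocumented units and its
absolute DRF values — and is used for rank statistics only; reproducing
those absolute magnitudes would require the original DFT runs and unit
conventions, which is out of scope by design.

## Synthetic fixtures: what they emulate, what they don't

The fixture generator stands in for the two expensive inputs the model
consumes.

*Geometries* are idealized planar fused hexagons (C–C 1.40 Å, C–H 1.09 Å,
C–O 1.36 Å, O–H 0.96 Å, C–CH₃ 1.50 Å) on a triangular lattice of ring
centers, with methyl/hydroxyl substituents placed radially. No geometry
optimization: the model consumes only positions and bond directions, for
which idealized geometry is adequate. Randomly drawn ring paths and
substituent patterns are rejection-sampled until bond perception yields a
chemically sane molecule (no sub-0.5 Å contacts, monovalent hydrogens).

*Charge-state triples* are solved, not simulated: neutral charges are the
minimum-norm solution of Σq = 0 plus the point-charge dipole equaling a
planted vector about the center of nuclear charge; the anion subtracts a
planted f⁺ distribution and the cation adds a planted f⁻. This guarantees
exact round-trips (finite-difference Fukui recovers the plants; the
point-charge dipole recovers the planted vector) while staying independent
of the engine under test. A strictly planar charge distribution cannot
carry an out-of-plane dipole — the constraint system is rank-deficient —
so planting such a dipole raises an error, and the random generator
samples in-plane dipoles unless out-of-plane atoms (methyl hydrogens)
exist. None of this emulates real charge-density partitioning
quantitatively: passing tests demonstrate that the pipeline computes its
defined quantities correctly, not that DFT-grade inputs would yield any
particular score.

*Dose–response curves* follow the assay design they emulate: 10 fivefold
dilutions from a 100 μM top dose, 3 replicates, increasing log-logistic
mean (default Hill 1.2, asymptotes 0/100 %BaP_max) plus Gaussian noise
(default σ = 5 %BaP_max when enabled). Real assay noise is
heteroscedastic and occasionally non-parallel between compounds; the
simulator is homoscedastic and exactly parallel, so recovery statistics
here are a best case.

*The brute-force oracle* re-derives the score with explicit Python loops,
its own leaf-pruning cycle detection and its own cosine arithmetic,
sharing no helpers with the engine; agreement within 1e−10 across 100
random fixtures is the equivalence criterion.

## Numerical choices

- **Fukui sign convention** in terms of charges: f⁺ = q(N) − q(N+1),
  f⁻ = q(N−1) − q(N); each full vector sums to 1 within the 1e−3 input
  tolerance on charge-set sums.
- **Ties** among maximal Fukui carbons (within 1e−3) are reported, not
  broken; orientation classification averages cos φ over the tied sites.
- **Ranking ties** break by compound name for a stable, documented order;
  duplicate names are an error.
- **Zero dipole** degenerates every cos φ to 0, the score to 0, and the
  orientation class to P.
- **EC50 fitting** works on log10 dose with the midpoint parameterized as
  log10 EC50 (positivity for free); initial values come from the data
  (min/max responses, dose nearest the half-maximum). The parallel fit
  first fits the reference unconstrained, then frees only the target's
  midpoint. Non-convergence raises with the compound named.
- **Terminal-site rule**: any carbon with an exocyclic neighbor (H, O, N,
  or a carbon outside every ring) contributes one site per such neighbor;
  ring membership comes from cycle detection on the bond graph. A methyl
  carbon therefore contributes its own C–H sites in addition to the ring
  carbon's C–C site — all terminal sites enter uniformly, including those
  on added rings.

## Design choices where the design was open

- The dipole's own direction defines "forward": orientation is classified
  against +D̂, and the F⁺/F⁻ choice (rather than a geometric receptor
  placement) carries the receptor's side of the interaction. This makes
  the score a pure ligand property given Q_net.
- Absolute score reproduction is deliberately not attempted (see Units);
  the validation targets are rank-order agreement with bioassay potency
  and internal exactness (oracle equivalence, symmetries, round-trips).
- The packaged reference EC50s are stored exactly as printed (10⁻¹ μM)
  with an explicit unit accessor, so the transcription stays
  byte-comparable to the source tables; a checksum guards against silent
  corruption.
- Association defaults to the reciprocal-EC50 potency scale; reciprocal
  and log10 transforms are exposed because regression axes on potency
  data are a genuine modeling choice, and published R² values for
  competing models could not be tied to a unique transform — none is
  asserted here.

## Problem sizes

The validation suite uses 100 random fixtures (1–6 rings) for
conservation/oracle/symmetry checks and 200 simulated curves for EC50
recovery; both complete in seconds and the Monte-Carlo margins (median
relative EC50 error ≈ 8% against a 10% bound) are stable across seeds.

## Known limitations

- The model ranks congeners of a series approaching one receptor; it says
  nothing about absolute affinity, kinetics, metabolism, or toxicity
  beyond receptor activation.
- Henderson–Hasselbalch charges ignore structural pKa shifts; the net
  charge of a folded domain can differ from the sequence-based estimate.
- Fukui functions from finite differences inherit every artifact of the
  chosen population analysis; hydrogen condensation is a convention, not
  physics.
- The terminal-site enumeration assumes organic frameworks whose reactive
  periphery is carbon-bonded H/O/N; metals and exotic valences are out of
  scope.
- EC50 estimates assume a monotone sigmoidal response; biphasic or
  cytotoxicity-suppressed curves need manual truncation before fitting.
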