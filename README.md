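# dirreact

Directional-reactivity scoring of small-molecule ligands against charged
receptors — a first-principles alternative to purely statistical potency
models, aimed at computational toxicologists and cheminformaticians who
have quantum-chemistry descriptors for a congener series and want to rank
the series by predicted receptor-mediated potency.

## The model

Before a ligand docks, long-range electrostatics dominate: the receptor's
charged residues (screened by cytosolic ions) exert a field that rotates
the ligand so its dipole moment **D** aligns with the line of action. The
ligand therefore arrives with a particular face forward, and binding is
favored when its most reactive atoms sit on that face. The **directional
reactivity factor** couples these ingredients:

```
DRF = C_LR · Q_net · Σₙ Fₙ± · |D| · cos φₙ
```

- `Q_net` — receptor net charge at the assay pH, from a
  Henderson–Hasselbalch sum over its ionizable residues
  (D, E, C, Y acidic; H, K, R basic; optional chain termini),
- `Fₙ±` — condensed Fukui function of terminal site *n* (a carbon bonded
  to H or a functional group), computed by finite differences of partial
  charges over the N/N±1-electron states: `f⁺ = q(N) − q(N+1)`,
  `f⁻ = q(N−1) − q(N)`. F⁺ is used when `Q_net > 0` (the ion-screened
  potential the ligand sees has the opposite sign), F⁻ otherwise,
- `cos φₙ` — angle between the dipole and the site's bond direction n̂;
  sites behind the molecule (`cos φ < 0`) subtract from the score,
- `C_LR` — the Coulomb prefactor `1/(4π ε₀ ε_R r)`, constant for one
  receptor at a fixed approach distance; defaults to 1, so scores are in
  model units (Fukui × Debye × e) and meaningful relative to one another.

The most reactive carbon's mean `cos φ` also yields an orientation class:
**F**orward (> cos 75°), **B**ackward (< −cos 75°), or **P**erpendicular.

The package additionally fits EC50s from reporter-assay dose–response data
(four-parameter log-logistic, optionally sharing slope and asymptotes with
a reference agonist — the equal-efficacy/parallelism assumption), and
correlates predicted scores with observed potencies (Pearson R², Spearman
ρ with mid-rank ties). A transcription of the published 12-compound
chrysene-homologue reference tables (electronic descriptors, DRF scores,
bioassay/QSAR/docking potencies) ships with the package.

Charge populations, dipoles and orbital energies are *inputs* (from any
population analysis, e.g. Hirshfeld); the package performs no
electronic-structure computation. A seeded synthetic-fixture module
generates idealized fused-ring geometries, charge-state triples with
planted Fukui vectors and dipoles, and noisy dose–response curves with
planted EC50s, so every pipeline stage can be validated against known
ground truth.

## Worked example

Receptor side — the 107-residue ligand-binding-domain census (5 His,
10 Arg, 5 Lys, 5 Asp, 6 Glu) at the bioassay pH:

```sh
$ dirreact netcharge --composition H:5,R:10,K:5,D:5,E:6 --ph 7.4
{
  "net_charge": 4.192518249657435,
  "per_type": {"D": -4.999111, "E": -5.995755, "H": 0.191433,
               "K": 4.996032, "R": 9.999921},
  ...
}
```

The receptor carries about +4.2 e: arginines and lysines are essentially
fully protonated, histidines contribute only ~0.04 e each, and the
acidics are fully deprotonated.

Ligand side — generate a synthetic bundle and score it:

```sh
$ dirreact simulate --seed 11 --out bundle/
$ dirreact drf --xyz bundle/molecule.xyz --charges bundle/charges.csv --qnet 4.1
{
  "compound": "ring1-seed11",
  "drf": -0.6668758028881392,
  "fukui_mode": "f_plus",
  "orientation_class": "B",
  ...
}
```

A negative score: this fixture's highest-Fukui carbon points away from
the dipole's line of action (class B), so the predicted pre-binding
configuration is unfavorable.

Model vs experiment on the packaged reference series:

```sh
$ dirreact compare --reference --method spearman
{
  "statistic": 0.9772344233319931,
  "p_value": 4.635469762685395e-08,
  "n": 12
}
```

Rank concordance ρ ≈ 0.98 between the DRF scores and the reciprocal
bioassay EC50s across the 12 homologues: the score orders the congeners
almost exactly as the in vitro assay does, with the 2-methyl congener most
potent on both scales.

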