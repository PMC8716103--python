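# Methods

## Scope and model

`ectodimer` analyses the quaternary conformation of two-subunit receptor
extracellular modules — the EGFR architecture is the motivating case: a
compact ligand-binding *head* (Domains I–III, mature residues 1–501) on an
elongated Domain IV *leg* (residues 501–614) that ends at the
membrane-proximal tip (Thr 614), followed by a seven-residue linker
(Asn 615–Ser 621) to the transmembrane helix. Ligand-bound dimers populate
an ensemble of conformations between two extremes: *tips-juxtaposed*
(large inter-head scissor rotation, tips ~5 Å apart) and *tips-separated*
(small scissor rotation, tips ~15 Å further apart, one leg swung toward the
head). The package measures where any given model sits on that axis,
quantifies the steric argument that couples the scissor rotation to the leg
swing, and reconstructs 1D free-energy profiles from umbrella-sampling data
of the tip-separation coordinate.

All residue numbering is *mature* (signal peptide excluded). Deposited
files may count the 24-residue signal peptide; `DimerMap` carries an
explicit `numbering_offset` (author − mature), and `validate_dimer_map`
checks residue-name anchors (Ile 190, Thr 249, Trp 492, Thr 614, Ile 619,
Ala 623) and suggests whichever of 0 / +24 fits. Numbering drift is the
chief silent-failure mode of this analysis, which is why validation is by
sequence anchors and never assumed.

## Descriptors

* **Scissor dihedral** — dihedral(Cα 190ᴬ, Cα 249ᴬ, Cα 249ᴮ, Cα 190ᴮ): the
  pseudo-torsion about the virtual bond joining the two Thr 249 Cα atoms.
  Sign follows the convention shared by biotite/mdtraj (cross-checked in the
  tests); because a chain swap flips the sign, reports carry both the signed
  value and the magnitude, and the magnitude is the headline number.
* **Tip separation** — |Cα 614ᴬ − Cα 614ᴮ|.
* **Closure angle** — per subunit, the angle at the Domain II centroid
  (Cα of 260–285) between the Domain I (7–200) and Domain III (317–470)
  centroids. Centroids are unweighted means over the resolved Cα of each
  span; a span below 50% coverage flags the descriptor missing (coverage
  fractions are always reported).
* **Leg hinge angle** — superpose the model on a reference over the head
  span of one subunit, then superpose the (moved) leg Cα onto the reference
  leg; the axis–angle magnitude of that second rotation, taken about the
  head/leg junction (Cα 501), is the swing angle. Frame-invariant because
  the head superposition removes the global pose.
* **Reference RMSD** — Cα RMSD over a stated span (canonically 1–501) after
  Kabsch superposition. Correspondence is by mature residue number with
  chains paired; resolved sets are intersected and the atom count reported.
  The default frame fits over both subunits at once; a per-subunit frame
  (fit on one subunit, deviation over all pairs) is available because the
  published comparisons superpose on one subunit and the one-number RMSDs
  do not state their frame.

Ensembles are ranked by descending scissor magnitude with ties broken by
ascending tip separation (competition ranks; identical models tie), and the
extremes are labelled `juxtaposed-like` / `separated-like`. Missing
descriptors propagate as NaN with reasons; one missing value never aborts a
report. Ligand/hetero atoms are never used by any descriptor.

## Clash analysis

`graft_leg` transplants a template leg onto a target chain by superposing
the shared head span (≥ 3 common Cα) and applying that rigid transform to
the template's leg-span atoms; grafted atoms carry a provenance flag.
`detect_clashes` supports two community conventions, since the source
analyses state no threshold: Cα-only (clash when d < 4.0 Å; usable on
backbone-only models) and heavy-atom van der Waals overlap
(d < r_a + r_b − 0.6 Å, radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å).
Candidates come from a k-d tree and every reported pair is re-checked
against its exact cutoff; the tests hold the implementation equal to an
all-pairs brute force on random instances. `hinge_scan` rotates a leg about
a pivot/axis over an angle grid and reports per-angle clash counts and the
smallest clash-free grid angle. The default axis is perpendicular to the
(Domain III centroid, pivot, leg centroid) plane — the swing that carries
the leg toward the head. When scanning grafted models the CLI excludes
atom pairs within the same chain and residues within ±2 of the junction,
so graft seams are not counted as clashes.

## WHAM

The estimator solves the standard self-consistent WHAM equations on a
uniform histogram (half-open bins), iterating the per-window free-energy
constants (gauge fixed to the first window) until the maximum change falls
below the tolerance; non-convergence and inter-window sampling gaps are
reported, never silent. Energies are kJ·mol⁻¹ internally; kcal inputs
convert at exactly 4.184. Defaults: bin width 0.1 Å, tolerance 10⁻⁶
kJ·mol⁻¹, 10⁵ iterations — unstated in the source protocol and standard
for 1D WHAM. The default temperature is 300 K (the simulation temperature)
although the conventional "room temperature" k_BT of 2.479 kJ·mol⁻¹
corresponds to 298.15 K; both are exposed and `kBT` computes R·T exactly.
`pmf_delta` interpolates linearly between bin centers. The published
protocol this mirrors: 20 windows spaced 1 Å (centers 8–27 Å on the
tip-separation coordinate), harmonic bias 1 kcal·mol⁻¹·Å⁻².

## Synthetic data: what it emulates and what it does not

`build_toy_dimer` produces a two-chain, Cα-only model in mature numbering
whose descriptors equal the spec *exactly* by construction, so the
generator is the oracle for the pipeline:

* Head template: Cα 249 at the origin, Cα 190 at 30 Å along +y; the three
  closure domains are zero-sum point clouds (4 Å spread) about centroids
  placed 25 Å from the Domain II vertex at the requested closure angle
  (Domain I absorbs the pinned 190 position in its cloud correction).
* Subunit placement: subunit B is the two-fold rotation of A about y
  through the midpoint of the 8 Å virtual bond; the scissor is realized by
  rotating the subunits by ±θ/2 about the bond axis, which makes the
  requested dihedral exact.
* Legs: 90 Å end-to-end (the folded Domain IV extent; the Cα spacing along
  it is schematic) with a 2 Å helical jitter vanishing at both ends, so leg
  point sets are never collinear and Kabsch fits stay conditioned. The
  requested tip separation is met in closed form by steering each leg's end
  point on its 90 Å sphere about the pivot to a two-fold-symmetric target
  with the tips separated purely along the inter-subunit axis; the hinge
  rotation is applied relative to a same-spec hinge-zero reference leg,
  which is emitted in the ground-truth record so hinge recovery is exact.
  Requests outside the reachable sphere raise an infeasibility error rather
  than producing a silently wrong model.
* Topology jitter comes from one fixed generator seed shared by all specs
  (so multi-model ensembles share topology); coordinate noise uses the
  spec's own seed. Generators are pure functions of (spec, seed).

What the toy does **not** emulate: real stereochemistry (bond lengths,
secondary structure, side chains), ligands, partial disorder, or
experimental coordinate error structure. Passing recovery tests therefore
demonstrates the correctness of the descriptor mathematics and its
missing-data handling — not robustness to the noise sources of real
deposited models, which is exercised only by the (network-dependent)
regression against deposited entries.

`sample_umbrella` draws window samples from the *exact* stationary density
of potential + bias: harmonic+harmonic is Gaussian in closed form,
flat+harmonic is a truncated Gaussian, flat unbiased is uniform; only the
double-well family uses Metropolis (burn-in 2000, thinning 5, acceptance
recorded). This makes WHAM recovery tests deterministic up to the seed and
removes MD autocorrelation from the picture — so these tests validate the
estimator, not the sampling convergence questions a real MD study faces.

## Numerical choices

* Collinearity/degeneracy: declared when the relevant cross-product norm
  falls below 1e-9 × the segment norms; Kabsch rejects point sets whose
  second singular value is below that threshold.
* Rotations are validated proper-orthogonal to 1e-9 on construction;
  axis–angle extraction falls back to the symmetric part near 180°.
* PDB output uses the format's fixed 3-decimal columns (coordinate
  quantization 5×10⁻⁴ Å, which perturbs angle descriptors at the ~10⁻³ deg
  level); mmCIF output writes 9 decimals, so the generator → file →
  descriptor round trip preserves values to well below every tolerance
  used here. Precision-critical round trips should use mmCIF.
* Altlocs collapse to the highest-occupancy conformer (ties: first seen).
* Flat-potential reconstruction checks bound each bin's deviation at the
  family-wise confidence of a single 3σ test (Bonferroni over bins): the
  literal max-over-bins vs per-bin-3σ comparison would fail ~5% of seeds
  by construction for any sample size.
* The statistical checks on stochastic quantities use fixed seeds in the
  tests; the acceptance script derives all its seeds from `--seed`.

## Problem sizes

Synthetic dimers use the full architecture (2 × 615 Cα); recovery suites
use 10-model ensembles. WHAM checks use 20 windows × 10⁴ samples
(harmonic) and 4×10⁴ samples (flat); clash oracles use 20 random
200-vs-200 atom instances. Everything runs in seconds on one core.

## Known limitations

* The head-span RMSD frame for the published one-number comparisons is not
  stated at the source; both frames are implemented and the default
  (dimer-wide) is an interpretation.
* The deposited-entry regression requires the coordinate files (fetched
  into `scratch/pdb_cache/` on first use); without them that test reports
  the inputs as unavailable.
* No 2D WHAM and no MBAR (MBAR is the natural alternative estimator; not
  implemented). No energy minimisation or side-chain repacking after
  grafting. No density-map handling.
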