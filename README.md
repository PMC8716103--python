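# ectodimer

Quaternary-conformation analysis of receptor ectodomain dimers.

Ligand-bound receptor tyrosine kinase dimers — EGFR bound to EGF or TGF-α
is the motivating system — do not sit in a single extracellular
conformation. The dimeric extracellular module populates an ensemble
between two extremes: a *tips-juxtaposed* state, with a large scissor-like
rotation between the two ligand-binding heads and the membrane-proximal
tips of the Domain IV legs close together (~5 Å), and a *tips-separated*
state, with a small scissor rotation and one leg swung up toward the head
so the tips sit ~15 Å further apart. Where a dimer sits on this axis
controls which transmembrane-helix dimer it can couple to, and hence the
signal the receptor sends. This package gives structural biologists the
measurements that define that axis, on any PDB/mmCIF model or ensemble:

* **scissor dihedral** `θ = dihedral(Cα₁₉₀ᴬ, Cα₂₄₉ᴬ, Cα₂₄₉ᴮ, Cα₁₉₀ᴮ)` —
  the pseudo-torsion about the virtual bond joining the Thr 249 Cα atoms
  of the two subunits (≈10–25° across a dimer ensemble);
* **tip separation** `d = |Cα₆₁₄ᴬ − Cα₆₁₄ᴮ|`;
* **closure angle** per subunit — the angle at the Domain II centroid
  (residues 260–285) between the Domain I (7–200) and Domain III (317–470)
  Cα centroids, a measure of ligand-binding-site compression;
* **leg hinge angle** — the rigid swing of the Domain IV leg (501–614)
  about the head/leg junction (Cα 501) versus a reference conformation;
* **reference RMSDs** — Cα RMSD over residues 1–501 against crystal
  references, by Kabsch superposition;
* **ensemble distance statistics** — e.g. Thr 614–Thr 614 or
  Ile 619–Ile 619 Cα distances across a 20-model NMR ensemble;
* **steric-clash analysis** — graft a template leg onto both subunits,
  count inter-leg clashes, and find the smallest hinge swing that relieves
  them;
* **WHAM** — reconstruct the potential of mean force F(d) along the
  tip-separation coordinate from umbrella-sampling windows
  (20 windows, 1 Å spacing, 1 kcal·mol⁻¹·Å⁻² bias is the canonical
  protocol), via the self-consistent equations
  `P(x_b) = Σᵢnᵢᵦ / Σᵢ Nᵢ exp[β(fᵢ − wᵢ(x_b))]`,
  `exp(−βfᵢ) = Σᵦ P(x_b) exp(−βwᵢ(x_b))`.

A synthetic-structure generator builds Cα-only toy dimers whose scissor,
tip, closure and hinge values are exact by construction, and umbrella
windows drawn from exact biased stationary distributions — these are the
ground-truth oracles for the whole pipeline. Residue numbering is mature
EGFR numbering (signal peptide excluded); files using precursor numbering
are detected by residue-name anchors and handled via an explicit offset.

## Worked example

Build a toy dimer with a 21° scissor angle, 7 Å tip separation and a 10°
hinge on one leg, then measure it back:

```
$ ectodimer simulate-dimer --scissor 21 --tip 7 --hinge-a 10 --seed 1 \
      --out toy.cif --format mmcif
wrote toy.cif and toy.truth.json
$ ectodimer measure toy.cif --chains A,B
Conformation report for toy-dimer-s21-t7 (1 models)
 model  scissor_abs  tip_separation  rank label
     1       21.000           7.000     1
```

The measured scissor magnitude (21.000°) and tip separation (7.000 Å) equal
the construction values — the generator is the oracle. The same `measure`
command runs on deposited multi-model files, ranking models from
juxtaposed-like (largest scissor, closest tips) to separated-like.

Umbrella sampling and WHAM, on synthetic windows drawn from a known
harmonic potential (curvature 2 kJ·mol⁻¹·Å⁻², minimum 17 Å) under the
20-window protocol:

```
$ ectodimer simulate-umbrella --potential harmonic:2.0:17 --n 2000 --seed 1 \
      --out windows
wrote 20 windows and manifest to windows
$ ectodimer wham --manifest windows/manifest.txt --bin-width 0.2 --out pmf.csv
Potential of mean force (WHAM)
  bins: 87 x 0.2 A, range [8.700, 25.900] A
  temperature: 300 K (kBT = 2.494 kJ/mol)
  converged: True after 562 iterations
  max free energy: 76.636 kJ/mol at 25.90 A
  minimum at 17.10 A
```

The reconstructed profile has its minimum at 17.1 Å (true: 17 Å) and rises
quadratically away from it; fitting the curve recovers the declared
curvature to well within 5% at 10⁴ samples per window. Distance statistics
over an ensemble:

```
$ ectodimer ensemble-stats toy.cif --pair A:614:CA,B:614:CA
{ "n_models": 1, "n_models_used": 1, "excluded_models": [],
  "mean_A": 7.0, "sd_A": 0.0, "min_A": 7.0, "max_A": 7.0 }
```

The library mirrors the CLI one-to-one (`ectodimer.scissor_dihedral`,
`tip_separation`, `closure_angle`, `leg_hinge_angle`,
`compare_to_reference`, `ensemble_report`, `graft_leg`, `detect_clashes`,
`hinge_scan`, `wham`, `build_toy_dimer`, `sample_umbrella`, …).

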