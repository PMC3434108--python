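# triadcore

Structural comparison of chymotrypsin-like serine proteases (MEROPS clan PA,
family S1) — the fold whose two β-barrels bring a His–Asp–Ser charge-relay
triad together at their interface (His57/Asp102/Ser195 in chymotrypsin
numbering).  The package is for structural bioinformaticians comparing
experimental and predicted protease structures across distant taxa: it
answers how much of the fold superposes, how tightly the catalytic triad
geometry is conserved, which alignment positions carry the conserved
active-site residues, and whether a model's backbone geometry is sound.

## What it computes

* **Rigid superposition with common-core detection** — Kabsch least-squares
  fit on a sequence-seeded Cα correspondence, then iterative pruning of
  pairs whose post-fit deviation exceeds a cutoff (default 2 Å) until the
  pair set is stable.  Reports RMSD over the final core and the percentage
  of target residues matched.
* **Catalytic-triad geometry** — the three Cα–Cα distances d(Asp,His),
  d(His,Ser), d(Asp,Ser), aggregated across structures as mean ± sample SD;
  residues within 6 Å of the site; stabilizing contacts (heavy-atom
  hydrogen-bond criterion d ≤ 3.5 Å, ∠ ≥ 120°; disulfide Sγ–Sγ ≤ 2.3 Å).
* **Conservation occupancy** — per-column % of alignment rows carrying the
  modal residue, with Clustal-style `*`/`:`/`.` symbols, and residue
  numbering mapped through a reference row (use a chymotrypsin row to get
  chymotrypsin numbering).
* **Composition profiles** — molar % per physico-chemical class (EMBOSS
  pepstats convention: tiny ACGST, small ACDGNPSTV, aliphatic AILV, aromatic
  FHWY, nonpolar ACFGILMPVWY, polar = its complement, charged DEHKR, basic
  HKR, acidic DE), with >1-SD outlier flags across a structure set.
* **Model-quality metrics** — φ/ψ/ω dihedrals, four-region Ramachandran
  summary (bundled 10°×10° grid map), heavy-atom clashscore (overlaps
  > 0.4 Å per 1000 atoms), and backbone bond-length/angle RMSD against
  Engh–Huber standard values.
* **Secondary structure & surface** — dihedral-window H/E/C assignment,
  Shrake–Rupley solvent-accessible surface area, and a qualitative reduced
  Coulomb classifier labelling surface points electronegative / neutral /
  electropositive.
* **Synthetic fixtures** — toy two-lobe proteases with the triad placed at
  exact Cα distances, ideal helix/strand backbones, seeded random rigid
  transforms + Gaussian noise, and alignments with controlled per-column
  occupancy, so the entire pipeline runs and is tested without downloads.

## Worked example

```bash
triadcore simulate toy-protease --seed 7 --noise 0.05 -o toy7.pdb
triadcore simulate toy-protease --seed 8 --noise 0.05 -o toy8.pdb
cat > config.yml <<'YML'
reference_id: TOY7
structures:
  - {path: toy7.pdb, model_id: TOY7, chain: A, taxon_label: synthetic-a,
     triad: {his: "A:13", asp: "A:14", ser: "A:15"}}
  - {path: toy8.pdb, model_id: TOY8, chain: A, taxon_label: synthetic-b,
     triad: {his: "A:13", asp: "A:14", ser: "A:15"}}
YML
triadcore run config.yml -o out/
cat out/study_report.tsv
```

prints

```
id	taxon	superposed_aa_pct	rmsd_A	d_asp_his_A	d_his_ser_A	d_asp_ser_A
TOY7	synthetic-a	100.0	0.000	6.4	8.3	9.9
TOY8	synthetic-b	100.0	0.105	6.4	8.5	9.7
mean_sd	n=2			6.4±0.05	8.4±0.11	9.8±0.10
```

Both toys were built with the triad at (6.4, 8.4, 9.8) Å and σ = 0.05 Å
coordinate noise: the full chains superpose (100%, the second at 0.105 Å
RMSD ≈ σ√3 as expected for one-sided noise), the per-structure distances
scatter by ~0.1 Å around the construction targets, and the footer
aggregates them to mean ± sample SD.  `out/study_report.json` holds the
same study at full precision plus per-structure quality, secondary-structure
and surface summaries.

Other subcommands (`superpose`, `triad`, `triad-stats`, `conserve`,
`quality`, `sse`, `surface`, `simulate alignment`) expose the individual
stages; every one is a thin wrapper over the library functions in
`triadcore.*`.

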