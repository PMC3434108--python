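# Methods

## Scope and object model

`triadcore` analyses chymotrypsin-like (PA-clan S1) serine protease
structures: rigid superposition with common-core detection, catalytic-triad
Cα geometry, alignment conservation, physico-chemical composition, and
geometry-based model validation.  Structures are parsed from PDB text
(gemmi underneath) into a chain → residue → atom hierarchy with author
residue numbering, because active-site residues in this field are named by
author numbers (e.g. His328/Asp359/Ser438 in a *P. falciparum* model) or by
chymotrypsin reference numbering (His57/Asp102/Ser195).  Parsing policy:
first MODEL only (the comparative set is X-ray), waters and non-amino-acid
heteroatoms dropped, and for alternate locations the highest-occupancy
conformer (ties → alphabetically first tag).  Out-of-range occupancies are
clamped to [0, 1] with a warning.  Multi-chain entries require an explicit
chain selector — deposited entries do not record which chain a comparative
study used, so the choice is always the caller's.

## Superposition and the common core

`kabsch_fit` solves the orthogonal Procrustes problem by SVD with the
standard sign correction, so the returned rotation always has det = +1 (no
reflections).  Degenerate inputs (N < 3, collinear clouds) are rejected
rather than silently fitted.

The "structurally conserved region" is found by `iterative_core_superpose`:
seed a residue correspondence from a global sequence alignment of the two
chains, fit, drop **all** Cα pairs whose post-fit deviation exceeds the
cutoff, refit, and repeat until the pair set is stable (a repeat-set guard
stops oscillations; an extra refit after the loop keeps the reported
transform/RMSD consistent with the final pair set).  All-at-once pruning
was chosen over one-at-a-time because it is simpler and monotone: dropped
pairs always deviate more than every kept pair, so the core RMSD is
non-increasing and the pair set non-growing, which guarantees termination.
The cutoff defaults to 2.0 Å — the reporting threshold used for predicted
models in cross-taxon comparisons — and is a config/CLI parameter, as
comparative studies also quote tighter descriptive thresholds (0.8/1 Å)
for closely related structures.  `fraction_matched` is always the final
pair count over the *target* chain's residue count, in percent; a
structure compared against itself reports 100% at 0 RMSD.

A consequence of all-at-once pruning worth knowing: if a displaced segment
is about half the chain, the initial compromise fit leaves *every* pair
outside a tight cutoff and the core collapses (reported as an error naming
the last good iteration).  The procedure isolates a common core reliably
when the core is the clear majority of the correspondence.

## Catalytic-triad geometry

`triad_geometry` measures the three Euclidean Cα–Cα distances of an
explicitly located His/Asp/Ser triad; a residue of unexpected type warns
but does not fail (predicted models can disagree with the alignment).
`aggregate_triad_stats` reports mean and **sample** SD (n−1), flagged as
such, with n printed alongside.  Published comparative tables of this kind
have printed SDs (±0.01/0.03/0.02 Å) that are inconsistent with their own
per-structure columns (the Asp–His column's sample SD is ≈ 0.21 Å); this
package reports the self-consistent statistic and makes no attempt to
reproduce the printed ones.

Active-site context: `proximal_residues` lists residues with any atom
strictly within a radius (default 6 Å, the conventional "close proximity"
bound) of any triad atom.  `detect_stabilizing_contacts` finds disulfides
(Cys Sγ–Sγ ≤ 2.3 Å, a conventional bound comfortably containing the
canonical ≈2.04 Å bond) and hydrogen bonds by a heavy-atom criterion —
donor N/O to acceptor distance ≤ 3.5 Å and antecedent–donor–acceptor angle
≥ 120° — because X-ray depositions usually lack hydrogens.  Backbone amide
N is a donor only (it has no free lone pair); acceptors are all oxygens
plus side-chain nitrogens; the N(i)–O(i−1) peptide-link pair is excluded.
All criteria are keyword parameters.

## Sequence analyses

`global_align` is Needleman–Wunsch with linear gap scoring and a fixed
deterministic tie-break (diagonal > up > left): its job is a reproducible
Cα correspondence for superposition, not substitution-matrix realism, so
match/mismatch/gap scalars suffice.  Tests check it against exhaustive
enumeration of all global alignments (short sequences) and against
Biopython's `PairwiseAligner` scores.

`column_conservation` reports per-column occupancy — rows carrying the
modal non-gap residue over **all** rows, gapped rows included in the
denominator (a 21-row alignment with 16 matches prints 76%) — and
Clustal-convention symbols: `*` all rows identical and gap-free; `:` all
non-gap residues inside one strong group (STA, NEQK, NHQK, NDEQ, QHRK,
MILV, MILF, HY, FYW); `.` one weak group (CSA, ATV, SAG, STNK, STPA, SGND,
SNDEQK, NDEQHK, NEQHRK, FVLIM, HFY); blank otherwise.  Gaps disqualify `*`
but not the group symbols.  Group tables are module constants and
overridable arguments.

`map_reference_numbering` numbers every sequence's residues by the
reference row's own residue indices (optionally offset); aligning against
a chymotrypsin row therefore yields chymotrypsin numbering, with columns
gapped in the reference labelled "insertion".

Composition classes follow the EMBOSS pepstats convention (listed in the
README); polar is defined as the complement of nonpolar over the 20
standard residues so nonpolar + polar = 100% exactly.  X residues are
excluded from the denominator.  `flag_composition_outliers` flags values
strictly outside mean ± 1 sample SD across ≥ 3 profiles; strict inequality
means identical profiles (SD 0) produce no flags.

## Model validation

Dihedrals follow the IUPAC definitions (φ = C′–N–CA–C′, ψ = N–CA–C′–N,
ω = CA–C′–N–CA), in (−180°, 180°]; a peptide C–N distance above 2.5 Å is
treated as a chain break and severs the affected dihedrals rather than
computing nonsense across a gap.

The Ramachandran summary classifies each defined (φ, ψ) pair on a 36×36
grid of 10° cells with four labels (most favoured / additional allowed /
generously allowed / disallowed).  The bundled map
(`data/rama_map.txt`) is a synthetic approximation of the classic
four-region layout — α, β and left-handed-α cores marked most favoured,
a one-cell dilation as additional allowed, two further cells as generously
allowed — since no exact region polygons are published in the comparative
literature this mirrors; any 36×36 {M,A,G,D} grid can replace it.
Glycine and proline use the same map (comparative tables report single
four-region totals).  Percentages are counts over residues with both
angles defined, rounded half-away-from-zero to 1 decimal;
`RamachandranSummary.from_counts` exposes the percentage arithmetic
directly so region counts from any source can be summarized identically.

Clashscore counts unordered heavy-atom pairs with van der Waals overlap
r(a)+r(b)−d > 0.4 Å per 1000 heavy atoms, using radii C 1.70 / N 1.55 /
O 1.52 / S 1.80 Å.  Pairs within 3 covalent bonds are excluded; the bond
graph is inferred from distances and covalent radii, and Sγ–Sγ disulfide
partners are excluded explicitly.  Because hydrogens are absent, absolute
values are not comparable to hydrogen-aware tools that add and clash-test
hydrogens; the score is for heavy-atom self-consistency and relative
comparison.

Bond-geometry RMSD compares observed backbone bonds and angles against
Engh–Huber standard values (N–CA 1.458, CA–C 1.525, C–N 1.329, C–O
1.231 Å; N–CA–C 111.2°, CA–C–N′ 116.2°, C–N–CA 121.7°, CA–C–O 120.8°,
O–C–N′ 123.0°), both tables overridable.  Covalent bonds without a table
entry (side chains) are counted as skipped, not silently mixed in.

## Secondary structure and surface

SSE assignment is dihedral-window based, not hydrogen-bond (DSSP-style):
helix-eligible φ ∈ [−100, −30] and ψ ∈ [−80, −5]; strand-eligible
φ ∈ [−180, −40] with ψ ∈ [60, 180] or [−180, −170]; maximal runs of ≥ 4
(helix) / ≥ 3 (strand) eligible residues become elements.  The windows are
module constants.  This choice is exactly testable on constructed
dihedrals; it will disagree with visual/H-bond assignments near element
termini, and element counts from rendered figures are not targets.

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, probe 1.4 Å): per atom, the unburied fraction of
points on the solvent-extended sphere times 4π(r+probe)².  Totals converge
within 2% between 960 and 4000 points on the toy structures.  Because the
point set has a fixed global orientation, rotating a structure changes the
occlusion pattern by the sampling error (~0.1% of total at 960 points);
this is inherent to all fixed-grid implementations and the invariance
tests are set at that level.

The surface classifier is deliberately qualitative, mirroring how
electrostatic surface figures are read: formal charges at side-chain
charged-group centroids (Asp/Glu −1 at the carboxylate O centroid,
Lys/Arg +1 at NZ / the guanidinium N centroid; His 0 by default since its
protonation is pH-dependent, settable; termini off by default), reduced
Coulomb potential V(p) = Σ qᵢ/dᵢ with no dielectric (absorbed into the
neutral band), and thresholding at ±t (default 0.05 charge/Å) into
negative / neutral / positive.  On Cα-only toys the centroid falls back to
the branch atom and finally Cα.  It is not a Poisson–Boltzmann solver and
no figure-matching is attempted.

## Synthetic data

The generators define the test conditions; they are geometric stand-ins,
**not folded proteins**.  `make_ideal_sse` builds backbones by NeRF
internal-coordinate construction at (φ, ψ) = (−57, −47) for helix and
(−120, 120) for strand, ω = 180°, on the Engh–Huber tables — so ideal
fixtures have exactly zero bond-geometry RMSD and exactly recoverable
dihedrals.  `make_toy_protease` (default 12 residues per lobe) places
His/Asp/Ser single-residue backbones with Cα exactly at the target
distances — defaults (6.4, 8.4, 9.8) Å, the experimental consensus for
this fold — between two strand lobes, then adds optional i.i.d. Gaussian
coordinate noise (σ = 0.1 Å in the recovery experiments, a typical
coordinate-uncertainty scale).  `apply_random_transform` draws a uniform
rotation by the normalized-quaternion method and a translation in
[−50, 50]³ Å.  `make_synthetic_alignment` fills background columns
uniformly over the 20 residues with 10% gaps and sets conserved columns to
⌈occupancy × n_rows⌉ seeded rows (remaining rows draw from the other 19
residues so the conserved residue is always modal); 21 rows matches the
size of the comparative sequence set.  Every generator takes a seed and
touches no global random state.

What passing on these fixtures shows — and does not: correctness of the
geometry, fitting, counting and classification machinery under known
ground truth.  It does not validate behaviour on real structures with
missing atoms/loops, alternate conformations beyond the altloc rule,
non-ideal peptide geometry, or biologically realistic surfaces.

## Numerical conventions

Internal values are never rounded; serialization rounds half-away-from-zero
(1 decimal for Å distances and percentages, 3 for superposition RMSD, 0 for
conservation occupancy), matching how such tables are conventionally
printed.  PDB coordinate fields are written at 8.3f, so file round trips
are exact to 1e-3 Å and pipeline aggregates computed from files are exact
to that precision.  All pipeline outputs are deterministic given the
config; structure-entry order determines only row order.

## Problem sizes

The test and acceptance workloads use toy scales chosen to exercise every
code path at full statistical meaningfulness: 27-residue toy proteases,
100 Monte-Carlo replicates for noise-recovery means (SEM ≈ 0.0014 Å),
100 random 5-point clouds for the brute-force Kabsch cross-check (dense
Euler-grid + multi-start refinement oracle), and 21×40 alignments.

## Known limitations

mmCIF, assemblies and nucleic acids are out of scope; superposition is
single-core rigid (no flexible or sequence-independent alignment);
rotamer-based and database-fitted quality scores (rotamer outliers,
Verify3D/ProSA/ERRAT analogues) are not implemented; the Ramachandran map
is an approximation, so absolute region percentages on real structures
will differ from PROCHECK's; clashscore is heavy-atom only.
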