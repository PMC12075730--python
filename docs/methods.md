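# Methods

## The screening model

`nosbond` treats NOS-linkage discovery as a two-stage problem: a
deterministic *screen* that reduces a structure databank to a table of
quality-assured S–N contact pairs with fifteen descriptors each, and an
unsupervised *subset search* that finds the smallest descriptor combination
under which verified NOS linkages separate from the bulk of contacts.

The working hypothesis is that genuine NOS candidates occupy the same
region of descriptor space as experimentally verified Lys-NOS-Cys linkages
(the *reference set*): short S–N separation, bonding-compatible C–S–N
geometry, low positional mobility (B-factors), and a packing/solvent
environment compatible with a buried covalent bridge. No labels are used in
training; the references only *name* clusters after unsupervised structure
has been found.

## Screening thresholds

| quantity | rule | rationale |
|---|---|---|
| experimental method | X-ray only | bond-level geometry needs real-space density checks |
| resolution | ≤ 2.0 Å (inclusive) | fine chemical detail unreliable beyond |
| dist(S, N) | ≤ 3.2 Å (inclusive) | covalent-interaction cutoff established for Lys/Cys |
| occupancy (S and N atoms) | > 0.8 (strict) | exclude high positional uncertainty |
| RSRZ (both residues) | < 2.0 (strict) | residue must fit its density |
| BDB B-factor | present for both atoms | recalibrated B-factors are a core descriptor |

Threshold comparisons at format boundaries absorb coordinate rounding with
a 1e-9 epsilon; occupancies and B-factors read through gemmi (float32) are
rounded back to text precision so that strict inequalities behave as
written. Missing RSRZ rejects the pair (`missing_rsrz`) rather than
defaulting to 0. Each rejected pair logs only its *first* failed criterion
in the fixed order occupancy → RSRZ → BDB; the retained set is
order-independent because it is the intersection of the three filters.

Default target classes use cysteine sulfur and exclude Cys–Cys and Cys–His
partners (disulfide bridges and metal-coordination artefacts, respectively);
Met SD and the excluded classes are still enumerated and tabulated, and a
config switch (`include_nondefault_classes`) restores them. Only the
deposited asymmetric unit is searched — symmetry mates are not generated —
and only the first model of multi-model files is used. Alternate locations
collapse to the highest-occupancy conformer (ties: lowest altloc letter).

## Descriptors

Fifteen numeric descriptors per pair, in fixed column order:

1–5. geometry: ∠CSN, ∠CNS, φ(C_S–S–N–C_N) in (−180°, 180°] with the
right-hand sign convention, dist(C_S, N), dist(S, N). C_S/C_N are the
closest carbons within covalent range (≤ 1.9 Å) of S/N; for a backbone
nitrogen the preceding residue's carbonyl carbon competes with the own Cα
and wins in ideal geometry (1.33 Å < 1.46 Å). dist(C, N) uses C_S, making
it the third side of the ∠CSN triangle.

6–9. B-factors of N and S from the deposited file and from the BDB.

10–11. Ngb^N, Ngb^S: distinct other residues with any non-hydrogen atom
within 4.0 Å (inclusive) of the residue's Cα. Any-atom counting is the most
inclusive reading of "neighbouring residues".

12–15. Shrake–Rupley SASA of the two atoms and their residues, probe
1.4 Å, 960 points per atom. The point set is a deterministic golden-spiral
distribution, so SASA is bit-reproducible; residue SASA is exactly the sum
of member-atom SASA. Radii: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20,
P 1.80 Å, default 1.70 Å with a warning for unknown elements. Waters are
excluded from the SASA computation entirely (crystallographic waters would
bury surfaces inconsistently across entries); other heteroatoms occlude.

A pair missing any component (no bonded carbon, no Cα, absent BDB value) is
excluded with a logged reason, never imputed.

## Subset search

All descriptor subsets of size ≥ 3 are enumerated in (size, lexicographic)
order — Σ_{i=3}^{15} C(15, i) = 32 647 subsets for the full search.

**Standardization.** Columns are z-scored before embedding; descriptors mix
degrees, Å, Å² and counts, so raw Euclidean geometry would be meaningless.
Verdicts are invariant to positive rescaling of any column.

**Embedding.** UMAP, Euclidean metric, `n_neighbors = 15`,
`min_dist = 0.1`, fixed `random_state` (single-threaded layout, hence
deterministic per seed). The embedding dimension is 3 for subsets larger
than three descriptors and 2 otherwise — at most three dimensions, enough
for well-separated clusters while staying inspectable.

**Clustering.** Mean-shift with bandwidth from the median-quantile
heuristic at quantile 0.3, bin seeding with a minimum bin occupancy of 3.
Quantile 0.2 was tried first and systematically fragmented single embedded
clusters into satellite modes (a planted two-blob fixture came back as four
clusters); 0.3 recovers planted partitions cleanly while still resolving
three-cluster structure. Bin seeding suppresses spurious low-density modes
that plain seeding produces on a single Gaussian cloud. Clusters are
renumbered by descending size.

**Acceptance gate.** A subset evaluation is accepted iff

* 2–3 clusters,
* Silhouette score (Euclidean, on the embedded coordinates) ≥ 0.5,
* the partition discriminates: at least one *probable* cluster (more than
  `ref_leak_tolerance = 2` references), at least one *improbable* cluster
  (at most 2 references), and at most 2 references total outside probable
  clusters.

The improbable-cluster-existence requirement is essential: on unstructured
data the references scatter proportionally across clusters, every cluster
would count as probable and the leak would be zero, so a gate without it
accepts noise.

**Selection and verdicts.** Accepted subsets are ranked by (subset size,
reference leak, −Silhouette, subset order); the top subset is the minimal
descriptor set. Every non-reference row inherits its cluster's
probable/improbable label. Reference descriptor vectors (computed on their
own Lys–Cys pairs) are injected as extra rows into every pair-class matrix
before embedding, so probable clusters can be anchored even in classes that
contain no verified linkage themselves.

## Reporting

Per-cluster summaries give the dominant density mode of each winning-subset
descriptor: argmax of a Gaussian KDE (Scott's-rule bandwidth) on a
512-point grid spanning [min, max]; constant input returns the constant.
The mode is permutation-invariant and affine-equivariant up to grid
resolution. Human-readable output rounds to two decimals; TSVs keep full
precision. Exports (`probable.tsv`, `improbable.tsv`) carry the full
candidate identifier (PDB id, chains, residue names/numbers, atom names)
plus all fifteen descriptors, and never contain reference rows.

## Synthetic data

The fixture generator is first-class code with two halves.

*Structures*: inverse-geometry construction places C_S, S, N, C_N exactly
at the requested dist(S, N), ∠CSN, ∠CNS and torsion, then hangs minimal
residue scaffolds off them with idealized bond lengths (peptide C–N 1.33 Å,
N–Cα 1.46 Å, Cβ–Sγ 1.81 Å), so descriptor extraction on the written files
reproduces the requested geometry to ~1e-4. Supported nitrogen classes:
backbone N (any residue name), Lys NZ, Arg NE and Arg NH1; side-chain
fragments are deliberately minimal so exactly one acceptor is planted per
entry. Each entry is written in the pipeline's on-disk layout
(`structure.cif`, `bdb.pdb`, `validation.xml`) with occupancies, PDB/BDB
B-factors, per-residue RSRZ and optional close-contact records as
specified, and a corpus manifest records the expected screening decision.

*Descriptor matrices*: Gaussian blobs at stated centres on an informative
descriptor subset (default separation 20σ), i.i.d. standard normal noise on
all other descriptors, reference rows drawn from their assigned blob;
seed-reproducible to the byte.

What the generator does **not** emulate: real packing environments (SASA
and neighbour counts on scaffolds are not protein-like in magnitude),
electron density, symmetry mates, correlated descriptor noise, and the
heavy class imbalance of real contact censuses. Passing tests therefore
demonstrate that the machinery is correct — thresholds exact, geometry
faithful, planted structure recovered, noise refused — not that the
descriptor set generalizes to any particular databank snapshot.

## Problem sizes and runtime

The test suite and acceptance script run at desk scale by choice of problem
size: grid corpora of 11–33 entries for threshold fidelity, a 50-entry
corpus for the end-to-end flow, 254-row matrices (180 candidates + 74
references, mirroring the size of the verified reference set) for
planted-subset recovery over 20 seeds, with the subset stream restricted to
the planted subset plus five random decoys per seed (the full 32 647-subset
search over a real pair-class matrix is an hours-scale batch job and is
exposed through the CLI, bounded by `--max-subset-size` or explicit
`--subset` lists). Null controls use the same sizes with zero blob
separation.

## Known limitations

* The bridging oxygen is absent from deposited models, so no descriptor
  sees it; verdicts are *candidates* for density inspection, not bond
  assignments.
* Exact published embedding hyperparameters and mean-shift bandwidths for
  any given study are not recoverable; published cluster sizes and
  Silhouette values are therefore reference points, not targets this
  package reproduces numerically.
* Symmetry-related contacts are not screened.
* Descriptor extraction assumes well-formed residues; exotic chemistry
  (selenomethionine handled via element defaults, covalent ligands) is
  untested.
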