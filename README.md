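# nosbond

Screening for overlooked covalent **NOS linkages** — nitrogen–oxygen–sulfur
bridges that act as redox switches — in crystallographic protein structures.

Crystallographic models are built under assumptions of known protein
chemistry, so an unanticipated covalent bond between a cysteine sulfur and a
nearby nitrogen is routinely modelled as a non-bonded "close contact" or
missed entirely. `nosbond` re-screens deposited models for S–N contact pairs
whose geometry, rigidity and solvent accessibility look like those of
experimentally verified NOS linkages, and ranks them as *probable* or
*improbable* bond candidates. It is aimed at structural bioinformaticians
and crystallographers who want to re-evaluate existing entries (e.g.
PDB-REDO models) without re-refining anything.

## Method

**Screening.** For each entry (mmCIF/PDB coordinates, a BDB companion file
carrying consistent full isotropic B-factors, and a wwPDB validation
report):

* entry level — X-ray structures with resolution ≤ 2.0 Å;
* contact level — side-chain sulfur (Cys SG, Met SD) to backbone or
  side-chain nitrogen of a standard residue with dist(S, N) ≤ 3.2 Å, the
  covalent-interaction cutoff established for Lys/Cys linkages;
* quality level — both target atoms with occupancy > 0.8, both residues
  with RSRZ < 2.0, and both atoms present in the BDB table.

**Descriptors.** Fifteen per retained pair: ∠CSN, ∠CNS, the torsion
φ(C_S–S–N–C_N), dist(C_S, N), dist(S, N); deposited and BDB B-factors of N
and S (Bfac, Bfac_BDB); neighbour-residue counts within 4 Å of the two Cα
atoms (Ngb^N, Ngb^S); and Shrake–Rupley SASA of the two atoms and their
residues (SASA_atom, SASA^N/S). C_S and C_N are the closest carbons
covalently bound to the sulfur and nitrogen.

**Subset search.** Every descriptor subset of size ≥ 3 (Σ_{i=3}^{15}
C(15, i) = 32 647 subsets) is z-scored, embedded with UMAP into at most
three dimensions, and clustered by mean-shift. A subset is accepted when it
yields 2–3 clusters with Silhouette score ≥ 0.5 and the experimentally
verified reference linkages concentrate in "probable" clusters, with at
most 2 references leaking into an "improbable" cluster. Accepted subsets
are ranked by (size, reference leak, −Silhouette); the top subset is the
minimal descriptor set, and every contact pair inherits its cluster's
probable/improbable verdict.

## Worked example

Generate a two-entry synthetic corpus (one good contact at 2.70 Å, one out
of range at 3.50 Å) and screen it:

```sh
$ cat specs.toml
[[contact]]
pdb_id = "cli1"
dist_sn = 2.7

[[contact]]
pdb_id = "cli2"
dist_sn = 3.5

$ nosbond simulate corpus specs.toml --out cli_corpus
wrote 2 entries to cli_corpus
$ nosbond screen cli_corpus --out cli_out/contacts.tsv
retained 1 pairs from cli_corpus; log: cli_out/contacts.rejections.json
```

Only `cli1` survives (the rejection log records `cli2: no_contact`). Next,
a planted-cluster descriptor matrix (two Gaussian blobs separated on the
first three descriptors, 20 reference rows in blob 0) and a restricted
search:

```sh
$ cat blobs.toml
[blobs]
n_rows = [60, 60]
n_reference = 20
seed = 3

$ nosbond simulate blobs blobs.toml --out blobs.tsv
wrote 140 rows to blobs.tsv
$ nosbond search blobs.tsv --out cli_search --seed 3 \
    --subset "angle_csn,angle_cns,torsion_cs_nc" \
    --subset "dist_cn,dist_sn,bfac_pdb_n"
winning subset: ['angle_csn', 'angle_cns', 'torsion_cs_nc']
  cluster 0 [probable] n=80 refs=20 modes={'angle_csn': -0.04, 'angle_cns': 0.3, 'torsion_cs_nc': -0.17}
  cluster 1 [improbable] n=60 refs=0 modes={'angle_csn': 19.53, 'angle_cns': 19.79, 'torsion_cs_nc': 20.53}
```

The informative subset wins; the cluster holding all 20 reference rows
(and the 60 co-located candidate rows) is labelled probable, and the
per-cluster density modes sit at the planted blob centres (0 and 20).
`cli_search/` then contains `probable.tsv`, `improbable.tsv`, the winning
embedding coordinates and the per-subset evaluation table.

The same flow is available as a library: `screen_corpus` →
`build_descriptor_table` → `run_search` → `export_candidates`; see
`docs/methods.md` for the model details and parameter defaults.

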