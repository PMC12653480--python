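# orsite

Prioritize candidate functional residues of membrane receptors — insect
odorant receptors (ORs) in particular — from three cheap, orthogonal
signals: evolutionary conservation, transmembrane topology, and a Cα-only
solvent-exposure proxy.

Insect ORs are 7-transmembrane ligand-gated channel subunits with an
inverted topology (cytoplasmic N-terminus). Their odorant-binding pocket is
formed by the extracellular loops and the extracellular ends of helices
TM3–TM7, so residues that are (a) strongly conserved across orthologs,
(b) located in those regions, and (c) solvent-exposed in a predicted
structure are prime candidates for mutagenesis. `orsite` turns that
three-filter argument into a reproducible pipeline.

## The statistics at its core

* **Column conservation** — for alignment column *i*,
  `C_i = max_r count(r) / n_i`, the modal residue frequency over valid
  residues (gaps and X/B/Z excluded from `n_i`). Range [0, 1].
* **JTT distances, NJ, bootstrap** — pairwise maximum-likelihood distances
  under the Jones–Taylor–Thornton model (`argmax_t Σ log π_a P_ab(t)`,
  `P(t) = e^{Qt}`, distances in expected substitutions/site),
  Saitou–Nei Neighbor-Joining, and bootstrap support
  `100 × (replicates containing the bipartition) / replicates` on the
  original tree's internal edges.
* **Simplified exposure score** — `ASA_i = max(0, 20 − N_i) + 2·D_i`, with
  `N_i` the number of other Cα atoms within 8 Å and `D_i` the nearest-Cα
  distance in Å, linearly rescaled to [0, 100]. A screening proxy, not a
  probe-based surface area.
* **Selection and ranking** — candidates are positions with `C_i ≥ 0.9`
  inside the candidate-region mask (extracellular loops plus TM3–TM7 by
  default), ranked by normalized exposure and truncated to the top *k*.

Topology (TM ranges + N-terminal side) and the Cα structure are *inputs*,
produced upstream by tools such as TOPCONS and AlphaFold2. Synthetic
generators — a tree-based family simulator and an ideal 7-helix bundle
builder — provide realistic inputs for testing and demonstration without
any downloads. See `docs/methods.md` for the full model description.

## Worked example

Generate the packaged demo dataset (11-member simulated ortholog family,
356-residue 7TM Cα bundle, matching topology) and run the pipeline:

```bash
orsite simulate --seed 42 -o demo
cat > config.yaml <<EOF
alignment: demo/family.fasta
structure: demo/structure.pdb
topology: demo/topology.txt
top_k: 5
seed: 42
bootstrap_replicates: 100
EOF
orsite run --config config.yaml -o out
```

which prints the ranked shortlist:

```
1	F257	EL3	Ci=1.000	ASA=100.0
2	P126	EL2	Ci=1.000	ASA=98.9
3	S128	EL2	Ci=1.000	ASA=97.6
4	S262	EL3	Ci=0.909	ASA=91.5
5	I354	TM7	Ci=1.000	ASA=82.9
```

Reading row 1: position 257 (a phenylalanine in the reference sequence)
sits in the third extracellular loop, its alignment column is fully
conserved (`C_i = 1.0`), and it is the most exposed of the 52 selected
candidates (normalized ASA 100.0 — few Cα neighbors, large nearest-neighbor
distance). `out/` also contains the per-column conservation table
(`conservation.tsv`), the region table (`regions.tsv`), the JTT distance
matrix (`distances.tsv`), the bootstrap-annotated NJ tree (`tree.nwk`),
the full candidate list (`all_candidates.tsv`), and a `manifest.json`
recording config, seed, package version and input checksums. Rerunning
with the same config and inputs reproduces every report byte for byte.

The same functionality is available as a library:

```python
from orsite import TopologySpec, derive_regions

spec = TopologySpec(
    protein_length=356,
    tm_segments=((11, 31), (42, 62), (103, 123), (157, 177),
                 (234, 254), (265, 285), (336, 356)),
    n_term_side="cytoplasmic",
)
ann = derive_regions(spec)
ann.by_label("EL2")   # Region(label='EL2', start=124, end=156, side='extracellular')
```

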