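# isinv

Detection and mechanistic classification of bacterial insertion-sequence (IS)
inversions caused by ectopic recombination between terminal inverted repeats
(TIRs), with ancestral-event reconstruction on a strain phylogeny and a
ground-truthed forward simulator.

## The problem

IS elements — the simplest bacterial DNA transposons, a transposase gene
bounded by two TIRs — can be inverted in place when the two TIRs of a single
copy recombine ectopically. In a multi-strain alignment of an insertion locus
(element plus flanking genomic anchor sequence) such an inversion shows up as
an element in reverse orientation relative to the other strains. Because the
two TIR "inward reads" of the canonical element are identical 23-mers except
for a single A/T mismatch at nucleotide position (np) 17, the five possible
inversion processes leave distinguishable TIR configurations behind (L and R
denote the canonical left/right inward reads, read from the element's outer
edge toward its interior):

| observed (left, right) | orientation | mechanism class |
|---|---|---|
| (L, R) | canonical | `not_inverted` |
| (R, L) | inverted  | `full_inversion_ab` — whole-element flip: precise excision/re-integration or recombination with the conversion tract upstream of np 17 (sequence-indistinguishable) |
| (L, R) | inverted  | `internal_inversion_c` — tract downstream of np 17: transposase flips, TIRs do not |
| (L, L) | inverted  | `conversion_left_d` — tract covers np 17, left TIR templates the conversion |
| (R, R) | inverted  | `conversion_right_e` — as (d), right TIR as template |

This package (i) simulates locus panels with known event histories, (ii)
parses aligned multi-FASTA loci and calls per-strain presence/orientation,
(iii) annotates element anatomy de novo (TIRs, transposase ORF, target-site
duplication, sigma-70 −35/−10 promoter boxes), (iv) applies the decision
table above, and (v) reconstructs the minimal insertion/inversion/deletion
history on a newick tree by Sankoff (weighted) parsimony over the states
{absent, canonical, inverted} with unit event costs (direct gain of an
inverted element costs 2).

## Worked example

```python
from isinv import (CanonicalElementSpec, SimConfig, simulate_locus,
                   analyse_locus)
from isinv.pipeline import locus_from_sim
from isinv.phyloevents import read_tree

cfg = SimConfig(n_strains=10, scenario="conversion_left_d", seed=3)
sim = simulate_locus(cfg)
aln = locus_from_sim(sim)
res = analyse_locus(aln, tree=read_tree(sim.truth.tree_newick))
for m in res.mechanisms:
    print(m.strain_id, m.mechanism_class, m.left_match, m.right_match)
print(res.reconstruction.events, res.reconstruction.total_cost)
```

prints

```
s03 conversion_left_d L L
s04 conversion_left_d L L
s05 not_inverted L R
[{'branch': 'n05', 'type': 'insertion', 'from': 'absent', 'to': 'canonical'},
 {'branch': 'n06', 'type': 'inversion', 'from': 'canonical', 'to': 'inverted'}] 2.0
```

i.e. strains s03/s04 carry an inverted element whose two TIR inward reads
both equal the canonical left TIR — the left-templated gene-conversion
outcome (d) — and the most parsimonious history is a single insertion in the
ancestor of the carrier clade followed by a single inversion in the ancestor
of s03/s04 (total cost 2).

The same analysis is available from the shell:

```sh
isinv simulate --config sim.yaml --out-dir out --seed 3
isinv classify --alignment out/locus01.fasta
isinv pipeline --config pipeline.yaml --out-dir results
```

A 22-locus panel with two loci carrying inversion events reports
`2/22 loci with inverted elements (9.1%)` in its summary.

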