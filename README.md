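# aylacostoma

Distance-based molecular evolution for short mitochondrial rRNA fragments,
built around the case of the High Paraná River *Aylacostoma* snails
(Caenogastropoda: Thiaridae).  The genus lost most of its species to the
impoundment of the Yacyretá Reservoir; the extinct *A. stigmaticum* is
known genetically only from a 12S rRNA fragment amplified from a dried
museum shell.  This package reimplements, as a tested desk-scale pipeline,
the analyses used to place that fragment: pairwise distances, tree
building, secondary-structure classification of variable sites, two
single-locus species-delimitation criteria, a molecular-clock test, and
net-divergence dating.

It is intended for researchers working with small single-locus barcoding
datasets (a handful of haplotypes, a few hundred sites) who want every
step of such an analysis to be scriptable, seedable and unit-tested.

## Methods at a glance

* **Distances** — uncorrected *p* and Kimura two-parameter
  `d = -½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`, with P/Q the transition and
  transversion proportions over gap-free shared sites (pairwise or
  complete deletion).  Standard errors by column bootstrap.
* **Trees** — Saitou–Nei neighbour joining with deterministic
  tie-breaking and column-bootstrap split supports; Newick I/O.
* **Structure** — variable sites mapped onto a dot-bracket rRNA model and
  classified as loop changes, pairing-preserving stem changes (GU wobble
  allowed) or pairing-breaking changes.
* **Species delimitation** — (a) barcode-gap partitioning over a
  geometric ladder of prior maximum intraspecific divergences *P*
  (a simplified, fully specified variant of ABGD), and (b) the K/θ test
  of the Evolutionary Genetic Species Concept: sister clades are distinct
  species (probability ≥ 0.95) when K/θ ≥ 4.
* **Clocks and dating** — Tajima's non-parametric relative rate test
  (χ² = (m₁−m₂)²/(m₁+m₂), 1 df), and net-divergence dating
  `T = Da/2μ` with `Da = d_XY − (d_X + d_Y)/2` and 95% CI = (Da ± 1.96·SE)/2μ,
  default 2μ = 0.006 substitutions/site/Myr.
* **Fixtures** — the study's 11 × 234 ingroup alignment rebuilt exactly
  from its printed polymorphic-site and base-composition tables, and a
  3-taxon clock simulator under K2P for calibration and recovery tests.

## Worked example

```sh
aylacostoma fixture paper --seed 0 -o aln.fasta --groups groups.tsv
aylacostoma profile aln.fasta --groups groups.tsv
```

```
11 sequences, 234 columns
13 variable positions: 27,28,42,67,68,102,104,123,163,164,177,214,225
stigmaticum: n=1 haplotypes=1 A=81 C=33 G=39 T=80 AT=69.10% len=233
brunneum: n=3 haplotypes=1 A=81 C=30 G=39 T=83 AT=70.39% len=233
chloroticum: n=7 haplotypes=1 A=80 C=28 G=40 T=86 AT=70.94% len=234
```

Each species carries a single haplotype; the three differ at 13 of 234
aligned columns (plus one indel separating *A. chloroticum* from the other
two).  Distances and delimitation:

```sh
aylacostoma distances aln.fasta -o dm.tsv     # K2P, pairwise deletion
aylacostoma delimit abgd dm.tsv               # prior ladder 0.001 -> 0.1
```

The species-level K2P distances are 0.040200 (stigmaticum–brunneum),
0.044873 (stigmaticum–chloroticum) and 0.021933 (chloroticum–brunneum);
the barcode-gap scan returns the three-species partition for the seven
priors up to 0.021544 and merges the two sister species above that.
Dating both splits of the guide topology:

```sh
aylacostoma date aln.fasta --groups groups.tsv \
    --tree "((chloroticum,brunneum),stigmaticum);" \
    --rate 0.006 --reps 1000 --seed 7
```

```
brunneum+chloroticum | stigmaticum  Da=0.0383535  SE=0.0126094  T=6.39 Myr  CI=[2.27, 10.51]
chloroticum | brunneum              Da=0.0219333  SE=0.0098794  T=3.66 Myr  CI=[0.43, 6.88]
```

So the radiation began roughly 6.4 Myr ago (late Miocene) and the sister
species split about 3.7 Myr ago, with wide intervals — the expected
resolution of a 234 bp fragment.  The whole analysis can also be run in
one shot from a YAML config with `aylacostoma run config.yaml`, which
writes one table per stage plus a provenance log.

## Layout

```
src/aylacostoma/
  fixtures.py       # table-derived alignment + clock simulator
  alignment_io.py   # MultipleAlignment, FASTA/groups I/O, site profiling
  distances.py      # p/K2P, matrices, group summaries, column bootstrap
  rna_structure.py  # dot-bracket parsing, stem/loop site classification
  nj_tree.py        # neighbour joining, Newick, bootstrap supports
  clock_dating.py   # Tajima relative rate test, net-divergence dating
  delimitation.py   # barcode-gap partitioning, K/theta test
  pipeline.py, cli.py
docs/methods.md     # models, parameter choices, limitations
```
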