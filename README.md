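# scrollsaw

Tools for delineating the ancient paralogs of large, duplication-rich protein
families — built around the ARF family of Ras-superfamily GTPases (Arfs,
Arls, Arfrp1, Sar1, SRβ), whose dozens of in-paralogs per genome and strongly
uneven evolutionary rates defeat naive phylogenetics. The central problem:
given thousands of family members from species spanning the known diversity
of eukaryotes, decide which paralogs were already present in the last
eukaryotic common ancestor (LECA), which lineages subsequently lost them,
and what each sequence actually is.

## What it does

**ScrollSaw filtering.** Sequences are partitioned into taxonomic groups
(13 eukaryote-wide groups by default). For every pair of groups *(A, B)*,
pairwise maximum-likelihood distances are estimated on the two-group subset
of the master alignment under WAG+Γ+I, and the *minimal-distance pairs* are
extracted: pairs *(a ∈ A, b ∈ B)* with

&nbsp;&nbsp;&nbsp;&nbsp;*d(a,b) = min<sub>b′∈B</sub> d(a,b′) = min<sub>a′∈A</sub> d(a′,b)*.

Pairs from all C(n,2) group comparisons are pooled; in the pan-eukaryotic
mode, sequences occurring in only one minimal-distance pair overall are
dropped. Because a long-branch sequence is rarely anyone's mutual nearest
neighbour, the retained set is strongly enriched for slowly evolving
representatives of each ancestral paralog — a tractable, artifact-resistant
core for tree inference.

**Distances.** Pairwise ML distances maximise the likelihood of a reversible
amino-acid CTMC (WAG exchangeabilities, discrete-gamma rate classes, optional
invariant-site class) over a single branch length, with pairwise deletion of
gapped/ambiguous columns, a distance cap for saturated pairs, and an
undefined-distance flag below a minimum column overlap.

**Tree operations.** Minimal-ancestor-deviation (MAD) rooting — for each
branch position, tip pairs deviate from the clocklike midpoint expectation by
*r = |2·d(tip, ancestor)/d(tip, tip′) − 1|*; the branch and position
minimising the RMS deviation (closed-form per branch) is the root. Dollo
parsimony maps presence–absence patterns as a single gain plus the provable
minimum number of losses. Paralog assignment takes the smallest ancestral
clade containing reference sequences whose branch support passes both
SH-aLRT ≥ 80 and ultrafast bootstrap ≥ 95.

**Annotation profiles.** Per-paralog position-specific log-odds profiles
(bits) with affine-gap local alignment scoring; a query is assigned to the
best-scoring paralog only when its margin over the runner-up is ≥ 20 bits.

**Introns and motifs.** Intron positions (coding-nucleotide offsets) map to
(residue, phase, alignment column) triples, giving exact shared-position
clusters and paralog-specific intron fingerprints. Membrane-attachment
screens cover Gly2 (N-myristoylation prerequisite), Lys3, N-terminal
cysteines, C-terminal CaaX, and k-of-n consensus over external lipidation
predictors (≥2 of 3 for myristoylation, ≥3 of 5 for palmitoylation).

**Synthetic data.** Every input the pipeline consumes can be generated with
ground truth (seeded): paralog families over a 13-group species tree with
designated fast-evolving lineages, planted intron sites, placed loss events,
and noisy predictor tables. All statistical guarantees in the test suite are
measured against this ground truth.

## Worked example

Simulate a family (13 groups × 3 species × 5 paralogs, 148 alignment
columns, one 4× fast species per group) and run the filtering:

```bash
$ scrollsaw simulate --seed 42 --out demo
wrote synthetic bundle (195 sequences) to demo

$ scrollsaw scrollsaw --alignment demo/alignment.fasta \
    --taxon-map demo/taxon_map.tsv --out demo/ss
195 in, 131 in pairs, 121 retained
```

195 sequences enter; 131 occur in at least one mutually-minimal cross-group
pair; 121 occur in at least two and are retained. `demo/ss/minimal_pairs.tsv`
lists every pair with its groups and ML distance:

```
id_a               id_b                   group_a    group_b        distance
P01_Amoebozoa_sp2  P01_Holomycota_sp2     Amoebozoa  Holomycota     0.853834
P01_Amoebozoa_sp2  P01_Holozoa_sp1        Amoebozoa  Holozoa        0.868214
```

Distances are substitutions/site: the two paralog-P01 sequences from
Amoebozoa and Holomycota are mutual nearest neighbours at 0.85 subs/site.
In this run 95–100% of the retained sequences are ground-truth slow
evolvers, and profiles built from the retained set classify the remaining
sequences to their true paralog with ≥ 99% accuracy (see the test suite).

The same stages are available as a library (`scrollsaw.minpairs.run_scrollsaw`,
`scrollsaw.treeops.mad_root`, `scrollsaw.treeops.dollo_map`, …) and through
`scrollsaw run-all`, which executes every stage for which inputs are given
and writes a manifest sufficient to re-run bit-identically.

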