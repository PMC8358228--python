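# Methods

This note documents the models and procedures implemented in `scrollsaw`,
the parameters that matter, the synthetic data the guarantees are measured
on, and the numerical and design choices a maintainer should know about.

## Substitution model and pairwise distances

The evolutionary model is a reversible amino-acid CTMC: rate matrix
Q<sub>ij</sub> = S<sub>ij</sub>·π<sub>j</sub> (i ≠ j) from the published WAG
exchangeabilities S and stationary frequencies π, diagonal set so rows sum
to zero, scaled so the expected number of substitutions per site per unit
branch length is 1 *after* accounting for rate classes. Among-site rate
variation uses the mean-of-equal-probability-bin discrete gamma (shape α,
default 4 categories; category means via the incomplete-gamma identity, so
the discretised mean is exactly 1). The invariant-site class ("+I") has rate
0 and weight p_inv; the gamma classes share weight (1−p_inv)/k and are
multiplied by 1/(1−p_inv) so the mixture mean stays 1. The published WAG
frequencies are used; an observed-frequency ("+F") variant is deliberately
not implemented.

Pairwise distances maximise the two-sequence likelihood over the single
branch length t: sites are summarised as a 20×20 pattern count matrix after
pairwise deletion of columns containing a gap or X in either row; the
per-pattern probability is π<sub>x</sub>·Σ<sub>c</sub> w<sub>c</sub>·P<sub>c</sub>(x→y | t),
evaluated through one cached spectral decomposition of the symmetrised rate
matrix. Counts are symmetrised up front (valid under reversibility), making
the estimate exactly independent of argument order. Optimisation is bounded
scalar minimisation on t ∈ (0, d_max] to an absolute tolerance of 1e-6.

Parameters and defaults: `d_max` = 10 subs/site (saturated pairs return the
cap, never infinity); `min_overlap` = 30 comparable columns (pairs below it
are flagged undefined, carried as NaN, and treated as +∞ by the pair
search); α = 1.0 and p_inv = 0 unless fitted.

**Weak identifiability of (α, p_inv).** `fit_rate_params` maximises the sum
of pairwise log-likelihoods over a seeded subsample of pairs (gamma shape
profiled on a log grid with the invariant fraction optimised per grid point,
then a Nelder–Mead polish). This composite likelihood has a long flat ridge
trading α against p_inv — a few log-likelihood units across α ≈ 0.5–3 with
p_inv compensating between 0 and ~0.35 — so the individual point estimates
are not reliable and should not be over-interpreted. Points on the ridge
yield nearly identical *distances* (within ~3% in our simulations, tightest
at short distances), which is the quantity the pipeline consumes; the test
suite checks exactly that, plus that the fit reaches the ridge.

## ScrollSaw filtering

For each unordered pair of taxonomic groups, distances are computed on the
two-group subset and the mutually-minimal cross-group pairs extracted. Ties
emit all co-minimal pairs (deterministically ordered); undefined distances
never pair. Only cross-group distances are computed — with pairwise deletion
this is exactly equivalent to recomputing the full subset matrix, at half
the cost. Pairs from all group comparisons are pooled into a ledger counting
pairs per sequence; the pan-eukaryotic mode retains sequences in ≥ 2 pairs,
the taxon-specific mode retains all paired sequences (both thresholds
configurable). The filter's enrichment for slow evolvers is a statistical
property, not a guarantee; on the default synthetic family ≥ 95% of retained
sequences are ground-truth slow.

## MAD rooting

For a candidate root at relative position ρ on branch (i, j) of length L,
every tip pair (b, c) contributes a relative deviation from the clocklike
expectation: pairs straddling the branch use the candidate root as ancestor,
r = |2·(d(b,i) + ρL)/d(b,c) − 1|; same-side pairs use their fixed
path-meeting node m, r = |d(b,m) − d(c,m)|/d(b,c), computed from path
distances via the three-point formula. The per-branch score is the RMS of r
over all pairs, with the straddling part quadratic in ρ and minimised in
closed form (ρ clamped to [0,1]); the global minimum over branches is the
root. Pairs at zero path distance are excluded with a warning; ties break by
deterministic branch enumeration; multifurcations need no binarisation since
everything is path-distance based; two-tip trees are a closed-form special
case (midpoint). Node–node distances come from per-node traversals of the
undirected topology (O(n²), fine at the tree sizes this pipeline roots).

On 16-tip Yule trees with strict-clock branch lengths perturbed by 5%
multiplicative lognormal noise, the true root branch is recovered about 95%
of the time (93–96% across 200-tree batches); failures are near-ties in
which the MAD score of a neighbouring branch comes within a few percent,
typically when the root branch is short relative to the noise.

## Dollo gain/loss mapping

Presence–absence patterns are explained by a single gain (at the MRCA of
present tips, or at the root for paralogs assumed ancestral) plus losses on
the stem edges of the maximal clades, within the gain subtree, whose scored
tips are all absent. This greedy placement attains the minimum loss count
under a single-gain model (verified exhaustively against a minimal-labelling
recursion in the tests). Tips scored unknown — e.g. lineages with
transcriptome-only data, NA cells in the matrix — are excluded from scoring:
they neither trigger nor block a loss.

## Clade assignment and profiles

Tree-based assignment walks from the query tip rootward and takes the first
ancestor whose subtree contains a reference and whose branch support passes
*both* thresholds (SH-aLRT ≥ 80, ultrafast bootstrap ≥ 95; missing supports
fail, which is the conservative reading). One reference label assigns it; a
label set matching a configured composite (e.g. {Arf1, Arf6} → "Arf1/6")
assigns the composite; anything else is unassigned.

Profiles are position-specific log-odds scores over match columns (residue
occupancy ≥ 50%), with background-weighted pseudocounts (mass 1.0) and
scoring by affine-gap Smith–Waterman (free ends, floor 0; gap open/extend
11/1 bits). This is deliberately not a plan7 HMM: absolute bit scores do not
match HMMER's. In particular, raw local-alignment scores of unrelated random
sequences sit around log2(mn) ≈ 10–18 bits rather than near zero, because no
null/length correction is applied. What is preserved is the decision rule —
assign to the best profile only when the best-vs-second margin is ≥ 20 bits
(configurable for recalibration) — and the tests calibrate at that level:
null margins stay far below 20 bits while true members classify with wide
margins. The "best 1 domain" notion is interpreted as the best single local
alignment, not a summed multi-hit score. Tree evidence, when present, takes
precedence over the profile rule.

## Introns and motifs

Intron positions are 1-based counts of coding nucleotides preceding the
intron, stop codon excluded; phase = n mod 3; phase-0 introns sit after
residue n/3, phase-1/2 introns belong to residue ⌊n/3⌋+1. Residues map to
alignment columns by counting non-gap characters. Shared-position clustering
is exact on (column, phase) — no fuzz window, since homology of intron
positions is assessed on curated alignments (a ±k hook exists in the cluster
key design but defaults to exact). Motif checks are purely positional (Gly2,
Lys3, N-terminal Cys within a 25-residue window, Cys fourth from the
C-terminus for CaaX; the CaaX "a" positions are reported, not enforced).
Predictor consensus is k-of-n with missing tool output counted as negative
(the literal "predicted by at least k tools"); a renormalising policy is
available.

## Synthetic data

The generator emulates a deep paralog-rich family: a Yule backbone over the
13 default taxonomic groups (depth 0.4 subs/site) with small Yule subtrees
of species within groups (depth 0.2), 5 paralogs each descending from a
shared ancestral sequence through its own duplication branch (length 1.0),
148 alignment columns (a trimmed GTPase-domain length), WAG+Γ(α=1) rates
shared across paralogs so columns are comparable family-wide, and one
designated fast species per group whose pendant branch is multiplied by 4.
Intron sites are planted per clade as (residue, phase) pairs and inherited
with a configurable retention probability; losses are placed on non-nested
edges whose union never tiles a larger clade (otherwise minimal Dollo
counting would merge them and exact recovery would be ill-posed); predictor
tables flip ground truth with per-tool false-positive/negative rates. All
streams derive from one seed.

What the simulation does *not* contain — and hence what passing tests do not
demonstrate about real data: indels and alignment error (columns are exact,
so intron round-trips and profile columns are cleaner than reality),
compositional heterogeneity across lineages, domain gains/losses, gene
conversion, and taxon sampling as uneven as real databases. The rate
contrast (4×, one fast species per group) is a mild stand-in for the extreme
divergence of real fast lineages.

## Numerical and scale choices

Likelihood evaluations run on observed site patterns only, through one
eigendecomposition per model; the ScrollSaw run on the default 195-sequence
family (~17,500 cross-group ML distances) takes ~10 s on one core. Problem
sizes in the test and acceptance runs — 10,000 sites for distance-recovery
envelopes, 200 trees for root-recovery rates, 10,000 sequences for consensus
envelopes, the 195-sequence family end-to-end — were chosen so each
statistical check has enough resolution while the whole suite stays
desk-scale. The distance optimiser tolerance is 1e-6; saturated pairs return
`d_max` exactly; profile scoring uses a one-pass vectorised row update that
is exact when gap-open ≥ gap-extend (double gaps in one row are then never
optimal).

## Known limitations

Pairwise (α, p_inv) estimation identifies a ridge, not a point (above).
Bit scores are not HMMER-comparable; the 20-bit margin is preserved as a
decision rule but anyone recalibrating against real hmmscan output should
re-derive the threshold. MAD rooting is O(n²·pairs) and intended for the
modest trees this workflow roots, not for thousands of tips. External tree
inference (IQ-TREE/MrBayes), alignment construction, and the internals of
TM/lipidation predictors are out of scope by design: trees with supports and
predictor call tables are consumed, never produced.
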