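# Methods

## Problem setting

Cold-shock proteins (Csps) are classified here by *anchor residues*:
positions stated in the numbering of a named reference protein (CspD
position 43, CspA position 4, ...) and projected through a multiple
sequence alignment onto every family member. The pipeline has four
computational stages — anchor typing, tree building with monophyly
assessment, per-genome distribution statistics, and band-quantitation
arithmetic — plus a synthetic-data generator that plants known structure
so every stage can be verified end to end.

## Coordinate mapping and trimming

Residue numbering is 1-based throughout the user-facing surface (matching
the "K43", "K4" convention); alignment columns are 0-based internally.
`column_of` finds the column holding the *k*-th non-gap character of the
reference row by a linear scan, so inserting all-gap columns can never
change the residue an anchor reads out.

Trimming keeps exactly the columns whose gap fraction is at most
`max_gap_frac` (default 0.8; the threshold is a free parameter because
published gap-removal settings vary) and records a *provenance map* from
surviving columns to original column indices, composed across repeated
trims. Anchors are always located on the untrimmed alignment and mapped
through the provenance, so an anchor whose column was trimmed resolves to
an explicit `trimmed` marker for every sequence rather than silently
shifting to a neighbouring column. Typing is done on the untrimmed
alignment by default — trimming exists for distance computation — and the
reports note this.

## Loop typing

The label is a pure function of the two loop-anchor residues:
(K,A) → K-A, (K,E) → K-E, (K,·) → K-other, (D,E) → D-E, a gap (or a
trimmed anchor) at either position → unaligned, anything else → other.
The ambiguity code X at either position yields "other" rather than an
error, because real proteomes contain ambiguity codes and an unknown
residue cannot support a positive type claim — this rule takes precedence
over the (K,·) → K-other branch. The K-first share statistic uses
{K-A, K-E, K-other} as its denominator (gapped members excluded), and the
dual-lysine count requires lysine at both the first loop anchor and the
K4 anchor. The per-protein table always carries the raw anchor residues
alongside the label so alternative typings can be derived without
recomputation.

## Phylogeny

Distances are p-distances over mutually ungapped columns with the Poisson
multiple-hit correction `-ln(1 - p)`; p is capped at 0.95 (with a warning)
so saturated pairs stay finite. Tree building is Saitou-Nei neighbor
joining, chosen as a deterministic desk-scale stand-in for
maximum-likelihood inference; externally inferred Newick trees are
accepted everywhere a tree is consumed, so a user can substitute an ML
tree without touching the rest of the pipeline. Two numerical rules make
NJ runs reproducible to the byte: Q-criterion ties break toward the
smallest (i, j) pair in working label order, and a negative branch length
from the join formulas is clamped to zero with the deficit moved to the
sibling branch (preserving the joined pair's path length). NJ is exact on
additive distances, which the tests exploit as an oracle.

Monophyly on the unrooted tree is the bipartition criterion: a leaf
subset is monophyletic iff it, or its complement, is a side of the split
induced by some edge (pendant edges included, so singletons and their
complements are trivially monophyletic). Because the criterion is
symmetric in a set and its complement, monophyly of a type never depends
on rooting. The report adds the minimal split distance to monophyly —
the smallest count of mismatched leaves against any split side — as a
graded measure when strict monophyly fails. No support values are
attached; clade claims are topological.

## Group comparison

Genomes are split at a Csp-count threshold (default 3: one-or-two versus
three-or-more). Features (genome size in bp, GC fraction) are compared
with a two-sided Mann-Whitney U test on midranks, U = min(U_x, U_y). The
p-value is exact by full enumeration of rank arrangements when the
smaller sample has ≤ 8 observations and there are no ties (at most
C(16,8) = 12,870 arrangements); otherwise a normal approximation with
tie-corrected variance and a 0.5 continuity correction is used, clipped
to (0, 1]. The comparison is always nonparametric: normality screening is
deliberately not implemented, since the rank test is the terminal choice
for these skewed features. Reports carry medians and IQRs (the natural
location summaries for a rank test) alongside means, the U statistic, the
p-value and the direction of effect; an empty group yields a
"not testable" verdict, never a fabricated p-value.

## Quantitation

Relative RNA levels divide each sample's band intensity by the reference
lane's intensity *within the same replicate*, so a common gain factor per
replicate cancels exactly; optional loading-control normalization
(e.g. tmRNA) pre-divides each lane and is off by default because
reference-lane division already defines the relative level. The
specificity score is computed per replicate — relative efficiency for
*baxL* (CspD reference) minus relative efficiency for *gdx* (CspA
reference) — then aggregated as mean ± sample SD (ddof = 1). Computing
per replicate and then aggregating, rather than scoring replicate means,
propagates replicate error into the reported SD; the output labels this
convention. Readthrough is `100 · RT / (T + RT)`; enrichment is the bound
sum over the crude sum of the listed component bands (full-length plus
truncated where both exist).

## Synthetic data

The family generator emulates the features the analysis depends on and
nothing more:

- **Scaffold**: a fixed 70-residue CSD-like ancestral core (the canonical
  *E. coli* CspA sequence) with the RNP1 ("KGFGF") and RNP2 ("VFVHF")
  blocks and the anchor sites held invariant under mutation.
- **Tree**: one Yule subtree per type, joined at a common backbone, so
  each planted type — in particular K-A — is a true clade. Within-subtree
  edges substitute each unprotected site with probability `sub_prob`
  (default 0.02, ≤ 0.3 by contract); backbone edges apply five rounds of
  that probability, encoding that the types are anciently diverged
  subfamilies and giving the planted clade a real phylogenetic signal
  rather than an anchor artifact.
- **Substitution model**: uniform replacement over the 19 alternatives.
  Downstream checks concern typing and topology recovery, not
  evolutionary realism, so no empirical exchange matrix is used.
- **Anchors and extensions**: loop residues are overwritten per type
  (K-A, K-E, D-E, and for "other" the loop pairs F-E, A-E, T-T, N-E seen
  in the remaining *E. coli* paralogs, cycled deterministically); K-A
  members get E and K-E members A at position 2; D-E members carry a
  3-residue N-terminal extension with lysine planted at full-sequence
  position 4. Core evolution is indel-free, so the true alignment is
  known exactly by left-padding the shorter members with gaps — alignment
  inference is out of scope and never needed.
- **Genomes**: Csp counts drawn from a fixed distribution over 1..10 with
  about two thirds of genomes carrying one or two Csps (mirroring the
  low/high balance of real surveys); base size 4 Mb lognormal (σ = 0.2),
  base GC 0.50 ± 0.04. The high-count group's size is multiplied by
  (1 + size_shift) (default 0.3) and its GC shifted by gc_shift (default
  0.05) before noise; zero shifts make the groups exchangeable, which the
  calibration checks use.
- **Quantitation**: intensity = base × planted relative efficiency ×
  lognormal(0, σ) per replicate, σ = 0.15 and three replicates by
  default; planted per-type efficiencies make K-A-like samples score
  positive and D-E/K-E-like samples negative.

What passing these simulations does *not* show: robustness to indels and
misalignment, to non-uniform substitution processes, to anchor-site
mutation (anchor sites are protected by construction), or to the
database-scale heterogeneity of real genome surveys. The generator
validates the pipeline's arithmetic and inference machinery, not its
behaviour on degraded real data.

## Problem sizes and determinism

Default study sizes are desk-scale by design: 40-member families
(12/8/12/8 across the four types), 6-leaf trees for additive-recovery
checks, 120 genomes, 2,000 null replicates at n = 30 per group for
calibration, 50-200 seeds for recovery rates. All generators are pure
functions of their seed; pipeline runs write a manifest (seed, config
echo, input SHA-256 checksums, package version) sufficient to reproduce
outputs bit-for-bit.

## Known limitations

- Exact duplicate removal only (100% identity on ungapped, upper-cased
  sequence); no similarity clustering at lower thresholds.
- NJ is the only built-in tree method; no bootstrap or other support
  estimation (external trees can carry their own support labels, which
  are ignored by topology comparisons).
- The chimera junction table encodes the published residue counts on the
  CspA side and transcribed offsets on the CspD side; it is shipped as
  editable configuration, not as ground truth.
- GenBank/RefSeq ingestion and homology search are outside the package;
  the pipeline consumes FASTA/Newick/TSV produced upstream.
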