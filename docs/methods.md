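# Methods

`iscutrace` re-implements, as a tested and fully seeded pipeline, a
comparative-genomics workflow for tracing the evolution of two Fe-S
cluster biogenesis proteins across prokaryotic proteomes: the frataxin
homolog CyaY and the scaffold IscU. The pipeline detects family members
by profile search with empirically calibrated E-values, accepts scaffold
homologs through a four-criterion rule, takes a census of the residue at
reference position 108, profiles CyaY/IscU co-occurrence, reconstructs
gain/loss histories by parsimony, and flags horizontal-transfer
candidates by taxonomic incongruence. Because the original corpus of
complete proteomes is not reconstructable, every stage is validated
against synthetic corpora with planted ground truth rather than against
corpus-specific counts.

## Profile model and glocal alignment

A family profile is a column-wise model estimated from a seed alignment.
Column frequencies use background-weighted pseudocounts,

    f_c(a) = (n_c(a) + α·q(a)) / (N_c + α),

with `q` a uniform background over the 20 amino acids and α = 1 by
default; scores are log-odds in bits, `log2(f/q)`. Columns with ≥ 50%
gaps in the seed are non-match columns and excluded from scoring (the
standard profile-construction heuristic). The seed's designated
reference row anchors a 1-based residue numbering; every downstream
positional statement ("the residue at position 108", "the motif at
99–103") is made in this coordinate system, converted from 0-based
column indices only at I/O boundaries.

Queries are aligned **glocally**: the profile must be traversed end to
end (leading/trailing profile deletions are charged) while query flanks
overhang free, so a domain embedded in a longer protein is found, and
the length of the unaligned flanks is itself informative. Gap runs cost
`open + (L−1)·extend` bits (defaults 4 and 1). The three-state dynamic
program is vectorized per column; insertions within a column reduce to a
running maximum, so alignment is O(n·m) with numpy inner loops.
Traceback tie-breaks are fixed (match > deletion > insertion; among end
cells the largest column, then the largest query position), making
outputs bit-reproducible. `X` scores 0 bits in every column (neutral
ambiguity); any other non-standard character is an error. The DP is
checked against exhaustive path enumeration on hundreds of random small
instances.

This is deliberately not a full profile HMM: no trained transition
probabilities, no forward algorithm, no analytic score statistics. The
search here is a retrieval step, and a deterministic log-odds DP is
auditable against a brute-force oracle.

## Empirical E-values

Scores are calibrated per profile by scoring `n` residue-shuffles of
randomly chosen corpus sequences (default 500; seeded). The survival
function is empirical below the 90th percentile of decoy scores and an
exponential tail fitted (mean-exceedance, i.e. maximum likelihood) above
it, so significant scores extrapolate smoothly:

    E(s) = N · P̂(S ≥ s),  P̂(s) = 0.1·exp(−(s−t)/λ) for s > t,

with `N` the database size, `t` the tail threshold and λ the fitted
scale. E is monotone non-increasing and never exceeds N. Two retrieval
policies mirror the two search regimes: *domain mode* keeps any hit with
E ≤ 0.1; *full-sequence mode* (used for CyaY) requires E ≤ 1.7e-7 and
≥ 90% coverage of both the profile match columns and the query span, so
a domain inside a fusion protein is excluded however significant its
score. Hits within 10× of the threshold are marked `borderline`,
replacing by an explicit number the visual curation such analyses
traditionally rely on. Self-consistency is tested: among 1,000 decoys
scored against their own calibration with N = 1,000, the number with
E ≤ 10 must fall in the central 99% binomial interval around 10.

## Scaffold acceptance criteria

A U-family domain hit is accepted as a genuine IscU-type scaffold only
if all four criteria hold:

1. **Cysteines** — Cys aligned at the three most Cys-conserved reference
   columns of the seed (auto-detected, conservation gate 0.95; for the
   built-in seed these are positions 37, 63 and 106). Auto-detection is
   used because only the identity of Cys106 is fixed by the biology.
2. **Chaperone motif** — residues aligned at reference 99–103 match
   LPPVK with at most one substitution, never at the two prolines.
   Family logos show cross-species variation in this region, so an exact
   match would be too strict; the pattern and budget are configuration
   and are echoed in the run manifest.
3. **No additional domain** — both unaligned query flanks ≤ 50 residues.
   This operationalizes the exclusion of NifU-like multi-domain fusions
   deterministically, without a second domain scan.
4. **Gene context** — at least one *other* gene annotated with an
   isc-operon label (iscR, iscS, iscU, iscA, hscB, hscA, fdx, iscX)
   within ±5 gene positions.

Accepted homologs are deduplicated to one representative per species
(best bit score) before any counting, because the downstream claims are
about species, not loci. The census tallies the residue at reference
position 108 per taxonomic group and reports the Ile/Leu/Val fraction;
the logo over 99–108 reports per-column frequencies (gaps excluded from
the denominator) and information `R = log2(20) − H` bits with no
small-sample correction by default.

## Phylogenetic profiling

Presence/absence of the two families per genome (accepted scaffolds;
full-sequence CyaY survivors) feeds three analyses.

**Co-occurrence.** The four (cyaY, iscU) combinations are counted and
every cyaY+/iscU− genome is listed as a violation of the containment
relation (frataxin should never occur without the scaffold).

**Parsimony.** Ancestral states on the rooted species tree are
reconstructed under two modes reported side by side, because a patchy
presence pattern cannot distinguish a loss-heavy single origin from
repeated gains: *Fitch* (unrestricted gains/losses; Hartigan's counting
algorithm, exact on polytomies, root ties resolved to absent — matching
the inference that the gene was absent in the last bacterial common
ancestor) and *Dollo* (single gain at the MRCA of present leaves, one
loss per maximal present-free subtree below it; cost = losses + 1).
Both are verified against brute-force minima over all internal
labelings on trees of ≤ 8 leaves.

**HGT flagging.** A neighbor-joining gene tree is built from
profile-alignment distances (1 − identity over shared aligned columns).
NJ uses deterministic tie-breaks (smallest index pair) and clamps
negative branch lengths to zero, moving the deficit to the sister
branch. Likelihood or Bayesian gene trees are deliberately out of scope;
NJ on these distances is a desk-scale stand-in. A leaf is flagged as a
transfer candidate when all of its k = 3 nearest gene-tree leaves (by
patristic distance) belong to a foreign phylum and fewer than 2 share
its own phylum. This is an explicit operationalization of
"emerges within a foreign clade", not a claim about how such calls were
made historically.

## Synthetic corpus generator

The generator produces miniature corpora with the statistical structure
the analysis assumes, plus complete truth labels.

- **Species tree**: pure-birth (Yule) tree, default 40 taxa, birth rate
  1.0, seeded. Phyla are assigned to crown clades by deterministic
  splitting of the largest clade (target 6 groups, preferring splits
  that avoid groups under 4 leaves; small phyla are tolerated — real
  corpora have them). Branches at or above the phylum crowns are
  lengthened 4× (`stem_scale`): clock-uniform trees lack the deep
  inter-phylum divergence that real corpora show, and the incongruence
  rule assumes between-phylum distances clearly exceed within-phylum
  ones.
- **Presence histories**: joint two-state Markov evolution per family
  with forced gains (iscU at the root; cyaY on a clade of ~25 leaves
  chosen to be a union of whole phyla, each with ≥ 3 members — a native
  near-singleton phylum would be indistinguishable from a transfer
  recipient). The dependency rule is enforced per branch: cyaY gains
  only where iscU is present, and iscU cannot be lost under cyaY, so no
  genome is ever cyaY+/iscU−. Loss/gain rates default to 0 for the demo
  composition and are exercised with nonzero values in tests.
- **Sequences**: root = profile consensus; along each branch each
  unconstrained column resamples from its *empirical* seed column
  distribution (observed counts, no pseudocount mass) with probability
  `min(1, 0.3 · branch length)`. Sampling from the empirical
  distribution means every emitted residue has positive log-odds, so
  the gapless identity alignment is strictly optimal and planted
  positional states are read back exactly — the model is invertible by
  construction, which is what makes exact planted-census tests possible.
  The three Cys columns and the motif are invariant; the column at
  reference 108 is forced per clade: one clade of ~12 leaves is
  designated Met (emulating the rickettsia-like and archaeal
  exceptions), all other phyla cycle through Ile/Leu/Val.
- **Genomes**: 30–45 genes each (random proteins of 60–200 residues);
  the planted scaffold gets an isc-labeled neighbor within ±5 with
  probability `p_ctx` (default 1; lower values create criterion-iv
  negatives); cyaY is placed without isc context. Decoys: NifU-like
  (intact domain + 200-residue extra segment → fails only the domain
  criterion), SufU-like (motif columns scrambled → fails only the motif
  criterion), structural-only analogs and random proteins (no sequence
  similarity → no hit at all). Defaults: 10 + 10 + 5 + 5 = 30 decoys.
- **HGT**: 2 transfers; recipients are iscU+/cyaY− leaves in distinct
  phyla without native cyaY (the emulated events involve two different
  recipient phyla; co-recipients in one phylum would shield each other
  from the k-NN rule); the recipient receives the donor's sequence with
  2% per-column divergence.

Same seed ⇒ byte-identical corpus (FASTA, TSV, Newick, truth JSON).

**What the generator does not emulate**: indel evolution (alignment
lengths are fixed apart from decoy fusions), substitution-matrix or
codon-level realism, rate heterogeneity across lineages, paralogy,
assembly artifacts, and annotation noise in gene labels. Passing tests
therefore demonstrate that the pipeline's logic is correct under its own
assumptions — exact recovery of planted signal in a well-separated
regime — not that real-corpus counts would be reproduced; on real data,
alignment ambiguity and borderline scores would make the `borderline`
flags and threshold choices matter far more.

## Problem sizes and numerical choices

The demo corpus is 40 genomes (~1,500 proteins); a full pipeline run
takes well under a minute on one core, and the complete test suite a
few minutes. Oracle comparisons use instances small enough for
exhaustive enumeration (queries/profiles ≤ 8 for alignment; ≤ 8 leaves
for parsimony), with 100–200 random cases each. Closed-form logo values
are asserted to 1e-9. Floating-point tie detection in traceback uses an
absolute tolerance of 1e-9; the exponential tail scale is floored at
1e-9 to keep E-values defined when tail exceedances degenerate. All
randomness descends from a single integer seed recorded in the run
manifest; independent stages draw from spawned child generators, so
adding draws to one stage does not perturb another.

## Known limitations

- The E-value calibration is empirical; its deep tail is an exponential
  extrapolation and should not be over-interpreted far beyond the decoy
  score range.
- The "no additional domain" criterion bounds unaligned flanks; it
  cannot detect an inserted domain that the glocal alignment absorbs as
  a long internal insertion (none of the planted decoys have this form).
- The k-NN incongruence rule flags any leaf isolated from its phylum in
  the gene tree; a native family member of a (near-)singleton phylum is
  indistinguishable from a transfer recipient by construction.
- Dollo reconstruction with zero present leaves returns an empty
  reconstruction of cost 0 (no gain), a degenerate case outside the
  usual single-origin premise.
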