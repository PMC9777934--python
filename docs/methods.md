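# Methods

`tefp` reconstructs, at desk scale, the computational workflow used to
profile the evolution of Tc1 (DD34E)-type cut-and-paste DNA transposon
families across genomes: mining transposase-homologous loci, delimiting
element boundaries, classifying copies, comparing sequence identities,
assigning clades, testing for horizontal transfer (HT), and summarising
integration-site preferences.  Because the underlying surveys run
against hundreds of public assemblies, the package ships a synthetic
genome generator with complete ground truth so that every stage can be
validated quantitatively without downloads.

## The element model

A family member is modelled as

```
5'TIR — spacer — single transposase ORF — spacer — 3'TIR
```

flanked on insertion by a duplicated TA target site (TSD).  Defaults
follow the ranges this family shows in practice: element length 1.6 kb
(most real full copies sit in 1.5–1.7 kb), TIRs 220 bp (typical range
180–300 bp, observed extremes 27–415 bp), transposase 340 aa (range
302–411 aa).  Classification follows the standard definitions:

- **full copy** — both TIRs detectable and identical flanking TSDs;
- **intact copy** — a full copy whose longest ORF encodes ≥ 300 aa
  (proxy for recent or current activity);
- everything else found by the homology search is a *hit-only* locus.

All coordinates are 0-based half-open; strands are `+`/`-`.

## Synthetic data generator (`tefp.simulate`)

A random ultrametric species tree (uniform merge heights below the root,
root at `tree_height` expected substitutions/site) supplies expected
pairwise divergences (twice the MRCA height).  Two host-gene stand-ins
(RPL3/RPL4-like CDS, 1,200 nt) evolve along the tree under Jukes–Cantor
at the species rate.  The element lineage of each species evolves along
the same tree at `te_rate_scale` (default 2.0) times the species rate:
ribosomal-protein CDS are under strong purifying selection whereas
transposon sequence drifts neutrally, so vertically transmitted element
divergence normally *exceeds* host-gene divergence — the premise that
makes an anomalously *low* element distance evidence of HT.  Two
constraints model selection for transposition competence in active
lineages:

- **TIR mirroring** — after every branch, the 3' TIR is reset to the
  exact reverse complement of the 5' TIR.  Without this, the two termini
  of a freely drifting element would decohere as inverted repeats and no
  real element lineage behaves that way.
- **ORF preservation** (`preserve_orf`, default on) — substitutions
  inside the master/copy ORF are resampled to avoid premature stops and
  keep the start and terminal stop codons.  This makes planted,
  non-truncated copies genuinely intact, so intact-recovery scoring is
  well defined; setting the flag off yields decayed pseudogene copies.

Copies are planted only at TA dinucleotides (strict by default), with
the target duplicated to give identical 2-nt TSDs.  Each copy receives
independent JC decay at `decay_rate`; with probability
`truncation_prob` it loses one terminus.  The truncated fraction is
drawn uniformly from 10–60% of the element but never less than the TIR
plus 10 nt — removing less would leave a detectable partial TIR and a
"truncated" copy that still classifies as full, which would make the
truth labels incoherent.  Insertion sites are kept ≥ ~6 kb apart so
extracted loci never overlap.  All randomness flows from the single
config seed through one generator; identical seeds give bit-identical
outputs.

HT is injected by replacing the recipient species' element lineage with
the donor's evolved for the stated (low) transfer divergence, TIRs
re-mirrored.  `expected_te_divergence` gives the resulting expected
element distance for every pair (vertical scaled divergence between
lineage origins plus the transfer extras); `choose_ht_edges` uses this
*expected-distance rule oracle* to pick edge sets whose footprint under
the 1.2× ratio rule is exactly the injected set, with a multiplicative
safety margin (default 1.4) so finite-sequence noise cannot flip a
decision.  This defines the study conditions by construction rather
than tuning anything against estimates.

## Homology search (`tefp.search`)

A TBLASTN-like translated search: genomes are translated in six frames
(N-containing codons → X), exact 4-aa word seeds are grouped by
diagonal band (two-hit requirement), and candidate windows are rescored
by local protein alignment (BLOSUM62, gap open/extend 11/1, via
Bio.Align).  Significance is the Karlin–Altschul E-value
`E = K·m·n·exp(−λS)` with the standard gapped BLOSUM62 constants
(λ = 0.267, K = 0.041) and database size `n` counted over both strands;
the reporting cutoff is 1e−4.  Exact-word seeding loses sensitivity
below ~45% amino-acid identity, so the search supports bounded
iterative re-querying (default 2 rounds): the longest recovered
transposase segments (up to 3) become fresh queries, which restores
sensitivity inside a genome whose copies are mutually similar — the
same device the original mining protocols use.  Hits are deduplicated
across frames, windows and rounds by coordinate overlap.

Copy counting is nucleotide-level: the per-genome consensus or
representative is searched back against the genome (12-nt exact seeds,
local alignment, match +1 / mismatch −2), hits with query coverage
> 40% and identity ≥ 90% are kept, and qualifying hits overlapping by
≥ 1 nt on one strand merge into a single copy.  Best hits are extracted
with 2 kb of flank on each side (clipped silently at contig edges, the
clipping recorded); minus-strand loci are reverse-complemented.

## Element annotation (`tefp.annotate`)

TIR detection is a gapless inverted-repeat scan: +1 per matching
column, −1 per mismatch, mismatches capped at 15% of the length,
lengths 20–450 bp, 5' candidate in the first and 3' candidate in the
last `search_window` nt.  For windows ≤ 800 nt the scan is exhaustive
over every (5' offset, 3' offset, length) triple, vectorised over the
diagonals of the match matrix with a per-diagonal total-match bound for
pruning (the pruning is exact: a window cannot beat the bound).  Ties
break toward longer length, then smaller 5' offset, then the outermost
3' start — documented because the oracle tests compare output
tuple-for-tuple.  Wider windows (pipeline loci carry 2-kb flanks, so
TIRs sit well inside) are first narrowed by exact inverted 10-mer seed
pairs bucketed on the anti-diagonal, then refined with the same
exhaustive scan inside the candidate subwindows; planted-recovery tests
cover the equivalence of the two paths.  Gapless scoring cannot model
indels within a TIR; for this family's decay regime that limitation is
immaterial, and the manual curation it replaces was also
alignment-column based.

Because a match plus a mismatch scores zero, the raw best pair tends to
overrun the true boundary by a few neutral columns — in particular any
TA-flanked boundary's duplicated-target columns pair with each other
for free (TA is self-complementary), which biases the raw score toward
spuriously *outer* TA boundaries.  A boundary-refinement step therefore
examines symmetric outer trims/extensions of the raw pair, collects
every candidate boundary flanked by the family TSD motif on both sides,
and walks from the innermost outward: an outer candidate replaces the
current one only when, after discounting the current candidate's two
self-pairing TSD columns (always +2 in the outer score), the remaining
columns still show repeat-like gain (more than ~0.2 per column, the
midpoint between the expected score drift of genuine repeat columns and
of background columns).  Without any TA-flanked candidate the
best-scoring shift wins.  This changepoint-style rule removes the
systematic outward bias without letting damaged repeat columns pull the
boundary inward, and is the automated counterpart of curating element
boundaries against the flanking alignment.

The ORF finder translates the element in all six frames and returns the
longest ATG-to-stop ORF (≥ 100 codons; ties to the earlier start).
Classification is then deterministic: both TIRs + matching TSDs →
full; additionally ≥ 300 aa → intact.  Per-genome references follow
the >10-copies rule: a column-majority consensus over a MAFFT alignment
(ties resolved with IUPAC codes, majority-gap columns dropped) above
the cutoff, otherwise the longest copy with intact-first preference.
Exactly 10 copies take the representative path (the published rule
leaves 10 undefined; "fewer than the cutoff" is read inclusively).

## Identities, clades, distances (`tefp.identity`, `tefp.phylo`, `tefp.distances`)

Percent identity uses a global end-gap-free pairwise alignment;
the denominator counts alignment columns between the first and last
doubly-occupied column (terminal overhangs free, internal gaps
penalised in the count).  Arguments are ordered canonically before
alignment so the measure is exactly symmetric even when co-optimal
alignments exist.  Group matrices average over all cross pairs (within
pairs on the diagonal, excluding self; single-sequence groups report an
undefined diagonal).  Protein domain partitions are defined on the
packaged reference: DBD = first 120 residues (through the linker),
DDE = remainder.

Clade assignment builds a neighbor-joining tree (own implementation;
Q-matrix ties break toward the lowest index pair, no branch-length
clamping, exact on additive matrices) over a MAFFT protein alignment of
queries plus a reference panel, using pairwise-deletion p-distances.
The tree is rooted at the outgroup-family reference (DD37D/maT); a
query takes the clade of the smallest ancestral subtree containing any
reference, or `other` if that subtree mixes clades or holds only
outgroup families.  Support is the fraction of column-resampled
bootstrap NJ trees (default 100) reproducing the full-data label.  The
packaged panel (`tefp.references`) is a deterministic *synthetic
stand-in* with the documented lengths (ZB 341 aa, SB100X 340 aa) and a
realistic identity structure (~61% clade↔sibling, ~35% ZB↔SB, ~25% to
the seven outgroup families); assignment depends only on relative
distances, not on the actual residues.

Distances are computed on aligned CDS with pairwise deletion and a
100-site floor.  `p`, `JC` and `K2P` are the textbook estimators;
`TN93-CL` mirrors the maximum-composite-likelihood behaviour of
distance packages by estimating base frequencies and the split of
substitutions into the two transition classes and transversions once
from counts pooled over *all* pairs in the run, then applying them to
each pair's own mismatch proportion through the Tamura–Nei formula.
Saturated logs and short overlaps are flagged, and flagged records
propagate to an `excluded` HT decision rather than a call.  The HT rule
is the conservative reading of "1.2 times smaller": a pair is HT iff
`d_TE × 1.2 < d_RPL3` **and** `d_TE × 1.2 < d_RPL4`, strict inequality
(boundary equality → vertical), after excluding pairs whose element
CDS identity is below 70%.  Aggregation marks a species "involved" for
a family if it appears in ≥ 1 HT pair; the involvement denominator is
the set of species in which the family was detected (species excluded
by the identity filter remain in the denominator).  Plain nucleotide
CDS alignment feeds the distances (codon-aware alignment is not
implemented); MAFFT is the aligner throughout.

## Integration-site profiles (`tefp.sitepref`)

Insertion windows are 40-mers with the target TA at 1-based positions
20–21 (minus-strand elements reverse-complemented; windows clipped at
contig edges dropped and counted).  Profiles report per-position
A/C/G/T counts and plug-in information content
`2 + Σ f·log2 f` bits against a uniform background (no small-sample
correction by default), plus a MEME-minimal export.  TIR end-motif
profiles pool the first 20 bp of the 5' TIR with the reverse complement
of the last 20 bp of the 3' TIR.  Windows are pooled across genomes per
family.

## Pipeline and summaries (`tefp.pipeline`, CLI `tefp`)

`run_pipeline` chains search → annotation → classification → reference
building → (optional) clade assignment → identities → distances → HT →
profiles → summary tables; re-running an identical configuration is
bit-identical, and a JSON log records every threshold applied.  Summary
tables bin genomes by full/intact copy number ({1–9, 10–99, ≥100}),
report mean ± SEM (sample SD/√n) of per-genome copy numbers with "/"
where n < 2, and recompute every percentage from its numerator and
denominator with half-up rounding to two decimals.  The CLI exposes
`simulate`, `search`, `annotate`, `identities`, `clades`, `ht-call`,
`profile` and `run` subcommands as thin wrappers.

## Validation conditions (`tefp.validation`)

The property suite runs at fixed, documented problem sizes chosen to
exercise each stage meaningfully: planted-element recovery on 12
simulated 1-Mb genomes with 20 copies each (decay 0.03, truncation
0.2); TIR-finder agreement with an exhaustive all-pairs oracle on 200
random 3-kb loci with planted repeats (20–415 bp, 0–15% mismatch);
distance calibration at true divergences {0.05, 0.2, 0.5} over 200
replicates of 10-kb pairs; HT recovery of 4 injected edges among 12
species with factor-monotonicity over {1.0, 1.2, 1.5, 2.0}; NJ
exactness on 100 random 5-taxon additive matrices; and the forced
2.0-bit centre of the insertion profile.  What these runs demonstrate
is the correctness of the machinery against known truth — not
performance on real assemblies, where fragmented contigs, nested and
mosaic insertions, indel-rich decay and non-TA microsatellite context
add failure modes the generator deliberately omits (no indel evolution
beyond whole-terminus truncation, no selection, no within-species
variation).

## Known limitations

- The translated search is not a general BLAST replacement: no
  composition-based statistics, no HSP chaining, exact-word seeding
  (sensitivity below ~45% aa identity relies on iterative re-querying).
- Gapless TIR scoring; boundary refinement assumes the family's TA TSD.
- NJ + nearest-reference stands in for ML tree inference; an exported
  alignment hook is provided for external ML runs.
- The reference panel is synthetic; real analyses should substitute the
  published transposase sequences.
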