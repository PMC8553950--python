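# Methods

This note documents the models, rules, defaults, and numerical choices
behind `luxscreen`, and what the synthetic-data experiments do and do not
demonstrate.

## Gene screen

**KO best-hit rule.** An ORF is a putative QS gene iff
max bitscore over QS-KO hits > max bitscore over all other KO-labelled
hits. The inequality is strict: an exact tie is rejected (and logged),
because a tie carries no evidence that the QS assignment is the better one.
Hits without a KO label do not compete — the rule compares KO-mapped scores
only. The rule is invariant under permutation and duplication of hit rows
(it depends only on per-group maxima). KO sets default to the AHL synthase
group {K13060, K13061, K13062, K18096} and the AHL receptor group
{K07782, K18098, K18099} and are configurable.

**Domain validation** consumes a precomputed Pfam hit table (running HMMER
is out of scope); a synthase needs the autoinducer-synthase domain
(Pfam00765), a receptor needs both the autoinducer-binding (Pfam03472) and
GerE DNA-binding (Pfam00196) domains, each at e-value ≤ 1e-5 (default,
configurable). An empty table leaves candidates "untested" rather than
failed. Pfam accessions are compared by numeric part, so `PF00765.29` and
`Pfam00765` match.

**Residue audit.** Conserved-residue positions (acyl binding: W66, D79,
P80, W94, G121; DNA binding: E187, L191, G197) are defined in the numbering
of a reference LuxR supplied by the user. The shipped default reference is
*synthetic*: a deterministic 210-aa scaffold with the expected residues
planted at the annotated positions. It gives the audit a well-defined
coordinate system for testing but is not a biological sequence; audits of
real proteins should supply a curated reference. Queries are globally
aligned to the reference (Bio.Align.PairwiseAligner, BLOSUM62, NCBI-style
affine gaps: a length-k gap costs 11 + k). A reference position aligned to
a gap is reported but not counted as missense; a mismatched residue is.
Ties between equally scoring alignments are broken by the aligner's
deterministic enumeration order.

**Cognate pairing.** The distance at which a luxI and luxR count as
cognate is not well defined in the literature; the default allows at most
3 intervening ORFs on the same contig, which captures adjacent and
divergent arrangements without bridging across operons. Matching is greedy
nearest-first (ties broken lexicographically by ORF id), each gene in at
most one pair. Orientation is classified from strands in contig order:
left gene on − and right gene on + is *divergent* (promoters share the
gap), the mirror arrangement is *convergent*, equal strands are *tandem*.

## Taxonomy

Per ORF, the S_best window keeps every hit with bitscore ≥ 0.95·S_best.
The boundary is inclusive (≥, not >) so a hit exactly at the cutoff — a
common artifact of tied database sequences — is kept; a strict mode is
available. The consensus function is the label held by strictly more than
half of the labelled window hits, otherwise "ambiguous" (no lexicographic
tie-breaking, so no silently arbitrary labels). The LCA is the deepest
lineage prefix shared by every window hit that carries a lineage; hits
without lineages are excluded, and lineages that disagree already at the
root yield "unclassified".

The tiered contig rule calls a contig for the target taxon when
(>6 ORFs and >50% target) or (4–6 ORFs and >60%) or (≤3 ORFs and 100%).
The published tiers leave exactly 3 ORFs uncovered ("between 4 and 6"
versus "fewer than 3"); tier iii is extended to n = 3, the conservative
choice (unanimity required), and every report where that extension fires
carries a note. Fraction thresholds for tiers i and ii are strict.
An ORF counts as target when the target lineage (or a single rank:name
pair, e.g. `genus:Nitrospira`) is a prefix of (appears in) its LCA, so
deeper species-level LCAs under the target still count.

## Lux-box model and scanning

**PWM.** Column counts from the aligned library (equal-length ACGT sites;
ambiguity codes are rejected in training) are smoothed with a pseudocount
of 0.1 per cell (default) and converted to log2-odds against the
background. The `N` base scores 0 — the background-expected contribution.

**Exact p-values.** Site significance is
P(score of a background-random w-mer ≥ observed score), computed exactly on
a discretized score lattice: all columns share one step ε (the widest
column's log-odds range divided by `granularity`, default 1000 bins), each
log-odds entry is rounded to its nearest lattice point, and the
distribution of the integer score sum is built by per-column convolution
under the background. The survival function is cached per (model,
granularity). Raw scores map to the nearest lattice point; scores at or
below the minimum return 1.0, scores above the maximum return the smallest
positive mass (never 0). With 1000 bins per column the lattice error in
log-odds is below 0.05% of the score range; the tests compare the DP
against brute-force enumeration over all 4^w sequences on the same lattice
and agree to < 1e-9.

**Background.** The null defaults to the scanned region's own nucleotide
composition with add-one smoothing (so a region lacking a base still has a
proper distribution); clipped regions fall back to the model's training
background. A fixed-model background is available (`background="model"`),
and is what the strand-symmetry tests use, since a region and its reverse
complement have complementary compositions.

**Upstream regions** are 400 bp (default), 1-based inclusive, oriented
5'→3' toward the start codon: for a + ORF starting at s, positions
[max(1, s−400), s−1]; for a − ORF ending at e, the reverse complement of
[e+1, min(L, e+400)]. Shorter-than-requested regions are flagged clipped;
an ORF flush with the contig edge yields an empty region with a warning.

**Scanning** scores both orientations at every offset and reports only the
better one (tie → +), so near-palindromic sites are not double-counted.
Hits with p < 1e-4 are kept; the regulon filter additionally requires ≤ 8
palindrome mismatches (the number of positions at which the site differs
from its reverse complement — always even). The cap of 8 is a decided
parameter, not a literature value: it must admit both experimentally
validated boxes, which have 2 and 8 mismatching positions respectively.

**Promoter context.** Downstream of a candidate site, −35 (TTGACA) and −10
(TATAAT) hexamers are matched with ≤ 2 mismatches each (σ⁷⁰ consensus
conventions); a compatible pair needs a 15–19 bp spacer and the
fewest-total-mismatch (then leftmost) pair wins, otherwise the elements are
reported individually as unpaired. The Shine–Dalgarno search looks in the
final 20 bp of the region for ≥ 4 consecutive matches to AGGAGG ending
4–14 nt before the start codon. `distance_upstream` counts nucleotides
strictly between the site's proximal edge and the first base of the start
codon. A site overlapping any ORF interval by ≥ 1 bp is *intragenic*. One
genomic site falling in the upstream regions of two divergently transcribed
ORFs yields two cross-referenced candidates — the bidirectional-promoter
situation the screen is designed to surface.

## Synthetic data

The generator emulates the study conditions at desk scale: 13 synthases, 9
cognate pairs, 21 receptor solos, a 54-site lux-box library drawn by
mutating the consensus `ACCTGGCGGTTCCGCCAGGT` at 5% per column, 40 contigs
of 2–20 kb at ~0.9 ORFs/kb and GC 0.5, and a taxa mix dominated by
proteobacterial classes with a *Nitrospira* component. Pair contigs carry a
receptor(−) / synthase(+) divergent arrangement with the box planted at
exact distances (defaults 81 bp to the synthase, 125 bp to the partner) in
the shared promoter gap; hit tables are constructed so the KO rule, window,
LCA, and tier rules hold for the planted roles; paired receptors carry the
unmutated reference protein while solos carry 1–3 recorded missense
substitutions in the acyl-binding residues. One root seed spawns
per-component child streams, and outputs are byte-identical under the same
(config, seed).

What this does *not* emulate: codon structure (ORFs are strand-labelled
intervals, never translated), sequencing error or assembly artifacts,
compositional heterogeneity along contigs, homology between decoy proteins,
or realistic bitscore distributions. Passing recovery tests therefore shows
the *rules* are implemented correctly and are recoverable under their own
assumptions — not that the screen's sensitivity on a real 3.7-Gb metagenome
would match. The headline counts of any real study depend on the assembly
and database versions and are not desk-reproducible; recovery of planted
truth is the appropriate test at this scale.

Scan-rate expectations: at p < 1e-4 on ~762 strand-offsets per 400-bp
region, roughly 7% of background regions would carry a spurious raw hit;
the palindrome filter and the discrete score lattice bring the observed
false-positive region rate to ≤ 5% in the planted-region experiment (100
regions, 50 planted, ≤ 2 substitutions), with recall ≥ 0.9.

## Pipeline

Stages run in screen order (load → classify → validate → audit → pair →
annotate taxonomy → bin contigs → build motif → predict regulon), each
echoing its parameters to a timestamped log; the summary JSON is
deterministic (no timestamps) and its counts are asserted against the
per-stage tables before writing. The GFP fold statistic aggregates
replicates as mean-of-ratios — mean(gfp/OD600) per condition, then the
induced/uninduced ratio — because per-replicate OD normalization is the
usual plate-reader convention; the hit call is strict (> 1.5). Statistical
comparison across promoter constructs (ANOVA, multiple-comparison tests) is
out of scope.

Problem sizes used by the test suite and `scripts/acceptance.py` (seeded,
a few seconds in total): 20 random PWMs of width ≤ 6 against 4^w
enumeration; 1,000 random windows for the LCA/consensus oracle; 100
planted regions for recall/false positives; a 6-contig community for
end-to-end recovery and the default 40-contig community for the
study-scale counts; 50 mutated receptor queries for the residue audit.
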