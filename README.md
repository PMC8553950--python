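# luxscreen

A reusable pipeline for screening assembled metagenomes for acyl-homoserine-
lactone (AHL) quorum-sensing machinery and for predicting the AHL-regulated
promoters ("lux boxes") of a target taxon. It is aimed at microbial
ecologists and bioinformaticians working with engineered communities such as
activated sludge, where QS-proficient organisms (e.g. the nitrite-oxidizing
genus *Nitrospira*) are hard to culture and must be characterized from
assembly products.

The pipeline consumes standard artifacts — contigs (FASTA), ORF calls
(GFF3), KO/taxonomy-annotated protein-search tables (BLAST/DIAMOND 12-column
tabular plus named extensions), and Pfam domain tables — and performs:

1. **luxI/luxR homolog screening** (`qs_gene_screen`). An ORF is a putative
   QS gene iff its best bitscore against a QS-related KEGG orthology (AHL
   synthase K13060/K13061/K13062/K18096; AHL receptor K07782/K18098/K18099)
   strictly exceeds its best bitscore against any other KO. Calls are
   validated against conserved Pfam domains (Pfam00765 for LuxI; Pfam03472
   **and** Pfam00196 for LuxR), receptors are audited for the conserved
   acyl-binding (W66, D79, P80, W94, G121) and DNA-binding (E187, L191,
   G197) residues via global alignment to a reference numbering scheme, and
   co-localized synthase/receptor genes are resolved into cognate pairs
   versus luxR "solos".
2. **Consensus taxonomy and contig binning** (`taxonomy`). Per ORF, hits
   within the S<sub>best</sub> window (bitscore ≥ 0.95·S<sub>best</sub>)
   yield a strict-majority consensus function and the lowest common ancestor
   (LCA) of their lineages. Contigs are called for a target taxon with a
   tiered rule: >50% target ORFs for contigs with >6 ORFs, >60% for 4–6
   ORFs, 100% for ≤3 ORFs.
3. **Lux-box regulon prediction** (`luxbox`). A position weight matrix is
   trained on an aligned library of 20-bp imperfect-palindromic lux boxes;
   the log2-odds score of a width-w site s is

   &nbsp;&nbsp;score(s) = Σᵢ log₂( p(i, sᵢ) / b(sᵢ) ),

   with p the pseudocount-smoothed column probabilities and b the background
   frequencies. Each ORF's 400-bp upstream region is scanned on both
   strands; significance is the exact tail probability
   P(score(random w-mer) ≥ score) computed by dynamic programming over a
   discretized score lattice. Sites with p < 10⁻⁴ and ≤ 8 palindrome
   mismatches are annotated with genomic location (intergenic/intragenic),
   distance to the start codon, σ⁷⁰ −35/−10 elements (TTGACA/TATAAT,
   15–19 bp spacer), and a Shine–Dalgarno motif, and lux boxes shared by two
   divergently transcribed genes are cross-linked.
4. **Synthetic communities with planted truth** (`synthetic_data`), used to
   verify end-to-end parameter recovery, and a **GFP fold-induction
   statistic** (`pipeline_cli.fold_induction`: OD600-normalized
   induced/uninduced ratio, hit call at > 1.5-fold).

## Worked example

Generate a seeded synthetic community (40 contigs, 13 planted synthases of
which 9 are paired, 21 receptor solos, lux boxes planted 81 bp upstream of
each paired synthase) and run the full screen:

```bash
luxscreen generate --seed 1 --outdir demo
luxscreen run-all \
    --contigs demo/community.fasta --orfs demo/orfs.gff3 \
    --hits demo/hits.tsv --domains demo/domains.tsv \
    --proteins demo/proteins.faa --motif-library demo/luxbox_library.fasta \
    --outdir demo_run
```

prints

```json
{
 "n_luxI": 13,
 "n_luxR": 30,
 "n_luxR_paired": 9,
 "n_luxR_solo": 21,
 "n_regulon_candidates": 6,
 "n_target_contigs": 6,
 "n_unpaired_synthases": 4
}
```

meaning: all 13 planted AHL synthases and 30 receptors were recovered by the
KO rule, the 9 cognate pairs and 21 solos were resolved by co-localization,
6 contigs were binned to the target genus *Nitrospira*, and scanning their
upstream regions found 6 regulon candidates — the three planted boxes that
fall on target-taxon contigs, each reported twice because it sits between
two divergently transcribed genes (`demo_run/regulon.tsv` lists the pairs
with `distance_upstream` 81 and 125 and mutual
`shared_bidirectional_with` links). Per-stage tables (`candidates.tsv`,
`conservation.tsv`, `assignments.tsv`, `contig_calls.tsv`, `regulon.tsv`),
the PWM in MEME minimal format, a provenance log, and `summary.json` are
written to `demo_run/`.

The fold statistic:

```bash
luxscreen fold --measurements gfp.csv      # sample,condition,replicate,gfp,od600
```

prints one line per sample, e.g. `Nspbox1   196.6   true`.

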