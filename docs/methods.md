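# Methods

This document describes the algorithms and conventions implemented by
saurannot, module by module, and the rationale behind the non-obvious
choices.

## Sequence I/O and conventions (`seqio`)

- FASTA input is uppercased and `U` is mapped to `T`, so RNA-style inputs
  behave identically to DNA. Duplicate ids and residue lines before the
  first header are errors (reported with line numbers).
- All coordinates in the library are **0-based half-open** on the forward
  strand. Minus-strand matches are normalized so that
  `subject_start < subject_end` always holds, with the strand carried in
  `subject_frame`. The tabular hit format converts to 1-based inclusive
  coordinates at the file boundary and encodes minus-strand hits as
  `sstart > send`, matching the widespread 12-column tabular search
  convention; two extra columns carry the query and subject frames, and
  12-column files from external tools are read back with the strand
  inferred from the coordinate order.
- Floats in tabular output are written with `repr`, so a read/write round
  trip is lossless.
- Adaptor trimming removes exact occurrences of the adaptor (either
  orientation); an internal occurrence splits the record into `id_1` and
  `id_2`, and retained pieces shorter than the retention length (default
  91, aligned with the short-sequence filter below) are dropped.
- Six-frame translation uses the standard genetic code, keeps stop codons
  as `*` (so searches can cross them when the scoring allows it) and
  translates codons containing `N` as `X`.

## Preprocessing (`preprocess`)

- **Length filter:** sequences of 90 nt and shorter are removed;
  91 nt sequences are the shortest kept. Below ~90 nt the e-value
  statistics of short matches become uninformative and assembly artifacts
  dominate.
- **Redundancy clustering:** greedy, longest-first. Each sequence joins
  the first existing representative with pairwise identity ≥ 0.95
  (strand-symmetric: both orientations are tried, identity is counted
  over the shorter sequence so a substring of a longer sequence scores
  1.0), otherwise founds its own cluster. A k-mer prefilter (word 10)
  skips alignment for pairs that cannot reach the threshold; the bound is
  exact for substitution-type differences, so for such inputs the greedy
  result equals the brute-force all-pairs result (verified in the tests).

## Search engine (`search`)

A seeded local aligner stands in for an external search tool:

- **Seeding:** exact shared words (11 nt in nucleotide mode, 4 aa in
  translated mode) select candidate query/subject/frame combinations.
  For long subjects (genomes) only windows around seed diagonals are
  aligned; short subjects are aligned whole. A cheap score-only pass runs
  before the full traceback alignment.
- **Scoring:** nucleotide mode uses match +2 / mismatch −3 with gap
  open 5, extend 2 (a gap of length *k* costs 5 + 2*k*); translated mode
  uses BLOSUM62 with gap 11 + *k*. `N` mismatches every base, so
  masked regions cannot create matches.
- **Statistics:** Karlin–Altschul, `E = K·m·n·exp(−λS)` with
  (λ, K) = (0.625, 0.41) for the nucleotide scoring and (0.267, 0.041)
  for BLOSUM62 11+*k*. Percent identity is computed over all alignment
  columns including gap columns, matching common tabular-output
  semantics.
- **Thresholds** live in named profiles: `nucleotide` and `translated`
  (e-value ≤ 1e-3; the nucleotide profile also requires ≥ 50 aligned
  positions), `genome-validation` (1e-5, ≥ 90% identity, ≥ 50 nt),
  `projection-reassembly` and `completeness` (1e-5, no length floor — the
  pieces being placed can be legitimately short). Translated-mode
  profiles carry no length floor because alignment lengths are counted in
  amino acids.
- **Ranking:** hits are ordered by the tuple (smallest e-value, longest
  alignment, highest identity), residual ties broken by ascending subject
  id so results are deterministic.
- `external_search` runs any command template with `{query}`, `{db}`,
  `{out}` placeholders and reads the tabular result back, so a
  production-scale search tool can replace the built-in engine without
  touching the rest of the pipeline.

## Iterative annotation (`homology`)

Queries are annotated against an **ordered** series of reference
databases; a query leaves the pipeline at the first stage that explains
it. The canonical order is: mtDNA (nucleotide), ncRNA (nucleotide), one
or more species' cDNA and UniGene/EST-cluster sets (translated, with
RBBH), then taxon-level mRNA (translated). Remaining queries are orphans;
an optional masking hook can label queries as `repeat` before the stages
run (a query whose masked fraction exceeds 0.5 is excluded from
annotation).

- **RBBH block:** within cDNA/UniGene stages, a query whose best hit to
  the database is reciprocated (the database sequence's best hit among
  the queries is that query) is finalized immediately as an `*_rbbh`
  record. A query whose best hit is *not* reciprocated is held
  **pending** rather than finalized: it continues through the remaining
  RBBH stages (it may be reciprocal-best against another species), and
  only when the last RBBH stage finishes is its best pending hit
  finalized as a plain `*_hit`. This keeps one-sided matches from
  consuming queries that a later reference could place more confidently.
- **Cross-dataset comparison:** after several datasets (species) are
  annotated, each dataset's orphans are searched (translated) against
  every other dataset's annotated set and orphans. A match re-categorizes
  the orphan as `cross_species`; when the matched partner is itself an
  orphan the re-categorization is symmetric. This surfaces
  lineage-specific genes conserved between the studied species but absent
  from all references.
- **Partition:** the *annotation* set is every query with a reference
  match (all hit and RBBH categories); the *phylogeny* set is the
  stricter RBBH-only subset, suitable for ortholog-dependent analyses.
  The two sets satisfy phylogeny ⊆ annotation by construction.

## Anchored consensus (`consensus`)

All queries whose best match is the same reference sequence (the
*anchor*) are assembled into one consensus named after that anchor.

- Each member is realigned to the anchor (oriented by its hit's strand);
  the anchor defines the coordinate frame but **never votes**.
- Per anchor column, the consensus symbol is the majority among covering
  members; ties go to the symbol voted by the best-ranked member (by the
  e-value/length/identity criteria of its hit). Uncovered columns emit
  `-` (exported as `N` runs, or stripped).
- **Insertions** relative to the anchor are kept only when a strict
  majority of the members covering that junction carry an identical
  inserted string.
- **Short-segment rule:** ungapped placement segments shorter than the
  seeding word size (11 columns) cast no votes. Such segments carry no
  seed support and are typically chance pairings adjacent to indel
  junctions, not homology. Longer chance pairings at junctions remain
  possible (as with any local aligner) but are rare.
- A single-member consensus ("one-to-one") is the member's sequence
  verbatim under the anchor's name; multi-member consensuses are
  "one-to-many". With `keep_insertions=False` the consensus is restricted
  to anchor coordinates outright — used for genome projection, where
  member insertions are introns by construction.
- Coverage statistics split the anchor into the 5′ 30%, middle 40% and 3′
  30% (`round(0.3·L)` at each end) and report per-region gap percentages,
  diagnosing end-biased coverage.

## Exon-projection genome annotation (`genome_projection`)

To annotate an unannotated genome from a related reference species:

1. **Extract** every reference transcript's exons (in transcript
   orientation) plus 1 kb 5′ and 3′ flanks (to capture UTRs) from the
   reference genome + GFF3, truncating flanks at contig edges.
2. **Project** each piece onto the target genome (nucleotide search, no
   length floor); the best hit with ≥ 80% alignment identity yields a
   *potential exon*. Overlapping projections from the same source
   transcript are merged per contig and strand.
3. **Reassemble:** potential exons are searched against the reference
   cDNA set; those sharing a best cDNA anchor are built into a consensus
   restricted to cDNA coordinates (introns excluded by the
   `keep_insertions=False` rule above).
4. **Filter** to a phylogeny-grade set: consensuses longer than 90 bp,
   optionally restricted to anchors with a given name prefix.

The 80% identity floor rejects paralogous or repeat-derived projections
from diverged genomes while accepting genuinely orthologous exons.

## Completeness and quality statistics (`completeness`)

- A reference gene set (conserved-gene panel) is searched against the
  annotation's consensus sequences (e-value ≤ 1e-5, no length floor). A
  reference counts as *found* when any hit passes; its *coverage* is the
  length of the union of all passing hit intervals on the reference
  divided by its length. The report gives the fraction found and the mean
  coverage over found references.
- `compare_annotated_vs_orphans` is a two-sided Welch unequal-variance
  t-test (Welch–Satterthwaite degrees of freedom) for comparing a quality
  statistic, typically length, between annotated sequences and orphans.
  Both samples must have ≥ 2 observations and positive variance.

## Synthetic data (`synthdata`)

Deterministic generators make the whole pipeline testable offline, with
every choice recorded in a truth table:

- Reference "cDNAs" are random open reading frames (ATG start, no
  internal stops, final stop) so translated search is genuinely
  exercised.
- Fragment generation samples sub-intervals, substitutes each position
  with the divergence probability (2:1 transition:transversion),
  reverse-complements half the fragments, and can plant adaptors,
  near-duplicates (exactly 2% substituted, guaranteeing ≥ 95% identity)
  and true orphans. Divergence is substitution-only so identity
  arithmetic in downstream checks stays exact.
- Genome generation embeds each gene as a 2–5 exon structure between
  random introns and intergenic spacers, on a random strand, and emits
  exact GFF3; splicing the GFF3 exons reconstructs the gene byte-for-byte.
- Each generator draws from a domain-separated random stream
  (`default_rng([seed, tag])`, distinct tag per generator), so the same
  seed can safely feed every generator. Without the separation a genome's
  "random" spacers would replay the bit stream that produced the genes'
  codons and be spuriously similar to the genes.

The generators model substitution divergence, variable coverage and
assembly redundancy; they deliberately do not model indels, sequencing
error profiles or chimeric contigs.

## Pipeline and CLI (`pipeline`, `cli`)

`run_annotate` wires preprocess → iterative annotation → partition →
per-set consensus, persisting every intermediate as a declared text
format (FASTA / TSV / id lists) plus a JSON manifest (config hash, seed,
per-stage and per-category counts; category counts always sum to the
number of annotated representatives). Reruns with identical inputs are
byte-identical. Each CLI command (`preprocess`, `search`, `annotate`,
`consense`, `project`, `assess`, `simulate …`) is a thin wrapper over one
library entry point.
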