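# Methods

This note records the models, thresholds and design choices behind each
module, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Element search

The search re-implements a "member retrieval" workflow — find every
genomic copy of a short element consensus — as exact-word seeding plus
gapped local alignment; the classic retrieval tool's internal
algorithm is unpublished, so equivalence is defined against planted
truth and a Smith–Waterman oracle rather than against its output.

**Alignment.** Scoring is BLASTN-like: match +1, mismatch −2, gap open
−5, gap extend −2; a gap of length L costs `open + L·extend`. The
engine is a Smith–Waterman–Gotoh DP vectorized per query row; the
within-row gap state collapses exactly to a decayed running maximum
(chained gaps are dominated by one longer gap under affine costs), so
the row recursion needs no inner loop. Subjects ≤ 1 kb are aligned by
full DP directly. For longer subjects, exact 11-mer word matches are
clustered by diagonal (±32) and subject adjacency (gap ≤ 100 bp —
seed runs inside a genuine alignment are near-contiguous, and a distant
chance word match must not chain two clusters together); each cluster
yields one window (seed extent + 92 bp margin) aligned independently,
so the separate exons of a spliced query give separate hits. Hits
overlapping > 50 % on the subject are subsumed by the best-scoring one,
ties broken by leftmost start. `N` never matches, and seeds cannot
contain `N`.

**Statistics.** Significance uses the ungapped Karlin–Altschul model
`E = K·m·n·exp(−λS)` with `n = genome length × 2` (both strands).
λ ≈ 1.332 is solved numerically for the scoring scheme at uniform base
frequencies; `K = 0.62` is a fixed documented constant. The defaults
are thresholds on this internal scale — absolute E-values from other
engines will differ, the accept/reject behaviour at `E ≤ 10⁻³` is what
matters.

**Intactness.** A copy is *intact* when the alignment reaches within
`end_mismatch_tol` (default 20 nt) of both consensus ends; one-end
failures are kept and flagged `near_intact_5trunc`/`near_intact_3trunc`;
both-end failures are dropped. Flanks (default 500 bp, clipped at
contig edges with actual lengths recorded) and the TSD — the longest
exact flank5-suffix/flank3-prefix match with length in 5–15 bp — are
annotated on every locus; a TSD is never required for acceptance.
Deduplication removes loci whose full flank5+element+flank3 string
matches a retained locus exactly (first in (chrom, start, id) order
wins).

A caveat on truncated copies: when a planted truncation boundary is
followed by genome bases that happen to match the next consensus
positions, the alignment legitimately extends a base or two past the
planted edge. Untruncated copies are recovered at exact coordinates.

## Site annotation

Interval mode (default when positioned gene models exist): an element
fully inside an exon → `exon`; overlapping an exon boundary →
`exon_intron_junction`; fully inside the gene body otherwise →
`intron`; within the proximal window (default 500 bp) of a gene →
`proximal_upstream`/`proximal_downstream`, oriented by gene strand;
then ncRNA containment, then TE intervals (class from the annotation's
biotype), else `intergenic`. Precedence is gene > ncRNA > TE >
intergenic, and a locus near two genes goes to the nearer one
(distance tie → lexicographically smaller gene id, logged).

Similarity mode reproduces the flank-homology approach used when no
positioned annotation is available: the merged 5′+3′ flanks are aligned
against cDNA/CDS/ncRNA/TE databases and the best hit at `E ≤ 10⁻¹⁰`
decides the category with the same precedence. When a flank matches several
databases at once there is no canonical priority; the precedence rule
here is this package's decision.

Summary percentages are rounded half-up to one decimal. One reference
value cannot be reproduced under any one-decimal rounding rule:
213/1886 = 11.29 %, which half-up renders 11.3 % where the reference
tabulation gives 11.2 % (consistent with truncation); the package
keeps half-up everywhere and treats agreement at the 0.1 grain as
exact.

## Comparative genomics

Two loci in different genomes are the *same insertion* when the last
`k` bp of flank5 and the first `k` bp of flank3 both match exactly.
`k` defaults to 50 bp per side (configurable up to the flank length):
the exact-identity criterion is deliberately conservative — it
undercounts shared insertions in the presence of any flank divergence —
and 50 bp balances specificity against clipped flanks. Loci with
flanks shorter than `k` are skipped with a warning. Pairing is
one-to-one: loci sharing a flank key are sorted by coordinate on each
side and zipped, making the relation symmetric and input-order
invariant. Distribution tables tally loci per (homoeologous group,
subgenome) from a chromosome map; anything unmapped is counted
explicitly, so cells + unmapped always equal the input size.

## In-silico PCR

Primer matching is exact and case-insensitive on both strands; no
mismatch or 3′-anchoring model is applied (site-specific PCR assays of this kind are validated by product
sequencing, not thermodynamics — a documented limitation). Every properly oriented site pair within `max_len`
(default 5000 bp) yields a product, lengths inclusive of both primer
footprints, so a full site exceeds its empty site by element length
plus TSD. A product is called *full* when it contains the element
(substring test against the supplied consensus, either orientation) or
matches empty + element within ±20 bp — the slack covers reported
full/empty pairs whose differences range roughly 172–183 bp around a
181-bp element; the shortest element-free product across the panel
anchors the empty length. Per-species presence is "full site in at
least one accession". Origin classes formalize the narrative classes:
all observed species present → `monomorphic_present`; no diploid
present → `hexaploid_only` / `tetra_and_hexaploid` (a
tetraploid-present row with the hexaploid missing counts here,
consistent with the packaged genotype panel's grouping); exactly one diploid
lineage → `diploid_inherited_{AA,BB,DD}`; several →
`multiple_diploid`; anything else (e.g. tetraploid-only with the
hexaploid observed absent) → `other`. Missing ("NA") species are
excluded from the row before classification.

## Transcript exonization

Element-containing transcripts are found with the same engine and
thresholds as the genome search. Maturity is decided from the
transcript-to-genome hit structure at `E < 10⁻¹⁰⁰`: a single hit
covering ≥ 99 % of the transcript at 100 % identity → `genomic_like`
(suspected genomic DNA or precursor); ≥ 2 partial hits on one strand of
one chromosome, collinear, separated by intron-sized gaps (≤ 50 kb),
jointly covering ≥ 90 % → `mature`; everything else → `unresolved`.
The two coverage thresholds are this package's quantification of a
qualitative full-hit/partial-hits rule and are exposed as parameters.
A transcript annotated as single-exon is `unresolved`, never
`genomic_like`: the hit structure cannot distinguish it from
contamination, so it is flagged rather than guessed. Note that the
stringent e-value threshold implies exon hits shorter than ~190 bp do
not qualify on a desk-scale search space; coverage of transcripts with
many very short exons is understated accordingly.

Variant grouping collects, per gene with ≥ 1 element-containing
variant, all its transcripts and reports totals. CDS impact uses the
annotated CDS span when present, else the longest forward-frame
ATG→stop ORF; protein length is CDS/3 − 1 when the span ends in a stop,
with non-multiple-of-3 spans flagged incomplete and floored.

## Expression (ΔΔCt)

`ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target − Ct_ref)_reference` and
`RQ = (2·efficiency)^(−ΔΔCt)` with efficiency a fraction in (0, 1] —
the doubling-based base is the variant this assay design reports,
implemented verbatim even though the wider qPCR convention is `(1+E)`; a flag switches
to the conventional base. Technical replicates are averaged to one Ct
before ΔΔCt; biological replicates propagate to the mean ± sample SD.

## Synthetic data

The generators emulate the *structure* of the study's data: i.i.d.
background sequence (default uniform base composition), non-overlapping
multi-exon genes, element insertions placed consistently with a
requested category with optional TSD (the target site is duplicated so
the flank5 suffix equals the flank3 prefix) and optional end
truncation, polyploids assembled by verbatim chromosome copying (so
shared insertions have identical flanks) plus subgenome-private
insertions, transcripts as exact exon concatenations with optional
retention of the element-containing intron and optional genomic-slice
contamination, and Ct tables whose expected RQ equals the planted fold.

Defaults are sized for a complete pipeline run in about a minute:
3 chromosomes × 500 kb, 50 genes, 50 insertions; exons 220–400 bp (so
true exon hits clear the 10⁻¹⁰⁰ transcript-to-genome threshold),
introns 300–800 bp, insertions ≥ 1.5 kb apart (flanks stay free of
neighbouring elements). All outputs are pure functions of the spec
including its seed.

What the generators do **not** emulate — and hence what passing tests
do not show about real data: sequence divergence between element copies
and between shared-insertion flanks (real flanks accumulate mutations,
so exact-identity sharing undercounts), nested or fragmented TE
landscapes, GC heterogeneity and repeat-induced seed ambiguity,
alternative splicing beyond single-intron retention, and qPCR
efficiency drift. Recovery and agreement rates of 100 % are properties
of the mutation-free regime.

## Known limitations

- The aligner reports one best hit per seed-cluster window; two
  repeats of the query closer than ~200 bp on the subject can merge
  into one window and yield a single hit.
- E-values are calibrated for the default scoring only; changing the
  scoring without re-deriving λ, K shifts the absolute scale.
- Exact primer matching ignores near-matches that would amplify in
  practice; genotype calls on diverged primer sites degrade to `none`.
- The maturity rule cannot classify single-exon transcripts and is
  insensitive to exons below the e-value floor.
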