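# Methods

## Data model and coordinate conventions

All genomic intervals are 0-based half-open internally; every user-facing
report is 1-based. A degradome read contributes exactly one event: the
genomic coordinate of its biological 5′ terminus (leftmost aligned base on
the + strand, rightmost on −). Read length is irrelevant after this
reduction, so 20-nt PARE reads and trimmed GMUCT reads are handled
identically. The `EndCountTable` stores strand-aware per-position counts;
collapsing conserves total read count, and writing/re-reading BED round-trips
exactly.

Two no-zero offset frames are used, matching how degradome positions are
conventionally reported:

* **end frame** — the uncapped-end nucleotide is +1; upstream positions are
  negative. In a 50-nt peak window (25 nt each side) the end is character 26.
  A motif "at position +4" starts 3 nt downstream of the end; a motif
  "at −8" occupies −8…−1, ending immediately upstream of it.
* **motif frame** — motif base 1 is +1. The two frames are mirror images:
  a motif at end-frame m ≥ 2 has the end at motif-frame −(m−1). `MotifModel`
  reports both (`modal_offset`, `peak_offset_in_motif_frame`).

## Region classification

Each (chrom, strand, position) receives exactly one of 5′UTR, CDS, 3′UTR,
intron, IGR. Labels are computed against same-strand transcripts only;
antisense positions over a gene are IGR on their own strand. When isoforms
disagree the priority is CDS > 3′UTR > 5′UTR > intron — a deterministic rule
is required because every end is counted in exactly one region, and
CDS-first matches common degradome practice. Transcripts with CDS but
without explicit UTR features get UTRs from the exon∖CDS set difference;
mRNAs with no CDS at all are treated as coding over their exons rather than
inventing UTRs. GFF3 parsing is delegated to gffutils (in-memory database).

## Peak calling

Every position with ≥ 1 read is a candidate (no minimum-count pre-filter;
the dominance and significance filters subsume one). Retention is
conjunctive:

* dominance (c₋₁+c₀+c₊₁)/n ≥ 0.5, boundary inclusive;
* binomial upper tail P(X ≥ x) < 10⁻⁵ with X ~ Binomial(n, q), q = 1/21.

The point mass C(n,x)qˣ(1−q)ⁿ⁻ˣ is exposed as `pvalue_mode="point"`; the
tail is the default because a p-value is conventionally a tail probability
and the tail is never smaller than the point mass, hence conservative — the
4-read significance floor ((1/21)⁴ ≈ 5.1×10⁻⁶ < 10⁻⁵ ≤ (1/21)³) is the same
either way. The tail is computed by `scipy.stats.binom.sf` (log-space
stable); tests verify it against an exact rational summation oracle to
10⁻¹² for all n ≤ 60.

Windows are genomic, not splice-aware: a 21-nt test window or 50-nt
sequence window may cross an intron boundary. Region labels come from the
end position alone. At chromosome edges missing positions count 0 and q
stays 1/21 (the simplest consistent null); truncated sequence windows are
N-padded and flagged. The top-1000 cap per region ranks by x (reads at the
end itself), ties broken by coordinate for determinism. miRNA-site exclusion
flags peaks within ±tolerance (default 0) of a listed cleavage site on the
same strand; flagging never alters the peak's statistics and flagged peaks
stay in the full report.

## Anchored motif discovery

The retained motifs of interest are short (6–8 nt), ZOOPS, and
position-fixed relative to the end, so discovery exploits the anchor
instead of running EM: exact words of widths 6–8 are counted over all
windows; words present in ≥ 5 distinct windows seed a greedy merge of
Hamming-distance-1 neighbours whose modal anchored offsets agree within
1 nt, giving IUPAC consensi; each consensus is re-scanned in ZOOPS mode
(keeping, per sequence, the occurrence nearest the global modal offset,
ties resolved upstream — the choice that maximizes the positional signal
selection acts on) and scored.

The E-value is an internal expected-false-discoveries score: with p_word =
Π column probabilities under a 0-order background fitted to the input
windows, p₀ = 1 − (1 − p_word)^(L−w+1) per sequence, and W = distinct words
of that width observed, E = W · P(K ≥ k), K ~ Binomial(N, p₀). It fills the
same retention role as a motif-discovery E-value (threshold E < 1) but no
numeric parity with external motif programs is claimed; windows exported as
FASTA plus the `import_sites_tsv` bridge keep an external discovery run
possible. Retained motifs additionally need positional dominance ≥ 0.5
(sites at the modal offset ±1 over all sites); modal ties resolve to the
smallest absolute offset, negative first.

Cross-run grouping is algorithmic (the analogous manual step is replaced
deliberately): greedy single-linkage over best ungapped consensus
alignments, column compatibility = non-empty IUPAC intersection, similarity
= compatible/aligned columns with the shorter motif fully contained in the
overlap, merge at ≥ 0.75. The full-containment rule exists because short
end-overlaps between degenerate consensi otherwise reach similarity 1.0 and
chain unrelated families. Every model lands in exactly one group;
representatives are column-wise unions and groups retain per-member modal
offsets (re-anchoring is not attempted). Shuffled controls draw a seeded
non-identity anagram of the consensus letter multiset.

## MORPH

Columns are the 20 no-zero offsets −10…−1, +1…+10 with the anchor base at
+1 — the split under which upstream truncation peaks (−3 for PUF-like
elements) and the downstream mispriming peak (+|adaptor|+1) both fall
inside the window. Reads under the motif body are counted like any other
column. Rows with zero reads are always dropped; the ">5" filter (on by
default) drops rows with total ≤ 5. Retained rows are normalized to sum to
1. Anchors near a chromosome edge read 0 in the missing columns and are
kept if they pass the filter.

Clustering is Ward linkage on Euclidean row distances via scipy
(hclust-ward.D2 semantics); `variant="D"` applies the same recurrence to
squared distances since the historical Ward.D/Ward.D2 distinction is
ambiguous in older pipelines. Tests verify the merge tree against a naive
O(n³) Lance–Williams oracle. Leaf order is scipy's deterministic dendrogram
order, making matrix TSVs stable golden files. Summaries report per-column
means and modal-locus fractions; a row tied for its maximum counts once, at
the most upstream tied column.

## Synthetic data

The generator writes a uniform-random genome (2 × 120 kb), 200 single-
isoform genes on a regular grid (100 nt 5′UTR, 300 nt CDS — 40% with a
150 nt intron — 200 nt 3′UTR, random strand) and 30 intergenic ncRNAs
(20 C/D-box with RTGATGA at bases 5–11, 5 H/ACA-box, 5 other). Signal
classes and defaults:

* background decay: Poisson(0.02)/exonic nt on the transcript strand — the
  uniform null the q = 1/21 test assumes;
* PUF-like truncation: TGTACATA in 60 distinct 3′UTRs, end at motif-frame
  −3, height ~ NegBin(mean 20, dispersion 5) so peaks near the 4-read
  significance floor occur and the test's boundary is genuinely exercised;
* miRNA cleavage: a random 21-mer's reverse-complement target in 10 CDSs,
  end opposite miRNA bases 10–11 (target base 12), written to an exclusion
  BED;
* snoRNA 5′ ends: NegBin peaks at base 1 of C/D- and H/ACA-box features
  ("other" ncRNAs get none);
* mispriming: GTCCGAC in 40 CDSs with false ends at frame +8.

Planted words are literally written into the genome at recorded
coordinates; all plantings use disjoint transcripts. Identical config+seed
yields byte-identical files; truth.tsv records every planted element and
conservation (table total = planted + background counts) is tested. Reads
are emitted as 20-mers from each end; an optional terminal-GC toggle and a
multi-hit fraction exist solely to exercise the QC and input-dialect paths.

What the generator does *not* emulate — sequencing errors, expression-level
heterogeneity, isoform complexity, chromatin-scale composition structure,
genuine MmeI chemistry — bounds what passing tests show: they validate the
statistics, frames and bookkeeping of the method, not its behaviour on the
full messiness of real libraries.

## Problem sizes and numerical choices

The default study (200 genes, ~5000 reads) keeps every pipeline stage in
seconds while leaving dozens of loci per signal class, enough for the
recovery rates to be meaningful. Peak sensitivity against truth counts all
planted peaks including those whose drawn height falls below the 4-read
floor, so values land near 0.97–0.99 rather than exactly 1 — an honest
reflection of the test's statistical limit, not a defect. Dominance 0.5 and
E < 1 boundaries are inclusive/exclusive exactly as stated above; MORPH row
normalization is checked to 10⁻⁹; binomial agreement to 10⁻¹².

## Known limitations

* Windows and MORPH profiles are genomic; signals spanning splice junctions
  smear. Transcript-coordinate projection is future work.
* The internal E-value is calibrated for retention ordering, not for
  cross-dataset comparison of absolute values.
* Motif grouping is heuristic single-linkage; very degenerate consensi can
  still chain families and may warrant a higher similarity threshold.
* IGR anchor scanning classifies only the motif's first base; a match
  straddling a gene boundary is attributed by that base alone.
* No statistical test is attached to composition bias (tabulated only), and
  artifact loci are reported, never removed from the input.
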