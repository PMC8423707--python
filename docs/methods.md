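# Methods

This note records the models, parameter choices and numerical decisions
behind `crypticsplice`, and what the synthetic generators do and do not
emulate.

## Coordinates and formats

All coordinates are internally 1-based inclusive (GTF-native). Regtools
BED12 junction files (0-based half-open anchors with block sizes) and
bedGraph conservation tracks are converted on read; the plain junction
TSV dialect (chrom, start, end, strand, count) is read and written
as-is, and round-trips exactly. Junction identity is
(chrom, start, end, strand); a junction of unknown strand matches either
stranded form when compared to an annotation, because user-supplied TSVs
may lack strand while GENCODE-derived junction sets carry it.
Chromosome-name style ("chr1" vs "1") must be consistent across samples;
an alias map can harmonise UCSC and GENCODE naming. The GTF reader is a
deliberately small line-oriented parser: it extracts only exon features,
reports malformed lines by line number and skips exons lacking a
`transcript_id` with a logged warning, which a database-building general
parser cannot do cheaply. Missing conservation values are NaN and are
excluded from means (per-base tracks have gaps).

## Junction clustering

Two junctions are adjacent when their intron intervals share a base *or*
share a splice site (identical donor or acceptor coordinate). Splice-site
sharing matters because alternative 5'/3' splice-site junctions may not
overlap in their interiors. Connected components are formed per strand;
unknown-strand junctions are eligible on both strands but can never
bridge a '+' and a '−' cluster (a '.' junction touching both appears in
both clusters — an order-independent rule, unlike first-come
assignment). Filters, applied to counts pooled across all samples
because the thresholds are experiment-level: introns > 200,000 bp are
removed up front; junctions contributing < 0.001 of their component's
pooled reads are dropped and components re-formed, iterated to a fixed
point (cap 100 iterations — removal changes the total, so a single pass
is not well-defined); components with < 60 pooled reads or fewer than
two junctions are discarded. Cluster ids are
`chrom:minStart-maxEnd:strand:k`, stable across runs and input
permutations.

## Dirichlet-multinomial differential splicing

Counts for the J junctions of a cluster in one sample are
DM(α = c·p): usage vector p on the simplex, concentration c (the
multinomial limit as c → ∞; intraclass correlation ρ = 1/(1+c)). The
null model shares one p across samples; the alternative gives each group
its own p. The LRT statistic 2Δℓ is referred to χ² with J−1 degrees of
freedom; negative values from optimizer tolerance are clamped to zero.
Proportions are optimised on an unconstrained softmax scale (J−1 free
logits), log-concentration bounded in [−10, 25], L-BFGS-B from two
starts (method-of-moments pooled proportions, and uniform), ftol 1e−8,
max 500 iterations. Samples with zero cluster counts contribute nothing;
a cluster is untestable unless each group has at least one read.

**Dispersion moderation.** With 3 samples per group, per-cluster ML of c
is badly behaved: fitting group-specific proportions absorbs
between-sample variation, so the residual dispersion is underestimated
and c overestimated (a classic incidental-parameter effect), inflating
the LRT — we measured a type-I error of ~0.13 at nominal 0.05 under the
generative model. The default batch mode therefore estimates ρ by the
intraclass-correlation moment formula
Var(p_sj) = p_j(1−p_j)(1/n + (1−1/n)ρ), pooling numerator and
denominator components *within groups* and *across all clusters* before
taking the ratio (the pooled ratio-of-sums is nearly unbiased, unlike a
median of per-cluster ratios, and within-group pooling keeps genuine
usage shifts from masquerading as overdispersion). Both models are then
fitted with the common c held fixed, so the LRT compares usage only;
measured type-I error is 0.04–0.06 across seeds. This mirrors the
common-dispersion moderation of edgeR/DRIMSeq. Per-cluster free-c
fitting remains available (`dispersion="per_cluster"`) for
heterogeneous data with many replicates. BH FDR is applied across
non-failed clusters; significance means q < 0.05.

## Cassette classification

A cassette triple (j1, j2, skip) requires j1.start = skip.start,
j2.end = skip.end and a non-empty central exon [j1.end+1, j2.start−1].
Exons longer than 250 bp are discarded at topology time, before any
quantification. When several triples yield the same exon, the one with
the highest pooled inclusion reads is kept (a deterministic tie-break).
Only clusters significant after FDR are scanned by default
(`scan_all_clusters=True` lifts this).

**PSI.** The bounded form PSI = m/(m+s) (m = mean of the two inclusion
counts, s = skipping count) is the default: the literal ratio m/s is
unbounded and incompatible with percentage thresholds like
"PSI > 90 %", so the bounded form is the only internally consistent
reading; the literal ratio is available behind `bounded=False` (capped
at 1). Samples with m+s below `min_event_reads` (default 15) are treated
as missing — there is no principled coverage floor for PSI in the
literature at this granularity; 15 avoids 0/0 and high-variance
estimates while keeping 3-sample groups quantifiable at depth ≥ ~100.
Group PSIs are means over non-missing samples; an event with an
all-missing group is unquantifiable.

**Labels.** cryptic ⇔ PSI_control < 0.10 ∧ ΔPSI > 0.10; skiptic ⇔
PSI_control > 0.90 ∧ ΔPSI < −0.10; else included (ΔPSI ≥ 0.10), skipped
(ΔPSI ≤ −0.10) or weak. Every quantifiable event receives exactly one
label. Novelty: both inclusion junctions and the skipping junction are
looked up in the annotation-derived junction set; an event is "novel"
unless all three are annotated.

## Sequence features

Frame preservation is length divisibility by 3 (null expectation 1/3
under uniform lengths). Mean conservation is the covered-base mean over
the exon. Class comparisons use the two-sided Mann–Whitney/Wilcoxon
rank-sum test. K-mer enrichment is presence/absence per sequence: the
two-proportion χ² test without continuity correction (the large-n
setting makes Yates over-conservative; zero-margin tables return p = 1),
Bonferroni within each k family (4^k tests — families are per length
because result tables are conventionally split by k), enrichment
reported as the ratio of presence proportions. Bases outside ACGT never
match; sequences shorter than k contain no k-mer. Bracket patterns
(`CCC[AT]`) expand positionally. An external differential motif finder
(MEME) is deliberately not wrapped: the k-mer scan is the verifiable
statistic.

## Expression overlap

The DE table is consumed, never computed (DESeq2 column names are
accepted). The expression-matched null is all genes whose
log10(baseMean) lies within mean ± 1 SD of the target genes' values,
excluding targets and any further excluded set (typically all
differentially spliced genes). "Downregulated" means log2FC < 0 among
genes with adjusted p < 0.05 — the bias proportion is over significant
genes only — compared between sets by the two-proportion χ² test.
Membership in the null window is invariant to rescaling all baseMeans.

## Histopathology scoring

Tiles are 1000 × 1000 px (0.345 mm² at the scan magnification), placed
by seeded rejection sampling until 300 tiles are placed or 10,000
consecutive proposals overlap; "< 300" is read as a hard cap of 300, the
only testable interpretation. Per case: normal-neuron density =
normals / (n_tiles × 0.345 mm²); mislocalisation score = 100 × (tiles
with ≥ 1 abnormal neuron) / n_tiles — a presence metric, invariant to
duplicate detections within a tile. The upstream CNN detector is out of
scope; the contract starts at labelled detection tables. Cumulative
onset curves sort cases by age at death (ties broken stably by case id),
accumulate mislocalisation and normalise by the group total; the median
crossing age is the smallest age at which the curve reaches 0.5, and the
onset gap is the difference between groups' crossing ages. Age
association uses two-sided Spearman correlation (n ≥ 5; constant scores
are flagged undefined). The packaged 96-case cohort table provides
demographic summaries: per-group means over non-missing values, rounded
half-up to one decimal to match tabular presentation, and M:F counts.

## Synthetic generators

One global seed fans out to fixed per-generator substreams
(`default_rng([seed, offset])`), so stages are independently
reproducible and every generator is a pure function of (config, seed).

*Junction datasets.* Default conditions: 200 cassette-topology clusters,
3 control vs 3 knockdown samples, 500 reads per cluster per sample,
concentration 50 (ρ ≈ 0.02, a realistic biological overdispersion for
isoform usage), 20 planted cryptic (control PSI ~ U(0, 0.08), ΔPSI ~
U(0.15, 0.40)) and 20 planted skiptic events (mirrored), remaining
clusters null with a common usage drawn per cluster. A PSI maps to
3-junction usage as (ψ, ψ, 1−ψ)/(1+ψ), which the bounded PSI estimator
recovers in expectation. This scale finishes the full cascade in a few
seconds on one CPU while leaving enough events for stable
sensitivity/precision estimates.

*Annotation.* A toy genome and GTF matching the planted coordinates:
null and skiptic clusters get inclusion and skipping isoforms (all
junctions annotated); cryptic clusters get only the skipping isoform,
so their inclusion junctions are novel by construction.

*Motif sets.* Two sequence sets over a configurable i.i.d. background;
each sequence receives one planted motif occurrence with its set's
prevalence (defaults 0.86 vs 0.48, motif CCCA, n = 100/set). Background
draws can also contain the motif by chance unless the alphabet excludes
it.

*Detections.* Two groups of 35 cases, 129 tiles each; per-tile abnormal
counts are Poisson with a logistic age ramp (midpoint 95 y, width 12 y,
maximum 0.08 per tile) times a lognormal per-case effect (σ = 1.5)
capturing between-individual variability; normal counts are Poisson(8).
The disease group's ramp midpoint and age distribution are both advanced
by the 18-year onset shift, so the planted cumulative-curve gap equals
the shift by construction. The rate and noise scales were chosen so the
control-group age correlation sits near Spearman r ≈ 0.55 at n = 35,
matching the strength of association this kind of ordinal, zero-inflated
tissue score realistically shows.

**What passing tests do and do not show.** The generators draw from
exactly the models the pipeline assumes (DM counts, Poisson detections,
clean cassette topologies, complete annotations). Real data add
unmodelled structure — mapping artefacts, overlapping genes, annotation
errors, partial coverage, batch effects — so recovery rates measured
here are upper bounds, and the DM calibration says nothing about
robustness to outlier samples. The accession-scale check against
deposited junction counts (see tests) is the only end-to-end evidence on
real data and requires the external downloads.

## Known limitations

- The cassette scan only considers three-junction topologies; multi-exon
  or nested events are not enumerated.
- Moderated dispersion assumes clusters share one concentration; strong
  dispersion heterogeneity would mis-calibrate tails (use per-cluster ML
  with adequate replication).
- The unbounded literal PSI ratio is provided for comparability but is
  not used by any classification default.
- Pattern brackets support single-position classes only (no nesting or
  quantifiers).
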