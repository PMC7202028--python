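# Methods

This note documents the models, rules and numerical choices behind
`abarddm`, the assumptions the synthetic-data generator makes, and the
limits of what passing tests demonstrate about real data.

## Coordinates and annotations

Internal coordinates are 0-based half-open; GFF3 I/O converts from/to the
1-based closed convention at the boundary. The TSS of a minus-strand gene is
its annotation's end coordinate, making promoters (`[tss − L, tss)` on +,
`[tss, tss + L)` on −) and flanks strand-symmetric. Promoters clipped by a
contig edge are kept and flagged rather than dropped, so gene counts are
preserved; promoters are *not* clipped at neighbouring genes. GFF3 parsing
uses gffutils' line parser with explicit duplicate-ID and strand checks so
errors carry line numbers.

## DEG groups

A gene enters the up (down) group of a comparison when log2FC >= 0.95
(<= −0.95) and FDR <= 0.05, both boundaries inclusive. The source material
is ambiguous between FDR <= 0.05 and FDR < 0.05; the inclusive reading was
chosen and the threshold is configurable. FDR values are consumed as input
(differential-expression model fitting is out of scope); a
Benjamini–Hochberg helper (via statsmodels) exists for synthetic tables that
only carry p-values. The counts-per-million filter keeps a gene when CPM >=
0.58 (inclusive) in at least k samples; the filter's k is not specified by
its originating protocol, so k defaults to the smallest experimental group
size (2 here) and is an explicit argument.

## Methylation

Region methylation is the pooled ("weighted") ratio Σ#C/Σ(#C+#T) over the
region's cytosines of one context — never the mean of per-site ratios — so
the value of a union of disjoint regions is the count-weighted combination
of its parts (an exact identity, tested). Symmetric CG sites on opposite
strands are pooled as independent calls; destranding would be a no-op for
pooled ratios.

Evaluability filters: genome-wide regions need mean coverage >= 5 and >= 2
sites; promoter regions >= 2x and >= 2 sites. The "minimum level" criterion
(10% CG/CHG, 1% CHH) is implemented as a separate reporting gate
(`is_methylated`) deciding whether a region counts as methylated at all,
not as an evaluability filter — the two rules are conflated in the source
description and separating them keeps each testable.

Promoters are tiled at 100 bp with tile 1 adjacent to the TSS and indices
growing upstream (so the −0.25 to −0.75 kb window is tiles 3–7). Tiles with
no covered sites are excluded from per-gene averages and metagene curves;
metagene values are arithmetic means of evaluable tile ratios across genes.
Genome-wide contrasts are computed on pooled counts over all captured
regions (a per-region mean is available but not the default).

Differential promoters: CG/CHG differential at >= 40 percentage points
absolute difference; CHH differential when min(mC_a, mC_b) <= 5% and the
absolute difference is >= 15 points ("one sample low" is read as the
minimum of the two); a CG gain >= +10 points is labelled CG
hypermethylation. Conversion rate = 1 − pooled ratio over all contexts of
the designated unmethylated (chloroplast-like) contig.

## Motif cascade

The ABRE is matched as an exact degenerate-base pattern
(`CACG[TC]G[TG]C[GC]`), both strands, overlapping matches included, with a
vector of allowed bases per position compiled to a lookahead regex; no
position-weight-matrix scoring or match p-values are computed, so scanning
is deterministic. `N` never satisfies a constrained position. Coupling
elements have no published consensus in the source analysis; the scanner
therefore takes an explicit CE motif list — empty in strict mode, with a
small literature-derived set (CE1 `TGCCACCGG`, CE3 `ACGCGTGTCCTC` from the
cereal ABA literature) available and used by the pipeline default, since
the simulator plants CE3 instances. A curated override list can force
literature-known primaries (the DEG requirement still applies).

Primary targets: DEG and (>= 2 ABREs or >= 1 ABRE + >= 1 CE). Secondary
prediction is single-step: DEG targets of GRN edges whose regulator is
primary, minus the primaries; self-loops are excluded by default;
regulators absent from the GRN contribute nothing. A multi-step transitive
closure exists behind a flag but is excluded from the headline statistic.
Explained fraction = 100·(n_primary + n_secondary)/n_total_DEG.

## siRNA depletion

The mutant's global siRNA loss distorts CPM normalization, so fold changes
are corrected by a composition factor anchored on MOP1-independent miRNAs:
per-miRNA mutant/wildtype CPM ratios on replicate-pooled counts, aggregated
by the median (ratio-of-sums is implemented as the alternative; the
aggregation is not specified by the source, and the median is robust to a
few disturbed miRNAs). miRNAs with a zero count in either genotype are
excluded and logged. Corrected log2FC = raw log2FC − log₂(factor); a
pseudocount of 0.5 avoids infinities at zero counts. Note log₂(2.2) =
1.1375; the value is carried at full precision.

A promoter is depleted when corrected log2FC <= −1 **and** a two-sided
binomial test of the mutant count against the null split implied by library
sizes times the factor gives p <= 0.05; regions below 1 pooled CPM in both
genotypes are excluded first. This explicit rule replaces the original
count-model differential test (out of scope); both thresholds are
configurable. Depletion rates are reported as 100·depleted/total to two
decimals, per analysis group plus a genome-wide row.

## TE context

"Adjacent to the 2-kb flank" is implemented as half-open interval
intersection with the flank (a TE overlapping by one base counts); a
nearest-only mode, which mirrors a bedtools-closest view and keeps distance
ties, exists behind a flag. A TE flanking several genes appears once per
gene in the records and once globally in deduplicated distributions; both
views are available. The background is the full supplied TE annotation.
Distributions are percentages over the closed 13-code superfamily set and
always sum to 100; comparisons are percentage-point deltas. No enrichment
test is attached — the output is compositional.

## Synthetic-data generator

The generator defines the study conditions; its defaults are the effects
the analysis is designed to detect and are not tuned per run.

* **Expression.** Condition means are additive per gene: WT_MS = 0,
  WT_ABA = a_wt, MUT_MS = m, MUT_ABA = m + a_mut; the four comparisons are
  differences of these. 40% of genes are ABA-responsive; of those, 25%
  respond only in wildtype (MOP1-dependent, a_mut = 0), and among mutant
  responders 30% are amplified (x1.8) and 30% attenuated (x0.3–0.75,
  which produces genes unique to a single comparison, as threshold-crossing
  does in real data). 8% of genes are misregulated by RdDM loss alone.
  Effect sizes |a| ~ N(2.0, 0.8) clipped at 1.0 log2 units — comfortably
  past the 0.95 cutoff but with realistic mass near it. Observed log2FC =
  truth + N(0, 0.15); p-values follow from the z-score of the observed
  value (uniform for nulls), FDR by Benjamini–Hochberg. DE tables are
  generated directly rather than via read counts, because DE model fitting
  is out of scope and the pipeline consumes statistics.
* **Methylome.** Capture-style: cytosines of both strands within every
  2-kb promoter. Context baselines CG 0.60, CHG 0.45, CHH 0.02 (typical
  maize promoter levels); CHH is multiplied by 0.32 in the mutant (a 68%
  reduction) and by 1.111 in ABA-treated wildtype (an 11.1% gain; every
  captured site is a promoter site, so the gain is promoter-borne).
  Coverage is Poisson(10) independent per site and condition,
  methylated counts are Binomial(coverage, p), zero-coverage sites are
  omitted. A 20-kb chloroplast-like contig is simulated at p = 0.005 (the
  non-conversion rate) in all conditions.
* **Motifs.** Promoter background is uniform-random, so background ABRE
  hits are rare (≈ 2L/4⁹ ≈ 1.5% per 2-kb promoter per strand pair);
  planted counts are verified by re-scanning and both are recorded in the
  truth table. 25% of promoters receive two ABREs, 15% one ABRE plus one
  CE3.
* **Small RNA.** Region counts are Poisson around lognormal per-region CPMs
  (mean 20); mutant rates are multiplied by the composition factor 2.2 and,
  for a truly depleted 20% of regions, by 0.25. miRNA counts (30 species,
  mean 100 CPM) are multiplied by 2.2 only — biologically stable, shifted
  in relative abundance. The factor estimated from simulated miRNAs
  therefore recovers 2.2 and corrected fold changes center at log₂ of the
  true per-region scale.
* **GRN.** Three tiers seeded preferentially with true primary targets,
  out-degree 4, targets biased (70%) toward true DEGs, random tissue
  labels from {leaf, root, SAM, seed}.
* **TEs.** 300 TEs of 0.3–3 kb placed uniformly, superfamily sampled from
  configurable weights (uniform by default).

Determinism: one `numpy` generator seeded from the config drives every
draw, and all writers are deterministic, so identical config + seed gives
byte-identical files (checksummed in the bundle manifest).

What the generator does **not** model: read-level data (FASTQ, alignment,
M-bias), linkage between neighbouring cytosines, overdispersed biological
replicates for methylation, sequence-capture probe geometry, realistic
motif background composition, or tissue-specific GRN structure. Passing
recovery tests therefore demonstrates correctness of the estimators and
decision rules under their stated sampling models, not robustness to
alignment artefacts or biological confounders.

## Problem sizes and tolerances

The headline recovery computation (acceptance script and the corresponding
test) uses 600 genes (~295,000 CHH sites) at 12x mean coverage: with
pooled-binomial sampling error ~0.5 percentage points on each recovered
effect, both the 68% mutant CHH reduction and the 11.1% wildtype ABA gain
are recovered well within +/-2 points. The shared test bundle uses 40
genes, and exact-recovery tests use a noiseless 120-gene bundle; the whole
suite runs in well under a minute. Property checks (pooling identity, tile
aggregation vs per-site summation, motif scan vs a vectorised
sliding-window oracle on 1,000 random 5-kb sequences, reverse-complement
invariance, GRN propagation vs a networkx oracle) use frozen seeds.

## Known limitations

* Depletion calls use a binomial test on pooled counts, which understates
  replicate-level overdispersion; rates on real data would be
  anti-conservative and should be read comparatively, not absolutely.
* The CHH differential-promoter rule is sensitive to the "low sample"
  reading; the implemented min-of-two interpretation is the only one
  consistent with both clauses of its source description but remains an
  interpretation.
* Exact degenerate-string matching finds consensus occurrences only; a
  PWM scanner would admit near-matches and report more hits.
* The explained-fraction statistic depends strongly on GRN completeness;
  on sparse networks it is a lower bound.
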