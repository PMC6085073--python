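# Methods

## Coordinate convention

All positions are 0-based transcript coordinates, 5'→3'. Two anchors are
defined per transcript: offset 0 on the **start anchor** is the first
nucleotide of the start codon, offset 0 on the **stop anchor** the first
nucleotide of the stop codon. The CDS length includes the stop codon and
must be a multiple of 3 and at least 6 nt. With this convention the
canonical 5'P signatures are literal offsets: a ribosome initiating with
its P-site on the AUG protects down to start offset −14, and the
termination pause leaves 5'P ends at stop offset −17. There *is* an
offset 0 (the published ±-numbered axes do not say whether their scale
has one); the choice is a documented convention, and all window bounds
are configurable, so any alternative reading of the axis is one
configuration away.

Genomic annotations (Ensembl-dialect GTF/GFF3, 1-based inclusive) are
projected by concatenating exons in transcript orientation; for
minus-strand genes a read's biological 5' end is the rightmost genomic
base of its alignment. When a gene has several transcripts, the first in
file order is kept (or the longest, configurable). Introns inside UTRs
beyond plain exon concatenation, and isoform resolution beyond this rule,
are out of scope.

## 5P-Seq read model

Reads carry an 8-nt 5' UMI, which is trimmed before alignment and kept
with the read. Reads sharing a gene, 5' mapping site and UMI are PCR
copies and collapse to one molecule; deduplication is idempotent and
order-independent. Coverage tables count deduplicated 5'P ends per
transcript position; rpm scaling divides by the deduplicated mapped
library size (×10⁶). The rpm denominator is a design choice — the
upstream protocol does not pin one down — and is the deduplicated count
because every downstream statistic consumes deduplicated reads. BAM/SAM
ingestion keeps primary alignments with MAPQ ≥ 1 (configurable) and drops
multimappers by default. Alignment itself is external (any splice-aware
aligner; the module consumes its output).

## Metagene profiles and frames

The metagene profile sums coverage (rpm or raw) across genes at each
anchor offset over a window (default [−100, 100], inclusive); genes too
short at an offset contribute nothing there. Summed pooled rpm is the
default aggregate; a per-gene-normalized variant
(`metagene_profile_per_gene_mean`) is provided for sensitivity analysis
since pooled profiles are dominated by highly covered genes. No coverage
floor is applied to metagene input (the ≥20-read filter applies only to
per-gene ratios), and no smoothing or peak calling beyond an argmax over
a stated search interval.

Reading-frame histograms count 5'P ends by `offset mod 3` relative to the
start codon, in the 5'UTR window (start offsets [−80, −1]) and the early
CDS ([0, 79]). One frame rule is used on both sides of the start codon so
the two regions are directly comparable.

## Windows and loading ratios

The published window bounds (uS −60..−15, dS −14..31, ddS 32..77,
uE −62..−17, dE −18..45, all described as 45 nt for the start windows)
are mutually inconsistent under any single inclusive convention, and the
printed uE/dE pair overlaps. The default scheme therefore reads the
printed left bounds as half-open intervals — uS [−60,−15), dS [−14,31),
ddS [32,77), uE [−62,−17), dE [−17,46) — which restores exact 45-nt
start-region windows, leaves a single unassigned nucleotide at start
offset −15, and makes uE/dE a clean partition. A `paper_literal` preset
exposes the printed inclusive bounds verbatim (with the overlap allowed)
for sensitivity analysis; which of the two uE/dE readings the original
analysis used cannot be determined from the text and is left as an open
question rather than guessed away.

Loading ratios are `log2(X/Y)` per gene with a 0.5 pseudocount applied
only when X or Y is zero, so the ratio is exactly antisymmetric whenever
both windows are nonzero. The ≥20-read filter is applied per ratio to
the sum of that ratio's two windows — a gene can pass uSvsdS and fail
uEvsdE. Genes whose 5'UTR (or CDS/3'UTR, for the stop windows) cannot
contain a full window are flagged and excluded from the affected ratios.
Replicate libraries are pooled (counts summed) before ratios by default,
with a per-replicate mode available.

## Genotype comparison

The per-gene score is the difference of log2 loading ratios, mutant minus
wild type, on genes passing the filter in both strains — equivalently the
log2 of the fold change of the raw window ratios, the only dimensionally
coherent reading of "log2(uSvsdS_mut / uSvsdS_wt)" when the ratios
themselves are logs. ECDFs are right-continuous; the median uses the
standard midpoint rule (mean of the central pair for even n). The median
increment is the difference of the two strains' medians, which equals the
median of per-gene scores only for symmetric distributions — both are
reported and the tests document a counterexample rather than asserting
equality.

The subset shift test is a Mann-Whitney U comparing subset vs non-subset
scores: exact null distribution when the smaller group has ≤ 8 members
and there are no ties, otherwise the normal approximation with tie and
continuity corrections. Two identical constant groups are a degenerate
special case (zero rank variance) and return p = 1. Two-sided by default;
a one-sided alternative is exposed for the directional "increased
difference" question. The subset is any user gene list; the simulator's
truth subset stands in during testing.

## MS enrichment funnel

Quantification follows the two label-free methods: `top3` (log2 of the
mean of the three most intense confident peptides per protein/sample;
fewer than three are averaged and flagged) and `count_mw`
(log2(peptide count / MW), an emPAI-like index). Each sample contributes
two gel-fraction sets (bait band, remainder); all four sets per sample
are log2-transformed and median-centred per set, the two count sets are
combined by per-protein averaging (summing raw counts pre-normalization
is available as an alternative reading of "combined"), and the intensity
sets stay separate. Proteins need quantitative values in ≥ 2 of 3
replicates; tests are equal-variance Student's t against the untagged
strain (Welch by flag), deliberately without FDR correction because the
funnel's output feeds orthogonal validation. Proteins absent from the
untagged control are compared against a floor imputed at the untagged
set's 5th percentile and flagged. Flags: *reproducibly enriched* = mean
log2 ratio > 1 with p < 0.05 in any method; *preferential* = p < 0.05
and log2 ratio > 1.5 over the untagged strain in both osmo-mRNA strains,
and > 1.5 over both control-mRNA strains, within one method ("either" by
default, "both" configurable — the original table shows both methods
without stating the rule).

## Assay calculators

Pull-down enrichment is (PD/I)tagged / (PD/I)untagged; the mRNA-pair
variant is (PD/I)mRNA1 / (PD/I)mRNA2. ddCt fold change is
E^−ΔΔCt with per-primer efficiency E ∈ (1, 2.2] (default 2.0; standard
curves are computed upstream). Half-life comes from the least-squares fit
of ln(abundance) vs time after transcription shut-off, t½ = ln 2 /(−slope),
SE by the delta method, with a non-negative slope flagged as no-decay
(infinite). Translation efficiency is trapezoidal protein AUC (to
plateau) over mRNA AUC (to a fixed 60-min horizon); the plateau is the
first time from which the curve stays within 5% (configurable) of its
running maximum — the plateau rule is artifact-defined, since "until the
levels reached a plateau" fixes no rule, and the detected plateau time is
reported alongside the ratio. P/FM sums polysomal fractions (default
3–8) over free+monosomal fractions (1–2); fraction index sets are
arguments, so either trace areas or per-fraction qPCR quantities can be
supplied.

## Synthetic data: what it emulates and what it does not

`simulate_degradome` draws 5'P ends from a per-gene intensity vector:
point mass `w_init` at start offset −14, `w_elong` per elongating codon
on the 3-nt lattice (start offsets −14 + 3k), `w_term` at stop offset
−17, and a uniform per-nucleotide background `w_bg`. The termination
peak is modelled independently of the initiation geometry because the
two pauses are reported as separate observations. The genotype effect
multiplies the background in the uS region (start offsets [−60, −15)) by
`f_utr5`, and additionally by `f_utr5_osr` on the OSR subset, so the
expected uSvsdS shift is exactly log2 of the multiplier. Unique
molecules are multinomial draws from the globally normalized
intensities; each gets a uniform random 8-nt UMI and 1 + Geometric PCR
copies (mean extra copies `pcr_dup_mean`). A `distinct_umis` mode
assigns collision-free within-site UMIs so deduplication oracles are
exact.

Defaults — 200 genes (5'UTRs 62–150 nt, CDS 100–500 codons, 3'UTRs
50–200 nt), 100,000 unique molecules, weights w_init = w_term = 5,
w_elong = 1, w_bg = 0.5/nt, one expected PCR copy per molecule — are the
package's standing study conditions: yeast-like gene sizes, an
initiation pause several-fold above the elongation lattice as in
published 5P-Seq metagenes, and enough 5'UTR background (~13 uS reads
per gene in wild type) that per-gene ratios are defined for nearly all
genes. The 5'UTR length floor of 62 nt guarantees the uS window fits;
real transcriptomes include shorter 5'UTRs, which the window layer
flags and excludes rather than truncates. No quantitative occupancy
model is claimed by the source analysis; these weights are documented
free parameters. The generator has no sequence-level realism: no
ligation or mapping bias, no rRNA contamination, no overdispersion
beyond PCR duplication, and gene expression varies only through gene
length. Passing tests therefore certify the *pipeline arithmetic and
statistics* under a known model, not robustness to those real-data
artifacts.

`simulate_ms_dataset` gives each protein a lognormal molecular weight
(~50 kDa), Poisson peptide counts with rate ∝ MW, and lognormal peptide
intensities with protein-level (sd 2), replicate-level (sd 0.3) and
peptide-level (sd 1) variation; spiked proteins gain `effect_log2` in
both intensity mean and count rate in the designated bait strains.
Peptides land in the bait gel fraction with probability 0.1. At the
published fixed thresholds this noise level yields occasional (≈1 per
500-protein dataset) false-positive preferential calls — consistent
with a funnel that explicitly forgoes FDR control in favour of
downstream validation.

`simulate_timecourse` produces 2^(−t/t½) decay with multiplicative
log-normal noise, and saturating induction curves in which the mutant's
protein curve is the wild type's scaled by the designed TE ratio.

## Numerical and testing choices

Pseudocounts (0.5, only on zeros) keep ratios antisymmetric elsewhere;
Mann-Whitney and t statistics come from scipy and are checked in the
test suite against independent oracles (exhaustive rank enumeration,
the pooled-variance formula) rather than against themselves. Simulation
sizes in the tests (default depth for single runs; 20-seed batteries
for recovery and power checks) were chosen so the whole suite completes
in a few minutes on one core. Known limitations: UMI collisions are
possible at heavily covered sites in the default mode (measured as
negligible at default depth, ≲1 collision per 10⁵ molecules);
the dedup key is per-gene rather than genome-wide, so paralogous
positions merged by a genome-wide key would differ; and the funnel's
imputed-floor handling of proteins absent from the untagged strain is
one of several defensible readings of a silent protocol.
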