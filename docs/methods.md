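# Methods

`marvelx` analyses alternative splicing in single-cell RNA-seq at two
resolutions: per-cell percent-spliced-in (PSI) of exon-level events for
plate-based protocols (Smart-seq2 and similar, where coverage is roughly
uniform along transcripts), and pseudo-bulk splice-junction usage for
droplet-based protocols (10x-style 3'-biased libraries, where per-cell
junction counts are too sparse for cell-level estimates). This note
documents the models, the rules and thresholds they use, the design
decisions that were genuinely open, and what the synthetic cohorts do and
do not establish.

## Coordinates and junction identity

All in-memory coordinates are 1-based inclusive (GTF convention). A splice
junction is identified by the first and last base of the removed intron —
the convention of STAR's `SJ.out.tab` — so the junction between an exon
ending at `e` and one starting at `s` is `(e+1, s-1)`. rMATS event tables
use 0-based starts; these are shifted once, at the read boundary, and raw
versus internal tables are kept distinct so the conversion cannot be
applied twice.

## Event catalog

Exon-level events (SE, MXE, RI, A5SS, A3SS) come from rMATS-style
coordinate tables; alternative first/last exons (AFE, ALE) are detected
from the annotation: for each gene, every unordered pair of distinct,
non-overlapping first (last) exons whose transcripts splice directly to a
shared flanking exon yields one event. Requiring the shared flank is what
makes a junction-ratio PSI well defined — both isoforms' terminal junctions
land on the same acceptor/donor. On the minus strand "distal" means
farther in transcription order, not genomic order. Events are
deduplicated by (type, coordinate block).

Each event carries explicit included/excluded junction sets (SE: two
inclusion junctions and one skip; MXE: two and two, with the record's
first alternative exon as the "included" form, rMATS's own convention;
A5SS/A3SS/AFE/ALE: one and one; RI: the skip junction only). A
cohort-level evidence filter retains an event only when all of its
junctions exist in the count matrix and their summed count across cells
and junctions is at least 10; the per-cell sufficiency rule is separate
(below).

Retained-intron quantification uses "independent" introns only: introns
overlapping any annotated exon of any gene are discarded, because exonic
reads inside the interval would inflate the coverage estimate. One
exception is built in: an exon that exactly spans the whole retained block
(upstream exon start through downstream exon end) is disregarded during
the scan, since the retained-intron isoform itself implies such an exon
and a literal scan would discard every intron.

## PSI

For junction-ratio events,

    psi = included_reads / (included_reads + excluded_reads)

per cell, with the value recorded as missing when fewer than 10
informative reads support the event in that cell (the floor applies to
the joint total, matching the denominator structure of the ratio). For
retained introns, with C the total per-base coverage over the intron, L
its length in bp and S the junction reads skipping it,

    c = C / L,    psi = c / (c + S)

missing when c < 10 or S < 10. PSI is stored on [0, 1]; every threshold
quoted on the percent scale is converted at the comparison site, never by
rescaling the matrix.

Droplet junction usage is pseudo-bulk: U = (sum of junction counts over a
population's cells) / (sum of that junction's gene counts over the same
cells), undefined when the denominator is zero. Droplet junctions are
first screened against the annotation: both flanking exonic positions
(start-1, end+1) must match exon boundaries of exactly one and the same
gene (exact coordinate match — STARsolo and the GTF share a reference, and
a tolerance window would itself create multi-mapping ambiguity).

## Modality classification

Events with a non-missing PSI in at least 25 cells are eligible. The
per-cell PSI sample is fitted with a beta distribution by maximum
likelihood (`scipy.stats.beta.fit` with location/scale fixed) and
classified by sequential rules on the fitted shapes (strict inequalities;
a boundary value falls through to the next rule):

1. bimodal if alpha < 0.5 or beta < 0.5
2. included if (alpha > 2 and beta < 1) or alpha/beta > 2
3. excluded if (beta > 2 and alpha < 1) or beta/alpha > 2
4. middle if alpha > 1, beta > 1 and alpha ~ beta
5. multimodal otherwise

The "alpha equals beta" clause of the middle rule is implemented as
|alpha - beta| <= 0.05 * max(alpha, beta): exact equality never occurs for
an MLE on data, and a relative 5% band keeps the rule scale-free. The
included/excluded rules as written are ambiguous in operator precedence;
they are read as (alpha > 2 AND beta < 1) OR ratio > 2, the only reading
that mirrors cleanly between the two rules. Included/excluded calls are
sub-classified by the empirical variance of the observed PSI values —
primary below 0.001, dispersed at or above. The empirical rather than the
model variance is used because it is robust to fit failures and is the
statistic the variance threshold was calibrated on.

Exact 0 and 1 observations (count-ratio extremes) are moved to 1e-3 and
1 - 1e-3 before fitting, because the beta likelihood is undefined at the
boundary. Interior values are deliberately left untouched: they pose no
likelihood problem, and clipping them measurably biases shape recovery for
U-shaped distributions (for Beta(0.3, 0.3), clipping the ~14% of mass
beyond 1e-3 inflates the fitted shapes by ~20%). A constant sample is
returned as a sharp moment-matched fit with a warning flag rather than an
optimizer failure.

### Bimodality adjustment

Amplification and capture artifacts make genuinely one-isoform events look
bimodal. For an event classified bimodal, let n_hi and n_lo be the cell
counts with PSI above 0.75 and below 0.25. The call is accepted as true
bimodality only when the fold difference max/min < 3 (computed on integer
counts so a fold of exactly 3 is exact) AND the absolute proportion
difference < 0.50, both strict. A one-sided distribution (min count 0,
fold infinite) always fails. False bimodals are reassigned to included
when the mean PSI exceeds 0.5, excluded otherwise, and then receive a
primary/dispersed sub-modality from their variance. Adjustment only ever
fires on events first classified bimodal.

### Modality dynamics

For a differentially spliced event with modality calls in both
populations: explicit when the five-class modality differs, implicit when
only the primary/dispersed sub-modality differs, restricted when neither
differs (a significant distribution shift without a class change); a
missing call in either population yields "undefined" and is excluded from
tallies.

## Differential splicing (plate)

Distribution-level two-sample tests on per-cell PSI: Kolmogorov–Smirnov,
k-sample Anderson–Darling (scipy's interpolated p-values, clamped to
[0.001, 0.25] — the clamp only compresses extreme tails and does not move
calls at the FDR 0.10 boundary), Wilcoxon rank-sum, Welch-free t-test, a
permutation test on the absolute mean difference, and the DTS statistic:
the integral of |F1 - F2| over the pooled sample, weighting each pooled
order statistic by the gap to the next one divided by the binomial
standard deviation sqrt(Fp(1-Fp)) of the pooled ECDF. DTS and the mean
permutation test use label-permutation inference (B = 1000 by default,
seeded, with the +1-smoothed estimator, so p >= 1/(B+1)).

The default pipeline runs AD and DTS, BH-adjusts each across tested
events separately, and calls the union of events with FDR < 0.10 in
either — the combination detects the complementary event sets of the two
statistics at the cost of mild anti-conservatism in the realized
false-discovery proportion (the union of two 10% lists can exceed 10%;
observed ~7–23% across synthetic cohorts at ~45 discoveries). Events are
eligible with >= 25 informative cells overall and >= 2 per group (fewer
per group yields a skip reason, not an exception). Finally, outlier
removal de-calls any significant event for which neither population has
at least 10 cells with PSI strictly inside (0, 1): such calls are driven
entirely by cells at the extremes. Removal never adds significance.
delta-PSI is reported on the percent scale as group2 - group1, the group
order echoed from the caller.

## Differential splicing (droplet)

After expression-rate filters — genes expressed in >= 10% of cells in
*both* populations, junctions expressed in >= 10% of *either*, junction
kept only if its gene is kept — each junction's observed usage difference
dPSI = 100 * (U2 - U1) is compared against a null built by shuffling the
cell-population labels (group sizes fixed) and recomputing usage from raw
counts per shuffle, B = 100 by default. p = (1 + #{|dPSI_perm| >=
|dPSI_obs|}) / (B + 1). A junction is called significant when the pooled
mean log2(x+1) expression of its gene across all cells of both
populations exceeds 1.0, |dPSI_obs| > 5 and p < 0.05 (raw p, as the rule
is stated; BH adjustment is available behind a flag). A permutation
replicate with an undefined usage (zero pseudo-bulk gene count in a
shuffled group) counts as non-exceeding; under the 10% filters this is
practically unreachable.

## Differential expression and integration

Gene-level differences use the Wilcoxon rank-sum test on log2(x+1) of the
normalized expression (the pseudocount of 1 is the field convention; fold
changes are therefore attenuated for weakly expressed genes), BH-adjusted;
a gene is differential at FDR < 0.10 with |log2FC| beyond 0.5 (plate) or
1.0 (droplet). Genes must be expressed in at least 3 cells.

Each differentially spliced event is then classed against its gene:
isoform_switching when the gene is not differentially expressed,
coordinated when the signs of log2FC and delta-PSI agree, opposing when
they differ. An event with delta-PSI exactly 0 (possible when only the
distribution shape shifts) has no sign to compare and is tie-broken to
isoform_switching with a log entry. A gene whose events span more than
one class summarizes to "complex".

PCA of PSI matrices recodes missing entries with i.i.d. Uniform(0, 100)/100
draws under a caller seed before centering (no unit-variance scaling — PSI
is already bounded); features observed in fewer than 25 cells are dropped
first. Recoded coordinates therefore vary with the seed while planted
group structure persists.

## NMD prediction

Candidates are differential events with |delta-PSI| > 5 percent and
FDR < 0.10, restricted to SE, RI, A5SS and A3SS — the types whose
alternative form is a single genomic segment that can be spliced into an
isoform (MXE/AFE/ALE change transcript structure in ways a single
insertion cannot model). For each candidate, every isoform of the gene
compatible with the segment (segment equals an existing exon, or lies
wholly inside one intron; partial exon overlap is incompatible) is
evaluated; if no isoform is compatible the event is recorded as a novel
isoform. The modified cDNA is assembled in genomic order with contiguous
blocks fused (an RI intron or an A5SS/A3SS extension merges with its
flanking exon and creates no new junction), reverse-complemented on the
minus strand, and translated from the annotated CDS start; transcripts
without CDS records fall back to the longest ATG-initiated ORF with a
logged downgrade, and yield "non_coding" when none exists. The first
in-frame stop codon is compared, by genomic coordinates of its bases,
with the unmodified isoform's stop: an unchanged stop is "orf_intact", a
changed one "ptc_introduced". Distance is measured in transcript
coordinates from the last base of the stop codon to the final exon-exon
junction of the modified transcript; NMD is predicted when the distance
strictly exceeds 50 bp (a stop downstream of the final junction gives a
negative distance and is never NMD). The anchor base (last base of the
stop codon) is a documented choice pinned by boundary tests; the rule's
source does not fix it.

## Synthetic cohorts

The plate generator is beta-binomial: each SE event has per-group beta
shapes; a cell draws a latent psi from its group's beta, an informative
read depth from a negative binomial (mean 60, size 3 — deep enough that
most cells clear the 10-read floor while a realistic minority goes
missing), and included reads from Binomial(depth, psi) split evenly
across the two inclusion junctions. Defaults are the study conditions
used throughout: 300 events, 40 of them with a planted +40-percentage-
point shift of the group-2 mean (null events share Beta(m·20, (1-m)·20)
shapes with m uniform on [0.15, 0.5]), 60 cells per group. Modality
fixtures plant seven archetypes at deeper coverage (mean 200 reads, so
the binomial observation noise does not blur the primary/dispersed
variance threshold or the middle rule's equality band): included primary
(100, 1), included dispersed (8, 1.2), their mirrors, bimodal (0.3, 0.3),
middle (40, 40), multimodal (1.2, 1.7). Spurious bimodality is planted as
monoallelic capture applied to a strongly included event (latent
Beta(8.5, 1.5), mean ~0.85, matching the observation that artifact
bimodals trend toward one extreme): the affected cell reports PSI 1 with
probability equal to its latent psi, else 0. Retained-intron fixtures
draw psi from Beta(4, 4) and emit a coverage matrix consistent with the
coverage-ratio equation. Expression is log-normal with a 1.5 log2-unit
group shift wired to each differential event's planted relation
(coordinated/opposing/none).

The droplet generator thins: gene counts are negative binomial (mean 20,
size 2) with 30% extra zero-inflation, and junction counts are
Binomial(gene count, u) with u the planted usage (0.3 null; 0.2 vs 0.5
for planted differential junctions), which guarantees junction <= gene
counts and hence usage in [0, 1]. Defaults: 300 junctions, 200 cells per
group.

What the synthetic cohorts do not emulate: real transcript structure
(isoform families, shared junctions between events), empirical depth and
dropout distributions, batch effects, ambient RNA, 3' positional bias
within genes, and correlated gene programs. Passing tests therefore
establish the correctness of the arithmetic, the rule logic, the
calibration of the permutation machinery under exchangeability, and
recovery of planted effects at realistic magnitudes — not performance on
any particular real dataset.

## Numerical choices and limitations

- Permutation p-values are +1-smoothed and bounded below by 1/(B+1);
  seeded generators make every stage byte-reproducible.
- scipy's Anderson–Darling p-values are interpolated and clamped to
  [0.001, 0.25]; with BH at FDR 0.10 over hundreds of events the clamp
  never changes a call in the regimes tested, but AD p-values should not
  be quoted below 0.001.
- The middle/multimodal boundary is the least stable classification: for
  a symmetric event the fitted shape difference scales with the sampling
  noise of the mean, so middle recovery is ~95% at 100 cells and mean
  depth 200 where other archetypes are at ~100%.
- The union-of-tests default trades exact FDR control for sensitivity;
  single-method mode (`method="ad"` etc.) gives plain BH control.
- Droplet usage compares pseudo-bulk ratios; it does not model per-cell
  variability and cannot detect within-population heterogeneity.
- The NMD walk assumes the annotated CDS start survives the modification
  (an inserted segment upstream of the start codon that disrupts the
  5' UTR is still translated from the annotated start).
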