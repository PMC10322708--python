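# Methods

This note documents the statistical model behind `hapdose`, the choices made
where the design was genuinely open, what the synthetic data do and do not
emulate, and the package's known limitations.

## Quantification of haplotype-specific transcription

**Per-gene summaries.** A cell's expression of gene *g* is reduced to the
TPM ratio *r<sub>g</sub>* (cell TPM over mean control TPM) and the allele
fraction *f*<sub>A,g</sub>, the haplotype-A share of haplotype-informative
reads pooled over the gene (gene-level pooling is more accurate than
site-level fractions when several informative sites fall in one transcript).

**Gene filters.** Genes are analyzed only if their control mean TPM exceeds
25 (low-expression genes are dominated by transcriptional and technical
noise) and their control allele fraction lies in 0.3–0.7, which removes
imprinted or otherwise allele-biased genes for which dosage cannot be read
from allelic shifts. Two exceptions: all X-linked genes are retained (the
inactive X is legitimately monoallelic), and genes inside a declared clonal
trisomy use the shifted window 0.2–0.4 for the single-copy haplotype. The
allelic filter pools all control cells in the run; per-batch pooling is
possible by passing batch-restricted control lists.

**QC.** Cells qualify by the number of genes with ≥ 5 informative reads:
6,000 for control cells, 4,000 for micronucleation-related cells (their
libraries are systematically sparser). These are genome-scale constants; on
synthetic catalogs the floors must be scaled to the catalog size (the
examples and acceptance runs use 300/200 on a 500-gene genome). Boundaries
are inclusive.

**Global rescaling.** TPM is compositional: a change anywhere renormalizes
everything. Each cell's ratios are multiplied by one constant chosen so
that the median across chromosomes of the chromosome-level weighted mean
ratio equals 1, after excluding chromosomes deviating more than 20% from
the across-chromosome median (aneuploid or outlier-dominated). Centring the
statistic that is actually reported makes disomic chromosome ratios exactly
1 in expectation; centring a plain gene median instead leaves the weighted
means ~exp(σ²/2) high (right-skew) and, on a compact genome where one
chromosome is 20% of all genes, drags the factor toward the aneuploid
ratio. The ungrouped form of `rescale_global` is the plain gene median. The
operation is idempotent and robust to single dominant genes.

**Weighted aggregation.** TPM ratios aggregate with inverse-variance
weights w<sub>g</sub> = 1/(σ̂²<sub>g</sub> + ε), ε = 0.01, σ̂²
estimated from rescaled control ratios, winsorized at the 95th percentile;
allele fractions aggregate with the cell's per-gene informative-read counts
(binomial precision), equally winsorized. Both weighting strategies are
parameters. Bins are 0-based half-open 10-Mb tiles with genes assigned by
midpoint; arm grouping uses a centromere table (synthetic genomes place the
centromere at the midpoint).

**Yield.** The normalized haplotype-specific transcription is
y<sub>h</sub> = (mean ratio) × (mean fraction of h); one normal homologue
contributes 0.5, so a duplicated homologue ~1.0 and a lost one ~0. Optional
per-chromosome display scalings (0.6 for X, 1.5 for a clonal-trisomy
segment) are applied uniformly to control and analysis cells, so z-scores —
and hence every classification — are invariant to them.

## References and classification

Per (chromosome, haplotype), the control cohort gives a normal reference
N(μ, σ) of yields (σ as sample s.d., n ≥ 5 required). Designated unstable
chromosomes get a two-pass screen: controls deviating > 3σ on either
homologue are dropped from that chromosome's reference (an automated,
reproducible stand-in for manual review of karyotypically unstable
chromosomes). The duplicated-homologue reference is fitted from harvested
bona fide trisomies — chromosome-wide ratio ≈ 1.5, haplotype fraction ≈
2/3, and sibling support (shared by siblings or mirrored by a sibling
monosomy), the last acting as a biological replicate — and otherwise falls
back, with a warning, to the distribution of total disomic transcription
(two copies of a duplicated homologue should transcribe like a disomic
pair). Yields below 0.1 are nullisomic by rule, not by test: a truly absent
haplotype should emit nothing, and the residual reflects technical error
with no estimable null.

Classification uses two-tailed z-tests with the reference σ treated as
known, Bonferroni-corrected by the number of homologues tested in the cell
(46 for a full karyotype; 10 on the default synthetic genome). Cascade:
nullisomic rule, then consistency with one copy ("1"), then with a
duplicated homologue ("2"), otherwise intermediate "1−"/"1+" signed by the
nearer reference mean; yields beyond the duplicated mean keep the maximal
label so the label order is monotone in yield. When both tests accept, the
smaller standardized deviation wins. Under the null the fraction of
homologues rejected at corrected α = 0.05 is ≈ 0.6% (measured over 500
simulated cells), comfortably below α; the per-cell any-flag rate is ≈ α by
construction, so a "no cell ever flags" expectation is a coin flip at any
finite sample — calibration statements in the tests are therefore made at
the homologue level.

## Family inference

Candidate scenarios (chromosome, haplotype, 1:3 or 2:2) predict state
patterns per role. The prediction never constrains the MN chromatid's own
yield — that is the identifiability principle which lets yield estimation
remain unbiased by selection. Evidence is graded: a match or violation
contributes ± its strength, where near-complete loss ("0") carries the
maximal weight 2 and other flags are graded by −log₁₀ of their corrected p
(clamped to [0.5, 2]), so a marginal flag produced by reference-estimation
noise neither anchors nor vetoes a scenario. An assignment requires a
unique best locus with total score ≥ 1; exact ties between distinct
chromosomes are reported as unresolved with all candidates listed, and
flag-free families are reported as "invisible-normal" (a fully
transcribing 2:2 MN chromosome leaves no transcriptome footprint — a
conservative outcome, not an error). A 1:3 family whose MN chromatid
transcribes fully is transcriptionally identical to a
micronucleus-independent reciprocal loss/gain; because families are
ascertained on an observed micronucleus, the MN reading is reported and the
reciprocal explanation recorded as competing. Reciprocal events on other
chromosomes are recorded separately. Chromosomes with known excess
variability (acrocentric analogues) can be down-weighted.

Yield estimation follows the scenario: generation-1 2:2 reads the MN
haplotype directly (*a* = y); generation-1 1:3 reports the excess over the
one-copy reference mean and classifies against disomic-level transcription;
generation-2 2:2 sums both daughters (fragments may be distributed
reciprocally); generation-2 1:3 sums per-daughter excesses and classifies
each daughter against both the one-copy and two-copy ranges.
Classification of *a* reuses the same z-machinery (near-silent below 0.1).
On the simulation grid (200 families per pattern, mixed generations,
splits, and yields) identifiability is 98–99% and the mean yield error per
basis is < 0.01.

## Clone chromatin accessibility

Peaks from all samples are transitively merged when within 400 bp (merged
GC is length-weighted). Counts are quantile-normalized (all samples jointly
as the target; average-rank tie handling — exact idempotence holds on
continuous data), then divided by local DNA copy number from 250-kb tracks
relative to the diploid baseline; copy-number-zero peaks are masked. Each
peak receives k = 50 background replicates sampled without replacement from
its ~500 nearest neighbours in standardized (GC, log1p mean control
accessibility) space with Gaussian kernel weights (bandwidth 0.1 s.d.),
never including itself. Interval tests tile the genome with non-overlapping
1/5/10-Mb windows anchored at 0; only intervals with ≥ 10 peaks per Mb are
eligible, giving at least 50¹⁰ ≈ 9.8 × 10¹⁶ permutations. The null
distribution of the interval mean is sampled n_perm times (desk default
10⁴; 10⁶ is a flag away); the null *mean* is computed in closed form over
the replicate matrix, so fold changes are exact and independent of n_perm,
and the one-sided empirical p uses the +1 correction (floor 1/(n_perm+1)).

Cohort scans re-centre each sample's fold changes by the sample's median
across eligible intervals and recompute p for the re-centred observation.
Rationale: with desk-scale peak sets, matching granularity is limited by
local peak density, and the resulting mean-shift leaves observed interval
means a systematic ~2% off their nulls; re-centring restores null p
uniformity (verified by KS over 200 null intervals) while leaving a genuine
regional suppression (fold change ≈ the injected factor) untouched.
Flagging requires fold change strictly below 0.70 *and* empirical p below
α (default 10⁻³; the printed threshold is a reduction criterion, and the α
accompanying it is configurable because no general value is stated for it).
Bulk per-copy expression divides globally rescaled TPM (scaling genes:
bi-allelic, mean TPM 1–1000) by local copy number and reports ratios
against the parental sample, isolating epigenetic suppression (ratio ≈ 0.5
at normal copy number) from dosage effects (ratio ≈ 1 at halved copy
number).

## Synthetic data: what it emulates, and what it does not

Gene baselines are log-normal (log-mean 4, log-s.d. 1) truncated so ≥ 80%
of genes clear the TPM > 25 floor, on 5 × 100-Mb chromosomes with 100 genes
each placed to cover every 10-Mb bin. A cell's expected expression scales
linearly with chromosome dosage (in per-homologue units: disomic =
(0.5, 0.5)); per-gene multiplicative log-normal noise (dispersion 0.15,
exposed as a parameter because the empirical per-gene ratio dispersion is
not pinned by any published value) is shared between the TPM and the
Poisson informative-read total, and haplotype-A counts are binomial in the
dosage share — the minimal structure under which allele fractions are
sufficient for dosage. Family geometries set role dosages exactly (e.g.
generation-1 1:3: sister 0, MN cell 0.5 + *a*). ATAC clones draw per-peak
log-normal baselines correlated with GC (so background matching is
non-trivial), Poisson counts with clone-level library factors and per-peak
log-normal noise, and inject suppression by multiplying case-clone means
inside the target interval.

Not emulated: read-level artifacts (alignment, duplicates), amplification
(SMART-seq) biases beyond dispersion, doublets, phasing errors, batch
effects, per-copy damping of trisomic transcription, and subclonal
heterogeneity within clones. Passing tests therefore demonstrate the
correctness and calibration of the inference given the stated statistical
structure, not robustness to upstream artifacts.

Problem sizes in the test and acceptance runs (30–100 control cells, 50
aneuploid cells, 200 families per pattern, 4,000–12,000 peaks, 10⁴
permutations) are the package's desk-scale defaults; every size is a
parameter.

## Numerical and policy details

- One integer seed per run; all substreams derive from a `SeedSequence`.
  Outputs are byte-identical across reruns (hashed in the run manifest).
- z-tests use known-σ normal tails (no small-sample t correction), matching
  the stated test; with ≥ 100 controls the difference is negligible.
- Fisher's exact test is two-sided by the probability-mass criterion.
- Bonferroni is min(1, p·n); empirical p never returns 0.
- Degenerate inputs fail loudly: empty gene sets, zero medians, missing
  references, all-zero tables, too-few controls or peaks all raise with the
  offending quantity named.

## Limitations

Arm-level events are supported only through the arm grouping option;
acentric-arm micronuclei with no transcribed genes are invisible to any
transcriptome method. The scenario space covers one MN event per family
plus independent reciprocal events; two simultaneous micronucleation events
on different chromosomes would tie and surface as unresolved. DNA-based
validation (copy-number and rearrangement calling) is consumed as input,
never produced.
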