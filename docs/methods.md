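# Methods

This note documents the models behind `mirrormeth`, the defaults that
matter, and what the synthetic data do and do not show.

## Synthetic genome

The genome (default 2 × 100 kb, 20 genes) is laid out in 19-kb
*tandem-gene cassettes*: a long gene (10-kb body) followed by a short gene
whose upstream window tiles the long gene's deep body. This guarantees that
all three DMR position classes exist **and are covered by promoter tiling
probes**: proximal slots at a TSS, intergenic slots in an upstream window
outside any gene body, and intragenic slots deep inside a gene body but
inside the *neighbouring* gene's −4000..+1000 window. Promoter windows are
strand-aware; cassette orientation is randomized. Coordinates are 0-based,
half-open throughout; interfaces are FASTA (genome), BED6 (TSS, DMRs) and
TSV tables.

The base sequence is generated CpG-free and CG dinucleotides are then
planted at controlled per-region rates, so CpG density is exact by
construction: background 0.01/bp; intermediate-CpG promoter islands
0.04/bp (unmethylated baseline); candidate DMR slots 0.03/bp (600 bp,
methylated baseline). Three controls sit in the head margin of chr1: a
CpG-free region, an imprinted-like region (50 % methylation, allelic) and
a fully methylated dense region. The density defaults were chosen so that
a ~375-bp fragment over a candidate slot carries ~11 CpGs (saturating the
elution model when methylated) while background fragments carry ~3–4,
near the elution midpoint — mirroring low-to-intermediate-CpG DMRs against
a mostly methylated genome.

## Methylome model

Each CpG has a population methylation fraction per cell state. MO and MAC
are constant in time; MAC (and flat DC) differ from MO by a truncated
Gaussian offset (sd 0.02) clipped above at +0.0099 so that no state ever
exceeds the MO baseline by more than the no-de-novo tolerance ε = 0.01 —
the system can only lose methylation. DC-lineage decay follows a
**zero-anchored logistic**

    f(t) = initial − (initial − final) · (σ(k(t−onset)) − σ(−k·onset)) / (1 − σ(−k·onset))

which equals `initial` exactly at t = 0, is monotone non-increasing, and
has its midpoint at `t = onset` up to the anchoring term (< 10⁻³ at the
default steepness k = 0.35 h⁻¹). The anchored form was chosen over a raw
logistic so that the t = 0 sample is the measured baseline by definition.

Planted DMRs draw MO baselines from U(0.85, 0.95) and DC terminal
fractions from U(0.02, 0.08) (the report thresholds "methylated ≥ 0.8",
"demethylated ≤ 0.2" are conventions matching near-binary heat-map-style
data, not measured values). Onsets are locus-specific with ±2 h per-CpG
jitter: early loci draw from U(18, 42) h, late loci from U(55, 90) h,
leaving the (42, 51] h gap empty by construction. The late range is
bounded at 90 h so that every onset lies inside the sampled part of the
time course (below).

## MCIp elution model

Per-molecule methylation is sampled per CpG as an independent Bernoulli
with the population fraction; a co-methylation correlation parameter is
exposed (default 0) and the imprinted control is drawn allelically
(all-or-none per fragment), which is what makes a 50 %-methylated
imprinted region split between pools instead of piling up at intermediate
loads. Fragments are truncated-Gaussian in length (mean 375 bp, sd 50,
min 100) with uniform starts; default coverage is 40 fragments/bp·mean_len
per state and replicate (~21 000 fragments per 200-kb genome).

The expected elution-step index is logistic in the methylated-CpG load m:

    E[index] = 6 · σ(1.2 · (m − 3.5))        index ∈ {0..6} ↔ {250..1000 mM}

rounded to the nearest step with a ±1-step assignment error of probability
0.05 per direction. These defaults imply the qualitative contracts used in
tests: 0 methylated CpGs → CpG pool (≤ 350 mM) with ≥ 95 % probability;
≥ 10 methylated CpGs → 1000 mM with ≥ 90 %; mean step monotone in m. The
pooling rule itself is fixed protocol: 250–350 mM = CpG pool,
400–1000 mM = mCpG pool.

A consequence worth knowing: background fragments (~3–4 CpGs, ~87 %
methylated) sit *near the elution midpoint*, so their pool split is
maximally sensitive to sampling noise. This is the dominant noise source
at the array stage and mirrors real MCIp, where mid-density fragments
spread across adjacent salt fractions.

## Array stage and the mirror statistic

Probe intensity is linear in the number of pool fragments overlapping the
probe plus background 5.0, with multiplicative lognormal noise
(σ_ln = 0.15) and a 1.15× dye bias on the DC channel that linear
(median-equalizing) normalization removes. Probes with any channel beyond
the 0.001/0.999 empirical quantiles are excluded. The score is

    s = log10(DC_CpG/MAC_CpG) − log10(DC_mCpG/MAC_mCpG),

positive for hypomethylation in DC; it is antisymmetric under label swap
and cancels any shift common to both ratios. Intensities are clipped at
10⁻³ before the log.

Calling: maximal same-sign runs of ≥ `min_probes` probes with
|s| ≥ threshold, intersected across the two biological replicates
(sign-consistent interval intersection, not score averaging). The
defaults **|s| ≥ 0.6 and ≥ 3 probes are values calibrated on the
synthetic data, not assay standards**: with the default coverage, the binomial pool-split noise of
midpoint-straddling background fragments occasionally produces
replicate-consistent |s| ≈ 0.5 runs, and calibration across seeds put the
operating point at sensitivity 1.0 / FDR 0.0 (true-DMR probes score
|s| ≈ 0.9–1.4). Both are exposed in `ArrayConfig`. Annotation: signed strand-aware distance from the central
probe midpoint to the nearest TSS; proximal if |d| ≤ 1000 bp, else
intragenic if inside *any* gene body, else intergenic; CpG count and GC
fraction over a 500-bp window centred on the central probe.

## EpiTYPER simulation

Only the informative T reaction of the reverse strand is modelled.
Bisulfite conversion is complete (no partial-conversion model). The
transcript is the reverse complement of the converted template (U for T);
cleavage cuts 3′ of every U. Because a methylated CpG reads G and an
unmethylated one reads A in this transcript, methylation changes fragment
mass by the G−A residue difference (16.00 Da with the average-mass table
used: A 329.21, C 305.18, G 345.21, U 306.17, +18.02 terminal) without
changing the cleavage pattern. The mass table is a documented convention —
only the G−A difference matters to quantification, and correctness is
defined against a residue-sum oracle.

Peak intensity for k methylated CpGs in an n-CpG unit is the
Poisson-binomial probability of k under the member CpG fractions, times
lognormal noise (sd 0.10). The unit ratio is Σk·I_k / (n·ΣI_k). A unit is
unmeasurable — flagged, never quantified — if any peak leaves the
1500–7000 Da detection window or lies within 0.5 Da of a peak from a
different fragment (duplicated fragment sequences therefore knock out
their units, as in real spectra). Amplicons are ~450 bp (bounds 200–600)
centred on the target region, with the platform's standard 10-mer forward
tag and T7 reverse tag.

Concordance: a region detected by both assays (≥ 1 measurable unit in
both samples) is concordant if sign(MAC − DC mean ratio) matches the
array call direction, or, for array-negative controls, if
|MAC − DC| < 0.1 (`delta_min`). This operational definition is this
package's own.

## Kinetics fitting and sampling design

Per-CpG time courses are fitted with the same anchored logistic by
bounded least squares (scipy `curve_fit`), multi-started over steepness
{0.1, 0.35, 1.0} because the likelihood is flat in (onset, k) when few
samples fall inside the transition. Classes: "none" if fitted total
change < 0.2 (min_delta) or the profile rises > 0.1 above its running
minimum (non-monotone beyond noise); otherwise early if onset ≤ 46.5 h,
late if > 46.5 h (midpoint rule for the unobserved 42–51 h gap; such fits
are flagged).

The default sampling grid is (0, 6, 18, 30, 42, 51, 66, 78, 96, 120,
168) h. The late points were placed so that **every modelled onset has a
sample inside its ~12-h logistic transition**; onsets deep inside an
unsampled gap are not identifiable to ±6 h at noise sd 0.02 by any
estimator, so grid density is a design requirement, not a tuning knob.

## Expression and ChIP arithmetic

Expression is simulated per gene × (state, time, donor) with lognormal
noise; about half of DMR-associated genes are induced ~4-fold along the DC
time course. Samples are scaled so each sample's 75th percentile equals a
common constant, then divided per gene by the median of the MO samples
(baseline 1). "Up-regulated" means max mean DC fold change ≥ 2.0 — an
explicit convention of this package. The Mann–Whitney U statistic uses the
rank formula with mid-ranks; the two-sided P comes from exact enumeration
of all group assignments when both groups have ≤ 8 members (handles ties
exactly; full ties give P = 1) and from the tie-corrected normal
approximation otherwise.

ChIP-qPCR: percent input = 100 · 2^((Ct_input − log2(1/f)) − Ct_IP) with
input fraction f = 0.05; enrichment is reported relative to the 0 h
sample, which is exactly 1 by construction.

## What the synthetic data do not show

* Planted DMRs are near-binary (0.9 → 0.05) with clean logistic decay;
  real DMRs have partial, heterogeneous methylation, so the recovery rates
  measured here bound the easy regime only.
* Per-molecule methylation is independent across CpGs (except the
  imprinted control); real co-methylation structure would fatten the tails
  of the fragment-load distribution.
* No PCR/labeling bias, bead capacity, repeat structure, SNPs or partial
  bisulfite conversion are modelled; probe responses are identical up to
  noise.
* The array false-discovery behaviour depends on fragment coverage; at
  much lower coverage the calibrated caller thresholds would need
  re-calibration.
* Expression and ChIP tables are illustrative generators for exercising
  the normalization and test arithmetic, not models of regulation.
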