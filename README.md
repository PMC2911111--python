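# mirrormeth

Simulation and analysis pipeline for detecting **active DNA demethylation**
during post-mitotic monocyte differentiation, built around comparative
methyl-CpG immunoprecipitation (MCIp) profiling and the *mirror-image*
two-array statistic, with in-silico EpiTYPER mass-spectrometric validation.

## The problem

Human peripheral blood monocytes (MO) differentiate into macrophages (MAC)
or dendritic cells (DC) without dividing, so any loss of CpG methylation
along the way must be *active* (enzymatic) rather than passive dilution
through replication. Detecting such differentially methylated regions
(DMRs) genome-wide combines several steps, each of which this package
models and tests end-to-end on synthetic data with planted ground truth:

1. **Methylome time course** (`mirrormeth.genome`, `mirrormeth.methylome`) —
   a toy promoter genome with controlled CpG densities and a per-CpG
   population methylation fraction for MO/MAC/DC. Planted DMRs are
   methylated in MO and MAC and decay in DC following a monotone,
   zero-anchored logistic with per-CpG onset (early: 18–42 h, late:
   > 51 h). No CpG ever gains methylation.
2. **MCIp fractionation** (`mirrormeth.mcip`) — sonicated fragments bind an
   MBD-Fc matrix with a strength that grows with their methylated-CpG
   load; fragments elute across salt steps 250–1000 mM NaCl and are pooled
   into an unmethylated pool (CpG, 250–350 mM) and a methylated pool
   (mCpG, 400–1000 mM). Spiked controls: a CpG-free region, an
   imprinted-like region at 50 % allelic methylation, and a fully
   methylated dense region.
3. **Mirror-image arrays** (`mirrormeth.arrays`) — for each biological
   replicate the DC and MAC pools are co-hybridized on two two-channel
   promoter tiling arrays (one per pool). The per-probe DMR statistic
   subtracts the two log-ratios,

   `s = log10(DC_CpG / MAC_CpG) − log10(DC_mCpG / MAC_mCpG)`,

   so a genuine methylation difference (which appears with opposite sign in
   the two comparisons) is doubled while copy-number or probe-affinity
   shifts cancel. DMRs are maximal runs of ≥ `min_probes` consecutive
   probes with |s| ≥ threshold and consistent sign in **both** replicates.
4. **EpiTYPER validation** (`mirrormeth.epityper`) — bisulfite conversion,
   reverse-strand in-vitro transcription off a T7-tagged primer,
   base-specific cleavage 3′ of U, and MALDI-TOF quantification: each
   methylated CpG shifts its cleavage fragment by the G−A residue mass
   (≈ 16 Da). CpG units whose peaks collide or leave the detection window
   are flagged, never quantified. Array/MS agreement is summarized as the
   percentage of concordant regions.
5. **Reporting** (`mirrormeth.kinetics`, `mirrormeth.expression`,
   `mirrormeth.stats`) — per-CpG demethylation-kinetics classification
   (early/late/none), Mann–Whitney U comparison (exact enumeration for
   small groups) of CpG/GC content between up-regulated and unchanged DMR
   genes, and ChIP-qPCR percent-input normalization
   (`100 × 2^((Ct_input − log2(1/f)) − Ct_IP)`, shown relative to 0 h).

## Worked example

The numbered scripts under `analysis/` run the study in order; each is a
thin driver over the library. For example:

```bash
python analysis/03_call_dmrs.py
```

prints (seed 1, default configuration):

```
probes: 1020  planted DMRs: 10  calls: 10
sensitivity 1.00  FDR 0.00  direction correct 1.00
dmr_call_id chrom  start   end  direction position_class  tss_distance  window_cpg_count
     call00  chr1   6200  6850 hypo_in_DC     intergenic         -2475                16
     call01  chr1   8700  9450 hypo_in_DC       proximal           125                15
     ...
```

Every planted DMR is recovered with the correct direction
(hypomethylated in DC) and no false calls; position classes (proximal
promoter / intragenic / intergenic) and CpG/GC content are annotated from
a 500-bp window around the central probe. `analysis/04_epityper_validation.py`
then quantifies the same regions by simulated mass spectrometry:

```
concordant regions: 16 / 16 (100.0%)
state          DC     MAC
call00     0.0386  0.8939
...
ctrl00     0.8490  0.8476
```

i.e. called DMRs show low DC / high MAC methylation ratios while
array-negative controls stay equal — the two assays agree on every region
detected by both. `analysis/05_report.py` classifies DMR CpG kinetics
(99 % correct, onset error < 1 h at measurement noise sd 0.02) and finds,
as expected under the null, no association between expression response and
local CpG content (Mann–Whitney P = 0.135).

Equivalent programmatic entry point:

```python
from mirrormeth import PipelineConfig, run_pipeline
out = run_pipeline(PipelineConfig(seed=1))
print(out["summary"])
```

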