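#!/usr/bin/env python
"""Generate the synthetic genome and three-state methylome time course.

Builds the toy promoter genome (2 x 100 kb, 20 genes laid out in
tandem-gene cassettes) and plants 10 actively demethylated regions:
methylated in monocytes (MO) and macrophages (MAC), decaying to low
methylation in dendritic cells (DC) with early (18-42 h) or late (> 51 h)
onsets.  Writes the genome FASTA, TSS BED, ground-truth DMR BED and a
per-CpG methylation time-course table.

Large per-CpG tables go to scratch/; small summaries to results/.
"""

from pathlib import Path

import pandas as pd

from mirrormeth import PipelineConfig, generate_genome, plant_methylome, sample_timecourse
from mirrormeth.methylome import write_bed
from mirrormeth.pipeline import derive_seeds

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = PipelineConfig(seed=1)
    seeds = derive_seeds(cfg.seed, 12)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    genome = generate_genome(cfg.genome, seed=seeds[0])
    methylome = plant_methylome(genome, cfg.methylome, seed=seeds[1])

    genome.to_fasta(SCRATCH / "genome.fa")
    write_bed(genome.tss_bed(), SCRATCH / "tss.bed")
    write_bed(methylome.dmr_bed(), RESULTS / "dmr_truth.bed")
    tc = sample_timecourse(methylome, sorted(cfg.report.timepoints_h))
    tc.to_csv(SCRATCH / "methylation_timecourse.tsv", sep="\t", index=False)

    by_class = pd.Series([r.position_class for r in methylome.registry]).value_counts()
    print(f"genome: {len(genome.genes)} genes, {methylome.n_cpg} CpGs")
    print(f"planted DMRs: {len(methylome.registry)} "
          f"({', '.join(f'{k}={v}' for k, v in by_class.items())})")
    print(f"onset classes: "
          f"{pd.Series([r.onset_class for r in methylome.registry]).value_counts().to_dict()}")
    print(f"wrote {RESULTS / 'dmr_truth.bed'} and scratch tables under {SCRATCH}")


if __name__ == "__main__":
    main()
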