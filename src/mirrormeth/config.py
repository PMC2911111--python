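"""Configuration objects for the simulation pipeline.

Every stage of the pipeline is parameterised through one of the dataclasses
below; :class:`PipelineConfig` bundles them together with a single master
seed, from which all per-stage random streams are derived deterministically
(``numpy.random.SeedSequence`` spawning).  A config can round-trip through
YAML so that a run is fully described by one plain-text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class GenomeConfig:
    """Parameters of the toy promoter genome.

    The genome is laid out in tandem-gene "cassettes" so that every DMR
    position class (proximal promoter, intragenic, intergenic) has slots
    that are covered by the promoter tiling windows of some gene.
    """

    n_chromosomes: int = 2
    chrom_length: int = 100_000
    n_genes: int = 20
    #: background CpG dinucleotide density per bp (outside special regions)
    background_cpg_density: float = 0.01
    #: CpG density inside intermediate-class promoter windows
    intermediate_cpg_density: float = 0.04
    #: CpG density inside candidate DMR slots
    candidate_cpg_density: float = 0.03
    #: probability that a promoter is of intermediate (vs low) CpG class
    intermediate_class_prob: float = 0.5
    #: length of candidate DMR slots (bp)
    dmr_length: int = 600
    gc_content: float = 0.42


@dataclass
class MethylomeConfig:
    n_dmrs: int = 10
    #: fraction of planted DMRs in each position class
    dmr_position_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # proximal, intragenic, intergenic
    #: fraction of DMRs with early demethylation onset
    early_fraction: float = 0.5
    early_onset_range: tuple[float, float] = (18.0, 42.0)
    late_onset_range: tuple[float, float] = (55.0, 90.0)
    #: per-CpG onset jitter inside a DMR (h)
    onset_jitter_h: float = 2.0
    #: logistic steepness of the demethylation curve (1/h)
    steepness: float = 0.35
    #: MO baseline of DMR CpGs drawn uniformly from this range
    dmr_methylated_range: tuple[float, float] = (0.85, 0.95)
    #: DC terminal fraction of DMR CpGs drawn uniformly from this range
    dmr_demethylated_range: tuple[float, float] = (0.02, 0.08)
    #: background (non-island) baseline range
    background_methylated_range: tuple[float, float] = (0.80, 0.95)
    #: unmethylated island baseline range
    island_unmethylated_range: tuple[float, float] = (0.02, 0.08)
    #: sd of the truncated-Gaussian state-offset noise between cell states
    state_noise_sd: float = 0.02
    #: hard no-de-novo tolerance: no state may exceed MO(0) by more than this
    de_novo_epsilon: float = 0.01
    #: "methylated" / "demethylated" report thresholds on population fractions
    methylated_threshold: float = 0.8
    demethylated_threshold: float = 0.2


@dataclass
class McipConfig:
    mean_fragment_len: int = 375
    sd_fragment_len: int = 50
    min_fragment_len: int = 100
    #: mean fragments per bp of genome (per cell state, per replicate)
    coverage: float = 40.0
    #: logistic midpoint of the affinity model (methylated CpGs per fragment)
    affinity_midpoint: float = 3.5
    affinity_slope: float = 1.2
    #: probability of a +/-1 salt-step assignment error (each direction)
    step_noise_p: float = 0.05
    #: per-molecule co-methylation correlation (0 = independent CpGs)
    comethylation_rho: float = 0.0


@dataclass
class ArrayConfig:
    probe_spacing: int = 100
    probe_length: int = 50
    window_upstream: int = 4000
    window_downstream: int = 1000
    background_intensity: float = 5.0
    gain: float = 1.0
    #: sd of multiplicative lognormal intensity noise (natural-log scale)
    intensity_log_sd: float = 0.15
    #: multiplicative dye bias applied to the DC channel before normalization
    dye_bias_dc: float = 1.15
    intensity_floor: float = 1e-3
    filter_low_q: float = 0.001
    filter_high_q: float = 0.999
    score_threshold: float = 0.6
    min_probes: int = 3
    n_replicates: int = 2
    #: window for DMR CpG/GC annotation (bp, centred on the central probe)
    annotation_window: int = 500


@dataclass
class EpityperConfig:
    amplicon_target_len: int = 450
    amplicon_len_bounds: tuple[int, int] = (200, 600)
    detection_window_da: tuple[float, float] = (1500.0, 7000.0)
    mass_resolution_da: float = 0.5
    peak_noise_sd: float = 0.10
    #: minimal |MAC - DC| ratio difference counted as a real difference
    delta_min: float = 0.1
    n_control_regions: int = 6


@dataclass
class ReportConfig:
    #: sampling grid dense enough that every modelled onset has a time point
    #: inside its logistic transition (width ~ 1/steepness)
    timepoints_h: tuple[float, ...] = (0, 6, 18, 30, 42, 51, 66, 78, 96, 120, 168)
    kinetics_min_delta: float = 0.2
    kinetics_noise_sd: float = 0.02
    early_late_boundary_h: float = 46.5
    fc_threshold: float = 2.0
    expression_n_donors: int = 3
    expression_percentile: float = 75.0
    expression_percentile_target: float = 100.0


@dataclass
class PipelineConfig:
    seed: int = 1
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)
    mcip: McipConfig = field(default_factory=McipConfig)
    array: ArrayConfig = field(default_factory=ArrayConfig)
    epityper: EpityperConfig = field(default_factory=EpityperConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            seed=int(raw.get("seed", 1)),
            genome=_load(GenomeConfig, raw.get("genome")),
            methylome=_load(MethylomeConfig, raw.get("methylome")),
            mcip=_load(McipConfig, raw.get("mcip")),
            array=_load(ArrayConfig, raw.get("array")),
            epityper=_load(EpityperConfig, raw.get("epityper")),
            report=_load(ReportConfig, raw.get("report")),
        )


def _load(cls, block):
    if not block:
        return cls()
    kwargs = {}
    for name, f in cls.__dataclass_fields__.items():
        if name in block:
            v = block[name]
            kwargs[name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)
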