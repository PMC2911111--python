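"""Synthetic promoter-array genome.

Generates a small multi-chromosome genome whose gene layout mimics the
promoter universe of a custom tiling array: every gene carries a strand-aware
promoter window (default -4,000..+1,000 bp around the TSS) that the probe
designer tiles.  Genes are laid out in tandem-gene *cassettes* so that three
kinds of candidate DMR slots exist and are all covered by some promoter
window:

* ``proximal``   - centred on a TSS (|distance| <= 1 kb),
* ``intergenic`` - in the upstream window of a gene, outside any gene body,
* ``intragenic`` - deep inside one gene's body, tiled by the *neighbouring*
  gene's upstream window.

The base sequence is built CpG-free and CpG dinucleotides are then planted
at a controlled per-region density, so the CpG landscape (background vs
intermediate-CpG promoter islands vs candidate slots) is exact by
construction.  Three MCIp control regions are reserved on the first
chromosome: a CpG-free ``empty`` region, a densely CpG'd imprinted-like
``snrpn`` region and a densely CpG'd fully-methylated ``dense`` region.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import GenomeConfig

# cassette geometry (offsets within a forward-oriented cassette)
CASSETTE_LEN = 19_000
HEAD_MARGIN = 4_000
_GENE_A = dict(tss=5_000, body=(5_000, 15_000))
_GENE_B = dict(tss=17_000, body=(17_000, 19_000))
_SLOTS = dict(
    proximal=(4_700, 5_300),
    intergenic=(2_200, 2_800),
    intragenic=(13_700, 14_300),
)
# control regions in the head margin of the first chromosome
_CONTROLS = dict(dense=(200, 1_200), empty=(1_500, 2_500), snrpn=(2_800, 3_800))

POSITION_CLASSES = ("proximal", "intragenic", "intergenic")


class GenomePackingError(ValueError):
    """Requested gene count does not fit the chromosome layout."""


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str  # "+" or "-"
    body_start: int
    body_end: int
    cpg_class: str  # "low" | "intermediate"

    def promoter_window(self, upstream: int = 4000, downstream: int = 1000) -> tuple[int, int]:
        """Strand-aware promoter window in genome coordinates (half-open)."""
        if self.strand == "+":
            return self.tss - upstream, self.tss + downstream + 1
        return self.tss - downstream, self.tss + upstream + 1


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    kind: str  # "candidate" | "empty" | "snrpn" | "dense"
    position_class: str | None = None


@dataclass
class GenomeModel:
    chrom_names: list[str]
    sequences: dict[str, str]
    genes: list[Gene]
    background_cpg_density: float
    candidate_regions: list[Region]
    control_regions: dict[str, Region]
    config: GenomeConfig = field(default_factory=GenomeConfig)

    def __post_init__(self):
        self._cpg_cache: dict[str, np.ndarray] = {}

    def cpg_positions(self, chrom: str) -> np.ndarray:
        """0-based positions of the C of every CG dinucleotide."""
        if chrom not in self._cpg_cache:
            seq = self.sequences[chrom]
            self._cpg_cache[chrom] = np.array(
                [m.start() for m in re.finditer("CG", seq)], dtype=np.int64
            )
        return self._cpg_cache[chrom]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.sequences[c]), id=c, description="")
            for c in self.chrom_names
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def sequences_from_fasta(cls, path: str | Path) -> dict[str, str]:
        return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}

    def tss_bed(self) -> pd.DataFrame:
        """TSS records as a BED6 frame (one-bp intervals at the TSS)."""
        return pd.DataFrame(
            {
                "chrom": [g.chrom for g in self.genes],
                "start": [g.tss for g in self.genes],
                "end": [g.tss + 1 for g in self.genes],
                "name": [g.gene_id for g in self.genes],
                "score": 0,
                "strand": [g.strand for g in self.genes],
            }
        )


def _cpg_free_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Random base sequence (as a byte array) containing no CG dinucleotide."""
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    seq = bases[idx]
    # demote every G that follows a C; cannot create a new CG
    cg = np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))
    seq[cg + 1] = b"A"
    return seq


def _plant_cpgs(rng: np.random.Generator, seq: np.ndarray, start: int, end: int, density: float) -> None:
    """Overwrite positions in [start, end) with CG pairs at the given density."""
    n = int(round(density * (end - start)))
    if n == 0:
        return
    grid = np.arange(start, end - 1, 2)
    if n > len(grid):
        raise ValueError(f"CpG density {density} too high for interval length {end - start}")
    pos = rng.choice(grid, size=n, replace=False)
    seq[pos] = b"C"
    seq[pos + 1] = b"G"


def _subtract(iv: tuple[int, int], blockers: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pieces of half-open interval iv not covered by any blocker."""
    pieces = [iv]
    for bs, be in blockers:
        nxt = []
        for s, e in pieces:
            if be <= s or bs >= e:
                nxt.append((s, e))
                continue
            if s < bs:
                nxt.append((s, bs))
            if be < e:
                nxt.append((be, e))
        pieces = nxt
    return [p for p in pieces if p[1] > p[0]]


def generate_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Generate the synthetic genome.

    Deterministic given ``(config, seed)``.  Raises
    :class:`GenomePackingError` when ``n_genes`` does not fit into the
    cassette layout of the requested chromosomes.
    """
    cfg = config or GenomeConfig()
    if cfg.chrom_length <= 0 or cfg.n_chromosomes <= 0:
        raise ValueError("chromosome dimensions must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    per_chrom_capacity = max(0, (cfg.chrom_length - HEAD_MARGIN) // CASSETTE_LEN)
    n_cassettes_needed = (cfg.n_genes + 1) // 2
    if n_cassettes_needed > per_chrom_capacity * cfg.n_chromosomes:
        raise GenomePackingError(
            f"cannot place {cfg.n_genes} genes: {per_chrom_capacity} cassettes per "
            f"chromosome x {cfg.n_chromosomes} chromosomes (2 genes per cassette)"
        )

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    candidates: list[Region] = []
    controls: dict[str, Region] = {}

    # assign cassettes round-robin-free: fill chromosomes in order
    cassette_slots = []  # (chrom_idx, cassette_start)
    for ci in range(cfg.n_chromosomes):
        for k in range(per_chrom_capacity):
            cassette_slots.append((ci, HEAD_MARGIN + k * CASSETTE_LEN))
    cassette_slots = cassette_slots[:n_cassettes_needed]

    genes_left = cfg.n_genes
    gene_idx = 0
    per_chrom_plan: dict[int, list] = {i: [] for i in range(cfg.n_chromosomes)}
    for ci, cs in cassette_slots:
        orientation = "+" if rng.random() < 0.5 else "-"
        per_chrom_plan[ci].append((cs, orientation, min(2, genes_left)))
        genes_left -= min(2, genes_left)

    for ci, chrom in enumerate(chrom_names):
        seq = _cpg_free_sequence(rng, cfg.chrom_length, cfg.gc_content)
        plant_jobs: list[tuple[int, int, float]] = []  # high-priority first
        occupied: list[tuple[int, int]] = []

        if ci == 0:
            for kind, (s, e) in _CONTROLS.items():
                controls[kind] = Region(chrom, s, e, kind)
                density = 0.0 if kind == "empty" else cfg.intermediate_cpg_density
                plant_jobs.append((s, e, density))
                occupied.append((s, e))

        windows: list[tuple[int, int, str]] = []  # (start, end, cpg_class)
        for cs, orientation, n_in in per_chrom_plan[ci]:
            L = CASSETTE_LEN

            def _map_iv(a, b):
                if orientation == "+":
                    return cs + a, cs + b
                return cs + L - b, cs + L - a

            def _map_tss(t):
                return cs + t if orientation == "+" else cs + L - t - 1

            gene_defs = [_GENE_A, _GENE_B][:n_in]
            for gd in gene_defs:
                tss = _map_tss(gd["tss"])
                bs, be = _map_iv(*gd["body"])
                cls = "intermediate" if rng.random() < cfg.intermediate_class_prob else "low"
                gene = Gene(f"gene{gene_idx:03d}", chrom, tss, orientation, bs, be, cls)
                genes.append(gene)
                gene_idx += 1
                windows.append((*gene.promoter_window(), cls))
            if n_in == 2:  # slots only meaningful with the full cassette
                for pcls, iv in _SLOTS.items():
                    s, e = _map_iv(*iv)
                    candidates.append(Region(chrom, s, e, "candidate", pcls))
                    plant_jobs.append((s, e, cfg.candidate_cpg_density))
                    occupied.append((s, e))

        # intermediate promoter windows, clipped against controls/candidates
        for ws, we, cls in windows:
            if cls != "intermediate":
                continue
            for s, e in _subtract((max(0, ws), min(cfg.chrom_length, we)), occupied):
                plant_jobs.append((s, e, cfg.intermediate_cpg_density))
        all_special = occupied + [
            (max(0, ws), min(cfg.chrom_length, we))
            for ws, we, cls in windows
            if cls == "intermediate"
        ]
        # background everywhere else
        for s, e in _subtract((0, cfg.chrom_length), sorted(all_special)):
            plant_jobs.append((s, e, cfg.background_cpg_density))

        for s, e, density in plant_jobs:
            _plant_cpgs(rng, seq, s, e, density)
        sequences[chrom] = seq.tobytes().decode("ascii")

    return GenomeModel(
        chrom_names=chrom_names,
        sequences=sequences,
        genes=genes,
        background_cpg_density=cfg.background_cpg_density,
        candidate_regions=candidates,
        control_regions=controls,
        config=cfg,
    )


def count_cpgs(seq: str) -> int:
    """Number of CG dinucleotide occurrences (overlap-free by nature)."""
    return seq.count("CG")


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)
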