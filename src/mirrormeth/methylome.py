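"""Three-state methylome time course with planted active-demethylation events.

Population methylation fractions are modelled per CpG for three cell states:
monocytes (MO), macrophages (MAC) and dendritic cells (DC).  MO and MAC are
constant in time; the DC lineage follows a monotone, zero-anchored logistic
decay with a per-CpG onset (midpoint) and steepness.  Planted DMR CpGs are
methylated in MO and MAC and decay to a low terminal fraction in DC; all
other CpGs are flat up to a small truncated-Gaussian between-state offset
that never exceeds the MO baseline by more than ``de_novo_epsilon`` - no CpG
ever gains methylation, mirroring a purely active-demethylation system.

DMR onsets fall in two kinetic classes: *early* (18-42 h) and *late*
(> 51 h), with a deliberate gap between the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MethylomeConfig
from .genome import GenomeModel, Region

STATES = ("MO", "MAC", "DC")


class DMRPlacementError(ValueError):
    """More DMRs requested than candidate slots available."""


def decay_curve(t, initial, final, onset, steepness):
    """Zero-anchored logistic decay.

    Equals ``initial`` exactly at t = 0, decays monotonically towards
    ``final`` with midpoint at ``t = onset`` (up to the anchoring term,
    negligible at default steepness).  All arguments broadcast.
    """
    t = np.asarray(t, dtype=float)
    initial = np.asarray(initial, dtype=float)
    final = np.asarray(final, dtype=float)
    onset = np.asarray(onset, dtype=float)
    steepness = np.asarray(steepness, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-steepness * (t - onset)))
    c = 1.0 / (1.0 + np.exp(steepness * onset))
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (sig - c) / (1.0 - c)
    g = np.where(np.isfinite(g), g, 0.0)
    return initial - (initial - final) * g


@dataclass(frozen=True)
class DMRRecord:
    dmr_id: str
    chrom: str
    start: int
    end: int
    position_class: str
    onset_class: str  # "early" | "late"
    direction: str  # always "hypo_in_DC"
    onset_h: float
    member_index: tuple[int, ...]  # row indices into the CpG table


@dataclass
class MethylomeState:
    """Per-CpG population methylation fractions for MO / MAC / DC."""

    chrom: np.ndarray  # per-CpG chromosome name (object)
    pos: np.ndarray  # per-CpG position (C of the CG)
    baseline: np.ndarray  # MO fraction, constant in time
    mac_offset: np.ndarray
    dc_initial: np.ndarray
    dc_final: np.ndarray
    onset: np.ndarray
    steepness: np.ndarray
    imprinted: np.ndarray  # bool; per-molecule allelic all-or-none methylation
    dmr_member: np.ndarray  # int index of owning DMR, -1 otherwise
    registry: list[DMRRecord]
    config: MethylomeConfig = field(default_factory=MethylomeConfig)

    @property
    def n_cpg(self) -> int:
        return len(self.pos)

    def fractions(self, state: str, times) -> np.ndarray:
        """(n_cpg, n_times) population fractions for one cell state."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if state == "MO":
            out = np.repeat(self.baseline[:, None], len(times), axis=1)
        elif state == "MAC":
            mac = np.clip(self.baseline + self.mac_offset, 0.0, 1.0)
            out = np.repeat(mac[:, None], len(times), axis=1)
        elif state == "DC":
            out = decay_curve(
                times[None, :],
                self.dc_initial[:, None],
                self.dc_final[:, None],
                self.onset[:, None],
                self.steepness[:, None],
            )
        else:
            raise ValueError(f"unknown state {state!r}")
        return np.clip(out, 0.0, 1.0)

    def cpg_indices_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        mask = (self.chrom == chrom) & (self.pos >= start) & (self.pos < end)
        return np.flatnonzero(mask)

    def dmr_bed(self) -> pd.DataFrame:
        """Planted-DMR registry as BED6 (direction in the name field)."""
        recs = self.registry
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in recs],
                "start": [r.start for r in recs],
                "end": [r.end for r in recs],
                "name": [
                    f"{r.dmr_id}|{r.direction}|{r.position_class}|{r.onset_class}"
                    for r in recs
                ],
                "score": [round(r.onset_h, 3) for r in recs],
                "strand": ".",
            }
        )


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return df


def plant_methylome(
    genome: GenomeModel,
    config: MethylomeConfig | None = None,
    n_dmrs: int | None = None,
    dmr_position_mix: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> MethylomeState:
    """Assign baselines, plant DMRs, and parameterise DC decay kinetics."""
    cfg = config or MethylomeConfig()
    if n_dmrs is None:
        n_dmrs = cfg.n_dmrs
    mix = dmr_position_mix or cfg.dmr_position_mix
    if n_dmrs < 0:
        raise ValueError("n_dmrs must be >= 0")
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError("dmr_position_mix must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))

    chrom_arr, pos_arr = [], []
    for chrom in genome.chrom_names:
        p = genome.cpg_positions(chrom)
        chrom_arr.append(np.full(len(p), chrom, dtype=object))
        pos_arr.append(p)
    chrom_ = np.concatenate(chrom_arr) if chrom_arr else np.array([], dtype=object)
    pos_ = np.concatenate(pos_arr) if pos_arr else np.array([], dtype=np.int64)
    n = len(pos_)

    lo, hi = cfg.background_methylated_range
    baseline = rng.uniform(lo, hi, size=n)
    imprinted = np.zeros(n, dtype=bool)

    def _members(region: Region) -> np.ndarray:
        m = (chrom_ == region.chrom) & (pos_ >= region.start) & (pos_ < region.end)
        return np.flatnonzero(m)

    # unmethylated islands: intermediate-class promoter windows
    island = np.zeros(n, dtype=bool)
    for gene in genome.genes:
        if gene.cpg_class != "intermediate":
            continue
        ws, we = gene.promoter_window()
        island |= (chrom_ == gene.chrom) & (pos_ >= ws) & (pos_ < we)
    # candidate slots and controls keep/override their own baselines
    special = np.zeros(n, dtype=bool)
    for region in genome.candidate_regions:
        special[_members(region)] = True
    ilo, ihi = cfg.island_unmethylated_range
    idx_island = np.flatnonzero(island & ~special)
    baseline[idx_island] = rng.uniform(ilo, ihi, size=len(idx_island))

    for kind, region in genome.control_regions.items():
        midx = _members(region)
        if kind == "snrpn":
            baseline[midx] = 0.5
            imprinted[midx] = True
        elif kind == "dense":
            baseline[midx] = 1.0

    # between-state offsets: truncated Gaussian, never above +de_novo tolerance
    eps = cfg.de_novo_epsilon
    mac_offset = np.clip(rng.normal(0.0, cfg.state_noise_sd, size=n), -3 * cfg.state_noise_sd, 0.99 * eps)
    dc_offset = np.clip(rng.normal(0.0, cfg.state_noise_sd, size=n), -3 * cfg.state_noise_sd, 0.99 * eps)
    mac_offset[imprinted] = 0.0
    dc_offset[imprinted] = 0.0

    # flat DC kinetics by default
    dc_level = np.clip(baseline + dc_offset, 0.0, 1.0)
    dc_initial = dc_level.copy()
    dc_final = dc_level.copy()
    onset = np.full(n, 1.0)
    steepness = np.full(n, cfg.steepness)
    dmr_member = np.full(n, -1, dtype=np.int64)

    # select DMRs from candidate slots per position class
    counts = _apportion(n_dmrs, mix)
    registry: list[DMRRecord] = []
    selected: list[Region] = []
    for pcls, want in zip(("proximal", "intragenic", "intergenic"), counts):
        avail = [r for r in genome.candidate_regions if r.position_class == pcls]
        if want > len(avail):
            raise DMRPlacementError(
                f"{want} {pcls} DMRs requested but only {len(avail)} candidate slots exist"
            )
        pick = rng.choice(len(avail), size=want, replace=False)
        selected.extend(avail[i] for i in sorted(pick))

    mlo, mhi = cfg.dmr_methylated_range
    dlo, dhi = cfg.dmr_demethylated_range
    elo, ehi = cfg.early_onset_range
    llo, lhi = cfg.late_onset_range
    for k, region in enumerate(selected):
        midx = _members(region)
        onset_class = "early" if rng.random() < cfg.early_fraction else "late"
        o = rng.uniform(elo, ehi) if onset_class == "early" else rng.uniform(llo, lhi)
        jitter = rng.uniform(-cfg.onset_jitter_h, cfg.onset_jitter_h, size=len(midx))
        cpg_onsets = np.clip(o + jitter, *((elo, ehi) if onset_class == "early" else (llo, lhi)))
        baseline[midx] = rng.uniform(mlo, mhi, size=len(midx))
        mac_offset[midx] = np.clip(
            rng.normal(0.0, cfg.state_noise_sd, size=len(midx)), -3 * cfg.state_noise_sd, 0.99 * eps
        )
        dc_initial[midx] = baseline[midx]
        dc_final[midx] = rng.uniform(dlo, dhi, size=len(midx))
        onset[midx] = cpg_onsets
        dmr_member[midx] = k
        registry.append(
            DMRRecord(
                dmr_id=f"dmr{k:02d}",
                chrom=region.chrom,
                start=region.start,
                end=region.end,
                position_class=region.position_class,
                onset_class=onset_class,
                direction="hypo_in_DC",
                onset_h=float(o),
                member_index=tuple(int(i) for i in midx),
            )
        )

    return MethylomeState(
        chrom=chrom_,
        pos=pos_,
        baseline=baseline,
        mac_offset=mac_offset,
        dc_initial=dc_initial,
        dc_final=dc_final,
        onset=onset,
        steepness=steepness,
        imprinted=imprinted,
        dmr_member=dmr_member,
        registry=registry,
        config=cfg,
    )


def _apportion(total: int, mix) -> list[int]:
    """Largest-remainder rounding of total into len(mix) integer parts."""
    raw = [total * m for m in mix]
    base = [int(np.floor(x)) for x in raw]
    rem = total - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)])  # largest remainder first
    for i in order[:rem]:
        base[i] += 1
    return base


def sample_timecourse(
    methylome: MethylomeState,
    times,
    states=STATES,
) -> pd.DataFrame:
    """Tidy per-CpG fraction table at the requested times.

    Columns: chrom, pos, state, time_h, fraction.
    """
    times = list(times)
    if any(t < 0 for t in times):
        raise ValueError("times must be non-negative")
    if sorted(times) != times:
        raise ValueError("times must be sorted")
    frames = []
    for state in states:
        f = methylome.fractions(state, times)
        for j, t in enumerate(times):
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": methylome.chrom,
                        "pos": methylome.pos,
                        "state": state,
                        "time_h": float(t),
                        "fraction": f[:, j],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
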