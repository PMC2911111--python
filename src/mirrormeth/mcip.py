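"""Methyl-CpG immunoprecipitation (MCIp) fractionation simulator.

Sonicated fragments of the synthetic genome carry per-molecule methylation
sampled from the population fractions of a chosen cell state and time point.
Each fragment is assigned to one of the seven NaCl elution steps
(250, 300, 350, 400, 450, 500, 1000 mM) according to a stochastic affinity
model: the expected step index is logistic in the fragment's methylated-CpG
load (more methylated CpGs bind the MBD-Fc matrix more tightly and elute at
higher salt), with a small probability of a +/-1-step assignment error.
Low-salt steps (250-350 mM) are pooled as the unmethylated "CpG" pool,
high-salt steps (400-1000 mM) as the methylated "mCpG" pool.

Fragments over the imprinted-like control region are methylated allele-wise
(all-or-none per molecule), so at a 50% population fraction they split
between the two pools instead of piling up at intermediate loads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import McipConfig
from .genome import GenomeModel, Region
from .methylome import MethylomeState

SALT_STEPS_MM = np.array([250, 300, 350, 400, 450, 500, 1000])
#: highest step index belonging to the unmethylated (CpG) pool: 350 mM
CPG_POOL_MAX_STEP = 2

FRAGMENT_COLUMNS = ["chrom", "start", "end", "state", "time_h", "n_cpg", "n_mcpg"]


def fragment_genome(
    genome: GenomeModel,
    methylome: MethylomeState,
    state: str,
    time_h: float,
    config: McipConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sonicate the genome and sample per-molecule methylation.

    Fragment starts are uniform over each chromosome, lengths are
    truncated-Gaussian around the configured mean.  Each CpG covered by a
    fragment is drawn as an independent Bernoulli with that CpG's population
    fraction; CpGs flagged as imprinted share a single per-fragment allele
    draw (optionally all CpGs do, at co-methylation correlation rho = 1).
    """
    cfg = config or McipConfig()
    if genome.total_length == 0:
        raise ValueError("empty genome")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    frames = []
    for chrom in genome.chrom_names:
        length = len(genome.sequences[chrom])
        n_frag = int(round(cfg.coverage * length / cfg.mean_fragment_len))
        starts = rng.integers(0, length, size=n_frag)
        lens = np.maximum(
            cfg.min_fragment_len,
            np.round(rng.normal(cfg.mean_fragment_len, cfg.sd_fragment_len, size=n_frag)),
        ).astype(np.int64)
        ends = np.minimum(starts + lens, length)

        cpg_pos = genome.cpg_positions(chrom)
        in_chrom = np.flatnonzero(methylome.chrom == chrom)
        # methylome rows are ordered by position within a chromosome
        frac = methylome.fractions(state, [time_h])[in_chrom, 0]
        imprinted = methylome.imprinted[in_chrom]

        lo = np.searchsorted(cpg_pos, starts, side="left")
        hi = np.searchsorted(cpg_pos, ends, side="left")
        counts = hi - lo
        total = int(counts.sum())
        # flattened (fragment, cpg) index pairs
        frag_of_pair = np.repeat(np.arange(n_frag), counts)
        offsets = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) if total else np.array([], dtype=np.int64)

        indep = rng.random(total) < frac[offsets]
        allele = rng.random(n_frag)[frag_of_pair] < frac[offsets]
        if cfg.comethylation_rho >= 1.0:
            correlated = np.ones(total, dtype=bool)
        elif cfg.comethylation_rho <= 0.0:
            correlated = imprinted[offsets]
        else:
            correlated = imprinted[offsets] | (
                rng.random(n_frag)[frag_of_pair] < cfg.comethylation_rho
            )
        meth = np.where(correlated, allele, indep)
        n_mcpg = np.zeros(n_frag, dtype=np.int64)
        if total:
            np.add.at(n_mcpg, frag_of_pair, meth.astype(np.int64))

        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "state": state,
                    "time_h": float(time_h),
                    "n_cpg": counts,
                    "n_mcpg": n_mcpg,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def expected_step_index(n_mcpg, config: McipConfig | None = None) -> np.ndarray:
    """Expected elution-step index (0..6), logistic in methylated-CpG load."""
    cfg = config or McipConfig()
    m = np.asarray(n_mcpg, dtype=float)
    return (len(SALT_STEPS_MM) - 1) / (1.0 + np.exp(-cfg.affinity_slope * (m - cfg.affinity_midpoint)))


def elute_fragments(
    fragments: pd.DataFrame,
    config: McipConfig | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign every fragment a salt elution step (adds a ``salt_mM`` column)."""
    cfg = config or McipConfig()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    idx = np.rint(expected_step_index(fragments["n_mcpg"].values, cfg)).astype(np.int64)
    u = rng.random(len(fragments))
    idx = idx + np.where(u < cfg.step_noise_p, -1, 0) + np.where(u > 1 - cfg.step_noise_p, 1, 0)
    idx = np.clip(idx, 0, len(SALT_STEPS_MM) - 1)
    out = fragments.copy()
    out["salt_mM"] = SALT_STEPS_MM[idx]
    return out


def elute_fragment(n_mcpg: int, config: McipConfig | None = None, rng: np.random.Generator | None = None) -> int:
    """Salt step (mM) for a single fragment with the given methylated load."""
    df = pd.DataFrame({"n_cpg": [max(n_mcpg, 0)], "n_mcpg": [n_mcpg]})
    if rng is None:
        rng = np.random.default_rng(0)
    return int(elute_fragments(df, config, rng=rng)["salt_mM"].iloc[0])


@dataclass
class ElutionProfile:
    fragments: pd.DataFrame  # with salt_mM

    @property
    def step_counts(self) -> pd.Series:
        counts = self.fragments["salt_mM"].value_counts()
        return counts.reindex(SALT_STEPS_MM, fill_value=0)


@dataclass
class PoolAssignment:
    """Fragments labelled CpG (unmethylated) or mCpG (methylated) pool."""

    fragments: pd.DataFrame  # with salt_mM and pool columns

    def pool(self, label: str) -> pd.DataFrame:
        return self.fragments[self.fragments["pool"] == label]

    def interval_abundance(self, chrom: str, starts, ends, pool: str, state: str | None = None) -> np.ndarray:
        """Number of pool fragments overlapping each query interval."""
        df = self.fragments
        mask = (df["chrom"] == chrom) & (df["pool"] == pool)
        if state is not None:
            mask &= df["state"] == state
        sub = df[mask]
        fs = np.sort(sub["start"].values)
        fe = np.sort(sub["end"].values)
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        return np.searchsorted(fs, ends, side="left") - np.searchsorted(fe, starts, side="right")


def pool_fractions(profile: ElutionProfile | pd.DataFrame) -> PoolAssignment:
    """Pool low-salt steps (<=350 mM) as CpG, high-salt (>=400 mM) as mCpG."""
    df = profile.fragments if isinstance(profile, ElutionProfile) else profile
    if "salt_mM" not in df.columns or df["salt_mM"].isna().any():
        raise ValueError("every fragment needs a salt-step assignment")
    out = df.copy()
    out["pool"] = np.where(
        out["salt_mM"] <= SALT_STEPS_MM[CPG_POOL_MAX_STEP], "CpG", "mCpG"
    )
    return PoolAssignment(out)


def control_recovery(pools: PoolAssignment, control_regions: dict[str, Region]) -> pd.DataFrame:
    """Per-control fraction of overlapping fragments in each pool.

    A fragment counts towards a control region when its midpoint lies
    inside the region.  Raises if a control region is outside every
    fragment's chromosome.
    """
    df = pools.fragments
    rows = []
    chroms = set(df["chrom"])
    for kind, region in control_regions.items():
        if region.chrom not in chroms:
            raise ValueError(f"control region {kind} on {region.chrom} not covered by any fragment")
        mid = (df["start"] + df["end"]) // 2
        sel = df[(df["chrom"] == region.chrom) & (mid >= region.start) & (mid < region.end)]
        n = len(sel)
        n_cpg_pool = int((sel["pool"] == "CpG").sum())
        rows.append(
            {
                "control": kind,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "n_fragments": n,
                "frac_cpg_pool": n_cpg_pool / n if n else float("nan"),
                "frac_mcpg_pool": (n - n_cpg_pool) / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def run_mcip(
    genome: GenomeModel,
    methylome: MethylomeState,
    state: str,
    time_h: float,
    config: McipConfig | None = None,
    seed: int = 0,
) -> PoolAssignment:
    """Fragment, elute and pool one cell state at one time point."""
    frags = fragment_genome(genome, methylome, state, time_h, config, seed=seed)
    frags = elute_fragments(frags, config, seed=seed)
    return pool_fractions(frags)
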