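"""Two-channel promoter tiling array simulation and mirror-image DMR calling.

The dual reciprocal design co-hybridizes, for each biological replicate, the
DC and MAC *unmethylated* (CpG) pools on one array and the two *methylated*
(mCpG) pools on a second array.  A genuine methylation difference shows up
with opposite sign in the two comparisons: a region demethylated in DC is
enriched in DC's CpG pool and depleted in DC's mCpG pool.  The per-probe DMR
statistic therefore subtracts the two log10 ratios,

    s = log10(DC_CpG / MAC_CpG) - log10(DC_mCpG / MAC_mCpG),

which cancels any non-reciprocal shift (copy number, probe affinity) and
doubles a reciprocal one.  Positive s indicates hypomethylation in DC.

DMRs are called as maximal runs of >= ``min_probes`` consecutive unflagged
probes with |s| >= threshold and consistent sign, present with the same sign
in both biological replicates (interval intersection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ArrayConfig
from .genome import GenomeModel, count_cpgs, gc_fraction
from .mcip import PoolAssignment

CHANNELS = ["i_dc_cpg", "i_mac_cpg", "i_dc_mcpg", "i_mac_mcpg"]


def design_probes(genome: GenomeModel, config: ArrayConfig | None = None) -> pd.DataFrame:
    """Tile every promoter window (strand-aware) at fixed probe spacing.

    Probe start positions run from -upstream to +downstream relative to the
    TSS (inclusive at both ends) in transcription direction; windows
    extending past chromosome ends are clipped.  Deterministic.
    """
    cfg = config or ArrayConfig()
    if cfg.probe_spacing <= 0 or cfg.probe_length <= 0:
        raise ValueError("probe spacing and length must be positive")
    rows = []
    for w, gene in enumerate(genome.genes):
        length = len(genome.sequences[gene.chrom])
        if gene.strand == "+":
            first = gene.tss - cfg.window_upstream
            last = gene.tss + cfg.window_downstream
        else:
            first = gene.tss - cfg.window_downstream
            last = gene.tss + cfg.window_upstream
        starts = np.arange(first, last + 1, cfg.probe_spacing)
        starts = starts[(starts >= 0) & (starts + cfg.probe_length <= length)]
        seq = genome.sequences[gene.chrom]
        for i, s in enumerate(starts):
            rows.append(
                {
                    "probe_id": f"{gene.gene_id}_p{i:03d}",
                    "chrom": gene.chrom,
                    "start": int(s),
                    "end": int(s + cfg.probe_length),
                    "gene_id": gene.gene_id,
                    "window": w,
                    "idx_in_window": i,
                    "gc": gc_fraction(seq[s : s + cfg.probe_length]),
                }
            )
    return pd.DataFrame(rows)


def _hybridize_channel(abundance: np.ndarray, cfg: ArrayConfig, rng: np.random.Generator, dye_bias: float) -> np.ndarray:
    mean = cfg.gain * abundance + cfg.background_intensity
    noise = np.exp(rng.normal(0.0, cfg.intensity_log_sd, size=len(abundance)))
    return np.maximum(dye_bias * mean * noise, cfg.intensity_floor)


def simulate_hybridization(
    pool_sets: list[dict[str, PoolAssignment]],
    probes: pd.DataFrame,
    config: ArrayConfig | None = None,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Raw two-channel signals for each replicate.

    ``pool_sets`` holds, per biological replicate, the MCIp pool assignment
    of each cell state (keys "DC" and "MAC").  Expected intensity is linear
    in the number of pool fragments overlapping the probe plus an additive
    background, with multiplicative lognormal noise and a configurable dye
    bias on the DC channel.
    """
    cfg = config or ArrayConfig()
    master = np.random.SeedSequence([seed, 505])
    children = master.spawn(len(pool_sets))
    signals = []
    for pools, child in zip(pool_sets, children):
        rng = np.random.default_rng(child)
        sig = probes[["probe_id", "chrom", "start", "end", "window", "idx_in_window"]].copy()
        for col in CHANNELS:
            sig[col] = 0.0
        for chrom, grp in probes.groupby("chrom", sort=False):
            starts, ends = grp["start"].values, grp["end"].values
            for state in ("DC", "MAC"):
                for pool in ("CpG", "mCpG"):
                    ab = pools[state].interval_abundance(chrom, starts, ends, pool)
                    col = f"i_{state.lower()}_{'mcpg' if pool == 'mCpG' else 'cpg'}"
                    bias = cfg.dye_bias_dc if state == "DC" else 1.0
                    sig.loc[grp.index, col] = _hybridize_channel(ab.astype(float), cfg, rng, bias)
        signals.append(sig)
    return signals


def normalize_channels(signal: pd.DataFrame, config: ArrayConfig | None = None) -> pd.DataFrame:
    """Linear (single-factor) normalization per hybridization.

    Within each hybridization (CpG-pool array: DC vs MAC channels; mCpG-pool
    array likewise) every channel is scaled so the two channel medians are
    equal (to their geometric mean).  Monotone, rank-preserving.
    """
    out = signal.copy()
    for a, b in (("i_dc_cpg", "i_mac_cpg"), ("i_dc_mcpg", "i_mac_mcpg")):
        ma, mb = out[a].median(), out[b].median()
        if ma <= 0 or mb <= 0:
            raise ValueError("channel medians must be positive for normalization")
        target = np.sqrt(ma * mb)
        out[a] = out[a] * (target / ma)
        out[b] = out[b] * (target / mb)
    return out


def filter_probes(signal: pd.DataFrame, low_q: float = 0.001, high_q: float = 0.999) -> pd.Series:
    """Flag probes with extreme intensity in any channel.

    A probe is flagged when any of its four channel intensities lies below
    the ``low_q`` or above the ``high_q`` empirical quantile of that channel.
    """
    if not (0 <= low_q < high_q <= 1):
        raise ValueError("need 0 <= low_q < high_q <= 1")
    flag = pd.Series(False, index=signal.index)
    for col in CHANNELS:
        lo = signal[col].quantile(low_q)
        hi = signal[col].quantile(high_q)
        if low_q > 0:
            flag |= signal[col] < lo
        if high_q < 1:
            flag |= signal[col] > hi
    return flag


def mirror_score(signal: pd.DataFrame, config: ArrayConfig | None = None, flags: pd.Series | None = None) -> pd.DataFrame:
    """Per-probe subtracted log10-ratio score.

    Adds ``r_cpg``, ``r_mcpg`` and ``score`` columns; flagged probes get NaN
    scores.  Intensities are clipped at a small positive floor before the
    log so the score is always finite for unflagged probes.
    """
    cfg = config or ArrayConfig()
    out = signal.copy()
    floor = cfg.intensity_floor
    i = {c: np.maximum(out[c].values, floor) for c in CHANNELS}
    out["r_cpg"] = np.log10(i["i_dc_cpg"] / i["i_mac_cpg"])
    out["r_mcpg"] = np.log10(i["i_dc_mcpg"] / i["i_mac_mcpg"])
    out["score"] = out["r_cpg"] - out["r_mcpg"]
    if flags is None and "flag" in out.columns:
        flags = out["flag"]
    if flags is not None:
        out["flag"] = flags.values
        out.loc[out["flag"], ["r_cpg", "r_mcpg", "score"]] = np.nan
    return out


def _candidate_runs(sig: pd.DataFrame, threshold: float, min_probes: int) -> list[dict]:
    """Per-replicate maximal same-sign super-threshold probe runs."""
    cands = []
    for w, grp in sig.groupby("window", sort=False):
        grp = grp.sort_values("idx_in_window")
        s = grp["score"].values
        sign = np.where(np.isnan(s), 0, np.sign(s) * (np.abs(s) >= threshold))
        i = 0
        n = len(sign)
        while i < n:
            if sign[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < n and sign[j + 1] == sign[i]:
                j += 1
            if j - i + 1 >= min_probes:
                cands.append(
                    {
                        "chrom": grp["chrom"].iloc[0],
                        "start": int(grp["start"].iloc[i]),
                        "end": int(grp["end"].iloc[j]),
                        "sign": int(sign[i]),
                        "window": w,
                    }
                )
            i = j + 1
    return _merge_runs(cands)


def _merge_runs(cands: list[dict]) -> list[dict]:
    """Merge overlapping same-sign candidate intervals (window overlap guard)."""
    out: list[dict] = []
    for c in sorted(cands, key=lambda d: (d["chrom"], d["sign"], d["start"])):
        if out and out[-1]["chrom"] == c["chrom"] and out[-1]["sign"] == c["sign"] and c["start"] <= out[-1]["end"]:
            out[-1]["end"] = max(out[-1]["end"], c["end"])
        else:
            out.append(dict(c))
    return out


def call_dmrs(
    signals: list[pd.DataFrame],
    config: ArrayConfig | None = None,
    threshold: float | None = None,
    min_probes: int | None = None,
) -> pd.DataFrame:
    """Replicate-consistent DMR calls from scored signals.

    Requires exactly matching probe sets across replicates.  A call is the
    intersection of overlapping same-sign candidate runs from the two
    replicates, kept when the intersection still spans >= ``min_probes``
    probes passing the threshold in *both* replicates.
    """
    cfg = config or ArrayConfig()
    thr = cfg.score_threshold if threshold is None else threshold
    mp = cfg.min_probes if min_probes is None else min_probes
    if thr <= 0 or mp < 1:
        raise ValueError("threshold must be > 0 and min_probes >= 1")
    if len(signals) < 2:
        raise ValueError("two biological replicates are required")
    ref = signals[0]["probe_id"].values
    for s in signals[1:]:
        if len(s) != len(ref) or not (s["probe_id"].values == ref).all():
            raise ValueError("replicate probe sets are mismatched")

    runs = [_candidate_runs(s, thr, mp) for s in signals[:2]]
    calls = []
    k = 0
    for c1 in runs[0]:
        for c2 in runs[1]:
            if c1["chrom"] != c2["chrom"] or c1["sign"] != c2["sign"]:
                continue
            start, end = max(c1["start"], c2["start"]), min(c1["end"], c2["end"])
            if start > end:
                continue
            sig1, sig2 = signals[0], signals[1]
            inmask = (
                (sig1["chrom"] == c1["chrom"])
                & (sig1["start"] >= start)
                & (sig1["start"] <= end)
            )
            s1 = sig1.loc[inmask, "score"].values
            s2 = sig2.loc[inmask.values, "score"].values
            ok = (
                np.isfinite(s1)
                & np.isfinite(s2)
                & (np.abs(s1) >= thr)
                & (np.abs(s2) >= thr)
                & (np.sign(s1) == c1["sign"])
                & (np.sign(s2) == c1["sign"])
            )
            n_support = int(ok.sum())
            if n_support < mp:
                continue
            sup = sig1.loc[inmask].iloc[np.flatnonzero(ok)]
            central = sup.iloc[len(sup) // 2]
            calls.append(
                {
                    "dmr_call_id": f"call{k:02d}",
                    "chrom": c1["chrom"],
                    "start": int(sup["start"].min()),
                    "end": int(sup["end"].max()),
                    "direction": "hypo_in_DC" if c1["sign"] > 0 else "hypo_in_MAC",
                    "mean_score": float(np.mean((s1[ok] + s2[ok]) / 2.0)),
                    "n_probes": n_support,
                    "replicate_support": "both",
                    "central_probe_start": int(central["start"]),
                    "central_probe_end": int(central["end"]),
                }
            )
            k += 1
    df = pd.DataFrame(
        calls,
        columns=[
            "dmr_call_id", "chrom", "start", "end", "direction", "mean_score",
            "n_probes", "replicate_support", "central_probe_start", "central_probe_end",
        ],
    )
    # dedupe identical intervals that can arise from merged runs
    if len(df):
        df = df.drop_duplicates(subset=["chrom", "start", "end", "direction"]).reset_index(drop=True)
        df["dmr_call_id"] = [f"call{i:02d}" for i in range(len(df))]
    return df


def annotate_dmrs(calls: pd.DataFrame, genome: GenomeModel, config: ArrayConfig | None = None) -> pd.DataFrame:
    """Positional and CpG/GC-content annotation of DMR calls.

    Signed TSS distance is measured from the central probe midpoint to the
    nearest TSS, strand-aware (negative = upstream of the gene).  Position
    class: proximal promoter when |distance| <= 1,000 bp; otherwise
    intragenic when the midpoint lies inside any gene body; else intergenic.
    CpG count and GC fraction are computed over a 500-bp window centred on
    the central probe.
    """
    cfg = config or ArrayConfig()
    half = cfg.annotation_window // 2
    ann_cols = [
        "nearest_gene", "tss_distance", "position_class",
        "window_cpg_count", "window_gc_fraction",
    ]
    if len(calls) == 0:
        out = calls.copy()
        for c in ann_cols:
            out[c] = pd.Series(dtype=object)
        return out
    rows = []
    for _, call in calls.iterrows():
        center = (int(call["central_probe_start"]) + int(call["central_probe_end"])) // 2
        chrom = call["chrom"]
        genes = [g for g in genome.genes if g.chrom == chrom]
        if not genes:
            dist, nearest, pclass = np.nan, "", "unknown"
        else:
            dists = []
            for g in genes:
                d = center - g.tss if g.strand == "+" else g.tss - center
                dists.append(d)
            i = int(np.argmin([abs(d) for d in dists]))
            dist, nearest = dists[i], genes[i].gene_id
            if abs(dist) <= 1000:
                pclass = "proximal"
            elif any(g.body_start <= center < g.body_end for g in genes):
                pclass = "intragenic"
            else:
                pclass = "intergenic"
        seq = genome.sequences[chrom]
        ws, we = max(0, center - half), min(len(seq), center + half)
        window = seq[ws:we]
        row = dict(call)
        row.update(
            {
                "nearest_gene": nearest,
                "tss_distance": dist,
                "position_class": pclass,
                "window_cpg_count": count_cpgs(window),
                "window_gc_fraction": gc_fraction(window),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_calls(calls: pd.DataFrame, registry) -> dict:
    """Sensitivity / false-discovery proportion against the planted registry.

    A planted DMR is recovered when some call overlaps it; a call is a false
    positive when it overlaps no planted DMR.  Direction correctness is
    evaluated on true-positive calls only.
    """
    n_planted = len(registry)
    recovered = 0
    for rec in registry:
        hit = (
            (calls["chrom"] == rec.chrom)
            & (calls["start"] < rec.end)
            & (calls["end"] > rec.start)
        )
        if hit.any():
            recovered += 1
    tp_calls = 0
    fp_calls = 0
    dir_ok = 0
    for _, call in calls.iterrows():
        match = None
        for rec in registry:
            if call["chrom"] == rec.chrom and call["start"] < rec.end and call["end"] > rec.start:
                match = rec
                break
        if match is None:
            fp_calls += 1
        else:
            tp_calls += 1
            if call["direction"] == match.direction:
                dir_ok += 1
    n_calls = len(calls)
    return {
        "n_planted": n_planted,
        "n_calls": n_calls,
        "n_recovered": recovered,
        "sensitivity": recovered / n_planted if n_planted else float("nan"),
        "fdr": fp_calls / n_calls if n_calls else 0.0,
        "direction_correct": dir_ok / tp_calls if tp_calls else float("nan"),
    }
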