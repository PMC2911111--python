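"""Synthetic expression time course, normalization, and DMR association.

Expression arrays are simulated per gene x sample (state, time, donor),
normalized so every sample's 75th percentile equals a common constant, and
baseline-transformed to the median of the monocyte samples per gene.  The
association analysis splits DMR-associated genes into up-regulated
(max DC fold change vs the monocyte baseline >= fc_threshold) vs unchanged
and compares the CpG counts (and GC fractions) of the two groups' DMR
windows with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ReportConfig
from .stats import mwu_test


def simulate_expression(
    gene_ids: list[str],
    dmr_gene_ids: list[str],
    config: ReportConfig | None = None,
    seed: int = 0,
    up_fraction: float = 0.5,
    up_fold: float = 4.0,
) -> pd.DataFrame:
    """Long expression table: gene_id, state, time_h, donor, value.

    About half of the DMR-associated genes are up-regulated along the DC
    time course (sigmoid induction to ``up_fold``); all other genes are
    flat up to lognormal noise.  MO exists at t = 0 only; MAC and DC span
    the configured time grid.
    """
    cfg = config or ReportConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 707]))
    base = dict(zip(gene_ids, rng.lognormal(5.0, 1.0, size=len(gene_ids))))
    dmr_set = list(dict.fromkeys(dmr_gene_ids))
    n_up = int(round(up_fraction * len(dmr_set)))
    up_genes = set(rng.choice(dmr_set, size=n_up, replace=False)) if n_up else set()

    rows = []
    donors = range(1, cfg.expression_n_donors + 1)
    samples = [("MO", 0.0)] + [("DC", t) for t in cfg.timepoints_h] + [("MAC", t) for t in (0.0, 168.0)]
    for gene in gene_ids:
        for state, t in samples:
            if gene in up_genes and state == "DC":
                fold = 1.0 + (up_fold - 1.0) / (1.0 + np.exp(-0.15 * (t - 40.0)))
            else:
                fold = 1.0
            for donor in donors:
                noise = np.exp(rng.normal(0.0, 0.15))
                rows.append(
                    {
                        "gene_id": gene,
                        "state": state,
                        "time_h": float(t),
                        "donor": donor,
                        "value": base[gene] * fold * noise,
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["up_genes"] = sorted(up_genes)
    return df


def normalize_expression(expr: pd.DataFrame, config: ReportConfig | None = None) -> pd.DataFrame:
    """Percentile normalization then per-gene monocyte-baseline transform.

    Every sample (state, time, donor) is scaled so its 75th percentile
    equals the configured target; every gene is then divided by the median
    of its monocyte (MO) samples, so MO sits at 1 by construction.
    """
    cfg = config or ReportConfig()
    out = expr.copy()
    q = cfg.expression_percentile / 100.0
    for _, idx in out.groupby(["state", "time_h", "donor"]).groups.items():
        vals = out.loc[idx, "value"]
        scale = cfg.expression_percentile_target / np.quantile(vals, q)
        out.loc[idx, "value"] = vals * scale
    mo_median = out[out["state"] == "MO"].groupby("gene_id")["value"].median()
    out["value"] = out["value"] / out["gene_id"].map(mo_median)
    out.attrs.update(expr.attrs)
    return out


def expression_association(
    dmr_genes: pd.DataFrame,
    expr_norm: pd.DataFrame,
    fc_threshold: float | None = None,
    config: ReportConfig | None = None,
) -> dict:
    """Mann-Whitney comparison of DMR CpG/GC content by expression response.

    ``dmr_genes`` needs columns gene_id, window_cpg_count,
    window_gc_fraction (one row per DMR).  Genes whose maximal mean DC
    expression across the time course reaches ``fc_threshold`` (relative to
    the monocyte baseline of 1) form the up-regulated group.
    """
    cfg = config or ReportConfig()
    fc = cfg.fc_threshold if fc_threshold is None else fc_threshold
    dc = expr_norm[expr_norm["state"] == "DC"]
    max_fc = dc.groupby(["gene_id", "time_h"])["value"].mean().groupby("gene_id").max()

    up, unchanged = [], []
    for _, row in dmr_genes.iterrows():
        g = row["gene_id"]
        if g not in max_fc.index:
            continue
        (up if max_fc[g] >= fc else unchanged).append(row)
    report = {
        "n_up": len(up),
        "n_unchanged": len(unchanged),
        "fc_threshold": fc,
        "up_genes": sorted({r["gene_id"] for r in up}),
    }
    if not up or not unchanged:
        report["skipped"] = True
        report["p_cpg"] = report["p_gc"] = float("nan")
        return report
    up_df, un_df = pd.DataFrame(up), pd.DataFrame(unchanged)
    u_cpg, p_cpg = mwu_test(up_df["window_cpg_count"], un_df["window_cpg_count"])
    u_gc, p_gc = mwu_test(up_df["window_gc_fraction"], un_df["window_gc_fraction"])
    report.update({"skipped": False, "u_cpg": u_cpg, "p_cpg": p_cpg, "u_gc": u_gc, "p_gc": p_gc})
    return report
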