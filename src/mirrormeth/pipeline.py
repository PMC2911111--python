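"""End-to-end orchestration of the simulation and analysis pipeline.

Runs synthetic genome/methylome generation, MCIp fractionation of the DC
and MAC day-7 samples (two biological replicates), the dual reciprocal
hybridizations with mirror-statistic DMR calling and annotation, EpiTYPER
validation with concordance assessment, kinetics classification, the
expression association and the ChIP-enrichment arithmetic, and collects one
summary report.  Identical config + seed reproduces every number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import arrays, epityper, expression, kinetics, mcip, methylome as meth, stats
from .config import PipelineConfig
from .genome import generate_genome

DAY7_H = 168.0


def derive_seeds(seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds (< 2**31) from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig | None = None, outdir: str | Path | None = None) -> dict:
    cfg = config or PipelineConfig()
    seeds = derive_seeds(cfg.seed, 12)
    out: dict = {"seed": cfg.seed}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - abort with stage context
            raise StageError(name, e) from e

    genome = _stage("generate_genome", lambda: generate_genome(cfg.genome, seed=seeds[0]))
    mstate = _stage("plant_methylome", lambda: meth.plant_methylome(genome, cfg.methylome, seed=seeds[1]))
    probes = _stage("design_probes", lambda: arrays.design_probes(genome, cfg.array))

    def _mcip():
        pool_sets = []
        rep_seeds = derive_seeds(seeds[2], 2 * cfg.array.n_replicates)
        for r in range(cfg.array.n_replicates):
            pools = {}
            for i, state in enumerate(("DC", "MAC")):
                pools[state] = mcip.run_mcip(
                    genome, mstate, state, DAY7_H, cfg.mcip, seed=rep_seeds[2 * r + i]
                )
            pool_sets.append(pools)
        return pool_sets

    pool_sets = _stage("mcip", _mcip)
    recovery = _stage(
        "control_recovery",
        lambda: mcip.control_recovery(pool_sets[0]["MAC"], genome.control_regions),
    )

    def _score():
        raw = arrays.simulate_hybridization(pool_sets, probes, cfg.array, seed=seeds[3])
        scored = []
        for sig in raw:
            norm = arrays.normalize_channels(sig, cfg.array)
            flags = arrays.filter_probes(norm, cfg.array.filter_low_q, cfg.array.filter_high_q)
            scored.append(arrays.mirror_score(norm, cfg.array, flags=flags))
        return scored

    scored = _stage("hybridization", _score)
    calls = _stage("call_dmrs", lambda: arrays.call_dmrs(scored, cfg.array))
    annotated = _stage("annotate_dmrs", lambda: arrays.annotate_dmrs(calls, genome, cfg.array))
    recovery_stats = arrays.evaluate_calls(annotated, mstate.registry)

    # --- EpiTYPER validation ------------------------------------------------
    def _validate():
        regions = annotated[["dmr_call_id", "chrom", "start", "end", "direction"]].copy()
        regions = regions.rename(columns={"dmr_call_id": "region_id"})
        selected = {r.dmr_id: (r.chrom, r.start, r.end) for r in mstate.registry}
        taken = set()
        for rec in mstate.registry:
            taken.add((rec.chrom, rec.start, rec.end))
        controls = []
        for i, cand in enumerate(c for c in genome.candidate_regions
                                 if (c.chrom, c.start, c.end) not in taken):
            if i >= cfg.epityper.n_control_regions:
                break
            controls.append({"region_id": f"ctrl{i:02d}", "chrom": cand.chrom,
                             "start": cand.start, "end": cand.end, "direction": None})
        regions = pd.concat([regions, pd.DataFrame(controls)], ignore_index=True)
        ms_seeds = derive_seeds(seeds[4], 2)
        units = pd.concat(
            [
                epityper.measure_regions(regions, genome, mstate, "DC", DAY7_H, cfg.epityper, seed=ms_seeds[0]),
                epityper.measure_regions(regions, genome, mstate, "MAC", DAY7_H, cfg.epityper, seed=ms_seeds[1]),
            ],
            ignore_index=True,
        )
        means = epityper.region_means(units)
        conc = epityper.assess_concordance(
            regions[regions["direction"].notna()].rename(columns={"region_id": "region_id"}),
            means,
            cfg.epityper.delta_min,
        )
        return regions, units, means, conc

    regions, units, ms_means, concordance = _stage("epityper", _validate)

    # --- kinetics classification -------------------------------------------
    def _kinetics():
        times = np.asarray(cfg.report.timepoints_h, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([seeds[5], 808]))
        dmr_idx = np.flatnonzero(mstate.dmr_member >= 0)
        flat_idx = np.flatnonzero((mstate.dmr_member < 0) & ~mstate.imprinted)
        flat_idx = rng.choice(flat_idx, size=min(100, len(flat_idx)), replace=False)
        idx = np.concatenate([dmr_idx, flat_idx])
        truth = np.array(
            [
                mstate.registry[m].onset_class if m >= 0 else "none"
                for m in mstate.dmr_member[idx]
            ]
        )
        f = mstate.fractions("DC", times)[idx]
        obs = np.clip(f + rng.normal(0.0, cfg.report.kinetics_noise_sd, size=f.shape), 0.0, 1.0)
        fits = kinetics.fit_demethylation_kinetics(times, obs, config=cfg.report, cpg_ids=idx)
        fits["true_class"] = truth
        fits["true_onset"] = np.where(mstate.dmr_member[idx] >= 0, mstate.onset[idx], np.nan)
        acc = float((fits["kinetic_class"] == fits["true_class"]).mean())
        err = (fits["onset_est"] - fits["true_onset"]).abs()
        onset_mae = float(err[fits["true_class"] != "none"].mean())
        return fits, acc, onset_mae

    kin_fits, kin_acc, kin_mae = _stage("kinetics", _kinetics)

    # --- expression association --------------------------------------------
    def _expression():
        gene_ids = [g.gene_id for g in genome.genes]
        dmr_genes = annotated[["nearest_gene", "window_cpg_count", "window_gc_fraction"]].rename(
            columns={"nearest_gene": "gene_id"}
        )
        expr = expression.simulate_expression(gene_ids, list(dmr_genes["gene_id"]), cfg.report, seed=seeds[6])
        norm = expression.normalize_expression(expr, cfg.report)
        assoc = expression.expression_association(dmr_genes, norm, config=cfg.report)
        return norm, assoc

    expr_norm, association = _stage("expression", _expression)

    # --- ChIP-enrichment demonstration table -------------------------------
    def _chip():
        times = [0.0, 18.0, 42.0, 66.0, DAY7_H]
        ct_input = 25.0
        rows = []
        ref_pi = None
        for t in times:
            # activating-mark recovery rises with demethylation progress
            pi_true = 0.5 * (1.0 + 4.0 / (1.0 + np.exp(-0.1 * (t - 40.0))))
            ct_ip = ct_input - np.log2(1.0 / 0.05) - np.log2(pi_true / 100.0)
            res = stats.chip_enrichment(ct_ip, ct_input, 0.05, ref_pi)
            if t == 0.0:
                ref_pi = res["percent_input"]
                res = stats.chip_enrichment(ct_ip, ct_input, 0.05, ref_pi)
            rows.append({"time_h": t, "ct_ip": ct_ip, "ct_input": ct_input, **res})
        return pd.DataFrame(rows)

    chip_table = _stage("chip_enrichment", _chip)

    summary = {
        "n_genes": len(genome.genes),
        "n_cpgs": mstate.n_cpg,
        "n_probes": len(probes),
        "n_planted_dmrs": len(mstate.registry),
        **{f"dmr_{k}": v for k, v in recovery_stats.items() if k != "n_planted"},
        "concordance_pct": concordance["percent_concordant"],
        "concordance_n_regions": concordance["n_regions"],
        "kinetics_accuracy": kin_acc,
        "kinetics_onset_mae_h": kin_mae,
        "assoc_p_cpg": association.get("p_cpg"),
        "assoc_p_gc": association.get("p_gc"),
        "empty_control_cpg_pool_frac": float(
            recovery.loc[recovery["control"] == "empty", "frac_cpg_pool"].iloc[0]
        ),
        "dense_control_mcpg_pool_frac": float(
            recovery.loc[recovery["control"] == "dense", "frac_mcpg_pool"].iloc[0]
        ),
        "snrpn_control_cpg_pool_frac": float(
            recovery.loc[recovery["control"] == "snrpn", "frac_cpg_pool"].iloc[0]
        ),
    }
    out.update(
        {
            "genome": genome,
            "methylome": mstate,
            "probes": probes,
            "signals": scored,
            "calls": annotated,
            "recovery": recovery,
            "units": units,
            "ms_means": ms_means,
            "concordance": concordance,
            "kinetics": kin_fits,
            "association": association,
            "chip": chip_table,
            "summary": summary,
        }
    )

    if outdir is not None:
        _write_outputs(out, cfg, Path(outdir))
    return out


def _write_outputs(out: dict, cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    genome = out["genome"]
    mstate = out["methylome"]
    genome.to_fasta(outdir / "genome.fa")
    meth.write_bed(genome.tss_bed(), outdir / "tss.bed")
    meth.write_bed(mstate.dmr_bed(), outdir / "dmr_truth.bed")
    tc = meth.sample_timecourse(mstate, sorted(cfg.report.timepoints_h))
    tc.to_csv(outdir / "methylation.tsv", sep="\t", index=False)
    out["probes"].to_csv(outdir / "probes.tsv", sep="\t", index=False)
    for i, sig in enumerate(out["signals"]):
        sig.to_csv(outdir / f"signal_rep{i + 1}.tsv", sep="\t", index=False)
    out["calls"].to_csv(outdir / "dmr_calls.tsv", sep="\t", index=False)
    if len(out["calls"]):
        bed = out["calls"][["chrom", "start", "end", "dmr_call_id", "mean_score", "direction"]].copy()
        bed.columns = ["chrom", "start", "end", "name", "score", "strand"]
        bed["strand"] = "."
        bed["name"] = out["calls"]["dmr_call_id"] + "|" + out["calls"]["direction"]
        meth.write_bed(bed, outdir / "dmr_calls.bed")
    out["recovery"].to_csv(outdir / "control_recovery.tsv", sep="\t", index=False)
    out["units"].to_csv(outdir / "epityper_units.tsv", sep="\t", index=False)
    out["kinetics"].to_csv(outdir / "kinetics.tsv", sep="\t", index=False)
    out["chip"].to_csv(outdir / "chip_enrichment.tsv", sep="\t", index=False)
    summary = pd.Series(out["summary"], name="value")
    summary.to_csv(outdir / "summary.tsv", sep="\t", header=True)
    lines = ["mirrormeth pipeline summary", f"seed: {cfg.seed}", ""]
    s = out["summary"]
    lines += [
        f"planted DMRs: {s['n_planted_dmrs']}  calls: {s['dmr_n_calls']}",
        f"sensitivity: {s['dmr_sensitivity']:.3f}  FDR: {s['dmr_fdr']:.3f}  "
        f"direction correct: {s['dmr_direction_correct']:.3f}",
        f"array/MS concordance: {s['concordance_pct']:.1f}% over {s['concordance_n_regions']} regions",
        f"kinetics class accuracy: {s['kinetics_accuracy']:.3f}  onset MAE: {s['kinetics_onset_mae_h']:.2f} h",
        f"association P (CpG count): {s['assoc_p_cpg']}  (GC): {s['assoc_p_gc']}",
    ]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
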