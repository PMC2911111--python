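"""MCIp fractionation: fragment sampling, elution model, pooling, controls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mirrormeth import mcip
from mirrormeth.config import McipConfig
from mirrormeth.mcip import (
    SALT_STEPS_MM,
    elute_fragments,
    expected_step_index,
    fragment_genome,
    pool_fractions,
)


def _frags(n_mcpg_values):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": 0,
            "end": 100,
            "n_cpg": [max(m, 1) for m in n_mcpg_values],
            "n_mcpg": list(n_mcpg_values),
        }
    )


def test_fragment_count_matches_coverage(genome, methylome):
    cfg = McipConfig(coverage=10.0)
    counts = [
        len(fragment_genome(genome, methylome, "MO", 0.0, cfg, seed=s)) for s in range(3)
    ]
    expected = cfg.coverage * genome.total_length / cfg.mean_fragment_len
    for n in counts:
        assert abs(n - expected) / expected < 0.05


def test_fragment_methylation_respects_site_bounds(genome, methylome):
    frags = fragment_genome(genome, methylome, "MAC", 168.0, McipConfig(coverage=5.0), seed=2)
    assert ((frags["n_mcpg"] >= 0) & (frags["n_mcpg"] <= frags["n_cpg"])).all()
    # no CpGs covered -> nothing to methylate
    assert (frags.loc[frags["n_cpg"] == 0, "n_mcpg"] == 0).all()


def test_fully_methylated_region_gives_degenerate_draws(genome, methylome):
    """CpGs at population fraction 1.0 are methylated on every molecule."""
    dense = genome.control_regions["dense"]
    frags = fragment_genome(genome, methylome, "MO", 0.0, McipConfig(coverage=20.0), seed=3)
    inside = frags[
        (frags["chrom"] == dense.chrom)
        & (frags["start"] >= dense.start)
        & (frags["end"] <= dense.end)
        & (frags["n_cpg"] > 0)
    ]
    assert len(inside) > 10
    assert (inside["n_mcpg"] == inside["n_cpg"]).all()


def test_unmethylated_fragments_land_in_cpg_pool():
    pools = pool_fractions(elute_fragments(_frags([0] * 10_000), seed=1))
    frac = (pools.fragments["pool"] == "CpG").mean()
    assert frac >= 0.95


def test_dense_fragments_elute_at_high_salt():
    eluted = elute_fragments(_frags([10] * 10_000), seed=1)
    assert (eluted["salt_mM"] == 1000).mean() >= 0.9


def test_mean_elution_step_is_monotone():
    means = []
    for m in (0, 1, 3, 10):
        eluted = elute_fragments(_frags([m] * 10_000), seed=m + 1)
        means.append(eluted["salt_mM"].mean())
    assert all(a <= b for a, b in zip(means, means[1:]))
    # and the deterministic expected index is monotone too
    idx = expected_step_index(np.array([0, 1, 3, 10]))
    assert (np.diff(idx) > 0).all()


def test_pooling_boundary_and_conservation():
    df = _frags([0, 5])
    df["salt_mM"] = [350, 400]
    pools = pool_fractions(df)
    assert list(pools.fragments["pool"]) == ["CpG", "mCpG"]
    n = 100
    pools2 = pool_fractions(elute_fragments(_frags([3] * n), seed=0))
    assert len(pools2.pool("CpG")) + len(pools2.pool("mCpG")) == n


def test_empty_input_gives_two_empty_pools():
    df = _frags([])
    df["salt_mM"] = pd.Series(dtype=int)
    pools = pool_fractions(df)
    assert len(pools.pool("CpG")) == 0 and len(pools.pool("mCpG")) == 0


def test_missing_salt_assignment_raises():
    with pytest.raises(ValueError):
        pool_fractions(_frags([1, 2]))


def test_imprinted_allelic_split_is_balanced():
    """All-or-none molecules at 50% population methylation split both pools."""
    rng = np.random.default_rng(11)
    m = np.where(rng.random(10_000) < 0.5, 15, 0)
    pools = pool_fractions(elute_fragments(_frags(m), seed=4))
    frac_cpg = (pools.fragments["pool"] == "CpG").mean()
    assert 0.3 <= frac_cpg <= 0.7


def test_control_recovery_report(pipeline_result):
    rec = pipeline_result["recovery"].set_index("control")
    assert rec.loc["empty", "frac_cpg_pool"] >= 0.95
    assert rec.loc["dense", "frac_mcpg_pool"] >= 0.90
    assert 0.3 <= rec.loc["snrpn", "frac_cpg_pool"] <= 0.7


def test_control_recovery_missing_chrom_raises():
    from mirrormeth.genome import Region

    pools = pool_fractions(elute_fragments(_frags([0, 1]), seed=0))
    with pytest.raises(ValueError):
        mcip.control_recovery(pools, {"empty": Region("chrUn", 0, 100, "empty")})


def test_methylation_abundance_separation(genome, methylome):
    """Region methylation rank is preserved in the mCpG-pool share.

    Evaluated over a region set spanning the methylation range (demethylated
    DMRs in DC day 7, unmethylated islands, the hemi-methylated and fully
    methylated controls, methylated candidate slots in MO): rank correlation
    between population methylation and the fraction of a region's fragments
    eluting in the methylated pool.
    """
    from mirrormeth.genome import Region

    sel = {(r.chrom, r.start, r.end) for r in methylome.registry}
    cand_sel = [c for c in genome.candidate_regions if (c.chrom, c.start, c.end) in sel]
    cand_un = [c for c in genome.candidate_regions if (c.chrom, c.start, c.end) not in sel][:10]
    islands = [
        Region(g.chrom, *g.promoter_window(), "window")
        for g in genome.genes
        if g.cpg_class == "intermediate"
    ]
    controls = [genome.control_regions["dense"], genome.control_regions["snrpn"]]
    plan = [("DC", 168.0, cand_sel), ("MO", 0.0, cand_un + islands + controls)]
    meth_means, shares = [], []
    for k, (state, t, regs) in enumerate(plan):
        pools = mcip.run_mcip(genome, methylome, state, t, McipConfig(), seed=17 + k)
        for r in regs:
            idx = methylome.cpg_indices_in(r.chrom, r.start, r.end)
            if len(idx) == 0:
                continue
            n_m = float(pools.interval_abundance(r.chrom, [r.start], [r.end], "mCpG")[0])
            n_u = float(pools.interval_abundance(r.chrom, [r.start], [r.end], "CpG")[0])
            if n_m + n_u == 0:
                continue
            meth_means.append(methylome.fractions(state, [t])[idx, 0].mean())
            shares.append(n_m / (n_m + n_u))
    rho, _ = spearmanr(meth_means, shares)
    assert rho >= 0.8
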