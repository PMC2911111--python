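"""Array pipeline: probe design, normalization, mirror statistic, calling."""

import numpy as np
import pandas as pd
import pytest

from mirrormeth import arrays
from mirrormeth.config import ArrayConfig, GenomeConfig
from mirrormeth.genome import Gene, GenomeModel


def _toy_genome(strand="+", length=20_000, tss=10_000):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    gene = Gene("g0", "chr1", tss, strand, tss, min(length, tss + 3000), "low")
    if strand == "-":
        gene = Gene("g0", "chr1", tss, strand, max(0, tss - 3000), tss + 1, "low")
    return GenomeModel(
        chrom_names=["chr1"],
        sequences={"chr1": seq},
        genes=[gene],
        background_cpg_density=0.01,
        candidate_regions=[],
        control_regions={},
        config=GenomeConfig(),
    )


def test_probe_count_per_window():
    cfg = ArrayConfig(probe_spacing=200, probe_length=50)
    probes = arrays.design_probes(_toy_genome("+"), cfg)
    assert len(probes) == 26  # 5000 / 200 + 1 start positions
    assert probes["start"].min() == 10_000 - 4000
    assert probes["start"].max() == 10_000 + 1000


def test_minus_strand_window_is_mirrored():
    cfg = ArrayConfig(probe_spacing=200, probe_length=50)
    probes = arrays.design_probes(_toy_genome("-"), cfg)
    assert len(probes) == 26
    assert probes["start"].min() == 10_000 - 1000
    assert probes["start"].max() == 10_000 + 4000


def test_window_clipped_at_chromosome_edge():
    cfg = ArrayConfig(probe_spacing=200, probe_length=50)
    probes = arrays.design_probes(_toy_genome("+", length=12_000), cfg)
    assert (probes["end"] <= 12_000).all()
    assert len(probes) < 26 or probes["end"].max() <= 12_000


def _signal_frame(n=1000, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 100,
            "end": np.arange(n) * 100 + 50,
            "window": 0,
            "idx_in_window": np.arange(n),
            "i_dc_cpg": rng.lognormal(3, 0.5, n),
            "i_mac_cpg": rng.lognormal(3, 0.5, n),
            "i_dc_mcpg": rng.lognormal(3, 0.5, n),
            "i_mac_mcpg": rng.lognormal(3, 0.5, n),
        }
    )


def test_normalization_equalizes_medians_and_preserves_rank():
    sig = _signal_frame()
    sig["i_dc_cpg"] *= 2.0  # median 2x off
    norm = arrays.normalize_channels(sig)
    assert norm["i_dc_cpg"].median() == pytest.approx(norm["i_mac_cpg"].median())
    assert norm["i_dc_mcpg"].median() == pytest.approx(norm["i_mac_mcpg"].median())
    assert (
        np.argsort(norm["i_dc_cpg"].values) == np.argsort(sig["i_dc_cpg"].values)
    ).all()


def test_normalization_identity_for_balanced_channels():
    sig = _signal_frame()
    sig["i_mac_cpg"] = sig["i_dc_cpg"].values  # identical -> equal medians
    norm = arrays.normalize_channels(sig)
    assert np.allclose(norm["i_dc_cpg"], sig["i_dc_cpg"])


def test_filter_vacuous_bounds_flag_nothing():
    sig = _signal_frame()
    assert arrays.filter_probes(sig, 0.0, 1.0).sum() == 0


def test_filter_flags_global_extremes():
    sig = _signal_frame(n=10_000)
    imax = sig["i_dc_cpg"].idxmax()
    flags = arrays.filter_probes(sig, 0.0, 0.999)
    assert flags.loc[imax]


def test_filter_count_matches_quantile_oracle():
    sig = _signal_frame(n=1000, seed=3)
    low_q, high_q = 0.01, 0.99
    flags = arrays.filter_probes(sig, low_q, high_q)
    expected = pd.Series(False, index=sig.index)
    for col in arrays.CHANNELS:
        expected |= sig[col] < sig[col].quantile(low_q)
        expected |= sig[col] > sig[col].quantile(high_q)
    assert (flags == expected).all()


def test_mirror_score_arithmetic():
    sig = _signal_frame(n=3)
    # construct exact ratios: r_cpg = +0.5, r_mcpg = -0.5 -> s = 1.0
    sig.loc[0, ["i_dc_cpg", "i_mac_cpg", "i_dc_mcpg", "i_mac_mcpg"]] = [
        10 ** 0.5 * 100, 100, 100, 10 ** 0.5 * 100,
    ]
    # copy-number-like shift: both ratios +0.3 -> s = 0
    sig.loc[1, ["i_dc_cpg", "i_mac_cpg", "i_dc_mcpg", "i_mac_mcpg"]] = [
        10 ** 0.3 * 50, 50, 10 ** 0.3 * 80, 80,
    ]
    scored = arrays.mirror_score(sig)
    assert scored.loc[0, "score"] == pytest.approx(1.0, abs=1e-12)
    assert scored.loc[1, "score"] == pytest.approx(0.0, abs=1e-12)
    # swapping the cell labels negates the score
    swapped = sig.rename(
        columns={
            "i_dc_cpg": "i_mac_cpg", "i_mac_cpg": "i_dc_cpg",
            "i_dc_mcpg": "i_mac_mcpg", "i_mac_mcpg": "i_dc_mcpg",
        }
    )
    assert arrays.mirror_score(swapped).loc[0, "score"] == pytest.approx(-1.0, abs=1e-12)


def test_mirror_score_antisymmetry_random_probes(rng):
    sig = _signal_frame(n=5000, seed=9)
    swapped = sig.rename(
        columns={
            "i_dc_cpg": "i_mac_cpg", "i_mac_cpg": "i_dc_cpg",
            "i_dc_mcpg": "i_mac_mcpg", "i_mac_mcpg": "i_dc_mcpg",
        }
    )
    s = arrays.mirror_score(sig)["score"].values
    s_swapped = arrays.mirror_score(swapped)["score"].values
    assert np.allclose(s, -s_swapped, atol=1e-12)


def test_flagged_probe_score_is_masked():
    sig = _signal_frame(n=10)
    flags = pd.Series([True] + [False] * 9)
    scored = arrays.mirror_score(sig, flags=flags)
    assert np.isnan(scored.loc[0, "score"])
    assert np.isfinite(scored.loc[1:, "score"]).all()


def _scored(scores, window=0):
    n = len(scores)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 100,
            "end": np.arange(n) * 100 + 50,
            "window": window,
            "idx_in_window": np.arange(n),
            "score": scores,
        }
    )


def test_all_zero_scores_give_no_calls():
    sig = _scored([0.0] * 20)
    assert len(arrays.call_dmrs([sig, sig.copy()], threshold=0.6, min_probes=3)) == 0


def test_single_replicate_support_is_rejected():
    hit = _scored([0.0] * 5 + [1.0] * 4 + [0.0] * 5)
    miss = _scored([0.0] * 14)
    assert len(arrays.call_dmrs([hit, miss], threshold=0.6, min_probes=3)) == 0
    both = arrays.call_dmrs([hit, hit.copy()], threshold=0.6, min_probes=3)
    assert len(both) == 1
    assert both.loc[0, "direction"] == "hypo_in_DC"
    assert both.loc[0, "n_probes"] == 4


def test_opposite_sign_runs_do_not_intersect():
    a = _scored([0.0] * 5 + [1.0] * 4 + [0.0] * 5)
    b = _scored([0.0] * 5 + [-1.0] * 4 + [0.0] * 5)
    assert len(arrays.call_dmrs([a, b], threshold=0.6, min_probes=3)) == 0


def test_mismatched_probe_sets_raise():
    a = _scored([0.0] * 5)
    b = _scored([0.0] * 6)
    with pytest.raises(ValueError):
        arrays.call_dmrs([a, b], threshold=0.6, min_probes=3)


def test_call_direction_flips_with_sign():
    neg = _scored([0.0] * 5 + [-1.0] * 4 + [0.0] * 5)
    calls = arrays.call_dmrs([neg, neg.copy()], threshold=0.6, min_probes=3)
    assert calls.loc[0, "direction"] == "hypo_in_MAC"


def _call_row(center, chrom="chr1"):
    return pd.DataFrame(
        [
            {
                "dmr_call_id": "c0",
                "chrom": chrom,
                "start": center - 100,
                "end": center + 100,
                "direction": "hypo_in_DC",
                "mean_score": 1.0,
                "n_probes": 3,
                "replicate_support": "both",
                "central_probe_start": center - 25,
                "central_probe_end": center + 25,
            }
        ]
    )


def test_annotation_classes():
    g = _toy_genome("+")  # tss 10_000, body 10_000..13_000
    ann = arrays.annotate_dmrs(_call_row(9_500), g)
    assert ann.loc[0, "tss_distance"] == -500
    assert ann.loc[0, "position_class"] == "proximal"
    ann2 = arrays.annotate_dmrs(_call_row(13_000 - 25 * 2), g)  # ~3 kb into the body
    assert ann2.loc[0, "position_class"] == "intragenic"
    ann3 = arrays.annotate_dmrs(_call_row(2_000), g)
    assert ann3.loc[0, "position_class"] == "intergenic"


def test_annotation_window_counts_match_string_oracle(genome, rng):
    cfg = ArrayConfig()
    for _ in range(100):
        chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
        seq = genome.sequences[chrom]
        center = int(rng.integers(300, len(seq) - 300))
        ann = arrays.annotate_dmrs(_call_row(center, chrom), genome, cfg)
        window = seq[center - 250 : center + 250]
        # naive scan oracle
        n_cg = sum(1 for i in range(len(window) - 1) if window[i : i + 2] == "CG")
        n_gc = sum(1 for b in window if b in "GC")
        assert ann.loc[0, "window_cpg_count"] == n_cg
        assert ann.loc[0, "window_gc_fraction"] == pytest.approx(n_gc / len(window))


def test_tandem_cg_window_annotation():
    seq = "AT" * 5000 + "CG" * 250 + "AT" * 5000
    g = GenomeModel(
        chrom_names=["chr1"],
        sequences={"chr1": seq},
        genes=[Gene("g0", "chr1", 100, "+", 100, 200, "low")],
        background_cpg_density=0.0,
        candidate_regions=[],
        control_regions={},
    )
    center = 10_000 + 250  # middle of the CG run
    ann = arrays.annotate_dmrs(_call_row(center), g)
    assert ann.loc[0, "window_gc_fraction"] == 1.0
    assert ann.loc[0, "window_cpg_count"] == 250


def test_planted_dmr_recovery(pipeline_result):
    s = pipeline_result["summary"]
    assert s["dmr_sensitivity"] >= 0.9
    assert s["dmr_fdr"] <= 0.1
    assert s["dmr_direction_correct"] == 1.0


def test_recovered_calls_annotated_consistently(pipeline_result):
    calls = pipeline_result["calls"]
    assert (calls["replicate_support"] == "both").all()
    assert set(calls["position_class"]) <= {"proximal", "intragenic", "intergenic"}
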