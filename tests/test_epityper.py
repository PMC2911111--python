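"""EpiTYPER simulation: conversion, cleavage, masses, quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirrormeth import epityper as ep


# --- bisulfite conversion -------------------------------------------------

def test_conversion_rule_examples():
    assert ep.bisulfite_convert("ACGTCC", [True]) == "ACGTTT"
    assert ep.bisulfite_convert("ACGTCC", [False]) == "ATGTTT"
    assert ep.bisulfite_convert("AGTTAG", []) == "AGTTAG"


def test_conversion_flag_mismatch_raises():
    with pytest.raises(ValueError):
        ep.bisulfite_convert("ACGT", [True, False])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=80), st.randoms(use_true_random=False))
def test_converted_c_only_at_methylated_cpgs(seq, rnd):
    sites = ep.cpg_sites(seq)
    flags = [rnd.random() < 0.5 for _ in sites]
    conv = ep.bisulfite_convert(seq, flags)
    meth = {p for p, f in zip(sites, flags) if f}
    for i, b in enumerate(conv):
        if b == "C":
            assert i in meth
    for p in meth:
        assert conv[p] == "C"


# --- cleavage -------------------------------------------------------------

def test_t_cleavage_examples():
    assert ep.cleave("GAUCGU") == ["GAU", "CGU"]
    assert ep.cleave("GGCAGC") == ["GGCAGC"]
    assert ep.cleave("U") == ["U"]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGU", min_size=1, max_size=120))
def test_fragments_partition_transcript(transcript):
    frags = ep.cleave(transcript)
    assert "".join(frags) == transcript


def test_methylation_reads_g_vs_a_on_reverse_transcript():
    template = "ATACGATTAA"  # one CpG at index 3
    conv_m = ep.bisulfite_convert(template, [True])
    conv_u = ep.bisulfite_convert(template, [False])
    tx_m = ep.reverse_strand_transcript(conv_m)
    tx_u = ep.reverse_strand_transcript(conv_u)
    diff = [i for i, (a, b) in enumerate(zip(tx_m, tx_u)) if a != b]
    assert len(diff) == 1
    assert tx_m[diff[0]] == "G" and tx_u[diff[0]] == "A"


# --- masses ---------------------------------------------------------------

def test_mass_shift_is_g_minus_a():
    delta = ep.fragment_mass("CAGU", 1) - ep.fragment_mass("CAGU", 0)
    assert delta == pytest.approx(ep.RESIDUE_MASS["G"] - ep.RESIDUE_MASS["A"], abs=1e-12)
    assert delta == pytest.approx(16.0, abs=0.01)


def test_fragment_mass_matches_residue_sum_oracle():
    frag = "GAU"
    oracle = sum(ep.RESIDUE_MASS[b] for b in frag) + ep.TERMINAL_MASS
    assert ep.fragment_mass(frag) == pytest.approx(oracle, abs=1e-12)
    assert ep.fragment_mass(frag) == ep.fragment_mass(frag)  # deterministic


def test_empty_fragment_mass_raises():
    with pytest.raises(ValueError):
        ep.fragment_mass("")


def test_mass_additivity_over_cleavage(rng):
    for _ in range(20):
        transcript = "".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 200))))
        frags = ep.cleave(transcript)
        total = sum(ep.fragment_mass(f) for f in frags) - len(frags) * ep.TERMINAL_MASS
        oracle = sum(ep.RESIDUE_MASS[b] for b in transcript)
        assert total == pytest.approx(oracle, abs=1e-9)


def test_masses_strictly_increase_with_methylation():
    amp_masses = ep.CleavageFragment("GACGAU", 0, (0, 1)).masses()
    assert (np.diff(amp_masses) > 0).all()


# --- quantification -------------------------------------------------------

def _toy_amplicon(template, region_id="r0"):
    sites = ep.cpg_sites(template)
    amp = ep.BisulfiteAmplicon(
        region_id=region_id,
        chrom="chr1",
        start=0,
        end=len(template),
        template=template,
        cpg_positions=tuple(sites),
    )
    amp.fragments = ep.build_fragments(amp)
    return amp


def test_noiseless_single_cpg_unit_recovers_fraction():
    # long A-free stretch around the CpG keeps the fragment in the window
    template = "TTT" + "GGCAGGCCGGGCAGGC" + "TTT"
    amp = _toy_amplicon(template)
    units = ep.quantify_units(amp, np.full(len(amp.cpg_positions), 0.6), noise_sd=0.0)
    measurable = units[units["measurable"]]
    assert len(measurable) >= 1
    assert measurable["ratio"].values == pytest.approx(0.6, abs=1e-6)


def test_all_intensity_at_k0_gives_zero_ratio():
    template = "TTT" + "GGCAGGCCGGGCAGGC" + "TTT"
    amp = _toy_amplicon(template)
    units = ep.quantify_units(amp, np.zeros(len(amp.cpg_positions)), noise_sd=0.0)
    measurable = units[units["measurable"]]
    assert (measurable["ratio"] == 0.0).all()


def test_two_cpg_unit_worked_example():
    """Fractions 0.5/0.5 give peak weights (1,2,1)/4 and ratio 0.5 exactly."""
    pk = ep._poisson_binomial(np.array([0.5, 0.5]))
    assert np.allclose(pk, [0.25, 0.5, 0.25])
    ratio = (np.arange(3) * pk).sum() / (2 * pk.sum())
    assert ratio == pytest.approx(0.5, abs=1e-12)
    # no A between the CpGs -> both map into one cleavage fragment
    template = "TTT" + "GGCGGCGGG" + "TTT"
    amp = _toy_amplicon(template)
    two = [f for f in amp.fragments if f.n_cpg == 2]
    assert two, "expected a 2-CpG unit in the toy amplicon"
    units = ep.quantify_units(amp, np.full(len(amp.cpg_positions), 0.5), noise_sd=0.0)
    m2 = units[(units["n_cpg"] == 2) & units["measurable"]]
    assert len(m2) == 1
    assert m2["ratio"].values == pytest.approx(0.5, abs=1e-6)


def test_duplicate_cpg_fragments_collide_and_are_flagged():
    # two identical CpG-bearing fragments -> mass collision -> unmeasurable
    template = "TACGAT" * 2 + "TT"
    amp = _toy_amplicon(template)
    units = ep.quantify_units(amp, np.full(len(amp.cpg_positions), 0.5), noise_sd=0.0)
    assert not units["measurable"].any()
    assert units["ratio"].isna().all()


def test_out_of_window_units_are_flagged():
    template = "TTTAACGAATTT"  # CpG fragment is 3 nt -> mass below the window
    amp = _toy_amplicon(template)
    units = ep.quantify_units(amp, np.array([0.5]), noise_sd=0.0)
    assert not units["measurable"].any()


def test_noiseless_recovery_on_genome_amplicons(genome, methylome):
    from mirrormeth.config import EpityperConfig

    cfg = EpityperConfig(peak_noise_sd=0.0)
    rec = methylome.registry[0]
    amp = ep.design_amplicon("r0", rec.chrom, rec.start, rec.end, genome, cfg)
    idx = np.flatnonzero(
        (methylome.chrom == amp.chrom) & np.isin(methylome.pos, np.asarray(amp.cpg_positions))
    )
    fr = methylome.fractions("MAC", [168.0])[idx, 0]
    units = ep.quantify_units(amp, fr, cfg, noise_sd=0.0)
    pos_to_frac = dict(zip(methylome.pos[idx], fr))
    for _, u in units[units["measurable"]].iterrows():
        member = [int(p) for p in u["cpg_positions"].split(",")]
        assert u["ratio"] == pytest.approx(np.mean([pos_to_frac[p] for p in member]), abs=1e-6)


def test_noisy_quantification_mae(rng):
    """Mean absolute error <= 0.05 at 10% multiplicative peak noise."""
    template = "TTT" + "GGCAGGCCGGGCAGGC" + "TTTT" + "GGGCACGGGGCAGGGC" + "TTT"
    amp = _toy_amplicon(template)
    errs = []
    g = np.random.default_rng(77)
    while len(errs) < 1000:
        frac = g.uniform(0, 1)
        units = ep.quantify_units(
            amp, np.full(len(amp.cpg_positions), frac), rng=g, noise_sd=0.10
        )
        for _, u in units[units["measurable"]].iterrows():
            errs.append(abs(u["ratio"] - frac))
    assert np.mean(errs) <= 0.05


def test_amplicon_design_tags_and_length(genome):
    rec_chrom = genome.chrom_names[0]
    amp = ep.design_amplicon("r0", rec_chrom, 10_000, 10_600, genome)
    assert amp.forward_primer.startswith(ep.FORWARD_TAG_10MER)
    assert amp.reverse_primer.startswith(ep.T7_PROMOTER_TAG)
    assert amp.forward_primer.count(ep.FORWARD_TAG_10MER) == 1
    assert amp.reverse_primer.count(ep.T7_PROMOTER_TAG) == 1
    assert 200 <= amp.length <= 600


# --- concordance ----------------------------------------------------------

def _ms_means(rows):
    import pandas as pd

    return pd.DataFrame(rows).set_index("region_id")


def test_toy_22_of_25_concordance():
    import pandas as pd

    rows = []
    calls = []
    for i in range(25):
        rid = f"r{i:02d}"
        calls.append({"region_id": rid, "direction": "hypo_in_DC"})
        # 22 concordant (MAC > DC), 3 discordant
        dc, mac = (0.1, 0.9) if i < 22 else (0.9, 0.1)
        rows.append({"region_id": rid, "DC": dc, "MAC": mac})
    rep = ep.assess_concordance(pd.DataFrame(calls), _ms_means(rows), delta_min=0.1)
    assert rep["n_regions"] == 25
    assert rep["n_concordant"] == 22
    assert rep["percent_concordant"] == pytest.approx(88.0)


def test_all_concordant_gives_100():
    import pandas as pd

    calls = pd.DataFrame([{"region_id": "a", "direction": "hypo_in_DC"}])
    means = _ms_means([{"region_id": "a", "DC": 0.1, "MAC": 0.8}])
    assert ep.assess_concordance(calls, means)["percent_concordant"] == 100.0


def test_empty_intersection_raises():
    import pandas as pd

    calls = pd.DataFrame([{"region_id": "a", "direction": "hypo_in_DC"}])
    means = _ms_means([{"region_id": "a", "DC": np.nan, "MAC": 0.8}])
    with pytest.raises(ValueError):
        ep.assess_concordance(calls, means)


def test_end_to_end_concordance(pipeline_result):
    assert pipeline_result["summary"]["concordance_pct"] >= 90.0
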