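"""In-silico EpiTYPER-style bisulfite mass-spectrometry quantification.

The workflow mirrors the MassCLEAVE assay: a target region is PCR-amplified
from bisulfite-converted DNA with a T7-promoter-tagged reverse primer (and a
10-mer tag on the forward primer), transcribed *in vitro* off the reverse
strand, and the transcript is cleaved base-specifically 3' of every U
(T reaction).  Because the reverse-strand transcript carries G opposite a
methylated CpG cytosine and A opposite an unmethylated (converted) one,
methylation shifts a cleavage fragment's mass by the G-A residue difference
(~ +16 Da) per methylated CpG without changing the cleavage pattern.  CpGs
sharing a cleavage fragment form one CpG *unit* quantified jointly:

    ratio = sum_k k * I_k / (n_CpG * sum_k I_k)

over the intensities I_k of the k-methylated mass peaks.  Units whose peaks
leave the detection window or collide (within the mass resolution) with a
peak of a different fragment are flagged unmeasurable, never quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EpityperConfig
from .genome import GenomeModel
from .methylome import MethylomeState

# standard hMC primer tags of the platform
FORWARD_TAG_10MER = "AGGAAGAGAG"
T7_PROMOTER_TAG = "CAGTAATACGACTCACTATAGGGAGAAGGCT"

#: average residue masses (Da) of ribonucleotides inside an RNA chain,
#: plus one terminal water; only the G-A difference matters downstream
RESIDUE_MASS = {"A": 329.21, "C": 305.18, "G": 345.21, "U": 306.17}
TERMINAL_MASS = 18.02
MASS_SHIFT_PER_METH = RESIDUE_MASS["G"] - RESIDUE_MASS["A"]  # 16.00 Da

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def cpg_sites(sequence: str) -> list[int]:
    """Positions of the C of every CG dinucleotide."""
    return [i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"]


def bisulfite_convert(sequence: str, cpg_methylated) -> str:
    """Complete bisulfite conversion of the forward strand.

    Every cytosine outside CpG context reads T; a CpG cytosine reads C when
    methylated and T when unmethylated.  ``cpg_methylated`` is a boolean
    per-CpG flag list aligned with :func:`cpg_sites` order.
    """
    sites = cpg_sites(sequence)
    flags = list(cpg_methylated)
    if len(flags) != len(sites):
        raise ValueError(f"need {len(sites)} CpG flags, got {len(flags)}")
    meth = {p for p, f in zip(sites, flags) if f}
    out = []
    for i, b in enumerate(sequence):
        if b == "C":
            out.append("C" if i in meth else "T")
        else:
            out.append(b)
    return "".join(out)


def reverse_strand_transcript(converted: str) -> str:
    """RNA transcript of the reverse strand of a (converted) template.

    The T7 tag on the reverse primer makes transcription run off the
    reverse strand, so the transcript equals the reverse complement of the
    forward template, with U for T.
    """
    return converted.translate(_COMPLEMENT)[::-1].replace("T", "U")


def cleave(transcript: str) -> list[str]:
    """T reaction: cut 3' of every U; fragments partition the transcript."""
    frags, cur = [], []
    for b in transcript:
        cur.append(b)
        if b == "U":
            frags.append("".join(cur))
            cur = []
    if cur:
        frags.append("".join(cur))
    return frags


def fragment_mass(fragment: str, methylated_count: int = 0) -> float:
    """Mass (Da) of a cleavage fragment carrying k methylated CpGs.

    The fragment sequence is given in its unmethylated form (A at CpG
    sites); each methylated CpG adds the G-A residue difference.
    """
    if not fragment:
        raise ValueError("empty fragment")
    if methylated_count < 0:
        raise ValueError("methylated_count must be >= 0")
    base = sum(RESIDUE_MASS[b] for b in fragment) + TERMINAL_MASS
    return base + methylated_count * MASS_SHIFT_PER_METH


@dataclass
class CleavageFragment:
    seq: str  # unmethylated form (A at CpG sites)
    start: int  # offset in the transcript
    cpg_ids: tuple[int, ...]  # amplicon CpG indices mapping into this fragment

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_ids)

    def masses(self) -> np.ndarray:
        """Peak masses for k = 0..n_cpg methylated CpGs (strictly increasing)."""
        return fragment_mass(self.seq, 0) + MASS_SHIFT_PER_METH * np.arange(self.n_cpg + 1)


@dataclass
class BisulfiteAmplicon:
    region_id: str
    chrom: str
    start: int
    end: int
    template: str  # unconverted forward genomic sequence
    cpg_positions: tuple[int, ...]  # genomic positions of member CpG C's
    forward_primer: str = ""
    reverse_primer: str = ""
    fragments: list[CleavageFragment] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def design_amplicon(
    region_id: str,
    chrom: str,
    start: int,
    end: int,
    genome: GenomeModel,
    config: EpityperConfig | None = None,
) -> BisulfiteAmplicon:
    """Centre an amplicon of the configured target length on a region."""
    cfg = config or EpityperConfig()
    seq = genome.sequences[chrom]
    center = (start + end) // 2
    half = cfg.amplicon_target_len // 2
    a, b = max(0, center - half), min(len(seq), center + half)
    lo, hi = cfg.amplicon_len_bounds
    if not (lo <= b - a <= hi):
        raise ValueError(f"amplicon length {b - a} outside bounds {cfg.amplicon_len_bounds}")
    template = seq[a:b]
    sites = [a + p for p in cpg_sites(template)]
    # primers designed on the fully-converted (unmethylated) sequence
    conv = bisulfite_convert(template, [False] * len(sites))
    fwd = FORWARD_TAG_10MER + conv[:24]
    rev = T7_PROMOTER_TAG + conv[-24:].translate(_COMPLEMENT)[::-1]
    amp = BisulfiteAmplicon(
        region_id=region_id,
        chrom=chrom,
        start=a,
        end=b,
        template=template,
        cpg_positions=tuple(sites),
        forward_primer=fwd,
        reverse_primer=rev,
    )
    amp.fragments = build_fragments(amp)
    return amp


def build_fragments(amplicon: BisulfiteAmplicon) -> list[CleavageFragment]:
    """Cleavage fragments of the reverse-strand transcript, with CpG mapping.

    The cleavage pattern does not depend on methylation (the variable
    residue is G vs A, never U), so fragments are computed once on the
    unmethylated transcript.
    """
    n = len(amplicon.template)
    conv = bisulfite_convert(amplicon.template, [False] * len(amplicon.cpg_positions))
    transcript = reverse_strand_transcript(conv)
    # transcript index of the residue complementary to the CpG cytosine
    cpg_tx = {n - 1 - (p - amplicon.start): i for i, p in enumerate(amplicon.cpg_positions)}
    frags = []
    offset = 0
    for seq in cleave(transcript):
        ids = tuple(cpg_tx[j] for j in range(offset, offset + len(seq)) if j in cpg_tx)
        frags.append(CleavageFragment(seq=seq, start=offset, cpg_ids=ids))
        offset += len(seq)
    return frags


def _poisson_binomial(probs: np.ndarray) -> np.ndarray:
    """P(k methylated) for independent per-CpG probabilities."""
    pk = np.array([1.0])
    for p in probs:
        pk = np.convolve(pk, [1.0 - p, p])
    return pk


def quantify_units(
    amplicon: BisulfiteAmplicon,
    cpg_fractions: np.ndarray,
    config: EpityperConfig | None = None,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Per-CpG-unit methylation ratios from simulated mass peaks.

    Peak intensity for k methylated CpGs is proportional to the
    Poisson-binomial population probability of k, times multiplicative
    lognormal noise.  A unit is unmeasurable when any of its peaks falls
    outside the detection window or within the mass resolution of a peak
    from a *different* fragment.
    """
    cfg = config or EpityperConfig()
    sd = cfg.peak_noise_sd if noise_sd is None else noise_sd
    if rng is None:
        rng = np.random.default_rng(0)
    cpg_fractions = np.asarray(cpg_fractions, dtype=float)
    if len(cpg_fractions) != len(amplicon.cpg_positions):
        raise ValueError("one population fraction per amplicon CpG required")
    frags = amplicon.fragments or build_fragments(amplicon)

    all_masses = [f.masses() for f in frags]
    lo, hi = cfg.detection_window_da
    rows = []
    unit_id = 0
    for i, frag in enumerate(frags):
        if frag.n_cpg == 0:
            continue
        masses = all_masses[i]
        in_window = bool((masses >= lo).all() and (masses <= hi).all())
        collision = False
        for j, other in enumerate(all_masses):
            if j == i:
                continue
            d = np.abs(masses[:, None] - other[None, :])
            if (d < cfg.mass_resolution_da).any():
                collision = True
                break
        measurable = in_window and not collision
        probs = cpg_fractions[list(frag.cpg_ids)]
        pk = _poisson_binomial(probs)
        intensities = pk * np.exp(rng.normal(0.0, sd, size=len(pk))) if sd > 0 else pk
        total = intensities.sum()
        if measurable and total > 0:
            ratio = float((np.arange(len(pk)) * intensities).sum() / (frag.n_cpg * total))
        else:
            ratio = float("nan")
            measurable = False if total == 0 else measurable
        rows.append(
            {
                "region_id": amplicon.region_id,
                "unit_id": f"{amplicon.region_id}_u{unit_id:02d}",
                "n_cpg": frag.n_cpg,
                "cpg_ids": ",".join(map(str, frag.cpg_ids)),
                "cpg_positions": ",".join(
                    str(amplicon.cpg_positions[c]) for c in frag.cpg_ids
                ),
                "measurable": measurable,
                "ratio": ratio,
            }
        )
        unit_id += 1
    return pd.DataFrame(rows)


def measure_regions(
    regions: pd.DataFrame,
    genome: GenomeModel,
    methylome: MethylomeState,
    state: str,
    time_h: float,
    config: EpityperConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """EpiTYPER measurement of a set of regions for one sample.

    ``regions`` needs columns region_id, chrom, start, end.  Returns the
    per-unit table with a ``sample`` column ``{state}_{time_h}h``.
    """
    cfg = config or EpityperConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    out = []
    for _, r in regions.iterrows():
        amp = design_amplicon(r["region_id"], r["chrom"], int(r["start"]), int(r["end"]), genome, cfg)
        on_chrom = methylome.chrom == amp.chrom
        idx = np.flatnonzero(on_chrom & np.isin(methylome.pos, np.asarray(amp.cpg_positions)))
        fr = methylome.fractions(state, [time_h])[idx, 0]
        units = quantify_units(amp, fr, cfg, rng=rng)
        units["sample"] = f"{state}_{time_h:g}h"
        units["state"] = state
        units["time_h"] = float(time_h)
        out.append(units)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def region_means(units: pd.DataFrame) -> pd.DataFrame:
    """Mean measurable-unit ratio per region and sample (wide by state)."""
    ok = units[units["measurable"]]
    g = ok.groupby(["region_id", "state"])["ratio"].mean().unstack("state")
    return g


def assess_concordance(
    array_calls: pd.DataFrame,
    ms_means: pd.DataFrame,
    delta_min: float = 0.1,
) -> dict:
    """Concordance between array DMR calls and MS methylation ratios.

    ``ms_means`` is indexed by region_id with columns "DC" and "MAC" (mean
    measurable-unit ratios).  A region with an array call is concordant when
    the sign of (MAC - DC) matches the call direction; an array-negative
    control region is concordant when |MAC - DC| < delta_min.  Regions
    without MS data (no measurable unit in either sample) are excluded from
    the denominator, mirroring "detected with both assays".
    """
    if delta_min < 0:
        raise ValueError("delta_min must be >= 0")
    direction = dict(zip(array_calls.get("region_id", array_calls.get("dmr_call_id")), array_calls["direction"]))
    detected = ms_means.dropna(subset=["DC", "MAC"])
    if len(detected) == 0:
        raise ValueError("no region detected with both assays")
    n_conc = 0
    per_region = {}
    for region_id, row in detected.iterrows():
        diff = row["MAC"] - row["DC"]
        d = direction.get(region_id)
        if d is None:  # array-negative control
            conc = abs(diff) < delta_min
        elif d == "hypo_in_DC":
            conc = diff > 0
        else:
            conc = diff < 0
        per_region[region_id] = bool(conc)
        n_conc += conc
    n = len(detected)
    return {
        "n_regions": n,
        "n_concordant": int(n_conc),
        "percent_concordant": 100.0 * n_conc / n,
        "per_region": per_region,
    }
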