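"""Rank statistics and ChIP-qPCR normalization arithmetic.

The Mann-Whitney U statistic is computed by the rank formula with mid-ranks
for ties; the two-sided P-value comes from exact enumeration of all group
assignments for small samples (both group sizes <= 8 by default) and from
the normal approximation with tie correction otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, erfc, sqrt, log2

import numpy as np

EXACT_MAX_N = 8


def mannwhitney_u(x, y) -> float:
    """U statistic of sample x (rank formula, mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n1 + n2)
    sorted_vals = pooled[order]
    i = 0
    r = np.arange(1, n1 + n2 + 1, dtype=float)
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        r[i : j + 1] = (i + 1 + j + 1) / 2.0
        i = j + 1
    ranks[order] = r
    r1 = ranks[:n1].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def _u_by_enumeration(x, y) -> float:
    """Brute-force U: count pairwise wins of x over y (ties count half)."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mwu_exact_p(x, y) -> float:
    """Exact two-sided P by enumerating all pooled group assignments.

    P = fraction of assignments whose |U - n1 n2 / 2| is at least the
    observed deviation; handles ties exactly (full-tie data give P = 1).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    pooled = x + y
    mean = n1 * n2 / 2.0
    u_obs = mannwhitney_u(x, y)
    dev = abs(u_obs - mean)
    hits = 0
    total = comb(n1 + n2, n1)
    idx = range(n1 + n2)
    for chosen in combinations(idx, n1):
        cs = set(chosen)
        gx = [pooled[i] for i in chosen]
        gy = [pooled[i] for i in idx if i not in cs]
        u = mannwhitney_u(gx, gy)
        if abs(u - mean) >= dev - 1e-12:
            hits += 1
    return hits / total


def mwu_normal_p(x, y) -> float:
    """Two-sided normal-approximation P with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    u = mannwhitney_u(x, y)
    mean = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u - mean) - 0.5) / sqrt(var)  # continuity correction
    z = max(z, 0.0)
    return erfc(z / sqrt(2.0))


def mwu_test(x, y) -> tuple[float, float]:
    """(U, two-sided P); exact enumeration when both groups are small."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u = mannwhitney_u(x, y)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return u, mwu_exact_p(x, y)
    return u, mwu_normal_p(x, y)


# --- ChIP-qPCR percent-input normalization -------------------------------

def percent_input(ct_ip: float, ct_input: float, input_fraction: float = 0.05) -> float:
    """IP recovery as percent of total input chromatin.

    The input aliquot is a known fraction (default 5%) of the material, so
    its Ct is first shifted by log2(1/fraction) to represent 100% input:
    percent = 100 * 2**((ct_input - log2(1/fraction)) - ct_ip).
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    if not (np.isfinite(ct_ip) and np.isfinite(ct_input)):
        raise ValueError("Ct values must be finite")
    return 100.0 * 2.0 ** ((ct_input - log2(1.0 / input_fraction)) - ct_ip)


def chip_enrichment(
    ct_ip: float,
    ct_input: float,
    input_fraction: float = 0.05,
    reference_percent_input: float | None = None,
) -> dict:
    """Percent-input and enrichment relative to the 0 h reference.

    Without a reference the relative value is undefined (NaN) but the
    percent-input is still returned; the reference sample against itself is
    identically 1.0.
    """
    pi = percent_input(ct_ip, ct_input, input_fraction)
    rel = pi / reference_percent_input if reference_percent_input else float("nan")
    return {"percent_input": pi, "relative_enrichment": rel}
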