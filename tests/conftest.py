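"""Shared fixtures and independent oracles used across the test suite.

The oracles here are deliberately written from scratch (per-base string
checks, direct enumeration) so they share no code path with the package
implementations they validate.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from repeatscape.types import GenomeSequence

# ---------------------------------------------------------------------------
# Brute-force SSR oracle
# ---------------------------------------------------------------------------

_MINLEN = {1: 12, 2: 12, 3: 12, 4: 12, 5: 20, 6: 18}


def _region_has_period(s: str, i: int, length: int, p: int) -> bool:
    return all(
        s[q] == s[q + p] and s[q] != "N"
        for q in range(i, i + length - p)
    )


def brute_force_ssrs(s: str, include_homopolymers: bool = False):
    """Enumerate maximal perfect tandem arrays directly from the string.

    Returns (start, end, unit, n_units) tuples after whole-unit trimming and
    length thresholds, before overlap resolution.
    """
    out = []
    kmin = 1 if include_homopolymers else 2
    for k in range(kmin, 7):
        for i in range(len(s) - k):
            # left-maximal at per-base level
            if i > 0 and s[i - 1] == s[i - 1 + k] and s[i - 1] != "N":
                continue
            # extend right per-base
            j = i
            while j + k < len(s) and s[j] == s[j + k] and s[j] != "N":
                j += 1
            m = j - i  # consecutive matches starting at i
            if m == 0:
                continue
            region_len = m + k
            # minimal-period check over the region
            if any(_region_has_period(s, i, region_len, p) for p in range(1, k)):
                continue
            n_units = region_len // k
            if n_units * k < _MINLEN[k]:
                continue
            unit = s[i : i + k]
            if "N" in unit:
                continue
            out.append((i, i + n_units * k, unit, n_units))
    return out


def resolve_overlaps_oracle(arrays):
    """Independent reimplementation of the overlap rule: longer array wins;
    tie -> smaller unit; tie -> leftmost."""
    ranked = sorted(
        arrays, key=lambda a: (-(a[1] - a[0]), len(a[2]), a[0])
    )
    kept = []
    for a in ranked:
        if all(a[1] <= b[0] or a[0] >= b[1] for b in kept):
            kept.append(a)
    return sorted(kept)


def oracle_scan(s: str):
    return resolve_overlaps_oracle(brute_force_ssrs(s))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def balanced_newick(n_tips: int, branch_length: float = 1.0) -> str:
    labels = [f"t{i}" for i in range(n_tips)]

    def rec(lo, hi):
        if hi - lo == 1:
            return f"{labels[lo]}:{branch_length}"
        mid = (lo + hi) // 2
        return f"({rec(lo, mid)},{rec(mid, hi)}):{branch_length}"

    return rec(0, n_tips) + ";"


def random_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary topology with exponential branch lengths."""
    nodes = [f"t{i}:{rng.exponential(1.0):.9f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(1.0):.9f}")
    return nodes[0] + ";"


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_genome(rng):
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return GenomeSequence(name="chr1", residues=seq)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


def hypergeom_tail_p(a: int, b: int, c: int, d: int) -> float:
    """One-tailed (greater) Fisher p by direct hypergeometric summation.

    Table [[a, b], [c, d]]: probability of >= a successes in the top-left
    cell given fixed margins.
    """
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    denom = math.comb(n, col1)
    hi = min(row1, col1)
    return sum(
        math.comb(row1, x) * math.comb(n - row1, col1 - x) for x in range(a, hi + 1)
    ) / denom
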