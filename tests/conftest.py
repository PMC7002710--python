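"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the implementation's code paths (the package
counts repeats with compiled regular expressions; the oracles use explicit
character scanning) so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from tmmkit.telomere_content import RepeatPatternSet

G_PATTERNS = ("TTAGGG", "TCAGGG", "TGAGGG", "TTGGGG")
C_PATTERNS = ("CCCTAA", "CCCTGA", "CCCTCA", "CCCCAA")


def brute_force_repeat_count(seq: str, patterns: tuple[str, ...]) -> int:
    """Greedy left-to-right scan by explicit character comparison."""
    i = 0
    n = 0
    while i + 6 <= len(seq):
        if seq[i : i + 6] in patterns:
            n += 1
            i += 6
        else:
            i += 1
    return n


def brute_force_is_telomeric(seq: str, threshold: int) -> bool:
    return (
        brute_force_repeat_count(seq, G_PATTERNS) >= threshold
        or brute_force_repeat_count(seq, C_PATTERNS) >= threshold
    )


def brute_force_tvr_scan(seq: str) -> list[tuple[int, str]]:
    """All-offsets greedy NNNGGG scan, returning (offset, hexamer) pairs."""
    out = []
    i = 0
    while i + 6 <= len(seq):
        h = seq[i : i + 6]
        if h[3:] == "GGG" and "N" not in h:
            out.append((i, h))
            i += 6
        else:
            i += 1
    return out


def ols_closed_form(x, y) -> tuple[float, float]:
    """Slope/intercept from the normal equations, independent of scipy."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = float(((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum())
    return slope, float(ybar - slope * xbar)


def brute_force_microhomology(flank: str, inserted: str, units=("TTAGGG", "CCCTAA")) -> int:
    """Largest junction left-shift keeping the repeat contiguous.

    Enumerates shifts m and re-checks the full shifted junction: the m flank
    bases plus the inserted sequence must read as one contiguous repeat run.
    """
    best = 0
    for unit in units:
        stream = unit * 40
        # phase of the inserted sequence
        probe = inserted[: min(len(inserted), 12)]
        phases = [p for p in range(6) if stream[p : p + len(probe)] == probe]
        if not phases:
            continue
        phi = phases[0]
        for m in range(1, len(flank) + 1):
            shifted = flank[-m:] + probe
            start = (phi - m) % 6
            if stream[start : start + len(shifted)] == shifted:
                best = max(best, m)
            else:
                break
    return best


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def patterns() -> RepeatPatternSet:
    return RepeatPatternSet()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
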