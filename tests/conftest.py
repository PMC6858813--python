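"""Shared fixtures and an independent brute-force scoring oracle.

The oracle re-derives duplex bond totals from first principles (a
literal pair-by-pair lookup over every window) without touching the
package's vectorized scan path, so oracle-equivalence tests are a real
dual-route check.
"""

import random

import pytest

# independent hydrogen-bond lookup: canonical G-C/A-U plus wobble G-U/A-C
ORACLE_BONDS = {
    ("G", "C"): 3,
    ("C", "G"): 3,
    ("A", "U"): 2,
    ("U", "A"): 2,
    ("G", "U"): 1,
    ("U", "G"): 1,
    ("A", "C"): 1,
    ("C", "A"): 1,
}


def oracle_window_bonds(mirna_seq: str, window: str) -> int:
    """Bond total of a gapless antiparallel duplex, recounted naively."""
    L = len(mirna_seq)
    assert len(window) == L
    total = 0
    for i in range(L):
        total += ORACLE_BONDS.get((mirna_seq[L - 1 - i], window[i]), 0)
    return total


def oracle_max_bonds(mirna_seq: str) -> int:
    return sum(3 if b in "GC" else (2 if b in "AU" else 0) for b in mirna_seq)


def oracle_scan(mirna_seq: str, transcript_seq: str, threshold_pct: float):
    """Exhaustive per-start enumeration: [(1-based start, bonds), ...]."""
    L = len(mirna_seq)
    mb = oracle_max_bonds(mirna_seq)
    hits = []
    for s in range(1, len(transcript_seq) - L + 2):
        b = oracle_window_bonds(mirna_seq, transcript_seq[s - 1 : s - 1 + L])
        if 100 * b >= threshold_pct * mb:
            hits.append((s, b))
    return hits


def random_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20190913)
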