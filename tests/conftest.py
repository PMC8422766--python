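"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately avoid the package's rank
encoding and vectorized counting: k-mer frequencies come from an
associative map of raw substrings, and the matched-pair oracle is a
literal step-by-step simulation of the greedy algorithm. They exist to
cross-check the fast implementations, so they must stay independent of
them.
"""

from __future__ import annotations

import random
from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def naive_counts(seq: str, k: int) -> Tuple[Dict[str, int], int]:
    """Substring-map k-mer counts; returns (counts, n_valid_windows)."""
    counts: Dict[str, int] = {}
    valid = 0
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if all(c in "ACGT" for c in window):
            counts[window] = counts.get(window, 0) + 1
            valid += 1
    return counts, valid


def naive_d1(seq_1: str, seq_2: str, k: int) -> float:
    c1, n1 = naive_counts(seq_1, k)
    c2, n2 = naive_counts(seq_2, k)
    total = 0.0
    for kmer in set(c1) | set(c2):
        total += abs(c1.get(kmer, 0) / n1 - c2.get(kmer, 0) / n2)
    return total


def naive_d2(seq_1: str, seq_2: str, k: int) -> float:
    def combined(seq: str) -> Dict[str, float]:
        counts, n = naive_counts(seq, k)
        freq = {m: c / n for m, c in counts.items()}
        out: Dict[str, float] = {}
        for m in set(freq) | {naive_rc(m) for m in freq}:
            out[m] = freq.get(m, 0.0) + freq.get(naive_rc(m), 0.0)
        return out

    g1 = combined(seq_1)
    g2 = combined(seq_2)
    total = 0.0
    for kmer in set(g1) | set(g2):
        total += abs(g1.get(kmer, 0.0) - g2.get(kmer, 0.0))
    return total / 2.0


def oracle_matched_pairs(
    row_ids: List[str],
    col_ids: List[str],
    values,
    threshold: float = 1.0,
) -> Tuple[List[Tuple[str, str, float]], Optional[float], Optional[float]]:
    """Literal simulation of the greedy matching steps.

    1. discard edges with distance > threshold; 2. empty vector;
    3. linear scan for the lowest remaining edge (ties: lexicographic on
    ids); 4. append; 5. drop both endpoint chromosomes; 6. repeat until
    exhausted, then report (pairs, minimum, median).
    """
    edges = [
        (float(values[i][j]), row_ids[i], col_ids[j])
        for i in range(len(row_ids))
        for j in range(len(col_ids))
        if values[i][j] <= threshold
    ]
    pairs: List[Tuple[str, str, float]] = []
    while edges:
        best = edges[0]
        for e in edges[1:]:
            if e < best:
                best = e
        value, rid, cid = best
        pairs.append((rid, cid, value))
        edges = [e for e in edges if e[1] != rid and e[2] != cid]
    if not pairs:
        return [], None, None
    vector = sorted(p[2] for p in pairs)
    n = len(vector)
    median = (
        vector[n // 2] if n % 2 else (vector[n // 2 - 1] + vector[n // 2]) / 2.0
    )
    return pairs, vector[0], median


def random_seq(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def py_rng() -> random.Random:
    return random.Random(20260929)


@pytest.fixture
def np_rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def fasta_writer(tmp_path):
    """Write a FASTA file from raw text and return its path."""

    def _write(text: str, name: str = "test.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
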