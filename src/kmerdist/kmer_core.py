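"""k-mer spectra and the single-strand (D1) / double-strand (D2) distances.

A chromosome of length L read 5'→3' has N = L - k + 1 sliding windows of
length k. The empirical frequency of k-mer m is f_m = n(m) / N. With
masked or ambiguous bases present, windows containing any non-ACGT symbol
are excluded and the divisor becomes the number of *valid* windows, so
frequencies still sum to 1.

The two distances between chromosomal strands S1 and S2 are

    D1^k(S1,S2) = sum_m | f_m(S1) - f_m(S2) |

the L1 norm over all 4^k k-mer frequencies on a single strand of each
chromosome, and

    D2^k(S1,S2) = sum_m | f_m(S1) + f_M(S1) - f_m(S2) - f_M(S2) | / 2

where M is the reverse complement of m, i.e. the same comparison carried
out on strand-symmetrized frequencies (every k-mer on the negative strand
appears as its reverse complement on the positive strand). The halving
compensates for each chromosome effectively contributing 2N counts. Both
distances lie in [0, 2]; D2 <= D1 always, and both vanish when one strand
is the reverse complement of the other (inversion symmetry — the
generalized second Chargaff rule — as a zero distance).

k-mers are rank-encoded lexicographically in base 4 with A=0, C=1, G=2,
T=3; the reverse-complement rank is computed arithmetically, which makes
the D2 pairing an O(1) permutation of the counts vector.
"""

from __future__ import annotations

import logging
import math
import struct
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import List, Union

import numpy as np

from .sequence_io import GenomeRecord

logger = logging.getLogger(__name__)

MAX_K = 12  # 4^12 counts (~134M int64) is the largest in-memory table allowed

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

PathLike = Union[str, Path]

_warned_kl: set = set()


@dataclass
class KmerSpectrum:
    """Counts of all 4^k k-mers on one strand.

    ``counts[r]`` is n(m) for the k-mer of lexicographic rank r;
    ``total_valid`` is N, the number of windows made purely of A/C/G/T;
    ``skipped_windows`` counts windows touching at least one other symbol.
    """

    k: int
    counts: np.ndarray
    total_valid: int
    skipped_windows: int
    source_id: str = ""


@dataclass
class FrequencyVector:
    """f_m for every k-mer; ``combined`` marks the strand-symmetrized f_m + f_M."""

    k: int
    freqs: np.ndarray
    combined: bool


@dataclass
class DistanceResult:
    k: int
    measure: str  # "D1" | "D2"
    value: float
    id_1: str
    id_2: str
    missing_fraction_1: float
    missing_fraction_2: float


def kl_limit(length_1: int, length_2: int) -> int:
    """Advisory upper k for reliable spectra: floor(0.7 ln min(L1, L2)).

    The KL limit is the k at which inversion symmetry starts failing at the
    10% level; it grows logarithmically with chromosome length. When two
    chromosomes of different lengths are compared the shorter one governs.
    The heuristic is advisory only — every operation accepts any k in
    [1, 12].
    """
    if length_1 <= 0 or length_2 <= 0:
        raise ValueError("chromosome lengths must be positive")
    if length_1 < 2 or length_2 < 2:
        raise ValueError("chromosome lengths must be >= 2")
    return math.floor(0.7 * math.log(min(length_1, length_2)))


def count_kmers(record: GenomeRecord, k: int) -> KmerSpectrum:
    """Sliding-window k-mer counts on the given strand, read 5'→3'.

    Windows containing any symbol outside uppercase {A,C,G,T} — N, masked
    bases, lowercase — are excluded from the counts and tallied in
    ``skipped_windows``.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    L = record.length
    if k > L:
        raise ValueError(f"sequence shorter than k (length {L} < k={k})")
    if L >= 2:
        kl = kl_limit(L, L)
        if k > kl and (k, kl) not in _warned_kl:
            _warned_kl.add((k, kl))
            logger.warning(
                "%s: k=%d exceeds the KL limit %d (inversion symmetry fails at "
                "the 10%% level beyond KL); distances remain defined but noisy "
                "(warning shown once per k/KL combination)",
                record.id,
                k,
                kl,
            )

    codes = _CODE[np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)]
    n_windows = L - k + 1
    invalid = (codes == 255).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(invalid)))
    window_ok = (cum[k:] - cum[:-k]) == 0

    c = codes.astype(np.int64)
    c[codes == 255] = 0
    ranks = np.zeros(n_windows, dtype=np.int64)
    for j in range(k):
        ranks = ranks * 4 + c[j : j + n_windows]

    counts = np.bincount(ranks[window_ok], minlength=4**k)
    total_valid = int(window_ok.sum())
    return KmerSpectrum(
        k=k,
        counts=counts,
        total_valid=total_valid,
        skipped_windows=n_windows - total_valid,
        source_id=record.id,
    )


def frequencies(spectrum: KmerSpectrum) -> FrequencyVector:
    """Single-strand frequencies f_m = n(m) / N (N = valid windows)."""
    if spectrum.total_valid <= 0:
        raise ValueError("no valid k-mer windows")
    return FrequencyVector(
        k=spectrum.k,
        freqs=spectrum.counts / spectrum.total_valid,
        combined=False,
    )


@lru_cache(maxsize=None)
def _rc_permutation(k: int) -> np.ndarray:
    """rank -> rank of the reverse-complement k-mer, computed arithmetically."""
    ranks = np.arange(4**k, dtype=np.int64)
    out = np.zeros_like(ranks)
    t = ranks.copy()
    for _ in range(k):
        out = out * 4 + (3 - (t & 3))  # complement of the current last base
        t >>= 2
    out.setflags(write=False)
    return out


def combined_frequencies(spectrum: KmerSpectrum) -> FrequencyVector:
    """Strand-symmetrized frequencies f_m + f_M (M = reverse complement of m).

    Entries sum to 2 (each frequency is counted in its own slot and in its
    partner's); a palindromic k-mer's entry equals 2 f_m.
    """
    single = frequencies(spectrum).freqs
    perm = _rc_permutation(spectrum.k)
    return FrequencyVector(k=spectrum.k, freqs=single + single[perm], combined=True)


def _check_pair(spec_1: KmerSpectrum, spec_2: KmerSpectrum) -> None:
    if spec_1.k != spec_2.k:
        raise ValueError(f"mismatched k: {spec_1.k} vs {spec_2.k}")
    if spec_1.total_valid <= 0 or spec_2.total_valid <= 0:
        raise ValueError("no valid k-mer windows")


def d1(spec_1: KmerSpectrum, spec_2: KmerSpectrum) -> DistanceResult:
    """Single-strand L1 k-mer distance D1."""
    _check_pair(spec_1, spec_2)
    f1 = frequencies(spec_1).freqs
    f2 = frequencies(spec_2).freqs
    return DistanceResult(
        k=spec_1.k,
        measure="D1",
        value=float(np.abs(f1 - f2).sum()),
        id_1=spec_1.source_id,
        id_2=spec_2.source_id,
        missing_fraction_1=missing_fraction(spec_1),
        missing_fraction_2=missing_fraction(spec_2),
    )


def d2(spec_1: KmerSpectrum, spec_2: KmerSpectrum) -> DistanceResult:
    """Double-strand L1 k-mer distance D2 (insensitive to segmental inversions)."""
    _check_pair(spec_1, spec_2)
    g1 = combined_frequencies(spec_1).freqs
    g2 = combined_frequencies(spec_2).freqs
    return DistanceResult(
        k=spec_1.k,
        measure="D2",
        value=float(np.abs(g1 - g2).sum() / 2.0),
        id_1=spec_1.source_id,
        id_2=spec_2.source_id,
        missing_fraction_1=missing_fraction(spec_1),
        missing_fraction_2=missing_fraction(spec_2),
    )


def missing_fraction(spectrum: KmerSpectrum) -> float:
    """Fraction of the 4^k possible k-mers with zero count, n(m) = 0."""
    return float(np.count_nonzero(spectrum.counts == 0)) / float(4**spectrum.k)


# ---------------------------------------------------------------------------
# rank <-> string and serialization


def rank_to_kmer(rank: int, k: int) -> str:
    return "".join("ACGT"[(rank >> (2 * (k - 1 - j))) & 3] for j in range(k))


def kmer_to_rank(kmer: str) -> int:
    rank = 0
    for ch in kmer:
        rank = rank * 4 + "ACGT".index(ch)
    return rank


def write_spectrum_tsv(spectrum: KmerSpectrum, path: PathLike) -> None:
    """Two-column TSV (kmer, count); zero-count rows included for completeness."""
    k = spectrum.k
    with open(path, "wt") as fh:
        fh.write(f"# k={k}\ttotal_valid={spectrum.total_valid}"
                 f"\tskipped_windows={spectrum.skipped_windows}"
                 f"\tsource_id={spectrum.source_id}\n")
        for rank, count in enumerate(spectrum.counts):
            fh.write(f"{rank_to_kmer(rank, k)}\t{int(count)}\n")


def read_spectrum_tsv(path: PathLike) -> KmerSpectrum:
    with open(path, "rt") as fh:
        header = fh.readline()
        meta = dict(item.split("=", 1) for item in header.lstrip("# ").rstrip().split("\t"))
        k = int(meta["k"])
        counts = np.zeros(4**k, dtype=np.int64)
        for line in fh:
            kmer, count = line.split("\t")
            counts[kmer_to_rank(kmer)] = int(count)
    return KmerSpectrum(
        k=k,
        counts=counts,
        total_valid=int(meta["total_valid"]),
        skipped_windows=int(meta["skipped_windows"]),
        source_id=meta.get("source_id", ""),
    )


_MAGIC = b"KSPC"


def save_spectrum(spectrum: KmerSpectrum, path: PathLike) -> None:
    """Compact binary: small header (k, totals, source id) + int64 counts."""
    sid = spectrum.source_id.encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<BQQH", spectrum.k, spectrum.total_valid,
                             spectrum.skipped_windows, len(sid)))
        fh.write(sid)
        fh.write(np.ascontiguousarray(spectrum.counts, dtype="<i8").tobytes())


def load_spectrum(path: PathLike) -> KmerSpectrum:
    with open(path, "rb") as fh:
        if fh.read(4) != _MAGIC:
            raise ValueError(f"{path}: not a spectrum file")
        k, total_valid, skipped, sid_len = struct.unpack("<BQQH", fh.read(19))
        source_id = fh.read(sid_len).decode("utf-8")
        counts = np.frombuffer(fh.read(8 * 4**k), dtype="<i8").astype(np.int64)
    return KmerSpectrum(k=k, counts=counts, total_valid=int(total_valid),
                        skipped_windows=int(skipped), source_id=source_id)


def write_distance_tsv(results: List[DistanceResult], path: PathLike) -> None:
    """One TSV row per result: id_1, id_2, k, measure, value."""
    with open(path, "wt") as fh:
        fh.write("id_1\tid_2\tk\tmeasure\tvalue\n")
        for r in results:
            fh.write(f"{r.id_1}\t{r.id_2}\t{r.k}\t{r.measure}\t{r.value:.12g}\n")
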