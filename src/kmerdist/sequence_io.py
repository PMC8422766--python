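"""FASTA input with explicit masking semantics, plus strand operations.

Genome comparisons here are run on one of three views of a chromosome:

``raw``
    the sequence exactly as stored in the FASTA (soft-masked lowercase
    preserved);
``unmasked``
    everything uppercased — soft-masked repeats participate in k-mer
    counting like ordinary sequence;
``masked``
    soft-masked (lowercase) bases are converted to ``N`` before
    uppercasing, so that both soft- and hard-masked tracts are excluded
    from any window that touches them.

Unifying soft and hard masking into ``N`` gives downstream k-mer counting a
single window-skipping rule. Ambiguity codes outside {A,C,G,T,N} are mapped
to ``N`` (with a logged count) because the distance definitions live on a
4-letter alphabet.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, List, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

MASKING_MODES = ("raw", "unmasked", "masked")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_NON_RC_ALPHABET = re.compile(r"[^ACGTNacgtn]")
_LOWERCASE = re.compile(r"[a-z]")
_NON_ACGTN = re.compile(r"[^ACGTN]")

PathLike = Union[str, Path]


class FastaParseError(ValueError):
    """Raised when a file does not look like FASTA."""


@dataclass
class GenomeRecord:
    """One chromosomal sequence.

    Parameters
    ----------
    id:
        First whitespace-delimited token of the FASTA header.
    sequence:
        Nucleotide string; alphabet depends on ``masking_mode``.
    masking_mode:
        One of :data:`MASKING_MODES`; records produced by
        :func:`read_fasta` or :func:`apply_masking` record the view they
        represent.
    """

    id: str
    sequence: str
    masking_mode: str = "raw"

    @property
    def length(self) -> int:
        return len(self.sequence)


def reverse_complement(s: str) -> str:
    """Reverse complement of ``s`` (case preserved, ``N`` self-complements).

    Raises ``ValueError`` naming the offending character and its 0-based
    position if ``s`` contains anything outside {A,C,G,T,N} (either case).
    Applying the function twice returns the input.
    """
    bad = _NON_RC_ALPHABET.search(s)
    if bad is not None:
        raise ValueError(
            f"invalid nucleotide {bad.group()!r} at position {bad.start()}"
        )
    return s.translate(_COMPLEMENT)[::-1]


def _transform(sequence: str, masking_mode: str, source: str = "") -> str:
    if masking_mode == "raw":
        return sequence
    if masking_mode == "masked":
        sequence = _LOWERCASE.sub("N", sequence)
    sequence = sequence.upper()
    sequence, n_mapped = _NON_ACGTN.subn("N", sequence)
    if n_mapped:
        logger.warning(
            "%s: mapped %d non-ACGTN symbol(s) to N", source or "<sequence>", n_mapped
        )
    return sequence


def apply_masking(record: GenomeRecord, masking_mode: str) -> GenomeRecord:
    """Return a new record holding the requested view of ``record``.

    Intended for in-memory genomes (e.g. simulator output carrying
    soft-masked tracts); masking never changes coordinates or length.
    """
    if masking_mode not in MASKING_MODES:
        raise ValueError(f"masking_mode must be one of {MASKING_MODES}, got {masking_mode!r}")
    return GenomeRecord(
        id=record.id,
        sequence=_transform(record.sequence, masking_mode, record.id),
        masking_mode=masking_mode,
    )


def _open_text(path: PathLike) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path: PathLike,
    masking_mode: str = "unmasked",
    min_length: int = 0,
) -> List[GenomeRecord]:
    """Read a (possibly gzipped) FASTA into :class:`GenomeRecord` objects.

    Records shorter than ``min_length`` (a proxy for dropping unplaced
    scaffolds / alt contigs) are discarded; order of the surviving records
    is preserved. An empty file yields an empty list with a logged warning;
    sequence data before the first header raises :class:`FastaParseError`
    naming the line number.
    """
    if masking_mode not in MASKING_MODES:
        raise ValueError(f"masking_mode must be one of {MASKING_MODES}, got {masking_mode!r}")

    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"found {line.strip()[:30]!r}"
                    )
                break
        else:
            logger.warning("empty FASTA file: %s", path)
            return []

    records: List[GenomeRecord] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = _transform(str(rec.seq), masking_mode, rec.id)
            if len(seq) >= min_length:
                records.append(GenomeRecord(id=rec.id, sequence=seq, masking_mode=masking_mode))
    return records


def write_fasta(records: List[GenomeRecord], path: PathLike, width: int = 70) -> None:
    """Write records as plain FASTA, preserving case (soft masking)."""
    with open(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
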