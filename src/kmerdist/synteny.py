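"""Synteny blocks and proximities between closely related bacterial strains.

Two strains of the same bacterium share long, nearly identical chromosome
segments. Local alignments between the two full chromosomes (BLAST tabular
output) are filtered to high-identity hits and classified by strand:
Direct Synteny Blocks (DSB) lie on the same strand in both genomes,
Inverse Synteny Blocks (ISB) on opposite strands. With L_DSB and L_ISB the
total covered lengths of each class, and L1, L2 the chromosome lengths,

    P_DSYN = L_DSB / min(L1, L2)
    P_SYN  = (L_DSB + L_ISB) / min(L1, L2)

are the direct and overall synteny proximities. These are meaningful only
for close relatives (where >90%-identity blocks exist at all) and are
compared against k-mer distances, with which they correlate negatively.

Coordinates are 1-based inclusive throughout (the alignment tabular
convention); the covered length of [a, b] is b - a + 1. Block intervals
live on the *query* genome, which callers should take as the shorter
genome so that coverage and the proximity denominator refer to the same
sequence.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class AlignerNotFoundError(RuntimeError):
    """External alignment tool is not available on PATH."""


class AlignmentParseError(ValueError):
    """Malformed 12-column alignment table."""


@dataclass
class AlignmentHit:
    """One row of 12-column tabular alignment output (outfmt-6 dialect).

    The query interval always satisfies q_start <= q_end; a subject
    interval with s_start > s_end signals reverse orientation.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    @property
    def orientation(self) -> str:
        return "inverse" if self.s_start > self.s_end else "direct"


@dataclass
class SyntenyBlock:
    """High-identity aligned segment, on query coordinates (1-based inclusive)."""

    start: int
    end: int
    identity_pct: float
    orientation: str  # "direct" | "inverse"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProximityResult:
    id_1: str
    id_2: str
    l_dsb: int
    l_isb: int
    min_length: int
    p_dsyn: float
    p_syn: float


def parse_alignment_table(path: PathLike) -> List[AlignmentHit]:
    """Parse standard 12-column tab-separated alignment output.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Coordinate conventions are preserved as
    read. Empty files (and comment lines starting with '#') yield an
    empty list.
    """
    hits: List[AlignmentHit] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 12:
                raise AlignmentParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"found {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity_pct=float(fields[2]),
                    align_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise AlignmentParseError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            hits.append(hit)
    return hits


def extract_blocks(
    hits: List[AlignmentHit],
    identity_threshold: float = 90.0,
    min_block_length: int = 0,
) -> List[SyntenyBlock]:
    """Filter hits into synteny blocks.

    Keeps hits with identity strictly above ``identity_threshold``
    ("higher than 90%"; the default threshold is arbitrary but guarantees
    high similarity) and alignment length >= ``min_block_length``.
    Orientation comes from the subject coordinate order; the block interval
    is the query interval.
    """
    if not 0.0 <= identity_threshold <= 100.0:
        raise ValueError("identity_threshold must be in [0, 100]")
    if min_block_length < 0:
        raise ValueError("min_block_length must be >= 0")
    blocks = []
    for hit in hits:
        if hit.identity_pct > identity_threshold and hit.align_length >= min_block_length:
            lo, hi = min(hit.q_start, hit.q_end), max(hit.q_start, hit.q_end)
            blocks.append(
                SyntenyBlock(
                    start=lo,
                    end=hi,
                    identity_pct=hit.identity_pct,
                    orientation=hit.orientation,
                )
            )
    return blocks


def filter_blocks(
    blocks: List[SyntenyBlock],
    identity_threshold: float = 90.0,
    min_block_length: int = 0,
) -> List[SyntenyBlock]:
    """Apply the strict identity threshold / length filter to existing blocks.

    Same filtering rule as :func:`extract_blocks`, for blocks that did not
    come from an alignment table (e.g. simulator ground truth).
    """
    return [
        b
        for b in blocks
        if b.identity_pct > identity_threshold and b.length >= min_block_length
    ]


def _covered_length(intervals: List[Tuple[int, int]], merge: bool) -> int:
    """Total covered length of 1-based inclusive intervals.

    With ``merge`` the union length is returned (overlapping repeated hits
    counted once); otherwise the raw sum of lengths.
    """
    if not intervals:
        return 0
    if not merge:
        return sum(b - a + 1 for a, b in intervals)
    total = 0
    cur_a, cur_b = None, None
    for a, b in sorted(intervals):
        if cur_a is None:
            cur_a, cur_b = a, b
        elif a <= cur_b + 1:
            cur_b = max(cur_b, b)
        else:
            total += cur_b - cur_a + 1
            cur_a, cur_b = a, b
    total += cur_b - cur_a + 1
    return total


def proximities(
    blocks: List[SyntenyBlock],
    length_1: int,
    length_2: int,
    merge_overlaps: bool = True,
    id_1: str = "",
    id_2: str = "",
) -> ProximityResult:
    """Direct and overall synteny proximity from classified blocks.

    L_DSB and L_ISB are the covered lengths of the direct and inverse
    classes; by default overlapping intervals are merged *within* each
    class (repeated HSPs counted once — the direct and inverse unions may
    still overlap each other), and both proximities use min(L1, L2) as
    denominator.
    """
    if length_1 < 1 or length_2 < 1:
        raise ValueError("chromosome lengths must be >= 1")
    direct = [(b.start, b.end) for b in blocks if b.orientation == "direct"]
    inverse = [(b.start, b.end) for b in blocks if b.orientation == "inverse"]
    l_dsb = _covered_length(direct, merge_overlaps)
    l_isb = _covered_length(inverse, merge_overlaps)
    min_length = min(length_1, length_2)
    return ProximityResult(
        id_1=id_1,
        id_2=id_2,
        l_dsb=l_dsb,
        l_isb=l_isb,
        min_length=min_length,
        p_dsyn=l_dsb / min_length,
        p_syn=(l_dsb + l_isb) / min_length,
    )


def run_aligner(fasta_1: PathLike, fasta_2: PathLike, work_dir: PathLike) -> Path:
    """Run the external local aligner (blastn) between two full genomes.

    Convenience hook: the shorter genome becomes the query so block
    coordinates live on the sequence that also supplies the proximity
    denominator. Plain (uncompressed) FASTA inputs only. Returns the path
    to the 12-column tabular output; every downstream stage equally accepts
    a pre-computed table via :func:`parse_alignment_table`.
    """
    exe = shutil.which("blastn")
    if exe is None:
        raise AlignerNotFoundError(
            "external tool missing: 'blastn' not found on PATH; run the "
            "alignment yourself with tabular output (outfmt 6) and load it "
            "with parse_alignment_table()"
        )
    from .sequence_io import read_fasta

    len_1 = sum(r.length for r in read_fasta(fasta_1, masking_mode="raw"))
    len_2 = sum(r.length for r in read_fasta(fasta_2, masking_mode="raw"))
    query, subject = (fasta_1, fasta_2) if len_1 <= len_2 else (fasta_2, fasta_1)

    out = Path(work_dir) / "alignment.tsv"
    try:
        subprocess.run(
            [exe, "-query", str(query), "-subject", str(subject),
             "-outfmt", "6", "-out", str(out)],
            check=True,
            capture_output=True,
            text=True,
        )
    except subprocess.CalledProcessError as exc:
        out.unlink(missing_ok=True)
        raise RuntimeError(f"aligner failed: {exc.stderr.strip()}") from exc
    return out


def write_blocks_tsv(blocks: List[SyntenyBlock], chrom: str, path: PathLike) -> None:
    """BED-like TSV: chrom, start (0-based), end (half-open), orientation, identity.

    Internal 1-based inclusive [a, b] is written as BED-style 0-based
    half-open [a-1, b).
    """
    with open(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\torientation\tidentity_pct\n")
        for b in blocks:
            fh.write(f"{chrom}\t{b.start - 1}\t{b.end}\t{b.orientation}\t{b.identity_pct:.4g}\n")


def read_blocks_tsv(path: PathLike) -> List[SyntenyBlock]:
    """Inverse of :func:`write_blocks_tsv` (coordinates restored to 1-based inclusive)."""
    blocks = []
    with open(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            _, start, end, orientation, identity = line.rstrip("\n").split("\t")
            blocks.append(
                SyntenyBlock(
                    start=int(start) + 1,
                    end=int(end),
                    identity_pct=float(identity),
                    orientation=orientation,
                )
            )
    return blocks


def write_proximity_tsv(results: List[ProximityResult], path: PathLike) -> None:
    with open(path, "wt") as fh:
        fh.write("id_1\tid_2\tL_DSB\tL_ISB\tmin_length\tP_DSYN\tP_SYN\n")
        for r in results:
            fh.write(
                f"{r.id_1}\t{r.id_2}\t{r.l_dsb}\t{r.l_isb}\t{r.min_length}"
                f"\t{r.p_dsyn:.8g}\t{r.p_syn:.8g}\n"
            )
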